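"""Mutational-effect maps and sequence-family clustering.

After mutagenic amplification of a parent sensor and re-assay, every
observed core within a small edit distance of the parent is decomposed into
its edit script (substitutions, insertions, deletions) and annotated with
the change in cleavage fraction and the variant's fold change. Positions are
1-based on the core; insertions are indexed by the gap after position p
(p = 0..L). Where several equal-cost alignments exist (e.g. a deletion in a
homopolymer run) the leftmost script is reported and flagged ambiguous.

Hit sequences are grouped into families by average-linkage agglomerative
clustering on pairwise Levenshtein distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

BASES = "ACGT"


@dataclass(frozen=True)
class Edit:
    """One edit: kind in {substitution, insertion, deletion}.

    ``position`` is 1-based on the parent for substitutions/deletions; for
    insertions it is the gap index (0 = before the first base).
    """

    kind: str
    position: int
    base: str = ""  # inserted or substituted-in base; "" for deletions


@dataclass(frozen=True)
class MutationEffect:
    parent: str
    edits: tuple[Edit, ...]
    variant: str
    delta_c_minus: float
    fold_change: float
    reads: int
    ambiguous: bool = False


def apply_script(parent: str, edits: Sequence[Edit]) -> str:
    """Apply an edit script (in left-to-right order) to the parent."""
    s = list(parent)
    # apply right-to-left so earlier parent positions stay valid; this also
    # keeps multiple insertions at one gap in their scripted order
    for e in reversed(edits):
        if e.kind == "substitution":
            s[e.position - 1] = e.base
        elif e.kind == "deletion":
            del s[e.position - 1]
        elif e.kind == "insertion":
            s.insert(e.position, e.base)
        else:
            raise ValueError(f"unknown edit kind {e.kind!r}")
    return "".join(s)


def edit_script(
    parent: str, variant: str, max_distance: int = 2
) -> tuple[tuple[Edit, ...], bool] | None:
    """Minimal edit script parent -> variant, leftmost convention.

    Returns (edits, ambiguous) or None when the Levenshtein distance exceeds
    ``max_distance``. ``ambiguous`` is True when another equal-cost script
    exists; the reported one places edits as far left as possible.
    """
    n, m = len(parent), len(variant)
    if abs(n - m) > max_distance:
        return None
    # full DP; cores are short so the quadratic table is cheap
    D = np.zeros((n + 1, m + 1), dtype=np.int32)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    pv = np.frombuffer(parent.encode(), dtype=np.uint8)
    vv = np.frombuffer(variant.encode(), dtype=np.uint8)
    offsets = np.arange(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        sub = D[i - 1, :-1] + (pv[i - 1] != vv)
        D[i, 1:] = np.minimum(sub, D[i - 1, 1:] + 1)
        # insertion recurrence row[j] = min(row[j], row[j-1] + 1), resolved
        # in one pass via a prefix minimum of row[j] - j
        row = D[i]
        D[i] = np.minimum.accumulate(row - offsets) + offsets
    if D[n, m] > max_distance:
        return None

    # backward traceback preferring matches so edits collect leftmost;
    # among edit moves prefer deletion, then insertion, then substitution
    edits: list[Edit] = []
    ambiguous = False
    i, j = n, m
    while i > 0 or j > 0:
        moves = []
        if i > 0 and j > 0 and pv[i - 1] == vv[j - 1] and D[i, j] == D[i - 1, j - 1]:
            moves.append("match")
        if i > 0 and D[i, j] == D[i - 1, j] + 1:
            moves.append("del")
        if j > 0 and D[i, j] == D[i, j - 1] + 1:
            moves.append("ins")
        if (
            i > 0
            and j > 0
            and pv[i - 1] != vv[j - 1]
            and D[i, j] == D[i - 1, j - 1] + 1
        ):
            moves.append("sub")
        if len(moves) > 1 and not (moves[0] == "match" and D[i, j] == 0):
            ambiguous = True
        move = moves[0]
        if move == "match":
            i, j = i - 1, j - 1
        elif move == "del":
            edits.append(Edit("deletion", i))
            i -= 1
        elif move == "ins":
            edits.append(Edit("insertion", i, variant[j - 1]))
            j -= 1
        else:
            edits.append(Edit("substitution", i, variant[j - 1]))
            i, j = i - 1, j - 1
    edits.reverse()
    return tuple(edits), ambiguous


def assign_variants(
    parent: str,
    parent_c_minus: float,
    parent_fold: float,
    observed: Mapping[str, tuple[float, float, int]],
    max_distance: int = 2,
) -> list[MutationEffect]:
    """Decompose observed cores near the parent into mutation effects.

    ``observed`` maps core sequence to (c_minus, fold_change, reads). Cores
    beyond ``max_distance`` edits are skipped. Effects are deltas against
    the parent's own measurements.
    """
    if not parent:
        raise ValueError("parent sequence is empty")
    effects = []
    for core, (c_minus, fold, reads) in sorted(observed.items()):
        script = edit_script(parent, core, max_distance)
        if script is None:
            continue
        edits, ambiguous = script
        effects.append(
            MutationEffect(
                parent=parent,
                edits=edits,
                variant=core,
                delta_c_minus=c_minus - parent_c_minus,
                fold_change=fold,
                reads=reads,
                ambiguous=ambiguous,
            )
        )
    return effects


def effect_matrix(
    effects: Sequence[MutationEffect],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Position x mutation matrices of delta cleavage and fold change.

    Only single-edit effects populate cells. Rows are a MultiIndex of
    (kind, position): L substitution/deletion positions plus L+1 insertion
    gaps; columns are the four bases plus a deletion column. Duplicate cells
    aggregate by read-weighted mean. Missing cells are NaN.
    """
    if not effects:
        raise ValueError("no effects given")
    parents = {e.parent for e in effects}
    if len(parents) > 1:
        raise ValueError("effects must share one parent")
    parent = parents.pop()
    L = len(parent)
    rows = [("substitution", p) for p in range(1, L + 1)]
    rows += [("insertion", p) for p in range(0, L + 1)]
    index = pd.MultiIndex.from_tuples(rows, names=["kind", "position"])
    cols = list(BASES) + ["del"]
    delta = pd.DataFrame(np.nan, index=index, columns=cols)
    fold = pd.DataFrame(np.nan, index=index, columns=cols)
    weights = pd.DataFrame(0.0, index=index, columns=cols)
    contributions = pd.DataFrame(0, index=index, columns=cols)

    for e in effects:
        if len(e.edits) != 1:
            continue
        ed = e.edits[0]
        if ed.kind == "substitution":
            key, col = ("substitution", ed.position), ed.base
        elif ed.kind == "deletion":
            key, col = ("substitution", ed.position), "del"
        else:
            key, col = ("insertion", ed.position), ed.base
        w_old = weights.loc[key, col]
        w_new = w_old + e.reads
        if w_old == 0:
            delta.loc[key, col] = e.delta_c_minus
            fold.loc[key, col] = e.fold_change
        else:  # conflicting duplicates: read-weighted mean
            delta.loc[key, col] = (
                delta.loc[key, col] * w_old + e.delta_c_minus * e.reads
            ) / w_new
            fold.loc[key, col] = (
                fold.loc[key, col] * w_old + e.fold_change * e.reads
            ) / w_new
        weights.loc[key, col] = w_new
        contributions.loc[key, col] += 1
    n_dup = int((contributions.to_numpy() > 1).sum())
    delta.attrs["duplicate_cells"] = fold.attrs["duplicate_cells"] = n_dup
    return delta, fold


def top_improvements(
    effects: Sequence[MutationEffect], n: int = 10
) -> pd.DataFrame:
    """Single-edit variants ranked by fold-change improvement."""
    singles = [e for e in effects if len(e.edits) == 1]
    rows = [
        {
            "position": e.edits[0].position,
            "kind": e.edits[0].kind,
            "base": e.edits[0].base,
            "delta_c_minus": e.delta_c_minus,
            "fold_change": e.fold_change,
            "reads": e.reads,
        }
        for e in singles
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["fold_change", "position"], ascending=[False, True]
    ).head(n).reset_index(drop=True)


@dataclass(frozen=True)
class SensorFamily:
    members: tuple[str, ...]  # accessions, sorted
    medoid: str  # sequence minimizing summed distance to the family
    max_distance: int


def cluster_families(
    sequences: Mapping[str, str],
    threshold: float | None = None,
    method: str = "average",
) -> list[SensorFamily]:
    """Group hit sequences into families by sequence similarity.

    ``sequences`` maps accession to core sequence. Agglomerative clustering
    on pairwise Levenshtein distance, cut at ``threshold`` (default 25% of
    the median core length). Input order never matters: accessions are
    sorted before distances are computed and ties resolve by accession
    order.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    accs = sorted(sequences)
    seqs = [sequences[a] for a in accs]
    if threshold is None:
        threshold = 0.25 * float(np.median([len(s) for s in seqs]))
    if len(accs) == 1:
        return [SensorFamily((accs[0],), seqs[0], 0)]
    dm = np.zeros((len(accs), len(accs)))
    for i, j in itertools.combinations(range(len(accs)), 2):
        d = edlib.align(seqs[i], seqs[j])["editDistance"]
        dm[i, j] = dm[j, i] = d
    Z = linkage(squareform(dm, checks=False), method=method)
    labels = fcluster(Z, t=threshold, criterion="distance")
    families = []
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        sub = dm[np.ix_(idx, idx)]
        medoid = seqs[idx[int(np.argmin(sub.sum(axis=1)))]]
        families.append(
            SensorFamily(
                tuple(accs[i] for i in idx),
                medoid,
                int(sub.max()),
            )
        )
    families.sort(key=lambda f: f.members)
    return families
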