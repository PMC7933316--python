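"""Read merging, demultiplexing and tabulation of cleavage-assay amplicons.

The assay encodes whether each transcribed RNA molecule self-cleaved in the
5' prefix of the sequenced amplicon: cleaved molecules receive a regenerated
prefix (e.g. ``Z``) while uncleaved molecules keep the original one (``W``).
Amplicons carry per-condition barcodes on both ends, an A-rich spacer suffix
(``X``), and a set of spike-in reference sequences at known concentration
that anchor read counts to absolute concentrations.

This module turns raw paired reads into a :class:`SequenceTable` of read
counts keyed by (core sequence, prefix, condition, replicate), the input to
:mod:`cleavedrive.cleaveseq`.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import edlib
import pandas as pd
import yaml

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class MalformedReadError(ValueError):
    """Raised for empty reads or quality strings of the wrong length."""


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read: sequences plus per-base Phred qualities."""

    id: str
    fwd: str
    fwd_qual: Sequence[int]
    rev: str
    rev_qual: Sequence[int]

    def __post_init__(self) -> None:
        for seq, qual, name in (
            (self.fwd, self.fwd_qual, "fwd"),
            (self.rev, self.rev_qual, "rev"),
        ):
            if len(seq) < 1:
                raise MalformedReadError(f"{name} read of {self.id!r} is empty")
            if len(qual) != len(seq):
                raise MalformedReadError(
                    f"{name} quality length {len(qual)} != sequence length "
                    f"{len(seq)} for {self.id!r}"
                )
            if not set(seq) <= VALID_BASES:
                raise MalformedReadError(
                    f"{name} read of {self.id!r} has bases outside ACGTN"
                )


@dataclass(frozen=True)
class Reference:
    """Spike-in sequence of known concentration (pM) and fixed prefix."""

    sequence: str
    prefix: str
    concentration_pM: float

    def __post_init__(self) -> None:
        if self.concentration_pM <= 0:
            raise ValueError("reference concentration must be > 0")


@dataclass(frozen=True)
class AmpliconScheme:
    """Layout of the sequenced amplicon.

    Parameters
    ----------
    prefixes
        Map of prefix label (``W``/``Z``/``A``) to its nucleotide string.
        ``W`` marks uncleaved molecules, ``Z`` regenerated (cleaved) ones and
        ``A`` a second regeneration prefix used between selection arms.
    suffix
        3' spacer ending every amplicon body.
    barcodes
        Map of condition id to (5' barcode, 3' barcode). Per side, barcodes
        must be prefix-free so a greedy match is unambiguous.
    references
        Spike-ins of known concentration used for absolute calibration.
    """

    prefixes: Mapping[str, str]
    suffix: str
    barcodes: Mapping[str, tuple[str, str]]
    references: tuple[Reference, ...] = ()

    def __post_init__(self) -> None:
        seqs = list(self.prefixes.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("prefix strings must be pairwise distinct")
        for side in (0, 1):
            codes = [bc[side] for bc in self.barcodes.values()]
            for i, a in enumerate(codes):
                for j, b in enumerate(codes):
                    if i != j and a.startswith(b):
                        raise ValueError(
                            f"barcodes are not prefix-free on side {side}: "
                            f"{b!r} is a prefix of {a!r}"
                        )

    @property
    def reference_sequences(self) -> frozenset[str]:
        return frozenset(r.sequence for r in self.references)

    def reference_prefix(self, sequence: str) -> str | None:
        for ref in self.references:
            if ref.sequence == sequence:
                return ref.prefix
        return None

    @classmethod
    def from_dict(cls, d: Mapping) -> "AmpliconScheme":
        refs = tuple(
            Reference(r["sequence"], r["prefix"], float(r["concentration_pM"]))
            for r in d.get("references", ())
        )
        barcodes = {
            str(k): (v[0], v[1]) for k, v in d.get("barcodes", {}).items()
        }
        return cls(
            prefixes=dict(d["prefixes"]),
            suffix=d["suffix"],
            barcodes=barcodes,
            references=refs,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AmpliconScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "prefixes": dict(self.prefixes),
            "suffix": self.suffix,
            "barcodes": {k: list(v) for k, v in self.barcodes.items()},
            "references": [
                {
                    "sequence": r.sequence,
                    "prefix": r.prefix,
                    "concentration_pM": r.concentration_pM,
                }
                for r in self.references
            ],
        }


def default_scheme(
    conditions: Sequence[str] = ("minus", "plus"),
    reference_concentration_pM: float = 18.0,
    seed: int = 20210304,
) -> AmpliconScheme:
    """A synthetic fixture scheme with the assay's structural properties.

    The real prefix/barcode/reference oligos are instrument-run specific; this
    fixture reproduces their structure: three distinguishable A-rich prefixes
    (W/Z/A), an A-rich spacer suffix, variable-length prefix-free barcodes per
    condition, and 15 spike-in references spanning five lengths and the three
    prefixes, each at a fixed 18 pM.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    prefixes = {
        "W": "AAACAAACAAAC",
        "Z": "AAAGAAAGAAAG",
        "A": "AAATAAATAAAT",
    }
    suffix = "AAACAAAGAAAT"
    # Variable-length barcodes, distinct first base per condition keeps them
    # prefix-free on both sides.
    first = "CGTA"
    barcodes: dict[str, tuple[str, str]] = {}
    for i, cond in enumerate(conditions):
        if i >= len(first):
            raise ValueError("fixture scheme supports at most 4 conditions")
        b5 = first[i] + "".join(rng.choice(list("ACGT"), size=i + 2))
        b3 = first[i] + "".join(rng.choice(list("ACGT"), size=i + 3))
        barcodes[cond] = (b5, b3)
    lengths = (40, 45, 50, 55, 60)
    refs = []
    for length in lengths:
        for prefix in ("W", "Z", "A"):
            seq = "".join(rng.choice(list("ACGT"), size=length))
            refs.append(Reference(seq, prefix, reference_concentration_pM))
    return AmpliconScheme(prefixes, suffix, barcodes, tuple(refs))


# ---------------------------------------------------------------------------
# read merging


def merge_pairs(
    pair: ReadPair,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> str | None:
    """Merge a read pair over their best consistent 3' overlap.

    The reverse read is reverse-complemented and slid against the forward
    read; every overlap of at least ``min_overlap`` bases whose mismatch
    fraction is at most ``max_mismatch_frac`` is a candidate. The candidate
    with the lowest mismatch fraction wins; ties resolve toward the maximal
    overlap (periodic amplicons otherwise admit spurious shifted merges).
    At mismatched positions the base with the higher Phred
    quality is kept (forward wins exact quality ties). Returns ``None`` when
    no consistent overlap exists.
    """
    if min_overlap < 5:
        raise ValueError("min_overlap must be >= 5")
    if not (0 <= max_mismatch_frac < 0.5):
        raise ValueError("max_mismatch_frac must be in [0, 0.5)")
    fwd, fq = pair.fwd, list(pair.fwd_qual)
    rev = reverse_complement(pair.rev)
    rq = list(pair.rev_qual)[::-1]

    best: tuple[float, int] | None = None  # (mismatch_frac, -overlap)
    max_l = min(len(fwd), len(rev))
    for L in range(min_overlap, max_l + 1):
        f_tail = fwd[len(fwd) - L:]
        r_head = rev[:L]
        mism = sum(1 for a, b in zip(f_tail, r_head) if a != b)
        frac = mism / L
        if frac > max_mismatch_frac:
            continue
        key = (frac, -L)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    L = -best[1]
    off = len(fwd) - L
    overlap = [
        fwd[off + i]
        if fwd[off + i] == rev[i] or fq[off + i] >= rq[i]
        else rev[i]
        for i in range(L)
    ]
    return fwd[:off] + "".join(overlap) + rev[L:]


# ---------------------------------------------------------------------------
# demultiplexing and prefix classification


def _hamming_leq(a: str, b: str, k: int) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mism += 1
            if mism > k:
                return False
    return mism <= k


def demultiplex(
    merged: str,
    scheme: AmpliconScheme,
    max_mismatch: int = 0,
    qc: Counter | None = None,
) -> tuple[str, str] | None:
    """Assign a merged read to a condition by its 5' and 3' barcodes.

    Returns ``(condition_id, barcode-stripped body)`` or ``None`` when no
    barcode pair matches. A read matching two conditions (possible only with
    ``max_mismatch`` > 0) is unassigned and tallied under ``"ambiguous"`` in
    ``qc``.
    """
    if not scheme.barcodes:
        raise ValueError("scheme has no barcodes")
    hits = []
    for cond, (b5, b3) in scheme.barcodes.items():
        if len(merged) < len(b5) + len(b3):
            continue
        if _hamming_leq(merged[: len(b5)], b5, max_mismatch) and _hamming_leq(
            merged[len(merged) - len(b3):], b3, max_mismatch
        ):
            hits.append((cond, merged[len(b5): len(merged) - len(b3)]))
    if len(hits) == 1:
        return hits[0]
    if len(hits) > 1 and qc is not None:
        qc["ambiguous"] += 1
    return None


def classify_prefix(
    body: str,
    scheme: AmpliconScheme,
    max_mismatch: int = 0,
) -> tuple[str | None, str]:
    """Identify the cleavage-state prefix and strip prefix + suffix.

    Returns ``(prefix label, core sequence)``; ``(None, "")`` when no prefix
    begins the body or the suffix does not end it (each within
    ``max_mismatch`` substitutions).
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    sfx = scheme.suffix
    for label, prefix in scheme.prefixes.items():
        if len(body) < len(prefix) + len(sfx):
            continue
        if _hamming_leq(body[: len(prefix)], prefix, max_mismatch) and _hamming_leq(
            body[len(body) - len(sfx):], sfx, max_mismatch
        ):
            return label, body[len(prefix): len(body) - len(sfx)]
    return None, ""


# ---------------------------------------------------------------------------
# tabulation

TABLE_COLUMNS = [
    "accession",
    "core_seq",
    "prefix",
    "condition",
    "replicate",
    "count",
    "is_reference",
    "flagged",
]


@dataclass
class SequenceTable:
    """Read counts per (core sequence, prefix, condition, replicate).

    Spike-in references are routed to ``is_reference`` rows by exact sequence
    match; distinct sample cores receive stable integer accessions assigned
    in lexicographic core order (so the numbering is independent of read
    order).
    """

    data: pd.DataFrame
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(TABLE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing SequenceTable columns: {sorted(missing)}")
        if (self.data["count"] < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> pd.DataFrame:
        return self.data[~self.data["is_reference"]]

    @property
    def references(self) -> pd.DataFrame:
        return self.data[self.data["is_reference"]]

    def counts(
        self,
        core: str,
        prefix: str,
        condition: str,
        replicate: str | int = "1",
    ) -> int:
        d = self.data
        m = (
            (d["core_seq"] == core)
            & (d["prefix"] == prefix)
            & (d["condition"] == condition)
            & (d["replicate"].astype(str) == str(replicate))
        )
        return int(d.loc[m, "count"].sum())

    def reference_reads(
        self, prefix: str, condition: str, replicate: str | int = "1"
    ) -> int:
        d = self.references
        m = (
            (d["prefix"] == prefix)
            & (d["condition"] == condition)
            & (d["replicate"].astype(str) == str(replicate))
        )
        return int(d.loc[m, "count"].sum())

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SequenceTable":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"condition": str, "replicate": str, "core_seq": str},
        )
        df["is_reference"] = df["is_reference"].astype(bool)
        df["flagged"] = df["flagged"].astype(bool)
        return cls(df)


def tabulate(
    classified: Iterable[tuple[str, str, str, str]],
    scheme: AmpliconScheme,
) -> SequenceTable:
    """Count classified reads into a :class:`SequenceTable`.

    ``classified`` yields ``(core, prefix_label, condition, replicate)``
    tuples. Reads whose core equals a scheme reference are counted as
    reference rows.
    """
    ref_seqs = scheme.reference_sequences
    counts: Counter = Counter()
    for core, prefix, condition, replicate in classified:
        counts[(core, prefix, str(condition), str(replicate))] += 1
    rows = []
    sample_cores = sorted(
        {key[0] for key in counts if key[0] not in ref_seqs}
    )
    accessions = {core: i + 1 for i, core in enumerate(sample_cores)}
    for (core, prefix, condition, replicate), n in sorted(counts.items()):
        is_ref = core in ref_seqs
        rows.append(
            {
                "accession": 0 if is_ref else accessions[core],
                "core_seq": core,
                "prefix": prefix,
                "condition": condition,
                "replicate": replicate,
                "count": n,
                "is_reference": is_ref,
                "flagged": False,
            }
        )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return SequenceTable(df)


def misassignment_filter(
    table: SequenceTable,
    max_distance: int = 1,
    abundance_ratio: float = 100.0,
) -> set[str]:
    """Flag likely PCR/sequencing misassignment artifacts.

    A core is flagged when its total read count is at most
    ``1/abundance_ratio`` of another core's total within Levenshtein distance
    ``max_distance``. Such low-count near-neighbors of very abundant
    sequences typically arise from amplification mutations that assign reads
    to the wrong sequence. Flagged cores stay in the table (``flagged``
    column set) but are excluded from hit calling.
    """
    samples = table.samples
    if samples.empty:
        raise ValueError("table has no sample rows")
    totals = samples.groupby("core_seq")["count"].sum()
    cores = list(totals.index)
    flagged: set[str] = set()
    for core in cores:
        for other in cores:
            if other == core:
                continue
            if totals[other] < abundance_ratio * totals[core]:
                continue
            d = edlib.align(core, other, k=max_distance)["editDistance"]
            if d != -1 and d <= max_distance:
                flagged.add(core)
                break
    mask = table.data["core_seq"].isin(flagged) & ~table.data["is_reference"]
    table.data.loc[mask, "flagged"] = True
    return flagged


# ---------------------------------------------------------------------------
# FASTQ plumbing


def _open_maybe_gz(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(r1: str | Path, r2: str | Path) -> Iterator[ReadPair]:
    """Stream read pairs from two (optionally gzipped) FASTQ files."""
    from Bio import SeqIO

    with _open_maybe_gz(r1) as fh1, _open_maybe_gz(r2) as fh2:
        for rec1, rec2 in zip(
            SeqIO.parse(fh1, "fastq"), SeqIO.parse(fh2, "fastq"), strict=True
        ):
            yield ReadPair(
                id=rec1.id,
                fwd=str(rec1.seq),
                fwd_qual=rec1.letter_annotations["phred_quality"],
                rev=str(rec2.seq),
                rev_qual=rec2.letter_annotations["phred_quality"],
            )


def process_run(
    pairs: Iterable[ReadPair],
    scheme: AmpliconScheme,
    replicate: str = "1",
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
    barcode_mismatch: int = 0,
    prefix_mismatch: int = 0,
) -> SequenceTable:
    """Full read-to-table pipeline: merge, demultiplex, classify, tabulate.

    QC tallies (reads in, merged, demultiplexed, classified, ambiguous) are
    stored on the returned table's ``qc`` attribute.
    """
    qc: Counter = Counter()
    classified = []
    for pair in pairs:
        qc["reads_in"] += 1
        merged = merge_pairs(pair, min_overlap, max_mismatch_frac)
        if merged is None:
            continue
        qc["merged"] += 1
        hit = demultiplex(merged, scheme, barcode_mismatch, qc)
        if hit is None:
            continue
        qc["demultiplexed"] += 1
        condition, body = hit
        label, core = classify_prefix(body, scheme, prefix_mismatch)
        if label is None:
            continue
        qc["classified"] += 1
        classified.append((core, label, condition, replicate))
    table = tabulate(classified, scheme)
    table.qc = dict(qc)
    return table


def write_qc(table: SequenceTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(table.qc, fh, indent=2, sort_keys=True)
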