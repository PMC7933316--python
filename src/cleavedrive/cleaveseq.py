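"""Cleavage fractions, fold changes, confidence intervals and hit calls.

The central quantity is the cleavage fraction of a sequence *s*,

    c_s = (r_Z,s / r_Z,ref) / (r_W,s / r_W,ref + r_Z,s / r_Z,ref)

where ``r_P,s`` counts reads of *s* carrying prefix ``P`` (``Z`` marks
cleaved, ``W`` uncleaved molecules) and ``r_P,ref`` counts spike-in
reference reads with that prefix. Referencing each prefix's count to its own
spike-in pool cancels the differing amplification efficiencies of the two
PCR arms.

Ligand response is reported as the fold change of the uncleaved fraction,

    f_s = k * (1 - c_s,+ligand) / (1 - c_s,-ligand)

with k chosen so that the median fold change across all sequences in the run
is 1.0 (only a small minority of library members respond to any ligand, so
the run median is a null anchor). Uncertainty comes from multinomial
bootstrap resampling of the observed read counts; hits are sequences with
f_s > 2 that are significant at a Bonferroni-corrected level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PrefixCounts:
    """Observed reads of one sequence and the references, one condition."""

    r_z: int
    r_w: int
    r_z_ref: int
    r_w_ref: int

    def __post_init__(self) -> None:
        if min(self.r_z, self.r_w, self.r_z_ref, self.r_w_ref) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.r_z + self.r_w


@dataclass(frozen=True)
class CleavageMeasurement:
    accession: int
    condition: str
    c: float
    ci_lo: float
    ci_hi: float
    reads_cleaved: int
    reads_uncleaved: int


@dataclass(frozen=True)
class SwitchResult:
    accession: int
    f: float
    ci_lo: float
    ci_hi: float
    p_value: float
    is_hit: bool = False


@dataclass(frozen=True)
class RunNormalization:
    k: float
    n_sequences_used: int
    min_reads: int


def reference_scale(
    reference_reads: int,
    n_references: int,
    concentration_pM: float = 18.0,
) -> float:
    """Concentration per read (pM/read) from spike-in reference counts.

    Each of ``n_references`` spike-ins enters at ``concentration_pM``; their
    pooled reads calibrate the run, so a sequence's concentration estimate is
    its read count times the returned scale.
    """
    if reference_reads <= 0:
        raise ValueError(
            "no reference reads for this prefix/condition; run unusable"
        )
    if n_references < 1 or concentration_pM <= 0:
        raise ValueError("need >= 1 reference at positive concentration")
    return concentration_pM * n_references / reference_reads


def reference_scale_from_table(
    table, prefix: str, condition: str, replicate: str | int = "1"
) -> float:
    """Concentration per read for one prefix/condition of a SequenceTable.

    Uses the scheme-independent convention that every spike-in entered at
    the same concentration; the per-species concentration is read from the
    table's reference rows being counted (callers with mixed-concentration
    schemes should use :func:`reference_scale` directly).
    """
    refs = table.references
    sub = refs[
        (refs["prefix"] == prefix)
        & (refs["condition"] == condition)
        & (refs["replicate"].astype(str) == str(replicate))
    ]
    n_species = sub["core_seq"].nunique()
    reads = int(sub["count"].sum())
    return reference_scale(reads, max(n_species, 1))


def cleavage_fraction(
    r_z_s: float, r_z_ref: float, r_w_s: float, r_w_ref: float
) -> float:
    """Reference-normalized cleavage fraction; NaN when both counts are 0."""
    if r_z_ref <= 0 or r_w_ref <= 0:
        raise ValueError("reference counts must be positive")
    if r_z_s < 0 or r_w_s < 0:
        raise ValueError("sample counts must be non-negative")
    z = r_z_s / r_z_ref
    w = r_w_s / r_w_ref
    if z + w == 0:
        return math.nan
    return z / (w + z)


def _median(values: np.ndarray) -> float:
    # even-N convention: mean of the two central order statistics
    return float(np.median(values))


def fold_change_table(
    c_minus: Mapping[int, float],
    c_plus: Mapping[int, float],
    reads_minus: Mapping[int, int] | None = None,
    reads_plus: Mapping[int, int] | None = None,
    min_reads: int = 30,
) -> tuple[RunNormalization, dict[int, float]]:
    """Normalized fold changes f_s for every sequence measured in a run.

    Sequences with at least ``min_reads`` reads in both conditions and a
    defined ratio (c_minus < 1) set the normalization k = 1/median(rho) where
    rho_s = (1 - c_plus)/(1 - c_minus); every sequence then gets
    f_s = k * rho_s. Sequences with c_minus = 1 get NaN.
    """
    shared = sorted(set(c_minus) & set(c_plus))
    rho: dict[int, float] = {}
    qualifying = []
    for acc in shared:
        cm, cp = c_minus[acc], c_plus[acc]
        if math.isnan(cm) or math.isnan(cp):
            continue
        if cm >= 1.0:
            rho[acc] = math.nan
            continue
        rho[acc] = (1.0 - cp) / (1.0 - cm)
        enough = True
        if reads_minus is not None and reads_minus.get(acc, 0) < min_reads:
            enough = False
        if reads_plus is not None and reads_plus.get(acc, 0) < min_reads:
            enough = False
        if enough:
            qualifying.append(acc)
    if not qualifying:
        raise ValueError("no qualifying sequences to set the normalization")
    k = 1.0 / _median(np.array([rho[a] for a in qualifying]))
    f = {acc: k * r for acc, r in rho.items()}
    return RunNormalization(k, len(qualifying), min_reads), f


def bootstrap_ci(
    counts: PrefixCounts,
    B: int = 1000,
    seed: int | None = None,
    counts_plus: PrefixCounts | None = None,
    k: float = 1.0,
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> dict[str, tuple[float, float]]:
    """Bootstrap percentile intervals for c_s (and f_s when two conditions).

    Each bootstrap replicate redraws the sequence's (cleaved, uncleaved)
    reads and the reference (Z, W) reads from multinomials with the observed
    proportions and observed totals, then recomputes the estimate. Returns
    the requested percentiles (default 5th/95th, a 90% interval) keyed
    ``"c"``, and additionally ``"c_plus"`` and ``"f"`` when ``counts_plus``
    is given.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)

    def resample(c: PrefixCounts) -> np.ndarray:
        if c.total < 1:
            raise ValueError("zero total reads")
        zs = rng.binomial(c.total, c.r_z / c.total, size=B)
        ref_total = c.r_z_ref + c.r_w_ref
        if ref_total <= 0 or min(c.r_z_ref, c.r_w_ref) <= 0:
            raise ValueError("reference counts must be positive")
        zr = rng.binomial(ref_total, c.r_z_ref / ref_total, size=B)
        zr = np.clip(zr, 1, ref_total - 1)  # keep both references non-empty
        wr = ref_total - zr
        z = zs / zr
        w = (c.total - zs) / wr
        with np.errstate(invalid="ignore"):
            return np.where(z + w > 0, z / (z + w), np.nan)

    out: dict[str, tuple[float, float]] = {}
    c_hat = resample(counts)
    lo, hi = np.nanpercentile(c_hat, percentiles)
    out["c"] = (float(lo), float(hi))
    if counts_plus is not None:
        cp_hat = resample(counts_plus)
        lo, hi = np.nanpercentile(cp_hat, percentiles)
        out["c_plus"] = (float(lo), float(hi))
        with np.errstate(divide="ignore", invalid="ignore"):
            f_hat = k * (1.0 - cp_hat) / (1.0 - c_hat)
        f_hat = f_hat[np.isfinite(f_hat)]
        if f_hat.size:
            lo, hi = np.percentile(f_hat, percentiles)
            out["f"] = (float(lo), float(hi))
        else:
            out["f"] = (math.nan, math.nan)
    return out


def proportion_test(
    cleaved_a: int, uncleaved_a: int, cleaved_b: int, uncleaved_b: int
) -> float:
    """Two-sided test of equal cleavage proportions on a 2x2 count table.

    Fisher's exact (conditional) test by default; chi-squared approximation
    above 1e4 reads in every cell, where it is numerically indistinguishable
    and much faster.
    """
    table = np.array([[cleaved_a, uncleaved_a], [cleaved_b, uncleaved_b]])
    if table.sum() == 0:
        raise ValueError("empty 2x2 table")
    if (table.min() > 10_000):
        return float(
            stats.chi2_contingency(table, correction=False).pvalue
        )
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def bonferroni_threshold(family_alpha: float, N: int) -> float:
    """Per-test alpha controlling the family-wise error over N tests."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0 < family_alpha <= 1):
        raise ValueError("family_alpha must be in (0, 1]")
    return family_alpha / N


def replicate_test(
    counts_rep1: Mapping[int, tuple[int, int]],
    counts_rep2: Mapping[int, tuple[int, int]],
    family_alpha: float = 0.1,
    min_reads: int = 100,
) -> tuple[dict[int, float], set[int]]:
    """Compare two assay replicates sequence by sequence.

    ``counts_repX`` map accession to (cleaved, uncleaved) reads. Sequences
    with at least ``min_reads`` in both replicates are tested two-sided for
    equal cleavage proportions; outliers are those below the Bonferroni
    threshold ``family_alpha / N``.
    """
    shared = [
        acc
        for acc in sorted(set(counts_rep1) & set(counts_rep2))
        if sum(counts_rep1[acc]) >= min_reads
        and sum(counts_rep2[acc]) >= min_reads
    ]
    if not shared:
        raise ValueError("no shared accessions with enough reads")
    pvals = {
        acc: proportion_test(*counts_rep1[acc], *counts_rep2[acc])
        for acc in shared
    }
    thr = bonferroni_threshold(family_alpha, len(shared))
    outliers = {acc for acc, p in pvals.items() if p < thr}
    return pvals, outliers


def switching_test(
    counts_minus: tuple[int, int],
    counts_plus: tuple[int, int],
    min_reads: int = 30,
) -> float | None:
    """P-value of the non-switching null for one sequence.

    ``counts_minus``/``counts_plus`` are (cleaved, uncleaved) reads per
    condition. Returns ``None`` (untested) below ``min_reads`` in either
    condition.
    """
    if sum(counts_minus) < min_reads or sum(counts_plus) < min_reads:
        return None
    return proportion_test(*counts_minus, *counts_plus)


def call_hits(
    results: Mapping[int, SwitchResult],
    N: int | None = None,
    min_fold: float = 2.0,
    flagged: set[int] | frozenset[int] = frozenset(),
) -> dict[int, SwitchResult]:
    """Flag potential sensors: f_s > min_fold and p < 1/N, not misassigned.

    ``N`` defaults to the number of tested sequences in ``results``.
    """
    if N is None:
        N = len(results)
    if N < 1:
        raise ValueError("N must be >= 1")
    thr = bonferroni_threshold(1.0, N)
    out = {}
    for acc, r in results.items():
        is_hit = (
            acc not in flagged
            and not math.isnan(r.f)
            and r.f > min_fold
            and r.p_value < thr
        )
        out[acc] = SwitchResult(acc, r.f, r.ci_lo, r.ci_hi, r.p_value, is_hit)
    return out


# ---------------------------------------------------------------------------
# table-level driver


def quantify_run(
    table,
    condition_minus: str,
    condition_plus: str,
    replicate: str = "1",
    min_reads: int = 30,
    B: int = 1000,
    seed: int | None = None,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """End-to-end quantification of one run from a SequenceTable.

    Computes per-sequence cleavage fractions in both conditions, normalized
    fold changes, bootstrap intervals, switching p-values and hit calls.
    Misassignment-flagged sequences are measured but never called hits.
    """
    samples = table.samples
    refs = {
        cond: {
            p: table.reference_reads(p, cond, replicate) for p in ("Z", "W")
        }
        for cond in (condition_minus, condition_plus)
    }
    for cond, r in refs.items():
        if r["Z"] <= 0 or r["W"] <= 0:
            raise ValueError(f"no Z/W reference reads in condition {cond!r}")

    def per_condition(cond):
        sub = samples[
            (samples["condition"] == cond)
            & (samples["replicate"].astype(str) == str(replicate))
        ]
        piv = (
            sub.pivot_table(
                index="accession",
                columns="prefix",
                values="count",
                aggfunc="sum",
                fill_value=0,
            )
            .reindex(columns=["Z", "W"], fill_value=0)
        )
        return piv

    piv_m = per_condition(condition_minus)
    piv_p = per_condition(condition_plus)
    flagged = set(
        samples.loc[samples["flagged"], "accession"].unique().tolist()
    )
    acc_core = samples.drop_duplicates("accession").set_index("accession")[
        "core_seq"
    ]

    c_m, c_p, reads_m, reads_p = {}, {}, {}, {}
    for acc in sorted(set(piv_m.index) | set(piv_p.index)):
        zm, wm = (
            (int(piv_m.loc[acc, "Z"]), int(piv_m.loc[acc, "W"]))
            if acc in piv_m.index
            else (0, 0)
        )
        zp, wp = (
            (int(piv_p.loc[acc, "Z"]), int(piv_p.loc[acc, "W"]))
            if acc in piv_p.index
            else (0, 0)
        )
        rm, rp = refs[condition_minus], refs[condition_plus]
        c_m[acc] = cleavage_fraction(zm, rm["Z"], wm, rm["W"]) if zm + wm else math.nan
        c_p[acc] = cleavage_fraction(zp, rp["Z"], wp, rp["W"]) if zp + wp else math.nan
        reads_m[acc], reads_p[acc] = zm + wm, zp + wp

    norm, f = fold_change_table(c_m, c_p, reads_m, reads_p, min_reads)
    rng = np.random.default_rng(seed)

    rows = []
    switch_results = {}
    for acc in sorted(f):
        zm, wm = (
            (int(piv_m.loc[acc, "Z"]), int(piv_m.loc[acc, "W"]))
            if acc in piv_m.index
            else (0, 0)
        )
        zp, wp = (
            (int(piv_p.loc[acc, "Z"]), int(piv_p.loc[acc, "W"]))
            if acc in piv_p.index
            else (0, 0)
        )
        p = switching_test((zm, wm), (zp, wp), min_reads)
        ci = (math.nan, math.nan)
        if zm + wm >= 1 and zp + wp >= 1:
            cm = PrefixCounts(zm, wm, refs[condition_minus]["Z"], refs[condition_minus]["W"])
            cp = PrefixCounts(zp, wp, refs[condition_plus]["Z"], refs[condition_plus]["W"])
            cis = bootstrap_ci(
                cm, B=B, seed=int(rng.integers(2**31)), counts_plus=cp, k=norm.k
            )
            ci = cis["f"]
        if p is not None:
            switch_results[acc] = SwitchResult(acc, f[acc], ci[0], ci[1], p)
        rows.append(
            {
                "accession": acc,
                "core_seq": acc_core.get(acc, ""),
                "c_minus": c_m.get(acc, math.nan),
                "c_plus": c_p.get(acc, math.nan),
                "reads_minus": reads_m.get(acc, 0),
                "reads_plus": reads_p.get(acc, 0),
                "f": f[acc],
                "f_ci_lo": ci[0],
                "f_ci_hi": ci[1],
                "p_value": p if p is not None else math.nan,
                "flagged": acc in flagged,
            }
        )
    called = call_hits(
        switch_results, N=len(switch_results), min_fold=min_fold, flagged=flagged
    )
    df = pd.DataFrame(rows).set_index("accession")
    df["is_hit"] = pd.Series(
        {acc: r.is_hit for acc, r in called.items()}, dtype="boolean"
    ).reindex(df.index, fill_value=False).astype(bool)
    df.attrs["k"] = norm.k
    df.attrs["N"] = len(switch_results)
    df.attrs["n_normalization"] = norm.n_sequences_used
    return df.reset_index()
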