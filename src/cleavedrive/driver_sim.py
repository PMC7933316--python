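"""Stochastic model of alternating cleavage/uncleaved selection rounds.

Selection alternates between rounds that amplify molecules that self-cleaved
without ligand (survival probability ``c_minus``) and rounds that amplify
molecules that stayed uncleaved with ligand present (survival probability
``1 - c_plus``). Relative composition is all that matters: PCR amplification
factors are common to all survivors and are absorbed into renormalization.

Against the dominant background of ligand-insensitive members that fold into
cleaving and non-cleaving conformations about half the time each
(c = 0.5 in both conditions, surviving every round with weight 0.5), an
ideal switch - always cleaving without ligand, never with it - gains at most
a factor 2 per round; realistic switches enrich around 1.2-1.6x/round,
which over a multi-week automated run of tens of rounds still compounds to
>1e12-fold enrichment.

The module also provides estimators for the per-round enrichment rate eta
and the back-extrapolated initial library fraction f0 from observed
per-round fractions, the dilution bottleneck ("constriction") used before
sequencing, and the combinatorics of the randomized-loop library designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

AVOGADRO = 6.022e23  # mol^-1

RoundType = Literal["cleaved", "uncleaved"]


@dataclass(frozen=True)
class SwitchPhenotype:
    """True cleavage probabilities of one library member.

    ``c_minus``: probability of self-cleavage without ligand;
    ``c_plus``: with ligand. A perfect ON-switch is (1, 0).
    """

    c_minus: float
    c_plus: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.c_minus <= 1 and 0 <= self.c_plus <= 1):
            raise ValueError("cleavage probabilities must be in [0, 1]")

    def survival(self, round_type: RoundType) -> float:
        if round_type == "cleaved":
            return self.c_minus
        if round_type == "uncleaved":
            return 1.0 - self.c_plus
        raise ValueError(f"unknown round type {round_type!r}")


@dataclass
class SelectionLibrary:
    """Phenotypes with relative abundances summing to one."""

    members: list[SwitchPhenotype]
    abundances: np.ndarray
    round_index: int = 0

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.members) != self.abundances.size:
            raise ValueError("one abundance per member required")
        if (self.abundances < 0).any():
            raise ValueError("abundances must be non-negative")
        total = self.abundances.sum()
        if total <= 0:
            raise ValueError("library is empty")
        self.abundances = self.abundances / total

    def fraction(self, label: str) -> float:
        idx = [i for i, m in enumerate(self.members) if m.label == label]
        return float(self.abundances[idx].sum())


@dataclass(frozen=True)
class RoundSchedule:
    """Ordered round types, e.g. "ZU" for alternating 1:1, "ZZU" for 2:1.

    ``Z`` denotes a cleaved-selection round (no ligand), ``U`` an
    uncleaved-selection round (ligand present). The pattern repeats to fill
    ``total_rounds``.
    """

    pattern: str
    total_rounds: int

    def __post_init__(self) -> None:
        if not self.pattern or set(self.pattern) - set("ZU"):
            raise ValueError("pattern must be a non-empty string over {Z, U}")
        if self.total_rounds < 1:
            raise ValueError("total_rounds must be >= 1")

    def round_types(self) -> list[RoundType]:
        full = (self.pattern * (self.total_rounds // len(self.pattern) + 1))[
            : self.total_rounds
        ]
        return ["cleaved" if ch == "Z" else "uncleaved" for ch in full]


def simulate_round(
    lib: SelectionLibrary,
    round_type: RoundType,
    M: int | None = None,
    rng: np.random.Generator | None = None,
) -> SelectionLibrary:
    """Apply one selection round.

    In expectation mode (``M`` is None) each abundance is multiplied by the
    member's survival weight and renormalized. In stochastic mode, ``M``
    surviving molecules are drawn multinomially from the post-selection
    expected composition.
    """
    w = np.array([m.survival(round_type) for m in lib.members])
    post = lib.abundances * w
    total = post.sum()
    if total <= 0:
        raise RuntimeError("library extinct: all survival weights are zero")
    post = post / total
    if M is not None:
        if M < 1:
            raise ValueError("M must be >= 1")
        rng = rng if rng is not None else np.random.default_rng()
        counts = rng.multinomial(M, post)
        post = counts / counts.sum()
    return SelectionLibrary(lib.members, post, lib.round_index + 1)


def mutate_library(
    lib: SelectionLibrary,
    mutation_rate: float,
    rng: np.random.Generator,
    kernel_sd: float = 0.1,
) -> SelectionLibrary:
    """Move a fraction of abundance mass to phenotype-perturbed variants.

    Models the random mutagenesis introduced by low-fidelity amplification:
    each round a fraction ``mutation_rate`` of every member's mass spawns a
    variant whose cleavage probabilities are the parent's plus Gaussian
    perturbations (sd ``kernel_sd``), clipped to [0, 1]. Variants carry the
    parent's label suffixed with ``*``.
    """
    if mutation_rate == 0:
        return lib
    members = list(lib.members)
    ab = list(lib.abundances * (1 - mutation_rate))
    for m, a in zip(lib.members, lib.abundances):
        dm, dp = rng.normal(0, kernel_sd, size=2)
        members.append(
            SwitchPhenotype(
                min(1.0, max(0.0, m.c_minus + dm)),
                min(1.0, max(0.0, m.c_plus + dp)),
                label=m.label + "*" if m.label else "",
            )
        )
        ab.append(a * mutation_rate)
    return SelectionLibrary(members, np.array(ab), lib.round_index)


def run_schedule(
    lib: SelectionLibrary,
    schedule: RoundSchedule,
    mutation_rate: float = 0.0,
    M: int | None = None,
    seed: int | None = None,
    track: Sequence[str] = (),
) -> tuple[list[SelectionLibrary], dict[str, list[float]]]:
    """Run a full schedule, returning per-round libraries and tracked f_n.

    ``track`` lists member labels whose summed fractions are recorded after
    every round (index 0 is the input library).
    """
    rng = np.random.default_rng(seed)
    trajectory = [lib]
    fractions = {label: [lib.fraction(label)] for label in track}
    current = lib
    for round_type in schedule.round_types():
        current = simulate_round(current, round_type, M=M, rng=rng)
        if mutation_rate:
            current = mutate_library(current, mutation_rate, rng)
        trajectory.append(current)
        for label in track:
            fractions[label].append(current.fraction(label))
    return trajectory, fractions


def max_enrichment(pheno: SwitchPhenotype, background_c: float = 0.5) -> float:
    """Per-round enrichment vs a ligand-insensitive background.

    Geometric mean over one alternating (cleaved, uncleaved) cycle of the
    member's survival relative to a background cleaving ``background_c`` of
    the time in both conditions. A perfect (1, 0) switch gives 2.0; the
    background itself gives 1.0.
    """
    w_cleaved = pheno.c_minus / background_c
    w_uncleaved = (1.0 - pheno.c_plus) / (1.0 - background_c)
    return math.sqrt(w_cleaved * w_uncleaved)


def expected_molecules(conc_fM: float, volume_ul: float) -> float:
    """Molecule count in ``volume_ul`` microliters at ``conc_fM`` femtomolar."""
    if conc_fM <= 0 or volume_ul <= 0:
        raise ValueError("concentration and volume must be positive")
    return conc_fM * 1e-15 * AVOGADRO * volume_ul * 1e-6


def constrict(
    lib: SelectionLibrary,
    volume_ul: float,
    conc_fM: float = 8.0,
    seed: int | None = None,
) -> tuple[SelectionLibrary, int]:
    """Dilution bottleneck before sequencing.

    Draws Poisson(expected molecules) total molecules, allocated
    multinomially by abundance; members drawing zero molecules are dropped.
    Constricting a high-diversity library to a few thousand molecules yields
    a low-diversity subset with roughly uniform representation, giving each
    surviving sequence enough sequencing reads to quantify.
    """
    rng = np.random.default_rng(seed)
    expected = expected_molecules(conc_fM, volume_ul)
    n = int(rng.poisson(expected))
    if n < 1:
        raise RuntimeError("constriction produced zero molecules")
    counts = rng.multinomial(n, lib.abundances)
    keep = counts > 0
    members = [m for m, k in zip(lib.members, keep) if k]
    return (
        SelectionLibrary(members, counts[keep].astype(float), lib.round_index),
        n,
    )


@dataclass(frozen=True)
class EnrichmentFit:
    """Exponential fit f_n = f0 * eta^n to per-round fractions."""

    eta: float
    f0: float
    eta_se: float
    log_f0_se: float
    n_points: int
    rounds: tuple[int, ...] = field(default=())
    fractions: tuple[float, ...] = field(default=())
    sds: tuple[float, ...] = field(default=())


def estimate_enrichment(
    observations: Sequence[tuple[int, float, int]],
) -> EnrichmentFit:
    """Fit the enrichment rate eta and initial fraction f0.

    ``observations`` are (round n, observed fraction f_n, total reads).
    Weighted least squares on log f_n vs n, with delta-method weights from
    the binomial-proportion standard deviation
    sd(log f) ~= sqrt((1 - f) / (reads * f)). eta = exp(slope);
    f0 = exp(intercept). Rounds with f_n = 0 are dropped.
    """
    pts = [(n, f, r) for n, f, r in observations if f > 0]
    if len(pts) < 2:
        raise ValueError("need >= 2 rounds with nonzero observed fraction")
    n = np.array([p[0] for p in pts], dtype=float)
    f = np.array([p[1] for p in pts], dtype=float)
    reads = np.array([p[2] for p in pts], dtype=float)
    y = np.log(f)
    var = np.clip((1.0 - f) / (reads * f), 1e-30, None)
    w = 1.0 / var
    X = np.column_stack([np.ones_like(n), n])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    beta = np.linalg.solve(xtwx, WX.T @ y)
    cov = np.linalg.inv(xtwx)
    intercept, slope = beta
    eta = math.exp(slope)
    sds = np.sqrt(f * (1 - f) / reads)
    return EnrichmentFit(
        eta=eta,
        f0=math.exp(intercept),
        eta_se=eta * math.sqrt(cov[1, 1]),
        log_f0_se=math.sqrt(cov[0, 0]),
        n_points=len(pts),
        rounds=tuple(int(x) for x in n),
        fractions=tuple(float(x) for x in f),
        sds=tuple(float(x) for x in sds),
    )


# ---------------------------------------------------------------------------
# library-design combinatorics

# The randomized-loop designs replace one ribozyme loop with 30 or 60
# degenerate bases and the other with 4-8, in both loop orientations:
# 2 orientations x 2 long-loop sizes x 5 short-loop sizes = 20 designs with
# 34-68 degenerate positions.
DEFAULT_DESIGNS: tuple[int, ...] = tuple(
    long + short for long in (30, 60) for short in (4, 5, 6, 7, 8)
) * 2


def library_space(designs: Sequence[int] = DEFAULT_DESIGNS) -> tuple[int, int]:
    """Total sequence-space size Sum(4^d) and floor(log10) of it."""
    if any(d < 0 for d in designs):
        raise ValueError("degenerate-position counts must be >= 0")
    total = sum(4**d for d in designs)
    return total, _floor_log10(total)


def contexts(d: int, k: int) -> tuple[int, int]:
    """Count of library sequences embedding a fixed k-mer at one placement.

    Returns (4^(d-k), nearest order of magnitude).
    """
    if k > d:
        raise ValueError("k must be <= d")
    n = 4 ** (d - k)
    return n, _round_log10(n)


def _floor_log10(n: int) -> int:
    return len(str(n)) - 1


def _round_log10(n: int) -> int:
    if n <= 0:
        raise ValueError("positive integer required")
    exact = math.log10(n)
    return int(round(exact))
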