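"""Ground-truth generators for every pipeline input.

Each generator draws from the same statistical forward model the analysis
assumes - binomial cleavage per molecule, multinomial read sampling by
abundance, fixed-concentration spike-ins, uniform substitution sequencing
error - so analysis outputs can be checked against planted truth
analytically. All generators are bit-reproducible under a fixed seed.

The count-level generator (:func:`generate_count_run`) produces the
tabulated counts directly (fast, used for large planted libraries); the
FASTQ generator (:func:`generate_cleaveseq_run`) additionally renders every
molecule as a barcoded paired-end read so the full merge/demultiplex/
classify path can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import Sensorgram, simulate_sensorgram
from .seqio import AmpliconScheme, SequenceTable, default_scheme, reverse_complement
from .seqio import TABLE_COLUMNS

BASES = np.array(list("ACGT"))


@dataclass
class TruthSpec:
    """Planted truth for a cleavage-assay run.

    ``members`` maps core sequence to (c_minus, c_plus); abundances are
    relative and normalized internally. ``reference_fraction`` is the
    fraction of reads arising from the spike-in pool, the count-level image
    of injecting the references at a fixed concentration against the
    library's nominal concentration (15 refs x 18 pM against a ~2 nM library
    gives roughly 0.1-0.15).
    """

    members: Mapping[str, tuple[float, float]]
    abundances: Mapping[str, float] | None = None
    scheme: AmpliconScheme = field(default_factory=default_scheme)
    depth: int = 100_000
    error_rate: float = 0.0
    reference_fraction: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate <= 0.05):
            raise ValueError("error rate must be in [0, 0.05]")
        for core, (cm, cp) in self.members.items():
            if not (0 <= cm <= 1 and 0 <= cp <= 1):
                raise ValueError(f"cleavage probabilities of {core!r} not in [0,1]")
        if self.abundances is None:
            self.abundances = {k: 1.0 for k in self.members}
        total = sum(self.abundances.values())
        self.abundances = {k: v / total for k, v in self.abundances.items()}

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "core_seq": list(self.members),
                "c_minus": [v[0] for v in self.members.values()],
                "c_plus": [v[1] for v in self.members.values()],
                "abundance": [self.abundances[k] for k in self.members],
            }
        )


def random_truth(
    n_sequences: int,
    n_switchers: int = 0,
    rho: float = 3.0,
    core_length: int = 50,
    c_range: tuple[float, float] = (0.3, 0.7),
    switch_c_range: tuple[float, float] = (0.7, 0.9),
    seed: int = 0,
    **kwargs,
) -> TruthSpec:
    """Random library: null members plus planted switchers.

    Null members draw c_minus = c_plus uniformly from ``c_range`` (the
    ligand-insensitive ~50%-cleaving background of a real selection).
    Switchers draw c_minus from ``switch_c_range`` (high enough that the
    requested ratio is attainable) and set c_plus so the uncleaved-fraction
    ratio (1 - c_plus)/(1 - c_minus) equals ``rho``. Switcher cores are the
    first ``n_switchers`` sequences.
    """
    rng = np.random.default_rng(seed)
    if rho * (1.0 - switch_c_range[0]) > 1.0:
        raise ValueError("rho unattainable from switch_c_range")
    cores = set()
    while len(cores) < n_sequences:
        cores.add("".join(rng.choice(BASES, size=core_length)))
    cores = sorted(cores)
    members = {}
    for i, core in enumerate(cores):
        if i < n_switchers:
            c = float(rng.uniform(*switch_c_range))
            members[core] = (c, 1.0 - rho * (1.0 - c))
        else:
            c = float(rng.uniform(*c_range))
            members[core] = (c, c)
    return TruthSpec(members=members, seed=seed, **kwargs)


def generate_count_run(
    truth: TruthSpec,
    conditions: Sequence[str] = ("minus", "plus"),
    replicate: str = "1",
    seed: int | None = None,
) -> SequenceTable:
    """Draw a tabulated run directly at the count level.

    Per condition: ``depth`` reads split between the reference pool
    (binomially at ``reference_fraction``) and library members
    (multinomially by abundance); each member read is cleaved (prefix Z)
    with the condition's cleavage probability, else uncleaved (prefix W).
    Reference reads spread uniformly over the spike-ins, each keeping its
    fixed prefix. ``seed`` overrides the truth's seed (e.g. for independent
    replicates of the same planted truth).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    cores = list(truth.members)
    ab = np.array([truth.abundances[c] for c in cores])
    refs = truth.scheme.references
    rows = []
    for cond in conditions:
        use_plus = cond == conditions[-1] and len(conditions) > 1
        n_ref = rng.binomial(truth.depth, truth.reference_fraction)
        ref_counts = rng.multinomial(n_ref, np.full(len(refs), 1 / len(refs)))
        for ref, n in zip(refs, ref_counts):
            if n:
                rows.append((0, ref.sequence, ref.prefix, cond, replicate, int(n), True, False))
        member_counts = rng.multinomial(truth.depth - n_ref, ab)
        for i, (core, n) in enumerate(zip(cores, member_counts)):
            if n == 0:
                continue
            c = truth.members[core][1 if use_plus else 0]
            cleaved = rng.binomial(n, c)
            if cleaved:
                rows.append((i + 1, core, "Z", cond, replicate, int(cleaved), False, False))
            if n - cleaved:
                rows.append((i + 1, core, "W", cond, replicate, int(n - cleaved), False, False))
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return SequenceTable(df)


def _mutate(seqs: list[str], error_rate: float, rng: np.random.Generator) -> list[str]:
    if error_rate == 0:
        return seqs
    out = []
    for s in seqs:
        arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
        hits = rng.random(arr.size) < error_rate
        if hits.any():
            repl = rng.choice(BASES, size=int(hits.sum()))
            for idx, b in zip(np.nonzero(hits)[0], repl):
                old = chr(arr[idx])
                new = b if b != old else "ACGT"[("ACGT".index(old) + 1) % 4]
                arr[idx] = ord(new)
        out.append(arr.tobytes().decode())
    return out


def generate_cleaveseq_run(
    truth: TruthSpec,
    out_dir: str | Path | None = None,
    conditions: Sequence[str] = ("minus", "plus"),
    read_length: int = 65,
    replicate: str = "1",
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], pd.DataFrame]:
    """Render a run as paired reads (and optionally paired FASTQ files).

    Each molecule drawn by the count-level model becomes an amplicon
    ``5'barcode + prefix + core + suffix + 3'barcode``, substitution errors
    are applied at ``error_rate``, and the amplicon is split into a forward
    read (first ``read_length`` bases) and a reverse read (reverse
    complement of the last ``read_length`` bases); reads must overlap.
    Returns (r1 records, r2 records, truth frame) with records as
    (id, sequence); when ``out_dir`` is given also writes ``r1.fastq``,
    ``r2.fastq`` and ``truth.tsv`` there.
    """
    rng = np.random.default_rng(truth.seed + 1)
    table = generate_count_run(truth, conditions, replicate)
    scheme = truth.scheme
    min_core = min(
        [len(s) for s in truth.members]
        + [len(r.sequence) for r in scheme.references]
    )
    shortest = (
        min(len(b5) for b5, _ in scheme.barcodes.values())
        + min(len(p) for p in scheme.prefixes.values())
        + min_core
        + len(scheme.suffix)
        + min(len(b3) for _, b3 in scheme.barcodes.values())
    )
    if read_length >= shortest:
        raise ValueError("read length must be shorter than the amplicon")

    r1, r2 = [], []
    i = 0
    for row in table.data.itertuples():
        b5, b3 = scheme.barcodes[row.condition]
        amplicon = b5 + scheme.prefixes[row.prefix] + row.core_seq + scheme.suffix + b3
        if len(amplicon) > 2 * read_length:
            raise ValueError("reads do not overlap; increase read_length")
        copies = _mutate([amplicon] * row.count, truth.error_rate, rng)
        for amp in copies:
            i += 1
            rid = f"synth_{i}"
            r1.append((rid, amp[:read_length]))
            r2.append((rid, reverse_complement(amp[-read_length:])))
    truth_df = truth.truth_frame()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, recs in (("r1.fastq", r1), ("r2.fastq", r2)):
            with open(out_dir / name, "w") as fh:
                for rid, seq in recs:
                    fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        truth_df.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return r1, r2, truth_df


def generate_flow_events(
    expression_ratio: float,
    n_cells: int = 10_000,
    control_ratio: float = 1.0,
    mcherry_mean_log10: float = 4.0,
    noise_sd_log10: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell two-color events with a planted GFP/mCherry ratio.

    mCherry draws log-normally around ``mcherry_mean_log10``; GFP is
    mCherry times the planted ratio with multiplicative log-normal noise.
    Columns ``GFP``/``mCherry``/``population`` with populations ``sample``
    (ratio = expression_ratio) and ``control`` (ratio = control_ratio).
    Events land above the transformed-cell gates by construction; the
    generator models already-viability-gated cells.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for pop, ratio in (("sample", expression_ratio), ("control", control_ratio)):
        mch = 10 ** rng.normal(mcherry_mean_log10, noise_sd_log10, n_cells)
        gfp = mch * ratio * 10 ** rng.normal(0, noise_sd_log10, n_cells)
        frames.append(pd.DataFrame({"GFP": gfp, "mCherry": mch, "population": pop}))
    return pd.concat(frames, ignore_index=True)


def generate_gel_lanes(
    fractions: Sequence[float],
    total_intensity: float = 1000.0,
    length_cleaved: float = 50.0,
    length_uncleaved: float = 100.0,
    background: float = 50.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Band-intensity table whose lanes invert to the planted fractions.

    Above-background intensities are set so that the length-normalized
    cleaved share equals the planted fraction:
    (I_cl - bg)/L_cl = f * S and (I_un - bg)/L_un = (1 - f) * S with
    S = total_intensity.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        if not (0 <= f <= 1):
            raise ValueError("fractions must be in [0, 1]")
        i_cl = background + f * total_intensity * length_cleaved
        i_un = background + (1 - f) * total_intensity * length_uncleaved
        if noise_sd:
            i_cl = max(0.0, i_cl + rng.normal(0, noise_sd))
            i_un = max(0.0, i_un + rng.normal(0, noise_sd))
        rows.append(
            {
                "i_cleaved": i_cl,
                "i_uncleaved": i_un,
                "i_bg": background,
                "length_cleaved": length_cleaved,
                "length_uncleaved": length_uncleaved,
                "true_fraction": f,
            }
        )
    return pd.DataFrame(rows)


def generate_sensorgrams(
    k_on: float,
    k_off: float,
    r_max: float,
    concentrations: Sequence[float],
    t_assoc: float = 180.0,
    t_dissoc: float = 180.0,
    dt: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[Sensorgram]:
    """Multicycle Langmuir sensorgrams at the given analyte concentrations."""
    rng = np.random.default_rng(seed)
    return [
        simulate_sensorgram(
            k_on, k_off, r_max, float(c), t_assoc, t_dissoc, dt,
            noise_sd=noise_sd, seed=int(rng.integers(2**31)),
        )
        for c in sorted(concentrations)
    ]
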