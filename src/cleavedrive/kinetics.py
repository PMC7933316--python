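"""Surface-plasmon-resonance sensorgram simulation and 1:1 Langmuir fits.

Under the 1:1 Langmuir binding model with analyte concentration C, the
response during association follows

    RU(t) = R_eq + (RU_0 - R_eq) * exp(-(k_on C + k_off) t),
    R_eq  = R_max * C / (C + K_D),      K_D = k_off / k_on,

and during dissociation RU(t) = RU_0 * exp(-k_off t). Raw instrument traces
are normalized by a three-step subtraction chain - reference flow cell,
blank (buffer-only) cycle, then a blank-subtracted negative-control RNA -
before fitting. Kinetic fits share (k_on, k_off, R_max) globally across
concentrations; the equilibrium route instead fits the saturation plateaus
against concentration and reads K_D off the isotherm inflection. Rates too
fast for the sampling (full transition under 2 s) are flagged
non-measurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

Mode = Literal["multicycle", "single-cycle"]


@dataclass
class Sensorgram:
    """One cycle's trace: time (s), response (RU), analyte concentration (M).

    ``t_assoc`` marks the association start, ``t_dissoc`` the start of
    dissociation (= association stop); the trace ends when dissociation
    stops.
    """

    time: np.ndarray
    ru: np.ndarray
    concentration: float
    t_assoc: float = 0.0
    t_dissoc: float = 180.0
    cycle: str = "1"
    flow_cell: str = "2"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ru = np.asarray(self.ru, dtype=float)
        if self.time.size != self.ru.size:
            raise ValueError("time and RU must have equal length")
        if (np.diff(self.time) <= 0).any():
            raise ValueError("time must be strictly increasing")
        if not (self.t_assoc <= self.t_dissoc <= self.time[-1] + 1e-9):
            raise ValueError("phases must be contiguous and within the trace")


@dataclass(frozen=True)
class KineticFit:
    k_on: float  # M^-1 s^-1
    k_off: float  # s^-1
    r_max: float  # RU
    measurable: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def kd_kinetic(self) -> float:
        return self.k_off / self.k_on


def langmuir_association(
    t: np.ndarray, k_on: float, k_off: float, r_max: float, conc: float,
    ru0: float = 0.0,
) -> np.ndarray:
    kobs = k_on * conc + k_off
    req = r_max * conc / (conc + k_off / k_on)
    return req + (ru0 - req) * np.exp(-kobs * np.asarray(t, dtype=float))


def langmuir_dissociation(
    t: np.ndarray, k_off: float, ru0: float
) -> np.ndarray:
    return ru0 * np.exp(-k_off * np.asarray(t, dtype=float))


def simulate_sensorgram(
    k_on: float,
    k_off: float,
    r_max: float,
    conc: float,
    t_assoc: float = 180.0,
    t_dissoc: float = 180.0,
    dt: float = 0.5,
    noise_sd: float = 0.0,
    seed: int | None = None,
    ru0: float = 0.0,
) -> Sensorgram:
    """Closed-form Langmuir sensorgram, optionally with Gaussian noise.

    Association runs for ``t_assoc`` seconds starting from ``ru0``,
    dissociation for ``t_dissoc`` more; the curve is continuous at the
    boundary.
    """
    if min(k_on, k_off, r_max, conc) <= 0:
        raise ValueError("parameters must be positive")
    time = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    assoc = time <= t_assoc
    ru = np.empty_like(time)
    ru[assoc] = langmuir_association(time[assoc], k_on, k_off, r_max, conc, ru0)
    ru_end = langmuir_association(
        np.array([t_assoc]), k_on, k_off, r_max, conc, ru0
    )[0]
    ru[~assoc] = langmuir_dissociation(time[~assoc] - t_assoc, k_off, ru_end)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ru = ru + rng.normal(0, noise_sd, size=ru.size)
    return Sensorgram(time, ru, conc, 0.0, t_assoc)


def normalize_sensorgram(
    fc2: Sensorgram,
    fc1: Sensorgram,
    blank: Sensorgram,
    negative_control: Sensorgram,
    negative_control_blank: Sensorgram | None = None,
) -> Sensorgram:
    """Three-step background subtraction to RU_norm.

    RU_norm = ((fc2 - fc1) - blank) - (negctrl - negctrl_blank); the
    negative control is itself blank-subtracted (defaulting to the same
    blank). All traces are linearly interpolated onto fc2's time grid;
    phase boundaries must agree.
    """
    for other in (fc1, blank, negative_control):
        if not (
            math.isclose(other.t_assoc, fc2.t_assoc)
            and math.isclose(other.t_dissoc, fc2.t_dissoc)
        ):
            raise ValueError("phase boundaries differ between traces")

    def on_grid(s: Sensorgram) -> np.ndarray:
        if s.time.size == fc2.time.size and np.allclose(s.time, fc2.time):
            return s.ru
        return np.interp(fc2.time, s.time, s.ru)

    nc_blank = (
        on_grid(negative_control_blank)
        if negative_control_blank is not None
        else on_grid(blank)
    )
    ru = (
        (fc2.ru - on_grid(fc1))
        - on_grid(blank)
        - (on_grid(negative_control) - nc_blank)
    )
    return Sensorgram(
        fc2.time.copy(), ru, fc2.concentration, fc2.t_assoc, fc2.t_dissoc,
        cycle=fc2.cycle,
    )


def _stack_multicycle(curves: Sequence[Sensorgram]):
    """Model evaluator over concatenated multicycle curves."""

    def model(_x, k_on, k_off, r_max):
        out = []
        for c in curves:
            assoc = c.time <= c.t_dissoc
            ru = np.empty_like(c.time)
            ru[assoc] = langmuir_association(
                c.time[assoc] - c.t_assoc, k_on, k_off, r_max, c.concentration
            )
            end = langmuir_association(
                np.array([c.t_dissoc - c.t_assoc]),
                k_on, k_off, r_max, c.concentration,
            )[0]
            ru[~assoc] = langmuir_dissociation(
                c.time[~assoc] - c.t_dissoc, k_off, end
            )
            out.append(ru)
        return np.concatenate(out)

    return model


def _stack_single_cycle(curves: Sequence[Sensorgram]):
    """Chained associations sharing one RNA surface; RU carries over."""
    ordered = sorted(curves, key=lambda c: c.concentration)

    def model(_x, k_on, k_off, r_max):
        out = []
        ru0 = 0.0
        for c in ordered:
            assoc = c.time <= c.t_dissoc
            ru = np.empty_like(c.time)
            ru[assoc] = langmuir_association(
                c.time[assoc] - c.t_assoc, k_on, k_off, r_max,
                c.concentration, ru0,
            )
            ru0 = langmuir_association(
                np.array([c.t_dissoc - c.t_assoc]),
                k_on, k_off, r_max, c.concentration, ru0,
            )[0]
            if (~assoc).any():
                ru[~assoc] = langmuir_dissociation(
                    c.time[~assoc] - c.t_dissoc, k_off, ru0
                )
                ru0 = ru[-1]
            out.append(ru)
        return np.concatenate(out)

    return model, ordered


def fit_kinetics(
    curves: Sequence[Sensorgram],
    mode: Mode = "multicycle",
    p0: tuple[float, float, float] | None = None,
) -> KineticFit:
    """Global Langmuir fit sharing (k_on, k_off, R_max) across curves.

    Requires normalized curves at >= 3 concentrations spanning at least
    10x. Single-cycle mode chains the association phases in concentration
    order with carried-over starting RU. On convergence failure the fit is
    returned with ``measurable=False`` and diagnostics.
    """
    concs = sorted(c.concentration for c in curves)
    if len(curves) < 3:
        raise ValueError("need curves at >= 3 concentrations")
    if concs[-1] < 10 * concs[0]:
        raise ValueError("concentrations must span at least 10x")
    if mode == "multicycle":
        model = _stack_multicycle(curves)
        y = np.concatenate([c.ru for c in curves])
    elif mode == "single-cycle":
        model, ordered = _stack_single_cycle(curves)
        y = np.concatenate([c.ru for c in ordered])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ru_scale = max(float(np.max(np.abs(c.ru))) for c in curves)
    if p0 is None:
        mid_c = concs[len(concs) // 2]
        p0 = (1.0 / mid_c * 1e-2, 1e-2, ru_scale)
    try:
        popt, pcov = curve_fit(
            model,
            xdata=np.zeros(1),
            ydata=y,
            p0=p0,
            bounds=([1e-3, 1e-8, 1e-6], [1e12, 1e4, 1e9]),
            maxfev=40000,
        )
    except RuntimeError as exc:
        return KineticFit(
            math.nan, math.nan, math.nan, measurable=False,
            diagnostics={"error": str(exc)},
        )
    k_on, k_off, r_max = (float(v) for v in popt)
    resid = y - model(None, *popt)
    fit = KineticFit(
        k_on, k_off, r_max,
        diagnostics={
            "rmse": float(np.sqrt(np.mean(resid**2))),
            "cov": pcov.tolist(),
        },
    )
    return fit


def equilibrium_plateaus(
    curves: Sequence[Sensorgram], window_s: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mean RU over the final seconds of each association phase."""
    concs, plateaus = [], []
    for c in sorted(curves, key=lambda s: s.concentration):
        m = (c.time >= c.t_dissoc - window_s) & (c.time <= c.t_dissoc)
        concs.append(c.concentration)
        plateaus.append(float(c.ru[m].mean()))
    return np.array(concs), np.array(plateaus)


@dataclass(frozen=True)
class EquilibriumFit:
    kd: float
    r_max: float
    kd_se: float
    bound: str | None  # None or "unbounded" when saturation is not reached


def fit_equilibrium(
    concentrations: Sequence[float],
    plateaus: Sequence[float],
) -> EquilibriumFit:
    """Langmuir isotherm fit to saturation plateaus vs concentration.

    RU(C) = R_max * C / (C + K_D): a fixed-slope sigmoid in log C whose
    inflection sits at C = K_D, where the plateau equals R_max / 2. With no
    curvature in the measured range (no approach to saturation) the K_D is
    flagged unbounded.
    """
    conc = np.asarray(concentrations, dtype=float)
    ru = np.asarray(plateaus, dtype=float)
    if conc.size < 4:
        raise ValueError("need >= 4 concentrations")
    span = ru.max() - ru.min()
    if span <= 1e-12 * max(1.0, abs(float(ru.max()))):
        return EquilibriumFit(math.nan, float(ru.mean()), math.nan, "unbounded")

    def isotherm(c, kd, r_max):
        return r_max * c / (c + kd)

    popt, pcov = curve_fit(
        isotherm,
        conc,
        ru,
        p0=[float(np.median(conc)), float(ru.max())],
        bounds=([conc.min() / 1e6, 0], [conc.max() * 1e6, np.inf]),
        maxfev=20000,
    )
    kd, r_max = (float(v) for v in popt)
    bound = "unbounded" if kd > conc.max() * 3 else None
    return EquilibriumFit(kd, r_max, float(np.sqrt(pcov[0, 0])), bound)


def flag_nonmeasurable(
    fit: KineticFit,
    max_concentration: float,
    min_transition_s: float = 2.0,
) -> bool:
    """Whether the fitted rates are slow enough to resolve.

    The time to 95% of a transition is ln(20)/rate with rate
    k_on*C + k_off during association (at the highest tested concentration)
    and k_off during dissociation. Either phase completing in under
    ``min_transition_s`` (boundary inclusive) makes the fit non-measurable;
    returns the measurable flag.
    """
    if not fit.measurable or not math.isfinite(fit.k_off):
        return False
    t95_assoc = math.log(20.0) / (fit.k_on * max_concentration + fit.k_off)
    t95_dissoc = math.log(20.0) / fit.k_off
    return t95_assoc > min_transition_s and t95_dissoc > min_transition_s


# ---------------------------------------------------------------------------
# long-format I/O

SENSORGRAM_COLUMNS = ["time", "ru", "cycle", "flow_cell", "concentration", "phase"]


def sensorgrams_to_frame(curves: Sequence[Sensorgram]) -> pd.DataFrame:
    rows = []
    for c in curves:
        phase = np.where(c.time <= c.t_dissoc, "association", "dissociation")
        rows.append(
            pd.DataFrame(
                {
                    "time": c.time,
                    "ru": c.ru,
                    "cycle": c.cycle,
                    "flow_cell": c.flow_cell,
                    "concentration": c.concentration,
                    "phase": phase,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def sensorgrams_from_frame(df: pd.DataFrame) -> list[Sensorgram]:
    curves = []
    for (cycle, fc, conc), sub in df.groupby(
        ["cycle", "flow_cell", "concentration"], sort=True
    ):
        sub = sub.sort_values("time")
        assoc = sub[sub["phase"] == "association"]
        t_dissoc = float(assoc["time"].max()) if len(assoc) else float(
            sub["time"].max()
        )
        curves.append(
            Sensorgram(
                sub["time"].to_numpy(),
                sub["ru"].to_numpy(),
                float(conc),
                float(sub["time"].min()),
                t_dissoc,
                cycle=str(cycle),
                flow_cell=str(fc),
            )
        )
    return curves
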