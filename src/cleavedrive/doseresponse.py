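"""EC50 estimation from fold-change dose-response data, and selectivity.

Responses (fold change of cleavage fraction vs the no-ligand condition) are
fit with a four-parameter logistic in log10 concentration,

    f(C) = bottom + (top - bottom) / (1 + (EC50 / C)^hill)

by weighted least squares. When the measured range does not bracket the
half-maximal response the EC50 is reported as a one-sided bound rather than
a point estimate. Selectivity across ligand analogs is summarized as a
sensor x molecule matrix of fold changes against a shared no-ligand
reference.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

_UNIT_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


def parse_concentration(text: str | float) -> float:
    """Concentration in molar from a number or a suffixed string ("5 uM")."""
    if isinstance(text, (int, float)):
        return float(text)
    m = re.fullmatch(
        r"\s*([0-9.eE+-]+)\s*(M|mM|uM|µM|μM|nM|pM)?\s*", text
    )
    if not m:
        raise ValueError(f"cannot parse concentration {text!r}")
    value = float(m.group(1))
    unit = m.group(2) or "M"
    return value * _UNIT_FACTORS[unit]


def four_pl(conc: np.ndarray, ec50: float, bottom: float, top: float, hill: float) -> np.ndarray:
    """Four-parameter logistic in concentration (EC50 on the linear scale)."""
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        return bottom + (top - bottom) / (1.0 + (ec50 / conc) ** hill)


@dataclass(frozen=True)
class EC50Fit:
    ec50: float
    bottom: float
    top: float
    hill: float
    ec50_se: float
    bound: str | None  # None, "lower" (EC50 >= value) or "unbounded"
    flat: bool = False
    non_monotone: bool = False


def fit_ec50(
    concentrations: Sequence[float],
    responses: Sequence[float],
    errors: Sequence[float] | None = None,
) -> EC50Fit:
    """Fit a 4PL dose-response curve.

    ``concentrations`` in molar, strictly increasing, at least four points
    (a zero-concentration point anchors the bottom asymptote and is kept out
    of the log grid). ``errors`` are per-point standard errors used as WLS
    weights. When the top concentration has not plateaued the EC50 is
    flagged as a lower bound; a flat response returns an unbounded flag.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.size < 4:
        raise ValueError("need at least 4 concentrations")
    if (conc < 0).any() or (np.diff(conc) <= 0).any():
        raise ValueError("concentrations must be >= 0 and strictly increasing")
    sigma = np.asarray(errors, dtype=float) if errors is not None else None

    span = resp.max() - resp.min()
    if span < 1e-12 or (
        sigma is not None and span < 2 * float(np.median(sigma))
    ):
        return EC50Fit(
            math.nan, float(resp.mean()), float(resp.mean()), math.nan,
            math.nan, bound="unbounded", flat=True,
        )

    pos = conc > 0
    c_pos = conc[pos]
    # crude midpoint initialization from the half-maximal crossing
    half = (resp.min() + resp.max()) / 2.0
    above = resp[pos] >= half
    ec0 = float(np.sqrt(c_pos[0] * c_pos[-1]))
    if above.any() and (~above).any():
        i = int(np.argmax(above)) if resp[pos][-1] > resp[pos][0] else int(
            np.argmax(~above)
        )
        ec0 = float(c_pos[max(i - 1, 0)] * c_pos[i]) ** 0.5
    p0 = [ec0, float(resp[0]), float(resp[-1]), 1.0]
    lower = [c_pos[0] / 1e4, -np.inf, -np.inf, 0.1]
    upper = [c_pos[-1] * 1e4, np.inf, np.inf, 10.0]
    popt, pcov = curve_fit(
        four_pl,
        conc,
        resp,
        p0=p0,
        sigma=sigma,
        absolute_sigma=sigma is not None,
        bounds=(lower, upper),
        maxfev=20000,
    )
    ec50, bottom, top, hill = popt
    ec50_se = float(np.sqrt(pcov[0, 0]))

    # monotonicity check on the measured points (beyond noise)
    tol = 3 * np.median(sigma) if sigma is not None else 0.05 * span
    diffs = np.diff(resp[pos])
    increasing = top >= bottom
    non_mono = bool(
        (diffs < -tol).any() if increasing else (diffs > tol).any()
    )

    bound = None
    if ec50 >= c_pos[-1] / 3:
        # response has not plateaued within the measured range
        bound = "lower"
    return EC50Fit(
        float(ec50), float(bottom), float(top), float(hill), ec50_se,
        bound=bound, non_monotone=non_mono,
    )


def selectivity_matrix(
    fold_changes: Mapping[tuple[str, str], float],
    concentrations: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Sensor x molecule matrix of fold changes vs the no-ligand condition.

    ``fold_changes`` maps (sensor, molecule) to the fold change measured
    with that molecule present (all molecules assayed at identical
    concentrations against a common no-ligand reference). Missing
    combinations are NaN, never imputed. Cell order is independent of input
    order.
    """
    sensors = sorted({s for s, _ in fold_changes})
    molecules = sorted({m for _, m in fold_changes})
    mat = pd.DataFrame(index=sensors, columns=molecules, dtype=float)
    for (s, m), v in fold_changes.items():
        if v <= 0:
            raise ValueError("fold changes must be positive")
        mat.loc[s, m] = v
    if concentrations is not None:
        mat.attrs["concentrations_M"] = dict(concentrations)
    return mat
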