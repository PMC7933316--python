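"""Gel-band and flow-cytometry quantification of ribozyme activity.

Gel route: the cleaved and uncleaved bands of a denaturing PAGE lane are
background-subtracted and normalized by product length (staining intensity
scales with nucleotides, so per-length normalization recovers molar
amounts):

    f = (I_cl - I_bg)/L_cl / [ (I_cl - I_bg)/L_cl + (I_un - I_bg)/L_un ]

with fold change (1 - f_+ligand) / (1 - f_-ligand), i.e. the ratio of
uncleaved fractions, the quantity proportional to intact transcript.

Flow route: in the two-color yeast reporter, per-cell GFP is normalized by
mCherry from the same plasmid; gated cells give
F_sample = mean(GFP_i / mCherry_i), scaled to relative fluorescence units
RFU = 100 * F_sample / F_control against the inactive-ribozyme control. The
activation ratio is RFU with ligand over RFU without.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

#: default transformed-cell gates, linear fluorescence units
MCHERRY_GATE = 10**3.2
GFP_GATE = 10**3.1


@dataclass(frozen=True)
class GelLane:
    """Band intensities (arbitrary units) and product lengths (nt)."""

    i_cleaved: float
    i_uncleaved: float
    i_bg: float
    length_cleaved: float
    length_uncleaved: float

    def __post_init__(self) -> None:
        if self.length_cleaved <= 0 or self.length_uncleaved <= 0:
            raise ValueError("product lengths must be positive")
        if min(self.i_cleaved, self.i_uncleaved, self.i_bg) < 0:
            raise ValueError("intensities must be non-negative")


def gel_fraction(lane: GelLane) -> float:
    """Length-normalized, background-subtracted fraction cleaved.

    Negative background-subtracted intensities clamp to zero with a warning
    (gel noise); both bands at or below background give NaN.
    """
    cl = lane.i_cleaved - lane.i_bg
    un = lane.i_uncleaved - lane.i_bg
    if cl < 0 or un < 0:
        warnings.warn(
            "band intensity below background clamped to zero", stacklevel=2
        )
    cl = max(cl, 0.0) / lane.length_cleaved
    un = max(un, 0.0) / lane.length_uncleaved
    if cl + un == 0:
        return math.nan
    return cl / (cl + un)


def gel_fold_change(f_plus: float, f_minus: float) -> float:
    """Ratio of uncleaved fractions, (1 - f_+ligand) / (1 - f_-ligand)."""
    if not (0 <= f_plus <= 1 and 0 <= f_minus <= 1):
        raise ValueError("fractions must be in [0, 1]")
    if f_minus >= 1:
        return math.nan
    return (1.0 - f_plus) / (1.0 - f_minus)


def flow_normalize(
    sample_gfp: np.ndarray,
    sample_mcherry: np.ndarray,
    control_gfp: np.ndarray,
    control_mcherry: np.ndarray,
    mcherry_gate: float = MCHERRY_GATE,
    gfp_gate: float = GFP_GATE,
) -> tuple[float, float]:
    """Mean per-cell reporter ratio and control-normalized RFU.

    Events are gated to transformed cells (mCherry and GFP above their
    thresholds) in both sample and control; returns
    (F_sample, RFU = 100 * F_sample / F_control). The control sample by
    definition reads 100 RFU.
    """

    def gated_mean_ratio(gfp, mch):
        gfp = np.asarray(gfp, dtype=float)
        mch = np.asarray(mch, dtype=float)
        if gfp.size != mch.size:
            raise ValueError("channel arrays must have equal length")
        keep = (mch > mcherry_gate) & (gfp > gfp_gate)
        if not keep.any():
            raise ValueError("no events pass the transformed-cell gates")
        return float(np.mean(gfp[keep] / mch[keep]))

    f_sample = gated_mean_ratio(sample_gfp, sample_mcherry)
    f_control = gated_mean_ratio(control_gfp, control_mcherry)
    return f_sample, 100.0 * f_sample / f_control


def activation_ratio(rfu_plus: float, rfu_minus: float) -> float:
    """Gene-regulatory activation: RFU with ligand over RFU without."""
    if rfu_minus <= 0:
        raise ValueError("RFU without ligand must be positive")
    return rfu_plus / rfu_minus
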