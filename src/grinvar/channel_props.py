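"""Open probability, proton-sensitivity ratio and surface-expression ratio.

Maximal open probability is estimated from the fold potentiation produced by
MTSEA modification of an engineered pore cysteine, which locks channels open:

    P_open = (gamma_MTSEA / gamma_control) * (1 / Potentiation)

with the single-channel conductance ratio gamma_MTSEA/gamma_control = 0.67 by
default.  Surface/total receptor expression comes from the slopes of linear
beta-lactamase reporter absorbance ramps, background-corrected and normalized
to the same-day wild-type ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MtseaMeasurement",
    "OpenProbabilityResult",
    "ExpressionMeasurement",
    "open_probability",
    "ph_current_ratio",
    "fit_absorbance_slope",
    "expression_ratio",
]

DEFAULT_GAMMA_RATIO = 0.67


@dataclass
class MtseaMeasurement:
    """Steady-state agonist response before and after MTSEA co-application."""

    cell_id: str
    i_control: float  # nA
    i_mtsea: float    # nA
    gamma_ratio: float = DEFAULT_GAMMA_RATIO

    def __post_init__(self) -> None:
        if self.i_mtsea <= 0:
            raise ValueError("post-MTSEA current must be positive")
        if self.i_control <= 0:
            raise ValueError("control current must be positive")
        if not 0 < self.gamma_ratio <= 1:
            raise ValueError("gamma ratio must be in (0, 1]")


@dataclass
class OpenProbabilityResult:
    value: Optional[float]
    status: str  # ok | no_potentiation | inconsistent
    potentiation: float
    cell_id: str = ""


def open_probability(measure: MtseaMeasurement) -> OpenProbabilityResult:
    """Maximal open probability from the MTSEA potentiation of one cell.

    No potentiation (post-MTSEA current at or below control, as seen for
    variants that MTSEA cannot lock open) yields a flagged status rather than
    a probability; estimates above 1 are kept but flagged as inconsistent
    with the assay's assumptions.
    """
    potentiation = measure.i_mtsea / measure.i_control
    if potentiation <= 1.0:
        return OpenProbabilityResult(None, "no_potentiation", potentiation,
                                     measure.cell_id)
    po = measure.gamma_ratio / potentiation
    status = "ok" if po <= 1.0 else "inconsistent"
    return OpenProbabilityResult(float(po), status, potentiation, measure.cell_id)


def ph_current_ratio(i_ph68: float, i_ph76: float) -> float:
    """Current at pH 6.8 as a percentage of the current at pH 7.6."""
    if i_ph76 <= 0 or i_ph68 <= 0:
        raise ValueError("currents must be positive")
    return 100.0 * i_ph68 / i_ph76


@dataclass
class ExpressionMeasurement:
    """Background-corrected absorbance slope for one reporter well."""

    well_id: str
    compartment: str  # surface | total
    slope: float      # absorbance / min
    background_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.compartment not in ("surface", "total"):
            raise ValueError("compartment must be 'surface' or 'total'")
        if self.slope - self.background_slope < 0:
            raise ValueError("corrected slope must be non-negative")

    @property
    def corrected_slope(self) -> float:
        return self.slope - self.background_slope


def fit_absorbance_slope(time_min: Sequence[float],
                         absorbance: Sequence[float]) -> float:
    """Rate of absorbance increase from an ordinary linear fit."""
    t = np.asarray(time_min, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points for a slope")
    return float(stats.linregress(t, a).slope)


def _mean_corrected(wells: Sequence[ExpressionMeasurement], compartment: str) -> float:
    vals = [w.corrected_slope for w in wells if w.compartment == compartment]
    if not vals:
        raise ValueError(f"no {compartment} wells supplied")
    return float(np.mean(vals))


def expression_ratio(surface_wells: Sequence[ExpressionMeasurement],
                     total_wells: Sequence[ExpressionMeasurement],
                     wt_surface_wells: Sequence[ExpressionMeasurement],
                     wt_total_wells: Sequence[ExpressionMeasurement]) -> float:
    """Surface/total expression of a construct relative to same-day wild type.

    The wild type's own ratio is 1.0 by construction.  The result is invariant
    to any plate-wide multiplicative gain because it is a ratio of ratios.
    """
    total = _mean_corrected(total_wells, "total")
    wt_total = _mean_corrected(wt_total_wells, "total")
    if total <= 0 or wt_total <= 0:
        raise ValueError("total-expression slope must be positive")
    ratio = _mean_corrected(surface_wells, "surface") / total
    wt_ratio = _mean_corrected(wt_surface_wells, "surface") / wt_total
    if wt_ratio <= 0:
        raise ValueError("wild-type surface/total ratio must be positive")
    return ratio / wt_ratio
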