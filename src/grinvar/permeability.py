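"""Reversal-potential screen for altered divalent (Ba2+) permeability.

Agonist-evoked difference currents are recorded at 15 mV voltage steps in a
Na+-based and then a Ba2+-based external solution.  The reversal potential of
each current-voltage family is interpolated at the zero-current crossing, the
Ba2+-induced shift DV_rev = V_rev(Ba) - V_rev(Na) is computed per construct,
and the screen statistic is the variant-minus-WT difference of shifts,

    DDV_rev = DV_rev(variant) - DV_rev(WT).

Differences beyond +/- 3.4 mV (the 99% confidence half-width of the WT shift)
are called as changed Ba2+ permeability, positive meaning increased and
negative decreased.  The predicted -6 mV junction-potential shift of the Ba2+
solution is deliberately left uncorrected, matching the recording convention
the threshold was derived under.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "IVFamily",
    "PermeabilityScreenResult",
    "estimate_reversal_potential",
    "ddv_rev_screen",
    "current_ratio",
    "compare_current_ratios",
    "ci99_halfwidth",
]

DEFAULT_DDVREV_THRESHOLD_MV = 3.4
DEFAULT_VOLTAGE_STEPS_MV = (-90.0, -75.0, -60.0, -45.0, -30.0, -15.0, 0.0,
                            15.0, 30.0)


@dataclass
class IVFamily:
    """Difference-current I-V relation for one cell in one solution."""

    cell_id: str
    solution: str  # Na | Ba
    voltages_mv: np.ndarray
    currents_na: np.ndarray

    def __post_init__(self) -> None:
        if self.solution not in ("Na", "Ba"):
            raise ValueError("solution must be 'Na' or 'Ba'")
        self.voltages_mv = np.asarray(self.voltages_mv, dtype=float)
        self.currents_na = np.asarray(self.currents_na, dtype=float)
        if self.voltages_mv.shape != self.currents_na.shape:
            raise ValueError("voltage and current arrays differ in length")
        if self.voltages_mv.size < 2:
            raise ValueError("need at least 2 voltage steps")
        if np.any(np.diff(self.voltages_mv) <= 0):
            raise ValueError("voltages must be strictly increasing")


@dataclass
class PermeabilityScreenResult:
    dv_rev_variant_mv: float
    dv_rev_wt_mv: float
    ddv_rev_mv: float
    call: str  # increased | decreased | no_change
    threshold_mv: float
    current_ratio_na: Optional[float] = None
    current_ratio_ba: Optional[float] = None


def estimate_reversal_potential(family: IVFamily):
    """Zero-current crossing of the I-V family by local linear interpolation.

    Returns ``(v_rev_mv, multiple_crossings)``; when the noisy family crosses
    zero more than once the crossing nearest 0 mV is used and flagged.
    """
    v, i = family.voltages_mv, family.currents_na
    sign = np.sign(i)
    crossings = []
    for k in range(v.size - 1):
        if sign[k] == 0:
            crossings.append(float(v[k]))
        elif sign[k] * sign[k + 1] < 0:
            frac = i[k] / (i[k] - i[k + 1])
            crossings.append(float(v[k] + frac * (v[k + 1] - v[k])))
    if sign[-1] == 0:
        crossings.append(float(v[-1]))
    if not crossings:
        raise ValueError("reversal not bracketed: currents do not change sign")
    crossings = sorted(set(crossings), key=abs)
    return crossings[0], len(crossings) > 1


def ddv_rev_screen(variant_shift_mv: float, wt_shift_mv: float,
                   threshold_mv: float = DEFAULT_DDVREV_THRESHOLD_MV,
                   current_ratio_na: Optional[float] = None,
                   current_ratio_ba: Optional[float] = None) -> PermeabilityScreenResult:
    """Apply the +/- threshold rule to a variant/WT pair of Ba2+ shifts."""
    ddv = variant_shift_mv - wt_shift_mv
    if ddv > threshold_mv:
        call = "increased"
    elif ddv < -threshold_mv:
        call = "decreased"
    else:
        call = "no_change"
    return PermeabilityScreenResult(variant_shift_mv, wt_shift_mv, float(ddv),
                                    call, threshold_mv,
                                    current_ratio_na, current_ratio_ba)


def current_ratio(family: IVFamily, v_negative_mv: float = -75.0,
                  v_positive_mv: float = 30.0) -> float:
    """Ratio of the currents at the hyperpolarized and depolarized steps."""
    v = family.voltages_mv

    def pick(target):
        idx = np.nonzero(np.isclose(v, target))[0]
        if idx.size == 0:
            raise ValueError(f"voltage step {target} mV not present")
        return float(family.currents_na[idx[0]])

    i_pos = pick(v_positive_mv)
    if abs(i_pos) < 1e-12:
        raise ValueError("current at the depolarized step is zero")
    return pick(v_negative_mv) / i_pos


def compare_current_ratios(ratio_na_variant: float, ratio_ba_variant: float,
                           ratio_na_wt: float, ratio_ba_wt: float,
                           rel_tol: float = 0.2) -> str:
    """Corroborating flag from the Ba/Na inward-current ratio pair.

    A variant whose Ba2+ inward current is suppressed relative to its Na+
    current, compared with the same relation in wild type, supports reduced
    Ba2+ permeability; the opposite supports increased permeability.
    """
    rel_var = abs(ratio_ba_variant) / abs(ratio_na_variant)
    rel_wt = abs(ratio_ba_wt) / abs(ratio_na_wt)
    if rel_var < (1 - rel_tol) * rel_wt:
        return "reduced"
    if rel_var > (1 + rel_tol) * rel_wt:
        return "increased"
    return "no_change"


def ci99_halfwidth(sem_mv: float, n: Optional[int] = None) -> float:
    """99% confidence half-width of a mean shift (normal approximation).

    ``n`` is accepted for interface symmetry but the z-quantile is used
    regardless: the screen threshold was derived with the normal quantile
    (2.576 x SEM), not Student's t.
    """
    if sem_mv < 0:
        raise ValueError("sem must be non-negative")
    return float(stats.norm.ppf(0.995) * sem_mv)
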