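"""Hill-equation concentration-response fitting.

Agonist activation is modelled as

    Response(%) = 100 / (1 + (EC50 / [agonist])^N)

and channel-blocker / Mg2+ inhibition as

    Response(%) = (100 - minimum) / (1 + ([blocker] / IC50)^N) + minimum

with the residual response ``minimum`` constrained to be non-negative.
Potency is estimated on the log10 scale and 95% confidence intervals are
normal-approximation intervals on log10(EC50) (or log10(IC50)) that are then
back-transformed, so the intervals are asymmetric around the potency itself.
Composite fits pool all cells of a construct after normalizing each cell's
responses to its own fitted maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from lmfit import Model
from scipy import stats

Mode = Literal["agonist", "inhibitor"]

__all__ = [
    "ConcentrationResponseSeries",
    "HillFit",
    "hill_agonist_response",
    "hill_inhibitor_response",
    "fit_agonist",
    "fit_inhibitor",
    "relative_response_ratio",
    "percent_inhibition_at",
    "ci_nonoverlap_significant",
]


def hill_agonist_response(concentration_um, ec50_um, hill_n):
    """Percent of maximal response at the given agonist concentration."""
    c = np.asarray(concentration_um, dtype=float)
    return 100.0 / (1.0 + (ec50_um / c) ** hill_n)


def hill_inhibitor_response(concentration_um, ic50_um, hill_n, minimum_pct=0.0):
    """Percent of control response remaining at the given blocker concentration."""
    c = np.asarray(concentration_um, dtype=float)
    return (100.0 - minimum_pct) / (1.0 + (c / ic50_um) ** hill_n) + minimum_pct


@dataclass
class ConcentrationResponseSeries:
    """Per-cell (concentration, response) pairs for one ligand on one construct.

    Concentrations are uM, responses percent of the cell's maximal response.
    """

    construct_id: str
    ligand: str
    cell_id: str
    concentrations_um: np.ndarray
    responses_pct: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations_um = np.asarray(self.concentrations_um, dtype=float)
        self.responses_pct = np.asarray(self.responses_pct, dtype=float)
        if self.concentrations_um.shape != self.responses_pct.shape:
            raise ValueError("concentration and response arrays differ in length")
        if np.any(self.concentrations_um <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations_um) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class HillFit:
    """Result of a composite Hill fit for one construct/ligand."""

    mode: Mode
    potency_um: float
    log10_potency: float
    hill_n: float
    ci95_low: float
    ci95_high: float
    n_cells: int
    minimum_pct: float = 0.0
    converged: bool = True
    warnings: list = field(default_factory=list)
    ligand: str = ""
    construct_id: str = ""

    def __post_init__(self) -> None:
        if self.converged and not (self.ci95_low <= self.potency_um <= self.ci95_high):
            raise ValueError("potency must lie inside its confidence interval")


def _pool(series_set: Iterable[ConcentrationResponseSeries]):
    series = list(series_set)
    if not series:
        raise ValueError("no concentration-response series supplied")
    conc = np.concatenate([s.concentrations_um for s in series])
    resp = np.concatenate([s.responses_pct for s in series])
    return series, conc, resp


def _normalize_per_cell(series: Sequence[ConcentrationResponseSeries],
                        mode: Mode) -> list[ConcentrationResponseSeries]:
    """Rescale each cell's responses to percent of its own fitted maximum.

    A free-amplitude Hill curve is fitted per cell; when that fit fails the
    cell's maximum observed response is used instead.
    """
    out = []
    for s in series:
        top = None
        if len(s.concentrations_um) >= 4 and mode == "agonist":
            try:
                model = Model(lambda c, top, lp, n:
                              top / (1.0 + (10.0 ** lp / c) ** n),
                              independent_vars=["c"])
                params = model.make_params(
                    top=float(np.max(s.responses_pct)),
                    lp=float(np.log10(np.median(s.concentrations_um))),
                    n=1.0,
                )
                params["n"].set(min=0.05, max=10)
                params["top"].set(min=1e-6)
                res = model.fit(s.responses_pct, params, c=s.concentrations_um)
                if res.success:
                    top = float(res.params["top"].value)
            except Exception:
                top = None
        if top is None or not np.isfinite(top) or top <= 0:
            top = float(np.max(np.abs(s.responses_pct))) or 1.0
        out.append(ConcentrationResponseSeries(
            s.construct_id, s.ligand, s.cell_id,
            s.concentrations_um, s.responses_pct * (100.0 / top)))
    return out


def _check_preconditions(conc: np.ndarray) -> None:
    if np.unique(conc).size < 4:
        raise ValueError("need at least 4 distinct concentrations to fit")


def _range_warning(potency_um: float, conc: np.ndarray) -> list[str]:
    notes = []
    if potency_um > 10 * conc.max() or potency_um < conc.min() / 10:
        notes.append("potency more than 10x outside the sampled range")
    return notes


_Z95 = float(stats.norm.ppf(0.975))


def fit_agonist(series_set: Iterable[ConcentrationResponseSeries],
                normalize: bool = True) -> HillFit:
    """Composite agonist fit pooling all cells of one construct.

    Parameters are log10(EC50) and the Hill slope N; the 95% CI is computed
    on log10(EC50) from the asymptotic standard error and back-transformed.
    """
    series, conc, resp = _pool(series_set)
    if normalize:
        series = _normalize_per_cell(series, "agonist")
        conc = np.concatenate([s.concentrations_um for s in series])
        resp = np.concatenate([s.responses_pct for s in series])
    _check_preconditions(conc)

    model = Model(lambda c, lp, n: 100.0 / (1.0 + (10.0 ** lp / c) ** n),
                  independent_vars=["c"])
    params = model.make_params(lp=float(np.log10(np.median(conc))), n=1.0)
    params["n"].set(min=0.05, max=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(resp, params, c=conc)

    lp = float(res.params["lp"].value)
    se = res.params["lp"].stderr
    notes = []
    converged = bool(res.success) and se is not None and np.isfinite(se)
    if not converged:
        notes.append("fit did not converge or has no standard error")
        se = np.nan
    lo, hi = 10.0 ** (lp - _Z95 * se), 10.0 ** (lp + _Z95 * se)
    potency = 10.0 ** lp
    notes += _range_warning(potency, conc)
    first = series[0]
    return HillFit(mode="agonist", potency_um=potency, log10_potency=lp,
                   hill_n=float(res.params["n"].value),
                   ci95_low=lo if converged else np.nan,
                   ci95_high=hi if converged else np.nan,
                   n_cells=len(series), converged=converged, warnings=notes,
                   ligand=first.ligand, construct_id=first.construct_id)


def fit_inhibitor(series_set: Iterable[ConcentrationResponseSeries],
                  constrain_minimum: bool = True) -> HillFit:
    """Composite inhibitor fit (response in the presence of maximal agonist).

    ``constrain_minimum`` keeps the residual response at saturating blocker
    non-negative, which is the default fitting convention.
    """
    series, conc, resp = _pool(series_set)
    _check_preconditions(conc)

    model = Model(lambda c, lp, n, minimum:
                  (100.0 - minimum) / (1.0 + (c / 10.0 ** lp) ** n) + minimum,
                  independent_vars=["c"])
    params = model.make_params(lp=float(np.log10(np.median(conc))), n=1.0,
                               minimum=0.0)
    params["n"].set(min=0.05, max=10)
    if constrain_minimum:
        params["minimum"].set(min=0.0, max=100.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(resp, params, c=conc)

    lp = float(res.params["lp"].value)
    se = res.params["lp"].stderr
    notes = []
    converged = bool(res.success) and se is not None and np.isfinite(se)
    if not converged:
        notes.append("fit did not converge or has no standard error")
        se = np.nan
    # flag gross non-monotonicity of the pooled means beyond noise
    order = np.argsort(conc)
    uniq, idx = np.unique(conc[order], return_inverse=True)
    means = np.array([resp[order][idx == i].mean() for i in range(uniq.size)])
    if uniq.size >= 3 and np.any(np.diff(means) > 15.0):
        notes.append("response increases with blocker concentration beyond noise")
    potency = 10.0 ** lp
    notes += _range_warning(potency, conc)
    first = series[0]
    return HillFit(mode="inhibitor", potency_um=potency, log10_potency=lp,
                   hill_n=float(res.params["n"].value),
                   minimum_pct=float(res.params["minimum"].value),
                   ci95_low=10.0 ** (lp - _Z95 * se) if converged else np.nan,
                   ci95_high=10.0 ** (lp + _Z95 * se) if converged else np.nan,
                   n_cells=len(series), converged=converged, warnings=notes,
                   ligand=first.ligand, construct_id=first.construct_id)


def relative_response_ratio(fit_variant: HillFit, fit_wt: HillFit,
                            concentration_um: float) -> float:
    """Variant-to-WT ratio of fractional responses at one agonist concentration.

    This is the R_GLY / R_GLU term of the charge-transfer composites: the
    agonist curve of each construct evaluated at the stated extracellular
    concentration, variant over WT.
    """
    if fit_variant.mode != "agonist" or fit_wt.mode != "agonist":
        raise ValueError("relative response ratio requires agonist-mode fits")
    rv = hill_agonist_response(concentration_um, fit_variant.potency_um,
                               fit_variant.hill_n)
    rw = hill_agonist_response(concentration_um, fit_wt.potency_um,
                               fit_wt.hill_n)
    return float(rv / rw)


def percent_inhibition_at(fit: HillFit, concentration_um: float = 1000.0) -> float:
    """Percent inhibition by the blocker at the given concentration."""
    if fit.mode != "inhibitor":
        raise ValueError("percent inhibition requires an inhibitor-mode fit")
    if concentration_um == 0:
        return 0.0
    return float(100.0 - hill_inhibitor_response(
        concentration_um, fit.potency_um, fit.hill_n, fit.minimum_pct))


def ci_nonoverlap_significant(fit_a: HillFit, fit_b: HillFit):
    """Significance call from non-overlap of the two 95% potency intervals.

    Returns ``(significant, direction)`` where direction describes the potency
    of ``fit_b`` relative to ``fit_a`` ("increased" means lower EC50/IC50).
    """
    disjoint = fit_a.ci95_high < fit_b.ci95_low or fit_b.ci95_high < fit_a.ci95_low
    if not disjoint:
        return False, "none"
    return True, "increased" if fit_b.potency_um < fit_a.potency_um else "decreased"
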