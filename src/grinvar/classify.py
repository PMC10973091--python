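"""Charge-transfer scoring and gain/loss-of-function classification.

The six per-variant assay measures are combined into two multiplicative
composites describing the relative output of variant versus wild-type
receptors.  For the synaptic (brief, high-glutamate) condition

    CT_syn = (tau_w,MUT / tau_w,WT) * (P_MUT / P_WT) * (Surf_MUT / Surf_WT)
             * R_GLY * R_GLU,syn * (Mg_MUT / Mg_WT)

and for the non-synaptic (sustained, low-glutamate) condition the same
product without the deactivation term and with R_GLU evaluated at 0.1 uM
glutamate.  R_GLY and R_GLU are variant/WT ratios of fractional responses at
the reference ligand concentrations (3 uM glycine; 1 mM or 0.1 uM glutamate)
and the Mg term is the ratio of percent inhibition by 1 mM Mg2+.

Each assay also casts a directional vote: increased agonist potency, higher
open probability, slower deactivation, weaker Mg2+ inhibition and higher
surface expression all support gain of function; their opposites support loss
of function.  Votes are graded high (H) or moderate (M) confidence, and the
final call follows a fixed decision order: unmeasurable deactivation with all
other assays complete gives "Indeterminant*"; agreeing votes give GoF or LoF;
conflicting or subthreshold votes are rescued to "Possible GoF"/"Possible
LoF" by a suprathreshold charge-transfer fold (> 2.5 or < 0.4), except that
two suprathreshold composites in opposite directions give "Indeterminant";
anything else is "no change".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import PipelineConfig, DEFAULT_CONFIG
from .dose_response import hill_agonist_response, hill_inhibitor_response

logger = logging.getLogger(__name__)

__all__ = [
    "AssayProfile",
    "VariantClassification",
    "ASSAYS",
    "relative_response",
    "synaptic_charge_transfer",
    "nonsynaptic_charge_transfer",
    "fold_change_ledger",
    "grade_assay_change",
    "classify",
    "classify_variant",
    "classify_summary",
    "count_suprathreshold",
    "RegressionResult",
    "regression_tau_vs_potency",
    "regression_glycine_vs_glutamate",
    "ec50_po_relation",
    "profiles_from_summary",
]

#: assay keys, in ledger display order
ASSAYS = ("glu", "gly", "mg", "po", "tau", "surf")

GOF = "GoF"
LOF = "LoF"


@dataclass
class AssayProfile:
    """Per-variant six-assay summary paired with its same-day WT reference.

    Potencies are uM; ``surface_ratio`` is already normalized to same-day WT
    (so the WT profile carries 1.0).  ``status`` marks each assay as
    ``measured``, ``nd`` (response too small to measure) or ``na`` (not
    assayed); ``significant`` carries the per-assay statistics flags
    (confidence-interval non-overlap or ANOVA outcome supplied upstream).
    """

    construct_id: str
    ec50_glu: Optional[float] = None
    ec50_gly: Optional[float] = None
    ic50_mg: Optional[float] = None
    po: Optional[float] = None
    tau_w: Optional[float] = None
    surface_ratio: Optional[float] = None
    hill_glu: Optional[float] = None
    hill_gly: Optional[float] = None
    hill_mg: Optional[float] = None
    mg_minimum_pct: float = 0.0
    mg_inhibition_pct: Optional[float] = None
    peak: Optional[float] = None
    status: dict = field(default_factory=dict)
    significant: dict = field(default_factory=dict)

    def assay_status(self, assay: str) -> str:
        if assay in self.status:
            return self.status[assay]
        value = {"glu": self.ec50_glu, "gly": self.ec50_gly,
                 "mg": self.ic50_mg, "po": self.po, "tau": self.tau_w,
                 "surf": self.surface_ratio}[assay]
        return "measured" if value is not None and np.isfinite(value) else "na"


@dataclass
class VariantClassification:
    construct_id: str
    fold_changes: dict
    votes: dict                 # assay -> (direction, confidence)
    n_high: dict                # direction -> count of H votes
    n_moderate: dict
    ct_synaptic: Optional[float]
    ct_nonsynaptic: Optional[float]
    call: str


_warned_missing_hill: set = set()


def _hill(profile: AssayProfile, which: str) -> float:
    slope = getattr(profile, f"hill_{which}")
    if slope is None:
        key = (profile.construct_id, which)
        if key not in _warned_missing_hill:
            _warned_missing_hill.add(key)
            logger.warning("no fitted Hill slope for %s/%s; assuming N = 1",
                           profile.construct_id, which)
        return 1.0
    return slope


def relative_response(profile: AssayProfile, wt: AssayProfile,
                      ligand: str, concentration_um: float) -> float:
    """Variant/WT ratio of fractional agonist responses at one concentration."""
    which = {"glutamate": "glu", "glycine": "gly"}[ligand]
    ec_v = getattr(profile, f"ec50_{which}")
    ec_w = getattr(wt, f"ec50_{which}")
    rv = hill_agonist_response(concentration_um, ec_v, _hill(profile, which))
    rw = hill_agonist_response(concentration_um, ec_w, _hill(wt, which))
    return float(rv / rw)


def _mg_inhibition(profile: AssayProfile, config: PipelineConfig) -> float:
    if profile.mg_inhibition_pct is not None:
        return profile.mg_inhibition_pct
    return float(100.0 - hill_inhibitor_response(
        config.mg_ref_um, profile.ic50_mg, _hill(profile, "mg"),
        profile.mg_minimum_pct))


def _common_terms(profile: AssayProfile, wt: AssayProfile,
                  config: PipelineConfig, glu_ref_um: float):
    for assay in ("glu", "gly", "mg", "po", "surf"):
        if profile.assay_status(assay) != "measured":
            return None
        if wt.assay_status(assay) != "measured":
            raise ValueError(f"WT reference missing assay {assay!r}")
    return (profile.po / wt.po
            * profile.surface_ratio / wt.surface_ratio
            * relative_response(profile, wt, "glycine", config.gly_ref_um)
            * relative_response(profile, wt, "glutamate", glu_ref_um)
            * _mg_inhibition(profile, config) / _mg_inhibition(wt, config))


def synaptic_charge_transfer(profile: AssayProfile, wt: AssayProfile,
                             config: PipelineConfig = DEFAULT_CONFIG
                             ) -> Optional[float]:
    """Relative fold change in synaptic charge transfer (None if a term is
    unmeasurable, which feeds the Indeterminant* logic downstream)."""
    if profile.assay_status("tau") != "measured":
        return None
    common = _common_terms(profile, wt, config, config.glu_synaptic_um)
    if common is None:
        return None
    return float(profile.tau_w / wt.tau_w * common)


def nonsynaptic_charge_transfer(profile: AssayProfile, wt: AssayProfile,
                                config: PipelineConfig = DEFAULT_CONFIG
                                ) -> Optional[float]:
    """Relative fold change in non-synaptic charge transfer (time-independent,
    evaluated at the ambient 0.1 uM glutamate concentration)."""
    common = _common_terms(profile, wt, config, config.glu_nonsynaptic_um)
    return None if common is None else float(common)


def fold_change_ledger(profile: AssayProfile, wt: AssayProfile) -> dict:
    """Per-assay folds in the display convention of the classification ledger.

    Agonist potencies are WT/variant EC50 (potency is reciprocal to EC50);
    Mg2+ IC50, open probability, weighted tau and surface expression are
    variant/WT.  In every case a fold above 1 supports gain of function.
    """
    folds = {}
    pairs = {"glu": (wt.ec50_glu, profile.ec50_glu),
             "gly": (wt.ec50_gly, profile.ec50_gly)}
    for assay, (num, den) in pairs.items():
        folds[assay] = (float(num / den)
                        if profile.assay_status(assay) == "measured" else None)
    direct = {"mg": ("ic50_mg",), "po": ("po",), "tau": ("tau_w",),
              "surf": ("surface_ratio",)}
    for assay, (attr,) in direct.items():
        if profile.assay_status(assay) == "measured":
            folds[assay] = float(getattr(profile, attr) / getattr(wt, attr))
        else:
            folds[assay] = None
    return folds


def grade_assay_change(assay: str, fold: Optional[float], significant: bool,
                       config: PipelineConfig = DEFAULT_CONFIG):
    """Directional graded vote for one assay's fold change.

    ``fold`` must follow the ledger display convention, so fold > 1 is
    GoF-supporting for every assay.  Significant changes of at least
    ``config.high_conf_fold`` in either direction are high confidence,
    smaller significant changes moderate; non-significant changes or exact
    unity cast no vote.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay key {assay!r}")
    if fold is None or not np.isfinite(fold) or fold == 1.0 or not significant:
        return (None, None)
    direction = GOF if fold > 1.0 else LOF
    magnitude = max(fold, 1.0 / fold)
    return (direction, "H" if magnitude >= config.high_conf_fold else "M")


def classify(votes: dict, ct_syn: Optional[float], ct_nonsyn: Optional[float],
             assay_statuses: Optional[dict] = None,
             config: PipelineConfig = DEFAULT_CONFIG) -> str:
    """Final call from the graded votes and the charge-transfer folds.

    The decision order is fixed; every input reaches a call.
    """
    statuses = assay_statuses or {}
    others_done = all(statuses.get(a, "measured") == "measured"
                     for a in ASSAYS if a != "tau")
    if statuses.get("tau") in ("nd", "tstm") and others_done:
        return "Indeterminant*"

    directions = {d for d, c in votes.values() if c in ("H", "M")}
    if len(directions) == 1:
        return directions.pop()

    def supra_up(ct):
        return ct is not None and ct > config.ct_upper

    def supra_down(ct):
        return ct is not None and ct < config.ct_lower

    both_conflicting = ((supra_up(ct_syn) and supra_down(ct_nonsyn)) or
                        (supra_down(ct_syn) and supra_up(ct_nonsyn)))
    if both_conflicting:
        return "Indeterminant"
    if supra_up(ct_syn) or supra_up(ct_nonsyn):
        return "Possible GoF"
    if supra_down(ct_syn) or supra_down(ct_nonsyn):
        return "Possible LoF"
    return "no change"


def classify_variant(profile: AssayProfile, wt: AssayProfile,
                     config: PipelineConfig = DEFAULT_CONFIG
                     ) -> VariantClassification:
    """Full classification of one variant against its WT reference."""
    folds = fold_change_ledger(profile, wt)
    votes = {assay: grade_assay_change(assay, folds[assay],
                                       bool(profile.significant.get(assay, False)),
                                       config)
             for assay in ASSAYS}
    ct_syn = synaptic_charge_transfer(profile, wt, config)
    ct_nonsyn = nonsynaptic_charge_transfer(profile, wt, config)
    statuses = {assay: profile.assay_status(assay) for assay in ASSAYS}
    call = classify(votes, ct_syn, ct_nonsyn, statuses, config)
    n_high = {d: sum(1 for dd, c in votes.values() if dd == d and c == "H")
              for d in (GOF, LOF)}
    n_mod = {d: sum(1 for dd, c in votes.values() if dd == d and c == "M")
             for d in (GOF, LOF)}
    return VariantClassification(profile.construct_id, folds, votes,
                                 n_high, n_mod, ct_syn, ct_nonsyn, call)


# ---------------------------------------------------------------------------
# operations on the tabulated per-variant summary
# ---------------------------------------------------------------------------

def profiles_from_summary(summary: pd.DataFrame):
    """Build (variant profiles, WT references) from a tabulated assay summary.

    The summary follows the ``assay_summary.csv`` schema: one row per
    construct and background block, WT rows flagged ``is_wt``.
    """
    def to_profile(row) -> AssayProfile:
        def val(col):
            x = row[col]
            return None if pd.isna(x) else float(x)

        status = {}
        for assay, col in (("glu", "glu_ec50"), ("gly", "gly_ec50"),
                           ("mg", "mg_ic50"), ("po", "po"),
                           ("surf", "surf")):
            status[assay] = "measured" if val(col) is not None else "nd"
        tau_status = row.get("tau_status")
        status["tau"] = (tau_status if isinstance(tau_status, str)
                         and tau_status and not pd.isna(tau_status) else "na")
        sig = {assay: bool(row.get(f"{col}_sig", 0))
               for assay, col in (("glu", "glu"), ("gly", "gly"), ("mg", "mg"),
                                  ("po", "po"), ("tau", "tau"),
                                  ("surf", "surf"))}
        return AssayProfile(
            construct_id=row["construct_id"],
            ec50_glu=val("glu_ec50"), ec50_gly=val("gly_ec50"),
            ic50_mg=val("mg_ic50"), po=val("po"), tau_w=val("tau_w"),
            surface_ratio=val("surf"), peak=val("peak"),
            status=status, significant=sig)

    wt_refs = {row["block"]: to_profile(row)
               for _, row in summary[summary.is_wt == 1].iterrows()}
    variants = {}
    for _, row in summary[summary.is_wt == 0].iterrows():
        variants[(row["block"], row["construct_id"])] = to_profile(row)
    return variants, wt_refs


def classify_summary(summary: pd.DataFrame,
                     config: PipelineConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Classify every variant row of a tabulated summary against its WT."""
    variants, wt_refs = profiles_from_summary(summary)
    rows = []
    for (block, cid), profile in variants.items():
        result = classify_variant(profile, wt_refs[block], config)
        row = {"block": block, "construct_id": cid,
               "ct_syn": result.ct_synaptic, "ct_nonsyn": result.ct_nonsynaptic,
               "call": result.call,
               "n_high_gof": result.n_high[GOF], "n_high_lof": result.n_high[LOF],
               "n_mod_gof": result.n_moderate[GOF],
               "n_mod_lof": result.n_moderate[LOF]}
        for assay in ASSAYS:
            row[f"fold_{assay}"] = result.fold_changes[assay]
            d, c = result.votes[assay]
            row[f"vote_{assay}"] = f"{d}:{c}" if d else ""
        rows.append(row)
    return pd.DataFrame(rows)


def _variant_root(construct_id: str) -> str:
    return construct_id.split("/")[0]


def count_suprathreshold(summary: pd.DataFrame, threshold: float = 2.5) -> dict:
    """Count variants whose charge-transfer folds exceed the threshold.

    The denominator deduplicates variants assayed on both GluN2A and GluN2B
    backgrounds, matching the panel-level convention.
    """
    v = summary[summary.is_wt == 0]
    return {
        "synaptic": int((v.ct_syn > threshold).sum()),
        "nonsynaptic": int((v.ct_nonsyn > threshold).sum()),
        "denominator": int(v.construct_id.map(_variant_root).nunique()),
    }


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    n: int


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if x.size < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.allclose(x, x[0]):
        raise ValueError("regressor has no variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(float(res.params[1]), float(res.params[0]),
                            float(res.rsquared), int(x.size))


def _fold_columns(summary: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    wt = summary[summary.is_wt == 1].set_index("block")
    v = summary[summary.is_wt == 0].copy()
    for col in columns:
        v[f"fold_{col}"] = v[col] / v["block"].map(wt[col])
    return v


def regression_tau_vs_potency(summary: pd.DataFrame,
                              ec50_floor_um: float = 0.03,
                              backgrounds: Optional[list[str]] = None
                              ) -> RegressionResult:
    """OLS of log10 weighted-tau fold on log10 glutamate-EC50 fold.

    Variants with EC50 at or below the floor (30 nM by default) are excluded
    because trace agonist contamination can distort such low potencies.
    ``backgrounds`` restricts the included summary blocks.
    """
    v = _fold_columns(summary, ["glu_ec50", "tau_w"])
    sel = v.tau_w.notna() & (v.glu_ec50 > ec50_floor_um)
    if backgrounds is not None:
        sel &= v.block.isin(backgrounds)
    s = v[sel]
    return _ols(np.log10(s.fold_glu_ec50.to_numpy(float)),
                np.log10(s.fold_tau_w.to_numpy(float)))


def regression_glycine_vs_glutamate(summary: pd.DataFrame,
                                    ec50_floor_um: float = 0.03,
                                    orientation: str = "glu_on_gly",
                                    backgrounds: Optional[list[str]] = None
                                    ) -> RegressionResult:
    """OLS relating the log10 glycine- and glutamate-potency fold changes.

    Both potencies must exceed the contamination floor.  ``orientation``
    selects which fold is the response variable: ``"glu_on_gly"`` (the
    convention that reproduces the reference fit tabulated for this panel) or
    ``"gly_on_glu"``.
    """
    v = _fold_columns(summary, ["glu_ec50", "gly_ec50"])
    sel = (v.glu_ec50 > ec50_floor_um) & (v.gly_ec50 > ec50_floor_um)
    if backgrounds is not None:
        sel &= v.block.isin(backgrounds)
    s = v[sel]
    x = np.log10(s.fold_gly_ec50.to_numpy(float))
    y = np.log10(s.fold_glu_ec50.to_numpy(float))
    if orientation == "glu_on_gly":
        return _ols(x, y)
    if orientation == "gly_on_glu":
        return _ols(y, x)
    raise ValueError("orientation must be 'glu_on_gly' or 'gly_on_glu'")


def ec50_po_relation(po_normalized: float, kd_um: float) -> float:
    """Two-state gating stand-in for the EC50 / open-probability coupling.

    For a binding step (dissociation constant Kd) followed by a gating
    equilibrium E, occupancy-based algebra gives EC50 = Kd / (1 + E); writing
    the normalized gating occupancy p = E / (1 + E) this is
    EC50 = Kd * (1 - p): stronger gating lowers the apparent potency
    threshold.  This generic relation is the module's own simple model of the
    coupling, not a fitted mechanism.
    """
    if not 0 <= po_normalized < 1:
        raise ValueError("normalized open probability must be in [0, 1)")
    if kd_um <= 0:
        raise ValueError("Kd must be positive")
    return kd_um * (1.0 - po_normalized)
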