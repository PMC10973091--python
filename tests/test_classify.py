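"""Charge-transfer composites, vote grading, the decision procedure and the
fold-change regressions on the tabulated variant panel."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import grinvar as g
from grinvar.classify import ASSAYS, GOF, LOF, profiles_from_summary


def _profile(cid="var", ec50_glu=3.5, ec50_gly=1.2, ic50_mg=19.0, po=0.24,
             tau_w=44.0, surf=1.0, sig=None, status=None, **kw):
    return g.AssayProfile(construct_id=cid, ec50_glu=ec50_glu,
                          ec50_gly=ec50_gly, ic50_mg=ic50_mg, po=po,
                          tau_w=tau_w, surface_ratio=surf,
                          hill_glu=1.0, hill_gly=1.0, hill_mg=1.0,
                          significant=sig or {}, status=status or {}, **kw)


WT = _profile("WT")


class TestChargeTransfer:
    def test_wt_self_comparison_is_unity(self):
        assert g.synaptic_charge_transfer(WT, WT) == pytest.approx(1.0)
        assert g.nonsynaptic_charge_transfer(WT, WT) == pytest.approx(1.0)

    def test_synaptic_product_of_stated_ratios(self):
        cfg = g.PipelineConfig()
        # tau x2, Po x2, Surf x0.5; potency terms and Mg unchanged -> 2.0;
        # then check full multiplicativity against an independently scaled Po
        var = _profile(tau_w=88.0, po=0.48, surf=0.5)
        assert g.synaptic_charge_transfer(var, WT, cfg) == pytest.approx(2.0)

    def test_multiplicativity_in_each_ratio(self):
        cfg = g.PipelineConfig()
        base = _profile(tau_w=88.0, po=0.48, surf=0.5)
        ct0 = g.synaptic_charge_transfer(base, WT, cfg)
        for field, k in (("po", 3.0), ("tau_w", 0.25), ("surface_ratio", 7.0)):
            var = _profile(tau_w=base.tau_w, po=base.po, surf=base.surface_ratio)
            setattr(var, field, getattr(base, field) * k)
            assert g.synaptic_charge_transfer(var, WT, cfg) == pytest.approx(
                k * ct0, rel=1e-9)

    def test_nonsynaptic_low_glutamate_ratio_hand_value(self):
        # EC50 0.3 vs 3.5 uM, N = 1, at 0.1 uM; all other terms unity:
        # (0.1/0.4)/(0.1/3.6) = 9.0
        var = _profile(ec50_glu=0.3)
        assert g.nonsynaptic_charge_transfer(var, WT) == pytest.approx(9.0,
                                                                       rel=1e-9)

    def test_missing_tau_yields_undefined_synaptic_fold(self):
        var = _profile(tau_w=None, status={"tau": "nd"})
        assert g.synaptic_charge_transfer(var, WT) is None
        assert g.nonsynaptic_charge_transfer(var, WT) == pytest.approx(1.0)


class TestFoldConventionAndGrading:
    def test_potency_folds_are_wt_over_variant(self):
        var = _profile(ec50_glu=0.35, ec50_gly=2.4, po=0.12)
        folds = g.fold_change_ledger(var, WT)
        assert folds["glu"] == pytest.approx(10.0)   # more potent -> fold > 1
        assert folds["gly"] == pytest.approx(0.5)
        assert folds["po"] == pytest.approx(0.5)     # direct variant/WT

    @pytest.mark.parametrize("assay,fold,sig,expected", [
        ("glu", 1.0, True, (None, None)),
        ("glu", 3.0, False, (None, None)),
        ("mg", 4.9, True, (GOF, "H")),     # strongly reduced Mg block
        ("surf", 0.055, True, (LOF, "H")),  # trafficking collapse
        ("po", 1.5, True, (GOF, "M")),
        ("tau", 0.6, True, (LOF, "M")),
    ])
    def test_vote_grading(self, assay, fold, sig, expected):
        assert g.grade_assay_change(assay, fold, sig) == expected

    def test_unknown_assay_rejected(self):
        with pytest.raises(ValueError):
            g.grade_assay_change("zinc", 2.0, True)


class TestDecisionProcedure:
    def test_all_quiet_is_no_change(self):
        votes = {a: (None, None) for a in ASSAYS}
        assert g.classify(votes, 1.0, 1.0) == "no change"

    def test_agreeing_votes_win(self):
        votes = {a: (None, None) for a in ASSAYS}
        votes["po"] = (LOF, "H")
        votes["surf"] = (LOF, "M")
        assert g.classify(votes, 0.012, 0.020) == LOF

    def test_conflicting_votes_rescued_by_suprathreshold_ct(self):
        votes = {a: (None, None) for a in ASSAYS}
        votes["po"] = (GOF, "H")
        votes["surf"] = (LOF, "H")
        assert g.classify(votes, 3.0, 1.0) == "Possible GoF"
        assert g.classify(votes, 1.0, 0.2) == "Possible LoF"

    def test_opposed_suprathreshold_composites_are_indeterminant(self):
        votes = {a: (None, None) for a in ASSAYS}
        votes["po"] = (GOF, "H")
        votes["surf"] = (LOF, "H")
        assert g.classify(votes, 3.0, 0.2) == "Indeterminant"

    def test_unmeasurable_tau_with_complete_assays_is_starred(self):
        votes = {a: (None, None) for a in ASSAYS}
        votes["po"] = (GOF, "H")
        statuses = {a: "measured" for a in ASSAYS}
        statuses["tau"] = "nd"
        assert g.classify(votes, None, 5.0, statuses) == "Indeterminant*"
        # with another assay missing the starred rule does not apply
        statuses["mg"] = "na"
        assert g.classify(votes, None, 5.0, statuses) == GOF

    def test_totality_and_order_stability(self):
        """Every random vote/charge-transfer combination reaches a valid call,
        and the call does not depend on assay ordering."""
        rng = np.random.default_rng(99)
        valid = {GOF, LOF, "Possible GoF", "Possible LoF", "Indeterminant",
                 "Indeterminant*", "no change"}
        options = [(None, None), (GOF, "H"), (GOF, "M"), (LOF, "H"),
                   (LOF, "M")]
        for _ in range(200):
            votes = {a: options[rng.integers(len(options))] for a in ASSAYS}
            cts = [None if rng.random() < 0.2 else float(10 **
                                                         rng.uniform(-2, 2))
                   for _ in range(2)]
            call = g.classify(votes, cts[0], cts[1])
            assert call in valid
            shuffled = dict(reversed(list(votes.items())))
            assert g.classify(shuffled, cts[0], cts[1]) == call

    def test_wt_self_profile_classifies_as_no_change(self):
        result = g.classify_variant(_profile("WT-copy"), WT)
        assert result.call == "no change"
        assert result.ct_synaptic == pytest.approx(1.0)


class TestTabulatedPanel:
    def test_strong_lof_variant_from_table(self, summary):
        variants, wt_refs = profiles_from_summary(summary)
        profile = variants[("N2B", "GluN2B-A652P")]
        result = g.classify_variant(profile, wt_refs["N2B"])
        assert result.call == LOF
        # the call is carried by the significant potency reductions
        lof_votes = [a for a, (d, c) in result.votes.items() if d == LOF]
        assert "glu" in lof_votes and "gly" in lof_votes
        assert result.ct_synaptic < 0.4

    def test_table_classification_covers_every_variant(self, summary):
        out = g.classify_summary(summary)
        assert len(out) == int((summary.is_wt == 0).sum())
        assert out.call.notna().all()

    def test_suprathreshold_counts(self, summary):
        counts = g.count_suprathreshold(summary)
        assert counts == {"synaptic": 27, "nonsynaptic": 32,
                          "denominator": 48}


class TestRegressions:
    def test_reciprocal_data_gives_slope_minus_one(self):
        import pandas as pd
        rows = [{"block": "B", "construct_id": "WT", "is_wt": 1,
                 "glu_ec50": 1.0, "tau_w": 100.0}]
        rng = np.random.default_rng(0)
        for i in range(8):
            fold = 10 ** rng.uniform(-1.5, 1.5)
            rows.append({"block": "B", "construct_id": f"v{i}", "is_wt": 0,
                         "glu_ec50": fold, "tau_w": 100.0 / fold})
        res = g.regression_tau_vs_potency(pd.DataFrame(rows))
        assert res.slope == pytest.approx(-1.0, abs=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_single_shared_fold_is_an_error(self):
        import pandas as pd
        rows = [{"block": "B", "construct_id": "WT", "is_wt": 1,
                 "glu_ec50": 1.0, "tau_w": 100.0}]
        rows += [{"block": "B", "construct_id": f"v{i}", "is_wt": 0,
                  "glu_ec50": 2.0, "tau_w": 50.0 + i} for i in range(4)]
        with pytest.raises(ValueError, match="variance"):
            g.regression_tau_vs_potency(pd.DataFrame(rows))

    def test_identical_agonist_shifts_give_unit_slope(self):
        import pandas as pd
        rows = [{"block": "B", "construct_id": "WT", "is_wt": 1,
                 "glu_ec50": 3.5, "gly_ec50": 1.2}]
        rng = np.random.default_rng(1)
        for i in range(10):
            fold = 10 ** rng.uniform(-1, 1)
            rows.append({"block": "B", "construct_id": f"v{i}", "is_wt": 0,
                         "glu_ec50": 3.5 * fold, "gly_ec50": 1.2 * fold})
        res = g.regression_glycine_vs_glutamate(pd.DataFrame(rows))
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert abs(res.intercept) < 1e-9


class TestGatingRelation:
    def test_limits_and_monotonicity(self):
        assert g.ec50_po_relation(0.0, 5.0) == pytest.approx(5.0)
        assert g.ec50_po_relation(0.5, 5.0) == pytest.approx(2.5)
        grid = np.linspace(0.0, 0.95, 20)
        vals = [g.ec50_po_relation(p, 5.0) for p in grid]
        assert np.all(np.diff(vals) < 0)

    def test_saturated_gating_rejected(self):
        with pytest.raises(ValueError):
            g.ec50_po_relation(1.0, 5.0)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(k=st.floats(0.05, 20.0))
def test_scaling_po_scales_both_composites_by_k(k):
    var = _profile(po=0.24 * k)
    assert g.synaptic_charge_transfer(var, WT) == pytest.approx(k, rel=1e-9)
    assert g.nonsynaptic_charge_transfer(var, WT) == pytest.approx(k, rel=1e-9)
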