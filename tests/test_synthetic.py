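"""Synthetic-data generators: determinism, noise-off round trips and schemas."""

import numpy as np
import pandas as pd
import pytest

import grinvar as g


class TestProfiles:
    def test_tau_order_canonicalized(self):
        p = g.GroundTruthProfile("x", 1.0, 1.0, tau_fast=100.0, tau_slow=30.0,
                                 frac_fast=0.2)
        assert (p.tau_fast, p.tau_slow) == (30.0, 100.0)
        assert p.frac_fast == pytest.approx(0.8)
        assert p.tau_weighted == pytest.approx(44.0)

    @pytest.mark.parametrize("field,value", [
        ("ec50_glu", -1.0), ("po_max", 0.0), ("po_max", 1.5),
        ("frac_fast", 1.2), ("tau_fast", 0.0)])
    def test_invalid_profiles_rejected(self, field, value):
        kwargs = dict(construct_id="x", ec50_glu=1.0, ec50_gly=1.0)
        kwargs[field] = value
        with pytest.raises(ValueError):
            g.GroundTruthProfile(**kwargs)

    def test_wt_presets_encode_tabulated_truth(self):
        a, b = g.get_preset("WT-GluN1/2A"), g.get_preset("WT-GluN1/2B")
        assert (a.ec50_glu, a.ic50_mg, a.po_max) == (3.5, 19.0, 0.24)
        assert a.tau_weighted == pytest.approx(44.0)
        assert b.po_max == 0.033
        assert b.tau_weighted == pytest.approx(524.0)

    def test_preset_overrides_do_not_mutate_the_registry(self):
        g.get_preset("WT-GluN1/2A", noise_cv=0.99)
        assert g.get_preset("WT-GluN1/2A").noise_cv != 0.99


class TestConfig:
    def test_bad_concentration_series_rejected(self):
        with pytest.raises(ValueError):
            g.SimulationConfig(concentration_series_um=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            g.SimulationConfig(concentration_series_um=[3.0, 2.0, 1.0, 4.0])

    def test_voltage_steps_must_bracket_zero(self):
        with pytest.raises(ValueError):
            g.SimulationConfig(voltage_steps_mv=[-90.0, -60.0, -30.0])

    def test_default_series_spans_four_decades(self):
        s = g.default_concentration_series(3.5)
        assert len(s) == 9
        assert s[0] == pytest.approx(0.035) and s[-1] == pytest.approx(350.0)


class TestDeterminism:
    def test_fixed_seed_reproduces_outputs_bitwise(self, wt2a):
        sim = g.SimulationConfig(seed=5, n_cells=3, sample_interval_ms=0.5)
        panel1 = g.generate_variant_panel([wt2a], sim)
        panel2 = g.generate_variant_panel([wt2a], sim)
        for key in panel1:
            pd.testing.assert_frame_equal(panel1[key], panel2[key])

    def test_different_seeds_differ(self, wt2a):
        a = g.generate_concentration_response(
            wt2a, g.SimulationConfig(seed=1, n_cells=1))
        b = g.generate_concentration_response(
            wt2a, g.SimulationConfig(seed=2, n_cells=1))
        assert not np.allclose(a[0].responses_pct, b[0].responses_pct)


class TestConcentrationResponse:
    def test_noise_off_equals_ideal_curve(self, wt2a_clean, sim):
        series = g.generate_concentration_response(wt2a_clean, sim,
                                                   "agonist", "glutamate")
        expected = g.hill_agonist_response(series[0].concentrations_um,
                                           3.5, wt2a_clean.hill_glu)
        np.testing.assert_allclose(series[0].responses_pct, expected)
        # half-maximal point sits at the EC50
        assert np.interp(3.5, series[0].concentrations_um,
                         series[0].responses_pct) == pytest.approx(50.0, abs=2.0)

    def test_inhibitor_mode_residual_at_saturation(self, sim):
        profile = g.get_preset("WT-GluN1/2A", cr_noise_cv=0.0,
                               ic50_mg=19.0, hill_mg=1.0)
        sim2 = g.SimulationConfig(seed=1, n_cells=1,
                                  concentration_series_um=[1.0, 10.0, 100.0,
                                                           1000.0])
        s = g.generate_concentration_response(profile, sim2, "inhibitor")[0]
        assert s.responses_pct[-1] == pytest.approx(1.864, abs=1e-3)

    def test_unknown_ligand_rejected(self, wt2a, sim):
        with pytest.raises(ValueError):
            g.generate_concentration_response(wt2a, sim, "agonist", "serine")


class TestTraces:
    def test_noise_off_round_trip_through_fit(self, wt2a_clean):
        sim = g.SimulationConfig(seed=0, sample_interval_ms=0.5)
        trace = g.generate_deactivation_trace(wt2a_clean, sim)
        fit = g.fit_deactivation(trace)
        assert fit.tau_fast == pytest.approx(30.0, rel=1e-2)
        assert fit.tau_slow == pytest.approx(100.0, rel=1e-2)
        assert fit.tau_weighted == pytest.approx(44.0, rel=1e-2)

    def test_single_exponential_when_frac_fast_is_one(self):
        profile = g.get_preset("WT-GluN1/2A", frac_fast=1.0, baseline_sd=0.0)
        sim = g.SimulationConfig(seed=0, sample_interval_ms=0.5)
        fit = g.fit_deactivation(g.generate_deactivation_trace(profile, sim))
        assert fit.tau_weighted == pytest.approx(profile.tau_fast, rel=1e-2)

    def test_rise_time_matches_configuration(self, wt2a_clean):
        sim = g.SimulationConfig(seed=0, sample_interval_ms=0.1,
                                 application_duration_ms=40.0,
                                 rise_time_10_90_ms=5.0)
        trace = g.generate_deactivation_trace(wt2a_clean, sim)
        assert g.rise_time_10_90(trace) == pytest.approx(5.0, abs=0.3)

    def test_undersampled_trace_rejected(self, wt2a):
        sim = g.SimulationConfig(seed=0, sample_interval_ms=40.0)
        with pytest.raises(ValueError, match="undersampled"):
            g.generate_deactivation_trace(wt2a, sim)

    def test_prolonged_application_desensitizes_to_plateau(self):
        profile = g.get_preset("WT-GluN1/2A", baseline_sd=0.05,
                               desens_plateau=0.5)
        sim = g.SimulationConfig(seed=3, sample_interval_ms=1.0)
        trace = g.generate_deactivation_trace(profile, sim, prolonged=True)
        assert g.desensitization_extent(trace) == pytest.approx(0.5, abs=0.05)


class TestMtsea:
    @pytest.mark.parametrize("po,expected", [(0.67, 1.0), (0.24, 2.792),
                                             (0.033, 20.3)])
    def test_noise_off_potentiation(self, po, expected):
        profile = g.get_preset("WT-GluN1/2A", po_max=po, noise_cv=0.0)
        pair = g.generate_mtsea_pair(profile, rng=0)
        assert pair.i_mtsea / pair.i_control == pytest.approx(expected, abs=2e-2)

    def test_round_trip_recovers_po(self):
        profile = g.get_preset("WT-GluN1/2A", noise_cv=0.0)
        pair = g.generate_mtsea_pair(profile, rng=0)
        assert g.open_probability(pair).value == pytest.approx(0.24, rel=1e-12)


class TestIVAndPanel:
    def test_noise_off_current_zero_at_reversal(self, wt2a_clean):
        sim = g.SimulationConfig(seed=0)
        fam = g.generate_iv_family(wt2a_clean, sim, "Na")
        assert fam.currents_na[np.isclose(fam.voltages_mv, 0.0)][0] == pytest.approx(0.0)
        vba, _ = g.estimate_reversal_potential(
            g.generate_iv_family(wt2a_clean, sim, "Ba"))
        assert vba == pytest.approx(12.1)

    def test_panel_csv_schemas(self, wt2a, tmp_path):
        sim = g.SimulationConfig(seed=2, n_cells=2, sample_interval_ms=1.0)
        panel = g.generate_variant_panel([wt2a], sim, out_dir=tmp_path)
        assert list(panel["cr_series"].columns) == [
            "cell_id", "construct_id", "ligand", "concentration_uM",
            "response_pct"]
        assert list(panel["mtsea"].columns) == [
            "construct_id", "cell_id", "i_control_nA", "i_mtsea_nA"]
        assert set(panel["iv"].solution) == {"Na", "Ba"}
        assert set(panel["expression"].compartment) == {"surface", "total"}
        for name in ("cr_series", "traces", "mtsea", "iv", "expression"):
            assert (tmp_path / f"{name}.csv").exists()


class TestParameterRecoveryBias:
    def test_median_relative_bias_below_5_percent(self):
        """Replicated noisy panels: the EC50, IC50, tau_w and P_open
        estimators are centred on the generating truth."""
        rng = np.random.default_rng(2024)
        profile = g.get_preset("WT-GluN1/2A")
        ec50s, ic50s, taus, pos = [], [], [], []
        for rep in range(12):
            sim = g.SimulationConfig(seed=int(rng.integers(2**31)), n_cells=6,
                                     sample_interval_ms=0.5)
            ec50s.append(g.fit_agonist(g.generate_concentration_response(
                profile, sim, "agonist", "glutamate")).potency_um)
            ic50s.append(g.fit_inhibitor(g.generate_concentration_response(
                profile, sim, "inhibitor")).potency_um)
            traces = g.generate_deactivation_panel(profile, sim, n_cells=6,
                                                   rng=rng)
            taus.append(np.mean([g.fit_deactivation(t).tau_weighted
                                 for t in traces]))
            pos.append(np.mean([g.open_probability(m).value for m in
                                g.generate_mtsea_panel(profile, 6, rng=rng)]))
        for est, truth in ((ec50s, 3.5), (ic50s, 19.0), (taus, 44.0),
                           (pos, 0.24)):
            assert abs(np.median(est) / truth - 1.0) < 0.05
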