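"""Polar decoding, tuning fits, congruency, ROC thresholds, lesions, weights."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from mscausal import characterization as chz
from mscausal import network
from mscausal.network import init_network
from mscausal.stats import bootstrap_ci, roc_area


class TestPolarGeometry:
    def test_three_four_five(self):
        rho, _ = chz.decode_polar(3.0, 4.0)
        assert rho == 5.0

    def test_zero_direction_convention(self):
        rho, phi = chz.decode_polar(0.0, 1.0)
        assert phi == 0.0  # arctan2(vx, vy) puts 0 deg on the +y argument
        rho, phi = chz.decode_polar(0.0, 0.0)
        assert rho == 0.0 and phi == 0.0

    def test_heading_axes(self):
        m = chz.heading_to_motion(0.0, 4.0)
        assert (m.vx, m.vy, m.vz, m.vr) == (0.0, 0.0, 4.0, 0.0)
        m = chz.heading_to_motion(90.0, 4.0)
        assert m.vx == pytest.approx(4.0) and m.vz == pytest.approx(0.0, abs=1e-12)
        m = chz.heading_to_motion(45.0, 4.0)
        assert m.vx == pytest.approx(2 * np.sqrt(2))
        assert m.vz == pytest.approx(2 * np.sqrt(2))

    def test_roundtrip_identity(self):
        for theta in (-135.0, -30.0, 0.0, 45.0, 120.0, 180.0):
            for speed in (0.5, 4.0):
                m = chz.heading_to_motion(theta, speed)
                rho, phi = chz.decode_polar(m.vx, m.vz)
                assert rho == pytest.approx(speed)
                assert phi == pytest.approx(theta)


class TestSinusoidFit:
    directions = chz.broad_directions(10)

    def test_exact_recovery(self):
        y = 2.0 * np.sin(np.radians(self.directions - 30.0)) + 1.0
        a, x_pref, b = chz.fit_sinusoid(self.directions, y)
        assert a == pytest.approx(2.0)
        assert x_pref == pytest.approx(30.0)
        assert b == pytest.approx(1.0)

    def test_noisy_recovery(self, rng):
        y = 2.0 * np.sin(np.radians(self.directions - 30.0)) + 1.0
        y = y + rng.normal(0, 0.01, size=y.shape)
        a, x_pref, b = chz.fit_sinusoid(self.directions, y)
        assert abs(x_pref - 30.0) < 1.0
        assert a == pytest.approx(2.0, rel=0.02)

    def test_constant_response_has_zero_amplitude(self):
        a, x_pref, b = chz.fit_sinusoid(self.directions, np.full(10, 3.3))
        assert a == 0.0 and np.isnan(x_pref) and b == pytest.approx(3.3)

    def test_too_few_directions_rejected(self):
        with pytest.raises(ValueError):
            chz.fit_sinusoid([0, 90, 180], [0, 1, 0])

    def test_amplitude_nonnegative_for_flipped_phase(self):
        y = -1.5 * np.sin(np.radians(self.directions - 10.0))
        a, x_pref, _ = chz.fit_sinusoid(self.directions, y)
        assert a == pytest.approx(1.5)
        assert x_pref == pytest.approx(190.0)


class TestPreferredDifferences:
    def _fits(self, prefs, amps):
        return pd.DataFrame(
            {"unit": np.arange(len(prefs)), "amplitude": amps, "x_pref": prefs}
        )

    def test_identical_tuning_lands_in_zero_bin(self):
        prefs = np.array([10.0, 50.0, 90.0, 130.0])
        amps = np.array([1.0, 2.0, 3.0, 4.0])
        hist = chz.preferred_difference_histogram(
            self._fits(prefs, amps), self._fits(prefs, amps)
        )
        assert hist.loc[hist["bin_lo"] == 0, "count"].iloc[0] == hist["count"].sum()

    def test_opposite_tuning_lands_in_180_bin(self):
        prefs = np.array([10.0, 50.0, 90.0, 130.0])
        amps = np.array([1.0, 2.0, 3.0, 4.0])
        hist = chz.preferred_difference_histogram(
            self._fits(prefs, amps), self._fits((prefs + 180) % 360, amps)
        )
        assert hist.loc[hist["bin_hi"] == 180, "count"].iloc[0] == hist["count"].sum()

    def test_circular_difference_wraps(self):
        assert chz.circular_difference(350.0, 10.0) == 20.0
        assert chz.circular_difference(0.0, 180.0) == 180.0


class TestCongruency:
    def _curve(self, cue, responses):
        return chz.TuningCurve(
            cue=cue, directions=chz.fine_directions(), responses=responses
        )

    def _responses_from_slope(self, slope, rng, noise=0.05):
        dirs = chz.fine_directions()
        resp = slope * dirs[:, None, None] + rng.normal(
            0, noise, size=(len(dirs), 30, 2)
        )
        return resp.astype(np.float32)

    def test_matched_slopes_are_congruent(self, rng):
        vest = self._curve("vestibular", self._responses_from_slope(0.5, rng))
        vis = self._curve("visual", self._responses_from_slope(0.8, rng))
        out = chz.congruency_index(vest, vis)
        assert (out["unit_class"] == "congruent").all()
        assert (out["congruency_index"] > 0.9).all()

    def test_opposed_slopes_are_opposite(self, rng):
        vest = self._curve("vestibular", self._responses_from_slope(0.5, rng))
        vis = self._curve("visual", self._responses_from_slope(-0.5, rng))
        out = chz.congruency_index(vest, vis)
        assert (out["unit_class"] == "opposite").all()
        assert (out["congruency_index"] < -0.9).all()

    def test_flat_response_is_intermediate_and_flagged(self, rng):
        vest = self._curve("vestibular", self._responses_from_slope(0.5, rng))
        flat = self._curve(
            "visual", np.zeros((10, 30, 2), np.float32)
        )
        out = chz.congruency_index(vest, flat)
        assert (out["unit_class"] == "intermediate").all()
        assert out["degenerate"].all()

    def test_classification_rule_arithmetic(self):
        # r_vest = 0.6 (significant), r_vis = -0.5 (significant) -> CI = -0.3
        assert chz.classify_from_correlations(0.6, 0.01, -0.5, 0.02) == "opposite"
        assert chz.classify_from_correlations(0.6, 0.01, -0.5, 0.2) == "intermediate"
        assert 0.6 * -0.5 == pytest.approx(-0.3)

    def test_classes_invariant_to_response_rescaling(self, rng):
        resp = self._responses_from_slope(0.5, rng)
        vest = self._curve("vestibular", resp)
        vis = self._curve("visual", self._responses_from_slope(0.7, rng))
        before = chz.congruency_index(vest, vis)["unit_class"]
        vest2 = self._curve("vestibular", 7.3 * resp)
        after = chz.congruency_index(vest2, vis)["unit_class"]
        assert (before == after).all()


class TestNeurometric:
    def test_optimal_integration_closed_forms(self):
        assert chz.predicted_threshold(3.0, 3.0) == pytest.approx(3.0 / np.sqrt(2))
        assert chz.predicted_threshold(3.0, 4.0) == pytest.approx(12.0 / 5.0)

    def test_prediction_never_exceeds_single_cue_thresholds(self, rng):
        for _ in range(200):
            sv, sw = rng.uniform(0.5, 50, 2)
            pred = chz.predicted_threshold(sv, sw)
            assert pred <= min(sv, sw) + 1e-12

    def test_roc_area_at_zero_direction_is_half(self, rng):
        x = rng.normal(0, 1, 500)
        y = rng.normal(0, 1, 500)
        assert roc_area(x, y) == pytest.approx(0.5, abs=0.06)
        assert roc_area(x, x) == 0.5  # identical samples: all ties

    def test_threshold_matches_analytic_ideal_observer(self, rng):
        # a unit responding theta + N(0, s) against its anti-unit has
        # neurometric function Phi(theta / (s/sqrt(2))): threshold s/sqrt(2)
        s = 12.0
        dirs = chz.fine_directions()
        resp = dirs[:, None, None] + rng.normal(0, s, size=(len(dirs), 400, 1))
        curve = chz.TuningCurve("visual", dirs, resp.astype(np.float32))
        areas = chz.neurometric_curve(curve)
        _, sigma_fit, ok = chz.fit_neurometric(dirs, areas[:, 0])
        assert ok
        assert sigma_fit == pytest.approx(s / np.sqrt(2), rel=0.10)

    def test_threshold_table_includes_prediction_and_ratio(self, rng):
        dirs = chz.fine_directions()
        def curve(s):
            r = dirs[:, None, None] + rng.normal(0, s, size=(len(dirs), 200, 1))
            return chz.TuningCurve("c", dirs, r.astype(np.float32))

        df = chz.neurometric_thresholds(
            {"vestibular": curve(15.0), "visual": curve(15.0), "combined": curve(10.0)}
        )
        assert np.isfinite(df["sigma_predicted"]).all()
        assert df["sigma_predicted"].iloc[0] <= min(
            df["sigma_vestibular"].iloc[0], df["sigma_visual"].iloc[0]
        )
        assert df["threshold_ratio"].iloc[0] == pytest.approx(
            df["sigma_combined"].iloc[0] / df["sigma_predicted"].iloc[0]
        )

    def test_untuned_unit_flagged_unresolvable(self, rng):
        dirs = chz.fine_directions()
        resp = rng.normal(0, 1, size=(len(dirs), 100, 1)).astype(np.float32)
        curve = chz.TuningCurve("visual", dirs, resp)
        df = chz.neurometric_thresholds({"vestibular": curve, "visual": curve})
        assert np.isnan(df["sigma_vestibular"]).all() or df["sigma_vestibular"].iloc[0] > 50


class TestWeightAndLesionToys:
    def _toy_params_and_classes(self):
        arch = network.Architecture(
            image_size=16, kernel_size=6, n_kernels=4, mt_units=8,
            pivc_units=4, mstd_units=4, vest_units=8,
        )
        p = init_network(0, "zero_fc", arch)
        p.out_w[:] = 0.0
        # units 0,1 congruent; 2,3 opposite (x axis)
        p.out_w[0, 0], p.out_w[1, 0] = 1.0, 3.0  # fusion x
        p.out_w[0, 4], p.out_w[1, 4] = -0.5, 0.5  # scission x
        p.out_w[2, 8], p.out_w[3, 8] = 2.0, 4.0  # causal x
        classes = pd.DataFrame(
            {
                "unit": [0, 1, 2, 3],
                "axis": ["x"] * 4,
                "unit_class": ["congruent", "congruent", "opposite", "opposite"],
                "pref_speed_visual": [1.0, 2.0, -1.0, -2.0],
                "pref_speed_vestibular": [1.0, 2.0, 1.0, 2.0],
            }
        )
        return p, classes

    def test_weight_summaries_hand_computed(self):
        p, classes = self._toy_params_and_classes()
        res = chz.weight_summaries(p, classes)
        s = res["summary"]
        assert s.loc["congruent", "abs_w_fusion"] == pytest.approx(2.0)  # (1+3)/2
        assert s.loc["congruent", "abs_w_scission"] == pytest.approx(0.5)
        assert s.loc["opposite", "w_causal"] == pytest.approx(3.0)  # (2+4)/2
        assert s.loc["congruent", "w_causal"] == pytest.approx(0.0)

    def test_all_zero_weights_give_zero_summaries(self):
        p, classes = self._toy_params_and_classes()
        p.out_w[:] = 0.0
        s = chz.weight_summaries(p, classes)["summary"]
        assert (s.to_numpy() == 0).all()

    def test_lesion_grid_size_and_identity(self, rng):
        p, classes = self._toy_params_and_classes()
        # make the network respond: pass-through vestibular stream
        p.pivc_w[:] = rng.normal(0, 0.3, p.pivc_w.shape)
        p.mstd_w[:] = rng.normal(0, 0.3, p.mstd_w.shape)
        cfg = chz.CharacterizationConfig(lesion_steps=5, map_trials=1, batch=64)
        res = chz.lesion_decoding_experiment(p, classes, 0, np.random.default_rng(0), cfg)
        assert res["n_cells"] == 25
        assert set(res["maps"]) == {
            (est, cond)
            for est in ("fusion", "scission")
            for cond in ("all", "congruent", "opposite")
        }
        full = chz.CharacterizationConfig(lesion_steps=31, map_trials=1, batch=512)
        # default grid: 31 linear steps -> 961 estimates
        assert np.linspace(-4, 4, full.lesion_steps).size**2 == 961

    def test_activity_map_errors_on_empty_class(self):
        p, classes = self._toy_params_and_classes()
        classes_no_opp = classes[classes["unit_class"] == "congruent"]
        with pytest.raises(ValueError, match="opposite"):
            chz.congruent_opposite_activity_map(
                p, classes_no_opp.rename(columns={}), np.random.default_rng(0)
            )


class TestAsymmetryCorrelations:
    def test_synthetic_asymmetry_drives_weights(self, rng):
        n = 40
        arch = network.Architecture(
            image_size=16, kernel_size=6, n_kernels=4, mt_units=8,
            pivc_units=4, mstd_units=n, vest_units=8,
        )
        p = init_network(0, "zero_fc", arch)
        a_vis = rng.uniform(0.5, 3.0, n)
        a_ves = rng.uniform(0.5, 3.0, n)
        asym = np.abs(a_vis - a_ves) / (a_vis + a_ves)
        p.out_w[:, 4] = asym * 2.0 + rng.normal(0, 0.05, n)  # x scission
        p.out_w[:, 6] = asym * 2.0 + rng.normal(0, 0.05, n)  # z scission
        fits_vis = pd.DataFrame(
            {"unit": np.arange(n), "amplitude": a_vis, "x_pref": 0.0}
        )
        fits_ves = pd.DataFrame(
            {"unit": np.arange(n), "amplitude": a_ves, "x_pref": 0.0}
        )
        classes = pd.DataFrame(
            {"unit": np.arange(n), "unit_class": "congruent"}
        )
        out = chz.asymmetry_correlations(
            p, classes, fits_vis, fits_ves, rng=rng, n_boot=500
        ).set_index("correlation")
        row = out.loc["congruent_asymmetry_vs_scission"]
        assert row["r"] > 0.8
        assert row["ci_lo"] > 0.5

    def test_degenerate_inputs_flagged(self):
        arch = network.Architecture(
            image_size=16, kernel_size=6, n_kernels=4, mt_units=8,
            pivc_units=4, mstd_units=4, vest_units=8,
        )
        p = init_network(0, "zero_fc", arch)
        fits = pd.DataFrame({"unit": [0, 1], "amplitude": [1.0, 1.0], "x_pref": 0.0})
        classes = pd.DataFrame({"unit": [0, 1], "unit_class": "congruent"})
        out = chz.asymmetry_correlations(p, classes, fits, fits).set_index("correlation")
        assert out.loc["congruent_asymmetry_vs_scission", "n"] == 2
        assert np.isnan(out.loc["congruent_asymmetry_vs_scission", "r"])


class TestBootstrap:
    def test_ci_coverage_on_gaussian_data(self):
        # the 95% percentile-bootstrap CI should contain the true mean in
        # roughly 95% of repetitions
        rng = np.random.default_rng(42)
        hits = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(1.0, 2.0, 40)
            lo, hi = bootstrap_ci(x, n_boot=800, rng=rng)
            hits += lo <= 1.0 <= hi
        assert hits / reps == pytest.approx(0.95, abs=0.03)
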