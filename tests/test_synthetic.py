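"""Generators: determinism, parameter recovery, and fault construction."""

import numpy as np
import pytest

import enzyval as ez
from enzyval.control_charts import ControlRule
from enzyval.synthetic import _rng


class TestReplicates:
    def test_same_seed_reproduces_bit_identical_series(self):
        profile = ez.DEFAULT_WINE_PROFILES[0]
        a1, m1 = ez.gen_replicates(profile, seed=5)
        a2, m2 = ez.gen_replicates(profile, seed=5)
        assert a1.values == a2.values and m1.values == m2.values
        a3, _ = ez.gen_replicates(profile, seed=6)
        assert a1.values != a3.values

    def test_zero_sd_yields_constant_series(self):
        profile = ez.WineProfile("flat", 3.0, 0.0, 3.1, 0.0)
        auto, manual = ez.gen_replicates(profile, seed=0)
        assert set(auto.values) == {3.0} and set(manual.values) == {3.1}

    def test_sweet_profile_means_recovered_within_clt_bound(self):
        """500 seeded datasets: the grand mean of per-dataset means sits
        within 3 standard errors of the generating means."""
        profile = next(p for p in ez.DEFAULT_WINE_PROFILES
                       if p.wine_id == "sweet")
        means_a, means_m = [], []
        for seed in range(500):
            auto, manual = ez.gen_replicates(profile, seed=seed)
            means_a.append(np.mean(auto.values))
            means_m.append(np.mean(manual.values))
        bound_a = 3 * profile.sd_auto / np.sqrt(500 * profile.n)
        bound_m = 3 * profile.sd_manual / np.sqrt(500 * profile.n)
        assert abs(np.mean(means_a) - profile.mean_auto) < bound_a
        assert abs(np.mean(means_m) - profile.mean_manual) < bound_m

    def test_substreams_are_independent_of_each_other(self):
        # drawing for one wine must not perturb another wine's stream
        p0, p1 = ez.DEFAULT_WINE_PROFILES[:2]
        a_only, _ = ez.gen_replicates(p0, seed=9)
        ez.gen_replicates(p1, seed=9)
        a_again, _ = ez.gen_replicates(p0, seed=9)
        assert a_only.values == a_again.values


class TestCalibrationGenerator:
    def test_zero_noise_recovers_truth_exactly(self):
        levels = ez.gen_calibration(slope=0.05, intercept=0.01, sigma=0.0)
        fit = ez.fit_calibration(levels)
        assert fit.slope == pytest.approx(0.05, abs=1e-12)
        assert fit.intercept == pytest.approx(0.01, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_default_noise_keeps_r_squared_near_unity(self):
        """At the default design the read noise is small against the signal;
        R^2 >= 0.995 in at least 95% of 200 seeded runs."""
        good = sum(
            ez.fit_calibration(ez.gen_calibration(seed=s)).r_squared >= 0.995
            for s in range(200)
        )
        assert good >= 190

    def test_least_squares_slope_is_unbiased(self):
        slopes = [
            ez.fit_calibration(ez.gen_calibration(seed=s)).slope
            for s in range(200)
        ]
        assert abs(np.mean(slopes) - 0.05) < 0.01 * 0.05


class TestControlGenerator:
    def test_spike_triggers_exactly_one_limit_flag(self):
        s = ez.gen_control_series(fault="spike", seed=3)
        flags = [f for f in ez.evaluate_rules(s)
                 if f.rule is ControlRule.BEYOND_LIMITS]
        assert len(flags) == 1

    def test_shift_triggers_same_side_run(self):
        s = ez.gen_control_series(fault="shift", seed=3)
        assert any(f.rule is ControlRule.SEVEN_SAME_SIDE
                   for f in ez.evaluate_rules(s))

    @pytest.mark.parametrize("fault,rule", [
        ("drift_up", ControlRule.SEVEN_ASCENDING),
        ("drift_down", ControlRule.SEVEN_DESCENDING),
    ])
    def test_drift_triggers_monotone_run(self, fault, rule):
        s = ez.gen_control_series(fault=fault, seed=3)
        assert any(f.rule is rule for f in ez.evaluate_rules(s))

    def test_in_control_false_positive_rate_matches_sign_run_theory(self):
        """With symmetric noise, a false same-side flag at length 20 depends
        only on the signs; the exact no-7-run probability from a run-length
        recursion (0.8849), times the simulated no-monotone-run factor
        (~0.995), predicts the observed clean-series rate."""
        def p_no_same_side_run(n, m=6):
            dp = {1: 2}
            for _ in range(n - 1):
                nd = {1: sum(dp.values())}
                for length, c in dp.items():
                    if length < m:
                        nd[length + 1] = nd.get(length + 1, 0) + c
                dp = nd
            return sum(dp.values()) / 2**n

        expected = p_no_same_side_run(20) * 0.995
        clean = sum(
            not ez.evaluate_rules(ez.gen_control_series(fault="none", seed=s))
            for s in range(400)
        ) / 400
        assert abs(clean - expected) < 0.05


class TestAbsorbanceGenerator:
    def test_zero_noise_roundtrip_recovers_concentrations(self, kit):
        gen = ez.gen_absorbances([2.0, 4.0, 6.0], kit=kit, sigma=0.0)
        for conc, reading in zip([2.0, 4.0, 6.0], gen["samples"]):
            out = ez.concentration_from_readings(
                reading, gen["blank"], gen["standard"], kit)
            assert out == pytest.approx(conc, abs=1e-9)

    def test_blank_honors_requested_a1_level(self, kit):
        gen = ez.gen_absorbances([1.0], kit=kit, blank_a1=0.123)
        assert gen["blank"].a1 == 0.123

    def test_recovery_error_scales_linearly_with_noise(self, kit):
        """Mean |concentration error| grows linearly in sigma with the error
        propagation factor C/span = 10 (g/L)/OD: the fitted slope equals
        10 * E|z| = 10*sqrt(2/pi) within a 3-sigma Monte-Carlo band, and the
        relationship is essentially exactly linear."""
        sigmas = np.array([0.001, 0.002, 0.003, 0.004, 0.005])
        mean_errs = []
        for sig in sigmas:
            errs = []
            for seed in range(100):
                gen = ez.gen_absorbances([3.0], kit=kit, sigma=sig, seed=seed)
                out = ez.concentration_from_readings(
                    gen["samples"][0], gen["blank"], gen["standard"], kit)
                errs.append(abs(out - 3.0))
            mean_errs.append(np.mean(errs))
        slope, intercept = np.polyfit(sigmas, mean_errs, 1)
        expected = 10.0 * np.sqrt(2 / np.pi)
        mc_band = 3 * 10.0 * np.sqrt(1 - 2 / np.pi) / np.sqrt(100)
        assert abs(slope - expected) < mc_band
        assert abs(intercept) < 1e-3
        corr = np.corrcoef(sigmas, mean_errs)[0, 1]
        assert corr > 0.999


def test_child_streams_are_deterministic_functions_of_tag():
    a = _rng(1, "x").standard_normal(3)
    b = _rng(1, "x").standard_normal(3)
    c = _rng(1, "y").standard_normal(3)
    assert np.allclose(a, b)
    assert not np.allclose(a, c)
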