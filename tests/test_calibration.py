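"""Calibration fitting, residual diagnostics, LOD/LOQ and the daily check."""

import numpy as np
import pytest

import enzyval as ez
from enzyval.calibration import CalibrationFit, LinearityThresholds
from enzyval.exceptions import InsufficientDataError, InvalidInputError


def make_levels(slope=0.1, intercept=0.0, sigma=0.0, reps=3, rng=None):
    rng = rng or np.random.default_rng(0)
    levels = []
    for x in ez.CALIBRATOR_LEVELS:
        noise = rng.standard_normal(reps) * sigma
        levels.append(ez.CalibrationLevel(x, tuple(intercept + slope * x + noise)))
    return levels


def ols_oracle(x, y):
    """Brute-force straight-line least squares via the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    se2 = np.sum(resid**2) / (n - 2)
    sa = np.sqrt(se2 * (1.0 / n + x.mean() ** 2 / sxx))
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    return slope, intercept, sa, np.sqrt(se2), r2


class TestFit:
    def test_noiseless_line_recovered_exactly(self):
        fit = ez.fit_calibration(make_levels(slope=0.1))
        assert fit.slope == pytest.approx(0.1, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n == 15

    def test_constant_responses_explain_nothing(self):
        levels = [ez.CalibrationLevel(x, (0.5, 0.5, 0.5))
                  for x in ez.CALIBRATOR_LEVELS]
        fit = ez.fit_calibration(levels)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0

    def test_too_few_distinct_levels_rejected(self):
        levels = [ez.CalibrationLevel(1.0, (0.1,)), ez.CalibrationLevel(2.0, (0.2,))]
        with pytest.raises(InsufficientDataError):
            ez.fit_calibration(levels)

    def test_noisy_fit_within_three_standard_errors_of_truth(self):
        rng = np.random.default_rng(7)
        fit = ez.fit_calibration(
            make_levels(slope=0.05, intercept=0.01, sigma=0.002, rng=rng))
        x = np.asarray(fit.x)
        sxx = np.sum((x - x.mean()) ** 2)
        se_slope = fit.residual_sd / np.sqrt(sxx)
        assert abs(fit.slope - 0.05) < 3 * se_slope
        assert abs(fit.intercept - 0.01) < 3 * fit.intercept_sd

    @pytest.mark.parametrize("seed", range(100))
    def test_agrees_with_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_levels = int(rng.integers(3, 7))
        xs = np.sort(rng.uniform(0.5, 10.0, n_levels))
        reps = int(rng.integers(1, 4))
        levels, pts_x, pts_y = [], [], []
        for x in xs:
            ys = 0.02 + 0.07 * x + rng.standard_normal(reps) * 0.005
            levels.append(ez.CalibrationLevel(float(x), tuple(ys)))
            pts_x += [x] * reps
            pts_y += list(ys)
        fit = ez.fit_calibration(levels)
        slope, intercept, sa, se, r2 = ols_oracle(pts_x, pts_y)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-12)
        if fit.n > 2:
            assert fit.intercept_sd == pytest.approx(sa, rel=1e-10, abs=1e-14)
            assert fit.residual_sd == pytest.approx(se, rel=1e-10, abs=1e-14)
        assert fit.r_squared == pytest.approx(r2, rel=1e-10)


class TestResidualDiagnostics:
    def test_noiseless_fit_has_all_zero_residual_flavors(self):
        fit = ez.fit_calibration(make_levels())
        for rec in fit.residuals:
            assert rec.absolute == pytest.approx(0.0, abs=1e-12)
            assert rec.normalized == pytest.approx(0.0, abs=1e-6)
            assert rec.standardized == pytest.approx(0.0, abs=1e-6)
            assert rec.studentized == pytest.approx(0.0, abs=1e-6)

    def test_least_squares_identities(self):
        fit = ez.fit_calibration(make_levels(sigma=0.01))
        assert sum(r.absolute for r in fit.residuals) == pytest.approx(0.0, abs=1e-9)
        assert sum(r.leverage for r in fit.residuals) == pytest.approx(2.0)

    def test_injected_gross_error_is_the_unique_flagged_outlier(self):
        sigma = 0.002
        rng = np.random.default_rng(3)
        xs = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        ys = [0.01 + 0.05 * x + rng.standard_normal() * sigma for x in xs]
        ys[2] += 10 * sigma
        fit = ez.fit_calibration(
            [ez.CalibrationLevel(x, (y,)) for x, y in zip(xs, ys)])
        flagged = [r.index for r in fit.residuals if abs(r.studentized) > 3]
        assert flagged == [2]

    def test_external_studentization_matches_leave_one_out_refit(self):
        rng = np.random.default_rng(11)
        fit = ez.fit_calibration(make_levels(sigma=0.004, rng=rng))
        x = np.asarray(fit.x)
        y = np.asarray(fit.y)
        for rec in fit.residuals[:5]:
            mask = np.arange(fit.n) != rec.index
            _, _, _, se_i, _ = ols_oracle(x[mask], y[mask])
            expected = rec.absolute / (se_i * np.sqrt(1 - rec.leverage))
            assert rec.studentized == pytest.approx(expected, rel=1e-8)

    def test_internal_and_external_studentization_converge_for_large_n(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 8, 200)
        y = 0.01 + 0.05 * x + rng.standard_normal(200) * 0.002
        levels = [ez.CalibrationLevel(float(xi), (float(yi),))
                  for xi, yi in zip(x, y)]
        fit = ez.fit_calibration(levels)
        rel = [
            abs(r.studentized - r.standardized) / abs(r.standardized)
            for r in fit.residuals if abs(r.standardized) > 0.2
        ]
        assert max(rel) < 0.05

    def test_small_designs_cannot_be_studentized(self):
        fit = CalibrationFit(slope=1, intercept=0, intercept_sd=0,
                             residual_sd=0, r_squared=1, n=3,
                             x=(1, 2, 3), y=(1, 2, 3))
        with pytest.raises(InsufficientDataError):
            ez.residual_diagnostics(fit)


class TestLinearityAssessment:
    def test_noiseless_line_passes_everything(self):
        report = ez.assess_linearity(ez.fit_calibration(make_levels()))
        assert report.verdict
        assert report.fraction_standardized_within_2 == 1.0
        assert report.outlier_indices == ()
        assert report.max_level_relative_deviation == pytest.approx(0.0, abs=1e-12)

    def test_gross_error_fails_with_outlier_flagged(self):
        sigma = 0.002
        rng = np.random.default_rng(3)
        xs = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        ys = [0.01 + 0.05 * x + rng.standard_normal() * sigma for x in xs]
        ys[2] += 10 * sigma
        fit = ez.fit_calibration(
            [ez.CalibrationLevel(x, (y,)) for x, y in zip(xs, ys)])
        report = ez.assess_linearity(fit)
        assert not report.verdict
        assert report.outlier_indices != ()

    def test_variance_growing_with_concentration_fails_homoskedasticity(self):
        rng = np.random.default_rng(2)
        levels = []
        for x in ez.CALIBRATOR_LEVELS:
            # SD proportional to concentration; 10 reads/level give the
            # |residual|-trend test power to detect it
            noise = rng.standard_normal(10) * (0.02 * x)
            levels.append(ez.CalibrationLevel(x, tuple(0.05 * x + noise)))
        report = ez.assess_linearity(ez.fit_calibration(levels))
        assert not report.homoskedasticity_pass

    def test_thresholds_are_tunable(self):
        fit = ez.fit_calibration(make_levels(sigma=0.001))
        strict = LinearityThresholds(max_level_relative_deviation=1e-12)
        assert not ez.assess_linearity(fit, strict).verdict


class TestDetectionLimits:
    def test_direct_arithmetic(self):
        fit = CalibrationFit(slope=0.1, intercept=0.0, intercept_sd=0.003,
                             residual_sd=0.003, r_squared=0.999, n=15,
                             x=(), y=())
        assert ez.lod(fit) == pytest.approx(0.09)
        assert ez.loq(fit) == pytest.approx(0.30)

    def test_zero_intercept_sd_gives_zero_limits(self):
        fit = ez.fit_calibration(make_levels())
        assert ez.lod(fit) == pytest.approx(0.0, abs=1e-10)
        assert ez.loq(fit) == pytest.approx(0.0, abs=1e-10)

    def test_loq_is_ten_thirds_of_lod(self):
        fit = ez.fit_calibration(make_levels(sigma=0.002))
        assert ez.loq(fit) / ez.lod(fit) == pytest.approx(10.0 / 3.0)

    def test_nonpositive_slope_rejected(self):
        fit = CalibrationFit(slope=0.0, intercept=0, intercept_sd=0.1,
                             residual_sd=0.1, r_squared=0, n=5, x=(), y=())
        with pytest.raises(InvalidInputError):
            ez.lod(fit)


class TestStandardCheck:
    def test_certified_standard_band_renders_378_422(self):
        check = ez.standard_check(4.0, nominal=4.0)
        assert (check.lower_rounded, check.upper_rounded) == (3.78, 4.22)
        assert check.passed

    def test_decision_uses_unrounded_bounds(self):
        assert not ez.standard_check(4.2241, nominal=4.0).passed
        assert ez.standard_check(3.7761, nominal=4.0).passed

    def test_center_always_passes(self):
        assert ez.standard_check(2.0, nominal=2.0).passed
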