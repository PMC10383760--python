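"""Calibration-line fitting and linearity diagnostics.

The assay calibrator carries five certified levels (0.90, 1.80, 3.60, 5.40,
7.20 g/L), each read in triplicate.  The calibration model is ordinary least
squares of the corrected 340 nm response on nominal concentration, with every
replicate read entering as its own point (n = 15 for the default design) so
that the intercept standard error Sa is estimated from genuine replication.

Diagnostics follow standard regression practice with four residual flavors:

* absolute residual        e_i  = y_i - yhat_i
* normalized residual      e_i / Se                       (Se = residual SD)
* standardized residual    e_i / (Se * sqrt(1 - h_i))     (internally studentized)
* studentized residual     e_i / (Se(i) * sqrt(1 - h_i))  (leave-one-out Se)

where h_i is the leverage of point i.  Under a correct model the studentized
residuals follow Student's t with n - h - 1 degrees of freedom (h = 2
parameters), which is what makes |e_S| > 3 a usable outlier screen.

Detection and quantification limits come from the calibration line itself:
LOD = 3*Sa/b and LOQ = 10*Sa/b with b the slope, so LOQ/LOD = 10/3 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from ._rounding import round_half_away
from .exceptions import InsufficientDataError, InvalidInputError

__all__ = [
    "CALIBRATOR_LEVELS",
    "CalibrationLevel",
    "ResidualRecord",
    "CalibrationFit",
    "LinearityThresholds",
    "LinearityAssessment",
    "AcceptabilityCheck",
    "fit_calibration",
    "residual_diagnostics",
    "assess_linearity",
    "lod",
    "loq",
    "standard_check",
]

#: Certified concentrations of the five-level commercial calibrator, g/L.
CALIBRATOR_LEVELS: tuple[float, ...] = (0.90, 1.80, 3.60, 5.40, 7.20)


@dataclass(frozen=True)
class CalibrationLevel:
    """One calibrator level: nominal concentration plus replicate responses."""

    nominal: float
    responses: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "responses", tuple(self.responses))
        if self.nominal <= 0:
            raise InvalidInputError("nominal concentration must be > 0")
        if len(self.responses) < 1:
            raise InsufficientDataError("each level needs at least one response")


@dataclass(frozen=True)
class ResidualRecord:
    """Per-point residual diagnostics for one calibration observation."""

    index: int
    x: float
    y: float
    fitted: float
    absolute: float       # e_i
    normalized: float     # e_i / Se
    standardized: float   # internally studentized
    studentized: float    # externally (leave-one-out) studentized
    leverage: float       # h_i


@dataclass(frozen=True)
class CalibrationFit:
    """Least-squares calibration line with replication-aware diagnostics."""

    slope: float
    intercept: float
    intercept_sd: float
    residual_sd: float
    r_squared: float
    n: int
    x: tuple[float, ...]
    y: tuple[float, ...]
    residuals: tuple[ResidualRecord, ...] = field(default=())

    def predict(self, concentration: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(concentration, dtype=float)


def _flatten(levels: Sequence[CalibrationLevel]) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for lvl in levels:
        for r in lvl.responses:
            xs.append(lvl.nominal)
            ys.append(float(r))
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


def fit_calibration(levels: Sequence[CalibrationLevel]) -> CalibrationFit:
    """OLS of response on nominal concentration over all replicate points.

    Requires at least three distinct calibrator levels.  ``intercept_sd`` is
    the standard error of the intercept; ``r_squared`` is the coefficient of
    determination, defined as 0 when the responses carry no variance at all
    (a flat line explains nothing).
    """
    distinct = {lvl.nominal for lvl in levels}
    if len(distinct) < 3:
        raise InsufficientDataError(
            f"calibration needs >= 3 distinct levels, got {len(distinct)}"
        )
    x, y = _flatten(levels)
    if np.ptp(x) == 0:
        raise InvalidInputError("zero variance in calibrator concentrations")

    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    se = float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(res.ssr) / ss_tot if ss_tot > 0 else 0.0

    fit = CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        intercept_sd=float(res.bse[0]),
        residual_sd=se,
        r_squared=r2,
        n=len(y),
        x=tuple(x),
        y=tuple(y),
    )
    if len(y) >= 4:
        fit = replace(fit, residuals=tuple(residual_diagnostics(fit)))
    return fit


def residual_diagnostics(fit: CalibrationFit) -> list[ResidualRecord]:
    """Absolute / normalized / standardized / studentized residuals + leverage.

    External studentization deletes each point in turn, so it needs
    n - h - 1 >= 1 residual degrees of freedom, i.e. at least 4 points for
    the straight-line model.
    """
    n = fit.n
    if n < 4:
        raise InsufficientDataError(
            "externally studentized residuals need at least 4 points"
        )
    x = np.asarray(fit.x)
    y = np.asarray(fit.y)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    influence = res.get_influence()
    h = influence.hat_matrix_diag
    e = res.resid
    se = float(np.sqrt(res.mse_resid))
    # a numerically perfect fit leaves Se at rounding level; the scaled
    # residual flavors are then 0/0 noise and are defined as zero
    scale = max(1.0, float(np.max(np.abs(y))))
    if se <= 1e-12 * scale:
        zeros = np.zeros(n)
        normalized = standardized = studentized = zeros
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            normalized = e / se
            standardized = np.asarray(influence.resid_studentized_internal)
            studentized = np.asarray(influence.resid_studentized_external)
        standardized = np.nan_to_num(standardized, nan=0.0)
        studentized = np.nan_to_num(studentized, nan=0.0)
    fitted = res.fittedvalues
    return [
        ResidualRecord(
            index=i, x=float(x[i]), y=float(y[i]), fitted=float(fitted[i]),
            absolute=float(e[i]), normalized=float(normalized[i]),
            standardized=float(standardized[i]), studentized=float(studentized[i]),
            leverage=float(h[i]),
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class LinearityThresholds:
    """Acceptance thresholds for the linearity assessment.

    ``fraction_standardized_within_2`` is the minimum share of standardized
    residuals expected inside +/-2 under normality; ``outlier_cutoff`` is the
    studentized-residual magnitude treated as a gross error; a per-level mean
    response must sit within ``max_level_relative_deviation`` of the fitted
    value; ``homoskedasticity_alpha`` is the significance level of the trend
    test of |e_i| on x_i.
    """

    fraction_standardized_within_2: float = 0.98
    outlier_cutoff: float = 3.0
    max_level_relative_deviation: float = 0.10
    homoskedasticity_alpha: float = 0.05


@dataclass(frozen=True)
class LinearityAssessment:
    r_squared: float
    fraction_standardized_within_2: float
    outlier_indices: tuple[int, ...]
    max_level_relative_deviation: float
    homoskedasticity_pass: bool
    verdict: bool


def assess_linearity(
    fit: CalibrationFit,
    thresholds: LinearityThresholds = LinearityThresholds(),
) -> LinearityAssessment:
    """Combine the four linearity checks into one pass/fail verdict.

    Passes iff (i) at least 98% of standardized residuals lie in [-2, 2],
    (ii) no studentized residual exceeds 3 in magnitude, (iii) the mean
    observed response at every calibrator level deviates from the fitted
    value by less than 10% (relative), and (iv) the magnitude of the
    residuals shows no significant trend with concentration (the
    homoskedasticity screen, replacing visual inspection of the absolute
    residual plot with a two-sided slope t-test).
    """
    records = fit.residuals if fit.residuals else tuple(residual_diagnostics(fit))
    standardized = np.array([r.standardized for r in records])
    studentized = np.array([r.studentized for r in records])
    frac = float(np.mean(np.abs(standardized) <= 2.0))
    outliers = tuple(
        int(r.index) for r in records
        if abs(r.studentized) > thresholds.outlier_cutoff
    )

    x = np.asarray(fit.x)
    max_dev = 0.0
    for level in np.unique(x):
        mask = x == level
        observed = float(np.mean(np.asarray(fit.y)[mask]))
        fitted = float(fit.predict(level))
        if fitted != 0:
            max_dev = max(max_dev, abs(observed - fitted) / abs(fitted))
        elif observed != 0:
            max_dev = np.inf

    abs_resid = np.abs([r.absolute for r in records])
    if np.ptp(abs_resid) == 0:
        homosked = True  # flat |residual| profile cannot trend
    else:
        trend = stats.linregress(x, abs_resid)
        homosked = bool(trend.pvalue >= thresholds.homoskedasticity_alpha)

    verdict = (
        frac >= thresholds.fraction_standardized_within_2
        and not outliers
        and max_dev < thresholds.max_level_relative_deviation
        and homosked
    )
    return LinearityAssessment(
        r_squared=fit.r_squared,
        fraction_standardized_within_2=frac,
        outlier_indices=outliers,
        max_level_relative_deviation=max_dev,
        homoskedasticity_pass=homosked,
        verdict=verdict,
    )


def lod(fit: CalibrationFit) -> float:
    """Limit of detection, ``3 * Sa / b`` in g/L (Sa = intercept SD, b = slope)."""
    if fit.slope <= 0:
        raise InvalidInputError("LOD requires a positive calibration slope")
    return 3.0 * fit.intercept_sd / fit.slope


def loq(fit: CalibrationFit) -> float:
    """Limit of quantification, ``10 * Sa / b`` in g/L; always (10/3) * LOD."""
    if fit.slope <= 0:
        raise InvalidInputError("LOQ requires a positive calibration slope")
    return 10.0 * fit.intercept_sd / fit.slope


@dataclass(frozen=True)
class AcceptabilityCheck:
    """Daily control-standard check against the C +/- 0.056*C band."""

    measured: float
    nominal: float
    lower: float
    upper: float
    lower_rounded: float
    upper_rounded: float
    passed: bool


def standard_check(
    measured: float,
    nominal: float = 4.0,
    repeatability_fraction: float = 0.056,
) -> AcceptabilityCheck:
    """Check a control-standard read against the acceptability band.

    The band is ``C +/- repeatability_fraction * C`` (for the certified
    4.0 g/L standard this renders as 3.78-4.22 g/L at two decimals).  The
    pass/fail decision uses the unrounded, inclusive bounds; the rounded
    bounds are reported for display only.
    """
    if nominal <= 0:
        raise InvalidInputError("nominal concentration must be > 0")
    half = repeatability_fraction * nominal
    lower, upper = nominal - half, nominal + half
    return AcceptabilityCheck(
        measured=measured,
        nominal=nominal,
        lower=lower,
        upper=upper,
        lower_rounded=round_half_away(lower, 2),
        upper_rounded=round_half_away(upper, 2),
        passed=lower <= measured <= upper,
    )
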