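"""Precision, uncertainty and method-equivalence statistics.

Given paired replicate series for one wine — ten concentrations measured by
the automated analyzer and ten by the manual reference procedure — this
module computes the full validation block:

* replicate mean and sample SD (n-1 denominator) per procedure;
* the repeatability limit ``r = 2*sqrt(2) * s_manual``, the largest absolute
  difference expected between two replicates of the reference procedure at
  95% coverage (2.8 * SD in ISO 5725 terms);
* the method-level repeatability limit ``r_M = 0.056 * C`` and
  reproducibility limit ``R_M = 0.12 + 0.076 * C``, both evaluated at the
  reference (manual) series mean C;
* the ratio ``r / r_M`` (observed vs. method-permitted repeatability);
* the holistic intra-laboratory uncertainty ``U = k * S_R`` with coverage
  factor k = 2 and the reproducibility standard deviation taken as
  ``S_R = R_M / sqrt(2)``, i.e. ``U = sqrt(2) * R_M``;
* per-method expanded uncertainties ``k * SD`` (k = 2);
* a two-sample mean-difference t test, and the suitability verdict.

The t statistic uses the convention

    t = |mean_manual - mean_auto| / sqrt((s_auto^2 + s_manual^2) / (n - 1))

with 2(n-1) degrees of freedom.  Note the n-1 (not n) in the denominator:
this is the convention of the validation protocol this package reproduces,
and it relates to the textbook equal-n pooled statistic by the exact factor
sqrt((n-1)/n).  Both conventions are available.

Suitability does not require statistical equality of the means.  A
significant difference is acceptable when it is smaller than the measurement
uncertainty at that concentration and the candidate (automated) method's
replicate SD is no worse than the reference's.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from math import sqrt
from typing import Sequence

import numpy as np
from scipy import stats

from ._rounding import format_p_value, round_half_away
from .exceptions import InsufficientDataError, InvalidInputError

__all__ = [
    "Procedure",
    "ReplicateSet",
    "TTestResult",
    "PrecisionReport",
    "replicate_stats",
    "repeatability_limit",
    "method_repeatability",
    "method_reproducibility",
    "uncertainty_holistic",
    "uncertainty_expanded",
    "two_sample_t",
    "suitability_verdict",
    "build_precision_report",
    "REPEATABILITY_FRACTION",
    "REPRODUCIBILITY_INTERCEPT",
    "REPRODUCIBILITY_SLOPE",
    "COVERAGE_FACTOR",
]

#: Method repeatability as a fraction of concentration: r_M = 0.056 * C.
REPEATABILITY_FRACTION = 0.056
#: Method reproducibility, affine in concentration: R_M = 0.12 + 0.076 * C.
REPRODUCIBILITY_INTERCEPT = 0.12
REPRODUCIBILITY_SLOPE = 0.076
#: Coverage factor for expanded uncertainties (~95% coverage).
COVERAGE_FACTOR = 2.0


class Procedure(str, Enum):
    AUTOMATED = "automated"
    MANUAL = "manual"


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate concentrations (g/L) for one wine under one procedure."""

    wine_id: str
    procedure: Procedure
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "procedure", Procedure(self.procedure))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.values) < 2:
            raise InsufficientDataError(
                f"replicate set '{self.wine_id}/{self.procedure.value}' needs "
                f"n >= 2, got {len(self.values)}"
            )
        if not all(np.isfinite(self.values)):
            raise InvalidInputError("replicate values must be finite")

    @property
    def n(self) -> int:
        return len(self.values)

    def scaled(self, c: float) -> "ReplicateSet":
        return ReplicateSet(self.wine_id, self.procedure,
                            tuple(c * v for v in self.values))


def replicate_stats(replicates: ReplicateSet) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator) of a replicate series."""
    v = np.asarray(replicates.values)
    return float(v.mean()), float(v.std(ddof=1))


def repeatability_limit(sd_reference: float) -> float:
    """Repeatability limit r = 2*sqrt(2) * SD of the reference series.

    The 95% bound on |difference of two replicates|: the difference of two
    iid measurements has SD sqrt(2)*s, and the coverage factor 2 gives
    2*sqrt(2)*s (~2.8s).
    """
    if sd_reference < 0:
        raise InvalidInputError("sd must be >= 0")
    return 2.0 * sqrt(2.0) * sd_reference


def method_repeatability(concentration: float) -> float:
    """Method-permitted repeatability r_M = 0.056 * C at concentration C (g/L)."""
    if concentration < 0:
        raise InvalidInputError("concentration must be >= 0")
    return REPEATABILITY_FRACTION * concentration


def method_reproducibility(concentration: float) -> float:
    """Method-permitted reproducibility R_M = 0.12 + 0.076 * C (g/L)."""
    if concentration < 0:
        raise InvalidInputError("concentration must be >= 0")
    return REPRODUCIBILITY_INTERCEPT + REPRODUCIBILITY_SLOPE * concentration


def uncertainty_holistic(method_reproducibility_limit: float) -> float:
    """Holistic intra-laboratory uncertainty U = sqrt(2) * R_M.

    Equivalent to U = k * S_R with coverage factor k = 2 and the
    reproducibility standard deviation identified from the method limit as
    S_R = R_M / sqrt(2).
    """
    if method_reproducibility_limit < 0:
        raise InvalidInputError("R_M must be >= 0")
    return sqrt(2.0) * method_reproducibility_limit


def uncertainty_expanded(sd: float, k: float = COVERAGE_FACTOR) -> float:
    """Expanded uncertainty k * SD for one method's replicate series."""
    if sd < 0:
        raise InvalidInputError("sd must be >= 0")
    return k * sd


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: int
    p_value: float
    t_critical: float
    significant: bool
    convention: str


def two_sample_t(
    auto: ReplicateSet,
    manual: ReplicateSet,
    alpha: float = 0.05,
    convention: str = "protocol",
) -> TTestResult:
    """Two-sample mean-difference t test between the paired replicate series.

    ``convention="protocol"`` (default) divides the summed variances by n-1,
    the convention of the validation protocol reproduced here;
    ``convention="classical"`` is the textbook equal-n pooled statistic
    (divide by n).  The two differ by the exact factor sqrt((n-1)/n); both
    use df = 2(n-1) and a two-sided test at level ``alpha``.
    """
    if auto.n != manual.n:
        raise InvalidInputError(
            f"equal replicate counts required, got {auto.n} and {manual.n}"
        )
    if convention not in ("protocol", "classical"):
        raise InvalidInputError("convention must be 'protocol' or 'classical'")
    n = auto.n
    mean_a, sd_a = replicate_stats(auto)
    mean_m, sd_m = replicate_stats(manual)
    denom_n = (n - 1) if convention == "protocol" else n
    pooled = sqrt((sd_a**2 + sd_m**2) / denom_n)
    df = 2 * (n - 1)
    if pooled == 0.0:
        t = 0.0 if mean_a == mean_m else float("inf")
    else:
        t = abs(mean_a - mean_m) / pooled
    p = float(2.0 * stats.t.sf(t, df))
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    return TTestResult(
        t_stat=float(t), df=df, p_value=p, t_critical=t_crit,
        significant=bool(t > t_crit), convention=convention,
    )


def suitability_verdict(
    mean_auto: float,
    mean_manual: float,
    sd_auto: float,
    sd_manual: float,
    uncertainty: float,
) -> tuple[bool, list[str]]:
    """Fitness-for-purpose verdict for the automated procedure.

    Suitable iff the absolute mean difference is below the holistic
    measurement uncertainty at that concentration AND the automated
    procedure's replicate SD is no larger than the reference's.  The t-test
    significance flag is reported separately and does not block suitability.
    """
    reasons: list[str] = []
    delta = abs(mean_auto - mean_manual)
    if delta < uncertainty:
        reasons.append(
            f"|mean difference| {delta:.4g} g/L is below the measurement "
            f"uncertainty {uncertainty:.4g} g/L"
        )
        delta_ok = True
    else:
        reasons.append(
            f"|mean difference| {delta:.4g} g/L reaches or exceeds the "
            f"measurement uncertainty {uncertainty:.4g} g/L"
        )
        delta_ok = False
    if sd_auto <= sd_manual:
        reasons.append(
            f"automated repeatability (SD {sd_auto:.4g}) is at least as good "
            f"as the reference's (SD {sd_manual:.4g})"
        )
        sd_ok = True
    else:
        reasons.append(
            f"automated repeatability (SD {sd_auto:.4g}) is worse than the "
            f"reference's (SD {sd_manual:.4g})"
        )
        sd_ok = False
    return delta_ok and sd_ok, reasons


@dataclass(frozen=True)
class PrecisionReport:
    """One wine's complete precision/equivalence block.

    All fields hold unrounded values; :meth:`to_rounded_dict` applies the
    reporting precision (3 decimals; the critical t value at 6).
    """

    wine_id: str
    n: int
    mean_auto: float
    mean_manual: float
    sd_auto: float
    sd_manual: float
    repeatability: float            # r = 2*sqrt(2)*sd_manual
    method_repeatability: float     # r_M = 0.056*C
    r_over_rm: float
    method_reproducibility: float   # R_M = 0.12 + 0.076*C
    uncertainty_holistic: float     # U = sqrt(2)*R_M
    uncertainty_auto: float         # 2*SD, from SD at reporting precision
    uncertainty_manual: float
    t_stat: float
    df: int
    p_value: float
    t_critical: float
    significant: bool
    suitable: bool
    reasons: tuple[str, ...]

    def to_rounded_dict(self, ndigits: int = 3) -> dict:
        r3 = lambda v: round_half_away(v, ndigits)
        return {
            "wine_id": self.wine_id,
            "n": self.n,
            "mean_auto": r3(self.mean_auto),
            "mean_manual": r3(self.mean_manual),
            "sd_auto": r3(self.sd_auto),
            "sd_manual": r3(self.sd_manual),
            "repeatability": r3(self.repeatability),
            "degrees_of_freedom": self.df,
            "method_repeatability": r3(self.method_repeatability),
            "r_over_rm": r3(self.r_over_rm),
            "method_reproducibility": r3(self.method_reproducibility),
            "uncertainty": r3(self.uncertainty_holistic),
            "uncertainty_auto": r3(self.uncertainty_auto),
            "uncertainty_manual": r3(self.uncertainty_manual),
            "t_experimental": r3(self.t_stat),
            "p": format_p_value(self.p_value),
            "t_critical": round_half_away(self.t_critical, 6),
            "significant": self.significant,
            "suitable": self.suitable,
        }


def build_precision_report(
    auto: ReplicateSet,
    manual: ReplicateSet,
    alpha: float = 0.05,
    t_convention: str = "protocol",
    reference_concentration: str = "manual_mean",
) -> PrecisionReport:
    """Assemble the full validation block for one wine.

    Every chained statistic uses unrounded intermediates, with one deliberate
    exception: the per-method expanded uncertainties (k * SD) take the SD at
    reporting precision (3 decimals), matching how summary certificates quote
    them.  ``reference_concentration`` selects which series' mean stands in
    for the concentration C in the method limits r_M and R_M: the manual
    (reference) series by default, ``"auto_mean"`` otherwise.
    """
    if auto.procedure is not Procedure.AUTOMATED:
        raise InvalidInputError("first argument must be the automated series")
    if manual.procedure is not Procedure.MANUAL:
        raise InvalidInputError("second argument must be the manual series")
    mean_a, sd_a = replicate_stats(auto)
    mean_m, sd_m = replicate_stats(manual)
    if reference_concentration == "manual_mean":
        c_ref = mean_m
    elif reference_concentration == "auto_mean":
        c_ref = mean_a
    else:
        raise InvalidInputError(
            "reference_concentration must be 'manual_mean' or 'auto_mean'"
        )
    r = repeatability_limit(sd_m)
    r_m = method_repeatability(c_ref)
    rep_m = method_reproducibility(c_ref)
    u_hol = uncertainty_holistic(rep_m)
    tt = two_sample_t(auto, manual, alpha=alpha, convention=t_convention)
    suitable, reasons = suitability_verdict(mean_a, mean_m, sd_a, sd_m, u_hol)
    return PrecisionReport(
        wine_id=auto.wine_id,
        n=auto.n,
        mean_auto=mean_a,
        mean_manual=mean_m,
        sd_auto=sd_a,
        sd_manual=sd_m,
        repeatability=r,
        method_repeatability=r_m,
        r_over_rm=r / r_m if r_m > 0 else float("nan"),
        method_reproducibility=rep_m,
        uncertainty_holistic=u_hol,
        uncertainty_auto=uncertainty_expanded(round_half_away(sd_a, 3)),
        uncertainty_manual=uncertainty_expanded(round_half_away(sd_m, 3)),
        t_stat=tt.t_stat,
        df=tt.df,
        p_value=tt.p_value,
        t_critical=tt.t_critical,
        significant=tt.significant,
        suitable=suitable,
        reasons=tuple(reasons),
    )
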