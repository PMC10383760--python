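"""Absorbance-to-concentration conversion for the hexokinase/G6PDH assay.

The enzymatic determination of glucose+fructose reads NADPH absorbance at
340 nm twice per cuvette: ``A1`` before the second reagent (hexokinase /
G6PDH) is added and ``A2`` after the reaction has run to completion.  The
response attributable to NADPH formation is the volume-corrected difference

    R = A2 - 0.84 * A1

and a sample concentration follows from single-point normalization against a
certified standard of concentration ``C``:

    [glucose+fructose] = (R_sample - R_blank) / (R_standard - R_blank) * C

Samples above the assay's linearity limit (8 g/L) are automatically diluted
by the analyzer according to a fixed factor table covering 0-160 g/L, and the
diluted read-back is multiplied by the factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from statistics import fmean
from typing import Callable, Sequence

from .exceptions import (
    DegenerateCalibrationError,
    InsufficientDataError,
    InvalidInputError,
    OutOfRangeError,
    UnresolvedDilutionError,
)

__all__ = [
    "Role",
    "Mode",
    "AssayReading",
    "KitParameters",
    "DilutionRule",
    "QuantResult",
    "DEFAULT_DILUTION_RULES",
    "corrected_response",
    "concentration_from_readings",
    "check_blank",
    "select_dilution",
    "quantify_with_autodilution",
    "mean_reading",
]


class Role(str, Enum):
    BLANK = "blank"
    STANDARD = "standard"
    SAMPLE = "sample"


class Mode(str, Enum):
    AUTOMATED = "automated"
    MANUAL = "manual"


@dataclass(frozen=True)
class AssayReading:
    """One cuvette/well: paired 340 nm absorbances and the reading's role.

    Parameters
    ----------
    a1 : float
        Optical density read before the second reagent is added (>= 0).
    a2 : float
        Optical density read after the enzymatic reaction (>= 0).
    role : Role
        Whether this cuvette holds the blank, the calibration standard, or a
        sample.
    label : str
        Free-text identifier carried through to reports.
    """

    a1: float
    a2: float
    role: Role
    label: str = ""

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise InvalidInputError(
                f"absorbances must be non-negative, got a1={self.a1}, a2={self.a2}"
            )
        object.__setattr__(self, "role", Role(self.role))


@dataclass(frozen=True)
class KitParameters:
    """Kit and analyzer constants for the glucose/fructose assay.

    ``correction_factor`` compensates for the volume change when the second
    reagent is added (0.84 for the standard kit geometry).  The two blank
    limits are the manufacturer's rejection thresholds for the reagent blank:
    0.300 OD on the automated analyzer, 0.500 OD for the manual kit.
    ``linearity_limit`` is the highest concentration the assay reads without
    dilution; ``standard_concentration`` is C of the normalization formula.
    """

    correction_factor: float = 0.84
    blank_limit_automated: float = 0.300
    blank_limit_manual: float = 0.500
    linearity_limit: float = 8.0
    standard_concentration: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 < self.correction_factor <= 1.0:
            raise InvalidInputError("correction_factor must be in (0, 1]")
        for name in ("blank_limit_automated", "blank_limit_manual",
                     "linearity_limit", "standard_concentration"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")

    def blank_limit(self, mode: Mode | str) -> float:
        mode = Mode(mode)
        return (self.blank_limit_automated if mode is Mode.AUTOMATED
                else self.blank_limit_manual)


@dataclass(frozen=True)
class DilutionRule:
    """One row of the analyzer's dilution table: [low, high) -> factor.

    Factor 0 means "no dilution" (multiplier 1); a positive factor f means the
    analyzer dilutes 1:f and multiplies the diluted read-back by f.  The top
    rule's upper bound is inclusive so that the full declared working range is
    tiled.
    """

    low: float
    high: float
    factor: int

    def __post_init__(self) -> None:
        if self.low >= self.high:
            raise InvalidInputError("rule requires low < high")
        if self.factor < 0:
            raise InvalidInputError("dilution factor must be >= 0")

    def contains(self, value: float, top: bool = False) -> bool:
        if top:
            return self.low <= value <= self.high
        return self.low <= value < self.high


#: The analyzer's built-in dilution table over the 0-160 g/L working range.
DEFAULT_DILUTION_RULES: tuple[DilutionRule, ...] = (
    DilutionRule(0.0, 8.0, 0),
    DilutionRule(8.0, 16.0, 2),
    DilutionRule(16.0, 32.0, 4),
    DilutionRule(32.0, 88.0, 11),
    DilutionRule(88.0, 160.0, 20),
)


@dataclass(frozen=True)
class QuantResult:
    """Outcome of one quantification, including QC flags.

    Negative concentrations (sample response below blank) are reported as-is
    with ``negative_flag`` set rather than clamped, so downstream statistics
    see the raw value.
    """

    concentration: float
    dilution_factor_applied: int
    blank_qc_pass: bool
    raw_ratio: float

    @property
    def negative_flag(self) -> bool:
        return self.concentration < 0


def corrected_response(reading: AssayReading, kit: KitParameters = KitParameters()) -> float:
    """NADPH response of one cuvette: ``A2 - correction_factor * A1``."""
    return reading.a2 - kit.correction_factor * reading.a1


def mean_reading(readings: Sequence[AssayReading]) -> AssayReading:
    """Average replicate reads of one cuvette (arithmetic mean of A1 and A2).

    Replicate absorbances (typically 3 reads per point) are averaged before
    response correction; the correction is linear so the order does not
    matter, but averaging first keeps one reading per cuvette downstream.
    """
    if not readings:
        raise InsufficientDataError("no readings to average")
    roles = {r.role for r in readings}
    if len(roles) != 1:
        raise InvalidInputError("cannot average readings with mixed roles")
    return AssayReading(
        a1=fmean(r.a1 for r in readings),
        a2=fmean(r.a2 for r in readings),
        role=readings[0].role,
        label=readings[0].label,
    )


def _require_role(reading: AssayReading, role: Role, slot: str) -> None:
    if reading.role is not role:
        raise InvalidInputError(
            f"{slot} slot requires a reading with role '{role.value}', "
            f"got '{reading.role.value}'"
        )


def concentration_from_readings(
    sample: AssayReading,
    blank: AssayReading,
    standard: AssayReading,
    kit: KitParameters = KitParameters(),
) -> float:
    """Single-point quantification against the certified standard.

    Returns ``(R_sample - R_blank) / (R_standard - R_blank) * C`` in g/L.
    Linear in the blank-subtracted sample response, so doubling
    ``R_sample - R_blank`` doubles the result.
    """
    _require_role(sample, Role.SAMPLE, "sample")
    _require_role(blank, Role.BLANK, "blank")
    _require_role(standard, Role.STANDARD, "standard")
    r_sample = corrected_response(sample, kit)
    r_blank = corrected_response(blank, kit)
    r_standard = corrected_response(standard, kit)
    denom = r_standard - r_blank
    if denom == 0.0:
        raise DegenerateCalibrationError(
            "standard response equals blank response; cannot normalize"
        )
    return (r_sample - r_blank) / denom * kit.standard_concentration


def check_blank(
    blank: AssayReading,
    mode: Mode | str,
    kit: KitParameters = KitParameters(),
    decision_absorbance: str = "a1",
) -> bool:
    """Blank QC: pass iff the decision absorbance does not exceed the mode's limit.

    The limit is inclusive (a blank at exactly 0.300/0.500 OD passes; only
    blanks *exceeding* the limit are rejected).  By default the decision is
    taken on A1, the pre-reaction read; set ``decision_absorbance="a2"`` for
    analyzers that gate on the post-reaction read.
    """
    _require_role(blank, Role.BLANK, "blank")
    if decision_absorbance not in ("a1", "a2"):
        raise InvalidInputError("decision_absorbance must be 'a1' or 'a2'")
    decision = getattr(blank, decision_absorbance)
    return decision <= kit.blank_limit(mode)


def select_dilution(
    measured: float,
    rules: Sequence[DilutionRule] = DEFAULT_DILUTION_RULES,
) -> int:
    """Look up the analyzer dilution factor for a first-pass measurement.

    Rules are lower-inclusive / upper-exclusive except the topmost, whose
    upper bound is inclusive.  Values above the table raise
    :class:`OutOfRangeError`.
    """
    if measured < 0:
        raise InvalidInputError("measured concentration must be >= 0")
    ordered = sorted(rules, key=lambda r: r.low)
    for i, rule in enumerate(ordered):
        if rule.contains(measured, top=(i == len(ordered) - 1)):
            return rule.factor
    raise OutOfRangeError(
        f"{measured} g/L is outside the method working range "
        f"[{ordered[0].low}, {ordered[-1].high}] g/L"
    )


def quantify_with_autodilution(
    first_pass: float,
    remeasure: Callable[[int], float],
    kit: KitParameters = KitParameters(),
    rules: Sequence[DilutionRule] = DEFAULT_DILUTION_RULES,
    blank_qc_pass: bool = True,
) -> QuantResult:
    """Emulate the analyzer's single automatic dilution pass.

    If the first-pass value is on-scale it is reported with factor 0.
    Otherwise the factor is chosen from the dilution table, ``remeasure`` is
    called exactly once with that factor, and the reported concentration is
    the diluted measurement times the factor.  One pass only: a diluted
    measurement still above the linearity limit raises
    :class:`UnresolvedDilutionError` rather than looping.
    """
    if first_pass < 0:
        raise InvalidInputError("first_pass must be >= 0")
    if first_pass <= kit.linearity_limit:
        return QuantResult(
            concentration=first_pass,
            dilution_factor_applied=0,
            blank_qc_pass=blank_qc_pass,
            raw_ratio=first_pass / kit.standard_concentration,
        )
    factor = select_dilution(first_pass, rules)
    multiplier = factor if factor > 0 else 1
    diluted = remeasure(factor)
    if diluted > kit.linearity_limit:
        raise UnresolvedDilutionError(
            f"diluted measurement {diluted} g/L still exceeds the "
            f"{kit.linearity_limit} g/L linearity limit at factor {factor}"
        )
    return QuantResult(
        concentration=diluted * multiplier,
        dilution_factor_applied=factor,
        blank_qc_pass=blank_qc_pass,
        raw_ratio=diluted / kit.standard_concentration,
    )
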