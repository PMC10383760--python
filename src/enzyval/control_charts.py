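"""Levey-Jennings control-chart engine for the certified control standard.

Every working session the 4.0 g/L certified multisugar standard is measured
and the result plotted around the center line (the nominal concentration)
with the acceptability band C +/- 0.056*C as chart limits.  Four run rules
signal loss of process control:

1. a point outside the acceptability limits (operator error, expired or
   badly stored control);
2. seven consecutive points strictly on one side of the center line
   (defective control kit);
3. seven consecutive strictly ascending points — positive drift (reagent
   aging, solvent evaporation from the standard);
4. seven consecutive strictly descending points — negative drift (standard
   or reagent obsolescence).

A point exactly on the center line breaks a same-side run, and equal
successive values break a monotone run.  A run longer than seven points
raises one flag, at the point that completes the first window of seven.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .calibration import standard_check
from .exceptions import InsufficientDataError, InvalidInputError

__all__ = [
    "ControlRule",
    "RuleFlag",
    "ControlSeries",
    "RULE_TEXT",
    "evaluate_rules",
    "in_control",
]

#: Points per run-rule window (7 points = 6 strict increases for a drift).
RUN_LENGTH = 7


class ControlRule(str, Enum):
    BEYOND_LIMITS = "beyond_limits"
    SEVEN_SAME_SIDE = "seven_same_side"
    SEVEN_ASCENDING = "seven_ascending"
    SEVEN_DESCENDING = "seven_descending"


#: Cause / decision text attached to each rule flag.
RULE_TEXT: dict[ControlRule, tuple[str, str]] = {
    ControlRule.BEYOND_LIMITS: (
        "The inexperience of the operator, expired check or incorrect "
        "conservation of the same.",
        "Repeat the analysis; if the point is within the limit of control "
        "continues, otherwise stop, locate, and resolve the cause.",
    ),
    ControlRule.SEVEN_SAME_SIDE: (
        "Defective kit control or incorrect conservation of the same",
        "If the eighth point falls on the side opposite to the line central "
        "continue, otherwise stop, locate, and resolve the cause.",
    ),
    ControlRule.SEVEN_ASCENDING: (
        "Obsolescence of reagents, progressive evaporation of solvent from "
        "the standard solution (positive drift)",
        "If the eighth point changes, the order continues; otherwise, stop, "
        "locate, and resolve the cause.",
    ),
    ControlRule.SEVEN_DESCENDING: (
        "Solution obsolescence, standards or reagents (negative drift)",
        "If the eighth point changes, the order continues; otherwise, stop, "
        "locate, and resolve the cause.",
    ),
}


@dataclass(frozen=True)
class RuleFlag:
    rule: ControlRule
    at_index: int
    possible_cause: str
    decision: str

    @classmethod
    def make(cls, rule: ControlRule, at_index: int) -> "RuleFlag":
        cause, decision = RULE_TEXT[rule]
        return cls(rule=rule, at_index=at_index,
                   possible_cause=cause, decision=decision)


@dataclass(frozen=True)
class ControlSeries:
    """Ordered control-standard measurements with chart limits.

    Limits default to the acceptability band of the center concentration
    (C +/- 0.056*C, the 3.78-4.22 g/L band for the 4.0 g/L standard); pass
    explicit ``lower``/``upper`` for sigma-based limits instead.
    """

    values: tuple[float, ...]
    center: float = 4.0
    lower: float | None = None
    upper: float | None = None
    indices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if not self.values:
            raise InsufficientDataError("control series is empty")
        if self.lower is None or self.upper is None:
            band = standard_check(self.center, nominal=self.center)
            if self.lower is None:
                object.__setattr__(self, "lower", band.lower)
            if self.upper is None:
                object.__setattr__(self, "upper", band.upper)
        if not self.lower < self.center < self.upper:
            raise InvalidInputError("require lower < center < upper")
        if self.indices is None:
            object.__setattr__(self, "indices", tuple(range(len(self.values))))
        else:
            idx = tuple(int(i) for i in self.indices)
            if len(idx) != len(self.values):
                raise InvalidInputError("indices and values length mismatch")
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise InvalidInputError("indices must be strictly increasing")
            object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.values)


def _run_flags(
    signs: Sequence[int],
    indices: Sequence[int],
    rule: ControlRule,
    run_length: int,
) -> list[RuleFlag]:
    """Flag each maximal run of +1s of length >= run_length, once, at the
    index completing its first window."""
    flags = []
    run = 0
    for i, s in enumerate(signs):
        run = run + 1 if s == 1 else 0
        if run == run_length:
            flags.append(RuleFlag.make(rule, indices[i]))
    # `run == run_length` fires exactly once per maximal run: extensions
    # push run past run_length without re-triggering.
    return flags


def evaluate_rules(
    series: ControlSeries,
    run_length: int = RUN_LENGTH,
) -> list[RuleFlag]:
    """Apply the four run rules; one flag per violation, in index order."""
    v = series.values
    idx = series.indices
    flags: list[RuleFlag] = [
        RuleFlag.make(ControlRule.BEYOND_LIMITS, idx[i])
        for i in range(len(v))
        if v[i] < series.lower or v[i] > series.upper
    ]
    above = [1 if x > series.center else 0 for x in v]
    below = [1 if x < series.center else 0 for x in v]
    flags += _run_flags(above, idx, ControlRule.SEVEN_SAME_SIDE, run_length)
    flags += _run_flags(below, idx, ControlRule.SEVEN_SAME_SIDE, run_length)
    # monotone runs: a window of k points needs k-1 strict steps; seed the
    # step sequence with one virtual run so point counts line up
    ups = [0] + [1 if b > a else 0 for a, b in zip(v, v[1:])]
    downs = [0] + [1 if b < a else 0 for a, b in zip(v, v[1:])]
    flags += _run_flags_steps(ups, idx, ControlRule.SEVEN_ASCENDING, run_length)
    flags += _run_flags_steps(downs, idx, ControlRule.SEVEN_DESCENDING, run_length)
    return sorted(flags, key=lambda f: (f.at_index, f.rule.value))


def _run_flags_steps(
    steps: Sequence[int],
    indices: Sequence[int],
    rule: ControlRule,
    run_length: int,
) -> list[RuleFlag]:
    """Like _run_flags but over step indicators: a monotone run of k points
    is k-1 consecutive strict steps, flagged at the run's run_length-th point."""
    flags = []
    run = 0
    for i, s in enumerate(steps):
        run = run + 1 if s == 1 else 0
        if run == run_length - 1:
            flags.append(RuleFlag.make(rule, indices[i]))
    return flags


def in_control(
    series: ControlSeries,
    run_length: int = RUN_LENGTH,
) -> tuple[bool, str]:
    """True with an empty note iff no rule fires; otherwise False with the
    prescribed corrective action for the first triggered rule."""
    flags = evaluate_rules(series, run_length=run_length)
    if not flags:
        return True, ""
    first = flags[0]
    return False, (
        f"{first.rule.value} at index {first.at_index}: {first.decision} "
        f"(possible cause: {first.possible_cause})"
    )
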