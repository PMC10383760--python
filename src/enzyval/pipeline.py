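"""End-to-end validation workflow: calibrate, quantify limits, compare
methods per wine, check process control, and issue one overall verdict.

``run_validation`` sequences the package's modules the way a validation
campaign does: fit and assess the calibration line, derive LOD/LOQ, build a
precision/equivalence block per wine from paired replicate series, evaluate
the control chart, and declare the automated procedure suitable only if
every wine's suitability criterion holds.  Inputs come from CSV files or,
where a file is not given, from the synthetic generators under a single
seed, so the full dossier can always be produced self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import calibration as cal
from . import control_charts as cc
from . import io as eio
from . import synthetic
from ._rounding import round_half_away
from .datasets import load_reference_sets
from .exceptions import EnzyvalError, InsufficientDataError
from .precision import Procedure, PrecisionReport, build_precision_report

__all__ = ["ValidationConfig", "ValidationDossier", "run_validation"]


@dataclass(frozen=True)
class ValidationConfig:
    """Inputs and options for one validation run.

    Any path left as None falls back to generated or bundled data: the
    bundled replicate certificates, a synthetic calibration at the default
    truth, and a synthetic in-control chart series.
    """

    calibration_csv: str | None = None
    replicates_csv: str | None = None
    control_csv: str | None = None
    seed: int = 0
    t_convention: str = "protocol"
    control_center: float = 4.0
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class ValidationDossier:
    """Machine-readable record of a full validation run."""

    calibration_fit: cal.CalibrationFit
    linearity: cal.LinearityAssessment
    lod: float
    loq: float
    precision_reports: tuple[PrecisionReport, ...]
    control_flags: tuple[cc.RuleFlag, ...]
    process_in_control: bool
    control_note: str
    overall_suitable: bool
    verdict_text: str

    def to_dict(self) -> dict[str, Any]:
        """Serialize at reporting precision, with unrounded values under
        ``raw``."""
        r3 = lambda v: round_half_away(float(v), 3)
        rounded = {
            "calibration": {
                "slope": r3(self.calibration_fit.slope),
                "intercept": r3(self.calibration_fit.intercept),
                "intercept_sd": round_half_away(self.calibration_fit.intercept_sd, 4),
                "r_squared": round_half_away(self.calibration_fit.r_squared, 4),
                "n": self.calibration_fit.n,
                "linearity_pass": self.linearity.verdict,
            },
            "lod_g_per_L": r3(self.lod),
            "loq_g_per_L": r3(self.loq),
            "wines": [rep.to_rounded_dict() for rep in self.precision_reports],
            "control_chart": {
                "in_control": self.process_in_control,
                "note": self.control_note,
                "flags": [
                    {"rule": f.rule.value, "at_index": f.at_index,
                     "decision": f.decision}
                    for f in self.control_flags
                ],
            },
            "overall_suitable": self.overall_suitable,
            "verdict": self.verdict_text,
        }
        rounded["raw"] = {
            "calibration": {
                "slope": self.calibration_fit.slope,
                "intercept": self.calibration_fit.intercept,
                "intercept_sd": self.calibration_fit.intercept_sd,
                "residual_sd": self.calibration_fit.residual_sd,
                "r_squared": self.calibration_fit.r_squared,
            },
            "lod_g_per_L": self.lod,
            "loq_g_per_L": self.loq,
            "wines": [
                {k: getattr(rep, k) for k in (
                    "wine_id", "n", "mean_auto", "mean_manual", "sd_auto",
                    "sd_manual", "repeatability", "method_repeatability",
                    "r_over_rm", "method_reproducibility",
                    "uncertainty_holistic", "uncertainty_auto",
                    "uncertainty_manual", "t_stat", "df", "p_value",
                    "t_critical", "significant", "suitable",
                )}
                for rep in self.precision_reports
            ],
        }
        return rounded


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except EnzyvalError as exc:
                raise EnzyvalError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("calibration")
def _load_calibration(config: ValidationConfig) -> list[cal.CalibrationLevel]:
    if config.calibration_csv is not None:
        return eio.read_calibration_csv(config.calibration_csv)
    return synthetic.gen_calibration(seed=config.seed)


@_stage("replicates")
def _load_replicates(config: ValidationConfig):
    if config.replicates_csv is not None:
        wines = eio.read_replicates_csv(config.replicates_csv)
        if not wines:
            raise InsufficientDataError(
                f"no replicate series found in {config.replicates_csv}"
            )
        return wines
    sets = load_reference_sets()
    return {
        wine: {Procedure.AUTOMATED: pair[0], Procedure.MANUAL: pair[1]}
        for wine, pair in sets.items()
    }


@_stage("control")
def _load_control(config: ValidationConfig) -> cc.ControlSeries:
    if config.control_csv is not None:
        return eio.read_control_csv(config.control_csv,
                                    center=config.control_center)
    return synthetic.gen_control_series(
        center=config.control_center, seed=config.seed
    )


def run_validation(config: ValidationConfig | dict | None = None) -> ValidationDossier:
    """Execute the full validation sequence and return the dossier.

    Deterministic for fixed inputs and seed.  Any stage failure is re-raised
    as :class:`EnzyvalError` naming the stage.
    """
    if config is None:
        config = ValidationConfig()
    elif isinstance(config, dict):
        config = ValidationConfig.from_dict(config)

    levels = _load_calibration(config)
    fit = cal.fit_calibration(levels)
    linearity = cal.assess_linearity(fit)
    lod_value = cal.lod(fit)
    loq_value = cal.loq(fit)

    replicates = _load_replicates(config)
    reports = []
    for wine, by_proc in replicates.items():
        if Procedure.AUTOMATED not in by_proc or Procedure.MANUAL not in by_proc:
            raise EnzyvalError(
                f"stage 'precision' failed: wine '{wine}' lacks one procedure"
            )
        reports.append(build_precision_report(
            by_proc[Procedure.AUTOMATED], by_proc[Procedure.MANUAL],
            alpha=config.alpha, t_convention=config.t_convention,
        ))

    series = _load_control(config)
    flags = tuple(cc.evaluate_rules(series))
    ok, note = cc.in_control(series)

    overall = all(r.suitable for r in reports)
    n_sig = sum(r.significant for r in reports)
    verdict = (
        f"Automated procedure {'SUITABLE' if overall else 'NOT SUITABLE'} "
        f"for the intended use: {sum(r.suitable for r in reports)}/"
        f"{len(reports)} wines meet the suitability criterion "
        f"({n_sig}/{len(reports)} show a statistically significant mean "
        f"difference, which does not preclude suitability when below the "
        f"measurement uncertainty)."
    )
    return ValidationDossier(
        calibration_fit=fit,
        linearity=linearity,
        lod=lod_value,
        loq=loq_value,
        precision_reports=tuple(reports),
        control_flags=flags,
        process_in_control=ok,
        control_note=note,
        overall_suitable=overall,
        verdict_text=verdict,
    )
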