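"""Synthetic data generators emulating the validation study's inputs.

No raw absorbances are distributed with assay kits, and replicate tables
live on paper certificates; every stage of the pipeline therefore has a
generator here that emulates its input's statistical structure:

* paired replicate series — independent Gaussian draws around per-wine,
  per-procedure means/SDs (the bundled profiles carry the study's four
  reference wines);
* calibration responses — a true line plus additive Gaussian read noise at
  each calibrator level;
* control-standard series — in-control Gaussian noise around the center
  line, optionally with an injected spike, sustained shift, or monotone
  drift, each constructed to trigger exactly its corresponding run rule;
* absorbance triplets — blank/standard/sample A1/A2 pairs built by inverting
  the single-point quantification formula, so that quantification recovers
  the requested concentrations exactly at zero noise.

Reproducibility: one integer seed governs everything; each generator derives
an independent child stream from (seed, operation-tag, index) via
``numpy.random.SeedSequence``, so adding draws to one generator never
perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calibration import CALIBRATOR_LEVELS, CalibrationLevel
from .control_charts import ControlSeries, RUN_LENGTH
from .exceptions import InvalidInputError
from .precision import Procedure, ReplicateSet
from .quantification import AssayReading, KitParameters, Role

__all__ = [
    "WineProfile",
    "SimulationSpec",
    "DEFAULT_WINE_PROFILES",
    "gen_replicates",
    "gen_calibration",
    "gen_control_series",
    "gen_absorbances",
]


def _rng(seed: int, tag: str, index: int = 0) -> np.random.Generator:
    """Deterministic child stream for (seed, operation tag, index)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(tag.encode()), int(index)])
    )


@dataclass(frozen=True)
class WineProfile:
    """Per-wine generating parameters: mean/SD per procedure, g/L."""

    wine_id: str
    mean_auto: float
    sd_auto: float
    mean_manual: float
    sd_manual: float
    n: int = 10

    def __post_init__(self) -> None:
        if self.sd_auto < 0 or self.sd_manual < 0:
            raise InvalidInputError("SDs must be >= 0")
        if self.n < 2:
            raise InvalidInputError("n must be >= 2")


#: The four reference wines of the validation study (summary statistics of
#: the replicate certificates, g/L).
DEFAULT_WINE_PROFILES: tuple[WineProfile, ...] = (
    WineProfile("dry_red", 2.623, 0.026, 2.417, 0.037),
    WineProfile("dry_white", 1.651, 0.013, 1.695, 0.048),
    WineProfile("moderately_sweet", 6.996, 0.052, 7.249, 0.089),
    WineProfile("sweet", 31.364, 0.485, 32.495, 0.874),
)


@dataclass(frozen=True)
class SimulationSpec:
    """Bundle of truth parameters for a full simulated validation run."""

    seed: int = 0
    profiles: tuple[WineProfile, ...] = DEFAULT_WINE_PROFILES
    calibration_slope: float = 0.05
    calibration_intercept: float = 0.01
    calibration_sigma: float = 0.002
    control_sigma: float = 0.04
    control_length: int = 20
    drift_per_index: float = 0.0
    shift_at_index: int | None = None
    shift_magnitude: float = 0.0


def gen_replicates(
    profile: WineProfile, seed: int = 0
) -> tuple[ReplicateSet, ReplicateSet]:
    """Draw paired (automated, manual) replicate series for one wine."""
    rng_a = _rng(seed, f"replicates/{profile.wine_id}/automated")
    rng_m = _rng(seed, f"replicates/{profile.wine_id}/manual")
    auto = profile.mean_auto + profile.sd_auto * rng_a.standard_normal(profile.n)
    manual = profile.mean_manual + profile.sd_manual * rng_m.standard_normal(profile.n)
    return (
        ReplicateSet(profile.wine_id, Procedure.AUTOMATED, tuple(auto)),
        ReplicateSet(profile.wine_id, Procedure.MANUAL, tuple(manual)),
    )


def gen_calibration(
    slope: float = 0.05,
    intercept: float = 0.01,
    sigma: float = 0.002,
    levels: Sequence[float] = CALIBRATOR_LEVELS,
    reps: int = 3,
    seed: int = 0,
) -> list[CalibrationLevel]:
    """Simulate triplicate calibrator reads on a true line plus read noise.

    Defaults emulate a realistic 340 nm response (slope 0.05 OD per g/L over
    the 0.9-7.2 g/L calibrator, per-read SD 0.002 OD, giving R^2 near 0.999
    at the default design).
    """
    if sigma < 0:
        raise InvalidInputError("sigma must be >= 0")
    rng = _rng(seed, "calibration")
    out = []
    for level in levels:
        noise = rng.standard_normal(reps) * sigma
        out.append(CalibrationLevel(
            nominal=level,
            responses=tuple(intercept + slope * level + noise),
        ))
    return out


def gen_control_series(
    center: float = 4.0,
    length: int = 20,
    sigma: float = 0.04,
    fault: str = "none",
    seed: int = 0,
    lower: float | None = None,
    upper: float | None = None,
) -> ControlSeries:
    """Simulate a control-standard series, optionally with one injected fault.

    ``sigma`` defaults to 1% of the 4.0 g/L standard, the automated
    analyzer's typical replicate SD at that level.  Faults are constructed to
    violate exactly their corresponding run rule:

    * ``"spike"`` — one mid-series point pushed beyond the upper limit;
    * ``"shift"`` — the last RUN_LENGTH points displaced upward by 3*sigma
      (clipped inside the limits) so they sit strictly above center;
    * ``"drift_up"`` / ``"drift_down"`` — the last RUN_LENGTH points replaced
      by a strictly monotone ramp inside the limits.
    """
    if length < 1:
        raise InvalidInputError("length must be >= 1")
    if fault not in ("none", "spike", "shift", "drift_up", "drift_down"):
        raise InvalidInputError(f"unknown fault kind: {fault}")
    rng = _rng(seed, f"control/{fault}")
    values = center + sigma * rng.standard_normal(length)
    series = ControlSeries(tuple(values), center=center, lower=lower, upper=upper)
    lo, hi = series.lower, series.upper

    if fault == "spike":
        i = length // 2
        values[i] = hi + max(3 * sigma, 0.1 * (hi - center) + 1e-9)
    elif fault == "shift":
        if length < RUN_LENGTH:
            raise InvalidInputError("shift fault needs length >= run length")
        tail = slice(length - RUN_LENGTH, length)
        shifted = np.abs(values[tail] - center) + center + 1e-6
        values[tail] = np.minimum(shifted, center + 0.9 * (hi - center))
    elif fault in ("drift_up", "drift_down"):
        if length < RUN_LENGTH:
            raise InvalidInputError("drift fault needs length >= run length")
        ramp = np.linspace(center - 0.8 * (center - lo),
                           center + 0.8 * (hi - center), RUN_LENGTH)
        if fault == "drift_down":
            ramp = ramp[::-1]
        values[length - RUN_LENGTH:] = ramp
    return ControlSeries(tuple(values), center=center, lower=lower, upper=upper)


def gen_absorbances(
    concentrations: Sequence[float],
    kit: KitParameters = KitParameters(),
    blank_a1: float = 0.05,
    sample_a1: float = 0.10,
    blank_response: float = 0.05,
    standard_span: float = 0.40,
    sigma: float = 0.0,
    seed: int = 0,
) -> dict:
    """Invert the quantification formula into consistent A1/A2 readings.

    Builds one blank, one standard at the kit's standard concentration, and
    one sample reading per requested concentration, such that the corrected
    responses satisfy

        R_sample = R_blank + (conc / C) * (R_standard - R_blank) + noise.

    ``standard_span`` is R_standard - R_blank in OD; ``sigma`` is additive
    Gaussian noise on each sample's corrected response (0 = exact
    round-trip).  Returns ``{"blank": ..., "standard": ..., "samples": [...]}``.
    """
    if kit.standard_concentration <= 0:
        raise InvalidInputError("standard concentration must be > 0")
    if standard_span == 0:
        raise InvalidInputError("standard span must be nonzero")
    rng = _rng(seed, "absorbances")
    cf = kit.correction_factor

    def reading(a1: float, response: float, role: Role, label: str) -> AssayReading:
        return AssayReading(a1=a1, a2=cf * a1 + response, role=role, label=label)

    blank = reading(blank_a1, blank_response, Role.BLANK, "blank")
    standard = reading(
        sample_a1, blank_response + standard_span, Role.STANDARD, "standard"
    )
    samples = []
    for j, conc in enumerate(concentrations):
        noise = float(rng.standard_normal()) * sigma if sigma > 0 else 0.0
        resp = blank_response + (conc / kit.standard_concentration) * standard_span
        samples.append(
            reading(sample_a1, resp + noise, Role.SAMPLE, f"sample_{j}")
        )
    return {"blank": blank, "standard": standard, "samples": samples}
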