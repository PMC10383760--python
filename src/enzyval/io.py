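"""CSV readers and writers for the pipeline's exchange formats.

All files are UTF-8 CSV with a header row and dot decimal separators:

* readings:     label, role, a1, a2
* calibration:  level_g_per_L, response          (one row per replicate read)
* replicates:   wine_id, procedure, replicate_index, value_g_per_L
* control:      index, measured_g_per_L
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .calibration import CalibrationLevel
from .control_charts import ControlSeries
from .exceptions import InvalidInputError
from .precision import Procedure, ReplicateSet
from .quantification import AssayReading

__all__ = [
    "read_readings_csv",
    "read_calibration_csv",
    "read_replicates_csv",
    "read_control_csv",
    "write_replicates_csv",
    "write_json",
]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{what} file is missing columns: {missing}")


def read_readings_csv(path: str | Path) -> list[AssayReading]:
    df = pd.read_csv(path)
    _require_columns(df, ["label", "role", "a1", "a2"], "readings")
    return [
        AssayReading(a1=float(r.a1), a2=float(r.a2), role=str(r.role),
                     label=str(r.label))
        for r in df.itertuples()
    ]


def read_calibration_csv(path: str | Path) -> list[CalibrationLevel]:
    df = pd.read_csv(path)
    _require_columns(df, ["level_g_per_L", "response"], "calibration")
    levels = []
    for nominal, grp in df.groupby("level_g_per_L", sort=True):
        levels.append(CalibrationLevel(
            nominal=float(nominal), responses=tuple(grp.response.astype(float))
        ))
    return levels


def read_replicates_csv(
    path: str | Path,
) -> dict[str, dict[Procedure, ReplicateSet]]:
    """Replicate table -> ``{wine_id: {procedure: ReplicateSet}}``."""
    df = pd.read_csv(path)
    _require_columns(
        df, ["wine_id", "procedure", "replicate_index", "value_g_per_L"],
        "replicates",
    )
    out: dict[str, dict[Procedure, ReplicateSet]] = {}
    for (wine, proc), grp in df.groupby(["wine_id", "procedure"], sort=False):
        grp = grp.sort_values("replicate_index")
        out.setdefault(str(wine), {})[Procedure(proc)] = ReplicateSet(
            str(wine), Procedure(proc), tuple(grp.value_g_per_L.astype(float))
        )
    return out


def read_control_csv(
    path: str | Path,
    center: float = 4.0,
    lower: float | None = None,
    upper: float | None = None,
) -> ControlSeries:
    df = pd.read_csv(path)
    _require_columns(df, ["index", "measured_g_per_L"], "control")
    df = df.sort_values("index")
    return ControlSeries(
        values=tuple(df.measured_g_per_L.astype(float)),
        center=center, lower=lower, upper=upper,
        indices=tuple(df["index"].astype(int)),
    )


def write_replicates_csv(
    sets: Sequence[ReplicateSet], path: str | Path
) -> None:
    rows = [
        {"wine_id": s.wine_id, "procedure": s.procedure.value,
         "replicate_index": i + 1, "value_g_per_L": v}
        for s in sets for i, v in enumerate(s.values)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
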