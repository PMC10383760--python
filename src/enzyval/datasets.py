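"""Bundled reference data: the validation study's replicate certificates.

The package ships the 80 replicate concentrations (4 wines x 2 procedures x
10 replicates, g/L) from the original validation campaign as a small CSV.
These are the golden inputs from which every precision, uncertainty and
equivalence statistic in the reference reports can be recomputed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .precision import Procedure, ReplicateSet

__all__ = ["WINE_ORDER", "load_reference_replicates", "load_reference_sets"]

#: Reference wines in ascending sugar order, as reported.
WINE_ORDER: tuple[str, ...] = (
    "dry_red", "dry_white", "moderately_sweet", "sweet",
)


def load_reference_replicates() -> pd.DataFrame:
    """The bundled replicate table as a tidy DataFrame.

    Columns: ``wine_id``, ``procedure``, ``replicate_index``,
    ``value_g_per_L``.
    """
    ref = resources.files("enzyval.data").joinpath("reference_replicates.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_reference_sets() -> dict[str, tuple[ReplicateSet, ReplicateSet]]:
    """Bundled replicates as ``{wine_id: (automated, manual)}`` pairs."""
    df = load_reference_replicates()
    out: dict[str, tuple[ReplicateSet, ReplicateSet]] = {}
    for wine in WINE_ORDER:
        pair = []
        for proc in (Procedure.AUTOMATED, Procedure.MANUAL):
            sub = df[(df.wine_id == wine) & (df.procedure == proc.value)]
            sub = sub.sort_values("replicate_index")
            pair.append(ReplicateSet(wine, proc, tuple(sub.value_g_per_L)))
        out[wine] = tuple(pair)
    return out
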