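"""Dataset schema and CSV round-tripping.

The single interchange format is a flat CSV with four culture-input
columns and six response columns:

    ce_pct, cf_pct, adding_day, harvest_day,
    dw_g_l, intra_ug_g, intra_ug_l, extra_ug_l, total_ug_l, portion_pct

Units: elicitor fractions in % v/v, days as culture days, dry weight in
g/l, paclitaxel in µg/g DW or µg/l, the extracellular portion in %.
Writers may stamp provenance as ``#``-prefixed comment lines before the
header; readers skip them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

INPUT_COLUMNS = ["ce_pct", "cf_pct", "adding_day", "harvest_day"]
RESPONSE_COLUMNS = [
    "dw_g_l",
    "intra_ug_g",
    "intra_ug_l",
    "extra_ug_l",
    "total_ug_l",
    "portion_pct",
]
DATASET_COLUMNS = INPUT_COLUMNS + RESPONSE_COLUMNS

RESPONSE_LABELS = {
    "dw_g_l": "Dry weight (g/l)",
    "intra_ug_g": "Intracellular paclitaxel (ug/g DW)",
    "intra_ug_l": "Intracellular paclitaxel (ug/l)",
    "extra_ug_l": "Extracellular paclitaxel (ug/l)",
    "total_ug_l": "Total yield of paclitaxel (ug/l)",
    "portion_pct": "Extracellular paclitaxel portion (%)",
}

INPUT_LABELS = {
    "ce_pct": "CE concentration level",
    "cf_pct": "CF concentration level",
    "adding_day": "Adding day",
    "harvest_day": "Harvest time",
}


class SchemaError(ValueError):
    """A dataset file violates the documented schema."""


def validate_dataset(df: pd.DataFrame, require_responses: bool = True) -> pd.DataFrame:
    """Check column presence, numeric dtype and finiteness.

    Returns the frame with columns in canonical order.  Errors name the
    offending column (and row, for value problems).
    """
    required = DATASET_COLUMNS if require_responses else INPUT_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = df[required].copy()
    for col in required:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))
        if bad.size:
            raise SchemaError(
                f"column {col!r} has non-numeric or missing values "
                f"(first offending row index: {bad[0]})"
            )
        out[col] = vals.astype(float)
    return out


def read_dataset(path: str | Path, require_responses: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    return validate_dataset(df, require_responses=require_responses)


def write_dataset(
    df: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    df = validate_dataset(df, require_responses=all(c in df.columns for c in RESPONSE_COLUMNS))
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False, lineterminator="\n")
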