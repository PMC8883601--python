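"""Reading and writing the standard recall delimited-text format.

One strict schema: comma-separated, UTF-8, "." decimal separator, required
header ``id,age_years,sex,pregnant,day,calcium_mg[,water_l][,weight]``.
``water_l`` and ``weight`` are optional columns; an empty ``water_l`` cell
means "not reported" (NaN), never zero. Validation failures name the
offending file lines (1-based, header is line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_recalls", "write_recalls", "RECALL_SCHEMA"]

RECALL_SCHEMA = ["id", "age_years", "sex", "pregnant", "day", "calcium_mg",
                 "water_l", "weight"]
_REQUIRED = RECALL_SCHEMA[:6]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_pregnant(col: pd.Series) -> pd.Series:
    s = col.astype(str).str.strip().str.lower()
    bad = ~s.isin(_TRUE | _FALSE)
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()
        raise ValueError(f"unparseable 'pregnant' values at lines {lines[:10]}")
    return s.isin(_TRUE)


def read_recalls(path: str | Path) -> pd.DataFrame:
    """Read and validate a recall file into the standard frame."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str, "sex": str, "pregnant": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing mandatory columns {missing}")

    df["pregnant"] = _parse_pregnant(df["pregnant"])
    df["sex"] = df["sex"].str.strip().str.lower()
    bad_sex = ~df["sex"].isin(["female", "male"])
    if bad_sex.any():
        raise ValueError(
            f"{path.name}: sex must be female/male at lines "
            f"{(np.flatnonzero(bad_sex) + 2).tolist()[:10]}"
        )

    for col, lo_ok in (("calcium_mg", False), ("age_years", True)):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0 if lo_ok else vals <= 0)
        if bad.any():
            lines = (np.flatnonzero(bad) + 2).tolist()
            raise ValueError(
                f"{path.name}: invalid {col} (must be "
                f"{'>= 0' if lo_ok else '> 0'}) at lines {lines[:10]}"
            )
        df[col] = vals

    dup = df.duplicated(subset=["id", "day"], keep=False)
    if dup.any():
        lines = (np.flatnonzero(dup) + 2).tolist()
        raise ValueError(f"{path.name}: duplicate (id, day) at lines {lines[:10]}")

    if "water_l" not in df.columns:
        df["water_l"] = np.nan
    else:
        df["water_l"] = pd.to_numeric(df["water_l"], errors="coerce")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    else:
        df["weight"] = pd.to_numeric(df["weight"], errors="coerce").fillna(1.0)

    return df[RECALL_SCHEMA]


def write_recalls(records: pd.DataFrame, path: str | Path) -> None:
    """Write records in the canonical format (round-trips through read_recalls)."""
    out = records.copy()
    out["pregnant"] = out["pregnant"].map({True: "true", False: "false"})
    out[RECALL_SCHEMA].to_csv(path, index=False, float_format="%.10g")
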