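"""Readers/writers for the tidy CSV dataset schemas of the study.

Eleven schemas (S1–S11) cover per-individual development records, tray-level
survival, per-female fecundity/winglength, tray-level productivity, and the
per-image regional preference/density tables.  Reading validates the column
set and applies unit checks (percentages in 0–100, proportions in 0–1,
positive development times); writing round-trips value-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """CSV does not conform to the requested dataset schema."""


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str = "any"  # any | numeric | percent | proportion | positive | nonnegative


def _cols(*specs) -> tuple[ColumnSpec, ...]:
    out = []
    for s in specs:
        if isinstance(s, str):
            out.append(ColumnSpec(s))
        else:
            out.append(ColumnSpec(*s))
    return tuple(out)


#: Column schemas keyed by dataset id.
SCHEMAS: dict[str, tuple[ColumnSpec, ...]] = {
    # density experiment: per-individual emergence day
    "S1": _cols("ID", "Container", "Density", "Number", ("Day", "positive")),
    # density experiment: tray-level larva-to-adult survival (%)
    "S2": _cols("Size", "Density", "Replicate", "Tray", ("LA", "percent")),
    # density experiment: per-female winglength (mm) and first-clutch eggs
    "S3": _cols("Size", "Density", "Replicate", ("MM", "positive"),
                ("Fecundity", "nonnegative")),
    # density experiment: tray-level productivity
    "S4": _cols("Size", "Density", "Replicate", ("Fecundity", "nonnegative"),
                ("Hatch", "percent"), ("Survival", "proportion"),
                ("Development", "positive"), ("PI", "numeric")),
    # diet experiment counterparts
    "S5": _cols("ID", "Size", "Diet", "Tray", "Replicate", ("Day", "positive")),
    "S6": _cols("Size", "Diet", "Replicate", "Tray", ("LA", "percent")),
    "S7": _cols("Size", "Diet", "Number", "Replicate", ("MM_Size", "positive"),
                ("Fecundity", "nonnegative")),
    "S8": _cols("Size", "Diet", "Tray", "Replicate", ("Fecundity", "nonnegative"),
                ("Hatch", "percent"), ("Survival", "proportion"),
                ("Development", "positive"), ("PI", "numeric")),
    # imaging: per-image, per-region preference and density (long form)
    "S9": _cols("ID", "Replicate", "Size", "Density", "Treatment", "Interval",
                "region", ("larper", "percent"), ("larml", "nonnegative")),
    # imaging: daily averages (wide form)
    "S10": _cols("ID", "Replicate", "Size", "Density", "Treat", "Interval",
                 ("Elarper", "percent"), ("Mlarper", "percent"),
                 ("Clarper", "percent"), ("Elarml", "nonnegative"),
                 ("Mlarml", "nonnegative"), ("Clarml", "nonnegative")),
    # imaging: repeatability table (per-photo area fractions and metrics)
    "S11": _cols("Size", "Density", "Replicate", "replicate1", "ID", "ID2", "Date",
                 ("edge", "percent"), ("intermediate", "percent"),
                 ("central", "percent"), ("total_coverage", "percent"),
                 ("eper", "percent"), ("mper", "percent"), ("cper", "percent"),
                 ("eml", "nonnegative"), ("mml", "nonnegative"),
                 ("cml", "nonnegative")),
}


def _check_units(df: pd.DataFrame, spec: ColumnSpec) -> None:
    if spec.kind == "any":
        return
    col = pd.to_numeric(df[spec.name], errors="coerce")
    if col.isna().any() and df[spec.name].notna().any():
        bad = df[spec.name][col.isna() & df[spec.name].notna()]
        raise SchemaError(f"column {spec.name!r} has non-numeric values: {list(bad[:3])}")
    vals = col.dropna()
    checks = {
        "percent": ((vals >= 0) & (vals <= 100), "in [0, 100]"),
        "proportion": ((vals >= 0) & (vals <= 1), "in [0, 1]"),
        "positive": (vals > 0, "> 0"),
        "nonnegative": (vals >= 0, "'>= 0'"),
        "numeric": (pd.Series(True, index=vals.index), ""),
    }
    ok, expect = checks[spec.kind]
    if not ok.all():
        offending = vals[~ok]
        raise SchemaError(
            f"unit violation in column {spec.name!r}: expected values {expect}, "
            f"found e.g. {offending.iloc[0]!r}"
        )


def read_dataset(path, schema_id: str) -> pd.DataFrame:
    """Read and validate a CSV against one of the S1–S11 schemas."""
    if schema_id not in SCHEMAS:
        raise SchemaError(f"unknown schema id {schema_id!r}")
    spec = SCHEMAS[schema_id]
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    expected = [c.name for c in spec]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        extra = [c for c in df.columns if c not in expected]
        raise SchemaError(
            f"{path}: schema {schema_id} mismatch; missing columns {missing}"
            + (f", unexpected columns {extra}" if extra else "")
        )
    for s in spec:
        _check_units(df, s)
    # put schema columns first, preserving any extras
    extras = [c for c in df.columns if c not in expected]
    return df[expected + extras]


def write_dataset(df: pd.DataFrame, path, schema_id: str) -> None:
    """Validate a table against a schema and write it as CSV."""
    if schema_id not in SCHEMAS:
        raise SchemaError(f"unknown schema id {schema_id!r}")
    expected = [c.name for c in SCHEMAS[schema_id]]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write schema {schema_id}: missing columns {missing}")
    for s in SCHEMAS[schema_id]:
        _check_units(df, s)
    df.to_csv(path, index=False)


def crosscheck_pi(df: pd.DataFrame, formula: str = "ln100fs", atol: float = 1e-6) -> pd.DataFrame:
    """Recompute PI from a productivity-schema table and compare to its PI column.

    Returns rows where the recomputed value differs by more than ``atol``
    (empty frame = full agreement).
    """
    from .lifehistory import productivity_table

    recomputed, errors = productivity_table(df, formula=formula)
    if errors:
        raise SchemaError(f"rows with invalid F/S/D: {errors}")
    delta = np.abs(recomputed["PI"].to_numpy(dtype=float)
                   - df["PI"].to_numpy(dtype=float))
    out = df.loc[delta > atol].copy()
    out["PI_recomputed"] = recomputed.loc[delta > atol, "PI"]
    return out
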