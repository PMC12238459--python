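"""Bundled reference tables (transcribed published values) and ingest of
user-supplied reference CSV / XLSX files for comparison reports."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "load_organ_masses",
    "load_sphere_self_svalues",
    "load_bm_comparison",
    "read_reference_csv",
]


def _bundled(name: str) -> pd.DataFrame:
    path = resources.files("voxdose.data.reference").joinpath(name)
    with path.open() as fh:
        return pd.read_csv(fh, comment="#")


def load_organ_masses() -> pd.DataFrame:
    """Organ masses: reference 25 g mouse vs the LR/HR phantom builds (g, %)."""
    return _bundled("organ_masses.csv")


def load_sphere_self_svalues(resolution: str | None = None) -> pd.DataFrame:
    """Unit-density sphere self-dose S-values (Gy MBq^-1 s^-1) by mass."""
    df = _bundled("sphere_self_svalues.csv")
    if resolution is not None:
        df = df[df["resolution"] == resolution.lower()].reset_index(drop=True)
    return df


def load_bm_comparison() -> pd.DataFrame:
    """Bone-marrow-targeted S-value comparison set (Gy Bq^-1 s^-1)."""
    return _bundled("bm_svalues_comparison.csv")


def read_reference_csv(path, required: tuple = ("source", "target", "s_reference")) -> pd.DataFrame:
    """Read a user reference table, validating required columns.

    Raises ValueError naming offending rows for malformed numeric fields.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"reference table {path} missing columns {missing}")
    bad_rows = []
    for col in df.columns:
        if col in ("source", "target", "organ", "resolution"):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        bad_rows.extend((col, i + 2) for i in bad)  # +2: header + 1-basing
        df[col] = coerced
    if bad_rows:
        raise ValueError(
            "malformed reference values at "
            + ", ".join(f"{c} row {r}" for c, r in bad_rows)
        )
    return df
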