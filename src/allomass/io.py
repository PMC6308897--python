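"""Reading and writing morphometric and result tables.

CSV dialect: UTF-8, comma-separated, ``.`` decimal separator, header
required. The morphometric header is
``individual_id,taxon,family,region,length_mm,width_mm,mass_mg`` with an
optional trailing ``is_larva`` column; empty cells mean "absent". Output
files are deterministic (fixed column order, explicit precision, no
timestamps) and are written atomically: a failed run never leaves a partial
file in place.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .records import REGIONS, normalize_name

MORPHOMETRIC_COLUMNS = [
    "individual_id", "taxon", "family", "region", "length_mm", "width_mm", "mass_mg",
]

#: Columns holding masses in mg; serialized at 4 significant figures.
_MASS_COLUMNS = ("mass_mg", "mass_pred_mg")


@dataclass
class MorphometricTable:
    """An ordered collection of morphometric records plus provenance."""

    df: pd.DataFrame
    source: str = "<memory>"
    filter_log: list[str] = field(default_factory=list)
    database_version: str | None = None

    def __len__(self) -> int:
        return len(self.df)


def read_morphometric_csv(path: str | Path) -> MorphometricTable:
    """Parse a morphometric CSV, rejecting malformed rows with line numbers.

    Raises :class:`FormatError` on a malformed header, a nonnumeric or
    nonpositive measurement (reported with its row number), a region outside
    the controlled vocabulary, or duplicated individual ids.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    got = list(df.columns)
    if got[: len(MORPHOMETRIC_COLUMNS)] != MORPHOMETRIC_COLUMNS or got not in (
        MORPHOMETRIC_COLUMNS,
        MORPHOMETRIC_COLUMNS + ["is_larva"],
    ):
        raise FormatError(
            f"{path}: header {got} does not match the morphometric dialect "
            f"{MORPHOMETRIC_COLUMNS} (+ optional is_larva)"
        )

    errors: list[str] = []

    def parse_float(col: str, positive: bool) -> pd.Series:
        raw = df[col].str.strip()
        out = pd.Series(np.nan, index=df.index, dtype=float)
        for i, v in raw.items():
            if v == "":
                continue
            try:
                x = float(v)
            except ValueError:
                errors.append(f"row {i + 2}: nonnumeric {col} {v!r}")
                continue
            if positive and not x > 0:
                errors.append(f"row {i + 2}: {col} must be > 0, got {v}")
                continue
            out.loc[i] = x
        return out

    out = pd.DataFrame(index=df.index)
    out["individual_id"] = df["individual_id"].str.strip()
    for col in ("taxon", "family"):
        out[col] = df[col].str.strip().replace("", None)
    region = df["region"].str.strip().map(lambda s: normalize_name(s) if s else None)
    bad_region = region.dropna()[~region.dropna().isin(REGIONS)]
    for i, v in bad_region.items():
        errors.append(f"row {i + 2}: region {v!r} not in {REGIONS}")
    out["region"] = region
    out["length_mm"] = parse_float("length_mm", positive=True)
    out["width_mm"] = parse_float("width_mm", positive=True)
    out["mass_mg"] = parse_float("mass_mg", positive=True)
    missing_len = out["length_mm"].isna() & ~df["length_mm"].str.strip().ne("")
    for i in out.index[missing_len]:
        errors.append(f"row {i + 2}: missing body length")
    if "is_larva" in df.columns:
        flags = df["is_larva"].str.strip().str.lower()
        ok = flags.isin(("", "0", "1", "true", "false"))
        for i in flags.index[~ok]:
            errors.append(f"row {i + 2}: bad is_larva value {df['is_larva'][i]!r}")
        out["is_larva"] = flags.isin(("1", "true"))
    else:
        out["is_larva"] = False

    dup = out["individual_id"][out["individual_id"].duplicated()]
    for i, v in dup.items():
        errors.append(f"row {i + 2}: duplicate individual_id {v!r}")
    if errors:
        raise FormatError(f"{path}: {len(errors)} bad row(s):\n  " + "\n  ".join(errors[:20]))
    return MorphometricTable(df=out, source=str(path))


def _serialize(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col in _MASS_COLUMNS:
            out[col] = out[col].map(lambda x: "" if pd.isna(x) else f"{x:.4g}")
        elif pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda x: "" if pd.isna(x) else f"{x:g}")
        elif pd.api.types.is_bool_dtype(out[col]):
            out[col] = out[col].map(lambda x: "1" if x else "0")
        else:
            out[col] = out[col].map(lambda x: "" if x is None or (isinstance(x, float) and pd.isna(x)) else str(x))
    return out


def write_results_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table deterministically and atomically.

    Mass columns use 4 significant figures; other floats use shortest
    round-trip ``%g``; booleans become 0/1; absent values become empty
    cells. Identical inputs give byte-identical files.
    """
    path = Path(path)
    payload = _serialize(df)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            payload.to_csv(fh, index=False, lineterminator="\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_morphometric_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a morphometric frame in the standard dialect (full precision)."""
    cols = MORPHOMETRIC_COLUMNS + (["is_larva"] if "is_larva" in df.columns else [])
    out = df[cols].copy()
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            _serialize_full(out).to_csv(fh, index=False, lineterminator="\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _serialize_full(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda x: "" if pd.isna(x) else repr(float(x)))
        elif pd.api.types.is_bool_dtype(out[col]):
            out[col] = out[col].map(lambda x: "1" if x else "0")
        else:
            out[col] = out[col].map(lambda x: "" if x is None or (isinstance(x, float) and pd.isna(x)) else str(x))
    return out
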