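"""Reading and writing delimited-text feature tables, inclusion lists and libraries."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .filtering import MZ_COL, RT_COL, InclusionList, validate_feature_table

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_inclusion_list",
    "read_mass_library",
]

def _read_delimited(path: str | Path, sep: str | None) -> pd.DataFrame:
    """Read CSV/TSV; when ``sep`` is None pick tab vs comma from the header.

    (csv.Sniffer-style detection misfires on single-column files, so the
    fallback is a simple count on the first line.)
    """
    if sep is not None:
        return pd.read_csv(path, sep=sep)
    suffix = Path(path).suffix.lower()
    if suffix in {".tsv", ".tab"}:
        return pd.read_csv(path, sep="\t")
    with open(path) as fh:
        header = fh.readline()
    return pd.read_csv(path, sep="\t" if header.count("\t") > header.count(",") else ",")


_MASS_COLUMN_CANDIDATES = (
    "monisotopic_moleculate_weight",  # HMDB export spelling
    "monoisotopic_mass",
    "neutral_mass",
    "exact_mass",
    "mass",
)


def read_feature_table(
    path: str | Path,
    mz_col: str = MZ_COL,
    rt_col: str = RT_COL,
    sep: str | None = None,
    rt_in_seconds: bool = False,
) -> pd.DataFrame:
    """Read a CSV/TSV feature table and standardize m/z and RT column names.

    ``sep=None`` sniffs the delimiter. ``rt_in_seconds=True`` converts RT
    to minutes on read. The returned frame always exposes ``mz`` and
    ``rt`` columns; other columns pass through untouched.
    """
    df = _read_delimited(path, sep)
    missing = [c for c in (mz_col, rt_col) if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing}; file has {list(df.columns)}"
        )
    df = df.rename(columns={mz_col: MZ_COL, rt_col: RT_COL})
    if rt_in_seconds:
        df[RT_COL] = df[RT_COL] / 60.0
    validate_feature_table(df)
    return df


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_inclusion_list(
    path: str | Path,
    tolerance_ppm: float = 5.0,
    mz_col: str = "mz",
    label_col: str | None = None,
    sep: str | None = None,
) -> InclusionList:
    """Read an inclusion list (one m/z per row, optional label column)."""
    df = _read_delimited(path, sep)
    if mz_col not in df.columns:
        raise ValueError(f"{path}: missing column {mz_col!r}; file has {list(df.columns)}")
    labels = None
    if label_col is not None:
        if label_col not in df.columns:
            raise ValueError(f"{path}: missing label column {label_col!r}")
        labels = tuple(str(x) for x in df[label_col])
    return InclusionList(tuple(df[mz_col].astype(float)), labels, tolerance_ppm)


def read_mass_library(
    path: str | Path,
    mass_col: str | None = None,
    formula_col: str | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a compound library of neutral monoisotopic masses.

    Returns a frame with a ``neutral_mass`` column (and ``formula`` when
    available). When ``mass_col`` is not given, common HMDB-style column
    names are tried.
    """
    df = _read_delimited(path, sep)
    if mass_col is None:
        lower = {c.lower(): c for c in df.columns}
        for cand in _MASS_COLUMN_CANDIDATES:
            if cand in lower:
                mass_col = lower[cand]
                break
    if mass_col is None or mass_col not in df.columns:
        raise ValueError(
            f"{path}: no neutral-mass column found (looked for "
            f"{list(_MASS_COLUMN_CANDIDATES)}); file has {list(df.columns)}"
        )
    out = df.rename(columns={mass_col: "neutral_mass"})
    if formula_col is not None:
        if formula_col not in df.columns:
            raise ValueError(f"{path}: missing formula column {formula_col!r}")
        out = out.rename(columns={formula_col: "formula"})
    out = out[out["neutral_mass"].notna() & (out["neutral_mass"] > 0)].reset_index(drop=True)
    if not len(out):
        raise ValueError(f"{path}: library contains no usable neutral masses")
    return out
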