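"""Readers and writers for the package's tabular formats.

All files are UTF-8, comma-separated with a header row and decimal points.
Parse errors name the offending line (header = line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genetics import GenotypeTable, genotype_table_from_long, genotype_table_from_wide, genotype_table_to_wide


class ParseError(ValueError):
    """A named, line-located error in an input file."""

    def __init__(self, path, line: int | None, message: str):
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.line = line


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns {sorted(missing)}")


def _check_numeric(df: pd.DataFrame, column: str, path) -> np.ndarray:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = np.flatnonzero(values.isna().to_numpy())
    if bad.size:
        # +2: header line plus 1-based numbering
        raise ParseError(path, int(bad[0]) + 2, f"non-numeric value in column {column!r}")
    return values.to_numpy(float)


def read_sites(path) -> pd.DataFrame:
    """Read a site table: id, lon, lat, cal_age_BP (File-S3-style columns)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["lon", "lat", "cal_age_BP"], path)
    out = pd.DataFrame(
        {
            "id": df["id"] if "id" in df.columns else [f"site{k+1}" for k in range(len(df))],
            "lon": _check_numeric(df, "lon", path),
            "lat": _check_numeric(df, "lat", path),
            "cal_age_BP": _check_numeric(df, "cal_age_BP", path),
        }
    )
    bad = np.flatnonzero(np.abs(out["lat"].to_numpy()) > 90.0)
    if bad.size:
        raise ParseError(path, int(bad[0]) + 2, "latitude outside [-90, 90]")
    return out


def write_sites(df: pd.DataFrame, path) -> None:
    df[["id", "lon", "lat", "cal_age_BP"]].to_csv(path, index=False)


def read_heterozygosity(path) -> pd.DataFrame:
    """Read a heterozygosity table: id, lon, lat, het."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["lon", "lat", "het"], path)
    out = pd.DataFrame(
        {
            "id": df["id"] if "id" in df.columns else [f"acc{k+1}" for k in range(len(df))],
            "lon": _check_numeric(df, "lon", path),
            "lat": _check_numeric(df, "lat", path),
            "het": _check_numeric(df, "het", path),
        }
    )
    bad = np.flatnonzero(np.abs(out["lat"].to_numpy()) > 90.0)
    if bad.size:
        raise ParseError(path, int(bad[0]) + 2, "latitude outside [-90, 90]")
    return out


def read_genotypes(path) -> GenotypeTable:
    """Read genotypes from a wide CSV (id, lon, lat, <locus>_a/<locus>_b...)
    or a long CSV (id, lon, lat, locus, allele1, allele2)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    for col in ("lon", "lat"):
        if col in df.columns:
            _check_numeric(df.drop_duplicates("id") if "locus" in df.columns else df, col, path)
    if "locus" in df.columns:
        df["lon"] = pd.to_numeric(df["lon"])
        df["lat"] = pd.to_numeric(df["lat"])
        return genotype_table_from_long(df)
    _require_columns(df, ["id", "lon", "lat"], path)
    df["lon"] = pd.to_numeric(df["lon"])
    df["lat"] = pd.to_numeric(df["lat"])
    return genotype_table_from_wide(df)


def write_genotypes(table: GenotypeTable, path) -> None:
    genotype_table_to_wide(table).to_csv(path, index=False)


def read_front(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["lon", "lat", "p1", "p2", "r1_age", "r1_het"], path)
    return df


def write_front(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_triplets(m: sp.spmatrix, path) -> None:
    """Write a sparse matrix as (i, j, value) text triplets for inspection."""
    coo = m.tocoo()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("i,j,value\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i},{j},{v:.12g}\n")


def read_triplets(path, shape) -> sp.csr_matrix:
    df = pd.read_csv(path)
    return sp.coo_matrix(
        (df["value"], (df["i"], df["j"])), shape=shape
    ).tocsr()
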