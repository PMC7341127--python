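"""Tab-separated I/O with schema validation.

All interchange files are TSV with header rows.  Physical coordinates are
1-based inclusive (nematode genome-browser convention); genetic positions are
nonnegative centimorgans.  Reads validate allele codes, uniqueness and
coordinate monotonicity and name the offending row/column on failure; writes
round-trip values losslessly (floats at full repr precision).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from riailmap.sim import MISSING, GenotypePanel, validate_marker_map

MAP_FILE_COLUMNS = {
    "marker": "marker",
    "chromosome": "chrom",
    "genetic_pos_cM": "cm",
    "physical_pos_bp": "bp",
}


class SchemaError(ValueError):
    """A file does not match its declared TSV schema."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_marker_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, MAP_FILE_COLUMNS, path)
    df = df.rename(columns=MAP_FILE_COLUMNS)[list(MAP_FILE_COLUMNS.values())]
    df["chrom"] = df["chrom"].astype(str)
    try:
        validate_marker_map(df)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    return df


def write_marker_map(marker_map: pd.DataFrame, path: str | Path) -> None:
    inverse = {v: k for k, v in MAP_FILE_COLUMNS.items()}
    marker_map.rename(columns=inverse).to_csv(path, sep="\t", index=False)


def read_genotypes(geno_path: str | Path, map_path: str | Path) -> GenotypePanel:
    """Read a lines x markers genotype TSV plus its marker map.

    The genotype file's first column is the line id; remaining columns are
    marker ids matching the map.  Allele codes must be 0, 1 or -1 (missing;
    empty cells are also read as missing).
    """
    marker_map = read_marker_map(map_path)
    df = pd.read_csv(geno_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"{geno_path}: duplicate line id {dup!r}")
    values = df.to_numpy()
    if values.dtype == object or np.isnan(values.astype(float)).any():
        df = df.fillna(MISSING)
    df = df.astype(np.int64)
    bad = ~np.isin(df.to_numpy(), (0, 1, MISSING))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise SchemaError(
            f"{geno_path}: invalid allele code {df.iat[i, j]!r} at line "
            f"{df.index[i]!r}, marker {df.columns[j]!r}"
        )
    if list(df.columns) != list(marker_map["marker"]):
        raise SchemaError(f"{geno_path}: marker columns do not match {map_path}")
    return GenotypePanel(df, marker_map)


def write_genotypes(panel: GenotypePanel, geno_path: str | Path, map_path: str | Path) -> None:
    panel.genotypes.to_csv(geno_path, sep="\t", index_label="line")
    write_marker_map(panel.marker_map, map_path)


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read a line-id-keyed trait table (lines x traits, numeric)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"{path}: duplicate line id {dup!r}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise SchemaError(f"{path}: non-numeric cell at line {row!r}, column {col!r}")
    return df.astype(float)


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, sep="\t", index_label="line")


def read_probe_positions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("probe", "chrom", "start"), path)
    df["chrom"] = df["chrom"].astype(str)
    if df["probe"].duplicated().any():
        dup = df.loc[df["probe"].duplicated(), "probe"].iloc[0]
        raise SchemaError(f"{path}: duplicate probe id {dup!r}")
    if (df["start"] < 1).any():
        row = df.index[df["start"] < 1][0]
        raise SchemaError(f"{path}: probe start < 1 at row {row} (1-based coordinates)")
    return df[["probe", "chrom", "start"]]


def write_probe_positions(positions: pd.DataFrame, path: str | Path) -> None:
    positions.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Generic results table writer (QTL, eQTL, hotspot, mediation tables)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
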