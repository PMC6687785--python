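"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices travel as TSV with genes as rows (first column gene
IDs, header row of sample IDs); gene sets as GMT (one set per line:
name, description, then member genes, tab-separated) or GMX (the
transposed, column-per-set layout); sample metadata as a TSV with one row
per sample.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("tumormatch")

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_gmt",
    "write_gmt",
    "read_gmx",
]

#: decimal precision used by every writer; round-tripping is exact at this
#: formatting because values are re-parsed from the printed representation
FLOAT_FORMAT = "%.10g"


class FormatError(ValueError):
    """Malformed input file."""


def read_expression_tsv(path: str | Path, require_counts: bool = False) -> pd.DataFrame:
    """Read a genes x samples TSV matrix.

    Duplicate gene or sample identifiers and non-numeric cells are hard
    errors that name the offending entry. With ``require_counts`` the
    values must additionally be finite and non-negative.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup_genes = df.index[df.index.duplicated()].unique().tolist()
    if dup_genes:
        raise FormatError(f"duplicate gene IDs in {path}: {dup_genes}")
    dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise FormatError(f"duplicate sample IDs in {path}: {dup_samples}")
    try:
        values = df.astype(float)
    except ValueError:
        for gene in df.index:
            for sample in df.columns:
                try:
                    float(df.at[gene, sample])
                except ValueError:
                    raise FormatError(
                        f"non-numeric cell at gene {gene!r}, sample {sample!r} "
                        f"in {path}: {df.at[gene, sample]!r}"
                    ) from None
        raise
    if require_counts:
        arr = values.to_numpy()
        if not np.isfinite(arr).all() or (arr < 0).any():
            bad = values.index[(~np.isfinite(arr) | (arr < 0)).any(axis=1)][:5].tolist()
            raise FormatError(f"negative or non-finite counts in {path}, e.g. genes {bad}")
    return values


def write_expression_tsv(x: pd.DataFrame, path: str | Path) -> None:
    x.to_csv(Path(path), sep="\t", index_label="gene_id", float_format=FLOAT_FORMAT)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata not found: {path}")
    meta = pd.read_csv(path, sep="\t")
    if "sample_id" not in meta.columns:
        raise FormatError(f"metadata {path} lacks a sample_id column")
    dup = meta["sample_id"][meta["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"duplicate sample IDs in {path}: {dup}")
    return meta.set_index("sample_id", drop=False)


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(Path(path), sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered ``{set name: gene list}`` mapping.

    Duplicate genes within a set are collapsed (order-preserving) with a
    logged warning; sets that are empty after collapsing are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene set file not found: {path}")
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT lines need >=3 tab-separated fields "
                    f"(name, description, genes), got {len(fields)}"
                )
            name = fields[0]
            genes = [g for g in fields[2:] if g.strip()]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning(
                    "set %s: collapsed %d duplicate gene entries", name, len(genes) - len(unique)
                )
            if not unique:
                logger.warning("set %s is empty after collapsing; dropped", name)
                continue
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = unique
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(Path(path), "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmx(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMX file (column-per-set transpose of GMT)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene set file not found: {path}")
    with open(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if len(rows) < 2:
        raise FormatError(f"{path}: GMX needs a name row, a description row and genes")
    names = rows[0]
    sets: dict[str, list[str]] = {}
    for j, name in enumerate(names):
        if not name.strip():
            continue
        genes = [row[j] for row in rows[2:] if j < len(row) and row[j].strip()]
        unique = list(dict.fromkeys(genes))
        if unique:
            sets[name] = unique
    return sets
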