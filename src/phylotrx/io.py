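"""Readers and writers for the pipeline's tab-separated formats.

File dialect: tab-separated, UTF-8, one header row, comment lines start with
'#'. Expression tables are one file per organ x strand named
``<organ>.<strand>.tsv`` with a ``gene_id`` column followed by one numeric
column per accession. The phylostratum map is ``gene_id<TAB>phylostratum``;
divergence tables are ``gene_id<TAB>dN<TAB>dS[<TAB>ratio]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    ORGANS,
    STRANDS,
    DivergenceTable,
    ExpressionTensor,
    ParseError,
    PhylostratumMap,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class LoadReport:
    """Per-file row counts and filter statistics collected while loading."""

    genes_per_slice: dict[tuple[str, str], int] = field(default_factory=dict)
    n_genes_union: int = 0
    n_accessions: int = 0
    divergence_dropped: dict[str, int] = field(default_factory=dict)


def expression_paths(directory: str | Path) -> dict[tuple[str, str], Path]:
    """Map (organ, strand) -> ``<organ>.<strand>.tsv`` under ``directory``."""
    directory = Path(directory)
    return {
        (o, s): directory / f"{o}.{s}.tsv"
        for o in ORGANS
        for s in STRANDS
        if (directory / f"{o}.{s}.tsv").exists()
    }


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except Exception as exc:  # malformed TSV
        raise ParseError(f"{path}: {exc}") from exc
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing required 'gene_id' column")
    return df


def read_expression_frame(path: str | Path) -> pd.DataFrame:
    """One genes x accessions slice; raises ParseError naming bad cells."""
    path = Path(path)
    df = _read_table(path)
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"{path}: duplicate gene ids {dups[:5]}")
    df = df.set_index("gene_id")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2  # +1 header, +1 1-based
            raise ParseError(
                f"{path}: non-numeric expression value "
                f"{df[col][bad].iloc[0]!r} at row {row}, column {col!r}"
            )
        df[col] = numeric
    return df


def read_expression(
    paths: Mapping[tuple[str, str], str | Path] | str | Path,
) -> tuple[ExpressionTensor, LoadReport]:
    """Read all (organ, strand) tables into a tensor on the union of genes.

    ``paths`` may be a directory following the ``<organ>.<strand>.tsv`` naming
    convention, or an explicit mapping. Absent (gene, accession) cells in any
    slice are zeros.
    """
    if isinstance(paths, (str, Path)):
        paths = expression_paths(paths)
    if not paths:
        raise ValidationError("no expression tables found")
    frames = {key: read_expression_frame(p) for key, p in paths.items()}
    tensor = ExpressionTensor.from_frames(frames)
    report = LoadReport(
        genes_per_slice={k: len(v) for k, v in frames.items()},
        n_genes_union=tensor.n_genes,
        n_accessions=tensor.n_accessions,
    )
    logger.info(
        "loaded %d slices: %d genes (union) x %d accessions",
        len(frames), report.n_genes_union, report.n_accessions,
    )
    return tensor, report


def write_expression(tensor: ExpressionTensor, directory: str | Path) -> list[Path]:
    """Write one ``<organ>.<strand>.tsv`` per slice; values round-trip exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for organ in ORGANS:
        for strand in STRANDS:
            df = tensor.slice_frame(organ, strand)
            df.index.name = "gene_id"
            path = directory / f"{organ}.{strand}.tsv"
            df.to_csv(path, sep="\t", float_format=None)
            out.append(path)
    return out


def read_phylostrata(path: str | Path) -> PhylostratumMap:
    """Read a two-column gene_id / phylostratum table."""
    path = Path(path)
    df = _read_table(path)
    if "phylostratum" not in df.columns:
        raise ParseError(f"{path}: missing 'phylostratum' column")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"{path}: duplicate gene ids {dups[:5]}")
    strata = pd.to_numeric(df["phylostratum"], errors="coerce")
    if strata.isna().any():
        row = int(np.argmax(strata.isna().to_numpy())) + 2
        raise ParseError(f"{path}: non-integer phylostratum at row {row}")
    s = pd.Series(strata.to_numpy(), index=df["gene_id"].to_numpy())
    s.index.name = "gene_id"
    m = PhylostratumMap(s)
    logger.info("loaded phylostratum map: %d genes", len(m))
    return m


def write_phylostrata(ps_map: PhylostratumMap, path: str | Path) -> None:
    df = ps_map.assignment.rename("phylostratum").to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_divergence(path: str | Path, species_label: str) -> DivergenceTable:
    """Read gene_id/dN/dS[/ratio] and apply the retention filter.

    Rows failing dN < 0.5, dS < 5 or dN/dS < 2 are dropped; the count of
    dropped rows is logged and stored on the returned table.
    """
    path = Path(path)
    df = _read_table(path)
    for col in ("dN", "dS"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing '{col}' column")
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals.isna() & df[col].notna()).any() or df[col].isna().any():
            row = int(np.argmax((vals.isna()).to_numpy())) + 2
            raise ParseError(f"{path}: non-numeric {col} at row {row}")
        df[col] = vals
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene ids")
    df = df.set_index("gene_id")
    if "ratio" in df.columns:
        df["ratio"] = pd.to_numeric(df["ratio"], errors="coerce")
    table = DivergenceTable.from_frame(df, species_label)
    logger.info(
        "loaded divergence table %s: %d retained, %d dropped by retention filter",
        species_label, len(table), table.n_dropped,
    )
    return table


def write_divergence(table: DivergenceTable, path: str | Path) -> None:
    df = table.table[["dN", "dS", "ratio"]].copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
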