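"""Shared data model for the phylotranscriptomic pipeline.

The analysis operates on three inputs: a strand-specific expression tensor
(normalized read counts per gene, accession, organ and strand), a phylostratum
map assigning each gene the phylogenetic node at which its oldest homology
domain emerged (an integer 1..12, old to young), and one table of
nonsynonymous/synonymous substitution-rate ratios (dN/dS) per reference
species. Containers here validate the invariants the downstream stages rely
on; they carry no analysis logic.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
import yaml

ORGANS: tuple[str, ...] = ("root", "seedling", "flower")
STRANDS: tuple[str, ...] = ("sense", "antisense")

#: Phylogenetic ladder for A. thaliana, oldest clade first.
STRATUM_NAMES: tuple[str, ...] = (
    "Cellular organisms",
    "Eukaryota",
    "Viridiplantae",
    "Embryophyta",
    "Tracheophyta",
    "Magnoliophyta",
    "Eudicotyledons",
    "core Eudicotyledons",
    "Rosids",
    "Brassicales",
    "Arabidopsis",
    "A. thaliana",
)

N_STRATA = len(STRATUM_NAMES)

#: The seven organ-presence groups for expressed genes, keyed by the
#: (root, seedling, flower) presence profile.
GROUP_BY_PROFILE: dict[tuple[bool, bool, bool], str] = {
    (True, False, False): "R",
    (False, True, False): "S",
    (False, False, True): "F",
    (True, True, False): "RS",
    (True, False, True): "FR",
    (False, True, True): "FS",
    (True, True, True): "RSF",
}

GROUP_NAMES: tuple[str, ...] = ("R", "S", "F", "RS", "FR", "FS", "RSF")


class PipelineError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(PipelineError, ValueError):
    """An input violates a structural invariant of the data model."""


class ParseError(PipelineError, ValueError):
    """A file could not be parsed; the message names the file and row."""


class UndefinedIndexError(PipelineError, ArithmeticError):
    """A weighted index is undefined (zero total expression in the sample)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionTensor:
    """Normalized expression (e.g. RPM) per (gene, accession, organ, strand).

    Every (organ, strand) slice covers the identical gene x accession grid;
    genes absent from a particular input table are explicit zeros there.
    """

    data: xr.DataArray

    def __post_init__(self) -> None:
        da = self.data
        if tuple(da.dims) != ("gene", "accession", "organ", "strand"):
            raise ValidationError(
                f"expected dims (gene, accession, organ, strand), got {da.dims}"
            )
        if tuple(da.coords["organ"].values) != ORGANS:
            raise ValidationError(f"organ axis must be {ORGANS}")
        if tuple(da.coords["strand"].values) != STRANDS:
            raise ValidationError(f"strand axis must be {STRANDS}")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.accession_ids, "accession ids")
        vals = da.values
        if not np.isfinite(vals).all():
            raise ValidationError("expression values must be finite")
        if (vals < 0).any():
            raise ValidationError("expression values must be non-negative")

    @classmethod
    def from_frames(
        cls, frames: Mapping[tuple[str, str], pd.DataFrame]
    ) -> "ExpressionTensor":
        """Assemble a tensor from per-(organ, strand) genes x accessions frames.

        Genes are the union over all frames (first-seen order); accession sets
        must agree across frames. Missing (gene, slice) cells become zeros.
        """
        missing = [k for k in frames if k[0] not in ORGANS or k[1] not in STRANDS]
        if missing:
            raise ValidationError(f"unknown (organ, strand) keys: {missing}")
        if not frames:
            raise ValidationError("no expression tables supplied")
        accessions: list[str] | None = None
        for key, df in frames.items():
            cols = list(df.columns)
            if accessions is None:
                accessions = cols
            elif set(cols) != set(accessions):
                raise ValidationError(
                    f"accession sets differ across tables (at {key[0]}.{key[1]}): "
                    f"{sorted(set(cols) ^ set(accessions))[:5]}"
                )
            _check_unique(df.index, f"gene ids in {key[0]}.{key[1]}")
        assert accessions is not None
        genes: list[str] = []
        seen: set[str] = set()
        for df in frames.values():
            for g in df.index:
                if g not in seen:
                    seen.add(g)
                    genes.append(g)
        arr = np.zeros((len(genes), len(accessions), len(ORGANS), len(STRANDS)))
        gpos = {g: i for i, g in enumerate(genes)}
        for (organ, strand), df in frames.items():
            oi, si = ORGANS.index(organ), STRANDS.index(strand)
            block = df.loc[:, accessions].to_numpy(dtype=float)
            rows = [gpos[g] for g in df.index]
            arr[rows, :, oi, si] = block
        da = xr.DataArray(
            arr,
            dims=("gene", "accession", "organ", "strand"),
            coords={
                "gene": genes,
                "accession": accessions,
                "organ": list(ORGANS),
                "strand": list(STRANDS),
            },
        )
        return cls(da)

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.coords["gene"].values]

    @property
    def accession_ids(self) -> list[str]:
        return [str(a) for a in self.data.coords["accession"].values]

    @property
    def n_genes(self) -> int:
        return self.data.sizes["gene"]

    @property
    def n_accessions(self) -> int:
        return self.data.sizes["accession"]

    def slice_frame(self, organ: str, strand: str) -> pd.DataFrame:
        """Genes x accessions frame for one (organ, strand) slice."""
        return self.data.sel(organ=organ, strand=strand).drop_vars(
            ["organ", "strand"]
        ).to_pandas()

    def sample(self, accession: str, organ: str, strand: str) -> pd.Series:
        """Expression vector over genes for one sample."""
        s = self.data.sel(accession=accession, organ=organ, strand=strand)
        return pd.Series(s.values, index=self.gene_ids, name=f"{accession}:{organ}")


@dataclass
class PhylostratumMap:
    """Gene -> phylostratum (integer 1..12, 1 = oldest)."""

    assignment: pd.Series
    stratum_names: tuple[str, ...] = STRATUM_NAMES
    stratum_ages: tuple[float, ...] | None = None  # Ma per stratum, optional

    def __post_init__(self) -> None:
        s = self.assignment
        if s.index.has_duplicates:
            dups = s.index[s.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids in phylostratum map: {dups[:5]}")
        vals = s.to_numpy()
        if len(vals) and (
            not np.issubdtype(np.asarray(vals).dtype, np.integer)
            and not np.all(np.asarray(vals) == np.asarray(vals).astype(int))
        ):
            raise ValidationError("phylostrata must be integers")
        self.assignment = s.astype(int)
        n = len(self.stratum_names)
        if n != N_STRATA:
            raise ValidationError(f"expected {N_STRATA} stratum names, got {n}")
        bad = self.assignment[(self.assignment < 1) | (self.assignment > n)]
        if len(bad):
            raise ValidationError(
                f"phylostrata out of range 1..{n} for genes {bad.index.tolist()[:5]}"
            )
        if self.stratum_ages is not None and len(self.stratum_ages) != n:
            raise ValidationError("stratum_ages length must match stratum count")

    def __len__(self) -> int:
        return len(self.assignment)

    def counts(self) -> pd.Series:
        """Number of genes per stratum, indexed 1..12 (zeros included)."""
        c = self.assignment.value_counts().reindex(range(1, N_STRATA + 1), fill_value=0)
        c.index.name = "phylostratum"
        return c

    def strata_for(self, genes: Sequence[str]) -> pd.Series:
        """Strata for the given genes; unassigned genes are dropped."""
        return self.assignment.reindex(genes).dropna().astype(int)


RETENTION_RULE = {"dn_max": 0.5, "ds_max": 5.0, "ratio_max": 2.0}


def apply_retention_filter(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep rows with dN < 0.5, dS < 5 and dN/dS < 2; return (kept, n_dropped).

    Rows with dS = 0 have an undefined ratio and are dropped with a warning.
    """
    if (df["dN"] < 0).any() or (df["dS"] < 0).any():
        bad = df.index[(df["dN"] < 0) | (df["dS"] < 0)].tolist()
        raise ValidationError(f"negative dN or dS for genes {bad[:5]}")
    zero_ds = df["dS"] == 0
    if zero_ds.any():
        warnings.warn(
            f"dropping {int(zero_ds.sum())} rows with dS = 0 (ratio undefined)",
            stacklevel=2,
        )
    df = df[~zero_ds].copy()
    if "ratio" in df.columns and df["ratio"].notna().all() and len(df):
        computed = df["dN"] / df["dS"]
        rel = np.abs(df["ratio"] - computed) / np.maximum(np.abs(computed), 1e-300)
        ok = (computed == df["ratio"]) | (rel <= 1e-6)
        if not ok.all():
            bad = df.index[~ok].tolist()
            raise ValidationError(
                f"supplied ratio disagrees with dN/dS for genes {bad[:5]}"
            )
    df["ratio"] = df["dN"] / df["dS"]
    keep = (
        (df["dN"] < RETENTION_RULE["dn_max"])
        & (df["dS"] < RETENTION_RULE["ds_max"])
        & (df["ratio"] < RETENTION_RULE["ratio_max"])
    )
    n_dropped = int((~keep).sum()) + int(zero_ds.sum())
    return df[keep], n_dropped


@dataclass
class DivergenceTable:
    """Per-gene dN, dS and dN/dS against one reference species.

    Rows are assumed to have passed the retention filter (dN < 0.5, dS < 5,
    dN/dS < 2); construct via :meth:`from_frame` to enforce it.
    """

    table: pd.DataFrame  # index gene_id; columns dN, dS, ratio
    reference_species: str
    n_dropped: int = 0

    def __post_init__(self) -> None:
        req = {"dN", "dS", "ratio"}
        if not req.issubset(self.table.columns):
            raise ValidationError(f"divergence table needs columns {sorted(req)}")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate gene ids in divergence table")
        t = self.table
        ok = (
            (t["dN"] < RETENTION_RULE["dn_max"])
            & (t["dS"] < RETENTION_RULE["ds_max"])
            & (t["ratio"] < RETENTION_RULE["ratio_max"])
            & (t["dN"] >= 0)
            & (t["dS"] > 0)
        )
        if not ok.all():
            raise ValidationError(
                f"{int((~ok).sum())} rows violate the retention rule; "
                "construct via DivergenceTable.from_frame"
            )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, reference_species: str) -> "DivergenceTable":
        kept, n_dropped = apply_retention_filter(df)
        return cls(kept, reference_species, n_dropped)

    @property
    def ratios(self) -> pd.Series:
        return self.table["ratio"]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class AnalysisConfig:
    """Thresholds and switches governing every pipeline stage.

    Defaults follow the study design: a gene counts as expressed in an organ
    (per strand) when >= 0.8 RPM in at least 5 of the accessions; bootstrap
    standard errors use 1,000 gene resamples; the old gene class is PS1-3.
    """

    rpm_threshold: float = 0.8
    min_accessions: int = 5
    n_bootstrap: int = 1000
    rng_seed: int = 0
    log_odds_base: float = math.e
    alpha: float = 0.05
    old_class_max_stratum: int = 3
    # correlation / clustering switches
    log_transform_correlation: bool = False
    clustering_linkage: str = "average"
    # enrichment switches
    expected_model: str = "genome"  # or "table"
    two_tailed_rule: str = "double"  # or "minlike"
    # index gene set: all annotated genes with nonzero expression ("expressed")
    # or only genes passing the expression call ("called")
    index_gene_mode: str = "expressed"

    def __post_init__(self) -> None:
        if self.rpm_threshold < 0:
            raise ValidationError("rpm_threshold must be >= 0")
        if self.min_accessions < 1:
            raise ValidationError("min_accessions must be >= 1")
        if self.n_bootstrap < 1:
            raise ValidationError("n_bootstrap must be >= 1")
        if self.log_odds_base <= 0 or self.log_odds_base == 1:
            raise ValidationError("log_odds_base must be positive and != 1")
        if self.expected_model not in ("genome", "table"):
            raise ValidationError("expected_model must be 'genome' or 'table'")
        if self.two_tailed_rule not in ("double", "minlike"):
            raise ValidationError("two_tailed_rule must be 'double' or 'minlike'")
        if self.index_gene_mode not in ("expressed", "called"):
            raise ValidationError("index_gene_mode must be 'expressed' or 'called'")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
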