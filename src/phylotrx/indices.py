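"""Transcriptome age and divergence indices with bootstrap standard errors.

The transcriptome age index (TAI) of a sample is the expression-weighted mean
phylostratum of its genes:

    TAI_s = sum_i ps_i * e_is / sum_i e_is

and the transcriptome divergence index (TDI) replaces the phylostratum ps_i
by the gene's dN/dS ratio. Both have an equivalent sum-of-products form over
partial concentrations f_is = e_is / sum_i e_is:

    TAI_s = sum_i ps_i * f_is

Standard errors come from resampling genes with replacement: for each
accession one resample per replicate is shared across that accession's
organs, which preserves the cross-organ dependence needed for the paired
organ comparisons (Mann-Whitney tests between the two organs' replicate
values).

Note the Mann-Whitney comparison treats bootstrap replicate values as
samples; with 1,000 replicates this yields very small p-values for even
modest index differences and should be read as "the bootstrap distributions
are separated", not as a test against biological variability (the study
design has no biological replicates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    ORGANS,
    AnalysisConfig,
    DivergenceTable,
    ExpressionTensor,
    PhylostratumMap,
    UndefinedIndexError,
    ValidationError,
)

_MAX_REDRAWS = 100


def partial_concentrations(expression: pd.Series) -> pd.Series:
    """f_i = e_i / sum(e) for one sample; requires a positive total."""
    total = float(expression.sum())
    if total <= 0:
        raise UndefinedIndexError("zero total expression: concentrations undefined")
    return expression / total


def _annotation_series(annotation: PhylostratumMap | DivergenceTable) -> pd.Series:
    if isinstance(annotation, PhylostratumMap):
        return annotation.assignment.astype(float)
    if isinstance(annotation, DivergenceTable):
        return annotation.ratios
    raise ValidationError(f"unsupported annotation {type(annotation).__name__}")


def weighted_index(expression: pd.Series, annotation: pd.Series) -> float:
    """Ratio-of-sums weighted mean: sum(a_i e_i) / sum(e_i) on shared genes."""
    a = annotation.reindex(expression.index).dropna()
    e = expression.loc[a.index]
    total = float(e.sum())
    if len(a) == 0:
        raise UndefinedIndexError("no annotated genes in sample")
    if total <= 0:
        raise UndefinedIndexError("zero total expression over annotated genes")
    return float((a * e).sum() / total)


def weighted_index_concentration_form(
    expression: pd.Series, annotation: pd.Series
) -> float:
    """Sum-of-products form: sum_i a_i f_is over the annotated genes."""
    a = annotation.reindex(expression.index).dropna()
    f = partial_concentrations(expression.loc[a.index])
    return float((a * f).sum())


def compute_tai(
    tensor: ExpressionTensor,
    ps_map: PhylostratumMap,
    accession: str,
    organ: str,
    strand: str = "sense",
) -> float:
    """TAI of one sample; genes without an assigned stratum are excluded."""
    return weighted_index(
        tensor.sample(accession, organ, strand), _annotation_series(ps_map)
    )


def compute_tdi(
    tensor: ExpressionTensor,
    div_table: DivergenceTable,
    accession: str,
    organ: str,
    strand: str = "sense",
) -> float:
    """TDI of one sample; genes without a retained dN/dS ratio are excluded."""
    return weighted_index(
        tensor.sample(accession, organ, strand), _annotation_series(div_table)
    )


@dataclass
class OrganIndex:
    """Bootstrap summary for one (accession, organ) cell."""

    estimate: float
    draws: np.ndarray
    boot_mean: float
    boot_se: float
    n_genes: int


@dataclass
class IndexResult:
    """TAI or TDI for one accession and strand across all organs."""

    index_kind: str  # "TAI" or "TDI"
    accession: str
    strand: str
    per_organ: dict[str, OrganIndex]
    reference_species: str | None = None
    n_redraws: int = 0

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for organ, oi in self.per_organ.items():
            rows.append(
                {
                    "accession": self.accession,
                    "organ": organ,
                    "strand": self.strand,
                    "index_kind": self.index_kind,
                    "reference_species": self.reference_species or "",
                    "estimate": oi.estimate,
                    "boot_mean": oi.boot_mean,
                    "boot_se": oi.boot_se,
                    "n_genes": oi.n_genes,
                }
            )
        return pd.DataFrame(rows)


def _eligible_genes(
    tensor: ExpressionTensor,
    annotation: pd.Series,
    accession: str,
    strand: str,
) -> pd.Index:
    """Annotated genes with any expression in this accession (any organ)."""
    block = tensor.data.sel(accession=accession, strand=strand)  # gene x organ
    any_expr = (block.values > 0).any(axis=1)
    genes = pd.Index(tensor.gene_ids)[any_expr]
    return genes.intersection(annotation.dropna().index)


def bootstrap_index(
    tensor: ExpressionTensor,
    annotation: PhylostratumMap | DivergenceTable,
    accession: str,
    config: AnalysisConfig,
    strand: str = "sense",
    rng: np.random.Generator | None = None,
) -> IndexResult:
    """Gene-resampling bootstrap of TAI (phylostratum map) or TDI (dN/dS).

    For each of ``config.n_bootstrap`` replicates, N genes are drawn with
    replacement from the N eligible genes (annotated and expressed somewhere
    in this accession); the same resample is applied to all organs of the
    accession in that replicate. The standard error is the standard deviation
    of the replicate index values. Replicates where some organ has zero total
    expression are redrawn (at most 100 times).
    """
    ann = _annotation_series(annotation)
    kind = "TAI" if isinstance(annotation, PhylostratumMap) else "TDI"
    species = (
        annotation.reference_species if isinstance(annotation, DivergenceTable) else None
    )
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    genes = _eligible_genes(tensor, ann, accession, strand)
    n = len(genes)
    if n == 0:
        raise UndefinedIndexError(
            f"no eligible genes for {kind} bootstrap in accession {accession!r}"
        )
    a = ann.loc[genes].to_numpy(dtype=float)
    e = np.column_stack(
        [
            tensor.sample(accession, organ, strand).loc[genes].to_numpy(dtype=float)
            for organ in ORGANS
        ]
    )  # n x 3
    ae = a[:, None] * e

    b = config.n_bootstrap
    idx = rng.integers(0, n, size=(b, n))
    num = ae[idx].sum(axis=1)  # b x organs
    den = e[idx].sum(axis=1)

    n_redraws = 0
    bad = (den <= 0).any(axis=1)
    while bad.any():
        if n_redraws >= _MAX_REDRAWS:
            raise UndefinedIndexError(
                f"replicates with zero total expression persisted after "
                f"{_MAX_REDRAWS} redraws (accession {accession!r})"
            )
        n_redraws += 1
        redo = rng.integers(0, n, size=(int(bad.sum()), n))
        num[bad] = ae[redo].sum(axis=1)
        den[bad] = e[redo].sum(axis=1)
        bad = (den <= 0).any(axis=1)

    draws = num / den
    per_organ: dict[str, OrganIndex] = {}
    for j, organ in enumerate(ORGANS):
        ej = pd.Series(e[:, j], index=genes)
        if ej.sum() <= 0:
            raise UndefinedIndexError(
                f"zero total expression for {accession!r}/{organ}/{strand}"
            )
        est = float((a * e[:, j]).sum() / e[:, j].sum())
        dj = draws[:, j]
        per_organ[organ] = OrganIndex(
            estimate=est,
            draws=dj,
            boot_mean=float(dj.mean()),
            boot_se=float(dj.std(ddof=1)) if b > 1 else 0.0,
            n_genes=n,
        )
    return IndexResult(
        index_kind=kind,
        accession=accession,
        strand=strand,
        per_organ=per_organ,
        reference_species=species,
        n_redraws=n_redraws,
    )


@dataclass
class OrganComparison:
    """Mann-Whitney tests between organ pairs' bootstrap draws."""

    index_kind: str
    accession: str
    strand: str
    tests: pd.DataFrame  # columns organ_a, organ_b, U, p


def compare_organs(result: IndexResult) -> OrganComparison:
    """Two-sided Mann-Whitney test between each organ pair's bootstrap draws.

    Uses exact enumeration for n <= 8 draws and the tie-corrected normal
    approximation otherwise.
    """
    rows = []
    organs = list(result.per_organ)
    for i in range(len(organs)):
        for j in range(i + 1, len(organs)):
            x = result.per_organ[organs[i]].draws
            y = result.per_organ[organs[j]].draws
            if len(x) != len(y):
                raise ValidationError("bootstrap draw vectors must have equal length")
            if len(x) < 2:
                warnings.warn(
                    f"skipping {organs[i]} vs {organs[j]}: fewer than 2 draws",
                    stacklevel=2,
                )
                continue
            method = "exact" if len(x) <= 8 else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            rows.append(
                {
                    "organ_a": organs[i],
                    "organ_b": organs[j],
                    "U": float(res.statistic),
                    "p": float(res.pvalue),
                }
            )
    return OrganComparison(
        index_kind=result.index_kind,
        accession=result.accession,
        strand=result.strand,
        tests=pd.DataFrame(rows, columns=["organ_a", "organ_b", "U", "p"]),
    )


def bootstrap_all(
    tensor: ExpressionTensor,
    annotation: PhylostratumMap | DivergenceTable,
    config: AnalysisConfig,
    strand: str = "sense",
    seed: int | None = None,
) -> dict[str, IndexResult]:
    """Bootstrap every accession with independent, reproducible substreams."""
    root = np.random.SeedSequence(config.rng_seed if seed is None else seed)
    children = root.spawn(tensor.n_accessions)
    out: dict[str, IndexResult] = {}
    for acc, ss in zip(tensor.accession_ids, children):
        out[acc] = bootstrap_index(
            tensor, annotation, acc, config, strand=strand,
            rng=np.random.default_rng(ss),
        )
    return out
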