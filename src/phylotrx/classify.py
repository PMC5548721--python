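"""Expression calls, organ-presence groups, and sample similarity.

A gene is called expressed in an organ (separately per strand) when its
normalized expression reaches the RPM threshold in at least ``min_accessions``
accessions. Expressed genes are then partitioned by their organ-presence
profile into the seven groups R, S, F, RS, FR, FS, RSF (root / seedling /
flower and their combinations). Sample similarity is Pearson correlation of
transcriptome profiles with agglomerative clustering of the correlation
profiles on Euclidean distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datamodel import (
    GROUP_BY_PROFILE,
    GROUP_NAMES,
    ORGANS,
    STRANDS,
    AnalysisConfig,
    ExpressionTensor,
    ValidationError,
)


@dataclass
class ExpressionCall:
    """Boolean expressed flags and supporting-accession counts.

    ``support`` and ``expressed`` are (gene, organ, strand) DataArrays;
    ``expressed`` is exactly ``support >= min_accessions``.
    """

    support: xr.DataArray
    expressed: xr.DataArray
    rpm_threshold: float
    min_accessions: int

    def expressed_genes(self, organ: str, strand: str) -> list[str]:
        mask = self.expressed.sel(organ=organ, strand=strand).values
        return [g for g, m in zip(self.expressed.coords["gene"].values, mask) if m]


def call_expression(tensor: ExpressionTensor, config: AnalysisConfig) -> ExpressionCall:
    """Apply the >= threshold / >= min_accessions expressed-gene rule."""
    if config.min_accessions > tensor.n_accessions:
        raise ValidationError(
            f"min_accessions={config.min_accessions} exceeds the "
            f"{tensor.n_accessions} accessions present"
        )
    support = (tensor.data >= config.rpm_threshold).sum("accession")
    expressed = support >= config.min_accessions
    return ExpressionCall(
        support=support,
        expressed=expressed,
        rpm_threshold=config.rpm_threshold,
        min_accessions=config.min_accessions,
    )


@dataclass
class ExpressionGroups:
    """Partition of one strand's expressed genes into the seven groups."""

    strand: str
    groups: dict[str, list[str]]
    unexpressed: list[str]

    def sizes(self) -> pd.Series:
        return pd.Series({g: len(self.groups[g]) for g in GROUP_NAMES}, name="count")

    def membership(self) -> pd.Series:
        """gene_id -> group label for every expressed gene."""
        items = [(g, name) for name in GROUP_NAMES for g in self.groups[name]]
        return pd.Series(dict(items), name="group")


def partition_groups(calls: ExpressionCall, strand: str) -> ExpressionGroups:
    """Assign each expressed gene to one of R, S, F, RS, FR, FS, RSF."""
    ex = calls.expressed.sel(strand=strand)
    genes = [str(g) for g in ex.coords["gene"].values]
    profiles = {o: ex.sel(organ=o).values for o in ORGANS}
    groups: dict[str, list[str]] = {name: [] for name in GROUP_NAMES}
    unexpressed: list[str] = []
    for i, g in enumerate(genes):
        profile = (
            bool(profiles["root"][i]),
            bool(profiles["seedling"][i]),
            bool(profiles["flower"][i]),
        )
        if not any(profile):
            unexpressed.append(g)
        else:
            groups[GROUP_BY_PROFILE[profile]].append(g)
    return ExpressionGroups(strand=strand, groups=groups, unexpressed=unexpressed)


@dataclass
class SampleSimilarity:
    """Pairwise Pearson correlations between samples plus their clustering.

    ``correlation`` is a symmetric samples x samples frame (labels
    ``accession:organ``); ``linkage`` is a scipy linkage matrix over the rows
    of the correlation matrix (Euclidean distance between correlation
    profiles); ``excluded`` lists zero-variance samples left out of the
    clustering.
    """

    strand: str
    correlation: pd.DataFrame
    linkage: np.ndarray | None
    clustered_labels: list[str]
    excluded: list[str] = field(default_factory=list)

    @property
    def leaf_order(self) -> list[str]:
        if self.linkage is None:
            return self.clustered_labels
        return [self.clustered_labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels at a cut producing ``n_clusters`` clusters."""
        if self.linkage is None:
            raise ValidationError("no clustering available")
        flat = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(flat, index=self.clustered_labels, name="cluster")

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with branch lengths."""
        if self.linkage is None:
            return "();"
        tree = hierarchy.to_tree(self.linkage)
        labels = self.clustered_labels

        def recurse(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{labels[node.id]}:{length:.6g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({recurse(tree.left, tree.dist)},{recurse(tree.right, tree.dist)});"


def sample_similarity(
    tensor: ExpressionTensor,
    strand: str,
    config: AnalysisConfig | None = None,
) -> SampleSimilarity:
    """Correlate all accession x organ samples of one strand and cluster them."""
    config = config or AnalysisConfig()
    if strand not in STRANDS:
        raise ValidationError(f"unknown strand {strand!r}")
    cols, labels = [], []
    for organ in ORGANS:
        frame = tensor.slice_frame(organ, strand)
        for acc in tensor.accession_ids:
            cols.append(frame[acc].to_numpy())
            labels.append(f"{acc}:{organ}")
    mat = np.column_stack(cols)
    if mat.shape[1] < 2:
        raise ValidationError("need at least 2 samples for correlation")
    if config.log_transform_correlation:
        mat = np.log1p(mat)
    sd = mat.std(axis=0)
    zero_var = sd == 0
    excluded = [lbl for lbl, z in zip(labels, zero_var) if z]
    if excluded:
        warnings.warn(
            f"zero-variance samples excluded from clustering: {excluded[:5]}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    corr[zero_var, :] = np.nan
    corr[:, zero_var] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=labels, columns=labels)

    keep = ~zero_var
    kept_labels = [lbl for lbl, k in zip(labels, keep) if k]
    linkage = None
    if keep.sum() >= 2:
        profiles = corr[np.ix_(keep, keep)]
        dists = pdist(profiles, metric="euclidean")
        linkage = hierarchy.linkage(dists, method=config.clustering_linkage)
    return SampleSimilarity(
        strand=strand,
        correlation=corr_df,
        linkage=linkage,
        clustered_labels=kept_labels,
        excluded=excluded,
    )


def organ_cluster_agreement(similarity: SampleSimilarity) -> float:
    """Fraction of samples whose 3-way cluster matches the majority organ map.

    1.0 means a 3-cluster cut of the dendrogram reproduces the organ
    partition exactly.
    """
    clusters = similarity.cut(len(ORGANS))
    organs = pd.Series(
        [lbl.rsplit(":", 1)[1] for lbl in similarity.clustered_labels],
        index=similarity.clustered_labels,
    )
    agree = 0
    for c in clusters.unique():
        members = organs[clusters == c]
        agree += (members == members.mode().iloc[0]).sum()
    return agree / len(clusters)
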