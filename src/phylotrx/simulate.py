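"""Synthetic study generator: expression, phylostrata and dN/dS with ground truth.

The generator emulates the statistical structure the analysis assumes: 12
phylostrata with an old-heavy age spectrum; 3 organs x 19 accessions x 2
strands of RPM-scale values in which organ effects dominate accession noise;
an old-to-young expression gradient ordered seedling < root < flower so the
seedling transcriptome is the evolutionarily oldest and flower the youngest;
sparse, age-independent antisense expression (under 1% of gene-accession
cells reach the 0.8 RPM call threshold); dN/dS ratios that increase with
gene age rank and always satisfy the retention filter; and organ-specific
gene groups with planted phylostratum enrichment peaks (seedling at
Embryophyta, root at Tracheophyta, flower at Magnoliophyta).

Expression noise is multiplicative log-normal with moderate gene-to-gene
dispersion, which keeps bootstrap standard errors of the indices a small
fraction of their means, as observed in real organ transcriptomes. An
optional age-magnitude slope can additionally make older genes more highly
expressed genome-wide.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .classify import ExpressionGroups
from .datamodel import (
    GROUP_NAMES,
    N_STRATA,
    ORGANS,
    AnalysisConfig,
    DivergenceTable,
    ExpressionTensor,
    PhylostratumMap,
    ValidationError,
)
from . import io as pio

#: The 19 MAGIC founder accessions used as default sample labels.
MAGIC_FOUNDERS: tuple[str, ...] = (
    "Bur-0", "Can-0", "Col-0", "Ct-1", "Edi-0", "Hi-0", "Kn-0", "Ler-0",
    "Mt-0", "No-0", "Oy-0", "Po-0", "Rsch-4", "Sf-2", "Tsu-0", "Wil-2",
    "Ws-0", "Wu-0", "Zu-0",
)

#: Genome-wide phylostratum proportions: 64.87% in PS1-3, 10.43% Embryophyta,
#: 6.22% Magnoliophyta, 6.94% A. thaliana, remainder uniform over the rest.
_REST = (1.0 - 0.6487 - 0.1043 - 0.0622 - 0.0694) / 6.0
DEFAULT_STRATUM_SPECTRUM: tuple[float, ...] = (
    0.30, 0.23, 0.1187,          # PS1-3, summing to 0.6487
    0.1043,                      # PS4 Embryophyta
    _REST,                       # PS5 Tracheophyta
    0.0622,                      # PS6 Magnoliophyta
    _REST, _REST, _REST, _REST, _REST,  # PS7-11
    0.0694,                      # PS12 A. thaliana
)

_GROUP_ORGANS: dict[str, tuple[str, ...]] = {
    "R": ("root",),
    "S": ("seedling",),
    "F": ("flower",),
    "RS": ("root", "seedling"),
    "FR": ("root", "flower"),
    "FS": ("seedling", "flower"),
    "RSF": ("root", "seedling", "flower"),
    "none": (),
}


@dataclass
class SimulationScenario:
    """Parameters of the synthetic study; defaults are the study conditions.

    ``organ_age_slope`` tilts each organ's expression by
    exp(slope * (ps - mean ps)), planting the seedling < root < flower
    transcriptome-age ordering. ``age_magnitude_slope`` is the genome-wide
    decline of base abundance with phylostratum. ``planted_peaks`` maps a
    gene group to {stratum: fold over-representation}.
    """

    n_genes: int = 2000
    n_accessions: int = 19
    stratum_spectrum: tuple[float, ...] = DEFAULT_STRATUM_SPECTRUM
    group_probs: dict[str, float] = field(
        default_factory=lambda: {
            "RSF": 0.40, "R": 0.06, "S": 0.02, "F": 0.06,
            "RS": 0.05, "FR": 0.04, "FS": 0.05, "none": 0.32,
        }
    )
    organ_age_slope: dict[str, float] = field(
        default_factory=lambda: {"seedling": -0.08, "root": 0.0, "flower": 0.08}
    )
    age_magnitude_slope: float = 0.0
    gene_log_mean: float = math.log(8.0)
    gene_log_sd: float = 0.35
    min_magnitude: float = 2.0   # RPM floor for expressed genes' base abundance
    accession_log_sd: float = 0.2
    antisense_gene_rate: float = 0.03
    antisense_cell_rate: float = 0.5
    antisense_log_sd: float = 1.0
    dnds_coverage: float = 0.85
    dnds_shape: float = 2.0
    dnds_scale_base: float = 0.10
    dnds_scale_slope: float = 0.02
    planted_peaks: dict[str, dict[int, float]] = field(
        default_factory=lambda: {"S": {4: 5.0}, "R": {5: 8.0}, "F": {6: 5.0}}
    )
    reference_species: tuple[str, ...] = ("A_lyrata",)
    accession_bias: bool = False  # zero a PS12 subset outside the first accession
    rng_seed: int = 0

    def __post_init__(self) -> None:
        spectrum = np.asarray(self.stratum_spectrum, dtype=float)
        if len(spectrum) != N_STRATA:
            raise ValidationError(f"stratum_spectrum needs {N_STRATA} entries")
        if not math.isclose(spectrum.sum(), 1.0, rel_tol=1e-6):
            raise ValidationError("stratum_spectrum must sum to 1")
        if (spectrum < 0).any():
            raise ValidationError("stratum_spectrum entries must be >= 0")
        total = sum(self.group_probs.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValidationError("group_probs must sum to 1")
        for g, peaks in self.planted_peaks.items():
            if g not in self.group_probs:
                raise ValidationError(f"planted peak for unknown group {g!r}")
            for stratum, fold in peaks.items():
                if not 1 <= stratum <= N_STRATA:
                    raise ValidationError(f"planted peak stratum {stratum} out of range")
                if fold <= 0:
                    raise ValidationError("fold-enrichments must be > 0")
                if self.group_probs[g] * fold >= 1:
                    raise ValidationError(
                        f"infeasible planted enrichment: group {g!r} x fold "
                        f"{fold} would exceed stratum {stratum} size"
                    )

    @property
    def accession_ids(self) -> list[str]:
        if self.n_accessions <= len(MAGIC_FOUNDERS):
            return list(MAGIC_FOUNDERS[: self.n_accessions])
        extra = [f"acc{i:02d}" for i in range(len(MAGIC_FOUNDERS), self.n_accessions)]
        return list(MAGIC_FOUNDERS) + extra


def default_scenario(**overrides) -> SimulationScenario:
    return SimulationScenario(**overrides)


def full_size_scenario(**overrides) -> SimulationScenario:
    """Genome-scale scenario (25,260 genes)."""
    overrides.setdefault("n_genes", 25260)
    return SimulationScenario(**overrides)


def null_scenario(**overrides) -> SimulationScenario:
    """No organ-age gradient and no planted enrichment."""
    overrides.setdefault(
        "organ_age_slope", {"seedling": 0.0, "root": 0.0, "flower": 0.0}
    )
    overrides.setdefault("planted_peaks", {})
    return SimulationScenario(**overrides)


@dataclass
class SimulatedDataset:
    """Generated inputs plus the ground truth that produced them."""

    tensor: ExpressionTensor
    ps_map: PhylostratumMap
    div_tables: dict[str, DivergenceTable]
    truth: dict


def simulate(
    scenario: SimulationScenario, seed: int | None = None
) -> SimulatedDataset:
    """Draw one synthetic study from the scenario (deterministic per seed)."""
    rng = np.random.default_rng(scenario.rng_seed if seed is None else seed)
    n = scenario.n_genes
    genes = [f"AT{i // 10000 + 1}G{(i % 10000) * 5 + 10000:05d}" for i in range(n)]
    accessions = scenario.accession_ids
    spectrum = np.asarray(scenario.stratum_spectrum, dtype=float)
    spectrum = spectrum / spectrum.sum()
    strata = rng.choice(np.arange(1, N_STRATA + 1), p=spectrum, size=n)
    mean_ps = float((spectrum * np.arange(1, N_STRATA + 1)).sum())

    # group labels with planted per-stratum fold over-representation
    labels = list(scenario.group_probs)
    base = np.array([scenario.group_probs[g] for g in labels])
    group = np.empty(n, dtype=object)
    for stratum in range(1, N_STRATA + 1):
        probs = base.copy()
        for g, peaks in scenario.planted_peaks.items():
            if stratum in peaks:
                probs[labels.index(g)] *= peaks[stratum]
        probs = probs / probs.sum()
        mask = strata == stratum
        if mask.any():
            group[mask] = rng.choice(labels, p=probs, size=int(mask.sum()))

    # base abundance: log-normal declining with stratum, floored at min_magnitude
    mu = scenario.gene_log_mean - scenario.age_magnitude_slope * (strata - mean_ps)
    lo = (math.log(scenario.min_magnitude) - mu) / scenario.gene_log_sd
    z = stats.truncnorm.rvs(lo, np.inf, size=n, random_state=rng)
    magnitude = np.exp(mu + scenario.gene_log_sd * z)

    member = {
        o: np.array([o in _GROUP_ORGANS[g] for g in group]) for o in ORGANS
    }
    n_acc = scenario.n_accessions
    arr = np.zeros((n, n_acc, len(ORGANS), 2))
    for oi, organ in enumerate(ORGANS):
        slope = scenario.organ_age_slope[organ]
        log_mean = np.log(magnitude) + slope * (strata - mean_ps)
        noise = rng.normal(0.0, scenario.accession_log_sd, size=(n, n_acc))
        vals = np.exp(log_mean[:, None] + noise)
        vals[~member[organ], :] = 0.0
        arr[:, :, oi, 0] = vals
    # antisense: sparse, age-independent
    active = rng.random(n) < scenario.antisense_gene_rate
    for oi in range(len(ORGANS)):
        cells = active[:, None] & (
            rng.random((n, n_acc)) < scenario.antisense_cell_rate
        )
        vals = np.exp(rng.normal(0.0, scenario.antisense_log_sd, size=(n, n_acc)))
        arr[:, :, oi, 1] = np.where(cells, vals, 0.0)

    if scenario.accession_bias:
        # presence/absence polymorphism: a PS12 subset present only in the
        # reference-like first accession
        ps12 = np.flatnonzero(strata == N_STRATA)
        chosen = rng.choice(ps12, size=max(1, len(ps12) // 4), replace=False)
        arr[np.ix_(chosen, np.arange(1, n_acc))] = 0.0

    import xarray as xr

    tensor = ExpressionTensor(
        xr.DataArray(
            arr,
            dims=("gene", "accession", "organ", "strand"),
            coords={
                "gene": genes,
                "accession": accessions,
                "organ": list(ORGANS),
                "strand": ["sense", "antisense"],
            },
        )
    )
    ps_map = PhylostratumMap(
        pd.Series(strata, index=pd.Index(genes, name="gene_id"))
    )

    div_tables: dict[str, DivergenceTable] = {}
    for species in scenario.reference_species:
        covered = rng.random(n) < scenario.dnds_coverage
        idx = np.flatnonzero(covered)
        scale = scenario.dnds_scale_base + scenario.dnds_scale_slope * strata[idx]
        ratio = rng.gamma(scenario.dnds_shape, scale)
        # redraw the rare tail so every row passes the retention filter
        bad = ratio >= 2.0
        while bad.any():
            ratio[bad] = rng.gamma(scenario.dnds_shape, scale[bad])
            bad = ratio >= 2.0
        ds_hi = np.minimum(4.9, 0.499 / ratio)
        ds = rng.uniform(0.05, ds_hi)
        dn = ratio * ds
        frame = pd.DataFrame(
            {"dN": dn, "dS": ds, "ratio": dn / ds},
            index=pd.Index([genes[i] for i in idx], name="gene_id"),
        )
        div_tables[species] = DivergenceTable(frame, species)

    truth = {
        "strata": pd.Series(strata, index=genes, name="phylostratum"),
        "groups": pd.Series(group, index=genes, name="group"),
        "planted_peaks": scenario.planted_peaks,
        "organ_age_slope": scenario.organ_age_slope,
        "expected_tai_order": ["seedling", "root", "flower"],
    }
    return SimulatedDataset(tensor, ps_map, div_tables, truth)


def write_scenario_fixtures(
    scenario: SimulationScenario, out_dir: str | Path, seed: int | None = None
) -> list[Path]:
    """Simulate and write every input file the pipeline reads, plus truth.yaml."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = simulate(scenario, seed=seed)
    paths = pio.write_expression(data.tensor, out_dir)
    pio.write_phylostrata(data.ps_map, out_dir / "phylostrata.tsv")
    paths.append(out_dir / "phylostrata.tsv")
    for species, table in data.div_tables.items():
        p = out_dir / f"dnds.{species}.tsv"
        pio.write_divergence(table, p)
        paths.append(p)
    truth = {
        "seed": scenario.rng_seed if seed is None else seed,
        "n_genes": scenario.n_genes,
        "n_accessions": scenario.n_accessions,
        "planted_peaks": {
            g: {int(k): float(v) for k, v in d.items()}
            for g, d in scenario.planted_peaks.items()
        },
        "organ_age_slope": {k: float(v) for k, v in scenario.organ_age_slope.items()},
        "group_sizes": {
            g: int((data.truth["groups"] == g).sum())
            for g in list(GROUP_NAMES) + ["none"]
        },
        "expected_tai_order": data.truth["expected_tai_order"],
    }
    with open(out_dir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
    paths.append(out_dir / "truth.yaml")
    return paths


def null_assignment(
    n_genes: int = 50000,
    seed: int = 0,
    groups: tuple[str, ...] = ("R", "S", "F", "RSF"),
) -> tuple[PhylostratumMap, ExpressionGroups]:
    """Uniform random strata and groups, independent of each other.

    A calibration input for the enrichment test: under this null every
    (group, stratum) cell follows the hypergeometric model exactly, so raw
    p-values should be (conservatively) uniform.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:06d}" for i in range(n_genes)]
    strata = rng.integers(1, N_STRATA + 1, size=n_genes)
    labels = rng.choice(list(groups), size=n_genes)
    ps_map = PhylostratumMap(pd.Series(strata, index=pd.Index(genes, name="gene_id")))
    grouped: dict[str, list[str]] = {g: [] for g in GROUP_NAMES}
    for gene, lab in zip(genes, labels):
        grouped[lab].append(gene)
    eg = ExpressionGroups(strand="sense", groups=grouped, unexpressed=[])
    return ps_map, eg
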