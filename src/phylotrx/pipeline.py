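"""End-to-end orchestration: classify -> indices -> relative expression -> enrichment.

``run_all`` executes the full analysis on a directory of input files (or an
in-memory dataset), writes every stage's tables, and records a manifest with
input/output digests, the configuration snapshot and per-stage counts so a
run can be reproduced and verified. ``report`` renders the summary surfaces:
expression-breadth (Venn) counts, TAI/TDI profiles with bootstrap error
bars, old/young relative-expression bars, and enrichment bars with
significance stars.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as pio
from .classify import (
    call_expression,
    organ_cluster_agreement,
    partition_groups,
    sample_similarity,
)
from .datamodel import (
    ORGANS,
    STRANDS,
    AnalysisConfig,
    DivergenceTable,
    ExpressionTensor,
    PhylostratumMap,
    PipelineError,
    UndefinedIndexError,
)
from .enrichment import enrich
from .indices import bootstrap_all, compare_organs
from .relexpr import class_contrast_table, relative_expression_profile

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    version: str
    seed: int
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


@dataclass
class Dataset:
    tensor: ExpressionTensor
    ps_map: PhylostratumMap
    div_tables: dict[str, DivergenceTable]


def load_dataset(input_dir: str | Path) -> tuple[Dataset, dict[str, str]]:
    """Read expression slices, the phylostratum map and all dN/dS tables."""
    input_dir = Path(input_dir)
    digests: dict[str, str] = {}
    paths = pio.expression_paths(input_dir)
    if not paths:
        raise PipelineError(f"no <organ>.<strand>.tsv expression tables in {input_dir}")
    tensor, _ = pio.read_expression(paths)
    for p in paths.values():
        digests[p.name] = _digest(p)
    ps_path = input_dir / "phylostrata.tsv"
    if not ps_path.exists():
        raise PipelineError(f"missing phylostratum map {ps_path}")
    ps_map = pio.read_phylostrata(ps_path)
    digests[ps_path.name] = _digest(ps_path)
    div_tables: dict[str, DivergenceTable] = {}
    for p in sorted(input_dir.glob("dnds.*.tsv")):
        species = p.name[len("dnds."):-len(".tsv")]
        div_tables[species] = pio.read_divergence(p, species)
        digests[p.name] = _digest(p)
    return Dataset(tensor, ps_map, div_tables), digests


def run_all(
    input_dir: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    strands: tuple[str, ...] = STRANDS,
) -> RunManifest:
    """Execute every stage and write all outputs plus ``manifest.json``."""
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__, seed=config.rng_seed,
        config=dataclasses.asdict(config),
    )
    caught: list[str] = []

    def _stage(name):
        logger.info("stage %s", name)
        manifest.stages.append(name)

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            dataset, digests = load_dataset(input_dir)
        except PipelineError as exc:
            raise PipelineError(f"stage 'load' failed: {exc}") from exc
        manifest.inputs = digests
        manifest.counts["n_genes"] = dataset.tensor.n_genes
        manifest.counts["n_accessions"] = dataset.tensor.n_accessions

        # ---- classify -------------------------------------------------
        _stage("classify")
        calls = call_expression(dataset.tensor, config)
        for strand in strands:
            groups = partition_groups(calls, strand)
            groups.membership().rename_axis("gene_id").to_frame().to_csv(
                out_dir / f"groups.{strand}.tsv", sep="\t"
            )
            groups.sizes().rename_axis("group").to_frame().to_csv(
                out_dir / f"venn.{strand}.tsv", sep="\t"
            )
            manifest.counts[f"expressed_{strand}"] = int(groups.sizes().sum())
            sim = sample_similarity(dataset.tensor, strand, config)
            sim.correlation.to_csv(out_dir / f"correlation.{strand}.tsv", sep="\t")
            (out_dir / f"dendrogram.{strand}.nwk").write_text(sim.to_newick() + "\n")

        # ---- indices --------------------------------------------------
        _stage("indices")
        index_rows, test_rows = [], []
        for strand in strands:
            annotations: list = [dataset.ps_map] + list(dataset.div_tables.values())
            for annotation in annotations:
                try:
                    results = bootstrap_all(
                        dataset.tensor, annotation, config, strand=strand
                    )
                except UndefinedIndexError as exc:
                    raise PipelineError(
                        f"stage 'indices' failed for strand {strand!r}: {exc}"
                    ) from exc
                for acc, res in results.items():
                    index_rows.append(res.summary_frame())
                    comp = compare_organs(res)
                    t = comp.tests.copy()
                    t.insert(0, "accession", acc)
                    t.insert(1, "index_kind", res.index_kind)
                    t.insert(2, "strand", strand)
                    t.insert(
                        3, "reference_species", res.reference_species or ""
                    )
                    test_rows.append(t)
        indices_df = pd.concat(index_rows, ignore_index=True)
        indices_df.to_csv(out_dir / "indices.tsv", sep="\t", index=False)
        pd.concat(test_rows, ignore_index=True).to_csv(
            out_dir / "organ_tests.tsv", sep="\t", index=False
        )
        manifest.counts["index_rows"] = len(indices_df)

        # ---- relative expression --------------------------------------
        _stage("relexpr")
        rel_rows, contrast_rows = [], []
        for strand in strands:
            for acc in dataset.tensor.accession_ids:
                try:
                    profile = relative_expression_profile(
                        dataset.tensor, dataset.ps_map, acc, strand, config
                    )
                except UndefinedIndexError as exc:
                    raise PipelineError(
                        f"stage 'relexpr' failed for {acc!r}/{strand}: {exc}"
                    ) from exc
                rel_rows.append(profile)
                contrast_rows.append(class_contrast_table(profile, config))
        pd.concat(rel_rows, ignore_index=True).to_csv(
            out_dir / "relexpr.tsv", sep="\t", index=False
        )
        pd.concat(contrast_rows, ignore_index=True).to_csv(
            out_dir / "class_tests.tsv", sep="\t", index=False
        )

        # ---- enrichment -----------------------------------------------
        _stage("enrichment")
        for strand in strands:
            groups = partition_groups(calls, strand)
            table = enrich(groups, dataset.ps_map, config)
            table.table.to_csv(
                out_dir / f"enrichment.{strand}.tsv", sep="\t", index=False
            )
            manifest.counts[f"enrichment_tests_{strand}"] = table.n_tests

        caught = [str(w.message) for w in wlist]

    manifest.warnings = caught
    for p in sorted(out_dir.glob("*.tsv")) + sorted(out_dir.glob("*.nwk")):
        manifest.outputs[p.name] = _digest(p)
    manifest.write(out_dir / "manifest.json")
    return manifest


def report(out_dir: str | Path, report_dir: str | Path | None = None) -> Path:
    """Render summary tables and figures from a completed run directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    report_dir = Path(report_dir) if report_dir else out_dir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    lines = ["# Pipeline summary", ""]

    for strand in STRANDS:
        venn_path = out_dir / f"venn.{strand}.tsv"
        if venn_path.exists():
            venn = pd.read_csv(venn_path, sep="\t", index_col=0)
            lines.append(f"## Expression breadth ({strand})")
            total = int(venn["count"].sum())
            if total == 0:
                lines.append("no calls\n")
                continue
            multi = int(
                venn.loc[[g for g in venn.index if len(g) > 1], "count"].sum()
            )
            lines.append(venn.to_markdown())
            lines.append(
                f"\nexpressed genes: {total}; shared by >1 organ: "
                f"{multi} ({100 * multi / total:.2f}%)\n"
            )

    idx_path = out_dir / "indices.tsv"
    if idx_path.exists():
        idx = pd.read_csv(idx_path, sep="\t")
        for kind in idx["index_kind"].unique():
            sub = idx[(idx["index_kind"] == kind) & (idx["strand"] == "sense")]
            if sub.empty:
                continue
            fig, ax = plt.subplots(figsize=(8, 3.2))
            for organ in ORGANS:
                o = sub[sub["organ"] == organ]
                ax.errorbar(
                    o["accession"], o["estimate"], yerr=o["boot_se"],
                    label=organ, marker="o", lw=1, capsize=2,
                )
            ax.set_ylabel(kind)
            ax.tick_params(axis="x", rotation=90, labelsize=7)
            ax.legend(fontsize=8)
            fig.tight_layout()
            fig.savefig(report_dir / f"{kind.lower()}_profile.png", dpi=120)
            plt.close(fig)
            mean_by_organ = sub.groupby("organ")["estimate"].mean().reindex(ORGANS)
            lines.append(f"## {kind} (sense), mean over accessions")
            lines.append(mean_by_organ.to_frame().to_markdown() + "\n")

    rel_path = out_dir / "relexpr.tsv"
    if rel_path.exists():
        rel = pd.read_csv(rel_path, sep="\t")
        sense = rel[rel["strand"] == "sense"]
        if not sense.empty:
            mean_re = (
                sense.groupby(["organ", "class"])["RE"].mean().unstack()
            ).reindex(ORGANS)
            ax = mean_re.plot(kind="bar", figsize=(5, 3))
            ax.set_ylabel("mean relative expression")
            ax.figure.tight_layout()
            ax.figure.savefig(report_dir / "relative_expression.png", dpi=120)
            plt.close(ax.figure)
            lines.append("## Mean relative expression by class (sense)")
            lines.append(mean_re.to_markdown() + "\n")

    for strand in STRANDS:
        enr_path = out_dir / f"enrichment.{strand}.tsv"
        if enr_path.exists():
            enr = pd.read_csv(enr_path, sep="\t")
            if enr["observed"].sum() == 0:
                lines.append(f"## Enrichment ({strand})\nno calls\n")
                continue
            groups = enr["group"].unique()
            fig, axes = plt.subplots(
                len(groups), 1, figsize=(7, 2.2 * len(groups)), sharex=True
            )
            for ax, g in zip(np.atleast_1d(axes), groups):
                sub = enr[enr["group"] == g]
                ax.bar(sub["phylostratum"], sub["log_odds"].fillna(0.0))
                ax.axhline(0, color="gray", lw=0.8)
                for _, row in sub.iterrows():
                    if row.get("significant", False):
                        stars = (
                            "***" if row["p_bonferroni"] < 0.001
                            else "**" if row["p_bonferroni"] < 0.01 else "*"
                        )
                        ax.annotate(
                            stars, (row["phylostratum"], row["log_odds"]),
                            ha="center", fontsize=7,
                        )
                ax.set_ylabel(g)
            fig.tight_layout()
            fig.savefig(report_dir / f"enrichment_{strand}.png", dpi=120)
            plt.close(fig)
            lines.append(f"## Enrichment ({strand}): significant cells")
            sig = enr[enr["significant"] == True]  # noqa: E712
            lines.append(
                (sig.to_markdown(index=False) if len(sig) else "none") + "\n"
            )

    summary = report_dir / "summary.md"
    summary.write_text("\n".join(lines) + "\n")
    return summary
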