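"""Phylostratum enrichment of organ-specific and shared expressed genes.

For each gene group (organ-specific R, S, F and the three-organ shared RSF)
and each phylostratum, the observed gene count is compared with the count
expected if group membership were independent of gene age. Enrichment is
summarized as a log-odds ratio log(observed/expected); zero means the group
draws from the stratum exactly in proportion to the genome. Significance is
a two-tailed hypergeometric test, Bonferroni-corrected over all tests
performed. A stratum containing zero genes of a group has an undefined
log-odds; the observed count is then conservatively set to one and the value
flagged as adjusted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    N_STRATA,
    AnalysisConfig,
    PhylostratumMap,
    ValidationError,
)
from .classify import ExpressionGroups

ENRICHMENT_GROUPS: tuple[str, ...] = ("R", "S", "F", "RSF")


def expected_count(group_size: int, stratum_total: int, genome_total: int) -> float:
    """Expected genes of a group in a stratum under independence.

    genome_total counts all genes with an assigned stratum (the background).
    """
    if genome_total <= 0:
        raise ValidationError("genome_total must be positive")
    if stratum_total < 0 or group_size < 0:
        raise ValidationError("counts must be non-negative")
    return group_size * stratum_total / genome_total


def log_odds(
    observed: float, expected: float, config: AnalysisConfig | None = None
) -> tuple[float, bool]:
    """log(observed / expected); returns (value, adjusted).

    observed = 0 is conservatively replaced by 1 before taking the ratio,
    and the result flagged adjusted. expected <= 0 yields NaN (undefined).
    """
    config = config or AnalysisConfig()
    if expected <= 0:
        return float("nan"), False
    adjusted = observed == 0
    obs = 1 if adjusted else observed
    return math.log(obs / expected, config.log_odds_base), adjusted


def hypergeom_test(
    observed: int,
    group_size: int,
    stratum_total: int,
    genome_total: int,
    rule: str = "double",
) -> float:
    """Two-tailed hypergeometric p for the overlap of a group and a stratum.

    The sampling model draws ``group_size`` genes without replacement from
    ``genome_total`` of which ``stratum_total`` belong to the stratum. The
    default two-sided rule doubles the smaller tail (each tail including the
    observed count), capped at 1; ``rule="minlike"`` instead sums the
    probabilities of all outcomes no more likely than the observed one.
    """
    if not (
        0 <= stratum_total <= genome_total and 0 <= group_size <= genome_total
    ):
        raise ValidationError("inconsistent totals for hypergeometric test")
    lo = max(0, group_size + stratum_total - genome_total)
    hi = min(group_size, stratum_total)
    if not lo <= observed <= hi:
        raise ValidationError(
            f"observed={observed} outside hypergeometric support [{lo}, {hi}]"
        )
    dist = stats.hypergeom(genome_total, stratum_total, group_size)
    if rule == "double":
        lower = float(dist.cdf(observed))
        upper = float(dist.sf(observed - 1))
        return min(1.0, 2.0 * min(lower, upper))
    if rule == "minlike":
        support = np.arange(lo, hi + 1)
        pmf = dist.pmf(support)
        p_obs = float(dist.pmf(observed))
        # tolerance guards against ties broken by floating-point noise
        return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-12)].sum()))
    raise ValidationError(f"unknown two-tailed rule {rule!r}")


@dataclass
class EnrichmentTable:
    """Observed/expected counts, log-odds and p-values per group x stratum."""

    strand: str
    table: pd.DataFrame
    genome_total: int
    n_tests: int
    n_unassigned: int  # grouped genes without a phylostratum, excluded

    def most_significant_stratum(self, group: str) -> int:
        """Stratum with the smallest raw p for a group (ties -> strongest enrichment)."""
        sub = self.table[(self.table["group"] == group) & self.table["p_raw"].notna()]
        if sub.empty:
            raise ValidationError(f"no tested strata for group {group!r}")
        sub = sub.sort_values(
            ["p_raw", "log_odds"], ascending=[True, False], kind="mergesort"
        )
        return int(sub.iloc[0]["phylostratum"])


def enrich(
    groups: ExpressionGroups,
    ps_map: PhylostratumMap,
    config: AnalysisConfig | None = None,
    group_names: tuple[str, ...] = ENRICHMENT_GROUPS,
) -> EnrichmentTable:
    """Full enrichment table over the requested groups x 12 strata.

    The background is every gene with an assigned phylostratum; grouped genes
    lacking a stratum are excluded from their group and counted. With
    ``config.expected_model == "table"`` the expectation instead uses the
    4 x 12 contingency table over grouped genes only
    (row total x column total / grand total).
    """
    config = config or AnalysisConfig()
    assignment = ps_map.assignment
    genome_total = len(assignment)
    if genome_total == 0:
        raise ValidationError("empty phylostratum map")
    stratum_totals = ps_map.counts()

    member_strata: dict[str, pd.Series] = {}
    n_unassigned = 0
    for g in group_names:
        genes = pd.Index(groups.groups.get(g, []))
        known = genes.intersection(assignment.index)
        n_unassigned += len(genes) - len(known)
        member_strata[g] = assignment.loc[known]

    if config.expected_model == "table":
        grand = sum(len(s) for s in member_strata.values())
        col_totals = (
            pd.concat(member_strata.values()).value_counts()
            .reindex(range(1, N_STRATA + 1), fill_value=0)
            if grand
            else stratum_totals * 0
        )

    rows = []
    n_tests = 0
    for g in group_names:
        strata = member_strata[g]
        group_size = len(strata)
        obs_counts = strata.value_counts().reindex(
            range(1, N_STRATA + 1), fill_value=0
        )
        for stratum in range(1, N_STRATA + 1):
            stratum_total = int(stratum_totals[stratum])
            observed = int(obs_counts[stratum])
            if config.expected_model == "table":
                expected = (
                    group_size * int(col_totals[stratum]) / grand if grand else 0.0
                )
            else:
                expected = expected_count(group_size, stratum_total, genome_total)
            if stratum_total == 0:
                warnings.warn(
                    f"stratum {stratum} holds no genes; excluded from testing",
                    stacklevel=2,
                )
                rows.append(
                    {
                        "group": g, "phylostratum": stratum,
                        "observed": observed, "expected": 0.0,
                        "log_odds": float("nan"), "adjusted": False,
                        "p_raw": float("nan"),
                    }
                )
                continue
            lo_val, adj = log_odds(observed, expected, config)
            p = hypergeom_test(
                observed, group_size, stratum_total, genome_total,
                rule=config.two_tailed_rule,
            )
            n_tests += 1
            rows.append(
                {
                    "group": g, "phylostratum": stratum,
                    "observed": observed, "expected": expected,
                    "log_odds": lo_val, "adjusted": adj, "p_raw": p,
                }
            )
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = np.minimum(1.0, df["p_raw"] * max(n_tests, 1))
    df["significant"] = df["p_bonferroni"] < config.alpha
    df.insert(0, "strand", groups.strand)
    return EnrichmentTable(
        strand=groups.strand,
        table=df,
        genome_total=genome_total,
        n_tests=n_tests,
        n_unassigned=n_unassigned,
    )
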