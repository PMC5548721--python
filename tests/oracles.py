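"""Independent brute-force oracles used to freeze expected values.

Everything here is deliberately naive (enumeration, direct sums) and shares
no code path with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def hypergeom_pmf_by_enumeration(genome_total: int, stratum_total: int,
                                 group_size: int) -> dict[int, Fraction]:
    """Exact overlap pmf by enumerating every C(genome, group) draw.

    The first ``stratum_total`` items are the stratum; every subset of size
    ``group_size`` is equally likely and contributes to its overlap count.
    """
    counts: dict[int, int] = {}
    stratum = set(range(stratum_total))
    total = 0
    for subset in itertools.combinations(range(genome_total), group_size):
        k = len(stratum.intersection(subset))
        counts[k] = counts.get(k, 0) + 1
        total += 1
    return {k: Fraction(c, total) for k, c in counts.items()}


def two_tailed_p_from_pmf(pmf: dict[int, Fraction], observed: int,
                          rule: str = "double") -> float:
    """Two-sided p from an exact pmf: doubled smaller tail or min-likelihood."""
    if rule == "double":
        lower = sum(p for k, p in pmf.items() if k <= observed)
        upper = sum(p for k, p in pmf.items() if k >= observed)
        return float(min(Fraction(1), 2 * min(lower, upper)))
    if rule == "minlike":
        p_obs = pmf[observed]
        return float(min(Fraction(1), sum(p for p in pmf.values() if p <= p_obs)))
    raise ValueError(rule)


def mannwhitney_two_sided_exact(x, y) -> tuple[float, float]:
    """(U of x, two-sided p) by enumerating all rank assignments.

    Assumes no ties. p doubles the smaller tail of the exact U distribution,
    capped at 1.
    """
    m, n = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == m + n, "oracle requires untied values"
    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    us = []
    for positions in itertools.combinations(range(m + n), m):
        xs = [pooled[i] for i in positions]
        rest = [pooled[i] for i in range(m + n) if i not in positions]
        us.append(sum(1 for xi in xs for yi in rest if xi > yi))
    total = len(us)
    lower = sum(1 for u in us if u <= u_obs) / total
    upper = sum(1 for u in us if u >= u_obs) / total
    return float(u_obs), min(1.0, 2 * min(lower, upper))


def exact_two_gene_bootstrap_sd(values_a: tuple[float, float],
                                expr: tuple[float, float]) -> float:
    """Exact resampling SD of a 2-gene expression-weighted mean.

    Drawing 2 genes with replacement has three outcomes with binomial
    weights 1/4, 1/2, 1/4; the SD is over that exact distribution.
    """
    (a1, a2), (e1, e2) = values_a, expr
    outcomes = [
        (0.25, (2 * a1 * e1) / (2 * e1)),
        (0.50, (a1 * e1 + a2 * e2) / (e1 + e2)),
        (0.25, (2 * a2 * e2) / (2 * e2)),
    ]
    mean = sum(w * v for w, v in outcomes)
    var = sum(w * (v - mean) ** 2 for w, v in outcomes)
    return math.sqrt(var)


def weighted_mean_direct(ann, expr) -> float:
    """Plain ratio-of-sums weighted mean over paired sequences."""
    num = sum(a * e for a, e in zip(ann, expr))
    den = sum(expr)
    return num / den
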