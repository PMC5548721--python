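"""Per-phylostratum relative expression and the old/young class contrast.

For each phylostratum l and organ s the mean partial expression g_ls (mean
of the partial concentrations f_is over the stratum's genes) is min-max
scaled across organs:

    RE_ls = (g_ls - g_lmin) / (g_lmax - g_lmin)

so RE is 0 at the organ where the stratum is least expressed and 1 where it
is most expressed. Strata are then collapsed into an evolutionarily old
class (PS1..old_class_max_stratum, default PS1-3: pre-land-plant origins)
and a young class (the remaining strata), and the two classes are compared
within each organ by Welch's t-test on the stratum-level RE values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    N_STRATA,
    ORGANS,
    AnalysisConfig,
    ExpressionTensor,
    PhylostratumMap,
    ValidationError,
)
from .indices import partial_concentrations


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def mean_partial_expression(
    concentrations: pd.Series, ps_map: PhylostratumMap, stratum: int
) -> float:
    """Mean of f_is over the genes of one stratum; NaN if the stratum is empty."""
    genes = ps_map.assignment[ps_map.assignment == stratum].index
    genes = genes.intersection(concentrations.index)
    if len(genes) == 0:
        return float("nan")
    return float(concentrations.loc[genes].mean())


def relative_expression(g_bar: pd.Series) -> pd.Series:
    """Min-max scale mean partial expression across organs into [0, 1].

    A degenerate stratum (identical g across all organs) maps to 0.5
    everywhere, with a warning.
    """
    if len(g_bar) < 2:
        raise ValidationError("relative expression needs >= 2 organs")
    lo, hi = float(g_bar.min()), float(g_bar.max())
    if hi == lo:
        warnings.warn(
            "degenerate stratum: identical mean partial expression across organs",
            stacklevel=2,
        )
        return pd.Series(0.5, index=g_bar.index)
    return (g_bar - lo) / (hi - lo)


def relative_expression_profile(
    tensor: ExpressionTensor,
    ps_map: PhylostratumMap,
    accession: str,
    strand: str = "sense",
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Long-format profile: one row per (stratum, organ) with g_bar, RE, class.

    Partial concentrations are computed per organ sample over the genes with
    an assigned stratum, so RE is invariant to per-sample rescaling of the
    raw expression.
    """
    config = config or AnalysisConfig()
    conc: dict[str, pd.Series] = {}
    for organ in ORGANS:
        e = tensor.sample(accession, organ, strand)
        e = e.loc[e.index.intersection(ps_map.assignment.index)]
        conc[organ] = partial_concentrations(e)
    rows = []
    for stratum in range(1, N_STRATA + 1):
        g_bar = pd.Series(
            {o: mean_partial_expression(conc[o], ps_map, stratum) for o in ORGANS}
        )
        if g_bar.isna().all():
            continue  # empty stratum: reported as missing
        re = relative_expression(g_bar)
        cls = "old" if stratum <= config.old_class_max_stratum else "young"
        for organ in ORGANS:
            rows.append(
                {
                    "accession": accession,
                    "strand": strand,
                    "phylostratum": stratum,
                    "organ": organ,
                    "g_bar": g_bar[organ],
                    "RE": re[organ],
                    "class": cls,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ClassContrast:
    """Welch t-test of old vs young stratum-level RE within one organ."""

    accession: str
    strand: str
    organ: str
    statistic: float
    p: float
    stars: str
    direction: str  # "old > young", "young > old" or "none"
    mean_old: float
    mean_young: float
    degenerate: bool = False


def class_contrast(
    profile: pd.DataFrame, organ: str, config: AnalysisConfig | None = None
) -> ClassContrast:
    """Compare old- and young-class RE values within one organ.

    Uses Welch's (unequal-variance) t-test on stratum-level RE. When both
    classes have zero variance the test statistic is undefined: equal means
    give p = 1, unequal means are reported as a maximally separated
    degenerate case (p = 0) with the effect direction.
    """
    sub = profile[profile["organ"] == organ]
    old = sub.loc[sub["class"] == "old", "RE"].to_numpy(dtype=float)
    young = sub.loc[sub["class"] == "young", "RE"].to_numpy(dtype=float)
    if len(old) < 2 or len(young) < 2:
        raise ValidationError(
            f"class contrast in {organ!r} needs >= 2 strata per class "
            f"(got {len(old)} old, {len(young)} young)"
        )
    acc = sub["accession"].iloc[0] if len(sub) else ""
    strand = sub["strand"].iloc[0] if len(sub) else ""
    mo, my = float(old.mean()), float(young.mean())
    direction = "old > young" if mo > my else ("young > old" if my > mo else "none")
    # variances below machine-noise level count as zero
    if old.var(ddof=1) < 1e-20 and young.var(ddof=1) < 1e-20:
        p = 1.0 if abs(mo - my) < 1e-9 else 0.0
        if p == 1.0:
            direction = "none"
        stat = 0.0 if p == 1.0 else float(np.sign(mo - my)) * float("inf")
        return ClassContrast(
            accession=acc, strand=strand, organ=organ, statistic=stat, p=p,
            stars=significance_stars(p), direction=direction,
            mean_old=mo, mean_young=my, degenerate=True,
        )
    res = stats.ttest_ind(old, young, equal_var=False)
    return ClassContrast(
        accession=acc, strand=strand, organ=organ,
        statistic=float(res.statistic), p=float(res.pvalue),
        stars=significance_stars(float(res.pvalue)), direction=direction,
        mean_old=mo, mean_young=my,
    )


def class_contrast_table(
    profile: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Class contrasts for every organ present in the profile."""
    rows = []
    for organ in ORGANS:
        c = class_contrast(profile, organ, config)
        rows.append(
            {
                "accession": c.accession,
                "strand": c.strand,
                "organ": c.organ,
                "t": c.statistic,
                "p": c.p,
                "stars": c.stars,
                "direction": c.direction,
                "mean_old_RE": c.mean_old,
                "mean_young_RE": c.mean_young,
                "degenerate": c.degenerate,
            }
        )
    return pd.DataFrame(rows)
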