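"""Genotype-phenotype association under the additive fixed-effects model.

Melatonin concentration is modelled as

    Y_ij = mu + G_i + P_j + e_ij

with genotype (G) and age class (P) as categorical fixed effects under
sum-to-zero constraints, fit by ordinary least squares. The genotype effect
is tested with a partial F-test (type-II sums of squares: genotype after
age). Reported per-genotype means are raw arithmetic class means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io import PhenotypeRecord

logger = logging.getLogger(__name__)


@dataclass
class AssociationModel:
    mu: float
    genotype_effects: dict[str, float]
    age_effects: dict[str, float]
    genotype_F: float
    genotype_p: float
    genotype_means: dict[str, float]
    residuals: np.ndarray
    nobs: int


@dataclass
class SiteAssociation:
    site: str
    genotype_counts: dict[str, int]
    model: AssociationModel | None
    significant: bool
    untestable: bool = False
    dropped_classes: list[str] = field(default_factory=list)


def _sum_to_zero_effects(result, factor: str, levels: list[str]) -> dict[str, float]:
    """Recover all level effects from a sum-coded fit (last level = -sum)."""
    effects = {}
    total = 0.0
    for level in levels[:-1]:
        name = f"C({factor}, Sum)[S.{level}]"
        value = float(result.params.get(name, 0.0))
        effects[level] = value
        total += value
    effects[levels[-1]] = -total
    return effects


def fit_association(
    records: list[PhenotypeRecord],
    site: str,
    alpha: float = 0.05,
    min_class_size: int = 2,
) -> SiteAssociation:
    """Fit the two-factor OLS model at one typed site and test the genotype term.

    Animals missing the genotype or age are excluded (complete-case
    analysis); genotype classes with fewer than ``min_class_size``
    observations are dropped with a notice. If fewer than two classes remain
    the site is flagged untestable.
    """
    rows = [
        {"melatonin": r.melatonin, "age": r.age, "genotype": r.genotypes[site]}
        for r in records
        if site in r.genotypes and r.age is not None
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return SiteAssociation(site, {}, None, False, untestable=True)

    counts = df["genotype"].value_counts().to_dict()
    dropped = [g for g, c in counts.items() if c < min_class_size]
    if dropped:
        logger.info("site %s: dropping genotype classes with < %d observations: %s",
                    site, min_class_size, sorted(dropped))
        df = df[~df["genotype"].isin(dropped)]
    genotype_counts = df["genotype"].value_counts().to_dict()
    if len(genotype_counts) < 2:
        return SiteAssociation(
            site, genotype_counts, None, False, untestable=True,
            dropped_classes=sorted(dropped),
        )

    g_levels = sorted(genotype_counts)
    a_levels = sorted(df["age"].unique())
    if len(a_levels) > 1:
        formula = "melatonin ~ C(genotype, Sum) + C(age, Sum)"
    else:
        # a single age level degenerates to one-way ANOVA on genotype
        formula = "melatonin ~ C(genotype, Sum)"
    result = smf.ols(formula, data=df).fit()

    anova = sm.stats.anova_lm(result, typ=2)
    F = float(anova.loc["C(genotype, Sum)", "F"])
    p = float(anova.loc["C(genotype, Sum)", "PR(>F)"])
    if not np.isfinite(p):
        # perfect fit (zero residual variance) with a real genotype effect
        ss_geno = float(anova.loc["C(genotype, Sum)", "sum_sq"])
        p = 0.0 if ss_geno > 0 else 1.0
        F = np.inf if ss_geno > 0 else 0.0

    model = AssociationModel(
        mu=float(result.params["Intercept"]),
        genotype_effects=_sum_to_zero_effects(result, "genotype", g_levels),
        age_effects=(
            _sum_to_zero_effects(result, "age", a_levels) if len(a_levels) > 1
            else {a_levels[0]: 0.0}
        ),
        genotype_F=F,
        genotype_p=p,
        genotype_means=df.groupby("genotype")["melatonin"].mean().to_dict(),
        residuals=np.asarray(result.resid),
        nobs=int(result.nobs),
    )
    return SiteAssociation(
        site=site,
        genotype_counts=genotype_counts,
        model=model,
        significant=bool(p < alpha),
        dropped_classes=sorted(dropped),
    )


def associate_all_sites(
    records: list[PhenotypeRecord], alpha: float = 0.05
) -> list[SiteAssociation]:
    sites = sorted({s for r in records for s in r.genotypes})
    return [fit_association(records, s, alpha=alpha) for s in sites]


def association_table(associations: list[SiteAssociation]) -> pd.DataFrame:
    rows = []
    for a in associations:
        rows.append(
            {
                "site": a.site,
                "classes": ";".join(sorted(a.genotype_counts)),
                "counts": ";".join(str(a.genotype_counts[g]) for g in sorted(a.genotype_counts)),
                "means": ";".join(
                    f"{a.model.genotype_means[g]:.4g}" for g in sorted(a.genotype_counts)
                ) if a.model else "",
                "F": a.model.genotype_F if a.model else np.nan,
                "p": a.model.genotype_p if a.model else np.nan,
                "significant": a.significant,
                "untestable": a.untestable,
            }
        )
    return pd.DataFrame(rows)


def summarize_bins(values, bin_edges=(0.0, 0.5, 1.0)) -> pd.DataFrame:
    """Bin phenotype values into left-closed right-open intervals (last open above).

    Returns a table of bin label, count, and percentage of the total rounded
    to one decimal place.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("summarize_bins requires at least one value")
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    if np.any(arr < edges[0]):
        raise ValueError(f"values below the first bin edge {edges[0]}")
    counts, _ = np.histogram(arr, bins=edges + [np.inf])
    labels = [f"[{a:g}, {b:g})" for a, b in zip(edges, edges[1:])] + [f">= {edges[-1]:g}"]
    total = arr.size
    return pd.DataFrame(
        {
            "bin": labels,
            "count": counts,
            "percent": np.round(100.0 * counts / total, 1),
        }
    )
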