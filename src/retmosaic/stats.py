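"""Group-level statistics: per-retina aggregation and comparison tests.

The retina, not the image, is the unit of statistical comparison: per-image
metric values are averaged to a retinal mean, and retinal means are compared
across genotypes — one-way ANOVA with Tukey HSD post-hoc tests for three or
more genotypes, Student's t-test for two, two-way ANOVA where a second
factor (e.g. threshold level) is crossed with genotype, and step-up
Benjamini–Hochberg adjustment where families of tests are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GROUP_TABLE_COLUMNS, validate_group_table

__all__ = [
    "StatsReport",
    "retina_means",
    "anova_tukey",
    "two_way_anova",
    "t_test",
    "bh_adjust",
]


@dataclass
class StatsReport:
    test_name: str
    groups: tuple[str, ...]
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    adjustment: str | None = None
    n_per_group: tuple[int, ...] = ()


def retina_means(per_image: pd.DataFrame, metric_name: str | None = None) -> pd.DataFrame:
    """Average per-image values to one retinal mean per retina.

    ``per_image`` needs columns image_id, retina_id, genotype, value (and
    optionally metric_name).  A retina carrying conflicting genotype labels
    is an upstream bookkeeping error and is rejected.
    """
    required = {"image_id", "retina_id", "genotype", "value"}
    missing = required - set(per_image.columns)
    if missing:
        raise ValueError(f"per-image table missing columns: {sorted(missing)}")
    geno_counts = per_image.groupby("retina_id")["genotype"].nunique()
    bad = geno_counts[geno_counts > 1]
    if len(bad):
        raise ValueError(f"retina(s) with conflicting genotype labels: {list(bad.index)}")
    out = (
        per_image.groupby(["retina_id", "genotype"], as_index=False)["value"].mean()
    )
    out["metric_name"] = metric_name or (
        str(per_image["metric_name"].iloc[0]) if "metric_name" in per_image else "value"
    )
    return validate_group_table(out[list(GROUP_TABLE_COLUMNS)])


def _groups_of(table: pd.DataFrame) -> dict[str, np.ndarray]:
    table = validate_group_table(table)
    return {str(g): sub["value"].to_numpy(float) for g, sub in table.groupby("genotype")}


def anova_tukey(table: pd.DataFrame) -> list[StatsReport]:
    """One-way ANOVA across genotypes plus all pairwise Tukey HSD tests.

    Tukey HSD uses the studentized-range distribution with the
    Tukey–Kramer correction for unequal group sizes.  Returns the omnibus
    report first, then one report per genotype pair.
    """
    groups = _groups_of(table)
    degenerate = [g for g, v in groups.items() if len(v) < 2]
    if len(groups) < 2 or degenerate:
        raise ValueError(
            f"ANOVA needs >=2 genotypes with >=2 retinas each; degenerate: {degenerate}"
        )
    labels = sorted(groups)
    f, p = sps.f_oneway(*(groups[g] for g in labels))
    reports = [
        StatsReport(
            test_name="one-way ANOVA",
            groups=tuple(labels),
            statistic=float(f),
            p_raw=float(p),
            n_per_group=tuple(len(groups[g]) for g in labels),
        )
    ]
    from itertools import combinations

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([groups[g] for g in labels])
    codes = np.concatenate([[g] * len(groups[g]) for g in labels])
    tk = pairwise_tukeyhsd(values, codes)
    pairs = [(str(a), str(b)) for a, b in combinations(tk.groupsunique, 2)]
    for (ga, gb), stat, padj in zip(pairs, tk.meandiffs, tk.pvalues):
        reports.append(
            StatsReport(
                test_name="Tukey HSD",
                groups=(ga, gb),
                statistic=float(stat),
                p_raw=float(padj),
                p_adjusted=float(padj),
                adjustment="tukey",
                n_per_group=(len(groups[ga]), len(groups[gb])),
            )
        )
    return reports


def two_way_anova(
    table: pd.DataFrame,
    factor_a: str = "genotype",
    factor_b: str = "threshold_level",
    response: str = "value",
) -> list[StatsReport]:
    """Two-way ANOVA with interaction over a complete two-factor layout.

    Returns reports for both main effects and the interaction (type II sums
    of squares; for a balanced layout these coincide with type I).
    """
    for col in (factor_a, factor_b, response):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    cells = table.groupby([factor_a, factor_b]).size()
    n_a = table[factor_a].nunique()
    n_b = table[factor_b].nunique()
    if len(cells) < n_a * n_b:
        raise ValueError("incomplete two-factor layout: some factor cells are empty")

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.rename(columns={factor_a: "A", factor_b: "B", response: "y"}).copy()
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    effects = {
        "C(A)": f"main effect: {factor_a}",
        "C(B)": f"main effect: {factor_b}",
        "C(A):C(B)": f"interaction: {factor_a} x {factor_b}",
    }
    reports = []
    for key, name in effects.items():
        reports.append(
            StatsReport(
                test_name=f"two-way ANOVA, {name}",
                groups=tuple(sorted(map(str, table[factor_a].unique()))),
                statistic=float(tab.loc[key, "F"]),
                p_raw=float(tab.loc[key, "PR(>F)"]),
            )
        )
    return reports


def t_test(table: pd.DataFrame, welch: bool = False) -> StatsReport:
    """Two-sided Student's t-test (equal variance by default) between the
    exactly two genotypes present in the group table."""
    groups = _groups_of(table)
    if len(groups) != 2:
        raise ValueError(f"t-test needs exactly 2 genotypes, got {sorted(groups)}")
    (ga, a), (gb, b) = sorted(groups.items())
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs at least 2 retinas")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return StatsReport(
        test_name="Welch t-test" if welch else "Student t-test",
        groups=(ga, gb),
        statistic=float(t),
        p_raw=float(p),
        n_per_group=(len(a), len(b)),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
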