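"""Heritability, half-diallel mode-of-inheritance and trait correlations.

Implements the plot-level analytics of a replicated multi-year melon trial:
broad-sense heritability from one-way ANOVA variance components, the
additive effect a (half the parental difference), dominance effect d (F1
minus mid-parent) and degree of dominance d/a per hybrid group, the
GCA-sorted half-diallel genotype-mean matrix, and Pearson correlations on
genotype means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HeritabilityEstimate",
    "HybridGroup",
    "MOIStats",
    "DiallelMatrix",
    "CorrelationResult",
    "estimate_heritability",
    "build_diallel_matrix",
    "hybrid_groups",
    "hybrid_group_stats",
    "dominance_distribution",
    "midparent_f1_correlation",
    "trait_correlation",
]


@dataclass(frozen=True)
class HeritabilityEstimate:
    var_g: float
    var_p: float
    h2: float
    n_genotypes: int
    n_reps: float  # harmonic-mean replicates
    clamped: bool  # True if a negative genetic variance component was set to 0


@dataclass(frozen=True)
class HybridGroup:
    """An F1 hybrid and its two parents, as trait means."""

    parent1: str
    parent2: str
    p1_mean: float
    p2_mean: float
    f1_mean: float


@dataclass(frozen=True)
class MOIStats:
    """Mode-of-inheritance statistics of one hybrid group.

    ``a`` is half the (absolute) parental difference; ``d`` the F1 deviation
    from the mid-parent, positive toward the high parent; ``degree`` = d/a,
    NaN when a = 0 (|degree| > 1 indicates over/under-dominance).
    """

    a: float
    d: float
    degree: float
    mid_parent: float


@dataclass
class DiallelMatrix:
    """Symmetric genotype-mean matrix of a half-diallel, parents on the
    diagonal, both axes sorted ascending by GCA (mean of each parent's
    off-diagonal crosses)."""

    matrix: pd.DataFrame
    gca: pd.Series

    @property
    def parents(self) -> list[str]:
        return list(self.matrix.index)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    r2: float
    n: int


def _check_trait(pheno: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = pheno[pheno["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} absent from phenotype table")
    return sub


def _anova_components(sub: pd.DataFrame) -> HeritabilityEstimate:
    groups = [g["value"].to_numpy(float) for _, g in sub.groupby("line")]
    k = len(groups)
    if k < 2:
        raise ValueError("heritability needs at least 2 genotypes")
    ns = np.array([len(g) for g in groups])
    if (ns >= 2).sum() == 0:
        raise ValueError("heritability needs replication within genotypes")
    n = ns.sum()
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_g = ss_between / (k - 1)
    df_e = n - k
    ms_e = ss_within / df_e if df_e > 0 else 0.0
    r_harm = stats.hmean(ns)
    var_g = (ms_g - ms_e) / r_harm
    clamped = var_g < 0
    var_g = max(var_g, 0.0)
    var_p = var_g + ms_e
    if var_p == 0:
        raise ValueError("phenotypic variance is zero; heritability undefined")
    return HeritabilityEstimate(var_g, var_p, var_g / var_p, k, float(r_harm), clamped)


def estimate_heritability(
    pheno: pd.DataFrame, trait: str, by: str | None = "year"
) -> HeritabilityEstimate | dict:
    """Broad-sense heritability H2 = Var(G)/Var(P) from one-way random-effects
    ANOVA on plot values.

    Var(G) = (MS_genotype - MS_error) / r, with r the harmonic-mean number
    of replicates per genotype (robust to unbalance); Var(P) = Var(G) +
    MS_error.  A negative Var(G) is clamped to 0 and flagged.  With ``by``
    set (default ``"year"``), one estimate is returned per experiment as a
    dict; with ``by=None`` a single pooled-replicate estimate.
    """
    sub = _check_trait(pheno, trait)
    if by is None:
        return _anova_components(sub)
    return {key: _anova_components(g) for key, g in sub.groupby(by)}


def build_diallel_matrix(
    pheno: pd.DataFrame, design: pd.DataFrame, trait: str = "TSS"
) -> DiallelMatrix:
    """Genotype-mean half-diallel matrix with parents on the diagonal.

    ``design`` lists genotype, p1, p2 (parents have p1 == p2 == genotype).
    Cell values are genotype means over all years/replicates; GCA(parent) is
    the mean of its off-diagonal cells and both axes are sorted ascending by
    GCA.  Cells without observations are left NaN (flagged missing).
    """
    sub = _check_trait(pheno, trait)
    means = sub.groupby("line")["value"].mean()
    parents = sorted(design.loc[design["p1"] == design["p2"], "genotype"])
    if not parents:
        raise ValueError("design table contains no parents (rows with p1 == p2)")
    missing = set(parents) - set(means.index)
    if missing:
        raise ValueError(f"parents absent from phenotypes: {sorted(missing)}")

    mat = pd.DataFrame(np.nan, index=parents, columns=parents)
    for _, row in design.iterrows():
        g, p1, p2 = row["genotype"], row["p1"], row["p2"]
        if g in means.index:
            mat.loc[p1, p2] = means[g]
            mat.loc[p2, p1] = means[g]
    off = mat.where(~np.eye(len(parents), dtype=bool))
    gca = off.mean(axis=1)
    order = gca.sort_values(kind="stable").index
    return DiallelMatrix(matrix=mat.loc[order, order], gca=gca.loc[order])


def hybrid_groups(
    pheno: pd.DataFrame, design: pd.DataFrame, trait: str = "TSS"
) -> list[HybridGroup]:
    """Assemble (F1, parent, parent) trait-mean triplets from a pedigree."""
    sub = _check_trait(pheno, trait)
    means = sub.groupby("line")["value"].mean()
    out = []
    for _, row in design.iterrows():
        g, p1, p2 = row["genotype"], row["p1"], row["p2"]
        if p1 == p2:
            continue
        if g in means.index and p1 in means.index and p2 in means.index:
            out.append(HybridGroup(p1, p2, means[p1], means[p2], means[g]))
    return out


def hybrid_group_stats(group: HybridGroup) -> MOIStats:
    """Additive effect, dominance effect and degree of dominance of a group.

    a = |p1 - p2| / 2 (non-negative); mid = (p1 + p2) / 2; d = f1 - mid,
    signed positive toward the high parent; degree = d/a, NaN when a = 0.
    """
    a = abs(group.p1_mean - group.p2_mean) / 2.0
    mid = (group.p1_mean + group.p2_mean) / 2.0
    d = group.f1_mean - mid
    degree = d / a if a > 0 else float("nan")
    return MOIStats(a=a, d=d, degree=degree, mid_parent=mid)


def dominance_distribution(groups: list[HybridGroup], a_min: float = 2.0) -> dict:
    """Dominance summary over hybrid groups with a > ``a_min``.

    Returns n_selected, mean_d, sd_d, mean_abs_degree, and a two-sided
    one-sample t-test of mean d against 0.
    """
    if a_min < 0:
        raise ValueError("a_min must be non-negative")
    stats_list = [hybrid_group_stats(g) for g in groups]
    sel = [s for s in stats_list if s.a > a_min]
    if not sel:
        raise ValueError(f"no hybrid group has a > {a_min}")
    d = np.array([s.d for s in sel])
    degree = np.array([s.degree for s in sel])
    if len(d) > 1 and np.std(d, ddof=1) > 0:
        t, p = stats.ttest_1samp(d, 0.0)
    else:
        t, p = (np.nan, np.nan) if len(d) < 2 else (0.0, 1.0)
    return {
        "n_selected": len(sel),
        "mean_d": float(d.mean()),
        "sd_d": float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
        "mean_abs_degree": float(np.abs(degree).mean()),
        "t_stat": float(t),
        "p_value": float(p),
    }


def _pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), r2=float(r) ** 2, n=len(x))


def midparent_f1_correlation(groups: list[HybridGroup]) -> CorrelationResult:
    """Pearson correlation between mid-parent and F1 trait means across
    hybrid groups; its r2 measures the additive share of hybrid variation."""
    mid = np.array([(g.p1_mean + g.p2_mean) / 2.0 for g in groups])
    f1 = np.array([g.f1_mean for g in groups])
    return _pearson(mid, f1)


def trait_correlation(
    pheno: pd.DataFrame, trait_x: str, trait_y: str, by: str | None = "year"
) -> CorrelationResult | dict:
    """Pearson correlation between two traits on genotype means, per
    experiment (default grouping by year)."""

    def one(sub: pd.DataFrame) -> CorrelationResult:
        mx = sub[sub["trait"] == trait_x].groupby("line")["value"].mean()
        my = sub[sub["trait"] == trait_y].groupby("line")["value"].mean()
        common = mx.index.intersection(my.index)
        return _pearson(mx.loc[common].to_numpy(), my.loc[common].to_numpy())

    for t in (trait_x, trait_y):
        _check_trait(pheno, t)
    if by is None:
        return one(pheno)
    return {key: one(g) for key, g in pheno.groupby(by)}
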