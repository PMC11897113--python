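"""Marker-level QTL statistics on inbred lines.

Single-marker genome scans with permutation and Benjamini-Hochberg FDR
thresholds, allelic effects and percent variation explained (PVE) at peak
markers, pairwise QTL interaction tests with connected-letters displays,
favorable-allele stacking contrasts, and the expected-versus-observed
additivity regression that quantifies less-than-additive epistasis.

Heterozygous and missing genotypes are excluded from all effect classes by
default (analyses operate on the two homozygote classes of inbred lines);
the scan can optionally keep heterozygotes as a third class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import GENO_AA, GENO_BB, GENO_HET, LineGenotypes, line_means

__all__ = [
    "EffectEstimate",
    "ScanResult",
    "PairInteraction",
    "StackResult",
    "marker_scan",
    "allelic_effect",
    "pair_interaction",
    "stack_analysis",
    "pair_expected_observed",
    "expected_vs_observed",
    "connected_letters",
]


@dataclass(frozen=True)
class EffectEstimate:
    """Allelic effect of a marker: homozygote class means, their difference
    (sign encodes the donor of the increasing allele: positive = parent A),
    PVE = 100 * SS_marker / SS_total, and the one-way ANOVA p-value."""

    marker: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    effect: float
    pve: float
    p: float


@dataclass
class ScanResult:
    """Genome-scan output: per-marker F/p/q table, the genome-wide
    permutation p-value threshold at the stated alpha, and the permutation
    null (per-permutation minimum p)."""

    table: pd.DataFrame
    perm_threshold: float
    alpha: float
    n_perm: int
    min_p_null: np.ndarray = field(repr=False, default=None)


@dataclass
class PairInteraction:
    """Two-way ANOVA of a marker pair on the four homozygote classes."""

    marker_a: str
    marker_b: str
    class_means: dict
    class_n: dict
    main_a: float
    main_b: float
    interaction: float
    p_interaction: float
    letters: dict
    missing_classes: list


@dataclass
class StackResult:
    """Favorable-allele stacking summary across a marker set."""

    markers: list
    classes: pd.DataFrame  # haplotype, n_favorable, mean, n
    contrast_abs: float
    contrast_pct: float
    empty_classes: list


def _aligned_phenotype(
    genos: LineGenotypes, pheno: pd.DataFrame, trait: str
) -> tuple[np.ndarray, np.ndarray]:
    """Line means aligned to the genotype-matrix row order."""
    means = line_means(pheno, trait)
    have = np.array([l in means.index for l in genos.lines])
    y = np.array([means.get(l, np.nan) for l in genos.lines])
    return y, have


def _f_tests(geno: np.ndarray, y: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-class one-way ANOVA F tests over all markers.

    ``geno``: lines x markers dosage matrix; classes are the two homozygote
    codes.  Markers with fewer than 2 lines in either class get NaN.
    """
    mask_a = (geno == GENO_AA) & valid[:, None]
    mask_b = (geno == GENO_BB) & valid[:, None]
    y0 = np.where(valid, y, 0.0)
    y2 = y0 ** 2
    na = mask_a.sum(axis=0).astype(float)
    nb = mask_b.sum(axis=0).astype(float)
    sa = mask_a.T @ y0
    sb = mask_b.T @ y0
    qa = mask_a.T @ y2
    qb = mask_b.T @ y2
    n = na + nb
    with np.errstate(divide="ignore", invalid="ignore"):
        grand = (sa + sb) / n
        ss_between = na * (sa / na - grand) ** 2 + nb * (sb / nb - grand) ** 2
        ss_within = (qa - sa ** 2 / na) + (qb - sb ** 2 / nb)
        df2 = n - 2
        f = (ss_between / 1.0) / (ss_within / df2)
    bad = (na < 2) | (nb < 2) | (df2 <= 0)
    f = np.where(bad, np.nan, f)
    ss_within = np.maximum(ss_within, 0.0)
    with np.errstate(invalid="ignore"):
        p = stats.f.sf(f, 1, np.maximum(df2, 1))
    # zero within-class variance: perfect separation -> smallest possible p
    zero_var = (~bad) & (ss_within <= 1e-12) & (ss_between > 0)
    p = np.where(zero_var, 0.0, p)
    p = np.where(bad, np.nan, p)
    return f, p


def marker_scan(
    genos: LineGenotypes,
    pheno: pd.DataFrame,
    trait: str = "TSS",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ScanResult:
    """Single-marker genome scan on line means with a permutation threshold.

    Each marker is tested by one-way ANOVA of the two homozygote classes
    (heterozygotes and missing excluded).  The genome-wide threshold is the
    alpha-quantile of the minimum p-value across markers over ``n_perm``
    phenotype permutations; Benjamini-Hochberg q-values are also reported.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable threshold")
    y, valid = _aligned_phenotype(genos, pheno, trait)
    f, p = _f_tests(genos.geno, y, valid)
    if np.all(np.isnan(p)):
        raise ValueError("no marker is polymorphic with >=2 lines per homozygote class")

    rng = np.random.default_rng(seed)
    idx = np.where(valid)[0]
    min_p = np.empty(n_perm)
    for b in range(n_perm):
        yp = y.copy()
        yp[idx] = y[idx][rng.permutation(len(idx))]
        _, pp = _f_tests(genos.geno, yp, valid)
        min_p[b] = np.nanmin(pp)
    perm_threshold = float(np.quantile(min_p, alpha))

    finite = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    table = genos.markers.copy()
    table["F"] = f
    table["p"] = p
    table["q"] = q
    table["pass_perm"] = finite & (p <= perm_threshold)
    return ScanResult(table, perm_threshold, alpha, n_perm, min_p)


def allelic_effect(
    genos: LineGenotypes, pheno: pd.DataFrame, marker: str, trait: str = "TSS"
) -> EffectEstimate:
    """Allelic effect, PVE and ANOVA p-value at one marker.

    Computed on line means over the two homozygote classes: effect =
    mean(hom A) - mean(hom B); PVE = 100 * SS_between / SS_total.
    """
    y, valid = _aligned_phenotype(genos, pheno, trait)
    g = genos.column(marker)
    a = y[(g == GENO_AA) & valid]
    b = y[(g == GENO_BB) & valid]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"marker {marker!r} needs >=2 lines in both homozygote classes "
            f"(got {len(a)} and {len(b)})"
        )
    grand = np.concatenate([a, b]).mean()
    ss_between = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ss_total = ((np.concatenate([a, b]) - grand) ** 2).sum()
    pve = 100.0 * ss_between / ss_total if ss_total > 0 else 0.0
    ss_within = ss_total - ss_between
    if ss_within <= 1e-12:
        p = 0.0 if ss_between > 0 else 1.0
    else:
        _, p = stats.f_oneway(a, b)
    return EffectEstimate(
        marker=marker,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=len(a),
        n_b=len(b),
        effect=float(a.mean() - b.mean()),
        pve=float(pve),
        p=float(p),
    )


def connected_letters(
    labels: list, means: dict, nonsig: set[frozenset]
) -> dict:
    """Connected-letters display from pairwise non-significance.

    Standard insert-and-absorb construction: groups are maximal sets of
    levels that are mutually not significantly different; each group gets a
    letter and levels collect the letters of every group they belong to.
    Levels are processed in descending mean order.
    """
    order = sorted(labels, key=lambda l: -means[l])
    groups: list[set] = []
    for lab in order:
        placed = False
        for grp in groups:
            if all(frozenset((lab, other)) in nonsig for other in grp):
                grp.add(lab)
                placed = True
        if not placed:
            groups.append({lab})
    # drop groups wholly contained in another (absorption)
    groups = [g for g in groups if not any(g < h for h in groups)]
    letters = {lab: "" for lab in labels}
    for i, grp in enumerate(groups):
        ch = chr(ord("a") + i)
        for lab in order:
            if lab in grp:
                letters[lab] += ch
    return letters


def pair_interaction(
    genos: LineGenotypes,
    pheno: pd.DataFrame,
    marker_a: str,
    marker_b: str,
    trait: str = "TSS",
    alpha: float = 0.05,
) -> PairInteraction:
    """Two-way ANOVA with interaction on the four double-homozygote classes,
    plus Tukey-HSD connected letters at the stated alpha."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    y, valid = _aligned_phenotype(genos, pheno, trait)
    ga = genos.column(marker_a)
    gb = genos.column(marker_b)
    keep = valid & np.isin(ga, (GENO_AA, GENO_BB)) & np.isin(gb, (GENO_AA, GENO_BB))
    df = pd.DataFrame(
        {
            "a": np.where(ga[keep] == GENO_AA, "A", "B"),
            "b": np.where(gb[keep] == GENO_AA, "A", "B"),
            "value": y[keep],
        }
    )
    df["cls"] = df["a"] + df["b"]
    counts = df["cls"].value_counts().to_dict()
    all_classes = ["AA", "AB", "BA", "BB"]
    missing = [c for c in all_classes if counts.get(c, 0) == 0]
    class_means = {c: float(df.loc[df["cls"] == c, "value"].mean()) for c in all_classes if c not in missing}
    class_n = {c: int(counts.get(c, 0)) for c in all_classes}
    if missing:
        return PairInteraction(
            marker_a, marker_b, class_means, class_n,
            np.nan, np.nan, np.nan, np.nan, {}, missing,
        )

    model = smf.ols("value ~ C(a) * C(b)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    p_int = float(anova.loc["C(a):C(b)", "PR(>F)"])
    if not np.isfinite(p_int):  # zero residual variance
        m = class_means
        inter_est = m["AA"] - m["AB"] - m["BA"] + m["BB"]
        p_int = 0.0 if abs(inter_est) > 1e-12 else 1.0
    m = class_means
    main_a = (m["AA"] + m["AB"]) / 2 - (m["BA"] + m["BB"]) / 2
    main_b = (m["AA"] + m["BA"]) / 2 - (m["AB"] + m["BB"]) / 2
    interaction = m["AA"] - m["AB"] - m["BA"] + m["BB"]

    letters: dict = {}
    if df.groupby("cls")["value"].var(ddof=1).fillna(0).sum() > 0:
        tuk = pairwise_tukeyhsd(df["value"], df["cls"], alpha=alpha)
        res = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
        nonsig = {
            frozenset((row["group1"], row["group2"]))
            for _, row in res.iterrows()
            if not row["reject"]
        }
    else:
        # all classes constant: equal means share one letter
        nonsig = {
            frozenset(pair)
            for pair in itertools.combinations(all_classes, 2)
            if abs(class_means[pair[0]] - class_means[pair[1]]) <= 1e-12
        }
    letters = connected_letters(all_classes, class_means, nonsig)
    return PairInteraction(
        marker_a, marker_b, class_means, class_n,
        float(main_a), float(main_b), float(interaction), p_int, letters, [],
    )


def stack_analysis(
    genos: LineGenotypes,
    pheno: pd.DataFrame,
    markers: list[str],
    favorable: dict[str, str],
    trait: str = "TSS",
) -> StackResult:
    """Group lines by their favorable-homozygote haplotype across markers.

    Lines heterozygous or missing at any marker are excluded.  The contrast
    is full-favorable minus full-unfavorable class means, absolute and as
    percent of the unfavorable mean.
    """
    if len(markers) < 2:
        raise ValueError("stacking needs at least 2 markers")
    for mk in markers:
        if favorable.get(mk) not in ("A", "B"):
            raise ValueError(f"favorable allele for {mk!r} must be declared as 'A' or 'B'")
    y, valid = _aligned_phenotype(genos, pheno, trait)
    cols = np.stack([genos.column(mk) for mk in markers], axis=1)
    hom = np.isin(cols, (GENO_AA, GENO_BB)).all(axis=1) & valid
    fav_code = np.array([GENO_AA if favorable[mk] == "A" else GENO_BB for mk in markers])
    is_fav = cols[hom] == fav_code[None, :]

    rows = []
    for hap in itertools.product((True, False), repeat=len(markers)):
        sel = (is_fav == np.array(hap)[None, :]).all(axis=1)
        vals = y[hom][sel]
        label = "".join("+" if h else "-" for h in hap)
        rows.append(
            {
                "haplotype": label,
                "n_favorable": sum(hap),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "n": int(len(vals)),
            }
        )
    classes = pd.DataFrame(rows)
    empty = classes.loc[classes["n"] == 0, "haplotype"].tolist()
    full = classes.loc[classes["haplotype"] == "+" * len(markers)].iloc[0]
    null = classes.loc[classes["haplotype"] == "-" * len(markers)].iloc[0]
    if full["n"] == 0 or null["n"] == 0:
        raise ValueError("no line in the full-favorable or full-unfavorable class")
    contrast = float(full["mean"] - null["mean"])
    pct = 100.0 * contrast / null["mean"] if null["mean"] != 0 else np.nan
    return StackResult(list(markers), classes, contrast, float(pct), empty)


def pair_expected_observed(
    genos: LineGenotypes,
    pheno: pd.DataFrame,
    marker_pairs: list[tuple[str, str]],
    favorable: dict[str, str],
    trait: str = "TSS",
) -> pd.DataFrame:
    """Expected and observed effects of QTL pairs.

    expected(pair) = sum of the two singular allelic effects (oriented
    toward the favorable allele); observed(pair) = double-favorable class
    mean minus double-unfavorable class mean.  Pairs with an empty extreme
    class are dropped.
    """
    rows = []
    for ma, mb in marker_pairs:
        singles = []
        for mk in (ma, mb):
            est = allelic_effect(genos, pheno, mk, trait)
            singles.append(est.effect if favorable[mk] == "A" else -est.effect)
        try:
            st = stack_analysis(genos, pheno, [ma, mb], favorable, trait)
        except ValueError:
            continue
        rows.append(
            {
                "marker_a": ma,
                "marker_b": mb,
                "expected": float(sum(singles)),
                "observed": float(st.contrast_abs),
            }
        )
    return pd.DataFrame(rows)


def expected_vs_observed(pairs: pd.DataFrame) -> dict:
    """Regression of observed pair effects on expected (sum-of-singles).

    A slope significantly below 1 indicates less-than-additive epistasis.
    Returns slope, intercept, r2, the two-sided p-value of slope = 1, and
    the per-pair table.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 QTL pairs for the additivity regression")
    x = pairs["expected"].to_numpy(float)
    yv = pairs["observed"].to_numpy(float)
    if np.std(x) == 0:
        raise ValueError("zero variance in expected pair effects")
    res = stats.linregress(x, yv)
    if res.stderr > 0:
        t = (res.slope - 1.0) / res.stderr
        p_slope_1 = 2.0 * stats.t.sf(abs(t), len(x) - 2)
    else:
        p_slope_1 = 0.0 if res.slope != 1.0 else 1.0
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue) ** 2,
        "p_slope_eq_1": float(p_slope_1),
        "n_pairs": len(x),
        "table": pairs,
    }
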