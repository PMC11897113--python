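"""Marker-level QTL analytics: scans vs brute-force F tests, BH q-values vs
the step-up enumeration oracle, effect/PVE contracts, two-way interaction
ANOVA, stacking, and the expected-vs-observed additivity regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from melonqtl import effects
from melonqtl import simulate as sim
from melonqtl.simulate import LineGenotypes


def make_genos(geno, positions=None, chrom="chr01"):
    geno = np.asarray(geno, dtype=np.int8)
    n_lines, n_markers = geno.shape
    positions = positions or [(i + 1) * 1_000_000 for i in range(n_markers)]
    markers = pd.DataFrame(
        {"marker": [f"m{i}" for i in range(n_markers)], "chrom": chrom, "pos": positions}
    )
    return LineGenotypes([f"L{i:03d}" for i in range(n_lines)], markers, geno)


def make_pheno(lines, values, trait="TSS"):
    return pd.DataFrame(
        {
            "line": lines,
            "genotype_class": "line",
            "year": 1,
            "rep": 1,
            "trait": trait,
            "value": values,
        }
    )


def bh_oracle(pvals):
    """Step-up Benjamini-Hochberg by direct enumeration."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def test_marker_scan_perfect_marker_is_significant():
    geno = np.array([[2, 2], [2, 0], [2, 2], [2, 0], [2, 2], [2, 0]], dtype=np.int8)
    genos = make_genos(geno)
    pheno = make_pheno(genos.lines, [10.0, 5.0, 10.0, 5.0, 10.0, 5.0])
    res = effects.marker_scan(genos, pheno, n_perm=200, seed=1)
    t = res.table.set_index("marker")
    assert t.loc["m1", "p"] == 0.0       # perfect partition, zero within-class var
    assert t.loc["m1", "pass_perm"]
    assert np.isnan(t.loc["m0", "p"])    # monomorphic marker
    with pytest.raises(ValueError):
        effects.marker_scan(genos, pheno, n_perm=50)


def test_marker_scan_p_values_match_scipy_f_oneway():
    rng = np.random.default_rng(4)
    geno = rng.choice([0, 2], size=(40, 15)).astype(np.int8)
    genos = make_genos(geno)
    pheno = make_pheno(genos.lines, rng.normal(10, 2, 40))
    res = effects.marker_scan(genos, pheno, n_perm=100, seed=0)
    y = pheno["value"].to_numpy()
    for k, row in res.table.iterrows():
        a, b = y[geno[:, k] == 2], y[geno[:, k] == 0]
        if len(a) >= 2 and len(b) >= 2:
            _, p_ref = stats.f_oneway(a, b)
            assert row["p"] == pytest.approx(p_ref, rel=1e-9)


def test_marker_scan_permutation_threshold_properties():
    rng = np.random.default_rng(12)
    geno = rng.choice([0, 2], size=(60, 30)).astype(np.int8)
    genos = make_genos(geno)
    pheno = make_pheno(genos.lines, rng.normal(0, 1, 60))
    res1 = effects.marker_scan(genos, pheno, n_perm=200, alpha=0.05, seed=5)
    res2 = effects.marker_scan(genos, pheno, n_perm=200, alpha=0.05, seed=5)
    assert res1.perm_threshold == res2.perm_threshold  # deterministic under seed
    res_small = effects.marker_scan(genos, pheno, n_perm=200, alpha=0.01, seed=5)
    assert res_small.perm_threshold <= res1.perm_threshold  # monotone in alpha


def test_marker_scan_genomewide_type_i_error_near_alpha():
    """Null phenotypes: some marker passes the permutation threshold in
    about alpha of replicate scans."""
    rng = np.random.default_rng(99)
    geno = rng.choice([0, 2], size=(50, 25)).astype(np.int8)
    genos = make_genos(geno)
    hits = 0
    n_scans = 120
    for s in range(n_scans):
        rng_s = np.random.default_rng(500 + s)
        pheno = make_pheno(genos.lines, rng_s.normal(0, 1, 50))
        res = effects.marker_scan(genos, pheno, n_perm=150, alpha=0.05, seed=s)
        hits += bool(res.table["pass_perm"].any())
    assert 0.0 <= hits / n_scans <= 0.12


def test_bh_qvalues_match_enumeration_oracle():
    cases = [
        [0.01, 0.02, 0.03, 0.04],
        [0.5, 0.01, 0.9, 0.02, 0.2],
        [0.04, 0.04, 0.04],
        list(np.random.default_rng(2).uniform(size=20)),
    ]
    for pvals in cases:
        from statsmodels.stats.multitest import multipletests

        q_pkg = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(q_pkg, bh_oracle(pvals), atol=1e-12)
    # p = (0.01, 0.02, 0.03, 0.04) at q* = 0.05: all four significant
    assert (bh_oracle([0.01, 0.02, 0.03, 0.04]) <= 0.05).all()


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
@settings(max_examples=50, deadline=None)
def test_bh_qvalues_property(pvals):
    from statsmodels.stats.multitest import multipletests

    q = multipletests(pvals, method="fdr_bh")[1]
    assert np.allclose(q, bh_oracle(pvals), atol=1e-12)
    # q-values are monotone with p-values
    order = np.argsort(pvals)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_allelic_effect_contracts():
    geno = np.array([[2], [2], [0], [0], [1]], dtype=np.int8)
    genos = make_genos(geno)
    pheno = make_pheno(genos.lines, [14.0, 14.0, 10.0, 10.0, 12.0])
    est = effects.allelic_effect(genos, pheno, "m0")
    assert est.effect == pytest.approx(4.0)
    assert est.pve == pytest.approx(100.0)
    assert est.p == 0.0
    assert est.n_a == 2 and est.n_b == 2  # the het line is excluded
    # identical class means: zero effect and zero PVE
    flat = make_pheno(genos.lines, [10.0, 12.0, 10.0, 12.0, 11.0])
    est0 = effects.allelic_effect(genos, flat, "m0")
    assert est0.effect == pytest.approx(0.0)
    assert est0.pve == pytest.approx(0.0)


def test_allelic_effect_requires_both_classes():
    geno = np.array([[2], [2], [2], [0]], dtype=np.int8)
    genos = make_genos(geno)
    pheno = make_pheno(genos.lines, [1.0, 2.0, 3.0, 4.0])
    with pytest.raises(ValueError):
        effects.allelic_effect(genos, pheno, "m0")


def test_allelic_effect_recovers_planted_qtl():
    """Mean estimated effect over replicate simulations is within 2 SEs of
    the planted 2-Brix effect at h2 = 0.6."""
    ests = []
    for s in range(40):
        truth = sim.BiparentalTruth(
            120, 6, [sim.QTL("chr01", 15_000_000, 2.0, "A")], h2=0.6, seed=s
        )
        genos, pheno = sim.simulate_biparental(
            truth, {"chr01": 30_000_000}, n_markers_per_chrom=20
        )
        est = effects.allelic_effect(genos, pheno, sim.qtl_marker_id("chr01", 15_000_000))
        ests.append(est.effect)
    se = np.std(ests, ddof=1) / np.sqrt(len(ests))
    assert np.mean(ests) == pytest.approx(2.0, abs=2 * se)


def _pair_data(class_means, n_per_class=6, noise_sd=0.0, seed=0):
    """Lines laid out over the 4 double-homozygote classes of two markers."""
    rng = np.random.default_rng(seed)
    rows_g, values = [], []
    for (ca, cb), m in class_means.items():
        for _ in range(n_per_class):
            rows_g.append([2 if ca == "A" else 0, 2 if cb == "A" else 0])
            values.append(m + (rng.normal(0, noise_sd) if noise_sd else 0.0))
    genos = make_genos(np.array(rows_g, dtype=np.int8))
    return genos, make_pheno(genos.lines, values)


def test_pair_interaction_additive_construction():
    means = {("B", "B"): 0.0, ("B", "A"): 1.0, ("A", "B"): 2.0, ("A", "A"): 3.0}
    genos, pheno = _pair_data(means, noise_sd=0.05, seed=3)
    res = effects.pair_interaction(genos, pheno, "m0", "m1")
    assert res.interaction == pytest.approx(0.0, abs=0.1)
    assert res.p_interaction > 0.05
    assert res.missing_classes == []


def test_pair_interaction_detects_epistasis():
    """More-than-additive class means (0,1,2,5) + small noise: interaction
    significant at alpha = 0.05 (explicit two-way ANOVA oracle check)."""
    means = {("B", "B"): 0.0, ("B", "A"): 1.0, ("A", "B"): 2.0, ("A", "A"): 5.0}
    genos, pheno = _pair_data(means, n_per_class=8, noise_sd=0.3, seed=7)
    res = effects.pair_interaction(genos, pheno, "m0", "m1")
    assert res.p_interaction < 0.05
    # oracle: balanced two-way ANOVA interaction SS by explicit sums
    y = pheno["value"].to_numpy()
    ga = genos.column("m0") == 2
    gb = genos.column("m1") == 2
    cell = {(a, b): y[(ga == a) & (gb == b)] for a in (0, 1) for b in (0, 1)}
    grand = y.mean()
    n = 8
    ma = {a: y[ga == a].mean() for a in (0, 1)}
    mb = {b: y[gb == b].mean() for b in (0, 1)}
    ss_int = sum(
        n * (cell[a, b].mean() - ma[a] - mb[b] + grand) ** 2 for a in (0, 1) for b in (0, 1)
    )
    ss_err = sum(((cell[k] - cell[k].mean()) ** 2).sum() for k in cell)
    f = (ss_int / 1) / (ss_err / (len(y) - 4))
    p_oracle = stats.f.sf(f, 1, len(y) - 4)
    assert res.p_interaction == pytest.approx(p_oracle, rel=1e-6)
    # interaction estimate equals the cell-mean contrast
    cm = res.class_means
    assert res.interaction == pytest.approx(cm["AA"] - cm["AB"] - cm["BA"] + cm["BB"])


def test_pair_interaction_letters_single_group_when_flat():
    means = {("B", "B"): 5.0, ("B", "A"): 5.0, ("A", "B"): 5.0, ("A", "A"): 5.0}
    genos, pheno = _pair_data(means)
    res = effects.pair_interaction(genos, pheno, "m0", "m1")
    assert set(res.letters.values()) == {"a"}


def test_pair_interaction_reports_missing_class():
    geno = np.array([[2, 2], [2, 2], [0, 0], [0, 0], [2, 0], [2, 0]], dtype=np.int8)
    genos = make_genos(geno)
    pheno = make_pheno(genos.lines, [5.0, 6.0, 1.0, 2.0, 3.0, 4.0])
    res = effects.pair_interaction(genos, pheno, "m0", "m1")
    assert "BA" in res.missing_classes


def test_connected_letters_separates_distinct_groups():
    letters = effects.connected_letters(
        ["hi", "mid", "lo"],
        {"hi": 10.0, "mid": 5.0, "lo": 0.0},
        {frozenset(("hi", "mid"))},  # hi~mid not different; lo different from both
    )
    assert letters["hi"] != letters["lo"]
    assert set(letters["mid"]) & set(letters["hi"])


def test_stack_analysis_additive_truth():
    """Three QTLs of +1 each, noiseless: triple-stack minus null-stack = 3,
    and class means are affine in the favorable-allele count."""
    rng = np.random.default_rng(21)
    geno = rng.choice([0, 2], size=(120, 3)).astype(np.int8)
    genos = make_genos(geno)
    values = 5.0 + (geno == 2).sum(axis=1).astype(float)
    pheno = make_pheno(genos.lines, values)
    fav = {"m0": "A", "m1": "A", "m2": "A"}
    res = effects.stack_analysis(genos, pheno, ["m0", "m1", "m2"], fav)
    assert res.contrast_abs == pytest.approx(3.0)
    assert res.contrast_pct == pytest.approx(100.0 * 3.0 / 5.0)
    by_j = res.classes.groupby("n_favorable")["mean"].mean()
    slope, intercept = np.polyfit(by_j.index, by_j.to_numpy(), 1)
    resid = by_j.to_numpy() - (slope * by_j.index + intercept)
    assert np.abs(resid).max() < 1e-9


def test_stack_analysis_label_symmetry():
    rng = np.random.default_rng(23)
    geno = rng.choice([0, 2], size=(60, 2)).astype(np.int8)
    genos = make_genos(geno)
    pheno = make_pheno(genos.lines, rng.normal(10, 1, 60))
    res_a = effects.stack_analysis(genos, pheno, ["m0", "m1"], {"m0": "A", "m1": "A"})
    res_b = effects.stack_analysis(genos, pheno, ["m0", "m1"], {"m0": "B", "m1": "B"})
    assert res_a.contrast_abs == pytest.approx(-res_b.contrast_abs)


def test_stack_analysis_validation():
    genos = make_genos(np.array([[2, 2], [0, 0]], dtype=np.int8))
    pheno = make_pheno(genos.lines, [1.0, 2.0])
    with pytest.raises(ValueError):
        effects.stack_analysis(genos, pheno, ["m0"], {"m0": "A"})
    with pytest.raises(ValueError):
        effects.stack_analysis(genos, pheno, ["m0", "m1"], {"m0": "A", "m1": "Z"})


def test_expected_vs_observed_additive_slope_one():
    pairs = pd.DataFrame(
        {"expected": [1.0, 2.0, 3.0, 4.0], "observed": [1.0, 2.0, 3.0, 4.0]}
    )
    res = effects.expected_vs_observed(pairs)
    assert res["slope"] == pytest.approx(1.0)
    assert res["r2"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        effects.expected_vs_observed(pairs.iloc[:1])


def test_expected_vs_observed_detects_diminishing_epistasis():
    """Multiplicative (less-than-additive) pairs: slope < 1 detected at
    alpha = 0.05 in most replicate simulations."""
    detected = 0
    n_sims = 40
    for s in range(n_sims):
        rng = np.random.default_rng(300 + s)
        expected = rng.uniform(1, 5, 40)
        observed = 0.7 * expected + rng.normal(0, 0.3, 40)
        res = effects.expected_vs_observed(pd.DataFrame({"expected": expected, "observed": observed}))
        detected += (res["slope"] < 1.0) and (res["p_slope_eq_1"] < 0.05)
    assert detected / n_sims >= 0.90


def test_pair_expected_observed_pipeline_on_simulation():
    truth = sim.BiparentalTruth(
        150,
        6,
        [sim.QTL("chr01", 8_000_000, 1.5, "A"), sim.QTL("chr01", 25_000_000, 2.0, "A")],
        h2=0.9,
        seed=17,
    )
    genos, pheno = sim.simulate_biparental(truth, {"chr01": 30_000_000}, n_markers_per_chrom=20)
    m1 = sim.qtl_marker_id("chr01", 8_000_000)
    m2 = sim.qtl_marker_id("chr01", 25_000_000)
    tab = effects.pair_expected_observed(genos, pheno, [(m1, m2)], {m1: "A", m2: "A"})
    assert len(tab) == 1
    # additive truth: observed close to expected (within sampling noise)
    assert tab["observed"].iloc[0] == pytest.approx(tab["expected"].iloc[0], abs=1.0)
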