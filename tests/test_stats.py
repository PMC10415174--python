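"""Differential-expression, multiple-testing, enrichment and multivariate
statistics against independent closed-form / brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfqstats.exceptions import LfqstatsError
from lfqstats.stats import (
    adjust_bh,
    ancova,
    anova,
    hcluster,
    ora,
    pca,
    read_annotation,
    ttest,
)

from conftest import make_dataset


# ---------------------------------------------------------------------------
# t-test


def welch_oracle(a, b):
    """Closed-form Welch t statistic and two-sided p (scipy-free)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    # two-sided p from the regularized incomplete beta function
    x = df / (df + t * t)
    from math import gamma

    def betainc(a_, b_, x_, n=20000):
        # simple composite-Simpson numeric integral of the beta density
        ts = np.linspace(1e-12, x_, n + 1)
        f = ts ** (a_ - 1) * (1 - ts) ** (b_ - 1)
        integral = np.trapezoid(f, ts)
        return integral * gamma(a_ + b_) / (gamma(a_) * gamma(b_))

    p = betainc(df / 2, 0.5, x)
    return t, p


def test_ttest_matches_closed_form_welch():
    a, b = [20.0, 21.5, 22.0], [23.0, 23.5, 24.5]
    vals = np.array([a + b, a + b]).T.reshape(6, 2)
    ds = make_dataset(vals, groups=list("AAABBB"))
    res = ttest(ds, "group", "A", "B").table.iloc[0]
    t_exp, p_exp = welch_oracle(a, b)
    assert res["statistic"] == pytest.approx(t_exp, abs=1e-9)
    assert res["p"] == pytest.approx(p_exp, rel=1e-4)
    assert res["log2_fc"] == pytest.approx(np.mean(a) - np.mean(b), abs=1e-12)


def test_ttest_identical_groups_gives_zero_statistic():
    col = [10.0, 12.0, 10.0, 12.0]
    ds = make_dataset(np.array([col]).T, groups=list("AABB"))
    row = ttest(ds, "group", "A", "B").table.iloc[0]
    assert row["statistic"] == 0.0
    assert row["p"] == pytest.approx(1.0)
    assert row["log2_fc"] == 0.0


def test_ttest_min_obs_gate_and_zero_variance_skip():
    vals = np.array([
        [1.0, 5.0],
        [1.0, 5.0],
        [2.0, np.nan],
        [2.0, 6.0],
    ])
    ds = make_dataset(vals, groups=list("AABB"))
    tab = ttest(ds, "group", "A", "B").table.set_index("protein_id")
    # P1: both groups zero variance, unequal means -> skipped, no epsilon
    assert tab.loc["P1", "status"] == "skipped_low_n"
    assert np.isnan(tab.loc["P1", "p"])
    # P2: only one observation in group B -> below min_obs
    assert tab.loc["P2", "status"] == "skipped_low_n"


def test_ttest_unknown_label_errors(toy_dataset):
    with pytest.raises(LfqstatsError, match="not present"):
        ttest(toy_dataset, "group", "A", "Z")


# ---------------------------------------------------------------------------
# ANOVA / ANCOVA


def test_anova_equals_squared_t_for_two_groups():
    rng = np.random.default_rng(4)
    vals = rng.normal(20, 2, size=(8, 6))
    ds = make_dataset(vals, groups=list("AAAABBBB"))
    f = anova(ds, "group").table["statistic"].to_numpy()
    t = ttest(ds, "group", "A", "B", equal_var=True).table["statistic"].to_numpy()
    np.testing.assert_allclose(f, t**2, atol=1e-9)


def test_anova_three_groups_matches_ss_decomposition():
    g = {"A": [1.0, 2.0, 3.0], "B": [2.0, 3.0, 4.0], "C": [6.0, 7.0, 8.0]}
    col = g["A"] + g["B"] + g["C"]
    ds = make_dataset(np.array([col]).T, groups=["A"] * 3 + ["B"] * 3 + ["C"] * 3)
    f = anova(ds, "group").table["statistic"].iloc[0]
    allv = np.array(col)
    grand = allv.mean()
    ssb = sum(3 * (np.mean(v) - grand) ** 2 for v in g.values())
    ssw = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in g.values())
    assert f == pytest.approx((ssb / 2) / (ssw / 6), abs=1e-9)


def test_anova_constant_matrix_skips_everything():
    ds = make_dataset(np.ones((9, 3)), groups=["A"] * 3 + ["B"] * 3 + ["C"] * 3)
    tab = anova(ds, "group").table
    assert (tab["status"] == "skipped_low_n").all()


def test_ancova_empty_covariates_equals_anova(toy_dataset):
    a = anova(toy_dataset, "group").table
    c = ancova(toy_dataset, "group", []).table
    np.testing.assert_allclose(
        a["statistic"].to_numpy(), c["statistic"].to_numpy(), atol=1e-9
    )
    np.testing.assert_allclose(a["p"].to_numpy(), c["p"].to_numpy(), atol=1e-9)


def test_ancova_partial_f_matches_nested_lstsq_oracle():
    rng = np.random.default_rng(5)
    n = 12
    groups = ["A"] * 6 + ["B"] * 6
    age = rng.uniform(30, 70, n)
    y = 20 + 0.05 * age + np.where(np.array(groups) == "B", 1.0, 0.0)
    y = y + rng.normal(0, 0.3, n)
    ds = make_dataset(y.reshape(-1, 1), groups=groups, covariates={"age": age})
    row = ancova(ds, "group", ["age"]).table.iloc[0]

    # independent nested least-squares oracle
    Xf = np.column_stack([np.ones(n), np.array(groups) == "B", age]).astype(float)
    Xr = np.column_stack([np.ones(n), age])
    rss = lambda X: np.sum(  # noqa: E731
        (y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2
    )
    f_exp = ((rss(Xr) - rss(Xf)) / 1) / (rss(Xf) / (n - 3))
    assert row["statistic"] == pytest.approx(f_exp, rel=1e-9)


def test_ancova_pure_confound_gives_p_near_one():
    n = 10
    groups = ["A"] * 5 + ["B"] * 5
    cov = np.arange(n, dtype=float)
    y = 2.0 * cov + 1.0  # exactly linear in the covariate, no group effect
    ds = make_dataset(y.reshape(-1, 1), groups=groups, covariates={"c": cov})
    row = ancova(ds, "group", ["c"]).table.iloc[0]
    assert row["status"] == "skipped_low_n" or row["p"] > 0.99


def test_ancova_collinear_covariates_skipped():
    n = 8
    groups = ["A"] * 4 + ["B"] * 4
    cov = np.arange(n, dtype=float)
    rng = np.random.default_rng(6)
    ds = make_dataset(
        rng.normal(size=(n, 2)), groups=groups,
        covariates={"c1": cov, "c2": 2 * cov},
    )
    tab = ancova(ds, "group", ["c1", "c2"]).table
    assert (tab["status"] == "skipped_low_n").all()


def test_ancova_missing_covariate_column_errors(toy_dataset):
    with pytest.raises(LfqstatsError, match="missing from metadata"):
        ancova(toy_dataset, "group", ["age"])


# ---------------------------------------------------------------------------
# BH adjustment


def bh_bruteforce(p):
    """Step-up definition applied literally."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def test_bh_worked_example():
    np.testing.assert_allclose(
        adjust_bh([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04], atol=1e-12
    )


def test_bh_preserves_nan_and_order():
    out = adjust_bh([0.5, np.nan, 0.01])
    assert np.isnan(out[1])
    assert out[2] <= out[0]


def test_bh_rejects_out_of_range():
    with pytest.raises(LfqstatsError):
        adjust_bh([0.5, 1.5])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_equals_bruteforce_stepup(ps):
    np.testing.assert_allclose(adjust_bh(ps), bh_bruteforce(ps), atol=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30))
def test_bh_monotone_in_sorted_p(ps):
    q = adjust_bh(sorted(ps))
    assert all(q[i] <= q[i + 1] + 1e-15 for i in range(len(q) - 1))


# ---------------------------------------------------------------------------
# ORA


def test_ora_matches_exhaustive_enumeration():
    """10-protein background, 5-protein term, 4 significant, overlap 4:
    p equals the exact enumeration of all 4-subsets."""
    background = {f"p{i}" for i in range(10)}
    term = {f"p{i}" for i in range(5)}
    significant = {"p0", "p1", "p2", "p3"}
    res = ora(significant, background, {"T": term}, min_term_size=2)
    p = res.table["p"].iloc[0]

    count = sum(
        1
        for sub in itertools.combinations(sorted(background), 4)
        if len(set(sub) & term) >= 4
    )
    total = math.comb(10, 4)
    assert p == pytest.approx(count / total, abs=1e-12)
    # closed form: C(5,4)*C(5,0)/C(10,4)
    assert p == pytest.approx(math.comb(5, 4) / math.comb(10, 4), abs=1e-12)


def test_ora_zero_overlap_is_near_one():
    background = {f"p{i}" for i in range(30)}
    res = ora({"p0"}, background, {"T": {"p28", "p29"}})
    assert res.table["p"].iloc[0] > 0.9


def test_ora_small_terms_excluded_and_subset_enforced():
    background = {"a", "b", "c", "d"}
    res = ora({"a"}, background, {"tiny": {"a"}, "ok": {"a", "b"}},
              min_term_size=2)
    assert res.table["term_id"].tolist() == ["ok"]
    with pytest.raises(LfqstatsError, match="not contained"):
        ora({"z"}, background, {"ok": {"a", "b"}})


def test_read_annotation_two_column_and_gaf(tmp_path):
    two = tmp_path / "ann.tsv"
    two.write_text("T1\tp1\nT1\tp2\nT2\tp3\n")
    ann = read_annotation(two)
    assert ann == {"T1": {"p1", "p2"}, "T2": {"p3"}}
    gaf = tmp_path / "ann.gaf"
    gaf.write_text("!gaf-version: 2.1\nDB\tp9\tSYM\t\tGO:1\tref\tIEA\n")
    assert read_annotation(gaf, gaf=True) == {"GO:1": {"p9"}}


# ---------------------------------------------------------------------------
# PCA


def test_pca_rank_one_data_has_ratio_one():
    t = np.linspace(0, 1, 5)
    vals = np.outer(t, [1.0, 2.0, 3.0])  # samples on a line
    ds = make_dataset(vals)
    _, _, ratio = pca(ds, 2)
    assert ratio[0] == pytest.approx(1.0, abs=1e-9)


def test_pca_full_rank_reconstruction_and_orthonormal_loadings():
    rng = np.random.default_rng(7)
    vals = rng.normal(size=(6, 4))
    ds = make_dataset(vals)
    scores, loadings, ratio = pca(ds, 4)
    centered = vals - vals.mean(axis=0)
    recon = scores.to_numpy() @ loadings.to_numpy().T
    assert np.abs(recon - centered).max() < 1e-8
    gram = loadings.to_numpy().T @ loadings.to_numpy()
    assert np.abs(gram - np.eye(4)).max() < 1e-8
    assert np.all(np.diff(ratio) <= 1e-12) and ratio.sum() <= 1 + 1e-9


def test_pca_matches_eigendecomposition_oracle():
    vals = np.array([[1.0, 2.0], [3.0, 5.0], [4.0, 3.0]])
    ds = make_dataset(vals)
    _, _, ratio = pca(ds, 2)
    c = vals - vals.mean(axis=0)
    eig = np.sort(np.linalg.eigvalsh(c.T @ c))[::-1]
    np.testing.assert_allclose(ratio, eig / eig.sum(), atol=1e-9)


def test_pca_rejects_missing_values():
    vals = np.array([[1.0, np.nan], [2.0, 3.0], [4.0, 5.0]])
    with pytest.raises(LfqstatsError, match="impute"):
        pca(make_dataset(vals), 1)


# ---------------------------------------------------------------------------
# hierarchical clustering


def test_hcluster_three_points_single_linkage_oracle():
    vals = np.array([[0.0], [1.0], [4.0]])
    tree, order = hcluster(vals, axis="samples", metric="euclidean",
                           linkage="single")
    # first merge {0,1} at height 1, then with {2} at height 3
    assert set(tree[0, :2].astype(int)) == {0, 1}
    assert tree[0, 2] == pytest.approx(1.0)
    assert tree[1, 2] == pytest.approx(3.0)
    assert sorted(order) == [0, 1, 2]


def test_hcluster_duplicates_merge_first_at_zero():
    vals = np.array([[1.0, 2.0], [5.0, 6.0], [1.0, 2.0]])
    tree, _ = hcluster(vals, axis="samples")
    assert set(tree[0, :2].astype(int)) == {0, 2}
    assert tree[0, 2] == pytest.approx(0.0)


@pytest.mark.parametrize("linkage", ["single", "complete", "average"])
def test_hcluster_heights_nondecreasing_and_order_is_permutation(linkage):
    rng = np.random.default_rng(11)
    vals = rng.normal(size=(7, 4))
    tree, order = hcluster(vals, axis="samples", linkage=linkage)
    assert np.all(np.diff(tree[:, 2]) >= -1e-12)
    assert sorted(order) == list(range(7))


def test_hcluster_constant_rows_under_correlation_rejected():
    vals = np.vstack([np.ones(4), np.arange(4.0)])
    with pytest.raises(LfqstatsError, match="constant"):
        hcluster(vals, axis="samples", metric="correlation")
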