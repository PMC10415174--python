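"""Preprocessing contracts: filtering, transforms, normalization, imputation."""

import numpy as np
import pandas as pd
import pytest

from lfqstats.exceptions import LfqstatsError
from lfqstats.preprocess import (
    filter_completeness,
    impute,
    log2_transform,
    normalize,
    remove_contaminants,
    sweep_pipelines,
    zero_to_missing,
)

from conftest import make_dataset


def test_remove_contaminants_counts_and_idempotence():
    ds = make_dataset(
        np.ones((2, 5)), contaminant=[False, True, True, False, False]
    )
    out = remove_contaminants(ds)
    assert out.n_proteins == 3
    assert out.log[-1].n_removed_or_imputed == 2
    twice = remove_contaminants(out)
    assert twice.n_proteins == 3
    assert twice.log[-1].n_removed_or_imputed == 0


def test_zero_to_missing_converts_exact_zeros_only():
    ds = make_dataset([[0.0, 1.0], [2.0, 3.0]])
    out = zero_to_missing(ds)
    assert np.isnan(out.matrix.iloc[0, 0])
    assert out.matrix.iloc[1, 0] == 2.0
    assert out.log[-1].n_removed_or_imputed == 1
    # untouched input, fully-zero protein kept as all-missing
    assert ds.matrix.iloc[0, 0] == 0.0
    allzero = zero_to_missing(make_dataset([[0.0, 1.0], [0.0, 2.0]]))
    assert allzero.matrix["P1"].isna().all()
    assert allzero.n_proteins == 2


@pytest.mark.parametrize(
    "min_fraction,expected_left",
    [(1.0, 1), (0.0, 3), (0.6, 2)],
)
def test_filter_completeness_ceiling_rule(min_fraction, expected_left):
    """4 samples: protein observed in 2 is dropped at 0.6 (ceil(2.4)=3)."""
    vals = np.ones((4, 3))
    vals[0, 0] = np.nan  # P1 observed in 3
    vals[:2, 1] = np.nan  # P2 observed in 2
    ds = make_dataset(vals)  # P3 complete
    out = filter_completeness(ds, min_fraction)
    assert out.n_proteins == expected_left


def test_log2_transform_requires_positive_values():
    assert log2_transform(make_dataset([[8.0]])).matrix.iloc[0, 0] == 3.0
    with pytest.raises(LfqstatsError, match="zero_to_missing"):
        log2_transform(make_dataset([[0.0, 1.0]]))
    ds = zero_to_missing(make_dataset([[0.0, 4.0]]))
    out = log2_transform(ds)
    assert np.isnan(out.matrix.iloc[0, 0])
    assert out.matrix.iloc[0, 1] == 2.0


def test_median_center_equalizes_medians():
    rng = np.random.default_rng(0)
    vals = rng.uniform(10, 30, size=(4, 9))
    ds = normalize(make_dataset(vals), "median_center")
    medians = np.nanmedian(ds.matrix.to_numpy(), axis=1)
    assert np.allclose(medians, medians[0], atol=1e-12)


def test_quantile_matches_rank_mean_definition():
    """Complete 2x3: both samples become the mean order statistics."""
    ds = normalize(make_dataset([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]), "quantile")
    np.testing.assert_allclose(
        ds.matrix.to_numpy(),
        [[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]],
        atol=1e-12,
    )


def test_quantile_complete_samples_share_sorted_values():
    rng = np.random.default_rng(1)
    vals = rng.uniform(15, 30, size=(5, 40))
    out = normalize(make_dataset(vals), "quantile").matrix.to_numpy()
    ref = np.sort(out[0])
    for i in range(1, 5):
        np.testing.assert_allclose(np.sort(out[i]), ref, atol=1e-9)


def test_quantile_ties_get_mean_of_rank_values():
    ds = normalize(make_dataset([[1.0, 1.0, 3.0], [4.0, 5.0, 6.0]]), "quantile")
    row = ds.matrix.to_numpy()[0]
    # ranks 0 and 1 are tied -> both get mean(ref[0], ref[1])
    assert row[0] == row[1] == pytest.approx((2.5 + 3.0) / 2)


def test_quantile_preserves_missing_cells():
    vals = np.array([[1.0, np.nan, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
    out = normalize(make_dataset(vals), "quantile").matrix.to_numpy()
    assert np.isnan(out[0, 1])
    assert np.isnan(out).sum() == 1


def test_zscore_postconditions_and_errors():
    rng = np.random.default_rng(2)
    vals = rng.uniform(10, 30, size=(3, 12))
    out = normalize(make_dataset(vals), "zscore").matrix.to_numpy()
    assert np.allclose(np.nanmean(out, axis=1), 0, atol=1e-9)
    assert np.allclose(np.nanstd(out, axis=1, ddof=1), 1, atol=1e-9)
    sparse = np.full((2, 3), np.nan)
    sparse[:, 0] = 1.0
    sparse[0, 1] = 2.0
    with pytest.raises(LfqstatsError, match="2 observed"):
        normalize(make_dataset(sparse), "zscore")


def test_normalization_identical_samples_stay_identical():
    vals = np.tile(np.array([[5.0, 7.0, 9.0, 11.0]]), (3, 1))
    for method in ("median_center", "quantile"):
        out = normalize(make_dataset(vals), method).matrix.to_numpy()
        assert np.allclose(out[0], out[1]) and np.allclose(out[1], out[2])


@pytest.mark.parametrize("method", ["mean", "median", "knn", "tree_iterative"])
def test_impute_fills_all_and_preserves_observed(method):
    rng = np.random.default_rng(3)
    vals = rng.uniform(18, 28, size=(6, 10))
    mask = rng.random(vals.shape) < 0.2
    mask[:, 0] = False  # keep one complete protein
    withna = vals.copy()
    withna[mask] = np.nan
    ds = make_dataset(withna, groups=list("AAABBB"))
    out = impute(ds, method, seed=7, k=2, n_estimators=10, max_iter=3)
    res = out.matrix.to_numpy()
    assert not np.isnan(res).any()
    np.testing.assert_array_equal(res[~mask], vals[~mask])
    assert out.log[-1].n_removed_or_imputed == int(mask.sum())


def test_impute_no_missing_is_identity(toy_dataset):
    for method in ("mean", "median", "knn", "tree_iterative"):
        out = impute(toy_dataset, method, seed=1, n_estimators=5, max_iter=2)
        assert out.matrix.equals(toy_dataset.matrix)


def test_impute_mean_simple_arithmetic():
    vals = np.array([[2.0, 1.0], [4.0, 1.0], [np.nan, 1.0]])
    out = impute(make_dataset(vals), "mean")
    assert out.matrix.iloc[2, 0] == 3.0


def test_impute_knn_k1_matches_brute_force_nearest():
    """3 samples, 2 proteins, 1 missing: fill equals the value of the
    closest sample by the shared-protein-scaled Euclidean distance."""
    vals = np.array([[1.0, 10.0], [1.2, 20.0], [np.nan, 21.0]])
    # distances over shared observed proteins (protein 2 only for S3):
    # d(S3,S1)=|21-10|=11, d(S3,S2)=|21-20|=1 -> nearest is S2 -> 1.2
    out = impute(make_dataset(vals), "knn", k=1)
    assert out.matrix.iloc[2, 0] == 1.2


def test_impute_knn_brute_force_oracle_random():
    """knn fill equals an exhaustive distance computation on random data."""
    rng = np.random.default_rng(8)
    vals = rng.uniform(0, 10, size=(5, 6))
    mask = rng.random(vals.shape) < 0.25
    mask[:, 0] = False
    withna = vals.copy()
    withna[mask] = np.nan
    k = 2
    out = impute(make_dataset(withna), "knn", k=k).matrix.to_numpy()

    def dist(i, j):
        shared = ~np.isnan(withna[i]) & ~np.isnan(withna[j])
        if not shared.any():
            return np.inf
        return np.sqrt(np.mean((withna[i, shared] - withna[j, shared]) ** 2))

    for i in range(5):
        for c in range(6):
            if not np.isnan(withna[i, c]):
                continue
            cands = sorted(
                (s for s in range(5) if s != i and not np.isnan(withna[s, c])
                 and np.isfinite(dist(i, s))),
                key=lambda s: (dist(i, s), s),
            )[:k]
            if cands:
                assert out[i, c] == pytest.approx(
                    np.mean([withna[s, c] for s in cands]), abs=1e-12
                )


def test_impute_errors():
    allna = np.array([[np.nan, 1.0], [np.nan, 2.0]])
    with pytest.raises(LfqstatsError, match="no observed value"):
        impute(make_dataset(allna), "mean")
    ok = np.array([[np.nan, 1.0], [2.0, 2.0]])
    with pytest.raises(LfqstatsError, match="k="):
        impute(make_dataset(ok), "knn", k=2)


@pytest.mark.parametrize("method", ["knn", "tree_iterative"])
def test_impute_seeded_determinism(method):
    rng = np.random.default_rng(9)
    vals = rng.uniform(18, 28, size=(6, 8))
    vals[rng.random(vals.shape) < 0.2] = np.nan
    vals[:, 0] = 1.0
    ds = make_dataset(vals)
    a = impute(ds, method, seed=123, k=2, n_estimators=10, max_iter=3)
    b = impute(ds, method, seed=123, k=2, n_estimators=10, max_iter=3)
    pd.testing.assert_frame_equal(a.matrix, b.matrix, check_exact=True)


def test_each_step_appends_exactly_one_log_entry(toy_dataset):
    ds = toy_dataset
    for fn in (
        remove_contaminants,
        zero_to_missing,
        lambda d: filter_completeness(d, 0.5),
        log2_transform,
        lambda d: normalize(d, "median_center"),
        lambda d: impute(d, "mean"),
    ):
        before = len(ds.log)
        ds = fn(ds)
        assert len(ds.log) == before + 1


def test_sweep_pipelines_cross_product(toy_dataset):
    ds = zero_to_missing(toy_dataset)
    out = sweep_pipelines(ds, ["median_center", None], ["mean", "median"], seed=0)
    assert set(out) == {
        ("median_center", "mean"), ("median_center", "median"),
        (None, "mean"), (None, "median"),
    }
    for (norm, imp), d in out.items():
        names = [s.name for s in d.log]
        assert names.count("normalize") == (1 if norm else 0)
        assert names.count("impute") == 1
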