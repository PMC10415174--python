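"""Preprocessing operations: contaminant removal, filtering, transform,
normalization and imputation.

Every operation is pure — it returns a new :class:`~lfqstats.dataset.DataSet`
and appends exactly one :class:`~lfqstats.dataset.PreprocessStep` whose
parameters (seeds included) suffice to replay it deterministically.
:func:`replay` re-applies a logged step sequence, which is the provenance
contract: ``replay(reset_preprocessing(ds), ds.log)`` reproduces ``ds.matrix``
bit-for-bit.

Intensity semantics: search engines report 0 for "not quantified", so
:func:`zero_to_missing` converts exact zeros to missing before
:func:`log2_transform`.  Normalization operates per sample over observed
values only; imputation fills missing cells per protein (across samples)
and never alters an observed value.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .dataset import DataSet, PreprocessStep
from .exceptions import LfqstatsError

__all__ = [
    "NORMALIZATION_METHODS",
    "IMPUTATION_METHODS",
    "remove_contaminants",
    "zero_to_missing",
    "filter_completeness",
    "log2_transform",
    "normalize",
    "impute",
    "replay",
    "sweep_pipelines",
]

NORMALIZATION_METHODS = ("median_center", "quantile", "zscore")
IMPUTATION_METHODS = ("mean", "median", "knn", "tree_iterative")


def remove_contaminants(ds: DataSet) -> DataSet:
    """Drop proteins flagged as contaminants/decoys.

    The flag series itself is left untouched (it stays indexed by the
    original protein set), so resetting and replaying the log reproduces
    the removal exactly.
    """
    flags = ds.contaminant.reindex(
        ds.matrix.columns, fill_value=False
    ).astype(bool)
    keep = list(ds.matrix.columns[~flags.to_numpy()])
    matrix = ds.matrix[keep].copy()
    step = PreprocessStep(
        name="remove_contaminants",
        params={},
        shape_after=matrix.shape,
        n_removed_or_imputed=int(flags.sum()),
    )
    return ds.with_step(matrix, step)


def zero_to_missing(ds: DataSet) -> DataSet:
    """Convert exact 0.0 intensities (engine code for 'not quantified') to NaN."""
    vals = ds.matrix.to_numpy(dtype=float).copy()
    zeros = vals == 0.0
    vals[zeros] = np.nan
    matrix = pd.DataFrame(vals, index=ds.matrix.index, columns=ds.matrix.columns)
    step = PreprocessStep(
        name="zero_to_missing",
        params={},
        shape_after=matrix.shape,
        n_removed_or_imputed=int(zeros.sum()),
    )
    return ds.with_step(matrix, step)


def filter_completeness(ds: DataSet, min_fraction: float) -> DataSet:
    """Drop proteins observed in fewer than ``ceil(min_fraction * n_samples)``
    samples."""
    if not 0.0 <= min_fraction <= 1.0:
        raise LfqstatsError("min_fraction must be in [0, 1]")
    need = int(np.ceil(min_fraction * ds.n_samples))
    observed = ds.matrix.notna().sum(axis=0)
    keep = list(ds.matrix.columns[(observed >= need).to_numpy()])
    matrix = ds.matrix[keep].copy()
    step = PreprocessStep(
        name="filter_completeness",
        params={"min_fraction": float(min_fraction)},
        shape_after=matrix.shape,
        n_removed_or_imputed=ds.n_proteins - len(keep),
    )
    return ds.with_step(matrix, step)


def log2_transform(ds: DataSet) -> DataSet:
    """log2-transform all observed intensities (requires strictly positive
    values; run :func:`zero_to_missing` first)."""
    vals = ds.matrix.to_numpy(dtype=float)
    if np.nanmin(vals, initial=np.inf) <= 0:
        raise LfqstatsError(
            "observed values <= 0 present; run zero_to_missing before "
            "log2_transform"
        )
    matrix = pd.DataFrame(
        np.log2(vals), index=ds.matrix.index, columns=ds.matrix.columns
    )
    step = PreprocessStep(
        name="log2_transform", params={}, shape_after=matrix.shape
    )
    return ds.with_step(matrix, step)


# ---------------------------------------------------------------------------
# normalization


def _quantile_reference(vals: np.ndarray) -> np.ndarray:
    """Reference distribution: mean of order statistics across samples.

    Built from complete samples when any exist; otherwise from per-rank means
    over whatever values are available at each rank.
    """
    n_samples, n_proteins = vals.shape
    complete = ~np.isnan(vals).any(axis=1)
    if complete.any():
        return np.sort(vals[complete], axis=1).mean(axis=0)
    counts = (~np.isnan(vals)).sum(axis=1)
    max_len = int(counts.max())
    if max_len == 0:
        raise LfqstatsError("cannot quantile-normalize an all-missing matrix")
    acc = np.zeros(max_len)
    nacc = np.zeros(max_len)
    for i in range(n_samples):
        obs = np.sort(vals[i][~np.isnan(vals[i])])
        acc[: len(obs)] += obs
        nacc[: len(obs)] += 1
    return acc / np.maximum(nacc, 1)


def _quantile_normalize(vals: np.ndarray) -> np.ndarray:
    ref = _quantile_reference(vals)
    out = vals.copy()
    L = len(ref)
    for i in range(vals.shape[0]):
        mask = ~np.isnan(vals[i])
        m = int(mask.sum())
        if m == 0:
            continue
        # reference values mapped to this sample's m rank positions
        if m == 1:
            mapped = np.array([ref.mean()])
        elif m == L:
            mapped = ref
        else:
            mapped = np.interp(
                np.linspace(0.0, 1.0, m), np.linspace(0.0, 1.0, L), ref
            )
        obs = vals[i][mask]
        order = np.argsort(obs, kind="stable")
        ranks = np.empty(m, dtype=int)
        ranks[order] = np.arange(m)
        new = mapped[ranks]
        # ties get the mean of their ranks' reference values
        uniq, inv = np.unique(obs, return_inverse=True)
        if len(uniq) < m:
            sums = np.bincount(inv, weights=new)
            cnts = np.bincount(inv)
            new = (sums / cnts)[inv]
        out[i, mask] = new
    return out


def normalize(ds: DataSet, method: str) -> DataSet:
    """Scale-location normalization per sample over observed values.

    ``median_center``: shift each sample so its observed median equals the
    grand median of sample medians. ``quantile``: replace each sample's
    observed values by the mean order statistics across samples (rank-based,
    ties averaged). ``zscore``: scale each sample to observed mean 0, sd 1.
    Missing cells stay missing.
    """
    if method not in NORMALIZATION_METHODS:
        raise LfqstatsError(
            f"unknown normalization {method!r}; choose from "
            f"{NORMALIZATION_METHODS}"
        )
    vals = ds.matrix.to_numpy(dtype=float).copy()
    if method == "median_center":
        medians = np.nanmedian(vals, axis=1)
        grand = np.median(medians)
        vals = vals - medians[:, None] + grand
    elif method == "quantile":
        vals = _quantile_normalize(vals)
    else:  # zscore
        n_obs = (~np.isnan(vals)).sum(axis=1)
        if (n_obs < 2).any():
            bad = ds.matrix.index[n_obs < 2].tolist()
            raise LfqstatsError(
                f"zscore requires >= 2 observed values per sample; "
                f"offending samples: {bad}"
            )
        mean = np.nanmean(vals, axis=1)
        sd = np.nanstd(vals, axis=1, ddof=1)
        if (sd == 0).any():
            bad = ds.matrix.index[sd == 0].tolist()
            raise LfqstatsError(f"zero-variance samples under zscore: {bad}")
        vals = (vals - mean[:, None]) / sd[:, None]
    matrix = pd.DataFrame(vals, index=ds.matrix.index, columns=ds.matrix.columns)
    step = PreprocessStep(
        name="normalize", params={"method": method}, shape_after=matrix.shape
    )
    return ds.with_step(matrix, step)


# ---------------------------------------------------------------------------
# imputation


def _impute_knn(vals: np.ndarray, k: int) -> np.ndarray:
    """Fill each missing cell with the per-protein mean of the k nearest
    samples (Euclidean over mutually observed proteins, scaled by the number
    of shared proteins; ties broken by sample order)."""
    n_samples, _ = vals.shape
    if k >= n_samples:
        raise LfqstatsError(f"k={k} must be < n_samples={n_samples}")
    obs = ~np.isnan(vals)
    # pairwise scaled distances
    dist = np.full((n_samples, n_samples), np.inf)
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            shared = obs[i] & obs[j]
            ns = int(shared.sum())
            if ns == 0:
                continue
            diff = vals[i, shared] - vals[j, shared]
            dist[i, j] = dist[j, i] = np.sqrt(np.sum(diff * diff) / ns)
    out = vals.copy()
    for i in range(n_samples):
        missing_cols = np.flatnonzero(~obs[i])
        if missing_cols.size == 0:
            continue
        # stable sort => ties broken by sample order
        order = np.argsort(dist[i], kind="stable")
        order = order[np.isfinite(dist[i][order])]
        for c in missing_cols:
            donors = [s for s in order if obs[s, c]][:k]
            if not donors:
                continue  # falls back to protein mean afterwards
            out[i, c] = vals[donors, c].mean()
    # any cell with no eligible donor falls back to the protein mean
    still = np.isnan(out)
    if still.any():
        col_means = np.nanmean(vals, axis=0)
        out[still] = np.broadcast_to(col_means, out.shape)[still]
    return out


def _impute_tree_iterative(
    vals: np.ndarray, n_estimators: int, max_iter: int, seed: int
) -> np.ndarray:
    """Iterative chained imputation with extra-trees regressors.

    Missing cells start at per-protein means; proteins are revisited in
    descending-missingness order until ``max_iter`` rounds or the relative
    change drops below 1e-3.
    """
    imputer = IterativeImputer(
        estimator=ExtraTreesRegressor(
            n_estimators=n_estimators, random_state=seed
        ),
        max_iter=max_iter,
        tol=1e-3,
        initial_strategy="mean",
        imputation_order="descending",
        random_state=seed,
        sample_posterior=False,
        keep_empty_features=False,
    )
    with warnings.catch_warnings():
        # hitting the round cap is the documented stopping rule, not a defect
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        return imputer.fit_transform(vals)


def impute(
    ds: DataSet,
    method: str,
    seed: int = 0,
    k: int = 3,
    n_estimators: int = 100,
    max_iter: int = 10,
) -> DataSet:
    """Fill all missing cells; observed cells are never altered.

    ``mean``/``median``: per-protein statistic over observed samples.
    ``knn``: per-protein mean of the ``k`` nearest samples (see
    :func:`_impute_knn`).  ``tree_iterative``: iterative chained prediction
    with regression-tree ensembles, proteins as features (seeded).
    """
    if method not in IMPUTATION_METHODS:
        raise LfqstatsError(
            f"unknown imputation {method!r}; choose from {IMPUTATION_METHODS}"
        )
    vals = ds.matrix.to_numpy(dtype=float).copy()
    obs_mask = ~np.isnan(vals)
    all_missing = ~obs_mask.any(axis=0)
    if all_missing.any():
        bad = ds.matrix.columns[all_missing].tolist()
        raise LfqstatsError(
            f"proteins with no observed value cannot be imputed: {bad[:5]}; "
            "apply filter_completeness first"
        )
    n_missing = int((~obs_mask).sum())
    if method == "mean":
        fill = np.nanmean(vals, axis=0)
        out = np.where(obs_mask, vals, fill[None, :])
    elif method == "median":
        fill = np.nanmedian(vals, axis=0)
        out = np.where(obs_mask, vals, fill[None, :])
    elif method == "knn":
        out = _impute_knn(vals, k)
    else:
        out = _impute_tree_iterative(vals, n_estimators, max_iter, seed)
        out = np.where(obs_mask, vals, out)  # guard: observed cells untouched
    params = {"method": method, "seed": int(seed)}
    if method == "knn":
        params["k"] = int(k)
    if method == "tree_iterative":
        params.update(n_estimators=int(n_estimators), max_iter=int(max_iter))
    matrix = pd.DataFrame(out, index=ds.matrix.index, columns=ds.matrix.columns)
    step = PreprocessStep(
        name="impute",
        params=params,
        shape_after=matrix.shape,
        n_removed_or_imputed=n_missing,
    )
    return ds.with_step(matrix, step)


# ---------------------------------------------------------------------------
# replay and pipeline sweep


def _replay_subset(ds: DataSet, sample_ids: list[str]) -> DataSet:
    from .dataset import subset as _subset

    return _subset(ds, keep=sample_ids)


def replay(ds: DataSet, log) -> DataSet:
    """Re-apply a logged sequence of preprocessing steps."""
    out = ds
    for step in log:
        p = step.params
        if step.name == "remove_contaminants":
            out = remove_contaminants(out)
        elif step.name == "zero_to_missing":
            out = zero_to_missing(out)
        elif step.name == "filter_completeness":
            out = filter_completeness(out, p["min_fraction"])
        elif step.name == "log2_transform":
            out = log2_transform(out)
        elif step.name == "normalize":
            out = normalize(out, p["method"])
        elif step.name == "impute":
            out = impute(out, **p)
        elif step.name == "subset":
            out = _replay_subset(out, p["sample_ids"])
        else:
            raise LfqstatsError(f"cannot replay unknown step {step.name!r}")
    return out


def sweep_pipelines(
    ds: DataSet,
    normalizations,
    imputations,
    seed: int = 0,
) -> dict:
    """Run the cross product of normalization x imputation choices.

    Returns ``{(normalization, imputation): DataSet}``; ``None`` in either
    list skips that stage.  Each output carries its own complete log, which
    is how systematic comparisons of preprocessing variants stay
    reproducible.
    """
    out = {}
    for norm in normalizations:
        base = ds if norm is None else normalize(ds, norm)
        for imp in imputations:
            out[(norm, imp)] = base if imp is None else impute(base, imp, seed=seed)
    return out
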