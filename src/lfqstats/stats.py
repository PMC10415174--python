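"""Per-protein differential expression and multivariate statistics.

Missing values are handled by observed-only analysis: each protein is tested
on the samples where it was quantified, gated by ``min_obs`` observations per
group (default 2).  Proteins failing the gate — or with zero within-group
scatter and unequal means, where the t statistic is undefined — are reported
with status ``skipped_low_n`` and an undefined p-value rather than being
patched with an epsilon.  Benjamini–Hochberg adjustment runs over the tested
proteins only.

The permutation-based SAM test lives in :mod:`lfqstats.sam` and is re-exported
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA as _SkPCA

from ._util import fmt_float
from .dataset import DataSet
from .exceptions import LfqstatsError
from .sam import SAMResult, sam  # noqa: F401  (re-export)

__all__ = [
    "DEResult",
    "OraResult",
    "ttest",
    "anova",
    "ancova",
    "sam",
    "SAMResult",
    "adjust_bh",
    "ora",
    "pca",
    "hcluster",
    "read_annotation",
]

STATUS_OK = "ok"
STATUS_SKIPPED = "skipped_low_n"

DE_COLUMNS = [
    "protein_id", "log2_fc", "statistic", "p", "q", "n1", "n2", "status",
]


@dataclass(frozen=True)
class DEResult:
    """Per-protein differential-expression table.

    ``table`` columns (stable order): protein_id, log2_fc, statistic, p, q,
    n1, n2, status.  ``log2_fc`` is the mean difference on the log2 scale
    (group1 − group2); it is NaN for multi-group tests.  ``q`` is the BH
    adjusted value over tested proteins.
    """

    table: pd.DataFrame
    test: str
    params: dict

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format=fmt_float)


def _make_de_table(rows: list[dict], test: str, params: dict) -> DEResult:
    table = pd.DataFrame(rows, columns=DE_COLUMNS)
    table["q"] = adjust_bh(table["p"].to_numpy(dtype=float))
    return DEResult(table=table, test=test, params=params)


def _group_values(ds: DataSet, group_column: str, label) -> np.ndarray:
    if group_column not in ds.metadata.columns:
        raise LfqstatsError(f"unknown metadata column {group_column!r}")
    mask = (ds.metadata[group_column] == label).to_numpy()
    if not mask.any():
        raise LfqstatsError(
            f"label {label!r} not present in metadata column {group_column!r}"
        )
    return ds.matrix.to_numpy(dtype=float)[mask]


def ttest(
    ds: DataSet,
    group_column: str,
    group1,
    group2,
    equal_var: bool = False,
    min_obs: int = 2,
) -> DEResult:
    """Two-sided per-protein t-test (Welch by default) between two groups."""
    if min_obs < 2:
        raise LfqstatsError("min_obs must be >= 2")
    x1 = _group_values(ds, group_column, group1)
    x2 = _group_values(ds, group_column, group2)
    rows = []
    for j, pid in enumerate(ds.matrix.columns):
        a = x1[:, j][~np.isnan(x1[:, j])]
        b = x2[:, j][~np.isnan(x2[:, j])]
        n1, n2 = len(a), len(b)
        if n1 < min_obs or n2 < min_obs:
            rows.append(_skip_row(pid, n1, n2))
            continue
        fc = float(a.mean() - b.mean())
        if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
            if fc == 0.0:
                rows.append(dict(
                    protein_id=pid, log2_fc=0.0, statistic=0.0, p=1.0,
                    q=np.nan, n1=n1, n2=n2, status=STATUS_OK,
                ))
            else:
                rows.append(_skip_row(pid, n1, n2, log2_fc=fc))
            continue
        with warnings.catch_warnings():
            # imputation can leave near-constant groups; the statistic is
            # still well defined, scipy just warns about precision
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        rows.append(dict(
            protein_id=pid, log2_fc=fc, statistic=float(t), p=float(p),
            q=np.nan, n1=n1, n2=n2, status=STATUS_OK,
        ))
    return _make_de_table(
        rows, "ttest",
        dict(group_column=group_column, group1=group1, group2=group2,
             equal_var=equal_var, min_obs=min_obs),
    )


def _skip_row(pid, n1, n2, log2_fc=np.nan):
    return dict(
        protein_id=pid, log2_fc=log2_fc, statistic=np.nan, p=np.nan,
        q=np.nan, n1=n1, n2=n2, status=STATUS_SKIPPED,
    )


def anova(ds: DataSet, group_column: str, min_obs: int = 2) -> DEResult:
    """Per-protein one-way ANOVA F-test across all groups in a column."""
    if group_column not in ds.metadata.columns:
        raise LfqstatsError(f"unknown metadata column {group_column!r}")
    labels = ds.metadata[group_column].to_numpy()
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise LfqstatsError("ANOVA needs >= 2 groups")
    vals = ds.matrix.to_numpy(dtype=float)
    rows = []
    for j, pid in enumerate(ds.matrix.columns):
        groups = []
        for lv in levels:
            g = vals[labels == lv, j]
            g = g[~np.isnan(g)]
            if len(g) >= min_obs:
                groups.append(g)
        n_tot = sum(len(g) for g in groups)
        if len(groups) < 2:
            rows.append(_skip_row(pid, n_tot, 0))
            continue
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df1 = len(groups) - 1
        df2 = n_tot - len(groups)
        if ss_within == 0.0 or df2 <= 0:
            rows.append(_skip_row(pid, n_tot, 0))
            continue
        f = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(f, df1, df2))
        rows.append(dict(
            protein_id=pid, log2_fc=np.nan, statistic=float(f), p=p,
            q=np.nan, n1=n_tot, n2=0, status=STATUS_OK,
        ))
    return _make_de_table(
        rows, "anova", dict(group_column=group_column, min_obs=min_obs)
    )


def ancova(
    ds: DataSet,
    group_column: str,
    covariates: list[str],
    min_obs: int = 2,
) -> DEResult:
    """Per-protein ANCOVA: partial F-test for the group factor adjusted for
    numeric covariates.

    Fits intensity ~ intercept + group indicators + covariates by least
    squares and compares against the covariate-only model.  Proteins whose
    observed design is rank deficient are skipped.
    """
    if group_column not in ds.metadata.columns:
        raise LfqstatsError(f"unknown metadata column {group_column!r}")
    for c in covariates:
        if c not in ds.metadata.columns:
            raise LfqstatsError(f"covariate column {c!r} missing from metadata")
        if not np.issubdtype(ds.metadata[c].dtype, np.number):
            raise LfqstatsError(f"covariate {c!r} must be numeric")
    labels = ds.metadata[group_column].to_numpy()
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise LfqstatsError("ANCOVA needs >= 2 groups")
    dummies = np.column_stack(
        [(labels == lv).astype(float) for lv in levels[1:]]
    )
    cov = (
        ds.metadata[list(covariates)].to_numpy(dtype=float)
        if covariates
        else np.empty((len(labels), 0))
    )
    intercept = np.ones((len(labels), 1))
    X_full = np.hstack([intercept, dummies, cov])
    X_red = np.hstack([intercept, cov])
    vals = ds.matrix.to_numpy(dtype=float)

    rows = []
    for j, pid in enumerate(ds.matrix.columns):
        y = vals[:, j]
        obs = ~np.isnan(y)
        n = int(obs.sum())
        # keep the min_obs-per-group gate consistent with the other tests
        counts = [int(((labels == lv) & obs).sum()) for lv in levels]
        if sum(c >= min_obs for c in counts) < 2:
            rows.append(_skip_row(pid, n, 0))
            continue
        Xf, Xr, yo = X_full[obs], X_red[obs], y[obs]
        rank_f = np.linalg.matrix_rank(Xf)
        rank_r = np.linalg.matrix_rank(Xr)
        df1 = rank_f - rank_r
        df2 = n - rank_f
        if df1 < 1 or df2 < 1 or rank_f < Xf.shape[1]:
            rows.append(_skip_row(pid, n, 0))
            continue
        rss_f = float(np.sum((yo - Xf @ np.linalg.lstsq(Xf, yo, rcond=None)[0]) ** 2))
        rss_r = float(np.sum((yo - Xr @ np.linalg.lstsq(Xr, yo, rcond=None)[0]) ** 2))
        if rss_f <= 0.0:
            rows.append(_skip_row(pid, n, 0))
            continue
        f = ((rss_r - rss_f) / df1) / (rss_f / df2)
        f = max(f, 0.0)
        p = float(sps.f.sf(f, df1, df2))
        rows.append(dict(
            protein_id=pid, log2_fc=np.nan, statistic=float(f), p=p,
            q=np.nan, n1=n, n2=0, status=STATUS_OK,
        ))
    return _make_de_table(
        rows, "ancova",
        dict(group_column=group_column, covariates=list(covariates),
             min_obs=min_obs),
    )


# ---------------------------------------------------------------------------
# multiple testing and enrichment


def adjust_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN entries stay NaN.

    Adjustment runs over the defined p-values only (m = number tested).
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    defined = ~np.isnan(p)
    vals = p[defined]
    if vals.size == 0:
        return out
    if (vals < 0).any() or (vals > 1).any():
        raise LfqstatsError("p-values must lie in [0, 1]")
    m = vals.size
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    out[defined] = q
    return out


@dataclass(frozen=True)
class OraResult:
    """Hypergeometric over-representation result, one row per tested term."""

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format=fmt_float)


def ora(
    significant: set,
    background: set,
    annotation: dict,
    min_term_size: int = 2,
) -> OraResult:
    """Over-representation analysis of annotation terms in a hit list.

    For each term (restricted to the background, size >= ``min_term_size``)
    the upper-tail hypergeometric p-value of the overlap with the
    significant set is computed, then BH-adjusted across tested terms.
    """
    significant = set(significant)
    background = set(background)
    if not significant <= background:
        extra = sorted(significant - background)
        raise LfqstatsError(
            f"significant ids not contained in background: {extra[:5]}"
        )
    if not annotation:
        raise LfqstatsError("annotation mapping is empty")
    N = len(background)
    n_sig = len(significant)
    rows = []
    for term, members in sorted(annotation.items()):
        in_bg = set(members) & background
        K = len(in_bg)
        if K < min_term_size:
            continue
        k = len(in_bg & significant)
        p = float(sps.hypergeom.sf(k - 1, N, K, n_sig))
        rows.append(dict(
            term_id=term, n_term_background=K, n_term_hits=k,
            n_sig=n_sig, n_background=N, p=min(p, 1.0),
        ))
    table = pd.DataFrame(
        rows,
        columns=["term_id", "n_term_background", "n_term_hits", "n_sig",
                 "n_background", "p"],
    )
    table["q"] = adjust_bh(table["p"].to_numpy(dtype=float)) if len(table) else []
    return OraResult(table=table)


def read_annotation(path, gaf: bool = False) -> dict:
    """Read a term→protein mapping from a two-column TSV (term_id,
    protein_id), or from a GAF-like file (term in column 5, id in column 2)."""
    ann: dict[str, set] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("!", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if gaf:
                if len(fields) < 5:
                    continue
                term, pid = fields[4], fields[1]
            else:
                if len(fields) < 2:
                    continue
                term, pid = fields[0], fields[1]
            ann.setdefault(term, set()).add(pid)
    return ann


# ---------------------------------------------------------------------------
# multivariate


def pca(ds: DataSet, n_components: int):
    """Principal component analysis of the (imputed) sample matrix.

    Columns are mean-centered; components are ordered by decreasing
    explained variance.  Sign convention: within each component the
    largest-magnitude loading is positive.  Returns
    ``(scores, loadings, explained_variance_ratio)`` with scores indexed by
    sample and loadings by protein.
    """
    vals = ds.matrix.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise LfqstatsError("matrix has missing values; impute before pca")
    max_comp = min(ds.n_samples - 1, ds.n_proteins)
    if not 1 <= n_components <= max_comp:
        raise LfqstatsError(
            f"n_components must be in [1, {max_comp}] for this matrix"
        )
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(vals)
    loadings = model.components_.T  # proteins x components
    # deterministic sign: largest-|loading| entry positive per component
    for c in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[i, c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0
    ratio = model.explained_variance_ratio_.astype(float)
    scores_df = pd.DataFrame(
        scores, index=ds.matrix.index,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    loadings_df = pd.DataFrame(
        loadings, index=ds.matrix.columns,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    return scores_df, loadings_df, ratio


def hcluster(
    matrix,
    axis: str = "samples",
    metric: str = "euclidean",
    linkage: str = "average",
):
    """Agglomerative hierarchical clustering of samples or proteins.

    Returns ``(merge_tree, leaf_order)`` where ``merge_tree`` is the
    standard (n−1)×4 linkage matrix (child, child, height, size) and
    ``leaf_order`` is the dendrogram leaf permutation (indices into the
    chosen axis).
    """
    if axis not in ("samples", "proteins"):
        raise LfqstatsError("axis must be 'samples' or 'proteins'")
    if metric not in ("euclidean", "correlation"):
        raise LfqstatsError("metric must be 'euclidean' or 'correlation'")
    if linkage not in ("average", "complete", "single"):
        raise LfqstatsError("linkage must be average, complete or single")
    vals = np.asarray(
        matrix.to_numpy(dtype=float) if hasattr(matrix, "to_numpy") else matrix,
        dtype=float,
    )
    if axis == "proteins":
        vals = vals.T
    if vals.shape[0] < 2:
        raise LfqstatsError("need >= 2 items to cluster")
    if np.isnan(vals).any():
        raise LfqstatsError("matrix has missing values; impute first")
    if metric == "correlation" and (np.std(vals, axis=1) == 0).any():
        raise LfqstatsError("constant rows are undefined under correlation")
    dists = pdist(vals, metric=metric)
    tree = sch.linkage(dists, method=linkage)
    leaf_order = [int(i) for i in sch.leaves_list(tree)]
    return tree, leaf_order
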