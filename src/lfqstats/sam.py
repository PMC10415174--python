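"""Significance Analysis of Microarrays (SAM), two-class unpaired.

SAM tests each protein with a regularized t-like score

    d_i = (mean(group1) - mean(group2)) / (s_i + s0)

where ``s_i`` is the pooled standard error and ``s0`` a small "fudge factor"
that damps the otherwise explosive scores of low-variance proteins.  The
null distribution is built by permuting the group labels: for each
permutation the full vector of d-scores is recomputed and sorted, and the
expected order statistics ``d_bar`` are the per-rank means over
permutations.  Scanning outward from the origin of the observed-vs-expected
plot, the first ordered score on each branch whose deviation from
expectation reaches ``delta`` sets the calling cut; every score beyond a
cut is called significant.

The false discovery rate at a given delta follows the classic convention:
the median number of permuted scores falling outside the data-derived cut
thresholds, scaled by the estimated fraction of truly null proteins (pi0)
and divided by the number of calls.

When the number of distinct label assignments is at most ``n_perm`` the
permutation set is enumerated exhaustively (the identity assignment
included); otherwise ``n_perm`` assignments are drawn uniformly with the
given seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from ._util import fmt_float
from .dataset import DataSet
from .exceptions import LfqstatsError

__all__ = ["SAMResult", "sam"]

S0_PERCENTILES = np.arange(0, 101, 5)


@dataclass(frozen=True)
class SAMResult:
    """Result of a two-class SAM run.

    ``table`` columns: protein_id, d, d_bar (expected order statistic at
    this protein's rank), perm_p, called.  ``delta_table`` columns: delta,
    n_called, median_false_called, fdr.
    """

    table: pd.DataFrame
    s0: float
    delta: float
    delta_table: pd.DataFrame
    n_perm_used: int
    exhaustive: bool
    excluded_ids: tuple[str, ...]
    params: dict

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format=fmt_float)


def _d_scores(vals: np.ndarray, mask1: np.ndarray, s0: float = 0.0):
    """d, numerator r and pooled scatter s for one group assignment.

    ``vals`` is proteins x samples; ``mask1`` selects group-1 columns.
    Missing values are ignored per protein; a side with no observation
    contributes a zero mean difference (d = 0), which only occurs when SAM
    runs on unimputed data.
    """
    obs = ~np.isnan(vals)
    o1 = obs[:, mask1]
    o2 = obs[:, ~mask1]
    v1 = np.where(o1, vals[:, mask1], 0.0)
    v2 = np.where(o2, vals[:, ~mask1], 0.0)
    n1 = o1.sum(axis=1)
    n2 = o2.sum(axis=1)
    ok = (n1 > 0) & (n2 > 0)
    m1 = np.divide(v1.sum(axis=1), n1, out=np.zeros(len(vals)), where=n1 > 0)
    m2 = np.divide(v2.sum(axis=1), n2, out=np.zeros(len(vals)), where=n2 > 0)
    ss1 = (np.where(o1, vals[:, mask1] - m1[:, None], 0.0) ** 2).sum(axis=1)
    ss2 = (np.where(o2, vals[:, ~mask1] - m2[:, None], 0.0) ** 2).sum(axis=1)
    dof = np.maximum(n1 + n2 - 2, 1)
    inv = np.divide(1.0, n1, out=np.zeros(len(vals)), where=n1 > 0) + np.divide(
        1.0, n2, out=np.zeros(len(vals)), where=n2 > 0
    )
    s = np.sqrt((ss1 + ss2) / dof * inv)
    r = np.where(ok, m1 - m2, 0.0)
    d = np.divide(r, s + s0, out=np.zeros(len(vals)), where=(s + s0) > 0)
    return d, r, s


def _tune_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Pick s0 among percentiles of s, minimizing the coefficient of
    variation of the windowed median absolute deviation of d.

    Proteins are windowed by quantiles of s; for each candidate s0 the MAD
    of d within each window is computed, and the candidate whose MADs are
    most uniform across windows (smallest cv) wins.  Ties and degenerate
    windows fall back to the smallest viable candidate.
    """
    n = len(s)
    candidates = np.unique(np.percentile(s, S0_PERCENTILES))
    n_windows = int(min(20, max(2, n // 5)))
    edges = np.percentile(s, np.linspace(0, 100, n_windows + 1))
    window = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)
    best_s0, best_cv = float(candidates[0]), np.inf
    for cand in candidates:
        d = r / (s + cand) if cand > 0 else np.divide(
            r, s, out=np.zeros(n), where=s > 0
        )
        mads = []
        for w in range(n_windows):
            dw = d[window == w]
            if dw.size:
                mads.append(np.median(np.abs(dw - np.median(dw))))
        mads = np.asarray(mads)
        if mads.size < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=0) / mads.mean()
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(cand)
    return best_s0


def _assignments(n: int, n1: int, n_perm: int, seed: int):
    """Group-1 index sets: exhaustive when feasible, else seeded draws."""
    total = comb(n, n1)
    if total <= n_perm:
        masks = np.zeros((total, n), dtype=bool)
        for b, idx in enumerate(combinations(range(n), n1)):
            masks[b, list(idx)] = True
        return masks, True
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=bool)
    for b in range(n_perm):
        masks[b, rng.choice(n, size=n1, replace=False)] = True
    return masks, False


def _cut_thresholds(d_sorted, d_bar, delta):
    """Calling cuts, scanning outward from the origin of the QQ-like plot.

    Moving up the ordered scores (the branch with nonnegative expected
    order statistics), the up-cut is the smallest score whose deviation
    from expectation reaches delta; symmetrically for the down branch.
    Restricting each cut to its branch keeps null data (d = 0 everywhere,
    d_bar spanning both signs) from producing spurious calls.
    """
    dev = d_sorted - d_bar
    up = d_sorted[(dev >= delta) & (d_bar >= 0)]
    low = d_sorted[(-dev >= delta) & (d_bar <= 0)]
    cut_up = float(up.min()) if up.size else np.inf
    cut_low = float(low.max()) if low.size else -np.inf
    return cut_low, cut_up


def _fdr_at_delta(d_sorted, d_bar, perm_d, pi0, delta):
    """n_called, median false calls and FDR at one delta threshold."""
    cut_low, cut_up = _cut_thresholds(d_sorted, d_bar, delta)
    called = (d_sorted >= cut_up) | (d_sorted <= cut_low)
    n_called = int(called.sum())
    false_per_perm = ((perm_d >= cut_up) | (perm_d <= cut_low)).sum(axis=0)
    median_false = float(np.median(false_per_perm))
    if n_called == 0:
        return 0, median_false, 0.0
    return n_called, median_false, float(min(1.0, pi0 * median_false / n_called))


def sam(
    ds: DataSet,
    group_column: str,
    group1,
    group2,
    n_perm: int = 1000,
    delta: float = 0.0,
    s0_mode: str = "auto",
    s0_value: float | None = None,
    seed: int = 0,
    min_obs: int = 2,
) -> SAMResult:
    """Two-class unpaired SAM with permutation FDR.

    Parameters
    ----------
    n_perm:
        Permutation budget; exhausted exactly when the number of distinct
        label assignments is at most this.
    delta:
        Calling threshold on the deviation between ordered scores and
        their expected order statistics (see :func:`_cut_thresholds`).
    s0_mode, s0_value:
        ``auto`` tunes the fudge factor over percentiles of the per-protein
        scatter (see :func:`_tune_s0`); ``fixed`` uses ``s0_value``.
    min_obs:
        Proteins with fewer observed values in either group are excluded
        (ids recorded in ``excluded_ids``).
    """
    if group1 == group2:
        raise LfqstatsError("group1 and group2 must differ")
    if n_perm < 1:
        raise LfqstatsError("n_perm must be >= 1")
    if s0_mode not in ("auto", "fixed"):
        raise LfqstatsError("s0_mode must be 'auto' or 'fixed'")
    if s0_mode == "fixed" and (s0_value is None or s0_value < 0):
        raise LfqstatsError("fixed s0 requires a nonnegative s0_value")
    if group_column not in ds.metadata.columns:
        raise LfqstatsError(f"unknown metadata column {group_column!r}")

    labels = ds.metadata[group_column]
    sel = labels.isin([group1, group2]).to_numpy()
    for lab in (group1, group2):
        if not (labels == lab).any():
            raise LfqstatsError(f"label {lab!r} not present in {group_column!r}")
    sub = ds.matrix.to_numpy(dtype=float)[sel].T  # proteins x samples
    sublabels = labels.to_numpy()[sel]
    mask1 = sublabels == group1

    obs = ~np.isnan(sub)
    n_obs1 = obs[:, mask1].sum(axis=1)
    n_obs2 = obs[:, ~mask1].sum(axis=1)
    tested = (n_obs1 >= min_obs) & (n_obs2 >= min_obs)
    excluded = tuple(np.asarray(ds.matrix.columns)[~tested].tolist())
    vals = sub[tested]
    pids = np.asarray(ds.matrix.columns)[tested]
    if vals.shape[0] < 2:
        raise LfqstatsError("fewer than 2 testable proteins for SAM")

    d0, r, s = _d_scores(vals, mask1, s0=0.0)
    s0 = _tune_s0(r, s) if s0_mode == "auto" else float(s0_value)
    d = r / (s + s0) if s0 > 0 else d0

    masks, exhaustive = _assignments(len(sublabels), int(mask1.sum()), n_perm, seed)
    B = masks.shape[0]
    perm_d = np.empty((len(d), B))
    for b in range(B):
        perm_d[:, b], _, _ = _d_scores(vals, masks[b], s0=s0)

    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    d_bar_sorted = np.sort(perm_d, axis=0).mean(axis=1)

    # pi0: fraction of observed d inside the permutation null's IQR, over 0.5
    q25, q75 = np.percentile(perm_d, [25, 75])
    pi0 = float(min(1.0, ((d >= q25) & (d <= q75)).mean() / 0.5))

    # per-protein permutation p with the +1 correction
    exceed = (np.abs(perm_d) >= np.abs(d)[:, None]).sum(axis=1)
    perm_p = (1.0 + exceed) / (1.0 + B)

    cut_low, cut_up = _cut_thresholds(d_sorted, d_bar_sorted, delta)
    called_sorted = (d_sorted >= cut_up) | (d_sorted <= cut_low)
    called = np.empty(len(d), dtype=bool)
    called[order] = called_sorted
    d_bar_by_protein = np.empty(len(d))
    d_bar_by_protein[order] = d_bar_sorted

    max_dev = float(np.abs(d_sorted - d_bar_sorted).max())
    grid = np.unique(np.concatenate([
        np.linspace(0.0, max_dev, 26), [float(delta)]
    ]))
    delta_rows = []
    for dl in grid:
        n_called, med_false, fdr = _fdr_at_delta(
            d_sorted, d_bar_sorted, perm_d, pi0, dl
        )
        delta_rows.append(dict(
            delta=float(dl), n_called=n_called,
            median_false_called=med_false, fdr=fdr,
        ))
    delta_table = pd.DataFrame(
        delta_rows, columns=["delta", "n_called", "median_false_called", "fdr"]
    )

    table = pd.DataFrame({
        "protein_id": pids,
        "d": d,
        "d_bar": d_bar_by_protein,
        "perm_p": perm_p,
        "called": called,
    })
    return SAMResult(
        table=table,
        s0=float(s0),
        delta=float(delta),
        delta_table=delta_table,
        n_perm_used=B,
        exhaustive=exhaustive,
        excluded_ids=excluded,
        params=dict(
            group_column=group_column, group1=group1, group2=group2,
            n_perm=n_perm, delta=float(delta), s0_mode=s0_mode,
            s0_value=s0_value, seed=seed, min_obs=min_obs,
        ),
    )
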