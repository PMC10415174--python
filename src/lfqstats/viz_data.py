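"""Plot-ready data structures and deterministic SVG export.

The statistics modules return tables; this module turns them into the data
behind the standard proteomics figures (volcano, clustered heatmap, PCA
scatter, dendrogram) and writes them as plain SVG 1.1.  Rendering is
intentionally minimal and fully deterministic: fixed element order, fixed
float formatting, no timestamps — equal inputs produce byte-identical
files, which makes figures diffable and end-to-end runs reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .dataset import DataSet
from .exceptions import LfqstatsError
from .stats import DEResult, hcluster

__all__ = [
    "VolcanoData",
    "volcano_data",
    "heatmap_data",
    "render_svg",
    "DEFAULT_STYLE",
]

CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_NS = "not_significant"
CLASS_SKIPPED = "skipped"

DEFAULT_STYLE = {
    "width": 640,
    "height": 480,
    "margin": 50,
    "point_radius": 3.0,
    "colors": {
        CLASS_UP: "#d62728",
        CLASS_DOWN: "#1f77b4",
        CLASS_NS: "#9e9e9e",
        CLASS_SKIPPED: "#e0e0e0",
        "line": "#333333",
        "cell_low": "#1f77b4",
        "cell_high": "#d62728",
    },
    "font_family": "sans-serif",
    "font_size": 11,
}


@dataclass(frozen=True)
class VolcanoData:
    """Volcano-plot data: per protein x = log2 fold change, y = −log10 p.

    ``table`` columns: protein_id, x, y, cls, label.  Proteins with an
    undefined p-value are class ``skipped`` and carry NaN y.
    """

    table: pd.DataFrame
    fc_cutoff: float
    alpha: float
    use_adjusted: bool


def volcano_data(
    de: DEResult,
    fc_cutoff: float = 1.0,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    annotate: list[str] | None = None,
) -> VolcanoData:
    """Classify proteins for a volcano plot.

    ``up``: log2_fc >= fc_cutoff and significance above −log10(alpha);
    ``down`` symmetrically; everything else tested is ``not_significant``.
    p-values of exactly 0 are clamped to the smallest positive float.
    Label annotation is opt-in via ``annotate`` (protein ids).
    """
    if not 0.0 < alpha < 1.0:
        raise LfqstatsError("alpha must be in (0, 1)")
    if fc_cutoff < 0:
        raise LfqstatsError("fc_cutoff must be >= 0")
    if de.table.empty:
        raise LfqstatsError("empty differential-expression result")
    tab = de.table
    pcol = tab["q"] if use_adjusted else tab["p"]
    p = pcol.to_numpy(dtype=float)
    clamped = p == 0.0
    p = np.where(clamped, np.nextafter(0.0, 1.0), p)
    y = -np.log10(p)
    x = tab["log2_fc"].to_numpy(dtype=float)
    ybar = -np.log10(alpha)
    cls = np.where(
        np.isnan(p) | (tab["status"] == "skipped_low_n"),
        CLASS_SKIPPED,
        np.where(
            (x >= fc_cutoff) & (y >= ybar),
            CLASS_UP,
            np.where((x <= -fc_cutoff) & (y >= ybar), CLASS_DOWN, CLASS_NS),
        ),
    )
    annotate = set(annotate or ())
    out = pd.DataFrame({
        "protein_id": tab["protein_id"],
        "x": x,
        "y": np.where(cls == CLASS_SKIPPED, np.nan, y),
        "cls": cls,
        "p_clamped": clamped,
        "label": [pid if pid in annotate else "" for pid in tab["protein_id"]],
    })
    return VolcanoData(
        table=out, fc_cutoff=float(fc_cutoff), alpha=float(alpha),
        use_adjusted=bool(use_adjusted),
    )


def heatmap_data(
    ds: DataSet,
    cluster_samples: bool = True,
    cluster_proteins: bool = True,
    metric: str = "euclidean",
    linkage: str = "average",
):
    """Reorder the matrix by hierarchical clustering for heatmap display.

    Returns a dict with the reordered matrix, the sample/protein orders and
    the linkage trees (``None`` where clustering was not requested).  The
    reordered matrix is a pure permutation of the input.
    """
    if ds.matrix.isna().to_numpy().any():
        raise LfqstatsError("matrix has missing values; impute first")
    sample_tree = protein_tree = None
    sample_order = list(range(ds.n_samples))
    protein_order = list(range(ds.n_proteins))
    if cluster_samples and ds.n_samples >= 2:
        sample_tree, sample_order = hcluster(
            ds.matrix, axis="samples", metric=metric, linkage=linkage
        )
    if cluster_proteins and ds.n_proteins >= 2:
        protein_tree, protein_order = hcluster(
            ds.matrix, axis="proteins", metric=metric, linkage=linkage
        )
    matrix = ds.matrix.iloc[sample_order, protein_order]
    return {
        "matrix": matrix,
        "sample_order": [ds.sample_ids[i] for i in sample_order],
        "protein_order": [ds.protein_ids[i] for i in protein_order],
        "sample_tree": sample_tree,
        "protein_tree": protein_tree,
    }


# ---------------------------------------------------------------------------
# SVG rendering


def _fmt(x: float) -> str:
    return f"{x:.4f}".rstrip("0").rstrip(".")


def _merge_style(style: dict | None) -> dict:
    merged = {k: v for k, v in DEFAULT_STYLE.items()}
    merged["colors"] = dict(DEFAULT_STYLE["colors"])
    for k, v in (style or {}).items():
        if k == "colors":
            merged["colors"].update(v)
        else:
            merged[k] = v
    return merged


def _svg_header(width, height) -> list[str]:
    return [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
    ]


def _scale(values, lo_px, hi_px):
    finite = values[np.isfinite(values)]
    lo = float(finite.min()) if finite.size else 0.0
    hi = float(finite.max()) if finite.size else 1.0
    if hi == lo:
        lo, hi = lo - 0.5, hi + 0.5
    span = hi - lo

    def f(v):
        return lo_px + (v - lo) / span * (hi_px - lo_px)

    return f


def _render_scatter(points, style, xlab, ylab) -> str:
    """points: list of (x, y, color, label)."""
    w, h, m = style["width"], style["height"], style["margin"]
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    fx = _scale(xs, m, w - m)
    fy = _scale(ys, h - m, m)
    out = _svg_header(w, h)
    out.append(
        f'<rect x="{m}" y="{m}" width="{w - 2 * m}" height="{h - 2 * m}" '
        f'fill="none" stroke="{style["colors"]["line"]}"/>'
    )
    font = (
        f'font-family="{style["font_family"]}" '
        f'font-size="{style["font_size"]}"'
    )
    out.append(
        f'<text x="{w // 2}" y="{h - 10}" text-anchor="middle" {font}>'
        f"{escape(xlab)}</text>"
    )
    out.append(
        f'<text x="15" y="{h // 2}" text-anchor="middle" {font} '
        f'transform="rotate(-90 15 {h // 2})">{escape(ylab)}</text>'
    )
    r = style["point_radius"]
    for x, y, color, label in points:
        if not (np.isfinite(x) and np.isfinite(y)):
            continue
        cx, cy = _fmt(fx(x)), _fmt(fy(y))
        out.append(f'<circle cx="{cx}" cy="{cy}" r="{r}" fill="{color}"/>')
        if label:
            out.append(
                f'<text x="{cx}" y="{_fmt(fy(y) - r - 2)}" '
                f'text-anchor="middle" {font}>{escape(label)}</text>'
            )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _render_volcano(v: VolcanoData, style) -> str:
    colors = style["colors"]
    pts = [
        (row.x, row.y, colors[row.cls], row.label)
        for row in v.table.itertuples()
        if row.cls != CLASS_SKIPPED
    ]
    return _render_scatter(pts, style, "log2 fold change", "-log10 p")


def _render_pca(scores: pd.DataFrame, style) -> str:
    colors = style["colors"]
    pts = [
        (row[0], row[1] if scores.shape[1] > 1 else 0.0, colors["line"], str(idx))
        for idx, row in zip(scores.index, scores.to_numpy())
    ]
    return _render_scatter(pts, style, scores.columns[0],
                           scores.columns[1] if scores.shape[1] > 1 else "")


def _render_heatmap(bundle: dict, style) -> str:
    mat = bundle["matrix"].to_numpy(dtype=float)
    w, h, m = style["width"], style["height"], style["margin"]
    n_s, n_p = mat.shape
    cw = (w - 2 * m) / n_p
    ch = (h - 2 * m) / n_s
    lo, hi = float(np.nanmin(mat)), float(np.nanmax(mat))
    span = (hi - lo) or 1.0
    out = _svg_header(w, h)
    for i in range(n_s):
        for j in range(n_p):
            t = (mat[i, j] - lo) / span
            # linear blue->red ramp
            red = int(round(31 + t * (214 - 31)))
            green = int(round(119 + t * (39 - 119)))
            blue = int(round(180 + t * (40 - 180)))
            out.append(
                f'<rect x="{_fmt(m + j * cw)}" y="{_fmt(m + i * ch)}" '
                f'width="{_fmt(cw)}" height="{_fmt(ch)}" '
                f'fill="rgb({red},{green},{blue})"/>'
            )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _dendrogram_segments(tree: np.ndarray, leaf_order: list[int]):
    """(x, height) line segments of a dendrogram in leaf coordinates."""
    n = tree.shape[0] + 1
    xpos = {leaf: float(rank) for rank, leaf in enumerate(leaf_order)}
    height = {leaf: 0.0 for leaf in range(n)}
    segments = []
    for k, (a, b, dist, _size) in enumerate(tree):
        a, b = int(a), int(b)
        xa, xb = xpos[a], xpos[b]
        segments.append((xa, height[a], xa, dist))
        segments.append((xb, height[b], xb, dist))
        segments.append((xa, dist, xb, dist))
        xpos[n + k] = (xa + xb) / 2.0
        height[n + k] = float(dist)
    return segments


def _render_dendrogram(payload, style) -> str:
    tree, leaf_order = payload
    w, h, m = style["width"], style["height"], style["margin"]
    segs = _dendrogram_segments(np.asarray(tree), list(leaf_order))
    max_h = max((s[3] for s in segs), default=1.0) or 1.0
    n_leaves = len(leaf_order)
    fx = lambda x: m + x / max(n_leaves - 1, 1) * (w - 2 * m)  # noqa: E731
    fy = lambda y: (h - m) - y / max_h * (h - 2 * m)  # noqa: E731
    out = _svg_header(w, h)
    color = style["colors"]["line"]
    for x1, y1, x2, y2 in segs:
        out.append(
            f'<line x1="{_fmt(fx(x1))}" y1="{_fmt(fy(y1))}" '
            f'x2="{_fmt(fx(x2))}" y2="{_fmt(fy(y2))}" stroke="{color}"/>'
        )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def render_svg(plot, path, style: dict | None = None) -> None:
    """Render a plot payload to an SVG file.

    Accepted payloads: :class:`VolcanoData`, a heatmap bundle (dict from
    :func:`heatmap_data`), a PCA score DataFrame, or a ``(tree,
    leaf_order)`` dendrogram tuple.  Output is deterministic: identical
    payload and style yield byte-identical files.
    """
    style = _merge_style(style)
    if isinstance(plot, VolcanoData):
        text = _render_volcano(plot, style)
    elif isinstance(plot, dict) and "matrix" in plot:
        text = _render_heatmap(plot, style)
    elif isinstance(plot, pd.DataFrame):
        text = _render_pca(plot, style)
    elif isinstance(plot, tuple) and len(plot) == 2:
        text = _render_dendrogram(plot, style)
    else:
        raise LfqstatsError(f"unsupported plot payload: {type(plot).__name__}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)
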