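"""Visual merge diagnostics: coordinate computations plus thin rendering.

Each diagnostic returns a :class:`PlotData` whose payload is purely
numeric (MDS coordinates, box statistics, linkage matrices, density
curves), so everything testable is separated from the drawing.  In every
rendered figure, color encodes the biological target label and
symbol/grouping encodes the batch.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .core import MergedExpressionSet, XmergeError
from .quantval import parzen_density, silverman_bandwidth

__all__ = [
    "PlotData",
    "mds_embedding",
    "rle_values",
    "genewise_boxplot_stats",
    "sample_dendrogram",
    "genewise_density",
    "render",
]

PLOT_KINDS = ("MDS", "RLE", "GENE_BOX", "DENDROGRAM", "GENE_DENSITY")
RENDER_FORMATS = ("png", "svg", "pdf")
#: default number of randomly kept samples for RLE / dendrogram displays
DEFAULT_MAX_SAMPLES = 40


@dataclass
class PlotData:
    kind: str
    payload: dict = field(default_factory=dict)
    target_labels: pd.Series | None = None   # color role
    batch_labels: pd.Series | None = None    # symbol / grouping role
    title: str = ""


def _resolve_gene(merged: MergedExpressionSet, gene: str) -> str:
    if gene in merged.values.index:
        return gene
    near = difflib.get_close_matches(gene, [str(g) for g in merged.genes], n=5)
    raise XmergeError(f"unknown gene {gene!r}; nearest matches: {near}")


def _subsample(samples, max_samples, seed):
    if max_samples is None or len(samples) <= max_samples:
        return list(samples)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(samples), size=max_samples, replace=False))
    return [samples[i] for i in keep]


def _box_stats(values: np.ndarray) -> dict:
    """Median, quartiles and Tukey whiskers (furthest point within 1.5 IQR)."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    in_lo = v[v >= q1 - 1.5 * iqr]
    in_hi = v[v <= q3 + 1.5 * iqr]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(in_lo.min()) if in_lo.size else float(q1),
        "whisker_high": float(in_hi.max()) if in_hi.size else float(q3),
        "n": int(v.size),
    }


def mds_embedding(merged: MergedExpressionSet, target_key: str,
                  batch_key: str | None = None) -> PlotData:
    """Classical (Torgerson) metric MDS of the Euclidean inter-sample
    distances into 2 dimensions.

    Samples close in expression space stay close in the plot; before
    correction samples typically cluster by batch (symbol), after a good
    correction by biology (color).
    """
    if merged.n_samples < 3:
        raise XmergeError("MDS needs at least 3 samples")
    batch_key = batch_key or merged.batch_key
    target = merged.annotation_column(target_key)
    batch = merged.annotation_column(batch_key)
    D = squareform(pdist(merged.matrix.T))
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(Bmat)
    order = np.argsort(eigval)[::-1][:2]
    lam = np.maximum(eigval[order], 0.0)
    coords = eigvec[:, order] * np.sqrt(lam)[None, :]
    return PlotData(
        kind="MDS",
        payload={"coordinates": pd.DataFrame(coords, index=merged.samples,
                                             columns=["MDS1", "MDS2"]),
                 "eigenvalues": eigval[order]},
        target_labels=target, batch_labels=batch,
    )


def rle_values(merged: MergedExpressionSet, batch_key: str | None = None,
               max_samples: int | None = DEFAULT_MAX_SAMPLES, seed: int = 0) -> PlotData:
    """Relative log expression: per-sample deviations from each gene's
    across-sample median, as per-sample box statistics.

    Boxes centered at 0 indicate comparable samples; a merge that worked
    pulls every batch's RLE medians toward 0.
    """
    batch_key = batch_key or merged.batch_key
    medians = np.median(merged.matrix, axis=1)
    rle = merged.matrix - medians[:, None]
    keep = _subsample(merged.samples, max_samples, seed)
    pos = {s: i for i, s in enumerate(merged.samples)}
    boxes = {s: _box_stats(rle[:, pos[s]]) for s in keep}
    return PlotData(
        kind="RLE",
        payload={"gene_medians": pd.Series(medians, index=merged.genes),
                 "boxes": boxes, "samples": keep},
        batch_labels=merged.annotation_column(batch_key).loc[keep],
    )


def genewise_boxplot_stats(merged: MergedExpressionSet, gene: str,
                           target_key: str, batch_key: str | None = None) -> PlotData:
    """Box statistics of one gene for every (batch x target-level) group."""
    batch_key = batch_key or merged.batch_key
    gene = _resolve_gene(merged, gene)
    target = merged.annotation_column(target_key)
    batch = merged.annotation_column(batch_key)
    vals = merged.values.loc[gene]
    groups = {}
    for b in pd.unique(batch):
        for t in pd.unique(target):
            mask = (batch == b) & (target == t)
            if mask.any():
                groups[(str(b), str(t))] = _box_stats(vals[mask].to_numpy())
    return PlotData(kind="GENE_BOX", payload={"gene": gene, "groups": groups},
                    target_labels=target, batch_labels=batch)


def sample_dendrogram(merged: MergedExpressionSet, batch_key: str | None = None,
                      max_samples: int | None = DEFAULT_MAX_SAMPLES, seed: int = 0) -> PlotData:
    """Complete-linkage hierarchical clustering of (subsampled) samples
    on Euclidean distance; leaves are labeled by batch."""
    if merged.n_samples < 2:
        raise XmergeError("dendrogram needs at least 2 samples")
    batch_key = batch_key or merged.batch_key
    keep = _subsample(merged.samples, max_samples, seed)
    X = merged.values[keep].to_numpy(dtype=float).T
    Z = linkage(X, method="complete", metric="euclidean")
    return PlotData(
        kind="DENDROGRAM",
        payload={"linkage": Z, "samples": keep},
        batch_labels=merged.annotation_column(batch_key).loc[keep],
    )


def genewise_density(merged: MergedExpressionSet, gene: str,
                     batch_key: str | None = None) -> PlotData:
    """Per-batch Parzen density curves of one gene on a shared grid."""
    batch_key = batch_key or merged.batch_key
    gene = _resolve_gene(merged, gene)
    batch = merged.annotation_column(batch_key)
    vals = merged.values.loc[gene]
    parts = {str(b): vals[batch == b].to_numpy(dtype=float) for b in pd.unique(batch)}
    for b, v in parts.items():
        if v.size < 2:
            raise XmergeError(f"gene-wise density: batch {b!r} has < 2 values")
    h = max(silverman_bandwidth(v) for v in parts.values())
    # 6-bandwidth padding keeps the truncated kernel tails (and hence the
    # trapezoid normalization error) below 1e-6
    lo = min(v.min() for v in parts.values()) - 6.0 * h
    hi = max(v.max() for v in parts.values()) + 6.0 * h
    grid = np.linspace(lo, hi, 256)
    curves = {b: parzen_density(v, grid, h, source=f"{b}:{gene}") for b, v in parts.items()}
    return PlotData(kind="GENE_DENSITY",
                    payload={"gene": gene, "grid": grid, "curves": curves,
                             "bandwidth": h},
                    batch_labels=batch)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _palette(labels):
    import matplotlib.pyplot as plt

    uniq = list(dict.fromkeys(labels))
    cmap = plt.get_cmap("tab10")
    return {u: cmap(i % 10) for i, u in enumerate(uniq)}


_MARKERS = ["o", "s", "^", "D", "v", "P", "X", "*"]


def _draw(ax, pd_obj: PlotData) -> None:
    if pd_obj.kind == "MDS":
        coords = pd_obj.payload["coordinates"]
        colors = _palette(pd_obj.target_labels)
        batches = list(pd.unique(pd_obj.batch_labels))
        for i, b in enumerate(batches):
            mask = pd_obj.batch_labels == b
            sub = coords[mask.to_numpy()]
            ax.scatter(sub["MDS1"], sub["MDS2"],
                       c=[colors[t] for t in pd_obj.target_labels[mask.to_numpy()]],
                       marker=_MARKERS[i % len(_MARKERS)], label=str(b), alpha=0.8)
        ax.set_xlabel("MDS1")
        ax.set_ylabel("MDS2")
        ax.legend(fontsize="small")
    elif pd_obj.kind == "RLE":
        boxes = pd_obj.payload["boxes"]
        samples = pd_obj.payload["samples"]
        colors = _palette(pd_obj.batch_labels)
        stats_list = [
            {"med": boxes[s]["median"], "q1": boxes[s]["q1"], "q3": boxes[s]["q3"],
             "whislo": boxes[s]["whisker_low"], "whishi": boxes[s]["whisker_high"],
             "fliers": []}
            for s in samples
        ]
        artists = ax.bxp(stats_list, showfliers=False, patch_artist=True)
        for patch, s in zip(artists["boxes"], samples):
            patch.set_facecolor(colors[pd_obj.batch_labels.loc[s]])
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_xticks([])
        ax.set_ylabel("relative log expression")
    elif pd_obj.kind == "GENE_BOX":
        groups = pd_obj.payload["groups"]
        keys = sorted(groups)
        colors = _palette([t for _, t in keys])
        stats_list = [
            {"med": groups[k]["median"], "q1": groups[k]["q1"], "q3": groups[k]["q3"],
             "whislo": groups[k]["whisker_low"], "whishi": groups[k]["whisker_high"],
             "fliers": []}
            for k in keys
        ]
        artists = ax.bxp(stats_list, showfliers=False, patch_artist=True)
        for patch, (b, t) in zip(artists["boxes"], keys):
            patch.set_facecolor(colors[t])
        ax.set_xticklabels([f"{b}\n{t}" for b, t in keys], fontsize="x-small")
        ax.set_ylabel(pd_obj.payload["gene"])
    elif pd_obj.kind == "DENDROGRAM":
        from scipy.cluster.hierarchy import dendrogram as _dendro

        samples = pd_obj.payload["samples"]
        batches = list(pd.unique(pd_obj.batch_labels))
        labels = [str(batches.index(pd_obj.batch_labels.loc[s])) for s in samples]
        _dendro(pd_obj.payload["linkage"], labels=labels, ax=ax,
                leaf_font_size=6, color_threshold=0.0)
        ax.set_ylabel("height")
    elif pd_obj.kind == "GENE_DENSITY":
        colors = _palette(list(pd_obj.payload["curves"]))
        grid = pd_obj.payload["grid"]
        step = grid[1] - grid[0] if len(grid) > 1 else 1.0
        for b, est in pd_obj.payload["curves"].items():
            ax.plot(grid, est.mass / step, label=str(b), color=colors[b])
        ax.set_xlabel(pd_obj.payload["gene"])
        ax.set_ylabel("density")
        ax.legend(fontsize="small")
    else:
        raise XmergeError(f"cannot render plot kind {pd_obj.kind!r}")
    if pd_obj.title:
        ax.set_title(pd_obj.title)


def render(plotdata, path, format: str | None = None) -> None:
    """Write one PlotData (or a side-by-side list of them) to an image file.

    ``format`` defaults to the path suffix; png, svg and pdf are supported.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if format is None:
        format = str(path).rsplit(".", 1)[-1].lower()
    if format not in RENDER_FORMATS:
        raise XmergeError(f"unsupported format {format!r}; use one of {RENDER_FORMATS}")
    items = plotdata if isinstance(plotdata, (list, tuple)) else [plotdata]
    if not items:
        raise XmergeError("nothing to render")
    fig, axes = plt.subplots(1, len(items), figsize=(6 * len(items), 5))
    if len(items) == 1:
        axes = [axes]
    for ax, item in zip(axes, items):
        _draw(ax, item)
    fig.tight_layout()
    try:
        fig.savefig(path, format=format)
    except OSError as exc:
        raise XmergeError(f"cannot write {path}: {exc}") from exc
    finally:
        plt.close(fig)
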