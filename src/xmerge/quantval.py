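"""Quantitative before/after indices for judging a merge.

Six indices: per-sample skewness drift, per-sample and per-gene
before/after Pearson correlation, overlap of top-ranked
differentially-expressed genes with known controls, average nearest
cross-batch sample distance, and the genes-overlap index GOV.

GOV compares, gene by gene, the value distributions of two studies:
each gene's values are turned into a normalized discrete density on a
shared grid by Parzen-Rosenblatt (Gaussian-kernel) estimation, and

    GOV_i = (1/2) * sum_grid |P_x - P_y|        (total-variation distance)
    GOV   = mean_i GOV_i  over the m common genes.

Both lie in [0, 1]: 0 when the two distributions coincide, 1 when their
supports are disjoint.  A successful batch-effect removal drives GOV
between the merged batches toward 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConsistencyError, ExpressionStudy, MergedExpressionSet, XmergeError

__all__ = [
    "DensityEstimate",
    "ValidationReport",
    "parzen_density",
    "silverman_bandwidth",
    "gov_from_masses",
    "measure_genes_overlap",
    "genes_overlap_between_batches",
    "measure_asymmetry",
    "measure_samples_mean_corr",
    "measure_genes_mean_corr",
    "measure_significant_genes_overlap",
    "measure_samples_overlap",
    "validation_report",
]

#: number of shared evaluation points for per-gene densities
GOV_GRID_SIZE = 256
#: grid padding, in bandwidths, beyond the pooled value range
GOV_GRID_PAD = 3.0


@dataclass
class DensityEstimate:
    """Normalized discrete probability vector of one gene in one study."""

    grid: np.ndarray       # strictly increasing evaluation points
    mass: np.ndarray       # non-negative, sums to 1
    bandwidth: float
    source: str            # "<study>:<gene>"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)


def parzen_density(values, grid, bandwidth: float, source: str = "") -> DensityEstimate:
    """Gaussian-kernel density on ``grid``, normalized to unit total mass."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise XmergeError("parzen_density: empty input")
    if bandwidth <= 0:
        raise XmergeError("parzen_density: bandwidth must be positive")
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - values[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z).sum(axis=1)
    total = dens.sum()
    if total <= 0:
        # all observations far outside the grid; put the mass at the edge
        # nearest the data to keep the unit-mass contract
        dens = np.zeros_like(grid)
        dens[np.argmin(np.abs(grid - values.mean()))] = 1.0
        total = 1.0
    return DensityEstimate(grid=grid, mass=dens / total, bandwidth=float(bandwidth), source=source)


def silverman_bandwidth(values) -> float:
    """Silverman's rule of thumb, with a small positive floor for degenerate data."""
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n < 2:
        return 1e-3
    sd = values.std(ddof=1)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * n ** (-0.2)
    return float(h) if h > 0 else 1e-3


def gov_from_masses(px, py) -> float:
    """Half the L1 distance between two unit-mass vectors on a shared grid."""
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    return float(0.5 * np.abs(px - py).sum())


def _gov_single_gene(x, y) -> float:
    h = max(silverman_bandwidth(x), silverman_bandwidth(y))
    lo = min(x.min(), y.min()) - GOV_GRID_PAD * h
    hi = max(x.max(), y.max()) + GOV_GRID_PAD * h
    if hi <= lo:               # both constant and equal
        return 0.0
    grid = np.linspace(lo, hi, GOV_GRID_SIZE)
    px = parzen_density(x, grid, h).mass
    py = parzen_density(y, grid, h).mass
    return gov_from_masses(px, py)


def measure_genes_overlap(set_a: ExpressionStudy, set_b: ExpressionStudy):
    """Genes-overlap index between two studies.

    Returns ``(GOV, GOV_i)`` with ``GOV_i`` a Series over the common
    genes.  The evaluation grid spans the pooled value range of each
    gene, padded by three bandwidths; the larger of the two studies'
    Silverman bandwidths is used for both, which makes the index
    symmetric in its arguments.
    """
    common = sorted(set(set_a.genes) & set(set_b.genes))
    if not common:
        raise ConsistencyError(
            f"no common genes between {set_a.study_id!r} and {set_b.study_id!r}"
        )
    A = set_a.values.loc[common].to_numpy(dtype=float)
    B = set_b.values.loc[common].to_numpy(dtype=float)
    gov_i = np.array([_gov_single_gene(A[i], B[i]) for i in range(len(common))])
    return float(gov_i.mean()), pd.Series(gov_i, index=common, name="GOV_i")


def _split_batches(merged: MergedExpressionSet) -> list[ExpressionStudy]:
    out = []
    for batch, cols in merged.batch_sample_index().items():
        sub = merged.values.iloc[:, cols]
        out.append(ExpressionStudy(str(batch), sub, merged.annotations.loc[sub.columns]))
    return out
# kept module-private: batch splitting is only meaningful for validation


def genes_overlap_between_batches(merged: MergedExpressionSet):
    """GOV averaged over all batch pairs of a merged set."""
    parts = _split_batches(merged)
    if len(parts) < 2:
        raise XmergeError("genes-overlap needs >= 2 batches in the merged set")
    govs, per_gene = [], []
    for i in range(len(parts)):
        for j in range(i + 1, len(parts)):
            g, gi = measure_genes_overlap(parts[i], parts[j])
            govs.append(g)
            per_gene.append(gi)
    gov_i = pd.concat(per_gene, axis=1).mean(axis=1)
    return float(np.mean(govs)), gov_i


# ---------------------------------------------------------------------------
# moment / correlation indices
# ---------------------------------------------------------------------------


def _matched(before: ExpressionStudy, after: ExpressionStudy):
    if list(before.samples) != list(after.samples):
        raise ConsistencyError("before/after sets do not contain the same samples")
    if list(before.genes) != list(after.genes):
        raise ConsistencyError("before/after sets do not contain the same genes")
    return before.matrix, after.matrix


def measure_asymmetry(before: ExpressionStudy, after: ExpressionStudy) -> dict:
    """Per-sample skewness (Fisher-Pearson g1) before and after adjustment.

    A good merge should not alter the samples' skewness.  Samples with
    zero variance across genes (skewness undefined) are flagged and
    excluded from the summary.
    """
    Xb, Xa = _matched(before, after)
    with warnings.catch_warnings():
        # constant samples trigger a precision warning; they are flagged below
        warnings.simplefilter("ignore", RuntimeWarning)
        g1_b = stats.skew(Xb, axis=0, bias=True)
        g1_a = stats.skew(Xa, axis=0, bias=True)
    ok = np.isfinite(g1_b) & np.isfinite(g1_a) & (Xb.std(axis=0) > 0) & (Xa.std(axis=0) > 0)
    flagged = [s for s, good in zip(before.samples, ok) if not good]
    diff = np.abs(g1_b[ok] - g1_a[ok])
    return {
        "before": pd.Series(g1_b, index=before.samples),
        "after": pd.Series(g1_a, index=before.samples),
        "mean_abs_diff": float(diff.mean()) if diff.size else float("nan"),
        "flagged": flagged,
    }


def _rowwise_pearson(A: np.ndarray, B: np.ndarray):
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((A * A).sum(axis=1))
    sb = np.sqrt((B * B).sum(axis=1))
    ok = (sa > 0) & (sb > 0)
    r = np.full(A.shape[0], np.nan)
    r[ok] = (A[ok] * B[ok]).sum(axis=1) / (sa[ok] * sb[ok])
    return r, ok


def measure_samples_mean_corr(before: ExpressionStudy, after: ExpressionStudy) -> dict:
    """Pearson correlation of each sample's gene profile before vs after."""
    Xb, Xa = _matched(before, after)
    r, ok = _rowwise_pearson(Xb.T, Xa.T)
    flagged = [s for s, good in zip(before.samples, ok) if not good]
    return {
        "per_sample": pd.Series(r, index=before.samples),
        "mean": float(np.nanmean(r[ok])) if ok.any() else float("nan"),
        "flagged": flagged,
    }


def measure_genes_mean_corr(before: ExpressionStudy, after: ExpressionStudy) -> dict:
    """Pearson correlation of each gene's value vector before vs after."""
    Xb, Xa = _matched(before, after)
    r, ok = _rowwise_pearson(Xb, Xa)
    flagged = [g for g, good in zip(before.genes, ok) if not good]
    return {
        "per_gene": pd.Series(r, index=before.genes),
        "mean": float(np.nanmean(r[ok])) if ok.any() else float("nan"),
        "flagged": flagged,
    }


# ---------------------------------------------------------------------------
# differential-expression overlap
# ---------------------------------------------------------------------------


def _welch_ranking(study: ExpressionStudy, target_key: str) -> list[str]:
    """Genes ranked by |Welch t| (descending), ties broken by gene ID."""
    labels = study.annotation_column(target_key).to_numpy()
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise XmergeError(
            f"target annotation {target_key!r} must have exactly 2 levels, "
            f"found {levels}"
        )
    mask = labels == levels[0]
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise XmergeError(f"target level with < 2 samples in {study.study_id!r}")
    X = study.matrix
    t = stats.ttest_ind(X[:, mask], X[:, ~mask], axis=1, equal_var=False).statistic
    t = np.nan_to_num(np.abs(t), nan=0.0)
    order = sorted(zip(-t, study.genes))
    return [g for _, g in order]


def measure_significant_genes_overlap(merged_before: MergedExpressionSet,
                                      merged_after: MergedExpressionSet,
                                      originals: list[ExpressionStudy],
                                      target_key: str,
                                      control_genes: list[str],
                                      top_n: int) -> dict:
    """Known control genes recovered among the top_n ranked genes.

    Rankings come from the two-group |Welch t| statistic on ``target_key``,
    computed separately in each original study and in the merged sets.
    """
    common = set(merged_after.genes)
    controls = [g for g in control_genes if g in common]
    if len(controls) != len(set(control_genes)):
        missing = sorted(set(control_genes) - common)
        raise ConsistencyError(f"control genes not in common gene set: {missing[:5]}")
    if top_n > len(merged_after.genes):
        raise XmergeError("top_n exceeds the number of common genes")
    result = {}
    for name, study in (
        [("before", merged_before), ("after", merged_after)]
        + [(s.study_id, s) for s in originals]
    ):
        ranking = _welch_ranking(study, target_key)
        top = set(ranking[:top_n])
        result[name] = int(len(top & set(controls)))
    result["n_controls"] = len(controls)
    result["top_n"] = int(top_n)
    return result


# ---------------------------------------------------------------------------
# sample mixing
# ---------------------------------------------------------------------------


def measure_samples_overlap(merged: MergedExpressionSet):
    """Average Euclidean distance of each sample to its nearest sample
    from a *different* batch; lower means better mixing.

    Returns ``(average, per_sample)``.
    """
    groups = merged.batch_sample_index()
    if len(groups) < 2:
        raise XmergeError("samples-overlap needs >= 2 batches")
    X = merged.matrix.T           # samples x genes
    batches = merged.batches.to_numpy()
    from scipy.spatial.distance import cdist

    dist = np.full(X.shape[0], np.inf)
    for b, cols in groups.items():
        other = np.flatnonzero(batches != b)
        dist[cols] = cdist(X[cols], X[other]).min(axis=1)
    return float(dist.mean()), pd.Series(dist, index=merged.samples)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Named collection of before/after index values for one merge comparison."""

    indices: dict = field(default_factory=dict)
    findings: list = field(default_factory=list)
    m: int = 0                       # number of common genes
    gov_before: pd.Series | None = None
    gov_after: pd.Series | None = None

    def to_dict(self) -> dict:
        return {"m": self.m, "indices": self.indices, "findings": self.findings}

    def to_json(self, path) -> None:
        import json

        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        rows = []
        for index, res in self.indices.items():
            if isinstance(res, dict):
                for key, val in res.items():
                    if np.isscalar(val):
                        rows.append((index, key, val))
            elif np.isscalar(res):
                rows.append((index, "", res))
        pd.DataFrame(rows, columns=["index", "quantity", "value"]).to_csv(
            path, sep="\t", index=False, lineterminator="\n"
        )


def validation_report(before: MergedExpressionSet, after: MergedExpressionSet,
                      config: dict | None = None) -> ValidationReport:
    """Run all applicable indices on a before/after pair of merged sets.

    ``config`` may carry ``target_key``, ``control_genes``, ``top_n`` and
    ``originals`` (for the significant-genes overlap) — without them that
    index is marked skipped.  Individual index failures are recorded as
    findings rather than raised.
    """
    config = config or {}
    report = ValidationReport(m=before.n_genes)

    def _try(name, fn):
        try:
            report.indices[name] = fn()
        except Exception as exc:  # recorded, not fatal
            report.findings.append(f"{name}: {exc}")

    def _asym():
        res = measure_asymmetry(before, after)
        return {"mean_abs_diff": res["mean_abs_diff"], "flagged": res["flagged"]}

    def _scorr():
        res = measure_samples_mean_corr(before, after)
        return {"mean": res["mean"], "flagged": res["flagged"]}

    def _gcorr():
        res = measure_genes_mean_corr(before, after)
        return {"mean": res["mean"], "flagged": res["flagged"]}

    def _soverlap():
        b, _ = measure_samples_overlap(before)
        a, _ = measure_samples_overlap(after)
        return {"before": b, "after": a}

    def _gov():
        gb, gib = genes_overlap_between_batches(before)
        ga, gia = genes_overlap_between_batches(after)
        report.gov_before, report.gov_after = gib, gia
        return {"before": gb, "after": ga}

    _try("asymmetry", _asym)
    _try("samples_mean_corr", _scorr)
    _try("genes_mean_corr", _gcorr)
    _try("samples_overlap", _soverlap)
    _try("genes_overlap", _gov)

    target_key = config.get("target_key")
    if target_key and config.get("control_genes") is None:
        report.indices["significant_genes_overlap"] = {"skipped": "no control genes"}
    elif target_key and config.get("control_genes") is not None:
        _try("significant_genes_overlap", lambda: measure_significant_genes_overlap(
            before, after, config.get("originals", []),
            target_key, list(config["control_genes"]), int(config.get("top_n", 100)),
        ))
    else:
        report.indices["significant_genes_overlap"] = {"skipped": "no target annotation"}
    return report
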