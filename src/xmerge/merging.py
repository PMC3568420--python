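"""Batch-effect-removal methods for merging expression studies.

Six methods are provided behind one dispatcher:

NONE      column concatenation, no transformation;
BMC       per-gene batch mean-centering;
GENENORM  per-gene per-batch z-score standardization;
COMBAT    empirical-Bayes location/scale adjustment (per-gene batch
          effects shrunk toward batch-level parametric priors);
DWD       removal of each batch's mean displacement along the
          distance-weighted-discrimination separating direction;
XPN       cross-platform normalization: per-(gene-cluster x
          sample-cluster) block-linear model fitted per platform, with
          platform-specific block parameters replaced by their
          sample-size-weighted common estimates, averaged over random
          clusterings.

XPN and DWD are defined for exactly two studies; more studies are merged
two-by-two by a left fold (``combine_pairwise``), the intermediate merge
being treated as a single batch at the next step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .core import (
    ConsistencyError,
    ExpressionStudy,
    MergedExpressionSet,
    XmergeError,
    intersect_genes,
)

logger = logging.getLogger("xmerge")

METHODS = ("NONE", "BMC", "GENENORM", "COMBAT", "DWD", "XPN")
#: methods defined for exactly two studies, folded pairwise otherwise
PAIRWISE_METHODS = ("DWD", "XPN")

DEFAULT_BATCH_KEY = "Study"

__all__ = [
    "METHODS",
    "PAIRWISE_METHODS",
    "MergeRequest",
    "BatchAdjustmentModel",
    "merge",
    "merge_none",
    "merge_bmc",
    "merge_genenorm",
    "merge_combat",
    "merge_dwd",
    "merge_xpn",
    "combine_pairwise",
    "derive_seed",
]


def derive_seed(seed: int, index: int) -> int:
    """Expand one user seed into a stream of per-step seeds (< 2**31)."""
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# assembly helpers
# ---------------------------------------------------------------------------


def _check_aligned(studies) -> None:
    genes = studies[0].genes
    for s in studies[1:]:
        if s.genes != genes:
            raise ConsistencyError(
                "studies are not gene-aligned; run intersect_genes first"
            )


def _batch_labels(study: ExpressionStudy) -> list[str]:
    """Per-sample batch label: original study of origin, survives pairwise folding."""
    if isinstance(study, MergedExpressionSet):
        return [str(x) for x in study.batches]
    return [study.study_id] * study.n_samples


def _source_ids(study: ExpressionStudy) -> list[str]:
    if isinstance(study, MergedExpressionSet):
        return list(study.provenance.get("studies", [study.study_id]))
    return [study.study_id]


def _assemble(studies, adjusted, method: str, batch_key: str, extra: dict | None = None) -> MergedExpressionSet:
    """Concatenate adjusted per-study matrices into a MergedExpressionSet."""
    genes = studies[0].genes
    frames = [
        pd.DataFrame(np.asarray(a, dtype=float), index=genes, columns=s.samples)
        for s, a in zip(studies, adjusted)
    ]
    values = pd.concat(frames, axis=1)
    if values.columns.duplicated().any():
        dup = values.columns[values.columns.duplicated()].tolist()
        raise ConsistencyError(f"duplicate sample IDs across studies: {dup[:5]}")
    ann = pd.concat([s.annotations for s in studies], axis=0).fillna("")
    labels: list[str] = []
    for s in studies:
        labels.extend(_batch_labels(s))
    ann = ann.loc[list(values.columns)]
    ann[batch_key] = pd.Series(labels, index=values.columns)
    sources: list[str] = []
    for s in studies:
        sources.extend(_source_ids(s))
    provenance = {"method": method, "studies": sources}
    if extra:
        provenance.update(extra)
    return MergedExpressionSet(
        study_id="+".join(sources),
        values=values,
        annotations=ann,
        batch_key=batch_key,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------


@dataclass
class MergeRequest:
    """A merge job: the studies, the method name and its options."""

    studies: list
    method: str
    options: dict = field(default_factory=dict)
    batch_key: str = DEFAULT_BATCH_KEY


def merge(studies, method: str | None = None, *, batch_key: str = DEFAULT_BATCH_KEY, **options) -> MergedExpressionSet:
    """Merge two or more studies with the named batch-effect-removal method.

    Accepts either a :class:`MergeRequest` or ``(studies, method, **options)``.
    Studies are first restricted to their sorted common gene set; pairwise-only
    methods (XPN, DWD) are folded two-by-two when given more than two studies.
    """
    if isinstance(studies, MergeRequest):
        req = studies
        studies, method, batch_key = req.studies, req.method, req.batch_key
        options = {**req.options, **options}
    if method is None:
        raise XmergeError("no merging method given")
    name = str(method).upper()
    if name not in METHODS:
        raise XmergeError(f"unknown merging method {method!r}; valid methods: {', '.join(METHODS)}")
    if len(studies) < 2:
        raise XmergeError("merging requires at least two studies")
    aligned = intersect_genes(list(studies))

    if name == "NONE":
        return merge_none(aligned, batch_key=batch_key)
    if name == "BMC":
        return merge_bmc(aligned, batch_key=batch_key)
    if name == "GENENORM":
        return merge_genenorm(aligned, batch_key=batch_key)
    if name == "COMBAT":
        merged, model = merge_combat(
            aligned, covariate_key=options.get("covariate_key"), batch_key=batch_key
        )
        merged.provenance["combat_converged"] = bool(model.converged)
        return merged
    # pairwise methods
    opts = dict(options)
    if len(aligned) == 2:
        if name == "DWD":
            return merge_dwd(aligned, penalty=opts.get("penalty"), batch_key=batch_key)
        return merge_xpn(
            aligned,
            n_gene_clusters=opts.get("n_gene_clusters"),
            n_sample_clusters=opts.get("n_sample_clusters"),
            n_repetitions=opts.get("n_repetitions", 30),
            seed=opts.get("seed", 0),
            batch_key=batch_key,
        )
    return combine_pairwise(aligned, name, opts, batch_key=batch_key)


# ---------------------------------------------------------------------------
# NONE / BMC / GENENORM
# ---------------------------------------------------------------------------


def merge_none(studies, batch_key: str = DEFAULT_BATCH_KEY) -> MergedExpressionSet:
    """Concatenate without transformation; every value equals its source value."""
    _check_aligned(studies)
    return _assemble(studies, [s.matrix for s in studies], "NONE", batch_key)


def merge_bmc(studies, batch_key: str = DEFAULT_BATCH_KEY) -> MergedExpressionSet:
    """Batch mean-centering: subtract each gene's per-batch mean."""
    _check_aligned(studies)
    adjusted = []
    for s in studies:
        x = s.matrix
        adjusted.append(x - x.mean(axis=1, keepdims=True))
    return _assemble(studies, adjusted, "BMC", batch_key)


def merge_genenorm(studies, batch_key: str = DEFAULT_BATCH_KEY) -> MergedExpressionSet:
    """Per-gene per-batch z-score standardization (sample sd, n-1).

    Zero-variance genes are centered only; they are logged and recorded in
    ``provenance["zero_variance_genes"]``.
    """
    _check_aligned(studies)
    adjusted = []
    flagged: dict[str, list[str]] = {}
    for s in studies:
        if s.n_samples < 2:
            raise XmergeError(
                f"GENENORM: batch {s.study_id!r} has {s.n_samples} sample(s); "
                "the standard deviation is undefined"
            )
        x = s.matrix
        centered = x - x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1)
        zero = sd == 0.0
        if zero.any():
            names = [g for g, z in zip(s.genes, zero) if z]
            flagged[s.study_id] = names
            logger.warning(
                "GENENORM: %d zero-variance gene(s) in batch %s centered only: %s%s",
                len(names), s.study_id, names[:5], "..." if len(names) > 5 else "",
            )
        sd_safe = np.where(zero, 1.0, sd)
        adjusted.append(centered / sd_safe[:, None])
    return _assemble(studies, adjusted, "GENENORM", batch_key,
                     extra={"zero_variance_genes": flagged})


# ---------------------------------------------------------------------------
# COMBAT — empirical-Bayes location/scale adjustment
# ---------------------------------------------------------------------------


@dataclass
class BatchAdjustmentModel:
    """Fitted per-gene, per-batch location/scale parameters of the EB model.

    ``gamma_hat``/``delta2_hat`` are the raw per-batch estimates on the
    standardized scale; ``gamma_star``/``delta2_star`` the empirical-Bayes
    shrunken ones.  Arrays indexed (batch, gene); ``batch_ids`` gives the
    batch order.
    """

    genes: list[str]
    batch_ids: list[str]
    alpha: np.ndarray            # per-gene grand location
    sigma2: np.ndarray           # per-gene pooled variance
    gamma_hat: np.ndarray        # (B, m) raw additive batch effects
    gamma_star: np.ndarray       # (B, m) shrunken additive effects
    delta2_hat: np.ndarray       # (B, m) raw multiplicative effects
    delta2_star: np.ndarray      # (B, m) shrunken multiplicative effects
    gamma_bar: np.ndarray        # (B,) prior mean of gamma per batch
    tau2_bar: np.ndarray         # (B,) prior variance of gamma per batch
    a_prior: np.ndarray          # (B,) inverse-gamma shape for delta^2
    b_prior: np.ndarray          # (B,) inverse-gamma scale for delta^2
    n_iterations: np.ndarray     # (B,) EB fixed-point iterations used
    converged: bool
    tol: float

    def shrinkage_holds(self) -> bool:
        """gamma* lies between gamma_hat and the batch prior mean, everywhere."""
        lo = np.minimum(self.gamma_hat, self.gamma_bar[:, None])
        hi = np.maximum(self.gamma_hat, self.gamma_bar[:, None])
        eps = 1e-9
        return bool(((self.gamma_star >= lo - eps) & (self.gamma_star <= hi + eps)).all())


def _combat_design(studies, covariate_key):
    """Batch one-hot design plus optional drop-first covariate dummies."""
    n_per = [s.n_samples for s in studies]
    N = sum(n_per)
    B = len(studies)
    design = np.zeros((N, B))
    start = 0
    for i, n in enumerate(n_per):
        design[start:start + n, i] = 1.0
        start += n
    if covariate_key is not None:
        labels = []
        for s in studies:
            labels.extend(str(v) for v in s.annotation_column(covariate_key))
        levels = sorted(set(labels))
        if len(levels) < 2:
            logger.warning("COMBAT: covariate %r has a single level; ignored", covariate_key)
        else:
            for lev in levels[1:]:
                design = np.column_stack([design, [1.0 if l == lev else 0.0 for l in labels]])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ConsistencyError(
            "COMBAT: design is confounded (a batch is fully determined by the covariate)"
        )
    return design, B


def merge_combat(studies, covariate_key: str | None = None,
                 batch_key: str = DEFAULT_BATCH_KEY,
                 tol: float = 1e-4, max_iter: int = 100):
    """Empirical-Bayes location/scale batch adjustment.

    The per-gene model is y = alpha_g + X beta_g + gamma_ig + delta_ig eps.
    Genes are standardized with the pooled variance; per-batch location
    (gamma) and scale (delta^2) estimates are shrunk toward parametric
    priors (normal for gamma across genes, inverse-gamma for delta^2)
    fitted per batch by method of moments, via the EB fixed-point
    iteration; the data are then back-transformed with the shrunken
    parameters.

    Returns ``(merged, model)``.
    """
    _check_aligned(studies)
    if len(studies) < 2:
        raise XmergeError("COMBAT requires at least two batches")
    for s in studies:
        if s.n_samples < 2:
            raise XmergeError(f"COMBAT: batch {s.study_id!r} needs >= 2 samples")
    genes = studies[0].genes
    m = len(genes)
    Y = np.hstack([s.matrix for s in studies])           # m x N
    n_per = [s.n_samples for s in studies]
    N = Y.shape[1]
    design, B = _combat_design(studies, covariate_key)

    # standardization: per-gene OLS fit of batch + covariate means
    beta_hat, *_ = np.linalg.lstsq(design, Y.T, rcond=None)  # p x m
    weights = np.asarray(n_per, dtype=float) / N
    alpha = weights @ beta_hat[:B]                           # per-gene grand location
    resid = Y - (design @ beta_hat).T
    sigma2 = (resid ** 2).mean(axis=1)                       # pooled, denominator N
    sigma2 = np.maximum(sigma2, 1e-12)
    stand_mean = alpha[:, None] + (design[:, B:] @ beta_hat[B:]).T if design.shape[1] > B \
        else np.repeat(alpha[:, None], N, axis=1)
    Z = (Y - stand_mean) / np.sqrt(sigma2)[:, None]

    # per-batch raw estimates and parametric priors
    idx, start = [], 0
    for n in n_per:
        idx.append(np.arange(start, start + n))
        start += n
    gamma_hat = np.vstack([Z[:, ix].mean(axis=1) for ix in idx])
    delta2_hat = np.vstack([Z[:, ix].var(axis=1, ddof=1) for ix in idx])
    delta2_hat = np.where(delta2_hat <= 0, delta2_hat + 1e-8, delta2_hat)

    gamma_bar = gamma_hat.mean(axis=1)
    tau2_bar = gamma_hat.var(axis=1, ddof=1)
    dmean = delta2_hat.mean(axis=1)
    ds2 = np.maximum(delta2_hat.var(axis=1, ddof=1), 1e-12)
    a_prior = (2.0 * ds2 + dmean ** 2) / ds2
    b_prior = (dmean * ds2 + dmean ** 3) / ds2

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    n_iterations = np.zeros(B, dtype=int)
    converged = True
    for i in range(B):
        n_i = n_per[i]
        g_old = gamma_hat[i].copy()
        d_old = delta2_hat[i].copy()
        ok = False
        for it in range(1, max_iter + 1):
            g_new = (n_i * tau2_bar[i] * gamma_hat[i] + d_old * gamma_bar[i]) / (
                n_i * tau2_bar[i] + d_old
            )
            sum2 = ((Z[:, idx[i]] - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_prior[i]) / (n_i / 2.0 + a_prior[i] - 1.0)
            d_new = np.maximum(d_new, 1e-12)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                ok = True
                break
        n_iterations[i] = it
        if not ok:
            converged = False
            logger.warning("COMBAT: EB fixed point for batch %s did not converge in %d iterations",
                           studies[i].study_id, max_iter)
        gamma_star[i] = g_old
        delta2_star[i] = d_old

    adjusted = []
    for i, s in enumerate(studies):
        Zi = (Z[:, idx[i]] - gamma_star[i][:, None]) / np.sqrt(delta2_star[i])[:, None]
        adjusted.append(Zi * np.sqrt(sigma2)[:, None] + stand_mean[:, idx[i]])
    model = BatchAdjustmentModel(
        genes=genes, batch_ids=[s.study_id for s in studies],
        alpha=alpha, sigma2=sigma2,
        gamma_hat=gamma_hat, gamma_star=gamma_star,
        delta2_hat=delta2_hat, delta2_star=delta2_star,
        gamma_bar=gamma_bar, tau2_bar=tau2_bar,
        a_prior=a_prior, b_prior=b_prior,
        n_iterations=n_iterations, converged=converged, tol=tol,
    )
    merged = _assemble(studies, adjusted, "COMBAT", batch_key)
    return merged, model


# ---------------------------------------------------------------------------
# DWD — distance-weighted discrimination
# ---------------------------------------------------------------------------


def _dwd_direction(X1: np.ndarray, X2: np.ndarray, penalty: float | None = None):
    """Unit separating direction w between two batches by the DWD program.

    Minimizes sum(1/margin_i) + C*sum(slack_i) over ||w|| <= 1; after
    eliminating the slacks the objective is the classic convex DWD loss
    V(r) = 1/r for r >= 1/sqrt(C), else 2*sqrt(C) - C*r.  The direction
    lies in the span of the samples, so the problem is solved in that
    (at most n-dimensional) subspace.
    """
    n1, n2 = X1.shape[1], X2.shape[1]
    X = np.hstack([X1, X2])
    y = np.concatenate([np.ones(n1), -np.ones(n2)])
    xbar = X.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(X - xbar, full_matrices=False)
    r = int((s > max(s[0], 1e-300) * 1e-12).sum()) if s.size else 0
    if r == 0:
        # all samples identical: any direction works, displacement is zero
        w = np.zeros(X.shape[0])
        w[0] = 1.0
        return w, {"status": "degenerate", "penalty": penalty}
    U = U[:, :r]
    T = U.T @ X                                   # r x n coordinates

    if penalty is None:
        med = np.median(cdist(X1.T, X2.T))
        penalty = 100.0 / max(med, 1e-12) ** 2
    C = float(penalty)
    thr = 1.0 / np.sqrt(C)

    def _loss_margin(f):
        small = f < thr
        val = np.where(small, 2.0 * np.sqrt(C) - C * f, 0.0)
        dV = np.full_like(f, -C)
        big = ~small
        with np.errstate(divide="ignore", over="ignore"):
            val[big] = 1.0 / f[big]
            dV[big] = -1.0 / f[big] ** 2
        return val.sum(), dV

    # the unit direction is parametrized as a = q/||q||, which turns the
    # norm constraint into a smooth unconstrained problem for BFGS
    def objective(p):
        q, b = p[:r], p[r]
        nq = np.linalg.norm(q)
        a = q / nq
        f = y * (T.T @ a + b)
        val, dV = _loss_margin(f)
        gf = dV * y
        ga = T @ gf
        gq = (ga - a * (a @ ga)) / nq
        return val, np.concatenate([gq, [gf.sum()]])

    mu_diff = U.T @ (X1.mean(axis=1) - X2.mean(axis=1))
    nd = np.linalg.norm(mu_diff)
    if nd < 1e-12:
        # batch means coincide in the sample span: no informative direction
        # and zero displacement to remove, so any unit vector will do
        return U[:, 0] if r else np.eye(X.shape[0])[0], {"status": "degenerate", "penalty": C}
    a0 = mu_diff / nd
    b0 = -0.5 * float(a0 @ (U.T @ (X1.mean(axis=1) + X2.mean(axis=1))))
    p0 = np.concatenate([a0, [b0]])
    res = minimize(objective, p0, jac=True, method="BFGS",
                   options={"maxiter": 5000, "gtol": 1e-12})
    if not np.isfinite(res.fun):
        raise XmergeError(f"DWD solver failure: status {res.status} ({res.message})")
    q = res.x[:r]
    w = U @ (q / np.linalg.norm(q))
    return w, {"status": "ok" if res.success else f"solver:{res.status}",
               "penalty": C, "grad_norm": float(np.linalg.norm(res.jac))}


def merge_dwd(studies, penalty: float | None = None,
              batch_key: str = DEFAULT_BATCH_KEY) -> MergedExpressionSet:
    """DWD batch adjustment for exactly two studies.

    Finds the DWD separating direction w between the two batches and
    removes, from every sample, its batch's mean displacement along w
    relative to the grand mean.  The overall location of the data is
    preserved; after adjustment each batch's mean deviation from the
    grand mean has zero projection on w.
    """
    _check_aligned(studies)
    if len(studies) != 2:
        raise XmergeError(
            "DWD merges exactly two studies; use combine_pairwise (or merge) "
            "for more"
        )
    for s in studies:
        if s.n_samples < 2:
            raise XmergeError(f"DWD: batch {s.study_id!r} needs >= 2 samples")
    X1, X2 = studies[0].matrix, studies[1].matrix
    w, info = _dwd_direction(X1, X2, penalty=penalty)
    n1, n2 = X1.shape[1], X2.shape[1]
    grand = (X1.sum(axis=1) + X2.sum(axis=1)) / (n1 + n2)
    adjusted = []
    for X in (X1, X2):
        shift = float((X.mean(axis=1) - grand) @ w)
        adjusted.append(X - shift * w[:, None])
    return _assemble(studies, adjusted, "DWD", batch_key, extra={"dwd": info})


# ---------------------------------------------------------------------------
# XPN — cross-platform normalization
# ---------------------------------------------------------------------------


def _xpn_block_fit(X, gene_cl, sample_cl, K, L, n_iter=50, tol=1e-9):
    """Fit x_gj = A[k(g), l(j)] * b_g + c_g + sigma_g * eps within one platform.

    Alternating least squares; blocks with no samples on this platform get
    weight 0 and are excluded from the common estimate later.
    """
    m, n = X.shape
    G = np.zeros((m, K))
    G[np.arange(m), gene_cl] = 1.0
    S = np.zeros((n, L))
    S[np.arange(n), sample_cl] = 1.0
    n_l = S.sum(axis=0)                       # samples per sample-cluster
    b = np.ones(m)
    c = X.mean(axis=1)
    sigma2 = np.ones(m)
    A = np.zeros((K, L))
    fitted_old = None
    for _ in range(n_iter):
        wgt = b / sigma2
        num = (G.T * wgt) @ (X - c[:, None]) @ S
        den = np.outer(G.T @ (b ** 2 / sigma2), n_l)
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        P = A[gene_cl][:, sample_cl]          # m x n block predictor
        p_mean = P.mean(axis=1)
        x_mean = X.mean(axis=1)
        p_var = (P ** 2).mean(axis=1) - p_mean ** 2
        cov = (P * X).mean(axis=1) - p_mean * x_mean
        nz = p_var > 1e-12
        b = np.where(nz, cov / np.where(nz, p_var, 1.0), b)
        c = x_mean - b * p_mean
        fitted = P * b[:, None] + c[:, None]
        sigma2 = np.maximum(((X - fitted) ** 2).mean(axis=1), 1e-8)
        if fitted_old is not None and np.max(np.abs(fitted - fitted_old)) < tol:
            break
        fitted_old = fitted
    return A, b, c, sigma2, fitted, n_l


def _xpn_once(X1, X2, K, L, rng_ints):
    """One XPN repetition: cluster, fit per platform, commonize, reconstruct."""
    m, n1 = X1.shape
    n2 = X2.shape[1]

    def _rowz(X):
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        return (X - mu) / np.where(sd > 0, sd, 1.0)

    Mstd = np.hstack([_rowz(X1), _rowz(X2)])
    gene_cl = KMeans(n_clusters=K, n_init=10, random_state=rng_ints[0]).fit_predict(Mstd)
    sample_cl = KMeans(n_clusters=L, n_init=10, random_state=rng_ints[1]).fit_predict(Mstd.T)
    s1, s2 = sample_cl[:n1], sample_cl[n1:]

    A1, b1, c1, v1, fit1, nl1 = _xpn_block_fit(X1, gene_cl, s1, K, L)
    A2, b2, c2, v2, fit2, nl2 = _xpn_block_fit(X2, gene_cl, s2, K, L)

    # sample-size-weighted common estimates; block means weighted by the
    # number of samples each platform contributes to the sample-cluster
    W1 = np.broadcast_to(nl1, (K, L))
    W2 = np.broadcast_to(nl2, (K, L))
    tot = np.maximum(W1 + W2, 1e-300)
    A_star = (W1 * A1 + W2 * A2) / tot
    b_star = (n1 * b1 + n2 * b2) / (n1 + n2)
    c_star = (n1 * c1 + n2 * c2) / (n1 + n2)
    sig_star = np.sqrt((n1 * v1 + n2 * v2) / (n1 + n2))

    out = []
    for X, fit, v, scl in ((X1, fit1, v1, s1), (X2, fit2, v2, s2)):
        P = A_star[gene_cl][:, scl]
        resid = (X - fit) / np.sqrt(v)[:, None]
        out.append(P * b_star[:, None] + c_star[:, None] + sig_star[:, None] * resid)
    return out


def merge_xpn(studies, n_gene_clusters: int | None = None,
              n_sample_clusters: int | None = None,
              n_repetitions: int = 30, seed: int = 0,
              batch_key: str = DEFAULT_BATCH_KEY) -> MergedExpressionSet:
    """Cross-platform normalization for exactly two studies.

    Defaults: 25 gene clusters, 5 sample clusters, 30 repetitions;
    defaults shrink automatically on small inputs
    (K <- min(25, n_genes // 2), L <- min(5, smallest batch)).
    Explicitly requested cluster counts that exceed the data are errors.
    Deterministic given ``seed``.
    """
    _check_aligned(studies)
    if len(studies) != 2:
        raise XmergeError("XPN merges exactly two studies; use combine_pairwise for more")
    m = studies[0].n_genes
    min_batch = min(s.n_samples for s in studies)
    if n_gene_clusters is None:
        K = max(1, min(25, m // 2))
    else:
        K = int(n_gene_clusters)
        if K > m or K < 1:
            raise XmergeError(f"XPN: n_gene_clusters={K} invalid for {m} genes")
    if n_sample_clusters is None:
        L = max(1, min(5, min_batch))
    else:
        L = int(n_sample_clusters)
        if L > min_batch or L < 1:
            raise XmergeError(
                f"XPN: n_sample_clusters={L} invalid for smallest batch of {min_batch}"
            )
    X1, X2 = studies[0].matrix, studies[1].matrix
    acc1 = np.zeros_like(X1)
    acc2 = np.zeros_like(X2)
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(int(n_repetitions))
    for child in children:
        ints = [int(v % (2**31)) for v in child.generate_state(2)]
        o1, o2 = _xpn_once(X1, X2, K, L, ints)
        acc1 += o1
        acc2 += o2
    acc1 /= n_repetitions
    acc2 /= n_repetitions
    return _assemble(
        studies, [acc1, acc2], "XPN", batch_key,
        extra={"xpn": {"K": K, "L": L, "repetitions": int(n_repetitions), "seed": int(seed)}},
    )


# ---------------------------------------------------------------------------
# recursive pairwise combination
# ---------------------------------------------------------------------------


def combine_pairwise(studies, pair_method: str, options: dict | None = None,
                     batch_key: str = DEFAULT_BATCH_KEY) -> MergedExpressionSet:
    """Left fold of a pairwise-only method over >= 2 studies.

    The first two studies are merged, the result is treated as a single
    batch (its samples keep their original study labels in the batch
    annotation) and merged with the next study, and so on.  The user seed
    is used as-is for the first pairwise step and expanded with
    :func:`derive_seed` for the later steps, so the two-study case is
    identical to a direct call.
    """
    name = str(pair_method).upper()
    if name not in PAIRWISE_METHODS:
        raise XmergeError(f"combine_pairwise supports {PAIRWISE_METHODS}, not {pair_method!r}")
    if len(studies) < 2:
        raise XmergeError("combine_pairwise requires at least two studies")
    options = dict(options or {})
    aligned = intersect_genes(list(studies))
    base_seed = int(options.get("seed", 0))
    current = aligned[0]
    for step, nxt in enumerate(aligned[1:]):
        step_seed = base_seed if step == 0 else derive_seed(base_seed, step)
        try:
            if name == "DWD":
                current = merge_dwd([current, nxt], penalty=options.get("penalty"),
                                    batch_key=batch_key)
            else:
                current = merge_xpn(
                    [current, nxt],
                    n_gene_clusters=options.get("n_gene_clusters"),
                    n_sample_clusters=options.get("n_sample_clusters"),
                    n_repetitions=options.get("n_repetitions", 30),
                    seed=step_seed,
                    batch_key=batch_key,
                )
        except XmergeError as exc:
            raise XmergeError(
                f"pairwise {name} failed merging "
                f"{_source_ids(current)} with {nxt.study_id!r}: {exc}"
            ) from exc
    return current
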