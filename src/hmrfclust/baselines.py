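"""Non-spatial comparison methods: independent Bernoulli mixture EM and
agglomerative hierarchical clustering.

The independent mixture is the natural ablation of the spatial model: it is
exactly the HMRF with every interaction strength pinned at 0 (and, in its
standard form, free mixing weights).  Hierarchical clustering is the
ubiquitous genomics baseline.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.special import logsumexp

from .containers import BinaryExpressionMatrix, FitResult, HMRFParams, Partition, Posteriors
from .hmrf import THETA_EPS, log_emission, m_step_theta, mpm_assign

__all__ = ["fit_independent_mixture", "fit_hclust"]


def _mixture_log_likelihood(logits: np.ndarray) -> float:
    return float(np.sum(logsumexp(logits, axis=1)))


def _fit_mixture_single(
    y: BinaryExpressionMatrix,
    n_clusters: int,
    init: str | Partition,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    weights: str,
    theta_update: str,
) -> FitResult:
    if isinstance(init, Partition):
        labels = init.labels
    else:
        labels = rng.integers(1, n_clusters + 1, size=y.n_voxels)
    part = Partition(labels=labels, n_clusters=n_clusters)
    theta = m_step_theta(y, part, n_clusters)
    for k in np.flatnonzero(np.isnan(theta).any(axis=1)):
        theta[k] = np.clip(y.y[rng.integers(y.n_voxels)].astype(float), THETA_EPS, 1 - THETA_EPS)
    log_pi = np.zeros(n_clusters) if weights == "uniform" else np.full(
        n_clusters, -math.log(n_clusters)
    )
    trace: list[float] = []
    converged = False
    it = 0
    t = np.zeros((y.n_voxels, n_clusters))
    for it in range(1, max_iter + 1):
        # E-step: responsibilities.  With uniform weights the constant prior
        # cancels in the normalization and is omitted.
        logits = log_emission(y, theta)
        if weights == "free":
            logits = logits + log_pi
        logits_c = logits - logits.max(axis=1, keepdims=True)
        t = np.exp(logits_c)
        t /= t.sum(axis=1, keepdims=True)
        # M-step
        if theta_update == "hard":
            part = mpm_assign(Posteriors(t=t))
            theta = m_step_theta(y, part, n_clusters)
        else:
            w = t.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                theta = (t.T @ y.y.astype(float)) / w[:, None]
            theta[w < 1e-12] = np.nan
            theta = np.where(np.isnan(theta), np.nan, np.clip(theta, THETA_EPS, 1 - THETA_EPS))
        for k in np.flatnonzero(np.isnan(theta).any(axis=1)):
            theta[k] = np.clip(
                y.y[rng.integers(y.n_voxels)].astype(float), THETA_EPS, 1 - THETA_EPS
            )
        if weights == "free":
            log_pi = np.log(np.clip(t.mean(axis=0), 1e-12, None))
            log_pi -= logsumexp(log_pi)
        logits = log_emission(y, theta)
        if weights == "free":
            logits = logits + log_pi
        else:
            logits = logits - math.log(n_clusters)
        ll = _mixture_log_likelihood(logits)
        trace.append(ll)
        if len(trace) >= 2 and abs(ll - trace[-2]) <= tol * (abs(trace[-2]) + 1e-12):
            converged = True
            break
    params = HMRFParams(theta=theta, beta=np.zeros(n_clusters))
    post = Posteriors(t=t)
    n_params = n_clusters * y.n_genes + (n_clusters - 1 if weights == "free" else 0)
    return FitResult(
        params=params,
        posteriors=post,
        partition=mpm_assign(post),
        log_likelihood_trace=trace,
        converged=converged,
        n_iter=it,
        n_params=n_params,
        model="mixture",
    )


def fit_independent_mixture(
    y: BinaryExpressionMatrix,
    n_clusters: int,
    seed: int | np.random.Generator | None = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 5,
    init: str | Partition = "random",
    weights: str = "free",
    theta_update: str = "soft",
) -> FitResult:
    """EM for a K-component independent-Bernoulli mixture (no spatial term).

    The default is the standard formulation: free mixing weights pi_k and
    soft responsibility-weighted theta updates.  ``weights="uniform"`` with
    ``theta_update="hard"`` makes the fit identical, step for step, to
    :func:`hmrfclust.hmrf.fit_hmrf` with the interaction strengths pinned at
    0 — the equivalence the spatial ablation rests on.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > y.n_voxels:
        raise ValueError(f"n_clusters={n_clusters} exceeds number of voxels {y.n_voxels}")
    if weights not in ("free", "uniform"):
        raise ValueError("weights must be 'free' or 'uniform'")
    if theta_update not in ("hard", "soft"):
        raise ValueError("theta_update must be 'hard' or 'soft'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    restarts = 1 if isinstance(init, Partition) else max(1, n_restarts)
    best: FitResult | None = None
    for _ in range(restarts):
        fit = _fit_mixture_single(
            y, n_clusters, init, rng, max_iter, tol, weights, theta_update
        )
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    best.bic = -2.0 * best.log_likelihood + best.n_params * math.log(y.n_voxels)
    return best


def fit_hclust(
    y: BinaryExpressionMatrix, n_clusters: int, method: str = "average"
) -> Partition:
    """Agglomerative clustering of the binary rows, cut at K clusters.

    Hamming distance between expression profiles with ``average`` (default)
    or ``complete`` linkage; ``ward`` uses Euclidean distance on the binary
    rows (a monotone transform of Hamming), the closest Ward-like variant.
    Deterministic given the linkage; scipy's tie-breaking (first-formed
    cluster index) applies.
    """
    if n_clusters > y.n_voxels:
        raise ValueError(f"n_clusters={n_clusters} exceeds number of voxels {y.n_voxels}")
    if method not in ("average", "complete", "ward"):
        raise ValueError("method must be 'average', 'complete' or 'ward'")
    rows = y.y.astype(float)
    if method == "ward":
        dist = pdist(rows, metric="euclidean")
    else:
        dist = pdist(rows, metric="hamming")
    Z = linkage(dist, method=method)
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    # fcluster can return fewer clusters than requested on degenerate data;
    # labels are already 1-based and contiguous
    return Partition(labels=labels.astype(np.int64), n_clusters=max(n_clusters, labels.max()))
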