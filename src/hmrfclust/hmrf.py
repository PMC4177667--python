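"""Hidden Markov random field with per-cluster Potts interaction and
Bernoulli emissions, fitted by mean-field EM.

Model
-----
Each voxel i carries a latent cluster label z_i in {1..K}.  The label field
is a Markov random field on the 6-neighborhood graph with Gibbs measure
P(z) ∝ exp(-U(z)) and pairwise energy

    U(z) = - sum_{(i,j) in edges} beta_{z_i} * 1[z_i == z_j],

an extension of the Potts model in which every cluster k has its own
interaction strength beta_k, so that spatially tight cell types can be more
cohesive than dispersed ones.  With all beta_k equal this is the standard
Potts energy.  Given z_i = k, the G gene indicators of voxel i are
independent Bernoulli(theta_{k,g}).

Because the partition function of the field is intractable, inference uses
the mean-field approximation: each voxel's neighbors enter the conditional
prior through their current expected memberships, giving the per-voxel
field weight exp(beta_k * sum_{j in N(i)} t_{jk}).  EM then alternates the
mean-field E-step with closed-form theta updates (on the hard MPM partition)
and projected gradient ascent for beta.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import logsumexp

from .containers import BinaryExpressionMatrix, FitResult, HMRFParams, Partition, Posteriors
from .graph import VoxelGraph

__all__ = [
    "potts_energy",
    "gibbs_log_partition_exact",
    "log_emission",
    "e_step",
    "m_step_theta",
    "m_step_beta",
    "mpm_assign",
    "surrogate_log_likelihood",
    "fit_hmrf",
]

THETA_EPS = 1e-6  # clip for Bernoulli parameters, avoids log(0) on binary data
BETA_MAX = 10.0  # cap for interaction strengths; unbounded beta degenerates the field
_EXACT_STATE_LIMIT = 10**6


def potts_energy(partition: Partition, graph: VoxelGraph, beta: np.ndarray) -> float:
    """Energy U(z) of a labeling under the per-cluster Potts field.

    Each edge whose endpoints share label k contributes ``-beta[k-1]``; more
    negative energy means a more spatially cohesive labeling (Gibbs weight
    ∝ exp(-U)).
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (partition.n_clusters,):
        raise ValueError(
            f"beta has length {beta.shape[0]} but partition has {partition.n_clusters} clusters"
        )
    if partition.n_voxels != graph.n_voxels:
        raise ValueError("partition and graph voxel counts differ")
    if graph.n_edges == 0:
        return 0.0
    zi = partition.labels[graph.edges[:, 0]]
    zj = partition.labels[graph.edges[:, 1]]
    same = zi == zj
    return float(-np.sum(beta[zi[same] - 1]))


def gibbs_log_partition_exact(graph: VoxelGraph, beta: np.ndarray, n_clusters: int) -> float:
    """log of the Gibbs normalizing constant by exhaustive enumeration.

    Sums exp(-U(z)) over all K^N labelings.  Only feasible for tiny graphs;
    this exists as an oracle against which the mean-field approximation can
    be benchmarked, never as part of the fitting path.
    """
    n = graph.n_voxels
    if n_clusters**n > _EXACT_STATE_LIMIT:
        raise ValueError(
            f"state space {n_clusters}^{n} exceeds {_EXACT_STATE_LIMIT}; "
            "exact enumeration is only for tiny graphs"
        )
    beta = np.asarray(beta, dtype=float)
    energies = []
    for labels in itertools.product(range(1, n_clusters + 1), repeat=n):
        part = Partition(labels=np.array(labels), n_clusters=n_clusters)
        energies.append(-potts_energy(part, graph, beta))
    return float(logsumexp(energies))


def log_emission(y: BinaryExpressionMatrix, theta: np.ndarray) -> np.ndarray:
    """N x K matrix of Bernoulli log-likelihoods log p(y_i | z_i = k).

    theta is clipped away from {0, 1} so that boundary estimates (common with
    finite counts) never produce -inf.
    """
    th = np.clip(np.asarray(theta, dtype=float), THETA_EPS, 1.0 - THETA_EPS)
    yf = y.y.astype(float)
    return yf @ np.log(th).T + (1.0 - yf) @ np.log(1.0 - th).T


def _neighbor_sums(graph: VoxelGraph, t: np.ndarray) -> np.ndarray:
    """s[i, k] = sum over neighbors j of i of t[j, k]."""
    return graph.adjacency() @ t


def e_step(
    y: BinaryExpressionMatrix,
    graph: VoxelGraph,
    params: HMRFParams,
    t_prev: Posteriors,
    sweep: str = "sync",
) -> Posteriors:
    """Mean-field posterior update.

    t_{ik} ∝ p(y_i | theta_k) * exp(beta_k * sum_{j in N(i)} t_prev_{jk}),
    normalized over k per voxel; computed in log space.

    ``sweep="sync"`` (default) updates all voxels synchronously from the
    previous iteration's posteriors.  ``sweep="checkerboard"`` is the
    asynchronous alternative: voxels are two-colored by coordinate parity
    (the 6-neighborhood grid graph is bipartite, so neighbors always have
    the opposite color) and the second color sees the first color's fresh
    values — a deterministic Gauss-Seidel sweep that damps the oscillations
    synchronous updates can exhibit.
    """
    if t_prev.n_voxels != y.n_voxels or t_prev.n_clusters != params.n_clusters:
        raise ValueError("posterior shape inconsistent with data/parameters")
    le = log_emission(y, params.theta)
    if sweep == "sync":
        logits = le + params.beta * _neighbor_sums(graph, t_prev.t)
        logits -= logits.max(axis=1, keepdims=True)
        t = np.exp(logits)
        t /= t.sum(axis=1, keepdims=True)
        return Posteriors(t=t)
    if sweep != "checkerboard":
        raise ValueError("sweep must be 'sync' or 'checkerboard'")
    adj = graph.adjacency()
    parity = (graph.coords.sum(axis=1) % 2).astype(bool)
    t = t_prev.t.copy()
    for mask in (~parity, parity):
        logits = le[mask] + params.beta * (adj[mask] @ t)
        logits -= logits.max(axis=1, keepdims=True)
        tm = np.exp(logits)
        tm /= tm.sum(axis=1, keepdims=True)
        t[mask] = tm
    return Posteriors(t=t)


def m_step_theta(
    y: BinaryExpressionMatrix, partition: Partition, n_clusters: int, clip: bool = True
) -> np.ndarray:
    """Closed-form Bernoulli update from a hard partition.

    theta_{kg} = (# voxels of cluster k with y_g = 1) / (# voxels of cluster k).
    Empty clusters get a row of NaN; callers re-seed them (see fit_hmrf).
    """
    if partition.n_voxels != y.n_voxels:
        raise ValueError("partition and expression voxel counts differ")
    counts = np.zeros((n_clusters, y.n_genes))
    sizes = np.zeros(n_clusters)
    np.add.at(counts, partition.labels - 1, y.y.astype(float))
    np.add.at(sizes, partition.labels - 1, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = counts / sizes[:, None]
    if clip:
        theta = np.where(np.isnan(theta), np.nan, np.clip(theta, THETA_EPS, 1 - THETA_EPS))
    return theta


def _logsumexp_rows(logits: np.ndarray) -> np.ndarray:
    """Row-wise logsumexp, plain numpy (hot path)."""
    m = logits.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(logits - m).sum(axis=1, keepdims=True)))[:, 0]


def _field_objective_and_grad(
    beta: np.ndarray, t: np.ndarray, s: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean-field surrogate of the label-field term and its beta gradient.

    F(beta) = sum_i [ sum_k t_ik * beta_k * s_ik - log sum_k exp(beta_k * s_ik) ],
    where s_ik is the neighbor posterior mass.  grad_k = sum_i (t_ik - p_ik) s_ik
    with p the per-voxel softmax of beta * s.
    """
    logits = beta * s
    lse = _logsumexp_rows(logits)
    obj = float(np.sum(t * logits) - np.sum(lse))
    p = np.exp(logits - lse[:, None])
    grad = np.sum((t - p) * s, axis=0)
    return obj, grad


def m_step_beta(
    t: Posteriors,
    graph: VoxelGraph,
    beta_init: np.ndarray,
    step: float = 0.01,
    max_iter: int = 60,
    tol: float = 1e-3,
    beta_max: float = BETA_MAX,
) -> np.ndarray:
    """Projected gradient ascent for the per-cluster interaction strengths.

    Ascends the mean-field field objective with an adaptive step: the base
    step is halved by backtracking until the objective improves, and doubled
    after a cleanly accepted step (the objective is shallow near its
    optimum, where a fixed small step crawls).  beta is projected to
    ``[0, beta_max]`` after every step.  Stops when the projected-gradient
    norm falls below ``tol`` or after ``max_iter`` steps.

    Raises
    ------
    RuntimeError
        If the objective keeps decreasing even at the smallest step size
        (divergence); the message carries the objective trace.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    beta = np.clip(np.asarray(beta_init, dtype=float).copy(), 0.0, beta_max)
    s = _neighbor_sums(graph, t.t)
    if t.n_clusters == 1:
        # softmax over a single term is identically 1: objective constant in beta
        return beta
    trace = []
    cur = step
    for _ in range(max_iter):
        obj, grad = _field_objective_and_grad(beta, t.t, s)
        trace.append(obj)
        # projected gradient: zero out components pushing past the box
        pg = grad.copy()
        pg[(beta <= 0.0) & (grad < 0)] = 0.0
        pg[(beta >= beta_max) & (grad > 0)] = 0.0
        if np.linalg.norm(pg) < tol:
            break
        improved = False
        for halve in range(30):
            cand = np.clip(beta + cur * grad, 0.0, beta_max)
            new_obj, _ = _field_objective_and_grad(cand, t.t, s)
            if new_obj >= obj - 1e-12:
                beta = cand
                improved = True
                if halve == 0:
                    cur = min(cur * 2.0, step * 1e4)
                break
            cur /= 2.0
        if not improved:
            # no step improves beyond float noise: converged at this scale
            break
    if trace and trace[-1] < trace[0] - 1e-8 * (1.0 + abs(trace[0])):
        raise RuntimeError(
            f"beta gradient ascent diverged; objective trace: {trace[-10:]}"
        )
    return beta


def mpm_assign(t: Posteriors) -> Partition:
    """Maximum posterior marginal labeling: argmax_k t_{ik} per voxel.

    Ties are broken toward the lowest cluster index (np.argmax convention).
    """
    labels = np.argmax(t.t, axis=1) + 1
    return Partition(labels=labels, n_clusters=t.n_clusters)


def surrogate_log_likelihood(
    y: BinaryExpressionMatrix, graph: VoxelGraph, params: HMRFParams, t: Posteriors
) -> float:
    """Mean-field surrogate of the observed-data log-likelihood.

    The intractable field prior is replaced by the per-voxel mean-field
    weights pi_{ik} ∝ exp(beta_k * s_ik) (normalized over k), giving
    sum_i log sum_k pi_{ik} p(y_i | theta_k).  This is the quantity traced
    across EM iterations and plugged into the BIC.
    """
    field_logits = params.beta * _neighbor_sums(graph, t.t)
    log_pi = field_logits - _logsumexp_rows(field_logits)[:, None]
    return float(np.sum(_logsumexp_rows(log_emission(y, params.theta) + log_pi)))


def _reseed_empty_clusters(
    theta: np.ndarray, y: BinaryExpressionMatrix, rng: np.random.Generator
) -> np.ndarray:
    """Replace NaN rows (empty clusters) by a randomly chosen voxel's profile."""
    empty = np.isnan(theta).any(axis=1)
    for k in np.flatnonzero(empty):
        voxel = rng.integers(y.n_voxels)
        theta[k] = np.clip(y.y[voxel].astype(float), THETA_EPS, 1 - THETA_EPS)
    return theta


def _init_state(
    y: BinaryExpressionMatrix,
    n_clusters: int,
    init: str | Partition,
    rng: np.random.Generator,
    beta_init: float,
) -> tuple[HMRFParams, Posteriors]:
    if isinstance(init, Partition):
        if init.n_clusters != n_clusters or init.n_voxels != y.n_voxels:
            raise ValueError("initialization partition inconsistent with data / K")
        labels = init.labels
    elif init == "random":
        labels = rng.integers(1, n_clusters + 1, size=y.n_voxels)
    else:
        raise ValueError(f"unknown init {init!r}; use 'random' or a Partition")
    part = Partition(labels=labels, n_clusters=n_clusters)
    theta = m_step_theta(y, part, n_clusters)
    theta = _reseed_empty_clusters(theta, y, rng)
    params = HMRFParams(theta=theta, beta=np.full(n_clusters, beta_init))
    t0 = np.full((y.n_voxels, n_clusters), 0.0)
    t0[np.arange(y.n_voxels), part.labels - 1] = 1.0
    return params, Posteriors(t=t0)


def _fit_single(
    y: BinaryExpressionMatrix,
    graph: VoxelGraph,
    n_clusters: int,
    init: str | Partition,
    rng: np.random.Generator,
    max_em_iter: int,
    em_tol: float,
    update_beta: bool,
    beta_init: float,
    theta_update: str,
    beta_kwargs: dict,
    sweep: str,
) -> FitResult:
    params, t = _init_state(y, n_clusters, init, rng, beta_init if update_beta else 0.0)
    if not update_beta:
        params = HMRFParams(theta=params.theta, beta=np.zeros(n_clusters))
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_em_iter + 1):
        t = e_step(y, graph, params, t, sweep=sweep)
        part = mpm_assign(t)
        if theta_update == "hard":
            theta = m_step_theta(y, part, n_clusters)
        else:  # soft responsibilities
            weights = t.t.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                theta = (t.t.T @ y.y.astype(float)) / weights[:, None]
            theta[weights < 1e-12] = np.nan
            theta = np.where(
                np.isnan(theta), np.nan, np.clip(theta, THETA_EPS, 1 - THETA_EPS)
            )
        theta = _reseed_empty_clusters(theta, y, rng)
        beta = (
            m_step_beta(t, graph, params.beta, **beta_kwargs)
            if update_beta
            else params.beta
        )
        params = HMRFParams(theta=theta, beta=beta)
        ll = surrogate_log_likelihood(y, graph, params, t)
        trace.append(ll)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(ll - prev) <= em_tol * (abs(prev) + 1e-12):
                converged = True
                break
        # stall detector: synchronous updates can enter a short limit cycle
        # at strong interaction; stop once the best value stops improving
        best_so_far = max(trace)
        if len(trace) >= 20 and best_so_far <= max(trace[:-15]) + 1e-9 * abs(best_so_far):
            break
    part = mpm_assign(t)
    return FitResult(
        params=params,
        posteriors=t,
        partition=part,
        log_likelihood_trace=trace,
        converged=converged,
        n_iter=it,
        n_params=n_clusters * y.n_genes + n_clusters,
        model="hmrf",
    )


def fit_hmrf(
    y: BinaryExpressionMatrix,
    graph: VoxelGraph,
    n_clusters: int,
    init: str | Partition = "random",
    seed: int | np.random.Generator | None = 0,
    max_em_iter: int = 500,
    em_tol: float = 1e-6,
    n_restarts: int = 5,
    update_beta: bool = True,
    beta_init: float = 0.1,
    theta_update: str = "hard",
    sweep: str = "sync",
    beta_step: float = 0.01,
    beta_max_iter: int = 60,
    beta_tol: float = 1e-3,
) -> FitResult:
    """Fit the HMRF by mean-field EM with multiple random restarts.

    Parameters
    ----------
    y, graph
        Binary expression matrix and its aligned voxel graph (row i of ``y``
        is the voxel at ``graph.coords[i]``).
    n_clusters
        Number of clusters K (fixed during the fit; see model selection for
        choosing it).
    init
        ``"random"`` samples initial hard labels uniformly; passing a
        :class:`Partition` (e.g. a hierarchical-clustering solution) seeds
        theta from its cluster means.  With an explicit partition only one
        restart is run.
    seed
        Integer seed or Generator; all randomness (initial labels, restarts,
        empty-cluster re-seeding) flows from it.
    n_restarts
        Independent random restarts; the fit with the best surrogate
        log-likelihood is returned (EM can converge to local maxima).
    update_beta
        With ``False`` the interaction strengths are pinned at 0 and the
        model reduces to an independent Bernoulli mixture with uniform
        weights.
    theta_update
        ``"hard"`` (default) re-estimates theta from the MPM partition;
        ``"soft"`` uses the posterior responsibilities.

    Returns
    -------
    FitResult
        Best restart, with surrogate log-likelihood trace and BIC.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > y.n_voxels:
        raise ValueError(f"n_clusters={n_clusters} exceeds number of voxels {y.n_voxels}")
    if y.n_voxels != graph.n_voxels:
        raise ValueError(
            f"expression matrix has {y.n_voxels} rows but graph has {graph.n_voxels} voxels"
        )
    if theta_update not in ("hard", "soft"):
        raise ValueError("theta_update must be 'hard' or 'soft'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta_kwargs = dict(step=beta_step, max_iter=beta_max_iter, tol=beta_tol)
    restarts = 1 if isinstance(init, Partition) else max(1, n_restarts)
    best: FitResult | None = None
    for _ in range(restarts):
        fit = _fit_single(
            y,
            graph,
            n_clusters,
            init,
            rng,
            max_em_iter,
            em_tol,
            update_beta,
            beta_init,
            theta_update,
            beta_kwargs,
            sweep,
        )
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    if isinstance(seed, (int, np.integer)):
        best.seed = int(seed)
    best.n_params = n_clusters * y.n_genes + (n_clusters if update_beta else 0)
    best.bic = -2.0 * best.log_likelihood + best.n_params * math.log(y.n_voxels)
    return best
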