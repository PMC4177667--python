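"""Evaluation utilities: partition agreement, cluster fingerprints and
interaction-strength recovery summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .containers import FitResult, HMRFParams, Partition

__all__ = [
    "jaccard_partitions",
    "jaccard_matched",
    "match_clusters",
    "aligned_theta_rmse",
    "specificity_scores",
    "top_genes",
    "ClusterFingerprint",
    "beta_recovery_report",
    "BetaRecoveryReport",
    "export_bioweb3d",
]


def _check_same_n(a: Partition, b: Partition) -> None:
    if a.n_voxels != b.n_voxels:
        raise ValueError(f"partitions have different sizes: {a.n_voxels} vs {b.n_voxels}")


def jaccard_partitions(a: Partition, b: Partition) -> float:
    """Pairwise co-membership Jaccard coefficient between two partitions.

    Over all unordered voxel pairs, J = (# pairs co-clustered in both) /
    (# pairs co-clustered in at least one).  Label-permutation invariant,
    symmetric, 1 iff the partitions are identical up to relabeling.  Computed
    from the contingency table, so it scales to large N.
    """
    _check_same_n(a, b)
    n = a.n_voxels
    if n < 2:
        return 1.0
    # contingency counts
    cont = np.zeros((a.n_clusters, b.n_clusters), dtype=np.int64)
    np.add.at(cont, (a.labels - 1, b.labels - 1), 1)

    def pairs(x: np.ndarray) -> float:
        return float((x * (x - 1) // 2).sum())

    n11 = pairs(cont)
    pa = pairs(cont.sum(axis=1))
    pb = pairs(cont.sum(axis=0))
    union = pa + pb - n11
    if union == 0:  # both partitions are all-singletons
        return 1.0
    return n11 / union


def jaccard_matched(truth: Partition, pred: Partition) -> float:
    """Best-matching per-cluster Jaccard (alternative to the pairwise form).

    Clusters are matched one-to-one by the Hungarian algorithm on shared
    voxel counts; the score is the average, over matched pairs, of
    |A ∩ B| / |A ∪ B| between the matched voxel sets.  1 iff the partitions
    are identical up to relabeling.
    """
    _check_same_n(truth, pred)
    mapping = match_clusters(truth, pred)
    scores = []
    for k, m in enumerate(mapping, start=1):
        pred_set = pred.labels == k
        if m == 0:
            scores.append(0.0)
            continue
        truth_set = truth.labels == m
        inter = np.sum(pred_set & truth_set)
        union = np.sum(pred_set | truth_set)
        scores.append(inter / union if union else 1.0)
    # truth clusters left unmatched (pred has fewer clusters) score 0
    unmatched_truth = truth.n_clusters - sum(1 for m in mapping if m > 0)
    scores.extend([0.0] * unmatched_truth)
    return float(np.mean(scores))


def match_clusters(truth: Partition, pred: Partition) -> np.ndarray:
    """Best one-to-one cluster matching (Hungarian on shared voxel counts).

    Returns an array mapping predicted label k (1-based) to the matched
    truth label at index k-1; unmatched predicted clusters (when the
    partitions have different K) map to 0.
    """
    _check_same_n(truth, pred)
    cont = np.zeros((pred.n_clusters, truth.n_clusters), dtype=np.int64)
    np.add.at(cont, (pred.labels - 1, truth.labels - 1), 1)
    rows, cols = linear_sum_assignment(-cont)
    mapping = np.zeros(pred.n_clusters, dtype=np.int64)
    mapping[rows] = cols + 1
    return mapping


def aligned_theta_rmse(theta_true: np.ndarray, theta_fit: np.ndarray, truth: Partition, pred: Partition) -> float:
    """RMSE between true and fitted Bernoulli profiles after cluster matching."""
    mapping = match_clusters(truth, pred)
    matched = [(k, m - 1) for k, m in enumerate(mapping) if m > 0]
    diffs = [theta_fit[k] - theta_true[m] for k, m in matched]
    return float(np.sqrt(np.mean(np.square(np.concatenate(diffs)))))


def specificity_scores(theta: np.ndarray, kind: str = "contrast") -> np.ndarray:
    """Score how exclusively each gene marks each cluster (K x G).

    ``contrast`` (default): S_{g,k} = theta_{kg} - mean of theta_{k'g} over
    the other clusters; a ubiquitously expressed gene scores 0 everywhere
    and each gene's scores sum to 0 over clusters.  ``ratio``:
    theta_{kg} / sum_k' theta_{k'g}, where a ubiquitous gene scores 1/K
    everywhere.  High scores mean the gene is expressed in this cluster and
    largely silent elsewhere.
    """
    theta = np.asarray(theta, dtype=float)
    K = theta.shape[0]
    if K < 2:
        raise ValueError("specificity is undefined for a single cluster")
    if kind == "contrast":
        others_mean = (theta.sum(axis=0, keepdims=True) - theta) / (K - 1)
        return theta - others_mean
    if kind == "ratio":
        denom = np.clip(theta.sum(axis=0, keepdims=True), 1e-300, None)
        return theta / denom
    raise ValueError("kind must be 'contrast' or 'ratio'")


@dataclass
class ClusterFingerprint:
    """Top-scoring marker genes of one cluster."""

    cluster: int
    genes: list[str]
    scores: list[float]
    theta: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": self.cluster,
                "rank": np.arange(1, len(self.genes) + 1),
                "gene": self.genes,
                "score": self.scores,
                "theta": self.theta,
            }
        )


def top_genes(
    params: HMRFParams,
    cluster: int,
    n_top: int = 3,
    gene_names: list[str] | None = None,
    kind: str = "contrast",
) -> ClusterFingerprint:
    """The ``n_top`` highest-specificity genes of one cluster (1-based).

    Ties are broken alphabetically by gene name.  The default of three
    genes reflects how few markers usually suffice to name a cell type.
    """
    G = params.n_genes
    if not 1 <= n_top <= G:
        raise ValueError(f"n_top must be in 1..{G}")
    if not 1 <= cluster <= params.n_clusters:
        raise ValueError(f"cluster must be in 1..{params.n_clusters}")
    names = list(gene_names) if gene_names is not None else [f"g{i + 1:04d}" for i in range(G)]
    scores = specificity_scores(params.theta, kind=kind)[cluster - 1]
    order = sorted(range(G), key=lambda g: (-scores[g], names[g]))[:n_top]
    return ClusterFingerprint(
        cluster=cluster,
        genes=[names[g] for g in order],
        scores=[float(scores[g]) for g in order],
        theta=[float(params.theta[cluster - 1, g]) for g in order],
    )


@dataclass
class BetaRecoveryReport:
    """Mean fitted interaction strengths across simulation generations."""

    mean_beta_reference: float
    mean_beta_generation1: float
    mean_beta_generation2: float | None = None
    mean_beta_randomized: float | None = None

    def underestimation(self) -> float:
        """Reference-fit mean beta minus generation-1 mean beta (positive =
        the first simulation round lost spatial coherency)."""
        return self.mean_beta_reference - self.mean_beta_generation1


def beta_recovery_report(
    reference_fit: FitResult,
    generation1_fit: FitResult,
    generation2_fit: FitResult | None = None,
    randomized_fit: FitResult | None = None,
) -> BetaRecoveryReport:
    """Summarize mean fitted beta across resimulation generations.

    ``reference_fit`` is the fit to the original (spatially sub-structured)
    data, ``generation1_fit`` the fit to data resimulated from it,
    ``generation2_fit`` the fit to data resimulated from the generation-1
    fit, and ``randomized_fit`` the spatial-randomization control.
    """

    def mb(fit: FitResult | None) -> float | None:
        return None if fit is None else float(np.mean(fit.params.beta))

    return BetaRecoveryReport(
        mean_beta_reference=float(np.mean(reference_fit.params.beta)),
        mean_beta_generation1=float(np.mean(generation1_fit.params.beta)),
        mean_beta_generation2=mb(generation2_fit),
        mean_beta_randomized=mb(randomized_fit),
    )


def export_bioweb3d(partition: Partition, coords: np.ndarray, name: str = "clusters") -> dict:
    """Partition as a 3-D viewer JSON document (per-cluster point lists).

    The dialect is the simple one used by browser point-cloud viewers: a
    dataset of xyz points plus a cluster document listing, for each cluster,
    the indices of its voxels.
    """
    coords = np.asarray(coords)
    if coords.shape[0] != partition.n_voxels:
        raise ValueError("coordinate rows and partition size differ")
    return {
        "dataset": {
            "name": name,
            "points": [[float(c) for c in row] for row in coords],
        },
        "information_layer": {
            "name": "cluster",
            "values": [int(l) for l in partition.labels],
            "clusters": [
                {
                    "id": int(k),
                    "voxels": [int(i) for i in np.flatnonzero(partition.labels == k)],
                }
                for k in range(1, partition.n_clusters + 1)
            ],
        },
    }
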