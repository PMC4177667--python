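"""Shared in-memory containers for the HMRF clustering pipeline.

All containers are thin dataclasses around numpy arrays with validation at
construction time.  Cluster labels are 1-based (``1..K``) throughout, matching
the convention of the partition files the package writes; voxel indices are
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BinaryExpressionMatrix",
    "HMRFParams",
    "Posteriors",
    "Partition",
    "FitResult",
]

_ROW_SUM_TOL = 1e-10


@dataclass
class BinaryExpressionMatrix:
    """Voxels x genes matrix of binarized expression calls.

    Parameters
    ----------
    y : ndarray of shape (N, G)
        Entries must be exactly 0 or 1.
    gene_names : sequence of str, optional
        One label per gene; defaults to ``g0001..``.
    """

    y: np.ndarray
    gene_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if y.ndim != 2 or y.shape[0] < 1 or y.shape[1] < 1:
            raise ValueError(f"expression matrix must be 2-D and non-empty, got shape {y.shape}")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("expression matrix entries must be exactly 0 or 1")
        self.y = y.astype(np.int8)
        if self.gene_names is None:
            self.gene_names = [f"g{i + 1:04d}" for i in range(y.shape[1])]
        else:
            self.gene_names = list(self.gene_names)
            if len(self.gene_names) != y.shape[1]:
                raise ValueError(
                    f"{len(self.gene_names)} gene names for {y.shape[1]} gene columns"
                )

    @property
    def n_voxels(self) -> int:
        return self.y.shape[0]

    @property
    def n_genes(self) -> int:
        return self.y.shape[1]


@dataclass
class HMRFParams:
    """Model parameters: Bernoulli success probabilities and interaction strengths.

    ``theta[k, g]`` is the probability that a voxel of cluster ``k+1`` expresses
    gene ``g``; ``beta[k]`` is the spatial-cohesion strength of cluster ``k+1``
    (0 means no spatial interaction).
    """

    theta: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if theta.ndim != 2:
            raise ValueError("theta must be K x G")
        if beta.shape != (theta.shape[0],):
            raise ValueError(
                f"beta has length {beta.shape[0]} but theta has {theta.shape[0]} clusters"
            )
        if not np.isfinite(theta).all() or (theta < 0).any() or (theta > 1).any():
            raise ValueError("theta entries must be finite probabilities in [0, 1]")
        if not np.isfinite(beta).all() or (beta < 0).any():
            raise ValueError("beta entries must be finite and non-negative")
        self.theta = theta
        self.beta = beta

    @property
    def n_clusters(self) -> int:
        return self.theta.shape[0]

    @property
    def n_genes(self) -> int:
        return self.theta.shape[1]


@dataclass
class Posteriors:
    """Mean-field posterior membership probabilities, one row per voxel."""

    t: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 2:
            raise ValueError("posterior matrix must be N x K")
        if (t < 0).any():
            raise ValueError("posterior probabilities must be non-negative")
        if not np.allclose(t.sum(axis=1), 1.0, atol=_ROW_SUM_TOL, rtol=0):
            raise ValueError(f"posterior rows must sum to 1 within {_ROW_SUM_TOL}")
        self.t = t

    @property
    def n_voxels(self) -> int:
        return self.t.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.t.shape[1]


@dataclass
class Partition:
    """Hard cluster assignment; labels take values in ``1..K``."""

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D array")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.array_equal(labels, labels.astype(int)):
                raise ValueError("labels must be integers")
        labels = labels.astype(np.int64)
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if labels.size and (labels.min() < 1 or labels.max() > self.n_clusters):
            raise ValueError(
                f"labels must lie in 1..{self.n_clusters}, "
                f"got range [{labels.min()}, {labels.max()}]"
            )
        self.labels = labels

    @property
    def n_voxels(self) -> int:
        return self.labels.shape[0]

    def cluster_sizes(self) -> np.ndarray:
        """Number of voxels per cluster, index k-1 for cluster k."""
        return np.bincount(self.labels - 1, minlength=self.n_clusters)


@dataclass
class FitResult:
    """Everything a model fit produces, sufficient to reproduce and audit it."""

    params: HMRFParams
    posteriors: Posteriors
    partition: Partition
    log_likelihood_trace: list[float] = field(default_factory=list)
    bic: float = float("nan")
    converged: bool = False
    seed: int | None = None
    n_iter: int = 0
    n_params: int = 0
    model: str = "hmrf"

    @property
    def log_likelihood(self) -> float:
        return self.log_likelihood_trace[-1] if self.log_likelihood_trace else float("nan")
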