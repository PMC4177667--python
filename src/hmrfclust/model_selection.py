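"""Choosing the number of clusters: BIC, K sweeps and the plateau rule.

The exact likelihood of the field is intractable, so the BIC is computed on
the mean-field surrogate log-likelihood.  The parameter count is
K*G Bernoulli parameters plus K interaction strengths for the spatial
model (mixture fits count their own free parameters).

Two selection rules are reported side by side: the classical argmin of the
BIC curve, and a plateau rule for tissues whose near-symmetry makes the
curve flatten instead of turning up (late splits of left/right copies of
the same tissue keep improving the likelihood just enough to offset the
penalty).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import BinaryExpressionMatrix, FitResult
from .graph import VoxelGraph
from .hmrf import fit_hmrf

__all__ = ["bic", "plateau_k", "sweep_k", "KSweepResult"]


def bic(fit: FitResult, n_voxels: int) -> float:
    """Bayesian Information Criterion: -2*logL + d*log(N); lower is better.

    ``d`` is taken from ``fit.n_params`` (K*G + K for the spatial model).
    The log-likelihood is the fit's mean-field surrogate.
    """
    if not fit.log_likelihood_trace:
        raise ValueError("fit has no log-likelihood trace")
    return -2.0 * fit.log_likelihood + fit.n_params * math.log(n_voxels)


def plateau_k(bic_curve: np.ndarray, k_values: np.ndarray | None = None, rel_tol: float = 0.005) -> int:
    """Smallest K after which the BIC curve stops improving meaningfully.

    Scans consecutive BIC values and returns the first K such that every
    subsequent relative improvement ``(b[i-1] - b[i]) / |b[i-1]|`` stays
    below ``rel_tol`` (default 0.5%).  Falls back to the argmin (with a
    warning) when the curve is still improving at the end of the range.
    """
    bic_curve = np.asarray(bic_curve, dtype=float)
    if bic_curve.size < 3:
        raise ValueError("plateau detection needs at least 3 BIC values")
    if k_values is None:
        k_values = np.arange(1, bic_curve.size + 1)
    else:
        k_values = np.asarray(k_values)
        if k_values.shape != bic_curve.shape:
            raise ValueError("k_values and bic_curve must have the same length")
    improvements = (bic_curve[:-1] - bic_curve[1:]) / np.maximum(np.abs(bic_curve[:-1]), 1e-300)
    small = improvements < rel_tol
    # first index i such that all improvements from i onward are small
    for i in range(improvements.size):
        if small[i:].all():
            return int(k_values[i])
    warnings.warn(
        "BIC curve still improving at the end of the sweep; falling back to argmin",
        stacklevel=2,
    )
    return int(k_values[int(np.argmin(bic_curve))])


@dataclass
class KSweepResult:
    """Outcome of fitting the model across a range of K."""

    k_values: list[int]
    fits: dict[int, FitResult] = field(default_factory=dict)
    bics: dict[int, float] = field(default_factory=dict)
    failures: dict[int, str] = field(default_factory=dict)
    chosen_k_min: int = 0
    chosen_k_plateau: int = 0

    def bic_curve(self) -> tuple[np.ndarray, np.ndarray]:
        ks = np.array([k for k in self.k_values if k in self.bics])
        return ks, np.array([self.bics[k] for k in ks])


def sweep_k(
    y: BinaryExpressionMatrix,
    graph: VoxelGraph,
    k_range,
    n_restarts: int = 3,
    seed: int | np.random.Generator | None = 0,
    plateau_rel_tol: float = 0.005,
    **fit_kwargs,
) -> KSweepResult:
    """Fit the HMRF for each K in ``k_range`` and select K two ways.

    Each K gets ``n_restarts`` random restarts; the best-restart BIC is
    recorded.  A failing K is logged in ``failures`` and the sweep
    continues.  Reports both the argmin-BIC K and the plateau K (the latter
    falls back to argmin for sweeps shorter than 3 successful fits).
    """
    k_values = [int(k) for k in k_range]
    if not k_values or sorted(k_values) != k_values:
        raise ValueError("k_range must be non-empty and ascending")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = KSweepResult(k_values=k_values)
    for k in k_values:
        try:
            fit = fit_hmrf(y, graph, k, seed=rng, n_restarts=n_restarts, **fit_kwargs)
            out.fits[k] = fit
            out.bics[k] = bic(fit, y.n_voxels)
        except Exception as exc:  # keep sweeping; report the failure
            out.failures[k] = f"{type(exc).__name__}: {exc}"
    if not out.bics:
        raise RuntimeError(f"every K in the sweep failed: {out.failures}")
    ks, curve = out.bic_curve()
    out.chosen_k_min = int(ks[int(np.argmin(curve))])
    if curve.size >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.chosen_k_plateau = plateau_k(curve, ks, rel_tol=plateau_rel_tol)
    else:
        out.chosen_k_plateau = out.chosen_k_min
    return out
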