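"""Turning continuous luminescence measurements into binary expression calls.

In-situ luminescence is only semi-quantitative (light contamination between
neighboring voxels, probe-to-probe efficiency differences), so the model
consumes presence/absence calls instead.  The primary path is per-gene
manual thresholds chosen by inspecting the images; :func:`auto_threshold`
is a convenience that automates the choice with a two-component Gaussian
mixture on the log scale, flagging genes whose intensity density is too
diffuse to binarize cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .containers import BinaryExpressionMatrix

__all__ = [
    "LuminescenceMatrix",
    "threshold_binarize",
    "auto_threshold",
    "AutoThresholdResult",
    "filter_genes",
]


@dataclass
class LuminescenceMatrix:
    """Voxels x genes matrix of non-negative luminescence values."""

    values: np.ndarray
    gene_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("luminescence matrix must be N x G")
        if not np.isfinite(values).all() or (values < 0).any():
            raise ValueError("luminescence values must be finite and non-negative")
        self.values = values
        if self.gene_names is None:
            self.gene_names = [f"g{i + 1:04d}" for i in range(values.shape[1])]
        else:
            self.gene_names = list(self.gene_names)
            if len(self.gene_names) != values.shape[1]:
                raise ValueError("gene name count does not match column count")


def threshold_binarize(lum: LuminescenceMatrix, thresholds: np.ndarray) -> BinaryExpressionMatrix:
    """Call a gene expressed where its value strictly exceeds its threshold.

    One threshold per gene; a value exactly equal to the threshold is called
    unexpressed (the boundary convention is fixed for reproducibility).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != (lum.values.shape[1],):
        raise ValueError(
            f"{thresholds.size} thresholds for {lum.values.shape[1]} genes"
        )
    y = (lum.values > thresholds).astype(np.int8)
    return BinaryExpressionMatrix(y=y, gene_names=list(lum.gene_names))


@dataclass
class AutoThresholdResult:
    """Outcome of automatic threshold selection for one gene."""

    threshold: float | None  # original (luminescence) scale; None if no clear split
    bimodal: bool
    means: tuple[float, float] | None = None  # log-scale component means (low, high)
    delta_bic: float = float("nan")  # BIC(1 component) - BIC(2 components); >0 favors 2


def auto_threshold(
    gene_values: np.ndarray, seed: int | None = 0, min_separation: float = 0.5
) -> AutoThresholdResult:
    """Choose a binarization threshold by a 2-component Gaussian mixture.

    Fits 1- and 2-component Gaussian mixtures to ``log(1 + value)``.  If the
    2-component model wins on BIC and its components are separated by at
    least ``min_separation`` pooled standard deviations, the returned
    threshold is the luminescence value at which the posterior
    responsibility of the high-mean component crosses 0.5 (located by
    bisection between the component means).  Otherwise the gene is flagged
    as lacking a clear threshold (diffuse density) and ``threshold`` is
    None.
    """
    gene_values = np.asarray(gene_values, dtype=float).ravel()
    if np.unique(gene_values).size < 2:
        raise ValueError("need at least 2 distinct values to choose a threshold")
    x = np.log1p(gene_values).reshape(-1, 1)
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(x)
    gm2 = GaussianMixture(n_components=2, n_init=3, random_state=seed).fit(x)
    delta_bic = float(gm1.bic(x) - gm2.bic(x))
    means = gm2.means_.ravel()
    sds = np.sqrt(gm2.covariances_.ravel())
    lo_i, hi_i = int(np.argmin(means)), int(np.argmax(means))
    pooled_sd = float(np.sqrt(0.5 * (sds[lo_i] ** 2 + sds[hi_i] ** 2)))
    separation = (means[hi_i] - means[lo_i]) / max(pooled_sd, 1e-12)
    bimodal = delta_bic > 0 and separation > min_separation
    if not bimodal:
        return AutoThresholdResult(
            threshold=None,
            bimodal=False,
            means=(float(means[lo_i]), float(means[hi_i])),
            delta_bic=delta_bic,
        )

    def high_resp_minus_half(v: float) -> float:
        resp = gm2.predict_proba(np.array([[v]]))[0, hi_i]
        return resp - 0.5

    a, b = float(means[lo_i]), float(means[hi_i])
    fa, fb = high_resp_minus_half(a), high_resp_minus_half(b)
    if fa >= 0 or fb <= 0:  # responsibilities do not bracket 0.5: collapsed fit
        return AutoThresholdResult(
            threshold=None, bimodal=False,
            means=(a, b), delta_bic=delta_bic,
        )
    for _ in range(100):
        mid = 0.5 * (a + b)
        if high_resp_minus_half(mid) < 0:
            a = mid
        else:
            b = mid
    boundary_log = 0.5 * (a + b)
    return AutoThresholdResult(
        threshold=float(np.expm1(boundary_log)),
        bimodal=True,
        means=(float(means[lo_i]), float(means[hi_i])),
        delta_bic=delta_bic,
    )


def filter_genes(
    matrix: BinaryExpressionMatrix | LuminescenceMatrix, drop: Sequence[str]
) -> "BinaryExpressionMatrix | LuminescenceMatrix":
    """Drop quality-failed genes by name, preserving the order of the rest.

    Screening in-situ patterns for microscopy artefacts and background noise
    is how a curated gene panel is produced from a larger set of generated
    patterns; this is the bookkeeping for that step.
    """
    drop_set = set(drop)
    unknown = drop_set - set(matrix.gene_names)
    if unknown:
        raise ValueError(f"genes to drop not present: {sorted(unknown)}")
    keep_idx = [i for i, g in enumerate(matrix.gene_names) if g not in drop_set]
    if not keep_idx:
        raise ValueError("filtering would drop every gene")
    names = [matrix.gene_names[i] for i in keep_idx]
    if isinstance(matrix, BinaryExpressionMatrix):
        return BinaryExpressionMatrix(y=matrix.y[:, keep_idx], gene_names=names)
    return LuminescenceMatrix(values=matrix.values[:, keep_idx], gene_names=names)
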