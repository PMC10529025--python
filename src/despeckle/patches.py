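"""Patch extraction, soft patch weighting, and noise-variance estimation.

The estimator works on a matrix of vectorized K x K patches.  Flat
("low-rank") patches are soft-selected by a weight in [0, 1]; the noise
variance is then the smallest eigenvalue of the weighted patch covariance.
The intuition: signal structure occupies a low-dimensional subspace of
patch space, while additive noise spreads isotropically, so the bottom of
the eigenvalue spectrum is the noise floor.

For multiplicative speckle, whose additive-domain variance is proportional
to the local signal level, :func:`estimate_speckle_level` normalizes every
patch by the square root of its own mean before forming the covariance,
making the noise floor equal to the speckle variance itself regardless of
the underlying intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .phantom import validate_image

__all__ = [
    "PatchMatrix",
    "extract_patches",
    "compute_patch_weights",
    "estimate_noise_variance",
    "estimate_speckle_level",
]


@dataclass
class PatchMatrix:
    """K^2 x n_e matrix of vectorized patches with per-patch soft weights.

    Column ``j`` is the row-major vectorization of the K x K patch whose
    top-left corner is ``origins[j]`` (0-based, half-open).  ``weights`` are
    the soft-selection coefficients C_j in [0, 1]; they default to ones.
    """

    E: np.ndarray
    K: int
    origins: np.ndarray  # (n_e, 2) int array of (row, col) corners
    weights: np.ndarray

    @property
    def n_patches(self) -> int:
        return self.E.shape[1]

    def patch(self, j: int) -> np.ndarray:
        return self.E[:, j].reshape(self.K, self.K)


def extract_patches(img: np.ndarray, K: int, stride: int = 1) -> PatchMatrix:
    """All fully interior K x K patches on the stride grid, row-major order."""
    arr = validate_image(img)
    h, w = arr.shape
    if K < 1 or K > min(h, w):
        raise ValueError(f"patch side K={K} out of range for image {arr.shape}")
    if stride < 1:
        raise ValueError("stride must be at least 1")
    windows = sliding_window_view(arr, (K, K))[::stride, ::stride]
    n_rows, n_cols = windows.shape[:2]
    E = windows.reshape(n_rows * n_cols, K * K).T.copy()
    rr, cc = np.meshgrid(
        np.arange(0, n_rows) * stride, np.arange(0, n_cols) * stride, indexing="ij"
    )
    origins = np.stack([rr.ravel(), cc.ravel()], axis=1)
    return PatchMatrix(E=E, K=K, origins=origins, weights=np.ones(E.shape[1]))


def compute_patch_weights(pm: PatchMatrix) -> np.ndarray:
    """Soft selection of low-rank patches: C_j = exp(-excess_j / s).

    ``excess_j`` is the patch variance above the floor set by the flattest
    patch, and ``s`` is the median positive excess, so weights adapt to the
    overall texture level.  Flat patches get weight 1; strongly textured
    patches decay toward 0.  A degenerate all-identical patch set keeps
    uniform weights 1.  The computed weights are also stored on ``pm``.
    """
    if pm.n_patches < 2:
        raise ValueError("soft selection needs at least two patches")
    variances = pm.E.var(axis=0, ddof=1)
    excess = variances - variances.min()
    positive = excess[excess > 0]
    if positive.size == 0:
        weights = np.ones(pm.n_patches)
    else:
        weights = np.exp(-excess / np.median(positive))
    pm.weights = weights
    return weights


def estimate_noise_variance(pm: PatchMatrix, *, bias_correction: bool = True) -> float:
    """Smallest eigenvalue of the weighted, mean-centered patch covariance.

    The covariance is ``E_c diag(C) E_c^T / sum(C)`` with the weighted mean
    removed first.  With ``bias_correction`` (default) the eigenvalue is
    divided by the finite-sample shrinkage factor ``(1 - sqrt(d/n_eff))**2``
    (the lower Marchenko–Pastur edge for d-dimensional patches and an
    effective sample count ``n_eff = (sum C)^2 / sum C^2``), which removes
    the systematic downward bias of the bottom eigenvalue.
    """
    C = np.asarray(pm.weights, dtype=np.float64)
    total = C.sum()
    if not total > 0:
        raise ValueError("patch weights must have a positive sum")
    d = pm.E.shape[0]
    if pm.n_patches < d:
        raise ValueError(
            f"need at least K^2={d} patches for a full-rank covariance, got "
            f"{pm.n_patches}; use a smaller K or a denser stride"
        )
    mean = (pm.E * C).sum(axis=1) / total
    centered = pm.E - mean[:, np.newaxis]
    cov = (centered * C) @ centered.T / total
    smallest = float(np.linalg.eigvalsh(cov)[0])
    smallest = max(smallest, 0.0)
    if bias_correction:
        n_eff = total**2 / float((C**2).sum())
        edge = 1.0 - np.sqrt(d / n_eff)
        if edge > 0.1:
            smallest /= edge**2
    return smallest


def estimate_speckle_level(
    img: np.ndarray,
    K: int = 8,
    stride: int = 2,
    mask_floor: float = 0.05,
) -> float:
    """Estimate the speckle variance of the H = 0.5 model from one image.

    Under ``J + sqrt(J) * eps`` the additive noise variance inside a flat
    region of level J is ``J * var(eps)``, so each patch is divided by the
    square root of its own mean — the model's additive domain — which maps
    the noise floor of every patch onto ``var(eps)`` directly.  Patches
    whose mean is at or below ``mask_floor`` (background: zero signal means
    zero speckle) are excluded.  Returns 0.0 when too few informative
    patches remain.
    """
    pm = extract_patches(img, K=K, stride=stride)
    means = pm.E.mean(axis=0)
    keep = means > mask_floor
    if keep.sum() < K * K:
        return 0.0
    normalized = PatchMatrix(
        E=pm.E[:, keep] / np.sqrt(means[keep]),
        K=K,
        origins=pm.origins[keep],
        weights=np.ones(int(keep.sum())),
    )
    compute_patch_weights(normalized)
    return estimate_noise_variance(normalized)
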