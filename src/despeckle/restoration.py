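"""Fuzzy non-local restoration.

Second despeckling stage: every pixel is re-estimated from local *and*
non-local candidate windows inside a search neighborhood.  A candidate is
graded by fuzzy trapezoidal membership over its mean ratio and variance
ratio against the center window (clearly dissimilar regions are thrown
away), weighted by a Gaussian of the window distance, smoothed by the local
linear minimum mean-square-error (LLMMSE, Lee-filter) estimator, and the
surviving candidates are collapsed by centroid defuzzification — a weighted
mean.  Because every LLMMSE estimate is a convex combination of values
already in the image and the defuzzified output is a convex combination of
those estimates, the restored image never leaves the input range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .phantom import validate_image

__all__ = [
    "WindowSpec",
    "MembershipParams",
    "MembershipConfig",
    "SimilarityRecord",
    "trapezoidal_membership",
    "window_similarity",
    "llmmse_estimate",
    "defuzzify_pixel",
    "restore_image",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry and the noise variance tau^2 driving the weights."""

    local_radius: int = 2
    search_radius: int = 7
    noise_variance: float = 0.0

    def __post_init__(self) -> None:
        if self.local_radius < 1:
            raise ValueError("local_radius must be at least 1")
        if self.search_radius < self.local_radius:
            raise ValueError("search_radius must be >= local_radius")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be non-negative")


@dataclass(frozen=True)
class MembershipParams:
    """Trapezoid corners Z1 <= Z2 <= Z3 <= Z4 (ratio units).

    Support is (Z1, Z4), the plateau [Z2, Z3]; equal corners degenerate
    into step edges.
    """

    Z1: float
    Z2: float
    Z3: float
    Z4: float

    def __post_init__(self) -> None:
        if not (self.Z1 <= self.Z2 <= self.Z3 <= self.Z4):
            raise ValueError("trapezoid corners must satisfy Z1 <= Z2 <= Z3 <= Z4")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.Z1, self.Z2, self.Z3, self.Z4)


# defaults roughly symmetric in log-ratio around 1
DEFAULT_Z_MEAN = MembershipParams(0.5, 0.8, 1.25, 2.0)
DEFAULT_Z_VAR = MembershipParams(0.25, 0.5, 2.0, 4.0)


@dataclass(frozen=True)
class MembershipConfig:
    z_mean: MembershipParams = DEFAULT_Z_MEAN
    z_var: MembershipParams = DEFAULT_Z_VAR
    floor: float = 0.1


@dataclass
class SimilarityRecord:
    """Similarity of one candidate window against the center window."""

    center: tuple[int, int]
    distance_tji: float
    mean_ratio: float
    variance_ratio: float
    membership: float
    weight: float
    center_value: float


def trapezoidal_membership(a, Z: MembershipParams):
    """Trapezoid membership: 0 outside (Z1, Z4), 1 on [Z2, Z3], linear ramps.

    Accepts scalars or arrays; degenerate (zero-width) ramps act as steps.
    """
    z1, z2, z3, z4 = Z.as_tuple()
    arr = np.asarray(a, dtype=np.float64)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.zeros_like(arr)
    out[(arr >= z2) & (arr <= z3)] = 1.0
    if z2 > z1:
        rising = (arr > z1) & (arr < z2)
        out[rising] = (arr[rising] - z1) / (z2 - z1)
    if z4 > z3:
        falling = (arr > z3) & (arr < z4)
        out[falling] = (z4 - arr[falling]) / (z4 - z3)
    return float(out[0]) if scalar else out


def window_similarity(
    Oj: np.ndarray,
    Oi: np.ndarray,
    spec: WindowSpec,
    z_mean: MembershipParams = DEFAULT_Z_MEAN,
    z_var: MembershipParams = DEFAULT_Z_VAR,
    floor: float = 0.1,
    center: tuple[int, int] = (0, 0),
) -> SimilarityRecord:
    """Grade candidate window ``Oi`` against reference window ``Oj``.

    The distance is the root mean squared pixel difference (normalizing by
    the window pixel count keeps tau^2 comparable across window sizes), the
    raw weight is ``exp(-t^2 / (2 tau^2))``, and the membership — the
    minimum of the mean-ratio and variance-ratio trapezoids — gates it:
    records below ``floor`` are rejected (weight 0), survivors are scaled
    by their membership.
    """
    Oj = np.asarray(Oj, dtype=np.float64)
    Oi = np.asarray(Oi, dtype=np.float64)
    if Oj.shape != Oi.shape:
        raise ValueError("windows must have equal shapes")
    mj, mi = float(Oj.mean()), float(Oi.mean())
    if abs(mj) < _EPS:
        mean_ratio = 1.0 if abs(mi) < _EPS else np.inf
    else:
        mean_ratio = mi / mj
    vj, vi = float(Oj.var()), float(Oi.var())
    if vj < _EPS and vi < _EPS:
        variance_ratio = 1.0
    elif vj < _EPS:
        variance_ratio = np.inf
    else:
        variance_ratio = vi / vj
    membership = min(
        trapezoidal_membership(mean_ratio, z_mean),
        trapezoidal_membership(variance_ratio, z_var),
    )
    t = float(np.sqrt(np.mean((Oj - Oi) ** 2)))
    if spec.noise_variance > 0:
        raw = float(np.exp(-(t**2) / (2.0 * spec.noise_variance)))
    else:
        raw = 1.0 if t == 0.0 else 0.0
    weight = raw * membership if membership >= floor else 0.0
    h, w = Oi.shape
    return SimilarityRecord(
        center=center,
        distance_tji=t,
        mean_ratio=float(mean_ratio),
        variance_ratio=float(variance_ratio),
        membership=float(membership),
        weight=weight,
        center_value=float(Oi[h // 2, w // 2]),
    )


def llmmse_estimate(window: np.ndarray, noise_variance: float) -> float:
    """Local linear MMSE (Lee-filter) estimate of the window center.

    ``m + k (x_c - m)`` with gain ``k = max(0, (s^2 - sigma_n^2) / s^2)``
    clipped to [0, 1]: a noise-free window passes the center through, a
    window drowned in noise collapses to its mean.
    """
    arr = np.asarray(window, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("window must be non-empty")
    if noise_variance < 0:
        raise ValueError("noise variance must be non-negative")
    m = float(arr.mean())
    s2 = float(arr.var())
    flat = arr.ravel()
    x_c = float(flat[flat.size // 2])
    if s2 < _EPS:
        return m
    k = min(max((s2 - noise_variance) / s2, 0.0), 1.0)
    return m + k * (x_c - m)


def defuzzify_pixel(
    records: list[SimilarityRecord], fallback: float | None = None
) -> float:
    """Centroid defuzzification: weighted mean of surviving center values.

    When every weight is zero, returns ``fallback`` (the LLMMSE estimate of
    the local window) and logs the degenerate case.
    """
    if not records:
        raise ValueError("at least one similarity record is required")
    total = sum(r.weight for r in records)
    if total <= 0.0:
        if fallback is None:
            raise ValueError("all weights are zero and no fallback was supplied")
        logger.info("all similarity weights zero; falling back to the LLMMSE value")
        return fallback
    return sum(r.center_value * r.weight for r in records) / total


def restore_image(
    img: np.ndarray,
    spec: WindowSpec = WindowSpec(),
    membership: MembershipConfig = MembershipConfig(),
) -> np.ndarray:
    """Fuzzy non-local restoration of every pixel.

    Vectorized over search offsets: for each of the (2 R_search + 1)^2
    candidate displacements the window statistics, distances, memberships
    and LLMMSE estimates are computed for all pixels at once with box
    filters, then accumulated into the defuzzification sums.  Borders are
    handled by symmetric padding.  ``tau^2 = 0`` (no noise) returns the
    input unchanged.  Deterministic: the result is a per-pixel weighted
    mean, independent of the order offsets are visited in.
    """
    arr = validate_image(img)
    tau2 = spec.noise_variance
    if tau2 <= 0.0:
        return arr.copy()

    lr, sr = spec.local_radius, spec.search_radius
    win = 2 * lr + 1
    pad_width = sr + lr
    padded = np.pad(arr, pad_width, mode="symmetric")
    mean_map = uniform_filter(padded, size=win)
    var_map = np.clip(uniform_filter(padded * padded, size=win) - mean_map**2, 0.0, None)

    h, w = arr.shape
    center = (slice(pad_width, pad_width + h), slice(pad_width, pad_width + w))
    mc, vc = mean_map[center], var_map[center]
    z_mean, z_var, floor = membership.z_mean, membership.z_var, membership.floor

    numerator = np.zeros_like(arr)
    denominator = np.zeros_like(arr)
    for dy in range(-sr, sr + 1):
        for dx in range(-sr, sr + 1):
            shifted = (
                slice(pad_width + dy, pad_width + dy + h),
                slice(pad_width + dx, pad_width + dx + w),
            )
            ms, vs = mean_map[shifted], var_map[shifted]
            xs = padded[shifted]
            if dy == 0 and dx == 0:
                d2 = np.zeros_like(arr)
            else:
                diff = padded - np.roll(padded, (-dy, -dx), axis=(0, 1))
                d2 = uniform_filter(diff * diff, size=win)[center]
            both_zero_mean = (np.abs(mc) < _EPS) & (np.abs(ms) < _EPS)
            mean_ratio = np.where(
                both_zero_mean, 1.0, ms / np.where(np.abs(mc) < _EPS, _EPS, mc)
            )
            both_flat = (vc < _EPS) & (vs < _EPS)
            var_ratio = np.where(
                both_flat, 1.0, vs / np.where(vc < _EPS, _EPS, vc)
            )
            memb = np.minimum(
                trapezoidal_membership(mean_ratio, z_mean),
                trapezoidal_membership(var_ratio, z_var),
            )
            weight = np.exp(-d2 / (2.0 * tau2)) * memb * (memb >= floor)
            gain = np.clip(
                (vs - tau2) / np.where(vs < _EPS, _EPS, vs), 0.0, 1.0
            )
            llmmse = ms + gain * (xs - ms)
            numerator += weight * llmmse
            denominator += weight
    # the self record (dy = dx = 0) always survives with weight 1, so the
    # denominator is bounded away from zero
    return numerator / denominator
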