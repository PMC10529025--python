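"""Shepp–Logan test phantom and multiplicative speckle simulation.

Ultrasound speckle follows the signal-dependent model

    J_noisy = J + J**H * eps

where ``eps`` is a zero-mean Gaussian field and ``H`` controls how strongly
the noise amplitude scales with the signal: ``H = 0.5`` approximates B-mode
ultrasound, ``H = 1`` is the fully multiplicative model.  A logarithmic
point transform turns the multiplicative model into an additive one, which
is where wavelet shrinkage operates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SHEPP_LOGAN_ELLIPSES",
    "SpeckleParams",
    "generate_shepp_logan",
    "add_speckle",
    "log_transform",
    "exp_transform",
    "validate_image",
]

MIN_SIDE = 16

# Modified (high-contrast) Shepp–Logan head phantom: one row per ellipse,
# (intensity, semi-axis a, semi-axis b, center x0, center y0, rotation phi in
# degrees), on the [-1, 1]^2 plane, intensities additive.
SHEPP_LOGAN_ELLIPSES: tuple[tuple[float, float, float, float, float, float], ...] = (
    (1.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.8, 0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (-0.2, 0.1100, 0.3100, 0.22, 0.0, -18.0),
    (-0.2, 0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.1, 0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, 0.1, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, -0.1, 0.0),
    (0.1, 0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.1, 0.0230, 0.0230, 0.0, -0.605, 0.0),
    (0.1, 0.0230, 0.0460, 0.06, -0.605, 0.0),
)


def validate_image(img: np.ndarray, *, min_side: int = MIN_SIDE) -> np.ndarray:
    """Check that ``img`` is a finite 2-D float raster of workable size.

    Returns the input as a float64 array.  Raises ``ValueError`` for
    non-2-D input (multi-channel images must be converted explicitly by the
    caller), non-finite pixels, or images smaller than ``min_side`` on a
    side, for which windows and patches are not well defined.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(
            f"expected a single-channel 2-D image, got shape {arr.shape}"
        )
    if arr.shape[0] < min_side or arr.shape[1] < min_side:
        raise ValueError(
            f"image {arr.shape} is smaller than the minimum {min_side} pixels per side"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite pixels")
    return arr


@dataclass(frozen=True)
class SpeckleParams:
    """Parameters of the speckle field.

    variance
        Variance of the zero-mean Gaussian noise field ``eps``.
    exponent_H
        Signal exponent of the noise term: 0.5 (B-mode approximation) or
        1.0 (fully multiplicative).
    seed
        Seed for the pseudo-random generator; identical parameters give
        bit-identical noise.
    """

    variance: float
    exponent_H: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("noise variance must be non-negative")
        if self.exponent_H not in (0.5, 1.0):
            raise ValueError("exponent_H must be 0.5 or 1.0")


def generate_shepp_logan(size: int) -> np.ndarray:
    """Render the modified Shepp–Logan head phantom at ``size`` x ``size``.

    Pixel centers sample the [-1, 1]^2 plane; each of the ten ellipses adds
    its intensity to every pixel it contains, giving values in [0, 1] with a
    zero background.  Sizes below 64 are rejected: the downstream patch and
    window machinery needs room to operate.
    """
    if size < 64:
        raise ValueError(f"phantom size must be at least 64, got {size}")
    axis = (np.arange(size) - (size - 1) / 2.0) * (2.0 / size)
    x = axis[np.newaxis, :]
    y = -axis[:, np.newaxis]  # row 0 is the top of the head
    img = np.zeros((size, size), dtype=np.float64)
    for intensity, a, b, x0, y0, phi in SHEPP_LOGAN_ELLIPSES:
        theta = np.deg2rad(phi)
        ct, st = np.cos(theta), np.sin(theta)
        xr = (x - x0) * ct + (y - y0) * st
        yr = -(x - x0) * st + (y - y0) * ct
        img += intensity * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    # additive ellipse intensities can leave values like -5e-17 at exact
    # boundary cancellations; snap those to zero
    np.clip(img, 0.0, None, out=img)
    return img


def add_speckle(img: np.ndarray, params: SpeckleParams) -> np.ndarray:
    """Inject multiplicative speckle: ``img + img**H * eps``.

    ``eps`` is a zero-mean Gaussian field with ``params.variance``, drawn
    from a generator seeded with ``params.seed``, so the output is
    deterministic.  ``variance = 0`` returns a bit-exact copy.  The result
    is *not* clipped: negative excursions are legitimate samples of the
    noise model and clipping them here would bias every downstream moment;
    clipping to the dynamic range happens only when an image is written to
    file.
    """
    arr = validate_image(img)
    if params.variance == 0.0:
        return arr.copy()
    rng = np.random.default_rng(params.seed)
    eps = rng.normal(0.0, np.sqrt(params.variance), size=arr.shape)
    gain = np.power(np.clip(arr, 0.0, None), params.exponent_H)
    return arr + gain * eps


def log_transform(img: np.ndarray, offset: float = 1e-6) -> np.ndarray:
    """``ln(img + offset)``; the offset guards the log at zero pixels."""
    arr = np.asarray(img, dtype=np.float64)
    if offset <= 0:
        raise ValueError("offset must be positive")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite pixels")
    shifted = arr + offset
    if np.any(shifted <= 0):
        raise ValueError(
            "image has pixels at or below -offset; clip negatives before the log"
        )
    return np.log(shifted)


def exp_transform(img: np.ndarray, offset: float = 1e-6) -> np.ndarray:
    """Inverse of :func:`log_transform`: ``exp(img) - offset``."""
    arr = np.asarray(img, dtype=np.float64)
    if offset <= 0:
        raise ValueError("offset must be positive")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite pixels")
    return np.exp(arr) - offset
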