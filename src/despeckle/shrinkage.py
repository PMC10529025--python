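"""Hard, soft and exponential shrinkage of wavelet detail coefficients.

The exponential rule interpolates between the two classical limits.  For a
coefficient ``c``, threshold level ``D`` and shape parameter ``alpha``:

    |c| <  D   ->  0
    |c| >= D   ->  sign(c) * (|c| - D * exp(-alpha * (|c| - D) / D))

At ``alpha = 0`` the surviving branch is ``sign(c) * (|c| - D)``, the soft
rule; as ``alpha`` grows the subtracted term vanishes and the rule tends to
the hard ("keep or kill") rule.  Every mode is an odd function of ``c`` and
a contraction (``|shrink(c)| <= |c|``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .swt import WaveletPyramid

__all__ = ["ThresholdParams", "threshold_coefficient", "shrink_pyramid", "MODES"]

logger = logging.getLogger(__name__)

MODES = ("hard", "soft", "exponential")


@dataclass(frozen=True)
class ThresholdParams:
    """The tunable pair searched by the optimizer.

    D      threshold level, in coefficient units, >= 0
    alpha  shape parameter of the exponential rule, >= 0
    """

    D: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("threshold level D must be non-negative")
        if self.alpha < 0:
            raise ValueError("shape parameter alpha must be non-negative")


def threshold_coefficient(
    c: float | np.ndarray, params: ThresholdParams, mode: str = "exponential"
):
    """Apply one shrinkage rule elementwise; scalar in, scalar out.

    ``D = 0`` with the exponential rule degenerates (the decay scale
    vanishes); it falls back to the identity and logs the fact.
    """
    if mode not in MODES:
        raise ValueError(f"unknown threshold mode '{mode}' (choose from {MODES})")
    arr = np.asarray(c, dtype=np.float64)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    a = np.abs(arr)
    D = params.D
    if mode == "hard":
        out = np.where(a >= D, arr, 0.0)
    elif mode == "soft":
        out = np.sign(arr) * np.maximum(a - D, 0.0)
    else:
        if D == 0.0:
            logger.info(
                "exponential threshold with D=0 has no decay scale; "
                "passing coefficients through unchanged"
            )
            out = arr.copy()
        else:
            decay = np.exp(-params.alpha * np.maximum(a - D, 0.0) / D)
            out = np.where(a < D, 0.0, np.sign(arr) * (a - D * decay))
    return float(out[0]) if scalar else out


def shrink_pyramid(
    pyr: WaveletPyramid, params: ThresholdParams, mode: str = "exponential"
) -> WaveletPyramid:
    """Threshold every detail band of a pyramid; approximation untouched.

    The approximation band carries the low-frequency bulk of the signal and
    is left exactly as-is.  Because every rule is a pointwise contraction,
    total detail energy never increases.
    """
    pyr.validate()
    new_details = [
        tuple(threshold_coefficient(band, params, mode) for band in bands)
        for bands in pyr.details
    ]
    return replace(
        pyr, approximation=pyr.approximation.copy(), details=new_details
    )
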