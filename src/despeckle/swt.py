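"""Redundant (stationary) wavelet analysis and synthesis.

The stationary wavelet transform (SWT) is the undecimated, shift-invariant
relative of the DWT: every subband keeps the full spatial resolution and the
transform inverts exactly.  That combination — redundancy plus perfect
reconstruction — is what makes it suitable for shrinkage-based denoising:
thresholding artifacts are not aliased by decimation, and an untouched
pyramid reconstructs the input to machine precision.

Bands are stored finest-first: ``details[0]`` is level 1 (highest
frequency).  Images whose sides are not divisible by ``2**levels`` are
padded symmetrically on the bottom/right; the padding is recorded on the
pyramid and removed on synthesis.  Boundary handling inside the transform
itself is periodic (the classic SWT formulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .phantom import validate_image

__all__ = ["WaveletPyramid", "forward_isfwt", "inverse_isfwt"]


@dataclass
class WaveletPyramid:
    """Undecimated multi-level subband set, all bands at full resolution.

    ``details[k]`` holds the (horizontal, vertical, diagonal) bands of
    level ``k + 1``, level 1 being the finest scale.
    """

    approximation: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    wavelet_name: str
    levels: int
    original_shape: tuple[int, int] = field(default=(0, 0))
    padding: tuple[int, int] = field(default=(0, 0))

    def band_shape(self) -> tuple[int, int]:
        return self.approximation.shape

    def validate(self) -> None:
        shape = self.approximation.shape
        if len(self.details) != self.levels:
            raise ValueError(
                f"pyramid declares {self.levels} levels but has {len(self.details)}"
            )
        for level, bands in enumerate(self.details, start=1):
            if len(bands) != 3:
                raise ValueError(f"level {level} must have 3 detail bands")
            for band in bands:
                if band.shape != shape:
                    raise ValueError(
                        f"level {level} band shape {band.shape} != {shape}"
                    )

    def detail_energy(self) -> float:
        """Sum of squared detail coefficients over all levels."""
        return float(
            sum(np.sum(band**2) for bands in self.details for band in bands)
        )

    def save_npz(self, path) -> None:
        """Debug dump of all bands to one NPZ container (not a public
        interchange format; shapes and names may change)."""
        arrays = {"approximation": self.approximation}
        for level, bands in enumerate(self.details, start=1):
            for name, band in zip(("H", "V", "D"), bands):
                arrays[f"level{level}_{name}"] = band
        np.savez(
            path,
            wavelet_name=np.array(self.wavelet_name),
            levels=np.array(self.levels),
            original_shape=np.array(self.original_shape),
            padding=np.array(self.padding),
            **arrays,
        )

    @classmethod
    def load_npz(cls, path) -> "WaveletPyramid":
        with np.load(path) as data:
            levels = int(data["levels"])
            details = [
                tuple(data[f"level{k}_{name}"] for name in ("H", "V", "D"))
                for k in range(1, levels + 1)
            ]
            return cls(
                approximation=data["approximation"],
                details=details,
                wavelet_name=str(data["wavelet_name"]),
                levels=levels,
                original_shape=tuple(int(v) for v in data["original_shape"]),
                padding=tuple(int(v) for v in data["padding"]),
            )


def _padded_size(n: int, levels: int) -> int:
    block = 2**levels
    return int(np.ceil(n / block) * block)


def forward_isfwt(
    img: np.ndarray, wavelet_name: str = "sym4", levels: int = 3
) -> WaveletPyramid:
    """Undecimated multi-level decomposition of a 2-D image.

    Linear in the input.  Raises for unknown wavelet names or
    ``levels < 1``.
    """
    arr = validate_image(img)
    if levels < 1:
        raise ValueError("levels must be at least 1")
    try:
        pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet '{wavelet_name}'") from exc
    h, w = arr.shape
    pad_r = _padded_size(h, levels) - h
    pad_c = _padded_size(w, levels) - w
    if pad_r or pad_c:
        arr = np.pad(arr, ((0, pad_r), (0, pad_c)), mode="symmetric")
    coeffs = pywt.swt2(arr, wavelet_name, level=levels, trim_approx=True, norm=True)
    approximation = coeffs[0]
    # pywt returns detail levels coarsest-first; store finest-first
    details = [tuple(bands) for bands in reversed(coeffs[1:])]
    return WaveletPyramid(
        approximation=approximation,
        details=details,
        wavelet_name=wavelet_name,
        levels=levels,
        original_shape=(h, w),
        padding=(pad_r, pad_c),
    )


def inverse_isfwt(pyr: WaveletPyramid) -> np.ndarray:
    """Synthesis inverse of :func:`forward_isfwt`; removes recorded padding."""
    pyr.validate()
    coeffs = [pyr.approximation] + [tuple(bands) for bands in reversed(pyr.details)]
    rec = pywt.iswt2(coeffs, pyr.wavelet_name, norm=True)
    h, w = pyr.original_shape
    if h and w:
        rec = rec[:h, :w]
    return np.asarray(rec, dtype=np.float64)
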