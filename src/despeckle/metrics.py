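"""Full-reference and no-reference image-quality metrics.

Full-reference (FR) metrics compare a test image against a clean reference:
MSE/RMSE/PSNR, SNR, AD, MD, NAE, NK, SC, CoC, UQI, QILV, LMSE, MSSIM,
Pratt's FOM and the composite Speckle Reduction Score (SRS).  No-reference
(NR) metrics judge a (noisy, filtered) pair without ground truth: ENL over
a homogeneous tile, the despeckling evaluation index (DEI), and the
alpha-beta-gamma composite (ABG) built on the ratio image
``noisy / filtered``.

Conventions (all pinned here, since the edge detector and window choices
materially change FOM/DEI values):

* SSIM: 11 x 11 Gaussian window, sigma 1.5, stabilizers (0.01 L)^2 and
  (0.03 L)^2.
* Canny: sigma 1.4, hysteresis thresholds 0.1 / 0.2 on the [0, L] scale.
* FOM: ``1/max(N_detected, N_ideal) * sum 1/(1 + d^2/9)`` with Euclidean
  distances from detected to nearest ideal edge pixel.
* UQI: sliding 8 x 8 windows; windows with a zero denominator are skipped.
* QILV: the UQI structural comparison applied globally to the two local
  variance maps (11 x 11 Gaussian window).
* LMSE: 4-neighbor Laplacian.
* DEI: narrow 3 x 3 window against broad 9 x 9, minimum of the narrow std
  over the broad window's interior positions; a constant neighborhood
  contributes 1.  Lower is better.
* ENL: mean^2/variance over the 32 x 32 tile of minimal variance (or a
  caller-declared mask).
* SRS = 100 * mean(SSIM map) * FOM, reported on a 0-100 scale.

Asymmetric metrics (NK, SC, NAE, AD, LMSE, SNR) are reference-first.
Undefined values (CoC/UQI on constant images) are reported as NaN; the
PSNR of identical images is ``inf``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.metrics import structural_similarity

__all__ = [
    "EdgeConfig",
    "SSIMConfig",
    "NRConfig",
    "mse_rmse_psnr",
    "mssim",
    "ssim_map",
    "pratt_fom",
    "fom_from_edge_maps",
    "fr_suite",
    "nr_suite",
    "srs",
    "full_report",
]

_EPS = 1e-12


@dataclass(frozen=True)
class EdgeConfig:
    sigma: float = 1.4
    low_threshold: float = 0.1
    high_threshold: float = 0.2


@dataclass(frozen=True)
class SSIMConfig:
    win_size: int = 11
    sigma: float = 1.5


@dataclass(frozen=True)
class NRConfig:
    narrow: int = 3
    broad: int = 9
    enl_tile: int = 32
    beta: float = 0.5
    ratio_floor: float = 1e-6


def _check_pair(test: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(test, dtype=np.float64)
    r = np.asarray(reference, dtype=np.float64)
    if t.shape != r.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {r.shape}")
    return t, r


def mse_rmse_psnr(
    test: np.ndarray, reference: np.ndarray, dynamic_range: float = 1.0
) -> tuple[float, float, float]:
    """Mean squared error, its root, and ``10 log10(L^2 / MSE)``.

    Identical images report ``PSNR = inf``.
    """
    t, r = _check_pair(test, reference)
    if dynamic_range <= 0:
        raise ValueError("dynamic range must be positive")
    mse = float(np.mean((t - r) ** 2))
    rmse = float(np.sqrt(mse))
    psnr = np.inf if mse == 0 else float(10.0 * np.log10(dynamic_range**2 / mse))
    return mse, rmse, psnr


def ssim_map(
    test: np.ndarray,
    reference: np.ndarray,
    dynamic_range: float = 1.0,
    cfg: SSIMConfig = SSIMConfig(),
) -> np.ndarray:
    """Per-window SSIM similarity map (the map whose mean is MSSIM)."""
    t, r = _check_pair(test, reference)
    if min(t.shape) < cfg.win_size:
        raise ValueError(
            f"image {t.shape} smaller than the {cfg.win_size}-pixel SSIM window"
        )
    _, smap = structural_similarity(
        r,
        t,
        data_range=dynamic_range,
        gaussian_weights=True,
        sigma=cfg.sigma,
        win_size=cfg.win_size,
        use_sample_covariance=False,
        full=True,
    )
    return smap


def mssim(
    test: np.ndarray,
    reference: np.ndarray,
    dynamic_range: float = 1.0,
    cfg: SSIMConfig = SSIMConfig(),
) -> float:
    """Mean structural similarity over local Gaussian-weighted windows."""
    return float(np.mean(ssim_map(test, reference, dynamic_range, cfg)))


def fom_from_edge_maps(detected: np.ndarray, ideal: np.ndarray) -> float:
    """Pratt's figure of merit from two boolean edge maps.

    ``FOM = 1/max(N_d, N_i) * sum over detected pixels of 1/(1 + d^2/9)``
    with ``d`` the Euclidean distance to the nearest ideal edge pixel;
    1 means perfect edge preservation, an empty detected map scores 0.
    """
    ideal = np.asarray(ideal, dtype=bool)
    detected = np.asarray(detected, dtype=bool)
    if detected.shape != ideal.shape:
        raise ValueError("edge maps must have the same shape")
    n_ideal = int(ideal.sum())
    n_detected = int(detected.sum())
    if n_ideal == 0:
        raise ValueError("reference edge map has no edge pixels; FOM is undefined")
    if n_detected == 0:
        return 0.0
    distances = ndimage.distance_transform_edt(~ideal)
    scores = 1.0 / (1.0 + distances[detected] ** 2 / 9.0)
    return float(scores.sum() / max(n_detected, n_ideal))


def _canny_edges(img: np.ndarray, dynamic_range: float, cfg: EdgeConfig) -> np.ndarray:
    scaled = np.clip(np.asarray(img, dtype=np.float64) / dynamic_range, 0.0, 1.0)
    return canny(
        scaled,
        sigma=cfg.sigma,
        low_threshold=cfg.low_threshold,
        high_threshold=cfg.high_threshold,
    )


def pratt_fom(
    test: np.ndarray,
    reference: np.ndarray,
    dynamic_range: float = 1.0,
    cfg: EdgeConfig = EdgeConfig(),
) -> float:
    """FOM between Canny edge maps of test and reference images."""
    t, r = _check_pair(test, reference)
    return fom_from_edge_maps(
        _canny_edges(t, dynamic_range, cfg), _canny_edges(r, dynamic_range, cfg)
    )


def _uqi(test: np.ndarray, reference: np.ndarray, win: int = 8) -> float:
    """Universal quality index: mean of per-window Q over sliding windows."""
    t, r = _check_pair(test, reference)
    if min(t.shape) < win:
        raise ValueError(f"image smaller than the {win}-pixel UQI window")

    def local_mean(a: np.ndarray) -> np.ndarray:
        c = ndimage.uniform_filter(a, size=win)
        m = win // 2
        return c[m : m + t.shape[0] - win + 1, m : m + t.shape[1] - win + 1]

    mx = local_mean(t)
    my = local_mean(r)
    sxx = local_mean(t * t) - mx * mx
    syy = local_mean(r * r) - my * my
    sxy = local_mean(t * r) - mx * my
    num = 4.0 * sxy * mx * my
    den = (sxx + syy) * (mx * mx + my * my)
    valid = np.abs(den) > _EPS
    if not np.any(valid):
        return float("nan")
    return float(np.mean(num[valid] / den[valid]))


def _qilv(
    test: np.ndarray, reference: np.ndarray, cfg: SSIMConfig = SSIMConfig()
) -> float:
    """Quality index based on local variance: structural comparison of the
    two local-variance maps (Gaussian window), compared globally."""
    t, r = _check_pair(test, reference)

    def local_var(a: np.ndarray) -> np.ndarray:
        m = ndimage.gaussian_filter(a, cfg.sigma, truncate=(cfg.win_size // 2) / cfg.sigma)
        m2 = ndimage.gaussian_filter(a * a, cfg.sigma, truncate=(cfg.win_size // 2) / cfg.sigma)
        return np.clip(m2 - m * m, 0.0, None)

    vt, vr = local_var(t), local_var(r)
    mu_t, mu_r = vt.mean(), vr.mean()
    st, sr_ = vt.std(), vr.std()
    cov = float(np.mean((vt - mu_t) * (vr - mu_r)))
    if st < _EPS or sr_ < _EPS or (mu_t**2 + mu_r**2) < _EPS:
        return float("nan")
    return float(
        (2 * mu_t * mu_r / (mu_t**2 + mu_r**2))
        * (2 * st * sr_ / (st**2 + sr_**2))
        * (cov / (st * sr_))
    )


def fr_suite(
    test: np.ndarray,
    reference: np.ndarray,
    dynamic_range: float = 1.0,
    edge_cfg: EdgeConfig = EdgeConfig(),
    ssim_cfg: SSIMConfig = SSIMConfig(),
) -> dict[str, float]:
    """Every full-reference metric for one (test, reference) pair.

    Pinned formulas (reference-first where asymmetric):

    * ``SNR  = 10 log10(sum ref^2 / sum (ref - test)^2)``
    * ``AD   = mean(ref - test)``; ``MD = max |ref - test|``
    * ``NAE  = sum |ref - test| / sum |ref|``
    * ``NK   = sum(ref * test) / sum ref^2``; ``SC = sum ref^2 / sum test^2``
    * ``CoC`` Pearson correlation (NaN for constant images)
    * ``LMSE = sum (lap(ref) - lap(test))^2 / sum lap(ref)^2`` (4-neighbor)
    """
    t, r = _check_pair(test, reference)
    mse, rmse, psnr = mse_rmse_psnr(t, r, dynamic_range)
    diff = r - t
    sum_r2 = float(np.sum(r**2))
    sum_d2 = float(np.sum(diff**2))
    snr = np.inf if sum_d2 == 0 else float(10.0 * np.log10(sum_r2 / sum_d2))
    lap_r = ndimage.laplace(r)
    lap_t = ndimage.laplace(t)
    sum_lap2 = float(np.sum(lap_r**2))
    lmse = (
        float("nan")
        if sum_lap2 < _EPS
        else float(np.sum((lap_r - lap_t) ** 2) / sum_lap2)
    )
    if r.std() < _EPS or t.std() < _EPS:
        coc = float("nan")
    else:
        coc = float(np.corrcoef(r.ravel(), t.ravel())[0, 1])
    report = {
        "MSE": mse,
        "RMSE": rmse,
        "PSNR": psnr,
        "SNR": snr,
        "AD": float(np.mean(diff)),
        "MD": float(np.max(np.abs(diff))),
        "NAE": float(np.sum(np.abs(diff)) / max(np.sum(np.abs(r)), _EPS)),
        "NK": float(np.sum(r * t) / max(sum_r2, _EPS)),
        "SC": float(sum_r2 / max(np.sum(t**2), _EPS)),
        "CoC": coc,
        "LMSE": lmse,
    }
    if min(t.shape) >= 8:
        report["UQI"] = _uqi(t, r)
        report["QILV"] = _qilv(t, r, ssim_cfg)
    if min(t.shape) >= ssim_cfg.win_size:
        report["MSSIM"] = mssim(t, r, dynamic_range, ssim_cfg)
        try:
            report["FOM"] = pratt_fom(t, r, dynamic_range, edge_cfg)
            report["SRS"] = srs(t, r, dynamic_range, edge_cfg, ssim_cfg)
        except ValueError:
            pass  # reference without edges: FOM/SRS undefined
    return report


def _windowed_std(img: np.ndarray, size: int) -> np.ndarray:
    m = ndimage.uniform_filter(img, size=size)
    m2 = ndimage.uniform_filter(img * img, size=size)
    return np.sqrt(np.clip(m2 - m * m, 0.0, None))


def _homogeneous_tile(img: np.ndarray, tile: int) -> tuple[slice, slice]:
    """The ``tile`` x ``tile`` block of minimal variance (stride tile/2)."""
    h, w = img.shape
    tile = min(tile, h, w)
    step = max(tile // 2, 1)
    best: tuple[float, slice, slice] | None = None
    for r0 in list(range(0, h - tile + 1, step)) or [0]:
        for c0 in list(range(0, w - tile + 1, step)) or [0]:
            block = img[r0 : r0 + tile, c0 : c0 + tile]
            v = float(block.var())
            if best is None or v < best[0]:
                best = (v, slice(r0, r0 + tile), slice(c0, c0 + tile))
    assert best is not None
    return best[1], best[2]


def _enl(region: np.ndarray) -> float:
    var = float(region.var())
    if var < _EPS:
        return np.inf
    return float(region.mean() ** 2 / var)


def dei(filtered: np.ndarray, cfg: NRConfig = NRConfig()) -> float:
    """Despeckling evaluation index: mean over positions of the minimum
    narrow-window std inside the broad window, divided by the broad-window
    std.  Equal (including zero) stds contribute 1; lower is better."""
    f = np.asarray(filtered, dtype=np.float64)
    narrow_std = _windowed_std(f, cfg.narrow)
    broad_std = _windowed_std(f, cfg.broad)
    inner = cfg.broad - cfg.narrow + 1
    min_narrow = ndimage.minimum_filter(narrow_std, size=inner)
    margin = cfg.broad // 2
    if f.shape[0] <= 2 * margin or f.shape[1] <= 2 * margin:
        raise ValueError("image too small for the DEI window pair")
    sl = (slice(margin, -margin), slice(margin, -margin))
    mn, bd = min_narrow[sl], broad_std[sl]
    flat = bd < _EPS
    ratios = np.where(flat, 1.0, mn / np.where(flat, 1.0, bd))
    return float(ratios.mean())


def nr_suite(
    noisy: np.ndarray,
    filtered: np.ndarray,
    cfg: NRConfig = NRConfig(),
    homogeneous_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """No-reference scores for a (noisy, filtered) pair.

    * ``ENL``: mean^2/variance of the filtered image over the homogeneous
      tile (auto-selected as the minimum-variance 32 x 32 tile of the
      filtered image, unless a boolean mask declares the region).
    * ``DEI``: see :func:`dei`, computed on the filtered image.
    * ``ABG = beta |tau_ENL| + (1 - beta) |tau_theta| + gamma`` where,
      with ratio image ``r = noisy / filtered`` (pixels with filtered
      values below the floor are treated as ratio 1):
      ``tau_ENL`` is ``1/ENL`` of the ratio over the homogeneous tile (0
      for an ideal, constant ratio), ``tau_theta`` is the standard
      deviation of the 9 x 9 local mean of ``r - 1`` (structure leaking
      into the ratio), and ``gamma`` is the Pearson correlation between
      the high-pass (Laplacian) noisy image and the high-pass ratio image
      (0 by convention when degenerate).  Lower is better.
    """
    n, f = _check_pair(noisy, filtered)
    if homogeneous_mask is not None:
        mask = np.asarray(homogeneous_mask, dtype=bool)
        if mask.shape != f.shape or not mask.any():
            raise ValueError("homogeneous mask must be a non-empty boolean image")
        tile_values_f = f[mask]
    else:
        rows, cols = _homogeneous_tile(f, cfg.enl_tile)
        tile_values_f = f[rows, cols].ravel()
    enl = _enl(tile_values_f)

    safe = np.abs(f) > cfg.ratio_floor
    ratio = np.where(safe, n / np.where(safe, f, 1.0), 1.0)
    if homogeneous_mask is not None:
        ratio_tile = ratio[mask]
    else:
        ratio_tile = ratio[rows, cols].ravel()
    enl_ratio = _enl(ratio_tile)
    tau_enl = 0.0 if np.isinf(enl_ratio) else 1.0 / enl_ratio

    local_mean = ndimage.uniform_filter(ratio, size=cfg.broad)
    tau_theta = float(np.std(local_mean - 1.0))

    hp_noisy = ndimage.laplace(n).ravel()
    hp_ratio = ndimage.laplace(ratio).ravel()
    if hp_noisy.std() < _EPS or hp_ratio.std() < _EPS:
        gamma = 0.0
    else:
        gamma = float(np.corrcoef(hp_noisy, hp_ratio)[0, 1])

    abg = cfg.beta * abs(tau_enl) + (1.0 - cfg.beta) * abs(tau_theta) + gamma
    return {
        "ENL": enl,
        "DEI": dei(f, cfg),
        "ABG": abg,
        "gamma": gamma,
        "tau_ENL": tau_enl,
        "tau_theta": tau_theta,
    }


def srs(
    test: np.ndarray,
    reference: np.ndarray,
    dynamic_range: float = 1.0,
    edge_cfg: EdgeConfig = EdgeConfig(),
    ssim_cfg: SSIMConfig = SSIMConfig(),
) -> float:
    """Speckle Reduction Score: local similarity combined with edge
    preservation, ``SRS = 100 * mean(SSIM map) * FOM`` on a 0-100 scale.

    Stage 1 computes the per-window similarity map; stage 2 collapses it
    and weights the result by Pratt's FOM, so the score only saturates when
    the test image is both structurally close to the reference and keeps
    its edges in place.  The combination rule is this package's own pinned
    formula.
    """
    smap = ssim_map(test, reference, dynamic_range, ssim_cfg)
    fom = pratt_fom(test, reference, dynamic_range, edge_cfg)
    return float(100.0 * smap.mean() * fom)


def full_report(
    filtered: np.ndarray,
    noisy: np.ndarray,
    reference: np.ndarray | None = None,
    dynamic_range: float = 1.0,
    edge_cfg: EdgeConfig = EdgeConfig(),
    ssim_cfg: SSIMConfig = SSIMConfig(),
    nr_cfg: NRConfig = NRConfig(),
) -> dict:
    """FR metrics (when a reference exists) plus NR metrics, with metadata."""
    report: dict = {
        "no_reference": nr_suite(noisy, filtered, nr_cfg),
        "metadata": {
            "dynamic_range": dynamic_range,
            "ssim_window": ssim_cfg.win_size,
            "canny_sigma": edge_cfg.sigma,
            "canny_thresholds": [edge_cfg.low_threshold, edge_cfg.high_threshold],
            "dei_windows": [nr_cfg.narrow, nr_cfg.broad],
            "enl_tile": nr_cfg.enl_tile,
        },
    }
    if reference is not None:
        report["full_reference"] = fr_suite(
            filtered, reference, dynamic_range, edge_cfg, ssim_cfg
        )
    return report
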