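"""Independent direct-formula oracles shared by the metric tests.

Everything here is a literal, loop-level evaluation of the pinned metric
definitions, kept free of the package's own implementations.
"""

import numpy as np


def reflect(i, n):
    if i < 0:
        return -i - 1
    if i >= n:
        return 2 * n - i - 1
    return i


def laplacian_oracle(img):
    """4-neighbor Laplacian with edge-sample reflection."""
    h, w = img.shape
    out = np.zeros_like(img)
    for r in range(h):
        for c in range(w):
            out[r, c] = (
                img[reflect(r - 1, h), c]
                + img[reflect(r + 1, h), c]
                + img[r, reflect(c - 1, w)]
                + img[r, reflect(c + 1, w)]
                - 4.0 * img[r, c]
            )
    return out


def fr_oracle(test, ref, L):
    """Scalar evaluation of every non-windowed full-reference metric."""
    diff = ref - test
    mse = float(np.mean(diff**2))
    out = {
        "MSE": mse,
        "RMSE": float(np.sqrt(mse)),
        "PSNR": np.inf if mse == 0 else 10.0 * np.log10(L**2 / mse),
        "SNR": 10.0 * np.log10(np.sum(ref**2) / np.sum(diff**2)),
        "AD": float(np.mean(diff)),
        "MD": float(np.max(np.abs(diff))),
        "NAE": float(np.sum(np.abs(diff)) / np.sum(np.abs(ref))),
        "NK": float(np.sum(ref * test) / np.sum(ref**2)),
        "SC": float(np.sum(ref**2) / np.sum(test**2)),
    }
    rm, tm = ref.mean(), test.mean()
    out["CoC"] = float(
        np.sum((ref - rm) * (test - tm))
        / np.sqrt(np.sum((ref - rm) ** 2) * np.sum((test - tm) ** 2))
    )
    lap_r = laplacian_oracle(ref)
    lap_t = laplacian_oracle(test)
    out["LMSE"] = float(np.sum((lap_r - lap_t) ** 2) / np.sum(lap_r**2))
    return out


def uqi_oracle(test, ref, win=8):
    """Literal sliding-window universal quality index."""
    values = []
    h, w = test.shape
    for r in range(h - win + 1):
        for c in range(w - win + 1):
            x = test[r : r + win, c : c + win].ravel()
            y = ref[r : r + win, c : c + win].ravel()
            mx, my = x.mean(), y.mean()
            sx, sy = x.var(), y.var()
            sxy = float(np.mean((x - mx) * (y - my)))
            den = (sx + sy) * (mx**2 + my**2)
            if abs(den) > 1e-12:
                values.append(4.0 * sxy * mx * my / den)
    return float(np.mean(values))
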