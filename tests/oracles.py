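"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (double loops over pixels and lags)
and shares no code with the package's FFT / vectorized paths.
"""

from __future__ import annotations

import numpy as np


def bilateral_double_loop(
    frame: np.ndarray, window: int, sigma_space: float, sigma_intensity: float
) -> np.ndarray:
    """Direct double-loop bilateral filter with reflect padding."""
    half = window // 2
    padded = np.pad(frame, half, mode="reflect")
    out = np.empty_like(frame, dtype=float)
    h, w = frame.shape
    for y in range(h):
        for x in range(w):
            centre = frame[y, x]
            num = 0.0
            den = 0.0
            for dy in range(-half, half + 1):
                for dx in range(-half, half + 1):
                    val = padded[y + half + dy, x + half + dx]
                    wt = np.exp(-(dx * dx + dy * dy) / (2 * sigma_space**2)) * np.exp(
                        -((val - centre) ** 2) / (2 * sigma_intensity**2)
                    )
                    num += wt * val
                    den += wt
            out[y, x] = num / den
    return out


def direction_correlation_double_loop(gamma: np.ndarray):
    """Mean cos(angle difference) over all valid pixel pairs, per signed lag.

    Returns (r, counts) on lags -(H-1)..(H-1) x -(W-1)..(W-1); NaN entries
    of ``gamma`` are treated as undefined and excluded.
    """
    h, w = gamma.shape
    r = np.full((2 * h - 1, 2 * w - 1), np.nan)
    counts = np.zeros((2 * h - 1, 2 * w - 1))
    for dy in range(-(h - 1), h):
        for dx in range(-(w - 1), w):
            acc = 0.0
            n = 0
            for y in range(h):
                for x in range(w):
                    y2, x2 = y + dy, x + dx
                    if 0 <= y2 < h and 0 <= x2 < w:
                        a, b = gamma[y, x], gamma[y2, x2]
                        if np.isfinite(a) and np.isfinite(b):
                            acc += np.cos(a - b)
                            n += 1
            counts[dy + h - 1, dx + w - 1] = n
            if n:
                r[dy + h - 1, dx + w - 1] = acc / n
    return r, counts


def magnitude_correlation_double_loop(m: np.ndarray):
    """Pearson-style lag correlation of a scalar field, per signed lag.

    Mean-subtracted and normalized by the population variance over all
    pixels, matching a covariance-model reading of the correlation.
    """
    h, w = m.shape
    mu = m.mean()
    var = m.var()
    r = np.full((2 * h - 1, 2 * w - 1), np.nan)
    for dy in range(-(h - 1), h):
        for dx in range(-(w - 1), w):
            acc = 0.0
            n = 0
            for y in range(h):
                for x in range(w):
                    y2, x2 = y + dy, x + dx
                    if 0 <= y2 < h and 0 <= x2 < w:
                        acc += (m[y, x] - mu) * (m[y2, x2] - mu)
                        n += 1
            if n:
                r[dy + h - 1, dx + w - 1] = acc / n / var
    return r
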