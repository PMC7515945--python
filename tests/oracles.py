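"""Brute-force reference implementations used as independent test oracles.

Deliberately naive (explicit loops, direct convolution) and shared by the
unit and acceptance tests; they never call the library code paths they
check.
"""

from __future__ import annotations

import numpy as np


def block_sum(raster: np.ndarray, factor: int) -> np.ndarray:
    """Naive double-loop block summation with trailing-edge crop."""
    rows = raster.shape[0] // factor
    cols = raster.shape[1] // factor
    out = np.zeros((rows, cols), dtype=float)
    for i in range(rows):
        for j in range(cols):
            for u in range(factor):
                for v in range(factor):
                    out[i, j] += raster[i * factor + u, j * factor + v]
    return out


def median_filter_direct(img: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window median with symmetric (reflect) boundary."""
    r = window // 2
    padded = np.pad(img.astype(float), r, mode="symmetric")
    out = np.zeros_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.median(padded[i:i + window, j:j + window])
    return out


def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_filter_direct(img: np.ndarray, sigma: float) -> np.ndarray:
    """Separable direct convolution with reflect boundary (matches truncate=4)."""
    k = gaussian_kernel_1d(sigma)
    r = len(k) // 2
    padded = np.pad(img.astype(float), r, mode="symmetric")
    # rows then columns; symmetric padding commutes with per-axis filtering
    tmp = np.zeros((padded.shape[0], img.shape[1]))
    for i in range(padded.shape[0]):
        for j in range(img.shape[1]):
            tmp[i, j] = np.dot(padded[i, j:j + 2 * r + 1], k[::-1])
    out = np.zeros_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.dot(tmp[i:i + 2 * r + 1, j], k[::-1])
    return out


def roi_mean_loop(values: np.ndarray, mask: np.ndarray) -> float:
    total, n = 0.0, 0
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            if mask[i, j]:
                total += values[i, j]
                n += 1
    return total / n


def threshold_components(values: np.ndarray, threshold: float) -> list[set]:
    """4-connected components of {value > threshold} by breadth-first flood fill."""
    above = values > threshold
    seen = np.zeros_like(above, dtype=bool)
    comps = []
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            if above[i, j] and not seen[i, j]:
                comp, queue = set(), [(i, j)]
                seen[i, j] = True
                while queue:
                    r, c = queue.pop()
                    comp.add((r, c))
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < values.shape[0] and 0 <= cc < values.shape[1] \
                                and above[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            queue.append((rr, cc))
                comps.append(comp)
    return comps
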