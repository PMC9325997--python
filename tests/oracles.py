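"""Independent brute-force oracles used by the test suite.

Everything here is written deliberately *differently* from the package
implementation — plain Python loops, dense matrices, direct formulas —
so that agreement between the two routes is meaningful evidence.
"""

from __future__ import annotations

import math

import numpy as np


def brute_median(grid: np.ndarray, size: int) -> np.ndarray:
    """Per-pixel window sort with nearest-edge replication.

    Window offsets span [-(size // 2), ..., +((size - 1) // 2)]; the
    median of an even population is the upper middle order statistic.
    """
    grid = np.asarray(grid)
    h, w = grid.shape
    lo = -(size // 2)
    hi = size - 1 + lo
    out = np.empty_like(grid)
    for i in range(h):
        for j in range(w):
            vals = []
            for di in range(lo, hi + 1):
                for dj in range(lo, hi + 1):
                    ii = min(max(i + di, 0), h - 1)
                    jj = min(max(j + dj, 0), w - 1)
                    vals.append(grid[ii, jj])
            vals.sort()
            out[i, j] = vals[len(vals) // 2]
    return out


def global_equalize(img8: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Plain global histogram equalization onto [0, 255].

    Mapping = rounded cumulative histogram scaled by 255 / n_pixels —
    the limit CLAHE approaches with one tile and no clipping.
    """
    img8 = np.asarray(img8)
    assert img8.dtype == np.uint8
    hist, _ = np.histogram(img8, bins=n_bins, range=(0, 256))
    lut = np.rint(np.cumsum(hist) * (255.0 / img8.size))
    bins = (img8.astype(np.int64) * n_bins) >> 8
    return lut[bins].astype(np.uint8)


def naive_clahe(
    img8: np.ndarray,
    clip_limit: float = 12.0,
    tile_grid: tuple[int, int] = (10, 10),
    n_bins: int = 256,
) -> np.ndarray:
    """Loop-based CLAHE in the OpenCV convention.

    Per tile: histogram, clip at max(int(clip_limit * tile_pixels /
    n_bins), 1), redistribute the excess (uniform batch, then one count
    per stride max(n_bins // residual, 1)), LUT = rounded scaled
    cumulative histogram.  Per pixel: bilinear interpolation among the
    four nearest tile-center LUTs, computed with explicit scalar loops.
    """
    img8 = np.asarray(img8)
    assert img8.dtype == np.uint8
    h, w = img8.shape
    t_rows, t_cols = tile_grid
    tile_h = math.ceil(h / t_rows)
    tile_w = math.ceil(w / t_cols)
    padded = np.pad(img8, ((0, tile_h * t_rows - h), (0, tile_w * t_cols - w)), mode="edge")
    area = tile_h * tile_w
    if math.isfinite(clip_limit):
        clip = max(int(clip_limit * area / n_bins), 1)
    else:
        clip = area

    luts = []
    for r in range(t_rows):
        row_luts = []
        for c in range(t_cols):
            tile = padded[r * tile_h:(r + 1) * tile_h, c * tile_w:(c + 1) * tile_w]
            hist = [0] * n_bins
            for v in tile.ravel().tolist():
                hist[(v * n_bins) >> 8] += 1
            excess = 0
            for b in range(n_bins):
                if hist[b] > clip:
                    excess += hist[b] - clip
                    hist[b] = clip
            if excess:
                batch, residual = divmod(excess, n_bins)
                hist = [v + batch for v in hist]
                if residual:
                    step = max(n_bins // residual, 1)
                    i = 0
                    while residual > 0 and i < n_bins:
                        hist[i] += 1
                        residual -= 1
                        i += step
            lut = []
            acc = 0
            for b in range(n_bins):
                acc += hist[b]
                # round half to even, as numpy's rint does
                lut.append(float(np.rint(acc * 255.0 / area)))
            row_luts.append(lut)
        luts.append(row_luts)

    ph, pw = padded.shape
    out = np.empty((ph, pw), dtype=np.uint8)
    for y in range(ph):
        fy = (y + 0.5) / tile_h - 0.5
        r0 = math.floor(fy)
        wy = fy - r0
        r1 = min(max(r0 + 1, 0), t_rows - 1)
        r0 = min(max(r0, 0), t_rows - 1)
        for x in range(pw):
            fx = (x + 0.5) / tile_w - 0.5
            c0 = math.floor(fx)
            wx = fx - c0
            c1 = min(max(c0 + 1, 0), t_cols - 1)
            c0 = min(max(c0, 0), t_cols - 1)
            b = (int(padded[y, x]) * n_bins) >> 8
            val = (
                luts[r0][c0][b] * (1 - wy) * (1 - wx)
                + luts[r0][c1][b] * (1 - wy) * wx
                + luts[r1][c0][b] * wy * (1 - wx)
                + luts[r1][c1][b] * wy * wx
            )
            out[y, x] = min(max(int(np.rint(val)), 0), 255)
    return out[:h, :w]


def dense_pca_components(
    channels: list[np.ndarray], n_components: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Eigen-images via the dense pixel-space covariance matrix.

    Builds the full n_pixels x n_pixels scatter matrix of the centered
    channel observations and eigendecomposes it directly — feasible only
    for tiny images, which is the point.  Returns (components, ratios);
    component signs are unconstrained.
    """
    X = np.stack([np.asarray(c, dtype=np.float64).ravel() for c in channels])
    Xc = X - X.mean(axis=0, keepdims=True)
    scatter = Xc.T @ Xc  # n_pixels x n_pixels
    eigvals, eigvecs = np.linalg.eigh(scatter)
    order = np.argsort(eigvals)[::-1][:n_components]
    shape = np.asarray(channels[0]).shape
    comps = [eigvecs[:, i].reshape(shape) for i in order]
    total = eigvals.sum()
    ratios = eigvals[order] / total
    return comps, ratios
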