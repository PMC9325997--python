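"""The two preprocessing branches feeding the spectral PCA.

Both branches operate per channel, independently, and are followed by the
same median filter:

* **Std** — each image row is standardized to zero mean and unit
  (population) standard deviation across its x-axis pixels.  This
  resamples the signal line by line and accentuates within-row tissue
  contrast, at the price of amplified noise where a row crosses no
  structure of interest.
* **CLAHE** — contrast-limited adaptive histogram equalization: per-tile
  histogram equalization with a clip limit on bin counts (the clipped
  excess is redistributed), and bilinear interpolation between the
  mappings of neighbouring tiles to suppress block artifacts.  CLAHE
  raises inter-structure contrast while keeping a better signal-to-noise
  ratio than row standardization.

The CLAHE operator follows the OpenCV convention throughout — normalized
clip limit ``clip_limit * tile_pixels / n_bins`` (truncated, minimum 1),
OpenCV's residual redistribution scheme, and mapping LUTs built as the
rounded cumulative histogram scaled onto [0, 255] — so the canonical
parameters (clip limit 12.0, tile grid 10x10) reproduce the contrast that
convention implies.  16-bit and float inputs are first min-max rescaled
onto the 8-bit domain, making the quantization explicit and reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .exceptions import ParameterError
from .io import ChannelImage, SpectralCube

Branch = Literal["std", "clahe"]

#: Canonical defaults for the pipeline: CLAHE clip limit / tile grid and
#: the size of the median filter applied after either branch.
DEFAULT_CLIP_LIMIT = 12.0
DEFAULT_TILE_GRID = (10, 10)
DEFAULT_MEDIAN_SIZE = 4


@dataclass(frozen=True)
class ClaheParams:
    """Parameters of the contrast-limited adaptive equalization operator.

    ``clip_limit`` uses the OpenCV-style normalized convention: the actual
    per-bin ceiling is ``clip_limit * tile_pixels / n_bins`` counts, so the
    limit is relative to both tile size and bin count.  ``tile_grid`` is
    (rows, cols) of tiles.  ``border_policy`` names how non-divisible image
    dimensions are handled; only edge replication is implemented.
    """

    clip_limit: float = DEFAULT_CLIP_LIMIT
    tile_grid: tuple[int, int] = DEFAULT_TILE_GRID
    n_bins: int = 256
    border_policy: str = "replicate_pad"

    def __post_init__(self) -> None:
        if not self.clip_limit > 0:
            raise ParameterError(f"clip_limit must be > 0, got {self.clip_limit}")
        rows, cols = self.tile_grid
        if rows < 1 or cols < 1:
            raise ParameterError(f"tile_grid components must be >= 1, got {self.tile_grid}")
        if self.n_bins < 2:
            raise ParameterError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.border_policy != "replicate_pad":
            raise ParameterError(f"unsupported border_policy {self.border_policy!r}")


@dataclass
class PreprocessedCube:
    """Per-channel output of one preprocessing branch, pre-PCA.

    Same geometry and channel order as the source cube; ``params_echo``
    records the exact parameters used, for provenance.
    """

    channels: list[np.ndarray]
    channel_names: list[str]
    branch: Branch
    params_echo: dict = field(default_factory=dict)

    @property
    def height(self) -> int:
        return self.channels[0].shape[0]

    @property
    def width(self) -> int:
        return self.channels[0].shape[1]

    @property
    def n_channels(self) -> int:
        return len(self.channels)


def _pixels_of(image) -> np.ndarray:
    return image.pixels if isinstance(image, ChannelImage) else np.asarray(image)


def std_scale_rows(image: ChannelImage | np.ndarray) -> np.ndarray:
    """Standardize each row to mean 0, population std 1 across its pixels.

    Rows with zero variance carry no within-row contrast and are mapped to
    all zeros rather than NaN, so degenerate rows do not poison the PCA.
    """
    px = _pixels_of(image).astype(np.float64)
    mean = px.mean(axis=1, keepdims=True)
    std = px.std(axis=1, keepdims=True)  # ddof=0: population convention
    out = np.zeros_like(px)
    # constancy via max == min, not std > 0: summation rounding can give a
    # bit-identical row a spuriously nonzero std
    ok = (px.max(axis=1) > px.min(axis=1)) & (std[:, 0] > 0)
    out[ok] = (px[ok] - mean[ok]) / std[ok]
    return out


def _quantize_to_8bit(image: ChannelImage | np.ndarray) -> np.ndarray:
    """Map a channel onto the uint8 domain CLAHE operates in.

    uint8 data passes through untouched; 16-bit and float data are linearly
    min-max rescaled onto [0, 255] and rounded (half to even).  A constant
    image maps to zeros.
    """
    px = _pixels_of(image)
    if px.dtype == np.uint8:
        return px
    px = px.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        return np.zeros(px.shape, dtype=np.uint8)
    return np.rint((px - lo) * (255.0 / (hi - lo))).astype(np.uint8)


def _clip_histogram(hist: np.ndarray, clip: int) -> np.ndarray:
    """Clip bins at ``clip`` and redistribute the excess, OpenCV-style.

    The bulk of the excess is spread uniformly; the remainder is dropped
    one count at a time onto bins 0, s, 2s, ... with stride
    ``max(n_bins // residual, 1)``.  No re-clipping pass is made, so bins
    may end slightly above the clip value.
    """
    n_bins = hist.size
    over = hist > clip
    excess = int((hist[over] - clip).sum())
    out = np.minimum(hist, clip)
    if excess == 0:
        return out
    batch, residual = divmod(excess, n_bins)
    out = out + batch
    if residual:
        step = max(n_bins // residual, 1)
        idx = np.arange(0, n_bins, step)[:residual]
        out[idx] += 1
    return out


def clahe(image: ChannelImage | np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization onto [0, 255].

    Steps: quantize to 8 bits; edge-replicate pad so height and width
    divide into the tile grid; build one clipped-and-redistributed
    histogram per tile; turn each into a lookup table (cumulative
    histogram scaled to [0, 255], rounded); map every pixel by bilinear
    interpolation among the LUTs of the four nearest tile centers
    (degrading to linear/nearest at borders and corners); crop the
    padding.
    """
    if params is None:
        params = ClaheParams()
    img8 = _quantize_to_8bit(image)
    h, w = img8.shape
    t_rows, t_cols = params.tile_grid
    if t_rows > h or t_cols > w:
        raise ParameterError(
            f"tile grid {params.tile_grid} larger than image {h}x{w} in at least one axis"
        )
    n_bins = params.n_bins

    tile_h = math.ceil(h / t_rows)
    tile_w = math.ceil(w / t_cols)
    pad_h = tile_h * t_rows - h
    pad_w = tile_w * t_cols - w
    padded = np.pad(img8, ((0, pad_h), (0, pad_w)), mode="edge")

    # bin index per pixel; identity for the canonical 256-bin case
    bins = (padded.astype(np.int64) * n_bins) >> 8

    tile_pixels = tile_h * tile_w
    if math.isfinite(params.clip_limit):
        clip = max(int(params.clip_limit * tile_pixels / n_bins), 1)
    else:
        clip = tile_pixels  # no bin can exceed the tile population: no clipping

    # one LUT per tile: clipped histogram -> scaled cumulative mapping
    luts = np.empty((t_rows, t_cols, n_bins), dtype=np.float64)
    scale = 255.0 / tile_pixels
    tiled = bins.reshape(t_rows, tile_h, t_cols, tile_w)
    for r in range(t_rows):
        for c in range(t_cols):
            hist = np.bincount(tiled[r, :, c, :].ravel(), minlength=n_bins)
            hist = _clip_histogram(hist, clip)
            luts[r, c] = np.rint(np.cumsum(hist) * scale)

    # bilinear interpolation among the 4 nearest tile-center mappings
    ph, pw = padded.shape
    fy = (np.arange(ph) + 0.5) / tile_h - 0.5
    fx = (np.arange(pw) + 0.5) / tile_w - 0.5
    y0 = np.floor(fy).astype(np.int64)
    x0 = np.floor(fx).astype(np.int64)
    wy = (fy - y0)[:, None]
    wx = (fx - x0)[None, :]
    y0c = np.clip(y0, 0, t_rows - 1)[:, None]
    y1c = np.clip(y0 + 1, 0, t_rows - 1)[:, None]
    x0c = np.clip(x0, 0, t_cols - 1)[None, :]
    x1c = np.clip(x0 + 1, 0, t_cols - 1)[None, :]

    out = (
        luts[y0c, x0c, bins] * (1 - wy) * (1 - wx)
        + luts[y0c, x1c, bins] * (1 - wy) * wx
        + luts[y1c, x0c, bins] * wy * (1 - wx)
        + luts[y1c, x1c, bins] * wy * wx
    )
    result = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return result[:h, :w]


def median_filter(grid: np.ndarray, size: int) -> np.ndarray:
    """Median rank filter with an explicit even-size convention.

    The window of an output pixel spans offsets ``[-(size // 2), ...,
    +((size - 1) // 2)]`` in each axis (for size 4: -2..+1, the common
    origin-0 rank-filter layout).  Out-of-bounds samples replicate the
    nearest edge.  For even window populations the *upper* of the two
    middle order statistics is taken (sorted index ``n // 2``, 0-based) —
    the median is always a member of the window, never an average.
    """
    if size < 1:
        raise ParameterError(f"median filter size must be >= 1, got {size}")
    grid = np.asarray(grid)
    if size == 1:
        return grid.copy()
    before = size // 2
    after = size - 1 - before
    padded = np.pad(grid, ((before, after), (before, after)), mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (size, size))
    flat = windows.reshape(*grid.shape, size * size)
    k = (size * size) // 2
    return np.partition(flat, k, axis=-1)[..., k]


def preprocess(
    cube: SpectralCube,
    branch: Branch,
    clahe_params: ClaheParams | None = None,
    median_size: int = DEFAULT_MEDIAN_SIZE,
) -> PreprocessedCube:
    """Apply one branch (std | clahe) then the median filter, per channel.

    The branch operator and the median filter both act on every channel
    independently; the filter always runs after the branch operator.
    """
    if branch not in ("std", "clahe"):
        raise ParameterError(f"branch must be 'std' or 'clahe', got {branch!r}")
    if clahe_params is None:
        clahe_params = ClaheParams()
    out: list[np.ndarray] = []
    for ch in cube.channels:
        if branch == "std":
            plane = std_scale_rows(ch)
        else:
            plane = clahe(ch, clahe_params).astype(np.float64)
        out.append(median_filter(plane, median_size))
    echo: dict = {"branch": branch, "median_size": median_size}
    if branch == "clahe":
        echo.update(
            clip_limit=clahe_params.clip_limit,
            tile_grid=tuple(clahe_params.tile_grid),
            n_bins=clahe_params.n_bins,
            border_policy=clahe_params.border_policy,
        )
    return PreprocessedCube(
        channels=out,
        channel_names=cube.channel_names,
        branch=branch,
        params_echo=echo,
    )
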