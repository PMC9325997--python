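"""Reading, writing and assembly of single-channel images and spectral cubes.

A *spectral cube* is the ordered stack of co-registered single-channel
acquisitions (typically blue, green, red and NIR emission) that the
enhancement pipeline consumes.  Channels are assumed co-registered, as is
the case for filter-wheel acquisition in front of a single camera; no
registration is attempted here.

Coordinate convention: row index = y (top to bottom), column index = x
(left to right), 0-based — i.e. plain raster order.  "Along the x-axis"
therefore means "within one image row".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import imageio.v3 as iio
import numpy as np
import tifffile

from .exceptions import FormatError, GeometryError, ValidationError

#: Default channel naming, by emission band, in acquisition order.
DEFAULT_CHANNEL_NAMES = ("blue", "green", "red", "nir")

_TIFF_EXTENSIONS = {".tif", ".tiff"}
_PNG_EXTENSIONS = {".png"}

BitDepth = Union[int, str]  # 8, 16 or "float"


def _bit_depth_of(dtype: np.dtype) -> BitDepth:
    dtype = np.dtype(dtype)
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    if dtype.kind == "f":
        return "float"
    raise FormatError(
        f"unsupported sample format {dtype}: expected uint8, uint16 or float"
    )


@dataclass
class ChannelImage:
    """One single-channel grayscale acquisition.

    Parameters
    ----------
    pixels
        2D array of intensities (unitless detector counts).
    channel_name
        Emission-band name; ``blue``/``green``/``red``/``nir`` by convention,
        any unique string is accepted.
    bit_depth
        8 or 16 for unsigned-integer data, ``"float"`` for real-valued
        intermediates (which bypass the integer range check).
    pixel_size_um
        Optional physical pixel pitch in micrometres.  Carried as metadata
        only; no computation uses it.
    """

    pixels: np.ndarray
    channel_name: str
    bit_depth: BitDepth = 8
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(
                f"channel {self.channel_name!r}: expected a 2D image, "
                f"got ndim={self.pixels.ndim}"
            )
        h, w = self.pixels.shape
        if h < 1 or w < 1:
            raise ValidationError(
                f"channel {self.channel_name!r}: empty image {h}x{w}"
            )
        if self.bit_depth not in (8, 16, "float"):
            raise ValidationError(
                f"channel {self.channel_name!r}: bit_depth must be 8, 16 or "
                f"'float', got {self.bit_depth!r}"
            )
        if self.bit_depth != "float":
            full = 2 ** int(self.bit_depth) - 1
            lo, hi = self.pixels.min(), self.pixels.max()
            if lo < 0 or hi > full:
                raise ValidationError(
                    f"channel {self.channel_name!r}: intensities [{lo}, {hi}] "
                    f"exceed the [0, {full}] range of {self.bit_depth}-bit data"
                )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def full_scale(self) -> float:
        """Maximum representable intensity (255, 65535, or 1.0 for float)."""
        if self.bit_depth == "float":
            return 1.0
        return float(2 ** int(self.bit_depth) - 1)


@dataclass
class SpectralCube:
    """Ordered, co-registered stack of :class:`ChannelImage`.

    Order is semantic: it fixes the loading indices reported by the PCA
    downstream, so the cube never reorders its channels.
    """

    channels: list[ChannelImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.channels) < 2:
            raise ValidationError(
                f"a spectral cube needs at least 2 channels, got {len(self.channels)}"
            )
        shapes = [(c.channel_name, c.height, c.width) for c in self.channels]
        h0, w0 = shapes[0][1], shapes[0][2]
        if any(h != h0 or w != w0 for _, h, w in shapes):
            detail = ", ".join(f"{n}: {h}x{w}" for n, h, w in shapes)
            raise GeometryError(f"channel dimensions differ: {detail}")
        names = [c.channel_name for c in self.channels]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate channel names: {dupes}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def height(self) -> int:
        return self.channels[0].height

    @property
    def width(self) -> int:
        return self.channels[0].width

    @property
    def channel_names(self) -> list[str]:
        return [c.channel_name for c in self.channels]

    def as_array(self) -> np.ndarray:
        """Stack as a (n_channels, height, width) float64 array."""
        return np.stack([c.pixels.astype(np.float64) for c in self.channels])


def read_channel(path: str | Path, channel_name: str) -> ChannelImage:
    """Read a single-plane grayscale TIFF or PNG as a :class:`ChannelImage`.

    Multi-plane or RGB(A) files are rejected: one acquisition channel is one
    2D plane by construction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"channel file not found: {path}")
    ext = path.suffix.lower()
    if ext in _TIFF_EXTENSIONS:
        data = tifffile.imread(path)
    elif ext in _PNG_EXTENSIONS:
        data = iio.imread(path)
    else:
        raise FormatError(f"unsupported image extension {ext!r} (use TIFF or PNG)")
    data = np.asarray(data)
    if data.ndim == 3:
        if data.shape[-1] in (3, 4):
            raise FormatError(
                f"{path.name}: {data.shape[-1]}-sample (RGB/RGBA) image; "
                "expected a single-plane grayscale channel"
            )
        raise FormatError(
            f"{path.name}: multi-plane image with {data.shape[0]} planes; "
            "expected a single-plane grayscale channel"
        )
    if data.ndim != 2:
        raise FormatError(f"{path.name}: expected 2D image data, got ndim={data.ndim}")
    return ChannelImage(
        pixels=data, channel_name=channel_name, bit_depth=_bit_depth_of(data.dtype)
    )


def write_channel(image: ChannelImage, path: str | Path) -> None:
    """Write one channel as grayscale TIFF or PNG, preserving its dtype."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _TIFF_EXTENSIONS:
        tifffile.imwrite(path, image.pixels)
    elif ext in _PNG_EXTENSIONS:
        if image.bit_depth == "float":
            raise FormatError("PNG cannot store float data; use TIFF")
        iio.imwrite(path, image.pixels)
    else:
        raise FormatError(f"unsupported image extension {ext!r} (use TIFF or PNG)")


def assemble_cube(images: Sequence[ChannelImage]) -> SpectralCube:
    """Stack channel images into a :class:`SpectralCube`, preserving order."""
    return SpectralCube(channels=list(images))


def _as_rgb_array(rgb) -> np.ndarray:
    """Accept an RGBComposite or an (H, W, 3) / (3, H, W) uint8 array."""
    planes = getattr(rgb, "planes", None)
    if planes is not None:
        arr = np.stack(planes, axis=-1)
    else:
        arr = np.asarray(rgb)
        if arr.ndim == 3 and arr.shape[0] == 3 and arr.shape[-1] != 3:
            arr = np.moveaxis(arr, 0, -1)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise FormatError(f"expected 3 RGB planes, got array of shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise FormatError(f"composite planes must be 8-bit, got {arr.dtype}")
    return arr


def write_composite(rgb, path: str | Path) -> None:
    """Write an 8-bit RGB composite as TIFF or PNG, chosen by extension.

    The write is lossless: re-reading yields identical samples per plane.
    """
    path = Path(path)
    arr = _as_rgb_array(rgb)
    ext = path.suffix.lower()
    if ext in _TIFF_EXTENSIONS:
        tifffile.imwrite(path, arr, photometric="rgb")
    elif ext in _PNG_EXTENSIONS:
        iio.imwrite(path, arr)
    else:
        raise FormatError(f"unsupported composite extension {ext!r} (use TIFF or PNG)")


def read_composite(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB composite back as an (H, W, 3) uint8 array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"composite file not found: {path}")
    ext = path.suffix.lower()
    if ext in _TIFF_EXTENSIONS:
        arr = tifffile.imread(path)
    elif ext in _PNG_EXTENSIONS:
        arr = iio.imread(path)
    else:
        raise FormatError(f"unsupported composite extension {ext!r}")
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise FormatError(f"{path.name}: expected an RGB image, got shape {arr.shape}")
    return arr


def read_label_map(path: str | Path) -> np.ndarray:
    """Read an integer label map stored as a single-plane TIFF/PNG."""
    img = read_channel(path, channel_name="labels")
    if img.bit_depth == "float":
        raise FormatError(f"{Path(path).name}: label maps must be integer-typed")
    return img.pixels.astype(np.int64)
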