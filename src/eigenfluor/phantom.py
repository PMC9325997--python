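"""Synthetic labeled tissue phantoms for the 4-channel acquisition model.

A phantom emulates the statistical structure of a stained periodontal
thick-section imaged through four emission filters (blue, green, red,
NIR):

* spatially structured regions standing in for tooth root, alveolar
  bone, periodontal ligament, gingiva and background;
* per-tissue 4-channel spectral signatures with *crosstalk* — each dye's
  emission leaks into neighbouring passbands, modeled by a row-stochastic
  mixing matrix applied to the signature;
* a low, uniform autofluorescence background, well below the labeling
  signal;
* a gentle multiplicative illumination tilt across the field;
* CCD-like noise: Poisson shot noise at a fixed photon budget plus
  additive Gaussian read noise, clipped and quantized to the stored bit
  depth.

Generation is a pure function of the spec (including its seed): the same
spec yields bit-identical cubes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .exceptions import ParameterError, ValidationError
from .io import ChannelImage, SpectralCube, assemble_cube

Geometry = Literal["band", "annulus", "voronoi_seeded"]

#: Default per-tissue emission signatures, as fractions of full scale in
#: (blue, green, red, nir) order.  Mineralized tissue (root, bone) is
#: bright in the blue/UV-excited channel (autofluorescence + calcein) and
#: dim in red/NIR; soft tissue (ligament, gingiva) dominates red/NIR
#: (SRB, WGA, TO-PRO3 nuclear stain); background is near-dark.  The five
#: dyes were picked for complementary contrasts, so the class structure
#: is deliberately three-dimensional in channel space (no single channel
#: orders all five tissues).
DEFAULT_TISSUES: tuple[tuple[str, tuple[float, ...]], ...] = (
    ("root", (0.80, 0.55, 0.25, 0.10)),
    ("bone", (0.65, 0.40, 0.45, 0.20)),
    ("ligament", (0.30, 0.50, 0.65, 0.40)),
    ("gingiva", (0.25, 0.65, 0.40, 0.60)),
    ("background", (0.05, 0.05, 0.05, 0.05)),
)


def default_crosstalk(n_channels: int = 4, leakage: float = 0.15) -> np.ndarray:
    """Row-stochastic mixing matrix with uniform off-diagonal leakage."""
    off = leakage
    diag = 1.0 - off * (n_channels - 1)
    if diag <= 0:
        raise ParameterError(f"leakage {leakage} too large for {n_channels} channels")
    m = np.full((n_channels, n_channels), off)
    np.fill_diagonal(m, diag)
    return m


@dataclass
class PhantomSpec:
    """Full generative description of one synthetic acquisition.

    ``tissues`` is an ordered list of (name, signature) pairs; signatures
    are per-channel emission strengths in [0, 1] fractions of full scale.
    ``geometry`` selects how the tissue regions partition the image:
    ``band`` (horizontal bands in list order), ``annulus`` (nested rings,
    first tissue innermost — the default, mimicking root wrapped in
    ligament, bone and gingiva), or ``voronoi_seeded`` (random convex
    cells).  ``illumination_gradient`` is the maximum relative
    multiplicative tilt across the width.  ``photon_budget`` is the mean
    photon count at full scale used for Poisson resampling, decoupling
    shot-noise magnitude from the stored bit depth.
    """

    height: int = 1040
    width: int = 1392
    tissues: Sequence[tuple[str, Sequence[float]]] = DEFAULT_TISSUES
    channel_names: Sequence[str] = ("blue", "green", "red", "nir")
    geometry: Geometry = "band"
    crosstalk: np.ndarray | None = None
    autofluorescence_level: float = 0.05
    gaussian_sd: float = 0.02
    poisson: bool = True
    illumination_gradient: float = 0.3
    bit_depth: int = 16
    seed: int = 0
    photon_budget: int = 2_000

    def __post_init__(self) -> None:
        k = len(self.channel_names)
        if self.height < 1 or self.width < 1:
            raise ParameterError(f"empty phantom geometry {self.height}x{self.width}")
        if len(self.tissues) < 1:
            raise ParameterError("at least one tissue is required")
        if self.crosstalk is None:
            self.crosstalk = default_crosstalk(k)
        self.crosstalk = np.asarray(self.crosstalk, dtype=np.float64)
        if self.crosstalk.shape != (k, k):
            raise ValidationError(
                f"crosstalk must be {k}x{k} for {k} channels, got {self.crosstalk.shape}"
            )
        row_sums = self.crosstalk.sum(axis=1)
        bad = np.nonzero(np.abs(row_sums - 1.0) > 1e-9)[0]
        if bad.size:
            raise ValidationError(
                f"crosstalk rows {bad.tolist()} are not stochastic "
                f"(sums {row_sums[bad].tolist()})"
            )
        for name, sig in self.tissues:
            sig = np.asarray(sig, dtype=np.float64)
            if sig.shape != (k,):
                raise ValidationError(
                    f"tissue {name!r}: signature length {sig.size} != {k} channels"
                )
            if sig.min() < 0 or sig.max() > 1:
                raise ValidationError(
                    f"tissue {name!r}: signature values must lie in [0, 1]"
                )
        if not 0 <= self.autofluorescence_level <= 1:
            raise ValidationError("autofluorescence_level must lie in [0, 1]")
        if self.gaussian_sd < 0 or self.illumination_gradient < 0:
            raise ValidationError("noise and gradient levels must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ParameterError(f"bit_depth must be 8 or 16, got {self.bit_depth}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def tissue_names(self) -> list[str]:
        return [name for name, _ in self.tissues]

    def signature_matrix(self) -> np.ndarray:
        """(n_tissues, n_channels) pre-crosstalk signature matrix."""
        return np.asarray([sig for _, sig in self.tissues], dtype=np.float64)


def _label_map(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Partition the image into tissue labels (one label per pixel)."""
    h, w, n = spec.height, spec.width, len(spec.tissues)
    yy, xx = np.mgrid[0:h, 0:w]
    if spec.geometry == "band":
        # vertical bands: every row crosses the full tissue sequence, the
        # layout row-wise standardization is designed for
        edges = np.linspace(0, w, n + 1)
        return np.minimum(np.searchsorted(edges, xx, side="right") - 1, n - 1)
    if spec.geometry == "annulus":
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        r = np.hypot((yy - cy) / max(h / 2.0, 1), (xx - cx) / max(w / 2.0, 1))
        # nested rings at equal radial steps; everything beyond the last
        # ring boundary belongs to the outermost (last) tissue
        edges = np.linspace(0, 1.0, n + 1)[1:-1]
        return np.searchsorted(edges, r, side="right").clip(max=n - 1)
    if spec.geometry == "voronoi_seeded":
        seeds_y = rng.uniform(0, h, size=n)
        seeds_x = rng.uniform(0, w, size=n)
        d2 = (yy[..., None] - seeds_y) ** 2 + (xx[..., None] - seeds_x) ** 2
        return np.argmin(d2, axis=-1)
    raise ParameterError(f"unknown geometry {spec.geometry!r}")


def generate_phantom(spec: PhantomSpec) -> tuple[SpectralCube, np.ndarray]:
    """Generate one synthetic acquisition and its ground-truth label map.

    Per pixel of tissue t the mean intensity vector is
    ``crosstalk @ signature(t) + autofluorescence``, modulated by the
    illumination tilt, Poisson-resampled (if enabled), perturbed by
    Gaussian read noise, clipped to [0, 1] fractions and quantized to the
    requested bit depth.  Returns ``(cube, labels)`` with labels indexing
    ``spec.tissues``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _label_map(spec, rng)
    mixed = spec.signature_matrix() @ spec.crosstalk.T  # (tissues, channels)
    mixed = np.clip(mixed + spec.autofluorescence_level, 0.0, 1.0)
    mean = mixed[labels]  # (H, W, k) fractional means

    if spec.illumination_gradient > 0:
        # per-row multiplicative tilt (top bright, bottom dim), emulating
        # uneven field illumination across the slow axis
        tilt = 1.0 - spec.illumination_gradient * (
            np.arange(spec.height) / max(spec.height - 1, 1)
        )
        mean = mean * tilt[:, None, None]

    if spec.poisson:
        frac = rng.poisson(mean * spec.photon_budget) / spec.photon_budget
    else:
        frac = mean.copy()
    if spec.gaussian_sd > 0:
        frac = frac + rng.normal(0.0, spec.gaussian_sd, size=frac.shape)

    full = 2**spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    quantized = np.rint(np.clip(frac, 0.0, 1.0) * full).astype(dtype)

    channels = [
        ChannelImage(
            pixels=quantized[..., i],
            channel_name=name,
            bit_depth=spec.bit_depth,
        )
        for i, name in enumerate(spec.channel_names)
    ]
    return assemble_cube(channels), labels.astype(np.int64)
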