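"""Channel-as-observation PCA: eigen-images and the RGB composite.

The decomposition here is deliberately *not* the per-pixel-spectrum PCA
common in hyperspectral work.  Each preprocessed channel, flattened to a
pixel-length vector in row-major order, is one observation; with a
1392x1040 acquisition the observations live in a 1,447,680-dimensional
vector space.  The principal axes therefore live in *pixel* space and
reshape back into rectangular "eigen-images", each carrying a
tissue-discriminating contrast pattern.  The top three eigen-images,
min-max normalized onto [0, 255], become the red, green and blue planes
of a false-color composite.

With only a handful of channel observations the decomposition is done
exactly through the k x k Gram matrix (k = channel count) rather than an
iterative SVD of the huge k x n_pixels matrix: for X centered over
observations, the eigenvectors u_i of G = X X^T give the pixel-space
axes v_i = X^T u_i / sqrt(lambda_i).  This is exact, cheap and
bit-stable, which makes composites reproducible run to run.

Sign convention: an eigenvector's sign is arbitrary, so each component is
flipped, if needed, such that its largest-magnitude channel loading is
positive (ties broken by lowest channel index).  No whitening is applied;
eigen-images are unit-norm axes before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .exceptions import DegenerateInputError, ParameterError
from .preprocess import PreprocessedCube

#: Relative eigenvalue threshold below which a component is treated as
#: null (its eigen-image is a zero grid and its loadings are zero).
_NULL_EIGENVALUE_RTOL = 1e-12


@dataclass
class EigenImageSet:
    """Retained eigen-images with their loadings and variance shares.

    ``components[i]`` is the i-th principal axis reshaped to image
    geometry; ``loadings[i, c]`` is the coordinate of centered channel c
    on that axis; ``explained_variance_ratio`` is non-increasing and sums
    to at most 1 (exactly 1 when n_components >= rank).
    """

    components: list[np.ndarray]
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    branch: str
    channel_names: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass
class RGBComposite:
    """8-bit false-color composite: PC1 -> red, PC2 -> green, PC3 -> blue."""

    planes: list[np.ndarray]  # [red, green, blue], each uint8 HxW
    branch: str

    @property
    def height(self) -> int:
        return self.planes[0].shape[0]

    @property
    def width(self) -> int:
        return self.planes[0].shape[1]

    def as_array(self) -> np.ndarray:
        """(H, W, 3) uint8 view suitable for writing."""
        return np.stack(self.planes, axis=-1)


def flatten_row_major(grid: np.ndarray) -> np.ndarray:
    """Flatten a 2D grid to 1D by concatenating rows (C order).

    Element ``k`` of the result is ``grid[k // width][k % width]``; a
    1392x1040 channel becomes a vector of length 1,447,680.
    """
    grid = np.asarray(grid)
    if grid.ndim != 2 or grid.size == 0:
        raise ParameterError(f"expected a nonempty 2D grid, got shape {grid.shape}")
    return grid.ravel(order="C")


def spectral_pca(pre: PreprocessedCube, n_components: int = 3) -> EigenImageSet:
    """Decompose a preprocessed cube into its top eigen-images.

    Builds the k x n_pixels observation matrix of flattened channels,
    centers it by subtracting the per-pixel mean across channels, and
    extracts the leading pixel-space principal axes via the exact Gram
    eigendecomposition (see module docstring).  Components whose
    eigenvalue is numerically zero come back as zero grids with zero
    loadings — centering k observations leaves rank at most k - 1, so
    with 4 channels the 3 retained ratios always sum to 1.
    """
    k = pre.n_channels
    if n_components > k:
        raise ParameterError(
            f"n_components={n_components} exceeds the {k} channel observations"
        )
    if n_components < 1:
        raise ParameterError(f"n_components must be >= 1, got {n_components}")
    shape = pre.channels[0].shape
    X = np.stack([flatten_row_major(ch).astype(np.float64) for ch in pre.channels])
    Xc = X - X.mean(axis=0, keepdims=True)

    gram = Xc @ Xc.T
    total_var = float(np.trace(gram))
    if total_var <= 0 or not np.isfinite(total_var):
        raise DegenerateInputError(
            "all channels are constant after preprocessing: zero total variance"
        )
    eigvals, eigvecs = np.linalg.eigh(gram)  # ascending
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    lam_max = eigvals[0]
    components: list[np.ndarray] = []
    loadings = np.zeros((n_components, k))
    ratios = np.zeros(n_components)
    for i in range(n_components):
        lam = eigvals[i]
        if lam <= lam_max * _NULL_EIGENVALUE_RTOL:
            components.append(np.zeros(shape))
            continue
        u = eigvecs[:, i]
        # deterministic sign: largest-|loading| channel positive; the
        # loadings are sqrt(lam) * u, so the rule reduces to u itself
        j = int(np.argmax(np.abs(u)))  # argmax takes the lowest index on ties
        if u[j] < 0:
            u = -u
        axis = (Xc.T @ u) / np.sqrt(lam)
        components.append(axis.reshape(shape))
        loadings[i] = np.sqrt(lam) * u
        ratios[i] = lam / total_var
    return EigenImageSet(
        components=components,
        loadings=loadings,
        explained_variance_ratio=ratios,
        branch=pre.branch,
        channel_names=list(pre.channel_names),
    )


def normalize_to_255(component: np.ndarray) -> np.ndarray:
    """Affine min-max map of a component onto [0, 255] as uint8.

    Rounds half to even; a constant component maps to all zeros.
    """
    component = np.asarray(component, dtype=np.float64)
    if component.size == 0:
        raise ParameterError("cannot normalize an empty component")
    lo, hi = component.min(), component.max()
    if hi == lo:
        return np.zeros(component.shape, dtype=np.uint8)
    scaled = (component - lo) * (255.0 / (hi - lo))
    return np.rint(scaled).astype(np.uint8)


def compose_rgb(eigen: EigenImageSet) -> RGBComposite:
    """Merge the three eigen-images into the false-color composite.

    Principal components 1, 2 and 3 become the red, green and blue
    planes respectively, each min-max normalized to [0, 255].
    """
    if eigen.n_components != 3:
        raise ParameterError(
            f"an RGB composite needs exactly 3 components, got {eigen.n_components}"
        )
    planes = [normalize_to_255(c) for c in eigen.components]
    return RGBComposite(planes=planes, branch=eigen.branch)
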