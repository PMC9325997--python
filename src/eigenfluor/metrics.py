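"""Class-separability scoring of a composite against a label map.

The enhancement claim — that the false-color composite discriminates
tissues better than any single raw channel — is quantified by a Fisher
scatter ratio: treating each pixel's plane values as a vector, the score
is trace(S_b) / trace(S_w), where S_b is the between-class scatter of
the class mean vectors (weighted by class pixel counts) and S_w the
pooled within-class scatter.  The trace ratio stays defined when a plane
is near-constant (where a determinant ratio would collapse); it is
invariant under translations, orthogonal maps and uniform rescaling
applied identically to all pixel vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, GeometryError

#: Score reported when classes have distinct means but zero within-class
#: scatter (e.g. planes exactly constant per class).
INFINITE_SEPARABILITY = float("inf")


@dataclass
class SeparabilityReport:
    """Between/within scatter summary of a set of planes vs. ground truth."""

    score: float
    per_class_means: np.ndarray  # (n_classes, n_planes)
    class_labels: np.ndarray  # (n_classes,) original label values
    class_counts: np.ndarray  # (n_classes,) pixels per class
    n_classes: int

    def to_dict(self) -> dict:
        """JSON-friendly view; an infinite score serializes as 'inf'."""
        return {
            "score": "inf" if np.isinf(self.score) else float(self.score),
            "n_classes": int(self.n_classes),
            "class_labels": self.class_labels.tolist(),
            "class_counts": self.class_counts.tolist(),
            "per_class_means": self.per_class_means.tolist(),
        }


def _stack_planes(planes) -> np.ndarray:
    arr = np.asarray(planes, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise GeometryError(f"expected a 2D plane or a stack of them, got shape {arr.shape}")
    return arr


def separability(planes, labels: np.ndarray) -> SeparabilityReport:
    """Fisher trace-ratio separability of plane values given labels.

    ``planes`` may be a single 2D grid, a list of 2D grids, or a
    (n_planes, H, W) array; ``labels`` is an integer map of the same
    spatial geometry.  Raises if fewer than two classes are present;
    returns the documented +inf sentinel when class means differ but the
    pooled within-class scatter is exactly zero.
    """
    arr = _stack_planes(planes)
    labels = np.asarray(labels)
    if labels.shape != arr.shape[1:]:
        raise GeometryError(
            f"label map {labels.shape} does not match plane geometry {arr.shape[1:]}"
        )
    x = arr.reshape(arr.shape[0], -1).T  # (n_pixels, n_planes)
    flat = labels.ravel()
    classes, inverse, counts = np.unique(flat, return_inverse=True, return_counts=True)
    if classes.size < 2:
        raise DegenerateInputError(
            f"separability needs at least 2 classes, found {classes.size}"
        )

    n_classes = classes.size
    d = x.shape[1]
    sums = np.zeros((n_classes, d))
    np.add.at(sums, inverse, x)
    means = sums / counts[:, None]
    grand = x.mean(axis=0)

    trace_b = float((counts[:, None] * (means - grand) ** 2).sum())
    trace_w = float(((x - means[inverse]) ** 2).sum())

    if trace_w == 0.0:
        score = INFINITE_SEPARABILITY if trace_b > 0 else 0.0
    else:
        score = trace_b / trace_w
    return SeparabilityReport(
        score=score,
        per_class_means=means,
        class_labels=classes,
        class_counts=counts,
        n_classes=n_classes,
    )
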