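"""Thresholding of filtered planes into marker-candidate masks.

The filtered plane is clipped at a single level: strictly greater than the
threshold -> 1 (marker candidate), less than or equal -> 0. The shipped
default of 2000 (filter-response units under the excess-green + marker
kernel pipeline at the reference deployment's scale) was chosen from a
histogram of labelled samples in which marker and background responses
formed two well-separated groups; :func:`select_threshold` formalises that
choice as the midpoint of the gap between the two training classes.

No morphological clean-up is applied: residual speckle is handled later by
keeping only the longest vertical run.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .exceptions import SeparationError

__all__ = [
    "ThresholdModel",
    "DEFAULT_THRESHOLD",
    "apply_threshold",
    "select_threshold",
    "write_mask",
]

#: Shipped clip level for the excess-green marker-kernel pipeline.
DEFAULT_THRESHOLD = 2000.0


@dataclass(frozen=True)
class ThresholdModel:
    """A clip level plus where it came from (``fixed`` or ``learned``)."""

    threshold: float
    provenance: str = "fixed"

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.provenance not in ("fixed", "learned"):
            raise ValueError(
                f"provenance must be 'fixed' or 'learned', got {self.provenance!r}"
            )


def apply_threshold(
    plane: np.ndarray, model: ThresholdModel | float
) -> np.ndarray:
    """Binarise a filtered plane: 1 iff value > threshold, else 0.

    Values exactly equal to the threshold fall in the 0 branch. Returns a
    uint8 {0, 1} mask of the same shape.
    """
    thr = model.threshold if isinstance(model, ThresholdModel) else float(model)
    arr = np.asarray(plane, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("apply_threshold expects a 2-D plane")
    if not np.all(np.isfinite(arr)):
        raise ValueError("plane contains non-finite values")
    return (arr > thr).astype(np.uint8)


def select_threshold(marker_samples, other_samples) -> ThresholdModel:
    """Learn a clip level from labelled filter-response samples.

    Given response values sampled on the marker bar and on other areas
    (sky, trees, crop), the classes must be separable — every marker value
    above every background value. The learned threshold is the midpoint of
    the empty interval between them, so both training classes are
    classified perfectly by the strictly-greater rule.

    Raises
    ------
    SeparationError
        If the classes overlap (max background >= min marker).
    """
    marker = np.asarray(list(marker_samples), dtype=np.float64)
    other = np.asarray(list(other_samples), dtype=np.float64)
    if marker.size == 0 or other.size == 0:
        raise ValueError("both sample lists must be non-empty")
    lo, hi = float(other.max()), float(marker.min())
    if lo >= hi:
        raise SeparationError(
            "marker and background responses overlap: "
            f"max(background) = {lo:g} >= min(marker) = {hi:g}"
        )
    return ThresholdModel(threshold=(lo + hi) / 2.0, provenance="learned")


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Export a {0, 1} mask as an 8-bit PNG/PGM (0/255)."""
    arr = np.asarray(mask)
    if arr.ndim != 2 or not np.isin(arr, (0, 1)).all():
        raise ValueError("expected a binary {0, 1} mask")
    Image.fromarray((arr * 255).astype(np.uint8), mode="L").save(path)
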