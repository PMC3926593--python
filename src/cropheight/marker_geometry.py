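"""Marker-bar detection in a binary mask and pixel-to-height conversion.

The marker bar is by far the longest vertical object in a segmented frame,
so it is located as the longest maximal contiguous run of 1-pixels within
a single column (no gap bridging; the marker kernel is designed to make
the bar solid). As the crop grows it hides more of the bar, and the crop
height follows from comparing the visible bar against the bar seen in the
initial frame:

    H = ((I - M) / I) * L + R

with I the initial visible bar height in pixels, L the same height in cm,
M the currently detected bar height in pixels and R the crop height (cm)
at the initial frame. Both boundary identities hold: a fully visible bar
(M = I) gives H = R, a fully hidden bar (M = 0) gives H = L + R.

When the topmost white stripe of the bar is indistinguishable from sky the
reference is shortened by whole stripes (:func:`adjust_reference_for_sky`)
so that the calibration describes only the detectable part of the bar.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import CalibrationError, DetectionError

__all__ = [
    "RunSegment",
    "MarkerReference",
    "above_ground_length",
    "longest_vertical_runs",
    "compute_height",
    "adjust_reference_for_sky",
]


@dataclass(frozen=True)
class RunSegment:
    """A maximal vertical run of mask pixels in one column (rows inclusive)."""

    column: int
    top_row: int
    bottom_row: int
    length: int

    def __post_init__(self) -> None:
        if self.top_row > self.bottom_row:
            raise ValueError("top_row must be <= bottom_row")
        if self.length != self.bottom_row - self.top_row + 1:
            raise ValueError("length must equal bottom_row - top_row + 1")

    @classmethod
    def from_rows(cls, column: int, top_row: int, bottom_row: int) -> "RunSegment":
        return cls(column, top_row, bottom_row, bottom_row - top_row + 1)


@dataclass(frozen=True)
class MarkerReference:
    """Calibration block tying marker pixels to centimetres.

    Attributes
    ----------
    initial_px : int
        Visible bar height in pixels in the initial frame (symbol I).
    initial_cm : float
        The same visible height in cm (symbol L).
    initial_crop_cm : float
        Crop height at the initial frame, cm (symbol R).
    above_ground_cm : float
        Bar length above ground = total length minus buried length.
    stripe_cm : float
        Height of one painted stripe, cm.
    marker_width_px : int
        Apparent bar width in pixels (sizes the marker kernel).
    """

    initial_px: int
    initial_cm: float
    initial_crop_cm: float
    above_ground_cm: float
    stripe_cm: float
    marker_width_px: int

    def __post_init__(self) -> None:
        if self.initial_px <= 0:
            raise ValueError("initial_px must be positive")
        if self.initial_cm <= 0:
            raise ValueError("initial_cm must be positive")
        if self.stripe_cm <= 0:
            raise ValueError("stripe_cm must be positive")
        if self.above_ground_cm <= 0:
            raise ValueError("above_ground_cm must be positive")

    @property
    def cm_per_px(self) -> float:
        return self.initial_cm / self.initial_px


def above_ground_length(total_cm: float, buried_cm: float) -> float:
    """Bar length above ground level: total minus the buried part."""
    if buried_cm < 0 or buried_cm >= total_cm:
        raise ValueError("buried length must lie in [0, total)")
    return total_cm - buried_cm


def _runs_in_column(col: np.ndarray):
    """Yield (top, bottom) for each maximal run of 1s in a 1-D column."""
    padded = np.concatenate(([0], col, [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1) - 1
    return zip(starts, stops)


def longest_vertical_runs(
    mask: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    n: int = 1,
) -> list[RunSegment]:
    """The ``n`` longest vertical runs of 1-pixels, longest first.

    A run lives entirely in one column. Ties are broken by smaller column
    index, then smaller top row, so detection is deterministic. With
    several bars in the field, ``n`` bars are recovered as the ``n``
    longest runs. Fewer than ``n`` runs may be returned if the mask does
    not contain that many.

    Parameters
    ----------
    mask : (H, W) binary array
    roi : (x0, y0, width, height), optional
        Restrict the search to this rectangle; reported coordinates stay
        in the full-image frame.
    n : int
        Number of runs wanted (>= 1).

    Raises
    ------
    DetectionError
        If the mask (within the ROI) contains no 1-pixels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    x_off = y_off = 0
    if roi is not None:
        x0, y0, w, h = (int(v) for v in roi)
        if w <= 0 or h <= 0:
            raise ValueError("ROI width and height must be positive")
        arr = arr[y0 : y0 + h, x0 : x0 + w]
        x_off, y_off = x0, y0
        if arr.size == 0:
            raise DetectionError("no marker candidate: ROI outside the image")
    arr = (arr != 0).astype(np.uint8)
    if not arr.any():
        raise DetectionError("no marker candidate: mask has no foreground pixels")
    segments: list[RunSegment] = []
    for c in range(arr.shape[1]):
        col = arr[:, c]
        if not col.any():
            continue
        for top, bottom in _runs_in_column(col):
            segments.append(
                RunSegment.from_rows(c + x_off, int(top) + y_off, int(bottom) + y_off)
            )
    segments.sort(key=lambda s: (-s.length, s.column, s.top_row))
    return segments[:n]


def compute_height(ref: MarkerReference, detected_px: float) -> float:
    """Crop height in cm from the detected visible bar length in pixels.

    Implements H = ((I - M) / I) * L + R. Strictly decreasing in the
    detected length; a detection longer than the initial bar is impossible
    geometry and raises.
    """
    m = float(detected_px)
    if m < 0:
        raise CalibrationError("detected marker length cannot be negative")
    if m > ref.initial_px:
        raise CalibrationError(
            f"detected marker ({m:g} px) exceeds the initial reference "
            f"({ref.initial_px} px): mis-detection or stale calibration"
        )
    return (ref.initial_px - m) / ref.initial_px * ref.initial_cm + ref.initial_crop_cm


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def adjust_reference_for_sky(
    ref: MarkerReference, cut_stripes: int
) -> MarkerReference:
    """Shorten the reference by whole top stripes lost against the sky.

    ``initial_cm`` drops by ``cut_stripes * stripe_cm`` and ``initial_px``
    shrinks proportionally (rounded to the nearest pixel, half away from
    zero), preserving the cm-per-pixel scale within rounding.
    """
    if cut_stripes < 0:
        raise ValueError("cut_stripes must be >= 0")
    if cut_stripes == 0:
        return ref
    cut_cm = cut_stripes * ref.stripe_cm
    new_cm = ref.initial_cm - cut_cm
    if new_cm <= 0:
        raise ValueError(
            f"cutting {cut_stripes} stripes removes the whole visible marker"
        )
    new_px = _round_half_away(ref.initial_px * new_cm / ref.initial_cm)
    return dataclasses.replace(ref, initial_cm=new_cm, initial_px=new_px)
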