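"""RGB band handling and excess-colour indices.

Field frames are 24-bit RGB rasters (H, W, 3) of 8-bit intensities. The
marker bar carries alternating red and white stripes, so no single band is
uniform along the bar; the excess-colour indices

    ExcessRed   = 2R - G - B
    ExcessGreen = 2G - R - B
    ExcessBlue  = 2B - G - R

are used instead. Excess green is the workhorse: both red and white stripes
score low against green (or gold) vegetation, which makes the whole bar a
homogeneous dark object, and the index is invariant to additive,
channel-common illumination shifts. All arithmetic is signed and unclipped
(range [-510, 510] for 8-bit input) because downstream thresholding acts on
the *filtered* plane and needs the full dynamic range preserved.

Coordinates are 0-based, x rightward (columns), y downward (rows),
everywhere in this package.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image

__all__ = [
    "split_bands",
    "excess_index",
    "excess_green",
    "read_rgb",
    "write_pgm",
    "validate_rgb",
]

_INDEX_ORDER = {"red": (0, 1, 2), "green": (1, 0, 2), "blue": (2, 1, 0)}


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is an (H, W, 3) 8-bit-range raster; return it as ndarray.

    Raises
    ------
    ValueError
        If the array is not three equally-shaped planes of values in [0, 255].
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected an (H, W, 3) RGB raster, got shape {arr.shape}"
        )
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image dimensions must be positive")
    if arr.dtype != np.uint8:
        if np.any(arr < 0) or np.any(arr > 255):
            raise ValueError("RGB intensities must lie in [0, 255]")
    return arr


def split_bands(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an RGB raster into red, green and blue planes (value-preserving).

    Returns float64 planes so later signed arithmetic cannot wrap.
    """
    arr = validate_rgb(img)
    r, g, b = (arr[..., i].astype(np.float64) for i in range(3))
    return r, g, b


def excess_index(img: np.ndarray, which: str) -> np.ndarray:
    """Per-pixel excess-colour index ``2X - Y - Z`` for the named band.

    Parameters
    ----------
    img : (H, W, 3) array
        8-bit RGB frame.
    which : {"red", "green", "blue"}
        Band whose excess index to compute.

    Returns
    -------
    (H, W) float64 plane, signed, unclipped. Zero wherever R = G = B.
    """
    try:
        i, j, k = _INDEX_ORDER[which]
    except KeyError:
        raise ValueError(
            f"unknown excess index {which!r}; expected 'red', 'green' or 'blue'"
        ) from None
    arr = validate_rgb(img).astype(np.float64)
    return 2.0 * arr[..., i] - arr[..., j] - arr[..., k]


def excess_green(img: np.ndarray) -> np.ndarray:
    """Shorthand for ``excess_index(img, "green")``."""
    return excess_index(img, "green")


def read_rgb(path: str | os.PathLike) -> np.ndarray:
    """Read a JPEG/PNG frame as an (H, W, 3) uint8 array.

    Greyscale or RGBA files are converted to RGB; the camera applies no
    gamma or white-balance correction and none is applied here.
    """
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_pgm(plane: np.ndarray, path: str | os.PathLike) -> None:
    """Export a scalar plane as portable greymap (PGM) for visual debugging.

    Signed planes are rescaled linearly so that [min, max] maps onto
    [0, 255]; a constant plane maps to 0.
    """
    arr = np.asarray(plane, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("write_pgm expects a 2-D plane")
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        arr = (arr - lo) * (255.0 / (hi - lo))
    else:
        arr = np.zeros_like(arr)
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path, format="PPM")
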