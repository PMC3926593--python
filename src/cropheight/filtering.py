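"""Convolution kernels for marker-bar extraction.

Three kernel families are provided:

* the standard 3x3 discrete Laplacian (4- and 8-neighbour), which finds
  edges in every direction but leaves the marker outline gappy;
* 3x3 directional first-derivative kernels, which find the bar's long
  vertical edges but also respond to stems and tree edges;
* the marker kernel, a square zero-row-sum kernel sized to the bar: for a
  bar w pixels wide the kernel is (2w+1) x (2w+1), its central w columns
  hold one negative constant and the (w+1)/2 outermost columns on each side
  hold one positive constant, every column being constant top to bottom.
  Sliding it over the excess-green plane, the dark bar under the negative
  centre and the bright vegetation under the positive flanks both push the
  response up, so the whole striped bar lights up as one solid object.

Coefficient magnitudes for the marker kernel are chosen as +w on the
positive columns and -(w+1) on the negative ones, the smallest integers
that zero every row sum for any odd w; only the sign pattern and the
zero-sum property matter downstream (the response is compared against a
threshold), so any zero-row-sum choice with this structure is equivalent
up to a rescaling of the threshold.
"""

from __future__ import annotations

import os

import numpy as np
from scipy import ndimage

__all__ = [
    "laplacian_kernel",
    "directional_kernel",
    "modified_kernel",
    "convolve",
    "kernel_to_text",
    "save_kernel",
]


def laplacian_kernel(neighbors: int = 4) -> np.ndarray:
    """3x3 discrete Laplacian (sum of second differences), zero total sum.

    ``neighbors=4`` uses the cross stencil (centre -4), ``neighbors=8`` the
    full box (centre -8). Negative-centre sign convention; the pipeline
    only ever thresholds magnitude-like responses, so the sign is moot.
    """
    if neighbors == 4:
        return np.array(
            [[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]]
        )
    if neighbors == 8:
        return np.array(
            [[1.0, 1.0, 1.0], [1.0, -8.0, 1.0], [1.0, 1.0, 1.0]]
        )
    raise ValueError(f"neighbors must be 4 or 8, got {neighbors!r}")


def directional_kernel(axis: str = "x") -> np.ndarray:
    """3x3 first-derivative kernel along ``axis`` ('x' = columns, 'y' = rows).

    Central-difference column (-1, 0, +1) replicated over three rows;
    zero sum, antisymmetric across the centre line orthogonal to the axis.
    The y kernel is the transpose of the x kernel.
    """
    k = np.array([[-1.0, 0.0, 1.0]] * 3)
    if axis == "x":
        return k
    if axis == "y":
        return k.T.copy()
    raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")


def modified_kernel(marker_width_px: int) -> np.ndarray:
    """Marker kernel sized for a bar ``marker_width_px`` pixels wide.

    Side length is ``2 * marker_width_px + 1`` (twice the bar width plus
    one): width 5 -> 11x11, width 3 -> 7x7, width 7 -> 15x15. Central
    ``w`` columns are -(w+1), the (w+1)/2 leftmost and rightmost columns
    are +w; every row sums to zero and every column is constant.

    Parameters
    ----------
    marker_width_px : int
        Apparent bar width in pixels; must be odd and >= 3.
    """
    w = int(marker_width_px)
    if w != marker_width_px or w < 3 or w % 2 == 0:
        raise ValueError(
            f"marker width must be an odd integer >= 3, got {marker_width_px!r}"
        )
    size = 2 * w + 1
    flank = (w + 1) // 2
    row = np.empty(size, dtype=np.float64)
    row[:flank] = float(w)
    row[-flank:] = float(w)
    row[flank:-flank] = -float(w + 1)
    return np.tile(row, (size, 1))


def convolve(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Correlate a scalar plane with a kernel, same-size output.

    Borders are handled by replicating the nearest edge pixel so that run
    lengths measured on the output are comparable across frames. The
    operation is correlation (no kernel flip); every kernel built here is
    mirror-symmetric about its vertical centre line, so the distinction is
    unobservable, but the contract is fixed as correlation.
    """
    plane = np.asarray(img, dtype=np.float64)
    k = np.asarray(kernel, dtype=np.float64)
    if plane.ndim != 2 or k.ndim != 2:
        raise ValueError("convolve expects 2-D plane and 2-D kernel")
    if k.shape[0] > plane.shape[0] or k.shape[1] > plane.shape[1]:
        raise ValueError(
            f"kernel {k.shape} larger than image {plane.shape}"
        )
    return ndimage.correlate(plane, k, mode="nearest")


def kernel_to_text(kernel: np.ndarray) -> str:
    """Render a kernel as a plain-text integer-friendly matrix."""
    k = np.asarray(kernel)
    rows = []
    for r in k:
        rows.append(" ".join(f"{v:g}" for v in r))
    return "\n".join(rows) + "\n"


def save_kernel(kernel: np.ndarray, path: str | os.PathLike) -> None:
    """Write a kernel to ``path`` as a whitespace-separated text matrix."""
    with open(path, "w") as fh:
        fh.write(kernel_to_text(kernel))
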