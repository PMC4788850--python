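"""Automatic initial-curve selection via window-kernel scanning.

The localized active contour is sensitive to its initial curve.  For each
facial feature the initial curve is the minimum-bounding rectangle of the
feature's dark blob, found by scanning a small all-ones window kernel
outward from the blob centroid in the four axis directions: the scan stops
at the first position where the elementwise product of kernel and binary
mask sums to zero, i.e. where the kernel has fully cleared the blob.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConvergenceError, InitializationError, InvalidInputError
from .imaging import default_min_pixels, otsu_threshold, remove_small_components

DIRECTIONS = ("left", "right", "up", "down")


@dataclass(frozen=True)
class KernelSpec:
    """All-ones window kernel of ``rows x cols`` pixels.

    A tall (``rows > cols``) kernel is the *vertical* form used for
    left/right scans; a wide one is the *horizontal* form used for
    up/down scans.
    """

    rows: int
    cols: int

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise InvalidInputError("kernel dimensions must be >= 1")

    @property
    def orientation(self) -> str:
        return "vertical" if self.rows >= self.cols else "horizontal"


@dataclass(frozen=True)
class InitRectangle:
    """Axis-aligned initial evolving curve, inclusive pixel bounds."""

    top: int
    bottom: int
    left: int
    right: int
    feature: str = ""

    def __post_init__(self):
        if not (self.top < self.bottom and self.left < self.right):
            raise InvalidInputError("degenerate initial rectangle")

    def interior_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the rectangle interior on an image grid."""
        m = np.zeros(shape, dtype=bool)
        m[
            max(0, self.top) : min(shape[0], self.bottom + 1),
            max(0, self.left) : min(shape[1], self.right + 1),
        ] = True
        return m


def _window_sum(mask: np.ndarray, kernel: KernelSpec, row: int, col: int) -> int:
    """Sum of mask pixels under the kernel centered at ``(row, col)``.

    The window is clipped at the image border; off-image cells count 0.
    """
    hr, hc = kernel.rows // 2, kernel.cols // 2
    r0 = max(0, row - hr)
    r1 = min(mask.shape[0], row - hr + kernel.rows)
    c0 = max(0, col - hc)
    c1 = min(mask.shape[1], col - hc + kernel.cols)
    if r0 >= r1 or c0 >= c1:
        return 0
    return int(mask[r0:r1, c0:c1].sum())


def scan_axis(
    mask: np.ndarray,
    kernel: KernelSpec,
    start: tuple[int, int],
    direction: str,
) -> int:
    """Slide the kernel one pixel at a time until its masked sum is zero.

    Returns the boundary coordinate at convergence: the column for
    ``left``/``right`` scans, the row for ``up``/``down`` scans.  Raises
    :class:`ConvergenceError` when the border is reached while the sum is
    still positive (the caller may enlarge the region of interest).
    """
    if direction not in DIRECTIONS:
        raise InvalidInputError(f"direction must be one of {DIRECTIONS}")
    m = np.asarray(mask, dtype=bool)
    row, col = int(start[0]), int(start[1])
    if not (0 <= row < m.shape[0] and 0 <= col < m.shape[1]):
        raise InvalidInputError(f"start {start} outside mask extent {m.shape}")
    dr, dc = {"left": (0, -1), "right": (0, 1), "up": (-1, 0), "down": (1, 0)}[direction]
    while 0 <= row < m.shape[0] and 0 <= col < m.shape[1]:
        if _window_sum(m, kernel, row, col) == 0:
            return col if dc else row
        row += dr
        col += dc
    raise ConvergenceError(
        f"no zero-sum kernel position scanning {direction} from {start}"
    )


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise InitializationError("empty mask after component cleanup")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def min_bounding_rectangle(
    roi: np.ndarray,
    feature: str = "",
    *,
    min_area_fraction: float = 0.01,
    start: str = "blob_centroid",
    min_kernel: int = 3,
) -> InitRectangle:
    """Minimum-bounding rectangle of a facial feature within its ROI.

    Pipeline: Otsu binarization with dark-foreground polarity (facial
    features are darker than skin) -> removal of 8-connected components
    below ``min_area_fraction`` of the ROI area -> kernel scans in the
    four axis directions from the largest blob's centroid (or the ROI
    center when ``start="roi_center"``).

    Kernel sizing: left/right scans use a vertical kernel of height
    ``ceil(0.5 * blob_height)``, up/down scans a horizontal kernel of
    width ``ceil(0.5 * blob_width)``, each at least ``min_kernel`` — a
    kernel shorter than the blob avoids premature zero sums inside
    concavities.
    """
    arr = np.asarray(roi, dtype=float)
    _, mask = otsu_threshold(arr, foreground="dark")
    mask = remove_small_components(
        mask, default_min_pixels(mask.shape, min_area_fraction)
    )
    if not mask.any():
        raise InitializationError(f"no component survived cleanup for {feature or 'roi'}")
    blob = _largest_component(mask)
    rows, cols = np.nonzero(blob)
    blob_h = int(rows.max() - rows.min() + 1)
    blob_w = int(cols.max() - cols.min() + 1)
    if start == "roi_center":
        center = (arr.shape[0] // 2, arr.shape[1] // 2)
    else:
        center = (int(round(rows.mean())), int(round(cols.mean())))
    vker = KernelSpec(max(min_kernel, -(-blob_h // 2)), 1)
    hker = KernelSpec(1, max(min_kernel, -(-blob_w // 2)))
    left = scan_axis(mask, vker, center, "left")
    right = scan_axis(mask, vker, center, "right")
    top = scan_axis(mask, hker, center, "up")
    bottom = scan_axis(mask, hker, center, "down")
    return InitRectangle(top=top, bottom=bottom, left=left, right=right, feature=feature)
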