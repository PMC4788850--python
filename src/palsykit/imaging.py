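"""Image ingestion, preprocessing and binary-mask utilities.

Every downstream stage (initial-curve selection, active contours, iris
detection, landmarks) consumes the products of this module: grayscale
rasters, the preprocessing chain (median filter -> histogram equalization
-> log transform), integral images, Otsu binarization and connected-
component hygiene.

Conventions
-----------
* Images are 2-D ``numpy`` arrays indexed ``[row, col]``, 0-based.
* Intensities are 8-bit style values in ``[0, 255]`` (integer or float).
* Boxes are half-open: a :class:`RoiBox` spans rows ``[top, top+height)``
  and columns ``[left, left+width)``.
* Binary masks are boolean arrays with the same shape as their source.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage import exposure

from .errors import (
    ConfigurationError,
    DegenerateImageError,
    DetectionError,
    InvalidInputError,
)

#: Standard luminance weights for RGB -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Feature labels a region-of-interest detector is expected to provide.
ROI_FEATURES = (
    "face",
    "eye_left",
    "eye_right",
    "eyebrow_left",
    "eyebrow_right",
    "nose",
    "mouth",
)


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned region of interest, half-open in both axes."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise InvalidInputError("RoiBox must have height, width >= 1")

    @property
    def bottom(self) -> int:
        return self.top + self.height

    @property
    def right(self) -> int:
        return self.left + self.width

    def slices(self) -> tuple[slice, slice]:
        return slice(self.top, self.bottom), slice(self.left, self.right)

    def clip_to(self, shape: tuple[int, int]) -> "RoiBox":
        """Clip the box to an image of the given ``(rows, cols)`` shape."""
        top = max(0, self.top)
        left = max(0, self.left)
        bottom = min(shape[0], self.bottom)
        right = min(shape[1], self.right)
        if bottom <= top or right <= left:
            raise InvalidInputError(f"box {self} lies outside image {shape}")
        return RoiBox(top, left, bottom - top, right - left)

    def extract(self, image: np.ndarray) -> np.ndarray:
        return image[self.slices()]

    def expanded(self, margin: int, shape: tuple[int, int]) -> "RoiBox":
        """Grow the box by ``margin`` pixels on every side, clipped to an
        image of the given shape."""
        return RoiBox(
            self.top - margin, self.left - margin,
            self.height + 2 * margin, self.width + 2 * margin,
        ).clip_to(shape)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a color raster to single-channel luminance.

    Already-gray input is returned unchanged.  RGB(A) input is reduced with
    the standard luminance weights 0.299/0.587/0.114 (alpha ignored).
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise InvalidInputError("empty image")
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        w = np.asarray(LUMA_WEIGHTS)
        return arr[..., :3].astype(float) @ w
    raise InvalidInputError(f"unsupported image shape {arr.shape}")


def _rescale_255(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:  # constant image: nothing to stretch
        return values
    return (values - lo) * (255.0 / (hi - lo))


def preprocess(
    image: np.ndarray,
    *,
    c: float = 0.1,
    median_size: int = 3,
) -> np.ndarray:
    """Contrast-enhancement chain applied before any segmentation.

    Order is fixed: 3x3 median filter (reflect padding), histogram
    equalization, then the log transform ``s = c * log(1 + v)`` on
    intensities normalized to ``[0, 1]``, min-max rescaled back to
    ``[0, 255]``.  The log step expands dark values and compresses bright
    ones, which helps the dark-feature binarization downstream.
    """
    if c <= 0:
        raise ConfigurationError(f"log-transform constant c must be > 0, got {c}")
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise InvalidInputError("preprocess expects a 2-D grayscale image")
    med = ndimage.median_filter(arr, size=median_size, mode="reflect")
    # equalize_hist maps to [0, 1] via the empirical CDF
    eq = exposure.equalize_hist(med / 255.0)
    logt = c * np.log1p(eq)
    return _rescale_255(logt)


def integral_image(image: np.ndarray) -> np.ndarray:
    """Cumulative-sum (summed-area) table, inclusive of the current cell.

    ``GI[x, y]`` is the sum of all pixels ``G[x', y']`` with ``x' <= x``
    and ``y' <= y``.  Integer input stays in integer arithmetic.
    """
    arr = np.asarray(image)
    dtype = np.int64 if np.issubdtype(arr.dtype, np.integer) else np.float64
    return np.cumsum(np.cumsum(arr.astype(dtype), axis=0), axis=1)


def rotated_integral_image(image: np.ndarray) -> np.ndarray:
    """45-degree rotated summed-area table.

    ``GR[x, y]`` sums all pixels ``G[x', y']`` satisfying
    ``x' <= x - |y - y'|`` (which implies ``x' <= x``), i.e. the cone
    opening upward at 45 degrees from ``(x, y)``.
    """
    arr = np.asarray(image)
    dtype = np.int64 if np.issubdtype(arr.dtype, np.integer) else np.float64
    g = arr.astype(dtype)
    rows, cols = g.shape
    # colcum[k, y'] = sum of g[0..k, y']
    colcum = np.cumsum(g, axis=0)
    out = np.zeros_like(g)
    yprime = np.arange(cols)
    for y in range(cols):
        shift = np.abs(y - yprime)  # per-column row limit offset
        for x in range(rows):
            limit = x - shift
            valid = limit >= 0
            out[x, y] = colcum[limit[valid], yprime[valid]].sum()
    return out


def rect_sum(gi: np.ndarray, box: RoiBox) -> float:
    """Sum of an image over ``box`` from its plain integral image (4 taps)."""
    r0, c0, r1, c1 = box.top - 1, box.left - 1, box.bottom - 1, box.right - 1
    total = gi[r1, c1]
    if r0 >= 0:
        total = total - gi[r0, c1]
    if c0 >= 0:
        total = total - gi[r1, c0]
    if r0 >= 0 and c0 >= 0:
        total = total + gi[r0, c0]
    return total


def otsu_threshold(
    image: np.ndarray, *, foreground: str = "bright"
) -> tuple[int, np.ndarray]:
    """Between-class-variance maximizing threshold and the resulting mask.

    The threshold ``t`` maximizes the between-class variance
    ``w0 * w1 * (mu0 - mu1)**2`` over all 256 candidate levels, where the
    two classes are ``image < t`` and ``image >= t``.  With
    ``foreground="bright"`` the mask is ``image >= t``; with ``"dark"`` it
    is inverted (used for irises, eyebrows and lips on lighter skin).
    """
    if foreground not in ("bright", "dark"):
        raise ConfigurationError(f"foreground must be 'bright' or 'dark', got {foreground!r}")
    arr = np.asarray(image)
    quantized = np.clip(arr, 0, 255).astype(np.uint8)
    hist = np.bincount(quantized.ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("constant image: Otsu threshold undefined")
    levels = np.arange(256, dtype=float)
    n = hist.sum()
    # class 0 = levels < t for t in 1..255  (both classes non-empty only
    # where the cumulative counts allow)
    w0 = np.cumsum(hist)[:-1]  # counts below t for t = 1..255
    w1 = n - w0
    csum = np.cumsum(hist * levels)[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum / w0
        mu1 = (hist @ levels - csum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = -np.inf
    t = int(np.argmax(sigma_b)) + 1
    mask = quantized >= t
    if foreground == "dark":
        mask = ~mask
    return t, mask


def remove_small_components(mask: np.ndarray, min_pixels: int) -> np.ndarray:
    """Drop 8-connected components smaller than ``min_pixels``.

    Never adds a pixel; idempotent.  The conventional default for
    ``min_pixels`` is 1% of the image area.
    """
    if min_pixels < 1:
        raise ConfigurationError("min_pixels must be >= 1")
    m = np.asarray(mask, dtype=bool)
    if min_pixels == 1:
        return m.copy()
    labels, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return m.copy()
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.concatenate(([False], sizes >= min_pixels))
    return keep[labels]


def default_min_pixels(shape: tuple[int, int], fraction: float = 0.01) -> int:
    """Component-size floor: ``fraction`` of the image area (>= 1)."""
    return max(1, int(round(shape[0] * shape[1] * fraction)))


def detect_rois(
    image: np.ndarray,
    detector=None,
    manual_boxes: Mapping[str, RoiBox] | None = None,
    *,
    required: tuple[str, ...] = ROI_FEATURES,
) -> dict[str, RoiBox]:
    """Locate the face and per-feature regions of interest.

    ``detector`` is any object with a ``detect(image) -> mapping`` method
    (e.g. a Haar-cascade wrapper or the synthetic-registry stub);
    ``manual_boxes`` overrides or supplements its output.  Eyebrow boxes
    are derived above each eye box when absent, since common detectors
    lack an eyebrow class.  All boxes are clipped to the image.
    """
    shape = np.asarray(image).shape[:2]
    boxes: dict[str, RoiBox] = {}
    if detector is not None:
        boxes.update(detector.detect(image))
    if manual_boxes:
        boxes.update(manual_boxes)
    for side in ("left", "right"):
        brow, eye = f"eyebrow_{side}", f"eye_{side}"
        if brow not in boxes and eye in boxes:
            e = boxes[eye]
            h = max(1, int(round(e.height * 1.2)))
            boxes[brow] = RoiBox(e.top - h, e.left, h, e.width)
    clipped = {name: box.clip_to(shape) for name, box in boxes.items()}
    missing = [name for name in required if name not in clipped]
    if missing:
        raise DetectionError(
            f"features not detected and no manual fallback: {', '.join(missing)}",
            missing=missing,
        )
    return clipped
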