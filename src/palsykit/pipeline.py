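"""End-to-end orchestration: images -> masks -> landmarks -> features.

For each of the five expression images the pipeline runs: region-of-
interest detection (pluggable detector or manual boxes) -> preprocessing
-> window-kernel curve initialization -> localized active contour per
facial feature -> optimized iris extraction -> key-point assembly.  The
per-expression analyses then feed the symmetry-feature computation.

Expression identity comes from the input manifest, never from image
content.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import curve_init, imaging, landmarks
from .errors import (
    ConvergenceError,
    DetectionError,
    InvalidInputError,
    PalsykitError,
    SegmentationError,
)
from .features import (
    EXPRESSIONS,
    ExpressionAnalysis,
    FeatureVector,
    extract_features,
)
from .iris import DaugmanParams, iris_area, segment_iris
from .lac import LacParams, evolve

SEGMENT_FEATURES = ("eye_left", "eye_right", "eyebrow_left", "eyebrow_right", "mouth")


@dataclass
class PipelineConfig:
    """Every stage's tunable parameters in one place.

    ``preprocess_mode`` selects what the segmentation stages consume:
    ``"median"`` (default) applies denoising only, keeping the native
    intensity scale; ``"full"`` additionally runs histogram equalization
    and the log transform.  The full chain helps photographs with a wide
    illumination spread, but its rank-flattening equalization erases the
    intensity bimodality the Otsu initialization relies on when a region
    of interest is nearly flat, so it is opt-in.
    """

    preprocess_mode: str = "median"
    preprocess_c: float = 0.1
    median_size: int = 3
    lac_feature: LacParams = field(
        default_factory=lambda: LacParams(lam=0.3, radius=9, iterations=100)
    )
    lac_iris: LacParams = field(
        default_factory=lambda: LacParams(lam=0.1, radius=12, iterations=100)
    )
    daugman: DaugmanParams = field(
        default_factory=lambda: DaugmanParams(r_min=7, r_max=16)
    )
    curve_start: str = "blob_centroid"  # or "roi_center"


@dataclass
class SubjectRecord:
    """One subject's five expression images (paths or arrays)."""

    subject_id: str
    images: dict[str, object]
    label: str | None = None

    def load(self, expression: str) -> np.ndarray:
        if expression not in self.images:
            raise InvalidInputError(
                f"subject {self.subject_id}: missing expression {expression!r}"
            )
        src = self.images[expression]
        if isinstance(src, (str, Path)):
            return np.asarray(iio.imread(src))
        return np.asarray(src)


class GeometricReference:
    """Deterministic reference point below the eyes.

    Places the reference on the face midline, halfway between the
    infra-orbital level and the mouth — a stable landmark-derived stand-in
    for a matched interest point when no texture matcher is configured.
    """

    def reference_point(self, keypoints: landmarks.KeyPointSet) -> tuple[int, int]:
        io_row = (keypoints.IO_left[0] + keypoints.IO_right[0]) / 2
        mouth_row = (keypoints.mouth_left[0] + keypoints.mouth_right[0]) / 2
        col = (keypoints.IC_left[1] + keypoints.IC_right[1]) // 2
        return (int(round(io_row + 0.5 * (mouth_row - io_row))), int(col))


class SiftReference:
    """Reference point from SIFT correspondences between two images.

    Detects and matches SIFT descriptors between the at-rest and
    compared image, restricts matches to the band from the infra-orbital
    level down half-way to the mouth, and picks the best-scoring match.
    Falls back to :class:`GeometricReference` when no match lands in the
    band.
    """

    def __init__(self, max_ratio: float = 0.8):
        self.max_ratio = max_ratio

    def matched_point(
        self,
        image_a: np.ndarray,
        image_b: np.ndarray,
        band: tuple[int, int],
    ) -> tuple[tuple[int, int], tuple[int, int]] | None:
        from skimage.feature import SIFT, match_descriptors

        det_a, det_b = SIFT(), SIFT()
        try:
            det_a.detect_and_extract(np.ascontiguousarray(image_a, dtype=float))
            det_b.detect_and_extract(np.ascontiguousarray(image_b, dtype=float))
        except RuntimeError:
            return None
        if det_a.keypoints.size == 0 or det_b.keypoints.size == 0:
            return None
        matches = match_descriptors(
            det_a.descriptors, det_b.descriptors, max_ratio=self.max_ratio,
            cross_check=True,
        )
        for ia, ib in matches:
            ra = det_a.keypoints[ia]
            if band[0] <= ra[0] <= band[1]:
                rb = det_b.keypoints[ib]
                return (int(ra[0]), int(ra[1])), (int(rb[0]), int(rb[1]))
        return None


def _place_mask(shape, box: imaging.RoiBox, roi_mask: np.ndarray) -> np.ndarray:
    full = np.zeros(shape, dtype=bool)
    full[box.slices()] = roi_mask
    return full


def analyze_expression(
    image: np.ndarray,
    boxes: dict[str, imaging.RoiBox],
    config: PipelineConfig | None = None,
) -> tuple[ExpressionAnalysis, dict[str, np.ndarray]]:
    """Segment one expression image and assemble its measurements.

    Returns the analysis (key points, per-side visible-iris areas and
    upper-iris points, reference point unset) and the full-frame masks.
    """
    config = config or PipelineConfig()
    gray = imaging.to_grayscale(image).astype(float)
    masks: dict[str, np.ndarray] = {}
    errors: dict[str, str] = {}
    from scipy.ndimage import median_filter

    for feat in SEGMENT_FEATURES:
        box = boxes[feat]
        # a blob clipped by the detector's box leaves the window-kernel
        # scan no zero-sum position; on that failure enlarge the ROI and
        # retry, as the initialization contract directs the caller to do
        for margin in (0, 4, 8):
            roi_box = box if margin == 0 else box.expanded(margin, gray.shape)
            roi = roi_box.extract(gray)
            if config.preprocess_mode == "full":
                pre = imaging.preprocess(
                    roi, c=config.preprocess_c, median_size=config.median_size
                )
            else:
                pre = median_filter(roi, size=config.median_size, mode="reflect")
            try:
                rect = curve_init.min_bounding_rectangle(
                    pre, feat, start=config.curve_start
                )
                result = evolve(pre, rect, config.lac_feature)
                masks[feat] = _place_mask(gray.shape, roi_box, result.mask)
                errors.pop(feat, None)
                break
            except ConvergenceError as exc:
                errors[feat] = str(exc)  # retry with a larger ROI
            except PalsykitError as exc:  # aggregate, keep partial outputs
                errors[feat] = str(exc)
                break
    if errors:
        raise DetectionError(
            "segmentation failed for: "
            + "; ".join(f"{k} ({v})" for k, v in errors.items()),
            missing=tuple(errors),
        )
    kps = landmarks.assemble_keypoints(masks)
    iris_areas: dict[str, float] = {}
    iris_tops: dict[str, tuple[int, int] | None] = {}
    for side in ("left", "right"):
        box = boxes[f"eye_{side}"]
        roi = box.extract(gray)
        roi_f = median_filter(roi, size=config.median_size, mode="reflect")
        try:
            mask_roi, _circle = segment_iris(
                roi_f, config.daugman, config.lac_iris
            )
            full = _place_mask(gray.shape, box, mask_roi)
        except PalsykitError:
            full = np.zeros(gray.shape, dtype=bool)
        masks[f"iris_{side}"] = full
        iris_areas[side] = float(iris_area(full))
        if full.any():
            rows, cols = np.nonzero(full)
            top_r = int(rows.min())
            iris_tops[side] = (top_r, int(np.median(cols[rows == top_r])))
        else:
            iris_tops[side] = None
    analysis = ExpressionAnalysis(
        keypoints=kps,
        iris_area_left=iris_areas["left"],
        iris_area_right=iris_areas["right"],
        iris_top_left=iris_tops["left"],
        iris_top_right=iris_tops["right"],
    )
    return analysis, masks


@dataclass
class SubjectResult:
    subject_id: str
    features: FeatureVector
    analyses: dict[str, ExpressionAnalysis]
    masks: dict[str, dict[str, np.ndarray]]
    manifest: dict


def run_subject(
    record: SubjectRecord,
    *,
    detector=None,
    manual_boxes=None,
    config: PipelineConfig | None = None,
    reference=None,
) -> SubjectResult:
    """Full feature extraction for one subject's five expressions."""
    config = config or PipelineConfig()
    reference = reference or GeometricReference()
    analyses: dict[str, ExpressionAnalysis] = {}
    all_masks: dict[str, dict[str, np.ndarray]] = {}
    timings: dict[str, float] = {}
    for expr in EXPRESSIONS:
        img = record.load(expr)
        t0 = time.perf_counter()
        boxes = imaging.detect_rois(img, detector=detector, manual_boxes=manual_boxes)
        analysis, masks = analyze_expression(img, boxes, config)
        analysis.reference_point = reference.reference_point(analysis.keypoints)
        analyses[expr] = analysis
        all_masks[expr] = masks
        timings[expr] = time.perf_counter() - t0
    fv = extract_features(analyses, subject_id=record.subject_id, label=record.label)
    cfg_repr = json.dumps(
        {"preprocess_c": config.preprocess_c, "median_size": config.median_size,
         "lac_feature": vars(config.lac_feature), "lac_iris": vars(config.lac_iris),
         "daugman": vars(config.daugman)},
        sort_keys=True, default=str,
    )
    manifest = {
        "subject_id": record.subject_id,
        "config_hash": hashlib.sha256(cfg_repr.encode()).hexdigest()[:16],
        "config": json.loads(cfg_repr),
        "timings_s": timings,
    }
    return SubjectResult(
        subject_id=record.subject_id,
        features=fv,
        analyses=analyses,
        masks=all_masks,
        manifest=manifest,
    )
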