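"""Synthetic faces and feature cohorts with ground truth.

Clinical facial-palsy photographs are not publicly distributable, so every
stage of the pipeline is exercised on two kinds of synthetic data:

* **Parametric frontal faces** — stylized grayscale renderings of the five
  protocol expressions (rest, eyebrow raise, gentle eye closure, nose
  screwing, smile) with analytic shapes: elliptical palpebral apertures,
  partially occluded circular irises, eyebrow bands, a tapered mouth.
  Every feature (eyebrow, iris, lips, and also the sclera) is rendered
  darker than skin so each feature forms a single dark-polarity blob for
  Otsu binarization and curve initialization.  A registry of ground-truth
  landmarks, masks and region boxes accompanies each rendering.

* **Tabular feature cohorts** — draws of f1..f9 from truncated normal
  distributions per class: healthy ratios near 1, peripheral palsy (PP)
  depressed across the board, central palsy (CP) with near-1 forehead/eye
  features but depressed mouth features (the forehead and eyes are spared
  in central palsy).  Regional House-Brackmann grades follow a monotone
  step rule on the regional feature means.

The asymmetry parameter ``a`` in ``[0, 1]`` controls the affected side's
deviation: ``a = 0`` renders an exactly mirror-symmetric face (noise
included).  Peripheral palsy attenuates brow, eye and mouth motion on the
affected side and adds a static eyelid droop; central palsy attenuates
mouth motion only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InvalidInputError
from .imaging import RoiBox

EXPRESSIONS = ("rest", "brow_raise", "eye_close", "snarl", "smile")

# per-expression baseline geometry deltas (pixels / fractions)
_APERTURE_H = {"rest": 16.0, "brow_raise": 18.0, "eye_close": 2.5, "snarl": 13.0, "smile": 13.0}
_DROOP = {"rest": 0.15, "brow_raise": 0.0, "eye_close": 0.0, "snarl": 0.30, "smile": 0.25}
_BROW_LIFT = {"rest": 0.0, "brow_raise": 26.0, "eye_close": 0.0, "snarl": 0.0, "smile": 0.0}
_MOUTH_DY = {"rest": 0.0, "brow_raise": 0.0, "eye_close": 0.0, "snarl": -3.0, "smile": -8.0}
_MOUTH_WIDEN = {"rest": 0.0, "brow_raise": 0.0, "eye_close": 0.0, "snarl": 0.0, "smile": 9.0}
_IRIS_DY = {"rest": 0.0, "brow_raise": -2.0, "eye_close": 0.0, "snarl": 0.0, "smile": 0.0}

#: static (expression-independent) deviations on the affected side, per
#: unit of asymmetry ``a``
_STATIC_DROOP = 0.45  # peripheral only: resting eyelid droop
_STATIC_MOUTH_DROP = 10.0  # both palsy types: mouth corner sag, px


@dataclass(frozen=True)
class FaceSpec:
    """Geometry, intensities and palsy profile of one synthetic subject."""

    height: int = 256
    width: int = 256
    eye_row: float = 105.0
    eye_offset: float = 55.5  # eye center distance from the face midline
    aperture_half_w: float = 26.0
    iris_radius: float = 11.0
    brow_row: float = 84.0  # band center; band spans +- thickness/2
    brow_half_w: float = 22.0
    brow_thickness: float = 7.0
    brow_arch: float = 0.0
    mouth_row: float = 200.0
    mouth_half_w: float = 30.0
    mouth_half_h: float = 7.0
    nose_row: float = 155.0
    skin: float = 170.0
    # dark enough that OTSU's dominant split separates the whole palpebral
    # aperture (sclera + iris) from skin rather than the iris from the rest
    sclera: float = 100.0
    iris: float = 40.0
    eyebrow: float = 60.0
    mouth: float = 85.0
    specular_level: float = 255.0
    noise_sd: float = 4.0
    motion_scale: float = 1.0  # scales all pixel-valued expression amplitudes
    asymmetry: float = 0.0
    affected_side: str = "right"
    palsy: str = "none"  # none | peripheral | central
    specular: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ConfigurationError("asymmetry must lie in [0, 1]")
        if self.palsy not in ("none", "peripheral", "central"):
            raise ConfigurationError(f"unknown palsy profile {self.palsy!r}")
        if self.affected_side not in ("left", "right"):
            raise ConfigurationError("affected_side must be 'left' or 'right'")
        if self.motion_scale <= 0:
            raise ConfigurationError("motion_scale must be > 0")
        if self.eye_row + _APERTURE_H["brow_raise"] * self.motion_scale + 6 >= self.mouth_row - 20:
            raise ConfigurationError("face layout out of bounds")
        if self.eye_offset + self.aperture_half_w + 4 >= self.width / 2:
            raise ConfigurationError("eyes exceed image bounds")


@dataclass(frozen=True)
class CohortSpec:
    """Class sizes and per-class feature distributions for tabular cohorts."""

    n_healthy: int = 15
    n_pp: int = 40
    n_cp: int = 10
    healthy_mean: float = 0.97
    healthy_sd: float = 0.02
    pp_mean: float = 0.80
    pp_sd: float = 0.08
    cp_spared_mean: float = 0.95  # forehead/eye features f1..f6
    cp_spared_sd: float = 0.02
    cp_mouth_mean: float = 0.85  # mouth features f7..f9
    cp_mouth_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.n_healthy, self.n_pp, self.n_cp) < 0:
            raise ConfigurationError("class sizes must be non-negative")
        for m in (self.healthy_mean, self.pp_mean, self.cp_spared_mean, self.cp_mouth_mean):
            if not 0.0 < m <= 1.0:
                raise ConfigurationError("class means must lie in (0, 1]")
        for s in (self.healthy_sd, self.pp_sd, self.cp_spared_sd, self.cp_mouth_sd):
            if s <= 0:
                raise ConfigurationError("class sds must be > 0")


@dataclass
class FaceRegistry:
    """Ground truth recorded while rendering one expression."""

    keypoints: dict[str, tuple[int, int]]
    masks: dict[str, np.ndarray]  # eye_*, eyebrow_*, mouth, iris_visible_*
    iris_circles: dict[str, tuple[float, float, float]]  # side -> (row, col, r)
    iris_areas: dict[str, float]
    iris_tops: dict[str, tuple[int, int] | None]
    boxes: dict[str, RoiBox]
    reference_point: tuple[int, int]
    lid_rows: dict[str, float] = field(default_factory=dict)


def _side_params(spec: FaceSpec, side: str, expression: str) -> dict[str, float]:
    """Expression geometry for one side, with palsy deviations applied."""
    a = spec.asymmetry if (spec.palsy != "none" and side == spec.affected_side) else 0.0
    upper_att = 1.0 - a if spec.palsy == "peripheral" else 1.0  # brow + eye motion
    mouth_att = 1.0 - a  # both palsy types affect the mouth
    static_droop = _STATIC_DROOP * a if spec.palsy == "peripheral" else 0.0
    ms = spec.motion_scale  # pixel-valued amplitudes follow the face scale
    p = {
        "aperture_h": (
            _APERTURE_H["rest"]
            + (_APERTURE_H[expression] - _APERTURE_H["rest"]) * upper_att
        ) * ms,
        "droop": float(
            np.clip(
                _DROOP["rest"]
                + (_DROOP[expression] - _DROOP["rest"]) * upper_att
                + static_droop,
                0.0,
                0.95,
            )
        ),
        "brow_lift": _BROW_LIFT[expression] * upper_att * ms,
        "iris_dy": _IRIS_DY[expression] * upper_att * ms,
        "mouth_dy": (_MOUTH_DY[expression] * mouth_att + _STATIC_MOUTH_DROP * a) * ms,
        "mouth_widen": _MOUTH_WIDEN[expression] * mouth_att * ms,
    }
    return p


def _supersample_mask(predicate, shape: tuple[int, int], factor: int = 2) -> np.ndarray:
    """Evaluate an analytic inequality on a ``factor``-times finer grid and
    return per-pixel coverage in [0, 1]."""
    h, w = shape
    step = 1.0 / factor
    coords = (np.arange(h * factor) + 0.5) * step - 0.5
    cols = (np.arange(w * factor) + 0.5) * step - 0.5
    yy, xx = np.meshgrid(coords, cols, indexing="ij")
    fine = predicate(yy, xx).astype(float)
    return fine.reshape(h, factor, w, factor).mean(axis=(1, 3))


def render_face(spec: FaceSpec, expression: str) -> tuple[np.ndarray, FaceRegistry]:
    """Render one expression and its ground-truth registry.

    Deterministic for a given ``(spec, expression)``; the pixel noise is
    generated on the left half and mirrored so that an ``asymmetry = 0``
    face equals its own horizontal mirror exactly.
    """
    if expression not in EXPRESSIONS:
        raise InvalidInputError(f"unknown expression {expression!r}")
    h, w = spec.height, spec.width
    cx = (w - 1) / 2.0
    canvas = np.full((h, w), spec.skin, dtype=float)
    masks: dict[str, np.ndarray] = {}
    keypoints: dict[str, tuple[int, int]] = {}
    circles: dict[str, tuple[float, float, float]] = {}
    areas: dict[str, int] = {}
    tops: dict[str, tuple[int, int] | None] = {}
    lid_rows: dict[str, float] = {}

    def paint(coverage: np.ndarray, level: float) -> None:
        np.copyto(canvas, canvas * (1 - coverage) + level * coverage)

    for side in ("left", "right"):
        p = _side_params(spec, side, expression)
        sgn = -1.0 if side == "left" else 1.0
        ecol = cx + sgn * spec.eye_offset
        brow_center = spec.brow_row - p["brow_lift"]

        def brow_pred(yy, xx, _c=brow_center, _e=ecol):
            dx = xx - _e
            yc = _c - spec.brow_arch * (1 - (dx / spec.brow_half_w) ** 2)
            return (np.abs(dx) <= spec.brow_half_w) & (
                np.abs(yy - yc) <= spec.brow_thickness / 2
            )

        brow_cov = _supersample_mask(brow_pred, (h, w))
        paint(brow_cov, spec.eyebrow)
        masks[f"eyebrow_{side}"] = brow_cov >= 0.5

        irow = spec.eye_row + p["iris_dy"]
        lid_row = irow - spec.iris_radius + p["droop"] * 2 * spec.iris_radius
        lid_rows[side] = lid_row

        def aperture_pred(yy, xx, _e=ecol, _h=p["aperture_h"], _lid=lid_row):
            ell = ((xx - _e) / spec.aperture_half_w) ** 2 + (
                (yy - spec.eye_row) / _h
            ) ** 2 <= 1.0
            return ell & (yy >= _lid)

        ap_cov = _supersample_mask(aperture_pred, (h, w))
        paint(ap_cov, spec.sclera)
        eye_mask = ap_cov >= 0.5
        masks[f"eye_{side}"] = eye_mask

        def iris_pred(yy, xx, _e=ecol, _r=irow, _h=p["aperture_h"], _lid=lid_row):
            disc = np.hypot(yy - _r, xx - _e) <= spec.iris_radius
            ell = ((xx - _e) / spec.aperture_half_w) ** 2 + (
                (yy - spec.eye_row) / _h
            ) ** 2 <= 1.0
            return disc & ell & (yy >= _lid)

        iris_cov = _supersample_mask(iris_pred, (h, w))
        paint(iris_cov, spec.iris)
        iris_mask = iris_cov >= 0.5
        masks[f"iris_visible_{side}"] = iris_mask
        circles[side] = (irow, ecol, spec.iris_radius)
        # antialiased coverage sum: a nearly exact area, free of the
        # binarization error that grows with the cut-boundary length
        areas[side] = float(iris_cov.sum())
        if iris_mask.any():
            rows, cols = np.nonzero(iris_mask)
            top_r = int(rows.min())
            tops[side] = (top_r, int(np.median(cols[rows == top_r])))
        else:
            tops[side] = None

        if spec.specular:
            def spec_pred(yy, xx, _e=ecol, _r=irow):
                return np.hypot(yy - (_r - 2), xx - (_e + 2)) <= 2.2

            spec_cov = _supersample_mask(spec_pred, (h, w)) * (iris_cov > 0)
            paint(spec_cov, spec.specular_level)

        keypoints[f"SO_{side}"] = (
            int(round(brow_center + spec.brow_thickness / 2 - 0.5)),
            int(round(ecol)),
        )
        keypoints[f"IO_{side}"] = (
            int(round(spec.eye_row + p["aperture_h"] - 0.5)),
            int(round(ecol)),
        )
        lateral = -1 if side == "left" else 1
        keypoints[f"OC_{side}"] = (
            int(round(spec.eye_row)),
            int(round(ecol + lateral * spec.aperture_half_w)),
        )
        keypoints[f"IC_{side}"] = (
            int(round(spec.eye_row)),
            int(round(ecol - lateral * spec.aperture_half_w)),
        )
        keypoints[f"upper_eyelid_{side}"] = (
            int(round(max(lid_row, spec.eye_row - p["aperture_h"]) + 0.5)),
            int(round(ecol)),
        )

    # mouth: tapered band with per-side corner displacement and widening
    pl = _side_params(spec, "left", expression)
    pr = _side_params(spec, "right", expression)
    half_w = {"left": spec.mouth_half_w + pl["mouth_widen"], "right": spec.mouth_half_w + pr["mouth_widen"]}
    corner_dy = {"left": pl["mouth_dy"], "right": pr["mouth_dy"]}

    def mouth_pred(yy, xx):
        dx = xx - cx
        hw = np.where(dx < 0, half_w["left"], half_w["right"])
        dy = np.where(dx < 0, corner_dy["left"], corner_dy["right"])
        t = np.clip(np.abs(dx) / hw, 0.0, 1.0)
        yc = spec.mouth_row + dy * t**2
        half_h = spec.mouth_half_h * np.sqrt(np.clip(1.0 - t**2, 0.0, 1.0))
        return (np.abs(dx) <= hw) & (np.abs(yy - yc) <= half_h)

    mouth_cov = _supersample_mask(mouth_pred, (h, w))
    paint(mouth_cov, spec.mouth)
    masks["mouth"] = mouth_cov >= 0.5
    mrows, mcols = np.nonzero(masks["mouth"])
    keypoints["mouth_left"] = (
        int(mrows[mcols == mcols.min()][0]),
        int(mcols.min()),
    )
    keypoints["mouth_right"] = (
        int(mrows[mcols == mcols.max()][0]),
        int(mcols.max()),
    )

    rng = np.random.default_rng(spec.seed)
    noise_half = rng.normal(0.0, spec.noise_sd, size=(h, w // 2 + w % 2))
    noise = np.concatenate([noise_half, noise_half[:, : w // 2][:, ::-1]], axis=1)
    image = np.clip(canvas + noise, 0.0, 255.0)

    boxes = _region_boxes(spec)
    registry = FaceRegistry(
        keypoints=keypoints,
        masks=masks,
        iris_circles=circles,
        iris_areas=areas,
        iris_tops=tops,
        boxes=boxes,
        reference_point=(int(round(spec.nose_row)), int(round(cx))),
        lid_rows=lid_rows,
    )
    return image, registry


def _region_boxes(spec: FaceSpec) -> dict[str, RoiBox]:
    h, w = spec.height, spec.width
    cx = (w - 1) / 2.0
    ms = spec.motion_scale
    boxes = {"face": RoiBox(0, 0, h, w)}
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        ecol = cx + sgn * spec.eye_offset
        c0 = int(round(ecol - spec.aperture_half_w - 6))
        # top sits just below the resting eyebrow band so the brow never
        # competes with the aperture blob inside the eye ROI
        boxes[f"eye_{side}"] = RoiBox(
            int(spec.eye_row - _APERTURE_H["brow_raise"] * ms + 1),
            c0,
            int(2 * _APERTURE_H["brow_raise"] * ms + 5),
            int(2 * spec.aperture_half_w + 13),
        )
        top = int(spec.brow_row - _BROW_LIFT["brow_raise"] * ms - spec.brow_thickness)
        boxes[f"eyebrow_{side}"] = RoiBox(
            top,
            int(round(ecol - spec.brow_half_w - 6)),
            int(spec.brow_row + spec.brow_thickness / 2 + 2 - top),
            int(2 * spec.brow_half_w + 13),
        )
    mouth_w = spec.mouth_half_w + _MOUTH_WIDEN["smile"] * ms + 8
    boxes["mouth"] = RoiBox(
        int(spec.mouth_row - spec.mouth_half_h - _MOUTH_WIDEN["smile"] * ms - 4),
        int(round(cx - mouth_w)),
        int(2 * spec.mouth_half_h + (_STATIC_MOUTH_DROP + _MOUTH_WIDEN["smile"]) * ms + 9),
        int(2 * mouth_w + 1),
    )
    boxes["nose"] = RoiBox(int(spec.nose_row - 15), int(round(cx - 15)), 31, 31)
    return boxes


class RegistryDetector:
    """Feature detector backed by a rendering registry, optionally jittered.

    Stands in for a trained cascade in tests and examples: returns the
    generator's region boxes, each perturbed by at most ``jitter`` pixels.
    """

    def __init__(self, registry: FaceRegistry, jitter: int = 0, seed: int = 0):
        self.registry = registry
        self.jitter = jitter
        self.rng = np.random.default_rng(seed)

    def detect(self, image) -> dict[str, RoiBox]:
        out = {}
        for name, box in self.registry.boxes.items():
            if self.jitter:
                dr, dc = self.rng.integers(-self.jitter, self.jitter + 1, size=2)
                out[name] = RoiBox(box.top + int(dr), box.left + int(dc), box.height, box.width)
            else:
                out[name] = box
        return out


# ---------------------------------------------------------------------------
# tabular cohorts

REGION_FEATURES = {
    "forehead": ("f1", "f2", "f3", "f4", "f5"),
    "eye": ("f1", "f6"),
    "mouth": ("f7", "f8", "f9"),
}

#: monotone step rule: regional mean >= threshold -> grade
GRADE_THRESHOLDS = (0.95, 0.875, 0.80, 0.70, 0.60)


def grade_from_mean(mean: float) -> int:
    """Regional House-Brackmann grade from the regional feature mean."""
    for grade, thr in enumerate(GRADE_THRESHOLDS, start=1):
        if mean >= thr:
            return grade
    return 6


def _truncnorm(rng, mean, sd, size):
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Labeled feature cohort mimicking the clinical class structure.

    Columns: ``subject_id``, ``label`` (healthy/PP/CP), ``f1``..``f10``,
    regional and overall House-Brackmann grades.  ``f10`` is the mean of
    ``f1..f9`` by definition.
    """
    from .classifier import overall_grade_lookup  # local import to avoid a cycle

    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rows = []
    plan = [("healthy", spec.n_healthy), ("PP", spec.n_pp), ("CP", spec.n_cp)]
    idx = 0
    for label, n in plan:
        for _ in range(n):
            f = np.empty(9)
            if label == "healthy":
                f[:] = _truncnorm(rng, spec.healthy_mean, spec.healthy_sd, 9)
            elif label == "PP":
                f[:] = _truncnorm(rng, spec.pp_mean, spec.pp_sd, 9)
            else:  # CP: forehead/eye spared, mouth depressed
                f[:6] = _truncnorm(rng, spec.cp_spared_mean, spec.cp_spared_sd, 6)
                f[6:] = _truncnorm(rng, spec.cp_mouth_mean, spec.cp_mouth_sd, 3)
            row = {"subject_id": f"S{idx:03d}", "label": label}
            row.update({f"f{i+1}": f[i] for i in range(9)})
            row["f10"] = f.mean()
            for region, names in REGION_FEATURES.items():
                row[f"grade_{region}"] = grade_from_mean(
                    np.mean([row[name] for name in names])
                )
            row["grade_overall"] = overall_grade_lookup(
                row["grade_forehead"], row["grade_eye"], row["grade_mouth"],
                fallback="max",
            )
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows)


def generate_grading_cohort(n: int = 240, sd: float = 0.02, seed: int = 0) -> pd.DataFrame:
    """Cohort for regional-grade recovery: each subject's regional grade is
    a monotone step function of an underlying regional mean, observed
    through feature noise of the stated standard deviation."""
    from .classifier import overall_grade_lookup  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        row = {"subject_id": f"G{i:03d}"}
        for region, names in REGION_FEATURES.items():
            m = rng.uniform(0.55, 1.0)
            for name in names:
                row[name] = float(np.clip(rng.normal(m, sd), 0.0, 1.0))
            row[f"grade_{region}"] = grade_from_mean(m)
        # f1 participates in both forehead and eye regions; the eye draw wins
        vals = [row[f"f{j}"] for j in range(1, 10)]
        row["f10"] = float(np.mean(vals))
        row["grade_overall"] = overall_grade_lookup(
            row["grade_forehead"], row["grade_eye"], row["grade_mouth"],
            fallback="max",
        )
        rows.append(row)
    return pd.DataFrame(rows)


def palsy_face_spec(
    label: str, asymmetry: float = 0.5, seed: int = 0, **overrides
) -> FaceSpec:
    """Convenience constructor mapping a class label to a palsy profile."""
    profile = {"healthy": "none", "PP": "peripheral", "CP": "central"}[label]
    a = 0.0 if label == "healthy" else asymmetry
    return replace(
        FaceSpec(palsy=profile, asymmetry=a, seed=seed), **overrides
    )
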