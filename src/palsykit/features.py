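"""Left/right symmetry features from iris exposure and key-point distances.

Ten features summarize one subject's five-expression photo set.  Each is
a ratio in ``[0, 1]`` where 1 means perfect left/right symmetry:

====  ==========================================================
f1    iris-area ratio while lifting the eyebrows (eyes upward)
f2    rate of movement, rest -> brow raise (SO to upper iris)
f3    rate of movement, rest -> brow raise (SO to IO)
f4    SO-IO vertical-distance ratio while lifting eyebrows
f5    SO-to-upper-iris vertical-distance ratio while lifting eyebrows
f6    SO-IO vertical-distance ratio while closing both eyes
f7    iris-area ratio while smiling / showing teeth
f8    IO-to-mouth-corner vertical-distance ratio while smiling
f9    iris-area ratio while screwing up the nose
f10   mean of f1..f9
====  ==========================================================

All pairwise ratios follow the min/max convention (smaller side divided
by larger).  The movement features compare, per side, the change of a
normalized vertical distance between the at-rest and brow-raise images,
anchored at a reference point below the eyes matched between the two
images (a SIFT correspondence in real photographs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .landmarks import KeyPointSet, Point

EXPRESSIONS = ("rest", "brow_raise", "eye_close", "snarl", "smile")
FEATURE_NAMES = tuple(f"f{i}" for i in range(1, 11))


@dataclass
class ExpressionAnalysis:
    """Everything measured on one expression image."""

    keypoints: KeyPointSet
    iris_area_left: float
    iris_area_right: float
    iris_top_left: Point | None = None  # topmost visible-iris pixel
    iris_top_right: Point | None = None
    reference_point: Point | None = None  # matched point below the eyes


@dataclass
class FeatureVector:
    """f1..f10 plus per-feature missingness flags."""

    values: np.ndarray
    subject_id: str = ""
    label: str | None = None
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (10,):
            raise InvalidInputError("feature vector must have 10 entries")

    def as_series(self) -> pd.Series:
        s = pd.Series(self.values, index=list(FEATURE_NAMES))
        s["subject_id"] = self.subject_id
        if self.label is not None:
            s["label"] = self.label
        return s


def sym_ratio(left: float, right: float) -> float:
    """Smaller measurement divided by larger; 1 for equal inputs.

    Both zero (bilateral absence) is symmetric by convention and returns
    1; exactly one zero returns 0.
    """
    if left < 0 or right < 0:
        raise InvalidInputError("measurements must be non-negative")
    if left == right == 0:
        return 1.0
    lo, hi = sorted((float(left), float(right)))
    return lo / hi


def vdist(p: Point, q: Point) -> float:
    """Vertical (row) component of the distance between two key points."""
    return float(abs(p[0] - q[0]))


def _movement(
    rest_y: float, rest_x: float, raise_y: float, raise_x: float
) -> float:
    """|y/x at rest - y/x at raise| for one side; 0 when x degenerate."""
    if rest_x <= 0 or raise_x <= 0:
        raise InvalidInputError("reference distances must be positive")
    return abs(rest_y / rest_x - raise_y / raise_x)


def rate_of_movement(
    rest: ExpressionAnalysis,
    brow_raise: ExpressionAnalysis,
    *,
    measure: str = "SO_IO",
) -> tuple[float, str | None]:
    """Symmetry of the eyebrow-raise motion between the two sides.

    Per side, the vertical distance from SO down to the measured point
    (IO, or the upper visible-iris boundary) is normalized by the
    vertical distance from SO to the matched reference point below the
    eyes, in both the at-rest and brow-raise images; the absolute change
    of that normalized distance is the side's movement magnitude.  The
    feature is the min/max ratio of the two magnitudes: ~1 for a
    symmetric raise, ~0 when only one side moves.  When neither side
    moves the value is 1 with a ``bilateral_inability`` flag (no
    asymmetry is observable).
    """
    if measure not in ("SO_IO", "SO_uIris"):
        raise InvalidInputError("measure must be 'SO_IO' or 'SO_uIris'")
    for analysis in (rest, brow_raise):
        if analysis.reference_point is None:
            return 1.0, "missing_reference"

    def side_y(analysis: ExpressionAnalysis, side: str) -> float | None:
        so = getattr(analysis.keypoints, f"SO_{side}")
        if measure == "SO_IO":
            return vdist(so, getattr(analysis.keypoints, f"IO_{side}"))
        top = getattr(analysis, f"iris_top_{side}")
        if top is None:
            return None
        return vdist(so, top)

    movements = {}
    for side in ("left", "right"):
        ys = [side_y(rest, side), side_y(brow_raise, side)]
        if any(y is None for y in ys):
            return 1.0, "missing_iris_top"
        xs = [
            vdist(getattr(a.keypoints, f"SO_{side}"), a.reference_point)
            for a in (rest, brow_raise)
        ]
        movements[side] = _movement(ys[0], xs[0], ys[1], xs[1])
    lo, hi = sorted(movements.values())
    if hi == 0:
        return 1.0, "bilateral_inability"
    return lo / hi, None


def extract_features(
    subject: Mapping[str, ExpressionAnalysis],
    *,
    subject_id: str = "",
    label: str | None = None,
    clip: bool = True,
) -> FeatureVector:
    """Compute f1..f10 from the five analyzed expressions.

    Missing constituents are imputed with 1.0 (no asymmetry detected) and
    flagged, so a vector is always emitted; the flags travel to the
    classifier for sensitivity analysis.
    """
    missing = [e for e in EXPRESSIONS if e not in subject]
    if missing:
        raise InvalidInputError(f"missing expressions: {', '.join(missing)}")
    flags: dict[str, str] = {}
    raise_a = subject["brow_raise"]
    kp_raise = raise_a.keypoints

    f = np.ones(10)
    f[0] = sym_ratio(raise_a.iris_area_left, raise_a.iris_area_right)
    f[1], flag = rate_of_movement(subject["rest"], raise_a, measure="SO_uIris")
    if flag:
        flags["f2"] = flag
    f[2], flag = rate_of_movement(subject["rest"], raise_a, measure="SO_IO")
    if flag:
        flags["f3"] = flag
    f[3] = sym_ratio(
        vdist(kp_raise.SO_left, kp_raise.IO_left),
        vdist(kp_raise.SO_right, kp_raise.IO_right),
    )
    if raise_a.iris_top_left is not None and raise_a.iris_top_right is not None:
        f[4] = sym_ratio(
            vdist(kp_raise.SO_left, raise_a.iris_top_left),
            vdist(kp_raise.SO_right, raise_a.iris_top_right),
        )
    else:
        flags["f5"] = "missing_iris_top"
    kp_close = subject["eye_close"].keypoints
    f[5] = sym_ratio(
        vdist(kp_close.SO_left, kp_close.IO_left),
        vdist(kp_close.SO_right, kp_close.IO_right),
    )
    smile = subject["smile"]
    f[6] = sym_ratio(smile.iris_area_left, smile.iris_area_right)
    f[7] = sym_ratio(
        vdist(smile.keypoints.IO_left, smile.keypoints.mouth_left),
        vdist(smile.keypoints.IO_right, smile.keypoints.mouth_right),
    )
    f[8] = sym_ratio(subject["snarl"].iris_area_left, subject["snarl"].iris_area_right)
    if clip:
        f[:9] = np.clip(f[:9], 0.0, 1.0)
    f[9] = f[:9].mean()
    return FeatureVector(values=f, subject_id=subject_id, label=label, flags=flags)


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """One row per subject, columns f1..f10 plus identifiers."""
    return pd.DataFrame([v.as_series() for v in vectors]).reset_index(drop=True)
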