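"""Key-point extraction from segmented facial-feature masks.

Ten landmarks drive the symmetry features: per side the supra-orbital
point SO (on the eyebrow), the infra-orbital point IO, the inner and
outer canthi IC/OC (eye corners), and the two mouth corners.  Each point
is an extremal foreground pixel of its feature's binary mask, located via
the distance transform: background pixels carry their distance to the
nearest foreground pixel, and the first zero-valued coordinate in a fixed
scan order from the queried side is the corner.

Side labels refer to the image: ``left`` is the viewer's left (smaller
column indices).  For the viewer-left eye the outer canthus is the
lateral (leftmost) extremal point and the inner canthus the medial
(rightmost) one; the roles swap on the right eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, LandmarkError

Point = tuple[int, int]  # (row, col)

REQUIRED_MASKS = ("eye_left", "eye_right", "eyebrow_left", "eyebrow_right", "mouth")


@dataclass
class KeyPointSet:
    """The 10 landmarks, rows/cols in full-image coordinates."""

    SO_left: Point
    SO_right: Point
    IO_left: Point
    IO_right: Point
    IC_left: Point
    IC_right: Point
    OC_left: Point
    OC_right: Point
    mouth_left: Point
    mouth_right: Point
    upper_eyelid_left: Point | None = None
    upper_eyelid_right: Point | None = None
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, Point]:
        d = {
            name: getattr(self, name)
            for name in (
                "SO_left", "SO_right", "IO_left", "IO_right",
                "IC_left", "IC_right", "OC_left", "OC_right",
                "mouth_left", "mouth_right",
            )
        }
        return d

    def validate(self) -> None:
        for side in ("left", "right"):
            so = getattr(self, f"SO_{side}")
            io = getattr(self, f"IO_{side}")
            if so[0] >= io[0]:
                raise LandmarkError(
                    f"SO_{side} {so} must lie above IO_{side} {io}"
                )


def extremal_point(
    mask: np.ndarray,
    side: str,
    *,
    window: tuple[slice, slice] | None = None,
) -> Point:
    """Extremal foreground pixel on the stated side of the mask.

    Computes the distance transform of the (optionally windowed) mask —
    each background pixel's distance to the nearest foreground pixel —
    and scans from the queried side for the first zero value.  Scan order
    is column-major from the scanned side for ``left``/``right`` (rows
    top-to-bottom within a column, so ties break toward the smaller row);
    for ``top``/``bottom`` the scan is row-major and a tie (flat extremal
    row) resolves to the center of the run, which is mirror-symmetric.
    Equivalent to a direct extremal-pixel scan.
    """
    m = np.asarray(mask, dtype=bool)
    offset = (0, 0)
    if window is not None:
        sub = m[window]
        offset = (window[0].start or 0, window[1].start or 0)
        m = sub
    if not m.any():
        raise LandmarkError("empty mask: no extremal point")
    # distance to nearest foreground pixel; zeros mark the foreground
    dist = ndimage.distance_transform_edt(~m)
    if side in ("left", "right"):
        cols = range(m.shape[1]) if side == "left" else range(m.shape[1] - 1, -1, -1)
        for c in cols:
            rows = np.nonzero(dist[:, c] == 0)[0]
            if rows.size:
                return (int(rows[0]) + offset[0], c + offset[1])
    elif side in ("top", "bottom"):
        rows = range(m.shape[0]) if side == "top" else range(m.shape[0] - 1, -1, -1)
        for r in rows:
            cols_nz = np.nonzero(dist[r] == 0)[0]
            if cols_nz.size:
                # rasterized ellipses have flat extremal rows; the center
                # of the run is the stable, mirror-symmetric choice
                return (r + offset[0], int(cols_nz[cols_nz.size // 2]) + offset[1])
    else:
        raise InvalidInputError(f"side must be left/right/top/bottom, got {side!r}")
    raise LandmarkError("empty mask: no extremal point")  # pragma: no cover


def eye_keypoints(eye_mask: np.ndarray, side_label: str) -> dict[str, Point]:
    """Upper eyelid, IO, IC and OC from a segmented eye mask.

    ``side_label`` resolves laterality: on the viewer-left eye the outer
    canthus is the leftmost point; on the viewer-right eye the rightmost.
    A mask only one pixel high is flagged degenerate (top and bottom
    coincide).
    """
    if side_label not in ("left", "right"):
        raise InvalidInputError("side_label must be 'left' or 'right'")
    lateral = "left" if side_label == "left" else "right"
    medial = "right" if side_label == "left" else "left"
    pts = {
        "upper_eyelid": extremal_point(eye_mask, "top"),
        "IO": extremal_point(eye_mask, "bottom"),
        "OC": extremal_point(eye_mask, lateral),
        "IC": extremal_point(eye_mask, medial),
    }
    pts["degenerate"] = pts["upper_eyelid"][0] == pts["IO"][0]
    return pts


def eyebrow_SO(eyebrow_mask: np.ndarray) -> Point:
    """Supra-orbital point: lowest eyebrow pixel on the vertical through
    the mask centroid (the point nearest the eye)."""
    m = np.asarray(eyebrow_mask, dtype=bool)
    if not m.any():
        raise LandmarkError("empty eyebrow mask")
    rows, cols = np.nonzero(m)
    ccol = int(round(cols.mean()))
    # fall back to the nearest populated column if the centroid column is empty
    populated = np.unique(cols)
    col = int(populated[np.argmin(np.abs(populated - ccol))])
    rmax = int(rows[cols == col].max())
    return (rmax, col)


def mouth_corners(mouth_mask: np.ndarray) -> tuple[Point, Point]:
    """Left and right mouth corners: each half of the mask is scanned
    from its outer side, mirroring the half-image procedure."""
    m = np.asarray(mouth_mask, dtype=bool)
    if not m.any():
        raise LandmarkError("empty mouth mask")
    mid = m.shape[1] // 2
    left = extremal_point(m, "left", window=(slice(None), slice(0, mid)))
    right = extremal_point(m, "right", window=(slice(None), slice(mid, None)))
    return left, right


def assemble_keypoints(masks: Mapping[str, np.ndarray]) -> KeyPointSet:
    """Build the full 10-point landmark set from per-feature masks.

    ``masks`` must contain ``eye_left``, ``eye_right``, ``eyebrow_left``,
    ``eyebrow_right`` and ``mouth`` (boolean arrays in full-image
    coordinates).  Missing masks raise a :class:`LandmarkError` naming
    them.
    """
    missing = [k for k in REQUIRED_MASKS if k not in masks]
    if missing:
        raise LandmarkError(f"missing masks: {', '.join(missing)}")
    eyes = {s: eye_keypoints(masks[f"eye_{s}"], s) for s in ("left", "right")}
    ml, mr = mouth_corners(masks["mouth"])
    kps = KeyPointSet(
        SO_left=eyebrow_SO(masks["eyebrow_left"]),
        SO_right=eyebrow_SO(masks["eyebrow_right"]),
        IO_left=eyes["left"]["IO"],
        IO_right=eyes["right"]["IO"],
        IC_left=eyes["left"]["IC"],
        IC_right=eyes["right"]["IC"],
        OC_left=eyes["left"]["OC"],
        OC_right=eyes["right"]["OC"],
        mouth_left=ml,
        mouth_right=mr,
        upper_eyelid_left=eyes["left"]["upper_eyelid"],
        upper_eyelid_right=eyes["right"]["upper_eyelid"],
        provenance={k: "mask" for k in REQUIRED_MASKS},
    )
    kps.validate()
    return kps
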