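"""Shared fixtures: synthetic eye scenes and rendered faces."""

import numpy as np
import pytest

from palsykit import synthetic as syn


def make_eye_scene(
    r=20,
    center=(50, 55),
    occlusion=0.0,
    specular=False,
    shape=(100, 110),
    seed=0,
    ground=120.0,
    iris=40.0,
    noise_sd=3.0,
):
    """Dark disc (partially lid-occluded from above) on a mid-gray ground."""
    img = np.full(shape, ground)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    disc = np.hypot(yy - center[0], xx - center[1]) <= r
    lid = center[0] - r + occlusion * 2 * r
    img[disc & (yy >= lid)] = iris
    if specular:
        img[np.hypot(yy - (center[0] - 3), xx - (center[1] + 2)) <= 2] = 255.0
    img += np.random.default_rng(seed).normal(0, noise_sd, shape)
    return np.clip(img, 0, 255)


@pytest.fixture(scope="session")
def eye_scene_factory():
    return make_eye_scene


@pytest.fixture(scope="session")
def symmetric_face():
    """One symmetric subject: images and registries for all expressions."""
    spec = syn.FaceSpec(seed=7)
    out = {}
    for expr in syn.EXPRESSIONS:
        out[expr] = syn.render_face(spec, expr)
    return spec, out


def registry_analysis(reg):
    """ExpressionAnalysis assembled from a rendering registry's masks."""
    from palsykit import features as ft, landmarks as lm

    kps = lm.assemble_keypoints(reg.masks)
    return ft.ExpressionAnalysis(
        keypoints=kps,
        iris_area_left=reg.iris_areas["left"],
        iris_area_right=reg.iris_areas["right"],
        iris_top_left=reg.iris_tops["left"],
        iris_top_right=reg.iris_tops["right"],
        reference_point=reg.reference_point,
    )


def subject_features(spec):
    """Feature vector of one subject, measured on registry ground truth."""
    from palsykit import features as ft

    return ft.extract_features(
        {
            expr: registry_analysis(syn.render_face(spec, expr)[1])
            for expr in syn.EXPRESSIONS
        }
    )
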