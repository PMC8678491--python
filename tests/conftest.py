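"""Shared fixtures: small cameras and pre-rendered scenes.

Session-scoped fixtures carry the expensive renders/estimations that several
tests share; everything is generated programmatically and seeded.
"""

from __future__ import annotations

import pytest

from lffundus.depth_estimation import estimate_depth
from lffundus.pipeline import RunConfig, process_raw
from lffundus.plenoptic_model import (
    CameraConfig,
    MagnificationModel,
    SensorSpec,
    desk_camera,
)
from lffundus.synthetic_data import make_fundus_scene, render_raw_lightfield


@pytest.fixture(scope="session")
def desk_cam() -> CameraConfig:
    return desk_camera()


@pytest.fixture(scope="session")
def mini_cam() -> CameraConfig:
    """A small but fully functional camera for fast unit tests."""
    return CameraConfig(
        sensor=SensorSpec(360, 280, 5.55, 16),
        lens_pitch_um=80.0,
        magnification=MagnificationModel(lateral_mag=1.5),
    )


@pytest.fixture(scope="session")
def tiny_cam() -> CameraConfig:
    """Seven-lens instance for exhaustive brute-force comparisons.

    The pitch is deliberately not a multiple of half a pixel so that rounded
    reverse-landing offsets never sit exactly on a .5 tie.
    """
    return CameraConfig(
        sensor=SensorSpec(50, 51, 5.55, 16),
        lens_pitch_um=83.3,  # ~15.009 px subimages
        magnification=MagnificationModel(lateral_mag=1.5),
    )


@pytest.fixture(scope="session")
def flat_scene():
    """Effectively flat fundus: constant virtual depth = reference depth."""
    return make_fundus_scene(0.0, seed=11, fundus_radius_mm=1e6)


@pytest.fixture(scope="session")
def flat_raw_mini(flat_scene, mini_cam):
    return render_raw_lightfield(flat_scene, mini_cam, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def flat_points_mini(flat_raw_mini):
    return estimate_depth(flat_raw_mini)


@pytest.fixture(scope="session")
def cup_scene_desk():
    return make_fundus_scene(0.8, seed=21)


@pytest.fixture(scope="session")
def cup_raw_desk(cup_scene_desk, desk_cam):
    return render_raw_lightfield(cup_scene_desk, desk_cam, noise_sd=0.0, seed=21)


@pytest.fixture(scope="session")
def cup_dmap_desk(cup_raw_desk):
    return process_raw(cup_raw_desk, RunConfig())
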