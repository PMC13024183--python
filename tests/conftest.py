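"""Shared fixtures: small rendered scenes, reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from stmdkit.synthetic import SceneSpec, render_sequence


@pytest.fixture(scope="session")
def clutter_scene():
    """64x64, 120-frame cluttered scene with a moving target (0.25 px/frame)."""
    spec = SceneSpec(
        height=64, width=64, n_frames=120, frame_rate=100.0,
        target_speed=25.0, background_speed=15.0, texture_seed=7,
    )
    frames, gt = render_sequence(spec)
    return spec, frames, gt


@pytest.fixture(scope="session")
def static_scene():
    """120 identical cluttered frames (no motion anywhere)."""
    spec = SceneSpec(
        height=64, width=64, n_frames=120, frame_rate=100.0,
        target_speed=0.0, background_speed=0.0, texture_seed=7,
    )
    frames, gt = render_sequence(spec)
    assert np.array_equal(frames[0], frames[-1])
    return spec, frames, gt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
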