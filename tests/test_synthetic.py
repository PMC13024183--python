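"""Synthetic scene generator: determinism, geometry, texture properties."""

from __future__ import annotations

import numpy as np
import pytest

from stmdkit.synthetic import (
    SceneSpec,
    fixture_suite,
    make_background,
    render_sequence,
    roc_benchmark_scene,
)

SMALL = dict(height=48, width=48, n_frames=40, frame_rate=100.0,
             target_speed=25.0, background_speed=15.0, texture_seed=3)


def test_render_is_deterministic():
    a, gt_a = render_sequence(SceneSpec(**SMALL))
    b, gt_b = render_sequence(SceneSpec(**SMALL))
    assert np.array_equal(a, b)
    assert gt_a.entries == gt_b.entries


def test_different_seeds_differ_substantially():
    a, _ = render_sequence(SceneSpec(**SMALL))
    b, _ = render_sequence(SceneSpec(**{**SMALL, "texture_seed": 4}))
    assert np.mean(a[0] != b[0]) > 0.10


def test_pixel_range_and_dtype():
    frames, _ = render_sequence(SceneSpec(**SMALL))
    assert frames.dtype == np.float64
    assert frames.min() >= 0.0 and frames.max() <= 255.0


def test_ground_truth_tracks_constant_speed_motion():
    spec = SceneSpec(**SMALL)
    _, gt = render_sequence(spec)
    step = spec.target_speed / spec.frame_rate
    rows = [r for _, r, _ in gt.entries]
    cols = [c for _, _, c in gt.entries]
    assert len(gt) == spec.n_frames
    assert all(r == spec.height / 2.0 for r in rows)
    # default: background right, target left, starting at the center
    assert cols[0] == spec.width / 2.0
    assert cols[1] == pytest.approx((spec.width / 2.0 - step) % spec.width)
    diffs = np.diff(cols)
    wrapless = diffs[np.abs(diffs) < spec.width / 2]
    assert np.allclose(wrapless, -step)


def test_target_start_col_honored_and_no_wrap():
    spec = SceneSpec(**{**SMALL, "target_start_col": 40.0})
    _, gt = render_sequence(spec)
    cols = np.array([c for _, _, c in gt.entries])
    assert cols[0] == 40.0
    assert np.all(np.diff(cols) < 0)  # monotone: never wrapped


def test_target_darkens_scene_locally():
    spec = SceneSpec(**{**SMALL, "texture_kind": "uniform", "background_speed": 0.0})
    frames, gt = render_sequence(spec)
    r, c = gt.position(0)
    r, c = int(round(r)), int(round(c))
    assert frames[0][r, c] == pytest.approx(255.0 * spec.target_luminance)
    far = frames[0].copy()
    far[r - 5 : r + 6, c - 5 : c + 6] = np.nan
    assert np.nanmin(far) == pytest.approx(140.0)  # uniform texture level


def test_subpixel_motion_changes_frames_smoothly():
    spec = SceneSpec(**SMALL)  # 0.25 / 0.15 px per frame
    frames, _ = render_sequence(spec)
    assert not np.array_equal(frames[0], frames[1])  # subpixel shift visible
    assert np.max(np.abs(frames[1] - frames[0])) < 160.0  # no integer jumps


def test_n_render_gives_identical_prefix():
    spec = SceneSpec(**SMALL)
    full, gt_full = render_sequence(spec)
    part, gt_part = render_sequence(spec, n_render=10)
    assert part.shape[0] == 10
    assert np.array_equal(part, full[:10])
    assert gt_part.entries == gt_full.entries[:10]


def test_background_translates_at_spec_rate():
    spec = SceneSpec(**{**SMALL, "target_luminance": 1.0})  # target invisible? no —
    # use a target far above/below sampled rows instead: compare rows away from it
    spec = SceneSpec(**SMALL)
    frames, _ = render_sequence(spec)
    # background moves 0.15 px/frame -> after 20 frames, 3 px. Rows far from
    # the target (row 24) should match a 3-px shifted window of frame 0.
    row = 5
    a = frames[0][row, 3:-3]
    b = frames[20][row, :]
    # background moves right on screen: frame 20 content appears shifted right
    shifted = b[6:]
    assert np.corrcoef(a[: shifted.size], shifted)[0, 1] > 0.98


def test_static_scene_frames_identical(static_scene):
    _, frames, _ = static_scene
    assert np.array_equal(frames[0], frames[60])
    assert np.array_equal(frames[0], frames[-1])


def test_skyline_corridor_clear_and_strips_cluttered():
    spec = roc_benchmark_scene()
    tex = make_background(spec)
    h = spec.height
    corridor = tex[int(h / 2 - h / 3) + 4 : int(h / 2 + h / 3) - 4, :]
    strips = np.vstack([tex[: int(h / 2 - h / 3) - 1, :], tex[int(h / 2 + h / 3) + 2 :, :]])
    assert corridor.min() > 50.0  # smooth base only, no near-black pixels
    assert (strips < 20.0).mean() > 0.05  # dense near-black clutter
    # distractors are near-black against a 70-130 base: strong contrast
    assert strips.min() < 10.0


def test_roc_benchmark_scene_is_frozen():
    spec = roc_benchmark_scene()
    assert (spec.height, spec.width, spec.n_frames) == (64, 64, 300)
    assert spec.frame_rate == 100.0
    assert spec.target_speed == spec.background_speed == 15.0
    assert spec.target_start_col == 55.0
    assert spec.texture_kind == "skyline"
    assert roc_benchmark_scene(9).texture_seed == 9


def test_full_scale_default_protocol_values():
    spec = SceneSpec()
    assert (spec.height, spec.width) == (250, 500)
    assert spec.n_frames == 900
    assert spec.frame_rate == 1000.0
    assert spec.target_size == 5
    assert spec.target_speed == 250.0
    assert spec.background_speed == 150.0
    assert spec.target_luminance == 0.0


def test_fixture_suite_contents():
    suite = fixture_suite()
    assert set(suite) == {
        "static", "target-only", "default-clutter", "wide-bar", "low-contrast"
    }
    for name, (spec, frames, gt) in suite.items():
        assert frames.shape == (spec.n_frames, spec.height, spec.width)
        assert len(gt) == spec.n_frames
    static_spec, static_frames, _ = suite["static"]
    assert np.array_equal(static_frames[0], static_frames[-1])
    assert suite["wide-bar"][0].target_size == 21


def test_scene_spec_validation_and_roundtrip():
    with pytest.raises(ValueError):
        SceneSpec(background_direction="up")
    with pytest.raises(ValueError):
        SceneSpec(texture_kind="checker")
    with pytest.raises(ValueError):
        SceneSpec(target_luminance=1.5)
    with pytest.raises(ValueError):
        SceneSpec(n_frames=0)
    spec = SceneSpec(**SMALL)
    assert SceneSpec.from_dict(spec.to_dict()) == spec
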