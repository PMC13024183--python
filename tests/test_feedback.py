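"""Trajectory feedback stage: NMS, tracking, response range, gain map."""

from __future__ import annotations

import math

import numpy as np
import pytest

from stmdkit.feedback import (
    Detection,
    FeedbackConfig,
    Trajectory,
    TrajectoryStore,
    classify_targets,
    feedback_map,
    find_candidates,
    response_range,
    update_trajectories,
)

from oracles import NaiveTracker, naive_nms_candidates


def as_tuples(dets):
    return [(d.position[0], d.position[1], d.response) for d in dets]


def test_find_candidates_empty_below_threshold():
    cfg = FeedbackConfig()
    grid = np.full((10, 10), 4.9)
    assert find_candidates(grid, cfg, frame=0) == []


def test_find_candidates_single_peak():
    cfg = FeedbackConfig()
    grid = np.zeros((10, 10))
    grid[3, 7] = 10.0
    dets = find_candidates(grid, cfg, frame=5)
    assert dets == [Detection((3, 7), 10.0, 5)]


def test_find_candidates_nms_keeps_strongest_and_breaks_ties_row_major():
    cfg = FeedbackConfig(nms_radius=3.0)
    grid = np.zeros((12, 12))
    grid[5, 5] = 8.0
    grid[5, 7] = 9.0  # within radius of (5,5): wins, suppresses it
    grid[9, 9] = 8.0  # tie with (5,5) but far away; kept
    grid[2, 2] = 8.0  # tie: row-major order decides ordering only
    dets = find_candidates(grid, cfg, frame=0)
    assert {d.position for d in dets} == {(5, 7), (2, 2), (9, 9)}


@pytest.mark.parametrize("seed", range(25))
def test_find_candidates_matches_bruteforce(seed, rng=None):
    r = np.random.default_rng(seed)
    grid = r.uniform(0, 10, (15, 15))
    # quantize to force response ties
    grid = np.round(grid * 2) / 2
    cfg = FeedbackConfig(candidate_threshold=5.0, nms_radius=float(r.uniform(1, 5)))
    got = as_tuples(find_candidates(grid, cfg, frame=0))
    want = naive_nms_candidates(grid, cfg.candidate_threshold, cfg.nms_radius)
    assert got == want


def test_update_trajectories_basic_association():
    cfg = FeedbackConfig()
    store = TrajectoryStore()
    update_trajectories(store, [Detection((10, 10), 7.0, 0)], 0, cfg)
    update_trajectories(store, [Detection((10, 12), 8.0, 1)], 1, cfg)
    assert len(store.trajectories) == 1
    traj = store.trajectories[0]
    assert traj.points == [(0, 10, 10), (1, 10, 12)]
    assert traj.trace == [7.0, 8.0]
    assert traj.status == "active"


def test_update_trajectories_distant_detection_starts_new_track():
    cfg = FeedbackConfig()
    store = TrajectoryStore()
    update_trajectories(store, [Detection((10, 10), 7.0, 0)], 0, cfg)
    update_trajectories(store, [Detection((20, 20), 8.0, 1)], 1, cfg)
    assert len(store.trajectories) == 2
    assert store.trajectories[0].status == "pending"


def test_grace_period_lifecycle():
    cfg = FeedbackConfig(grace=3)
    store = TrajectoryStore()
    update_trajectories(store, [Detection((5, 5), 7.0, 0)], 0, cfg)
    traj = store.trajectories[0]
    for t in range(1, 4):  # misses 1..3 tolerated
        update_trajectories(store, [], t, cfg)
        assert traj.status == "pending"
    update_trajectories(store, [], 4, cfg)  # missed = 4 > grace
    assert traj.status == "terminated"


def test_pending_rematch_resets_miss_count():
    cfg = FeedbackConfig()
    store = TrajectoryStore()
    update_trajectories(store, [Detection((5, 5), 7.0, 0)], 0, cfg)
    update_trajectories(store, [], 1, cfg)
    update_trajectories(store, [Detection((5, 6), 9.0, 2)], 2, cfg)
    traj = store.trajectories[0]
    assert traj.status == "active"
    assert traj.missed == 0
    assert traj.points[-1] == (2, 5, 6)


def test_update_trajectories_rejects_stale_detections():
    cfg = FeedbackConfig()
    store = TrajectoryStore()
    with pytest.raises(ValueError, match="frame"):
        update_trajectories(store, [Detection((1, 1), 6.0, 3)], 5, cfg)


@pytest.mark.parametrize("seed", range(30))
def test_tracking_matches_bruteforce(seed):
    r = np.random.default_rng(100 + seed)
    cfg = FeedbackConfig(
        assoc_radius=float(r.uniform(2, 6)), grace=int(r.integers(1, 4))
    )
    store = TrajectoryStore()
    ref = NaiveTracker(cfg.assoc_radius, cfg.grace)
    for t in range(12):
        k = int(r.integers(0, 5))
        dets = [
            (int(r.integers(0, 20)), int(r.integers(0, 20)), float(r.uniform(5, 20)))
            for _ in range(k)
        ]
        update_trajectories(
            store, [Detection((dr, dc), resp, t) for dr, dc, resp in dets], t, cfg
        )
        ref.update(dets, t)
    got = [
        (tr.points, tr.trace, tr.status) for tr in store.trajectories
    ]
    want = [
        (tr["points"], tr["trace"], tr["status"]) for tr in ref.tracks
    ]
    assert got == want


def test_response_range_windowing():
    traj = Trajectory(id=0)
    for i, v in enumerate([10.0, 55.0, 20.0, 30.0]):
        traj.append(i, 0, 0, v)
    assert response_range(traj, 75) == 45.0
    assert response_range(traj, 2) == 10.0  # only [20, 30]
    assert response_range(traj, math.inf) == 45.0
    with pytest.raises(ValueError):
        response_range(Trajectory(id=1), 75)


def test_classify_targets_active_only_and_threshold():
    cfg = FeedbackConfig()
    store = TrajectoryStore()
    hot = store.new(0, 4, 4, 10.0)
    hot.append(1, 4, 5, 55.0)  # RV 45 > 35
    cold = store.new(0, 9, 9, 10.0)
    cold.append(1, 9, 9, 30.0)  # RV 20
    paused = store.new(0, 14, 14, 5.0)
    paused.append(1, 14, 14, 80.0)  # RV 75 but pending
    paused.status = "pending"
    assert classify_targets(store, cfg, 1) == [(4, 5)]


def test_feedback_map_zero_without_targets():
    cfg = FeedbackConfig()
    assert np.array_equal(feedback_map([], cfg, (8, 8)), np.zeros((8, 8)))


def test_feedback_map_analytic_peak():
    cfg = FeedbackConfig()  # a=30, sigma_f=2
    f = feedback_map([(10, 10)], cfg, (21, 21))
    assert f[10, 10] == pytest.approx(30.0 / (2 * math.pi * 4.0), rel=1e-12)
    assert f[10, 10] == pytest.approx(1.1937, abs=1e-4)
    assert np.argmax(f) == 10 * 21 + 10


def test_feedback_map_superposition():
    cfg = FeedbackConfig()
    both = feedback_map([(10, 10), (10, 50)], cfg, (21, 61))
    a = feedback_map([(10, 10)], cfg, (21, 61))
    b = feedback_map([(10, 50)], cfg, (21, 61))
    assert np.allclose(both, a + b, atol=1e-15)


def test_feedback_map_locality_below_one_percent_beyond_3sigma():
    cfg = FeedbackConfig()
    f = feedback_map([(20, 20)], cfg, (41, 41))
    rr, cc = np.mgrid[0:41, 0:41]
    far = (rr - 20) ** 2 + (cc - 20) ** 2 > (3 * cfg.sigma_f) ** 2
    assert f[far].max() < 0.01 * f.max()


def test_feedback_map_out_of_bounds_raises():
    cfg = FeedbackConfig()
    with pytest.raises(ValueError, match="outside"):
        feedback_map([(50, 2)], cfg, (10, 10))


def test_feedback_config_validation():
    with pytest.raises(ValueError):
        FeedbackConfig(gain=0.0)
    with pytest.raises(ValueError):
        FeedbackConfig(sigma_f=-1.0)
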