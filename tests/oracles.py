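"""Independent brute-force reference implementations used as test oracles.

Everything here is written with plain loops and explicit index arithmetic,
deliberately avoiding the library code paths (scipy.ndimage, vectorized NMS,
the pipeline classes) so that agreement is meaningful evidence of
correctness rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def naive_conv2d_replicate(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Textbook 2-D convolution with replicate padding, explicit loops."""
    kh, kw = kernel.shape
    ch, cw = kh // 2, kw // 2
    h, w = image.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for i in range(kh):
                for j in range(kw):
                    # convolution: output(r,c) = sum kernel(i,j) * image(r-(i-ch), c-(j-cw))
                    rr = min(max(r - (i - ch), 0), h - 1)
                    cc = min(max(c - (j - cw), 0), w - 1)
                    acc += kernel[i, j] * image[rr, cc]
            out[r, c] = acc
    return out


def naive_pathway(
    frames: np.ndarray,
    g1: np.ndarray,
    h_weights: np.ndarray,
    gam3_weights: np.ndarray,
    k_weights: np.ndarray,
) -> list[np.ndarray]:
    """Reference feedforward pathway (no feedback): returns D per frame.

    Temporal sums treat missing history as zero.
    """
    n = frames.shape[0]
    p_seq = [naive_conv2d_replicate(np.asarray(f, dtype=np.float64), g1) for f in frames]
    out = []
    off_seq: list[np.ndarray] = []
    for t in range(n):
        l_grid = np.zeros_like(p_seq[0])
        for s in range(h_weights.size):
            if t - s < 0:
                break
            l_grid = l_grid + h_weights[s] * p_seq[t - s]
        s_on = np.where(l_grid > 0, l_grid, 0.0)
        off_raw = np.where(l_grid < 0, -l_grid, 0.0)
        off_seq.append(off_raw)
        s_off = np.zeros_like(off_raw)
        for s in range(gam3_weights.size):
            if t - s < 0:
                break
            s_off = s_off + gam3_weights[s] * off_seq[t - s]
        s_grid = s_on * s_off
        d = naive_conv2d_replicate(s_grid, k_weights)
        out.append(np.where(d > 0, d, 0.0))
    return out


def naive_nms_candidates(
    grid: np.ndarray, threshold: float, radius: float
) -> list[tuple[int, int, float]]:
    """Greedy peak selection: highest response first, row-major tie-break."""
    h, w = grid.shape
    cands = [
        (float(grid[r, c]), r, c)
        for r in range(h)
        for c in range(w)
        if grid[r, c] > threshold
    ]
    cands.sort(key=lambda x: (-x[0], x[1], x[2]))
    kept: list[tuple[int, int, float]] = []
    for resp, r, c in cands:
        if all((r - kr) ** 2 + (c - kc) ** 2 > radius**2 for kr, kc, _ in kept):
            kept.append((r, c, resp))
    return kept


class NaiveTracker:
    """Reference greedy nearest-pair tracker mirroring the published rules."""

    def __init__(self, assoc_radius: float, grace: int) -> None:
        self.assoc_radius = assoc_radius
        self.grace = grace
        self.tracks: list[dict] = []  # {"id", "points", "trace", "missed", "status"}
        self._next_id = 0

    def update(self, detections: list[tuple[int, int, float]], t: int) -> None:
        live = [tr for tr in self.tracks if tr["status"] != "terminated"]
        pairs = []
        for ti, tr in enumerate(live):
            lr, lc = tr["points"][-1][1], tr["points"][-1][2]
            for di, (r, c, _resp) in enumerate(detections):
                dist = math.hypot(r - lr, c - lc)
                if dist <= self.assoc_radius:
                    pairs.append((dist, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            r, c, resp = detections[di]
            live[ti]["points"].append((t, r, c))
            live[ti]["trace"].append(resp)
            live[ti]["missed"] = 0
            live[ti]["status"] = "active"
        for ti, tr in enumerate(live):
            if ti not in used_t:
                tr["missed"] += 1
                tr["status"] = "terminated" if tr["missed"] > self.grace else "pending"
        for di, (r, c, resp) in enumerate(detections):
            if di not in used_d:
                self.tracks.append(
                    {
                        "id": self._next_id,
                        "points": [(t, r, c)],
                        "trace": [resp],
                        "missed": 0,
                        "status": "active",
                    }
                )
                self._next_id += 1


def naive_match(
    dets: list[tuple[float, float]],
    targets: list[tuple[float, float]],
    epsilon: float,
) -> tuple[int, int]:
    """Nearest-first one-to-one matching; returns (true positives, false)."""
    pairs = []
    for di, (dr, dc) in enumerate(dets):
        for gi, (gr, gc) in enumerate(targets):
            dist = math.hypot(dr - gr, dc - gc)
            if dist <= epsilon:
                pairs.append((dist, di, gi))
    pairs.sort()
    used_d: set[int] = set()
    used_g: set[int] = set()
    for dist, di, gi in pairs:
        if di in used_d or gi in used_g:
            continue
        used_d.add(di)
        used_g.add(gi)
    return len(used_g), len(dets) - len(used_d)
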