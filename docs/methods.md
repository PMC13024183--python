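# Methods

This document describes the model implemented by `stmdkit`: the signal
flow, the equations of each stage, the default parameters and why they
have the values they do, the synthetic stimulus protocol, and the
numerical choices that matter for reproducibility.

Notation: frames are grayscale grids `I(x, y, t)` on the 0–255 scale,
`x` = row (downward), `y` = column, `t` = frame index. `[u]_+ = max(u, 0)`
and `[u]_- = min(u, 0)` denote half-wave rectifications. All temporal
filters are causal and sampled at integer frame lags, so time constants
are expressed in frames.

## 1. Feedforward motion pathway

### 1.1 Ommatidia (photoreceptor) stage

Each frame is blurred with a small unit-sum Gaussian:

    P(x, y, t) = I(x, y, t) * G_{σ1}(x, y)

with σ1 = 1 px on a 3×3 grid. This models optical blur and suppresses
single-pixel noise without eroding a 5×5 target.

### 1.2 Lamina band-pass (LMC)

Temporal band-pass via a difference of discrete Gamma kernels:

    Γ_{n,τ}(s) = (n s)^n e^{−n s/τ} / ((n−1)! · τ^{n+1}),  s = 0, 1, 2, …
    H(s) = Γ_{n1,τ1}(s) − Γ_{n2,τ2}(s)
    L(x, y, t) = Σ_s H(s) · P(x, y, t−s)

Defaults: n1=2, τ1=3 (fast, excitatory) and n2=6, τ2=9 (slow,
inhibitory), truncated at 24 lags. Each Γ integrates to ≈ 1 and peaks at
lag τ. After truncation, H is mean-subtracted so its weights sum to
*exactly* zero (see §5), making the stage an exact DC blocker: a static
scene — however cluttered — produces exactly zero output once the filter
memory is full (24 frames).

Missing history at the start of a sequence is treated as zero, so the
first 24 frames are warm-up and are excluded from detection.

### 1.3 ON/OFF channels and the OFF delay

    S_ON(x, y, t)  = [L(x, y, t)]_+
    S_OFF(x, y, t) = −[L(x, y, t)]_-
    S_OFF^d(x, y, t) = Σ_s Γ_{n3,τ3}(s) · S_OFF(x, y, t−s)

The OFF channel is delayed with a Gamma kernel n3=5, τ3=25 over 75 lags.
A small dark target produces an OFF transient at its leading edge and an
ON transient at its trailing edge ~(size/speed) frames later; the delay
brings the two into temporal coincidence.

### 1.4 Feedback injection and correlation

The attention loop (§2) supplies a nonnegative gain map `F(x, y, t)`
(zero until a target is classified). It is added to both channels, which
are then multiplied:

    S(x, y, t) = (S_ON + F) · (S_OFF^d + F)

The multiplicative correlation makes the detector respond only where ON
and delayed-OFF evidence coincide — the signature of a small moving
object — and lets a modest additive gain produce a strong
(quadratic-cross-term) output boost at attended locations.

### 1.5 Lateral inhibition

    D(x, y, t) = [ S(x, y, t) * K(x, y) ]_+
    K = φ·[g]_+ + ψ·[g]_-,   g = G_{σ2} − e·G_{σ3} − ρ

with σ2=1.5, σ3=3, e=1, ρ=0, φ=1, ψ=3 on a 13×13 grid; the Gaussians here
are raw density samples (not renormalized). The positive center / negative
surround structure suppresses spatially extended activation: `D` peaks for
compact activations a few pixels across and nearly vanishes for wide bars
(size selectivity). `D` is the detector output ("D′" when feedback is
active).

## 2. Trajectory response-range feedback

The discriminative statistic is the *response range* of a feature tracked
over time. A genuinely moving target sweeps across ever-changing local
background, so its detector response fluctuates strongly; a
background-locked fake feature translates rigidly with the background and
keeps a nearly constant response.

Per frame (after warm-up):

1. **Candidates.** Pixels with `D > ϑ` (ϑ = 5) are reduced by greedy
   non-maximum suppression (radius 5 px, strongest first, ties row-major)
   into candidate detections.
2. **Tracking.** Candidates are associated to live trajectories by greedy
   nearest-pair assignment within 5 px; each side is matched at most once
   per frame. Unmatched candidates seed new trajectories; unmatched
   trajectories become *pending* and terminate after more than 3
   consecutive misses (occlusion grace period). A pending trajectory that
   re-matches resumes with its miss count reset.
3. **Classification.** For each active trajectory, over the last
   W = 75 trace values:

       RV = max(trace) − min(trace)

   Trajectories with `RV > υ` (υ = 35) are classified as true targets.
4. **Feedback map.** Each classified position contributes a Gaussian bump

       F(x, y) = a/(2π σ_f²) · exp(−d²/(2 σ_f²))

   with gain a = 30 and spread σ_f = 2 px, injected at the *next* frame
   (one-frame latency). With σ_f = 2, ±2σ covers the 5×5 target footprint,
   and on the integer pixel grid every pixel farther than 3σ_f from a bump
   center receives < 1% of the peak gain (d > 6 ⟹ d² ≥ 37 ⟹
   exp(−37/8) ≈ 0.0098), so the attention is strictly local.

## 3. Global background suppression

The feedback loop boosts true targets but background responses in heavy
clutter can still out-thresold them. The final stage subtracts a
large-scale blurred copy of the (feedback-modulated) detector map:

    B = D * G_{σ4}           (unit-sum 61×61 Gaussian, σ4 = 15, replicate padding)
    R = D − λ·B              (λ = 50, signed; thresholding happens downstream)

A spatially diffuse response field is annihilated (`c − 50c < 0`), while
an isolated target-sized peak survives: the blur spreads a 5×5 peak so
thin that `λ·B` at its center stays below the peak height, and because
`λ·B` is smooth at the peak scale, the peak's *prominence* over its local
surround is preserved almost entirely (≈ 80% measured for an isolated 5×5
blob under defaults). Final detections are peaks of `R` above
`final_threshold` (default 10; the ROC sweep variable) after the same NMS
rule.

### Ablation modes

- `full` — feedback and suppression active.
- `no_feedback` — `F ≡ 0`, suppression active.
- `no_suppression` — feedback active, `R = D`.
- `estmd_baseline` — both disabled: the classical feedforward
  small-target detector.

## 4. Synthetic stimulus protocol

`SceneSpec` defaults encode the full-scale protocol: a 250×500 px scene,
900 frames at 1000 Hz, with a 5×5 px target of luminance 0 (darker than
all clutter) crossing at 250 px/s against a background translating at
150 px/s in the opposite direction — per-frame displacements of 0.25 and
0.15 px, resolved by exact subpixel rendering: the target square is drawn
with per-pixel area coverage, and the background window slides over a
wide procedural texture with linear interpolation. The texture is wider
than the frame by the total background travel, so the background never
wraps; the target starts at the horizontal center and, at the default
speeds, never reaches a frame edge within 900 frames.

Texture kinds:

- `blobs` (default) — band-limited noise base (σ=6) stretched to
  mid-range luminance, plus dark elliptical distractors with diameters
  ~2–40 px. Distractors smaller than the inhibition surround are kept at
  moderate contrast so that they behave as *background-locked fake
  features* — above the candidate threshold, below the range threshold —
  which is exactly the population the feedback stage must reject.
- `skyline` — a clear flight corridor (central 2/3 of the height) over a
  smooth low-contrast base, with dense near-black target-sized
  distractors (radii 2.2–3.2 px, ≈ 1 per 150 px², ≥ 7.5 px apart so
  lateral inhibition does not annihilate neighbours) confined to the top
  and bottom strips. This is the classic small-target scenario — sky
  corridor bordered by vegetation — and it decouples the two cluttered
  regimes: the strips produce many strong target-like responses that a
  plain correlation detector cannot reject, while the corridor keeps the
  local background estimate low at the target, so suppression removes the
  strip clutter as a population without harming the target.
- `uniform`, `bandlimited-noise` — controls.

### Scaled benchmark scene

`roc_benchmark_scene()` freezes a 64×64, 300-frame, 100 Hz `skyline`
scene with target luminance 0.05, both speeds 15 px/s (0.15 px/frame, the
full-scale background displacement), and the target starting at column 55
moving left. The start column keeps the target inside the frame for the
whole sequence, mirroring the no-wrap property of the full-scale
protocol; a centered start would wrap at the edge and insert an
artificial ~20-frame disappearance transient. The scaled scene exists so
ROC comparisons across all four ablation modes complete in seconds rather
than hours; only its texture seed is meant to vary.

## 5. Numerical choices

- **Exact zero-sum band-pass.** After truncation and mean-subtraction, a
  floating-point residual of order 1e−17 remains in `Σ H`. The residual
  is eliminated by iteratively absorbing it into a weight chosen so the
  correction actually moves the computed (pairwise) sum, stopping at
  exactly 0.0. This makes the static-scene invariance exact rather than
  approximate.
- **Gamma kernels in the log domain.** `(n t)^n` overflows quickly;
  weights are evaluated as `exp(n·log(nt) − nt/τ − lgamma(n) − (n+1)·log τ)`.
- **Separable suppression blur.** The 61×61 Gaussian is applied as two
  1-D passes (exactly equal to the 2-D convolution for an isotropic
  kernel with replicate padding) for a ~30× speedup.
- **Replicate (nearest) padding** for all spatial convolutions, so frame
  borders do not ring.
- **Determinism.** All randomness flows through seeded
  `numpy.random.Generator` instances; rendering and the pipeline are
  byte-deterministic given a `SceneSpec` and a `PipelineConfig`.

### Stage warm-up

Each temporal stage is silent about its own memory: the band-pass (and
every stage downstream of the ON channel) flushes the onset transient
after 24 frames; the delayed OFF channel carries it for a further 75
frames (its Gamma delay length), so `S_OFF^d` is only guaranteed zero on
a static scene from frame 99. Detection output is gated on the 24-frame
warm-up; the OFF-delay tail is harmless there because `D = S_ON · S_OFF^d`
and `S_ON` is already zero.

### Measuring feedback enhancement

The injected gain `F` enters the channels *additively*, so the cleanest
observable of the enhancement is the correlation output `S`: with
identical inputs, `S_full − S_no_feedback = F·(S_ON + S_OFF^d + F)`,
strictly positive wherever `F > 0` (the ON/OFF channels themselves are
input-driven and identical across modes). At the *inhibited* output `D`,
the boost also wins — the output peak near the target strictly exceeds
its no-feedback counterpart — but the exact target pixel can sit in the
inhibitory surround of the boosted peak (which trails the subpixel
ground-truth position by a few pixels), so pointwise comparisons at `D`
are made on the local peak, not a single pixel.

## 6. Limitations

- Backgrounds translate rigidly and horizontally; no rotation, parallax,
  or camera shake.
- One target per scene in the generator; the tracker itself handles
  multiple trajectories, but multi-target evaluation is untested.
- The range threshold υ assumes the background is cluttered enough to
  modulate a moving target's response; over a perfectly uniform
  background a target's RV grows more slowly.
- Suppression strength λ is fixed; heavily non-stationary clutter density
  would benefit from an adaptive λ.
- Evaluation uses center distance (ε = 5 px), not overlap, as appropriate
  for targets without meaningful extent.
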