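# myoknn

Myoelectric velocity decoding for a 3-DOF virtual prosthetic hand, built as
a fully testable, end-to-end synthetic pipeline.

Modern hand prostheses are driven by electromyography (EMG): electrical
activity of residual forearm muscles is decoded into movement commands.
Chronically implanted intramuscular electrodes promise far cleaner signals
than surface arrays — less crosstalk between channels, higher
signal-to-noise ratio, and stability over months — which in turn allows a
*single, fixed* decoder to control several degrees of freedom
simultaneously. This package re-implements such a decoding and evaluation
stack for three DOFs (forearm pronation/supination, wrist
flexion/extension, hand open/close) and pairs it with a virtual subject and
EMG simulator so every stage is exercisable without any recorded data.

## What is inside

- **`myoknn.synthetic`** — the virtual subject: 8 muscles with unit-norm
  directional tuning **W** ∈ ℝ⁸ˣ³ drive band-limited (15–375 Hz, 2 kHz)
  amplitude-modulated Gaussian carriers with activation
  a(t) = b + max(0, **W**·u(t)) for intent u(t) ∈ [−1,1]³; a row-stochastic
  crosstalk matrix mixes muscle sources into channels (near-diagonal for
  intramuscular recordings, ring-smeared for a circumferential surface
  array), plus sensor noise calibrated to a target SNR.
- **`myoknn.features`** — sliding-window time-domain features, 200 ms
  window every 50 ms: per channel the Mean Absolute Value
  MAV = mean|x| and Waveform Length WFL = Σ|xᵢ − xᵢ₋₁|, 16 dimensions for
  8 channels, each normalized to a training-set maximum of 1.
- **`myoknn.labeling`** — the cued training protocol (27 posture codes
  {−1,0,+1}³ × 5 repetitions; 2 s prepare / 2 s go / 1 s rest) and
  *assumed intent* regression targets: inside each trial's active window
  (go + 1.5 s) the cue code is scaled by an EMG-derived effort
  e(t) = m(t)/mean(m) clipped to [0,1], and set to zero elsewhere.
- **`myoknn.decoder`** — the controller: inverse-distance-weighted
  K-nearest-neighbor regression, ŷ(x) = Σᵢ wᵢ tᵢ / Σᵢ wᵢ with
  wᵢ = 1/(dᵢ + ε) over the K = 100 nearest training frames by Euclidean
  distance, plus leave-one-out Variance Accounted For,
  VAF = 100·(1 − var(residual)/var(target)) per DOF.
- **`myoknn.control`** — velocity shaping (±10% dead-band threshold, gain
  3, capped), virtual-hand kinematics over the ROMs 0–180°, −60–70°,
  0–100%, and the posture-matching task: success = all DOFs within ±15% of
  ROM for 1 s (20 consecutive 50 ms frames) within 30 s; sessions of 80
  targets in 5 blocks of 16 with ≥30%-ROM separation between consecutive
  targets.
- **`myoknn.metrics`** — success rate, path efficiency (straight-line over
  traveled distance in ROM-normalized space, to the start of the winning
  dwell), trial time.
- **`myoknn.quality`** — crosstalk as zero-lag channel correlation, an
  automated burst SNR/duty-cycle estimator for cyclic contractions, Box's M
  test for covariance equality, Wilcoxon rank-sum.
- **`myoknn.stats`** — stability regressions
  y = β₀ + β₁·knn + β₂·week·intact + β₃·week·knn (with an optional
  reciprocal transform for trial times), interaction selection by nested-F
  ANOVA, and Kruskal–Wallis across arm-posture conditions.
- **`myoknn.pipeline`** — `RunConfig`/`run_pipeline`: one-call reproducible
  end-to-end runs with a hash manifest.

## Worked example

`examples/closed_loop_posture_matching.py` trains the decoder on one
synthetic cue session and runs a closed-loop 16-target session:

```
session of 16 targets:
  success rate     : 100.0%
  path efficiency  : 97.3 +- 2.7%
  trial time       : 1.37 +- 0.11 s
oracle-decoder ceiling: 100% success, 94.6% efficiency
```

Every target is acquired (success rate 100%), the hand travels nearly
straight to each target (path efficiency close to 100%), and trials finish
in well under the 30 s timeout — the 1 s dwell is included in the trial
time. The oracle line replaces the EMG decode path with the subject's true
intent: the full EMG→KNN loop matches that ceiling, i.e. decoding noise is
not what limits performance here. The other scripts in `examples/` walk
through simulation, offline VAF, the intramuscular-vs-surface signal
quality comparison, and the stability statistics.

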