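# Methods

This note documents the models, conventions and numerical choices behind
`myoknn`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where design latitude existed.

## Signal model (the virtual subject)

Eight muscle sources are tuned to the 3-DOF intent space
u(t) ∈ [−1, 1]³ (ordered pronation/supination, wrist flexion/extension,
hand close/open) by unit-norm rows of a synergy matrix **W**. Activation is
rectified-linear, a(t) = b + max(0, **W**·u(t)): a muscle pulls in one
preferred direction only, and the opposite movement comes from its
antagonist — the first six synergy rows are perturbed ±axis directions
(agonist/antagonist pairs per DOF), remaining rows random unit vectors
(muscles with mixed actions). Baseline tone b defaults to 0 (quiet rest).

Each source is its activation envelope times an independent, unit-RMS,
wide-sense-stationary carrier: white Gaussian noise band-passed 15–375 Hz
with a 4th-order Butterworth filter (zero-phase), sampled at 2 kHz. A
Gaussian carrier was chosen for analyzability; any stationary carrier with
that band would serve. Amplitude quantization is not modeled (negligible at
these SNRs), nor are motor-unit physiology, volume conduction, or fatigue.

Channels are a row-stochastic, non-negative crosstalk mix of sources plus
white sensor noise:

- *intramuscular* preset: identity-dominant mixing (1% off-diagonal row
  mass split between ring neighbours) and a 34 dB SNR target;
- *surface* preset: a ring-smoothing kernel (0.4 / 0.2 / 0.2 / 0.1 / 0.1
  over offsets 0, ±1, ±2 — every channel mixes five sources) and a 25 dB
  target, emulating an untargeted circumferential array.

**SNR convention and calibration.** SNR is defined as
20·log₁₀(RMS_active / RMS_quiet) per channel, where active samples are
those with intent norm > 0.05 and quiet samples have exactly zero intent.
Given the clean active RMS r of a channel, the sensor-noise sigma
σ = r / √(10^(SNR/10) − 1) makes the realized ratio match the target
exactly in expectation; measured realizations land within ~0.1 dB.
Channels whose muscle never fires in a recording receive the median sigma
of the signal-bearing channels (sensor noise is an amplifier property, not
a muscle property); a recording with no activity at all gets unit-variance
noise. The sigma calibrated on the training recording is reused for
closed-loop synthesis so online features live on the training scale.

**The subject.** A proportional-with-saturation policy stands in for the
human: intent = clip(g·(target − hand)/ROM_span, −1, 1) plus Gaussian
noise (sd 0.05), acting on a 200 ms delayed view of the hand, clipped
again. The gain default is 2.0 — full-speed command once the error exceeds
half the ROM, a plausible human strategy; delay and noise follow common
reaction-time and motor-noise magnitudes. Real users differ in strategy,
learning and fatigue; none of that is modeled, so closed-loop results
characterize the *pipeline* under an idealized compliant user, not human
performance. Closed-loop trial times (~1.4 s) are accordingly faster than
a human's.

**Closed-loop synthesis.** Each 50 ms control step synthesizes one fresh
200 ms window at the current activation (new carrier draw, calibrated
noise) rather than streaming a continuous carrier. The decoder consumes
windowed statistics (MAV/WFL), so only the per-window distribution
matters; the 150 ms overlap correlation present in a streamed signal would
smooth consecutive feature frames slightly but not change their
distribution. This choice keeps the generator stateless and exactly
reproducible per step.

## Front end

Features use a 200 ms buffer updated every 50 ms: per channel, MAV
(mean rectified amplitude) and WFL (cumulative absolute first difference,
no carry-over across frames) — 16 dimensions for 8 channels, columns
ordered [mav_0..7, wfl_0..7]. Windows are 0-based and half-open; frames
align to the window END time (a feature at t summarizes the preceding
200 ms, matching causal online use); trailing partial windows are dropped,
never padded. Each dimension is divided by its training-set maximum;
online values may exceed 1 and are deliberately not clipped (KNN distances
tolerate it, and clipping would discard effort information).

## Training labels ("assumed intent")

True intent is unobservable, so regression targets are constructed from
the cue schedule plus EMG effort. The schedule presents the 27 posture
codes {−1, 0, +1}³ in seeded random order, 5 repetitions, with 2 s
prepare / 2 s go / 1 s rest per trial. The active window of a trial is the
go phase plus 1.5 s of spill-over (muscle activity reliably outlasts the
cue); spill frames overlapping the next trial's prepare phase belong to
the EARLIER trial — later cues have not been acted on yet. Outside every
active window intent is exactly [0, 0, 0].

Inside a window, intent = code × e(t) with effort
e(t) = m(t) / mean_window(m), m(t) the mean MAV across channels
(un-normalized; the window-mean division cancels any common scaling).
Unclipped effort has window mean 1 by construction; it is clipped to
[0, 1] so labels stay in the intent cube. Two documented alternatives are
exposed behind flags: a constant per-trial effort (`effort_mode="scalar"`)
and unclipped labels (`clip_effort=False`, returned as an explicitly
unbounded series). Trials with zero mean MAV are labeled zero with a
warning. Effort uses MAV only, never WFL.

## Decoder

A lazy inverse-distance-weighted KNN: Euclidean distances from the 16-D
query to every stored training frame, K = 100 nearest selected, targets
averaged with weights 1/(d + ε), ε = 1e−9. Numerical conventions:

- ties at the K-th distance break by training-row index (ascending) —
  reproducibility over speed;
- zero distances degrade gracefully through ε (no exact-match
  short-circuit), so online and leave-one-out paths share one code path;
- outputs are clipped to [−1, 1]³ (a no-op in exact arithmetic, kept as a
  contract);
- `predict` computes distances elementwise rather than via the expanded
  square, keeping it bit-faithful to the brute-force definition; the
  leave-one-out path uses the fast expanded-square form with chunking,
  since its contract is statistical rather than exact.

Leave-one-out VAF excludes only the identical frame by default
(leave-one-trial-out available via `trial_ids`). Target columns whose
variance sits at rounding level raise an explicit undefined-VAF error.

## Task and metrics

The hand integrates shaped velocity at 50 ms steps, saturating at its ROM
bounds (0–180°, −60–70°, 0–100%). Velocity shaping: commands below a
±10% dead-band are zeroed, the rest multiplied by gain 3 and capped at
full scale, then mapped to physical rates — defaults 180°/s, 130°/s,
100%/s, i.e. one full ROM per second. Success needs all three DOFs within
±15% of ROM (closed tolerance) for 20 *consecutive* frames; leaving
tolerance resets the counter (strictest reading of a 1 s hold). Failures
run the full 30 s. Sessions: 80 seeded targets in 5 blocks of 16, every
consecutive pair ≥30% of ROM apart per DOF and every target ≥15% from both
bounds (sampled directly from the admissible interval union — exact, no
rejection loop); the postural protocol alternates the neutral posture with
random 10%/90% extremes in blocks of 16. The hand starts each block at
neutral and carries over between trials within a block.

Path efficiency divides straight-line by traveled distance in
ROM-normalized coordinates (so 1° of wrist and 1% of aperture weigh
equally), measured from the trial start to the frame where the winning
dwell began — holding still inside tolerance neither helps nor hurts. For
failed trials the straight-line reference is start→target (the minimum the
trial demanded) over the full 30 s path, which can exceed 100% when the
hand stopped short; failures are included in summaries by default. Trial
time runs to dwell completion and includes the dwell second; failures
report 30 s.

## Signal quality and statistics

Crosstalk is the zero-lag Pearson correlation matrix of the raw
band-limited signals (not envelopes): that is the quantity a correlation
heat map with unit diagonal implies. Both signed and absolute off-diagonal
means are reported, since symmetric mixing can hide in a signed mean.

The cyclic-contraction SNR estimator is this package's own definition,
validated against generator ground truth: envelope = 2 Hz low-passed
rectified signal; Otsu split of envelope amplitudes separates noise from
activity; noise RMS from the raw signal inside the eroded noise class;
activity mask = envelope > 3 × noise RMS; SNR = 20·log₁₀(active RMS /
quiet RMS) with a 0.25 s guard band around transitions excluded from both
RMS pools (envelope smoothing smears burst edges and would otherwise bias
low-SNR estimates down by several dB); duty cycle is the active fraction
of the un-eroded mask. Recovery is within ±0.1 dB and ±0.04 duty over
SNR 15–35 dB and duty cycles 1/3–2/3. A unimodal envelope (pure noise)
raises an estimation error rather than returning numbers.

Box's M uses the chi-square approximation with Box's correction (verified
against an independent implementation and an F-test in the univariate
case). Rank-sum is the tie-corrected two-sided Mann–Whitney form;
Kruskal–Wallis is tie-corrected with an explicit (H = 0, p = 1) degenerate
case when every value is identical.

The stability regression has NO common week main effect — the design is
exactly [1, knn, week·intact, week·knn], giving one time trend per
controller. Per-trial observations are treated as independent;
session-level clustering is a known limitation, not modeled. The
reciprocal transform (for right-skewed trial times) is monotone:
shorter times mean larger transformed response, and the controller
coefficient's sign flips accordingly. The interaction is retained when the
nested-model F test rejects at α = 0.05.

## Problem sizes and reproducibility

Default experiment sizes: training = 27 postures × 5 repetitions (675 s of
synthetic EMG, ~13.5k feature frames); closed-loop evaluation = 16-target
sessions over 5 task seeds; statistical calibration checks use 500
replicates. All generators and the task engine are bitwise-reproducible
given their seeds, and `run_pipeline` writes a manifest of config, seeds
and output hashes; re-running an identical config reproduces every output
byte-for-byte (HDF5 timestamps disabled).

## What passing tests do and do not show

The simulator realizes the stated signal structure (directional tuning,
band-limited carriers, condition-dependent crosstalk and SNR), so green
tests demonstrate that the pipeline is internally correct and that the
decoder recovers intent under that structure. Real intramuscular EMG adds
non-Gaussian carriers, nonstationary activation, electrode drift and a
human learner; closed-loop numbers here are therefore ceilings of pipeline
correctness, not predictions of clinical performance.
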