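"""Velocity shaping, virtual-hand kinematics and the posture-matching task.

The decoder's raw [-1, 1]^3 output passes through a per-DOF dead-band
threshold (default +-10% of the normalized velocity range) and gain (default
3), is capped at full scale, and is mapped to physical velocity (deg/s for
pronation and wrist, %/s for aperture).  The hand integrates that velocity at
50 ms steps, saturating at its ROM bounds.

A trial succeeds when all three DOFs stay within +-15% of ROM of the target
for 20 consecutive frames (1 s dwell); trials time out at 30 s.  Sessions
present 80 targets in 5 blocks of 16 (temporal protocol) or alternating
neutral/extreme blocks of 16 (postural protocol), with the hand state carried
across trials within a block.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from . import decoder as _decoder
from .features import FeatureScale, apply_normalization, features_from_window
from .hand import (
    ROM_MAX,
    ROM_MIN,
    ROM_SPAN,
    HandState,
    clip_to_rom,
    neutral_posture,
    to_rom_fraction,
)
from .metrics import path_efficiency
from .synthetic import (
    SubjectPolicy,
    VirtualSubjectConfig,
    muscle_activation,
    virtual_subject_intent,
    _unit_rms_carriers,
)

#: Control-loop step (seconds): one feature frame per velocity update.
DT_S = 0.050
#: Position tolerance as a fraction of ROM, per DOF.
TOLERANCE_FRAC = 0.15
#: Required consecutive in-tolerance duration (seconds).
DWELL_S = 1.0
#: Trial timeout (seconds).
TIMEOUT_S = 30.0


@dataclass(frozen=True)
class ControllerConfig:
    """Threshold/gain velocity shaping and physical speed mapping."""

    threshold: float = 0.10
    gain: float = 3.0
    dt: float = DT_S
    max_speed: tuple = (180.0, 130.0, 100.0)

    def __post_init__(self):
        thr = np.broadcast_to(np.asarray(self.threshold, float), (3,)).copy()
        g = np.broadcast_to(np.asarray(self.gain, float), (3,)).copy()
        ms = np.asarray(self.max_speed, float)
        object.__setattr__(self, "threshold", thr)
        object.__setattr__(self, "gain", g)
        object.__setattr__(self, "max_speed", ms)
        if np.any(thr < 0) or np.any(thr >= 1):
            raise ValueError("thresholds must lie in [0, 1)")
        if np.any(g <= 0):
            raise ValueError("gains must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class SessionSpec:
    """One posture-matching session's protocol."""

    n_targets: int = 80
    block_size: int = 16
    protocol: str = "temporal"
    seed: int = 0

    def __post_init__(self):
        if self.n_targets % self.block_size != 0:
            raise ValueError("n_targets must be divisible by block_size")
        if self.protocol not in ("temporal", "postural"):
            raise ValueError(f"unknown protocol {self.protocol!r}")


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one posture-matching trial."""

    target: HandState
    trajectory: np.ndarray  # (n_frames + 1, 3), dt cadence, row 0 = start
    success: bool
    trial_time_s: float
    path_efficiency: float
    dwell_start_index: int = None  # trajectory index where the winning dwell began


@dataclass(frozen=True)
class SessionResult:
    trials: tuple
    summary: dict
    spec: SessionSpec = None


def shape_velocity(raw: np.ndarray, cfg: ControllerConfig) -> np.ndarray:
    """Dead-band, gain, cap, and physical-unit scaling of a raw command.

    Per DOF: commands below the threshold are treated as erroneous and
    zeroed; the rest are multiplied by the gain and capped at full scale
    before scaling by ``max_speed`` (deg/s, deg/s, %/s).
    """
    raw = np.asarray(raw, dtype=float)
    v = np.where(np.abs(raw) < cfg.threshold, 0.0, raw * cfg.gain)
    return np.clip(v, -1.0, 1.0) * cfg.max_speed


def integrate_hand(state: np.ndarray, v: np.ndarray, dt: float) -> np.ndarray:
    """Euler step of the hand, saturating (not wrapping) at ROM bounds."""
    return clip_to_rom(np.asarray(state, float) + np.asarray(v, float) * dt)


def _sample_dof(rng, prev_frac: float) -> float:
    """Sample a ROM fraction in [0.15, 0.85] at distance >= 0.30 from prev.

    Direct sampling from the admissible union of intervals (no rejection):
    length-weighted interval choice, then uniform within it.
    """
    lo, hi = 0.15, 0.85
    intervals = []
    left = (lo, min(hi, prev_frac - 0.30))
    right = (max(lo, prev_frac + 0.30), hi)
    for a, b in (left, right):
        if b > a:
            intervals.append((a, b))
    if not intervals:
        raise RuntimeError("no admissible target region (unreachable given bounds)")
    lengths = np.array([b - a for a, b in intervals])
    a, b = intervals[rng.choice(len(intervals), p=lengths / lengths.sum())]
    return float(rng.uniform(a, b))


def generate_session_targets(spec: SessionSpec) -> list:
    """Seeded random targets: >= 30% ROM from the previous target in every
    DOF and >= 15% ROM from both bounds (all targets can be overshot)."""
    rng = np.random.default_rng(spec.seed)
    prev = to_rom_fraction(neutral_posture().as_array())
    targets = []
    for _ in range(spec.n_targets):
        frac = np.array([_sample_dof(rng, prev[d]) for d in range(3)])
        targets.append(HandState.from_array(ROM_MIN + frac * ROM_SPAN))
        prev = frac
    return targets


def validate_session_targets(targets, prev_start: HandState = None) -> None:
    """Post-hoc check of the separation and bounds constraints (raises)."""
    prev = to_rom_fraction(
        (prev_start or neutral_posture()).as_array()
    )
    for i, t in enumerate(targets):
        frac = to_rom_fraction(t.as_array())
        if np.any(frac < 0.15 - 1e-9) or np.any(frac > 0.85 + 1e-9):
            raise AssertionError(f"target {i} closer than 15% ROM to a bound")
        if np.any(np.abs(frac - prev) < 0.30 - 1e-9):
            raise AssertionError(f"target {i} closer than 30% ROM to its predecessor")
        prev = frac


def generate_postural_block(seed: int) -> list:
    """16 targets alternating neutral posture and random near-extreme postures.

    Even indices (0-based) are the neutral posture (per-DOF ROM midpoint);
    odd indices place every DOF at 10% or 90% of its ROM, chosen at random
    (extremes pulled in so they can be overshot).
    """
    rng = np.random.default_rng(seed)
    block = []
    for i in range(16):
        if i % 2 == 0:
            block.append(neutral_posture())
        else:
            frac = rng.choice([0.10, 0.90], size=3)
            block.append(HandState.from_array(ROM_MIN + frac * ROM_SPAN))
    return block


class OracleDecoder:
    """Perfect decoder: passes the subject's intent straight through.

    The sanity ceiling for the task engine — no EMG, no estimation error.
    """

    def decode(self, intent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return np.asarray(intent, dtype=float)


class EmgClosedLoopDecoder:
    """Full decode path: intent -> synthetic EMG window -> features -> KNN.

    Each 50 ms step synthesizes one 200 ms window at the subject's current
    muscle activation (fresh band-limited carrier, calibrated sensor noise),
    extracts MAV/WFL, normalizes with the TRAINING scale and queries the KNN.
    """

    def __init__(
        self,
        model: _decoder.KnnModel,
        cfg: VirtualSubjectConfig,
        noise_sigma: np.ndarray,
        scale: FeatureScale = None,
        window_s: float = 0.200,
    ):
        self.model = model
        self.cfg = cfg
        self.noise_sigma = np.asarray(noise_sigma, dtype=float)
        self.scale = scale if scale is not None else model.scale
        if self.scale is None:
            raise ValueError("a FeatureScale is required (from training)")
        self.window_n = int(round(window_s * cfg.sample_rate))
        self._sos = cfg.bandpass_sos()

    def decode(self, intent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        act = muscle_activation(np.asarray(intent, float)[None, :], self.cfg)[0]
        carriers = _unit_rms_carriers(
            rng, self.cfg.n_muscles, self.window_n, self._sos
        )
        sources = act[:, None] * carriers
        x = self.cfg.crosstalk @ sources
        x = x + self.noise_sigma[:, None] * rng.standard_normal(x.shape)
        feats = features_from_window(x) / self.scale.divisors
        return _decoder.predict(self.model, feats)


def run_trial(
    decoder_obj,
    policy: SubjectPolicy,
    target: HandState,
    cfg: ControllerConfig = None,
    seed: int = 0,
    initial_state: HandState = None,
    rng: np.random.Generator = None,
    timeout_s: float = TIMEOUT_S,
) -> TrialRecord:
    """Run one closed-loop posture-matching trial.

    The virtual subject observes the hand with its reaction delay, emits an
    intent, the decoder turns it into a raw velocity command, and the shaped
    velocity moves the hand.  Success requires 20 consecutive frames with
    every DOF inside +-15% of ROM of the target; leaving tolerance resets the
    dwell counter.  Failed trials run the full 30 s.
    """
    cfg = cfg or ControllerConfig()
    rng = rng if rng is not None else np.random.default_rng(seed)
    hand = (initial_state or neutral_posture()).as_array()
    tgt = target.as_array()
    tol = TOLERANCE_FRAC * ROM_SPAN

    delay_frames = int(round(policy.reaction_delay / cfg.dt))
    seen = deque([hand.copy()] * (delay_frames + 1), maxlen=delay_frames + 1)

    dwell_needed = int(round(DWELL_S / cfg.dt))
    max_frames = int(round(timeout_s / cfg.dt))
    traj = [hand.copy()]
    dwell = 0
    success = False
    trial_time = timeout_s
    dwell_start = None

    for frame in range(1, max_frames + 1):
        intent = virtual_subject_intent(seen[0], tgt, policy, rng)
        raw = decoder_obj.decode(intent, rng)
        v = shape_velocity(raw, cfg)
        hand = integrate_hand(hand, v, cfg.dt)
        traj.append(hand.copy())
        seen.append(hand.copy())
        if np.all(np.abs(hand - tgt) <= tol + 1e-12):
            dwell += 1
        else:
            dwell = 0
        if dwell >= dwell_needed:
            success = True
            trial_time = frame * cfg.dt
            dwell_start = frame - dwell_needed + 1
            break

    trajectory = np.asarray(traj)
    pe = path_efficiency(trajectory, tgt, arrival_index=dwell_start)
    return TrialRecord(
        target=target,
        trajectory=trajectory,
        success=success,
        trial_time_s=trial_time,
        path_efficiency=pe,
        dwell_start_index=dwell_start,
    )


def run_session(
    spec: SessionSpec,
    decoder_obj,
    policy: SubjectPolicy = None,
    cfg: ControllerConfig = None,
    condition_label: str = "",
) -> SessionResult:
    """Run a full session of posture-matching trials.

    Temporal protocol: ``n_targets`` seeded random targets split into blocks.
    Postural protocol: blocks of 16 alternating neutral/extreme targets.
    The hand starts each block at neutral and carries over between trials
    within a block.
    """
    from .metrics import summarize

    policy = policy or SubjectPolicy()
    cfg = cfg or ControllerConfig()
    if spec.n_targets == 0:
        return SessionResult(
            trials=(), summary={"undefined": True, "n_trials": 0}, spec=spec
        )
    if spec.protocol == "temporal":
        targets = generate_session_targets(spec)
    else:
        n_blocks = spec.n_targets // spec.block_size
        targets = []
        for b in range(n_blocks):
            targets.extend(generate_postural_block(spec.seed + b))

    rng = np.random.default_rng(spec.seed)
    trials = []
    state = neutral_posture()
    for i, target in enumerate(targets):
        if i % spec.block_size == 0:
            state = neutral_posture()
        rec = run_trial(
            decoder_obj, policy, target, cfg, initial_state=state, rng=rng
        )
        trials.append(rec)
        state = HandState.from_array(rec.trajectory[-1])
    summary = summarize(trials)
    if condition_label:
        summary["condition"] = condition_label
    return SessionResult(trials=tuple(trials), summary=summary, spec=spec)
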