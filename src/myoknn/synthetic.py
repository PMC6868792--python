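"""Synthetic multichannel EMG and a virtual subject for closed-loop testing.

No public recordings exist for this decoding problem, so every downstream
stage is exercised against a signal model: 8 muscles, each directionally
tuned to the 3-DOF intent space by a unit-norm synergy vector, drive
amplitude-modulated band-limited (15–375 Hz) Gaussian carriers sampled at
2 kHz.  A row-stochastic crosstalk matrix mixes muscle sources into channels
(near-diagonal for intramuscular recordings, spatially smeared for a
circumferential surface array), and white sensor noise is added at a
calibrated level so the realized channel SNR — RMS of active segments over
RMS of zero-intent segments, in dB — matches a target.

A proportional-with-saturation ``SubjectPolicy`` stands in for the human
closing the loop during posture matching.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .hand import ROM_SPAN
from .labeling import ACTIVE_SPILL_S, CueSchedule, IntentSeries, active_window

SAMPLE_RATE = 2000.0
CARRIER_BAND = (15.0, 375.0)
#: SNR presets (dB) for the two recording conditions.
SNR_PRESET_INTRAMUSCULAR = 34.0
SNR_PRESET_SURFACE = 25.0


class ObservabilityError(ValueError):
    """Fewer muscles than controlled DOFs: intent space not observable."""


class ConfigurationError(ValueError):
    """Inconsistent virtual-subject configuration (e.g. unreachable SNR)."""


def make_synergy_matrix(n_muscles: int, seed: int) -> np.ndarray:
    """Unit-row-norm (n_muscles x 3) directional tuning matrix of rank 3.

    The first six rows are perturbed +-axis directions (agonist/antagonist
    pairs per DOF, mirroring wrist flexor/extensor, pronator/supinator and
    digit flexor/extensor muscle groups); additional rows are random unit
    vectors (muscles with mixed actions).
    """
    if n_muscles < 3:
        raise ObservabilityError(
            f"need >= 3 muscles to observe 3 DOFs, got {n_muscles}"
        )
    rng = np.random.default_rng(seed)
    axes = np.concatenate([np.eye(3), -np.eye(3)], axis=0)
    rows = []
    for m in range(n_muscles):
        if m < 6:
            base = axes[m] + 0.15 * rng.standard_normal(3)
        else:
            base = rng.standard_normal(3)
        norm = np.linalg.norm(base)
        while norm < 1e-6:  # essentially impossible; keeps rows well-defined
            base = rng.standard_normal(3)
            norm = np.linalg.norm(base)
        rows.append(base / norm)
    W = np.asarray(rows)
    if np.linalg.matrix_rank(W) < 3:
        raise ObservabilityError("synergy matrix is rank-deficient")
    return W


def identity_crosstalk(n: int, offdiag_mass: float = 0.01) -> np.ndarray:
    """Near-diagonal row-stochastic mixing: intramuscular electrodes.

    Each channel takes ``1 - offdiag_mass`` from its own muscle and splits the
    remainder between its two ring neighbours.
    """
    C = np.eye(n) * (1.0 - offdiag_mass)
    for i in range(n):
        C[i, (i - 1) % n] += offdiag_mass / 2
        C[i, (i + 1) % n] += offdiag_mass / 2
    return C


def surface_crosstalk(n: int) -> np.ndarray:
    """Spatially smeared row-stochastic mixing: circumferential surface array.

    A fixed smoothing kernel over ring neighbours; every channel mixes at
    least five sources with weight > 0.05.
    """
    kernel = {0: 0.40, 1: 0.20, -1: 0.20, 2: 0.10, -2: 0.10}
    C = np.zeros((n, n))
    for i in range(n):
        for off, w in kernel.items():
            C[i, (i + off) % n] += w
    return C


@dataclass(frozen=True)
class VirtualSubjectConfig:
    """Signal model for one synthetic recording setup.

    Parameters
    ----------
    n_muscles : int
        Number of muscle sources (and channels), default 8.
    synergy : ndarray (n_muscles, 3)
        Unit-row-norm directional tuning; built from ``seed`` when omitted.
    baseline_activation : float
        Resting muscle tone in [0, 1), default 0 (quiet rest).
    carrier_band : (float, float)
        Pass band of the EMG carrier in Hz.
    sample_rate : float
        Sampling rate in Hz.
    crosstalk : ndarray (n_channels, n_muscles)
        Row-stochastic, non-negative mixing matrix; identity-dominant default.
    target_snr_db : float
        Realized active/quiet RMS ratio to calibrate sensor noise to, in dB.
    seed : int
        Seed for carrier and noise generation.
    """

    n_muscles: int = 8
    synergy: np.ndarray = None
    baseline_activation: float = 0.0
    carrier_band: tuple = CARRIER_BAND
    sample_rate: float = SAMPLE_RATE
    crosstalk: np.ndarray = None
    target_snr_db: float = SNR_PRESET_INTRAMUSCULAR
    condition: str = "intramuscular"
    seed: int = 0

    def __post_init__(self):
        if self.synergy is None:
            object.__setattr__(
                self, "synergy", make_synergy_matrix(self.n_muscles, self.seed)
            )
        if self.crosstalk is None:
            object.__setattr__(self, "crosstalk", identity_crosstalk(self.n_muscles))
        object.__setattr__(self, "synergy", np.asarray(self.synergy, dtype=float))
        object.__setattr__(self, "crosstalk", np.asarray(self.crosstalk, dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.n_muscles < 3:
            raise ObservabilityError("need >= 3 muscles")
        if self.synergy.shape != (self.n_muscles, 3):
            raise ConfigurationError("synergy must be (n_muscles, 3)")
        if not np.allclose(np.linalg.norm(self.synergy, axis=1), 1.0, atol=1e-6):
            raise ConfigurationError("synergy rows must be unit-norm")
        if self.crosstalk.shape[1] != self.n_muscles:
            raise ConfigurationError("crosstalk columns must match n_muscles")
        if np.any(self.crosstalk < 0):
            raise ConfigurationError("crosstalk entries must be >= 0")
        if not np.allclose(self.crosstalk.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("crosstalk rows must sum to 1")
        lo, hi = self.carrier_band
        if not (0 < lo < hi < self.sample_rate / 2):
            raise ConfigurationError("carrier band must lie within (0, Nyquist)")
        if not (0 <= self.baseline_activation < 1):
            raise ConfigurationError("baseline activation must be in [0, 1)")
        if self.target_snr_db <= 0:
            raise ConfigurationError(
                "target SNR must exceed 0 dB (noise variance would be "
                "non-positive otherwise)"
            )

    @property
    def n_channels(self) -> int:
        return self.crosstalk.shape[0]

    def bandpass_sos(self) -> np.ndarray:
        return signal.butter(
            4, self.carrier_band, btype="bandpass", fs=self.sample_rate, output="sos"
        )


def apply_recording_condition(
    cfg: VirtualSubjectConfig, condition: str
) -> VirtualSubjectConfig:
    """Return a copy of ``cfg`` configured for one electrode condition.

    "intramuscular": identity-dominant crosstalk (off-diagonal row mass <= 2%)
    and a 34 dB SNR preset.  "surface": ring-smoothing crosstalk (each channel
    mixes >= 3 sources) and a 25 dB preset.  The input config is unchanged.
    """
    if condition == "intramuscular":
        return dataclasses.replace(
            cfg,
            crosstalk=identity_crosstalk(cfg.n_muscles),
            target_snr_db=SNR_PRESET_INTRAMUSCULAR,
            condition="intramuscular",
        )
    if condition == "surface":
        return dataclasses.replace(
            cfg,
            crosstalk=surface_crosstalk(cfg.n_muscles),
            target_snr_db=SNR_PRESET_SURFACE,
            condition="surface",
        )
    raise ValueError(f"unknown recording condition {condition!r}")


@dataclass(frozen=True)
class EmgRecording:
    """Channels x samples signal with acquisition metadata."""

    samples: np.ndarray
    sample_rate: float
    channel_labels: tuple = ()
    condition: str = "other"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        x = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", x)
        if not self.channel_labels:
            object.__setattr__(
                self,
                "channel_labels",
                tuple(f"ch{i}" for i in range(x.shape[0])),
            )
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        if not np.all(np.isfinite(x)):
            raise ValueError("all samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


def _unit_rms_carriers(rng, n_muscles, n_samples, sos):
    white = rng.standard_normal((n_muscles, n_samples))
    carriers = signal.sosfiltfilt(sos, white, axis=1)
    rms = np.sqrt(np.mean(carriers**2, axis=1, keepdims=True))
    return carriers / np.where(rms > 0, rms, 1.0)


def muscle_activation(intent: np.ndarray, cfg: VirtualSubjectConfig) -> np.ndarray:
    """Rectified-linear synergy drive: baseline + max(0, W . intent).

    Muscles only pull in their preferred direction; the opposite movement is
    produced by the antagonist muscle, as in real flexor/extensor pairs.
    """
    drive = intent @ cfg.synergy.T
    return cfg.baseline_activation + np.maximum(0.0, drive)


def simulate_emg(
    intent: IntentSeries,
    cfg: VirtualSubjectConfig,
    noise_sigma: np.ndarray = None,
) -> EmgRecording:
    """Generate a multichannel EMG recording that realizes an intent trajectory.

    Each muscle source is its activation envelope (intent linearly
    interpolated to the sample rate) times an independent unit-RMS
    band-limited Gaussian carrier; channels are the crosstalk mix of sources
    plus white sensor noise.  When ``noise_sigma`` is None the per-channel
    noise level is solved analytically so the realized SNR (active-RMS over
    quiet-RMS, dB) matches ``cfg.target_snr_db``; pass the calibrated sigma
    back in to reuse one noise level across recordings.

    Deterministic given ``cfg.seed``.  The sigma actually used is stored in
    ``recording.meta["noise_sigma"]``.
    """
    values = intent.values
    if np.any(np.abs(values) > 1 + 1e-9):
        raise ValueError("intent values must lie in [-1, 1]")
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate
    n_samples = int(round(intent.times[-1] * fs))
    t = np.arange(n_samples) / fs
    intent_up = np.column_stack(
        [np.interp(t, intent.times, values[:, d]) for d in range(3)]
    )
    act = muscle_activation(intent_up, cfg)  # (n_samples, n_muscles)

    carriers = _unit_rms_carriers(rng, cfg.n_muscles, n_samples, cfg.bandpass_sos())
    sources = act.T * carriers
    clean = cfg.crosstalk @ sources  # (n_channels, n_samples)

    active = np.linalg.norm(intent_up, axis=1) > 0.05
    if noise_sigma is None:
        if np.any(active):
            rms_clean = np.sqrt(np.mean(clean[:, active] ** 2, axis=1))
        else:
            rms_clean = np.zeros(cfg.n_channels)
        snr_lin_sq = 10.0 ** (cfg.target_snr_db / 10.0) - 1.0
        noise_sigma = rms_clean / np.sqrt(snr_lin_sq)
        pos = noise_sigma > 0
        if np.any(pos):
            # channels whose muscle never fired still carry sensor noise at
            # the same amplifier level as their neighbours
            noise_sigma = np.where(pos, noise_sigma, np.median(noise_sigma[pos]))
        else:
            # pure-rest recording: no signal reference, emit unit noise
            noise_sigma = np.ones_like(noise_sigma)
    noise_sigma = np.asarray(noise_sigma, dtype=float)
    samples = clean + noise_sigma[:, None] * rng.standard_normal(clean.shape)
    return EmgRecording(
        samples=samples,
        sample_rate=fs,
        condition=cfg.condition,
        meta={"noise_sigma": noise_sigma, "seed": cfg.seed},
    )


def realized_snr_db(recording: EmgRecording, intent: IntentSeries) -> np.ndarray:
    """Per-channel active/quiet RMS ratio in dB — the module's own SNR oracle.

    Active samples are those where the driving intent has norm > 0.05; quiet
    samples are those with exactly zero intent.
    """
    fs = recording.sample_rate
    t = np.arange(recording.n_samples) / fs
    intent_up = np.column_stack(
        [np.interp(t, intent.times, intent.values[:, d]) for d in range(3)]
    )
    norms = np.linalg.norm(intent_up, axis=1)
    active, quiet = norms > 0.05, norms == 0.0
    if not np.any(active) or not np.any(quiet):
        raise ValueError("need both active and quiet segments to measure SNR")
    x = recording.samples
    rms_a = np.sqrt(np.mean(x[:, active] ** 2, axis=1))
    rms_q = np.sqrt(np.mean(x[:, quiet] ** 2, axis=1))
    return 20.0 * np.log10(rms_a / rms_q)


def cue_intent_trajectory(
    schedule: CueSchedule,
    step_s: float = 0.05,
    rise_s: float = 0.1,
    plateau: float = 1.0,
) -> IntentSeries:
    """Ground-truth intent a compliant subject produces while following cues.

    Inside each trial's active window the posture code is scaled by a
    trapezoidal effort profile (linear 100 ms rise and fall, ``plateau``
    in between); zero elsewhere.  This is the trajectory that DRIVES the
    simulator; the labeling stage independently reconstructs assumed intent
    from the resulting EMG.
    """
    end = schedule.duration
    times = np.arange(step_s, end + 1e-9, step_s)
    values = np.zeros((len(times), 3))
    for trial in schedule.trials:
        lo, hi = active_window(trial, schedule_end=end)
        mask = (times >= lo) & (times < hi)
        if not np.any(mask):
            continue
        tt = times[mask]
        up = np.clip((tt - lo) / rise_s, 0.0, 1.0)
        down = np.clip((hi - tt) / rise_s, 0.0, 1.0)
        effort = plateau * np.minimum(up, down)
        values[mask] = np.asarray(trial.posture_code, dtype=float) * effort[:, None]
    return IntentSeries(times=times, values=values)


def axis_pulse_intent(
    n_cycles: int = 2,
    on_s: float = 2.0,
    off_s: float = 2.0,
    step_s: float = 0.05,
) -> IntentSeries:
    """Cyclic contractions cycling through all six +-axis directions.

    Each cycle pulses one DOF direction ([+1,0,0], [-1,0,0], ..., [0,0,-1])
    for ``on_s`` with ``off_s`` of rest between pulses, repeated ``n_cycles``
    times — so every directionally tuned muscle produces activity bursts.
    Used to exercise the SNR estimator and condition-contrast comparisons.
    """
    dirs = []
    for d in range(3):
        for sgn in (1.0, -1.0):
            v = np.zeros(3)
            v[d] = sgn
            dirs.append(v)
    period = on_s + off_s
    total = period * len(dirs) * n_cycles
    times = np.arange(step_s, total + 1e-9, step_s)
    values = np.zeros((len(times), 3))
    idx = ((times - 1e-9) // period).astype(int) % len(dirs)
    phase = times % period
    on = phase < on_s
    for i, v in enumerate(dirs):
        values[on & (idx == i)] = v
    return IntentSeries(times=times, values=values)


@dataclass(frozen=True)
class SubjectPolicy:
    """Proportional-with-saturation stand-in for the human user.

    intent = clip(gain * (target - hand) / ROM_span, -1, 1) + noise, acting on
    a ``reaction_delay``-old view of the hand, clipped again to [-1, 1].
    """

    gain: float = 2.0
    saturation: float = 1.0
    reaction_delay: float = 0.2
    intent_noise_sd: float = 0.05

    def __post_init__(self):
        if self.saturation != 1.0:
            raise ValueError("intent saturation is fixed at 1")
        if self.reaction_delay < 0 or self.intent_noise_sd < 0:
            raise ValueError("reaction delay and noise sd must be >= 0")


def virtual_subject_intent(
    hand: np.ndarray,
    target: np.ndarray,
    policy: SubjectPolicy,
    rng: np.random.Generator = None,
) -> np.ndarray:
    """One step of the virtual subject's intent, given its (delayed) view."""
    err = (np.asarray(target, float) - np.asarray(hand, float)) / ROM_SPAN
    intent = np.clip(policy.gain * err, -1.0, 1.0)
    if rng is not None and policy.intent_noise_sd > 0:
        intent = intent + policy.intent_noise_sd * rng.standard_normal(3)
    return np.clip(intent, -1.0, 1.0)


def simulate_cyclic_contraction(
    n_cycles: int,
    on_s: float,
    off_s: float,
    snr_db: float,
    cfg: VirtualSubjectConfig = None,
    seed: int = 0,
) -> tuple:
    """Single-muscle burst train with known ground truth, for SNR estimation.

    Rectangular on/off envelope over ``n_cycles`` cycles; the burst amplitude
    is set so ground-truth 20*log10(burst RMS / noise RMS) equals ``snr_db``
    (burst RMS includes the noise floor, as an estimator would see it).

    Returns ``(recording, truth)`` where ``truth`` holds noise_rms, burst_rms,
    snr_db and duty_cycle.
    """
    if n_cycles < 2:
        raise ValueError("need >= 2 cycles")
    if on_s <= 0 or off_s <= 0:
        raise ValueError("on/off durations must be positive")
    fs = cfg.sample_rate if cfg is not None else SAMPLE_RATE
    band = cfg.carrier_band if cfg is not None else CARRIER_BAND
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    rng = np.random.default_rng(seed)

    on_n, off_n = int(round(on_s * fs)), int(round(off_s * fs))
    env = np.tile(np.r_[np.zeros(off_n), np.ones(on_n)], n_cycles)
    n = env.size
    carrier = _unit_rms_carriers(rng, 1, n, sos)[0]
    amp = np.sqrt(10.0 ** (snr_db / 10.0) - 1.0)
    noise = rng.standard_normal(n)
    x = amp * env * carrier + noise

    on_mask = env > 0
    noise_rms = float(np.sqrt(np.mean(x[~on_mask] ** 2)))
    burst_rms = float(np.sqrt(np.mean(x[on_mask] ** 2)))
    truth = {
        "noise_rms": noise_rms,
        "burst_rms": burst_rms,
        "snr_db": 20.0 * np.log10(burst_rms / noise_rms),
        "duty_cycle": on_s / (on_s + off_s),
    }
    rec = EmgRecording(
        samples=x[None, :], sample_rate=fs, condition="other", meta={"seed": seed}
    )
    return rec, truth
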