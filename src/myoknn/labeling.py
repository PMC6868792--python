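"""Training-cue schedule and "assumed intent" regression targets.

The decoder is trained from cued contractions: each of the 27 postures with
every DOF at an extreme or neutral (codes in {-1, 0, +1}^3, ordered
[pronation/supination, wrist flexion/extension, hand close/open]) is presented
several times.  Each cue trial has a 2 s Prepare phase, a 2 s Go phase and a
1 s Rest phase.  Muscle activity reliably outlasts the Go phase, so the
"Active Movement" window used for labeling is the Go phase plus the first
1.5 s of the following Rest (spilling into the next trial's Prepare).

Because true intent is unobservable, regression targets are an *assumed
intent*: inside a trial's active window the cued movement code is scaled by a
time-varying effort estimate derived from the mean MAV across channels
(normalized to unit mean over the window); outside every active window intent
is exactly zero.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureFrame

logger = logging.getLogger(__name__)

#: Default phase durations (seconds).
PREPARE_S = 2.0
GO_S = 2.0
REST_S = 1.0
#: Activity spill-over past the Go phase included in the active window.
ACTIVE_SPILL_S = 1.5


@dataclass(frozen=True)
class CueTrial:
    """A single cued posture: code triple plus phase timing."""

    posture_code: tuple
    start_time: float
    prepare_s: float = PREPARE_S
    go_s: float = GO_S
    rest_s: float = REST_S

    def __post_init__(self) -> None:
        if len(self.posture_code) != 3 or any(
            c not in (-1, 0, 1) for c in self.posture_code
        ):
            raise ValueError(f"posture code {self.posture_code} not in {{-1,0,1}}^3")
        if min(self.prepare_s, self.go_s, self.rest_s) <= 0:
            raise ValueError("phase durations must be positive")

    @property
    def duration(self) -> float:
        return self.prepare_s + self.go_s + self.rest_s

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class CueSchedule:
    """Ordered, contiguous list of cue trials."""

    trials: tuple
    repetitions: int = 5

    @property
    def duration(self) -> float:
        return self.trials[-1].end_time if self.trials else 0.0


@dataclass(frozen=True)
class IntentSeries:
    """Per-frame 3-DOF intent in [-1, 1]^3, time-aligned to a FeatureFrame.

    ``bounded=False`` relaxes the range check for diagnostic series (raw,
    unclipped effort); decoder training and EMG synthesis expect bounded
    series.
    """

    times: np.ndarray
    values: np.ndarray
    bounded: bool = True

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[1] != 3:
            raise ValueError("intent values must be (n_frames, 3)")
        if values.shape[0] != times.shape[0]:
            raise ValueError("intent times/values length mismatch")
        if not np.all(np.isfinite(values)):
            raise ValueError("intent values must be finite")
        if self.bounded and np.any(np.abs(values) > 1 + 1e-9):
            raise ValueError("intent values must lie in [-1, 1]")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def all_posture_codes() -> list:
    """The 27 posture codes {-1,0,1}^3 in lexicographic order."""
    return [tuple(c) for c in itertools.product((-1, 0, 1), repeat=3)]


def build_cue_schedule(repetitions: int = 5, seed: int = 0) -> CueSchedule:
    """Seeded random ordering of the 27 posture codes x ``repetitions``.

    Trials are contiguous, each spanning prepare + go + rest = 5 s.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    codes = all_posture_codes() * repetitions
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(codes))
    trials = []
    t = 0.0
    for idx in order:
        trial = CueTrial(posture_code=codes[idx], start_time=t)
        trials.append(trial)
        t = trial.end_time
    return CueSchedule(trials=tuple(trials), repetitions=repetitions)


def active_window(trial: CueTrial, schedule_end: float = np.inf) -> tuple:
    """(start, end) of the Active Movement window of one trial, in seconds.

    Go phase plus the first 1.5 s of Rest (which spills into the next trial's
    Prepare phase); truncated at the end of the schedule.
    """
    start = trial.start_time + trial.prepare_s
    end = min(start + trial.go_s + ACTIVE_SPILL_S, schedule_end)
    return (start, end)


def assumed_intent(
    features: FeatureFrame,
    schedule: CueSchedule,
    effort_mode: str = "modulated",
    clip_effort: bool = True,
) -> IntentSeries:
    """Construct assumed-intent regression targets from cues and EMG effort.

    Parameters
    ----------
    features : FeatureFrame
        UN-normalized features on the schedule's time base; the MAV columns
        supply the effort signal m(t) = mean over channels of MAV.
    schedule : CueSchedule
        The cue schedule the recording followed.
    effort_mode : {"modulated", "scalar"}
        "modulated" scales the posture code by e(t) = m(t) / mean(m) over the
        active window (time-varying effort); "scalar" uses a constant unit
        effort per trial (sensitivity-analysis mode).
    clip_effort : bool
        Clip e(t) to [0, 1] so labels stay inside [-1, 1] (default).

    Returns
    -------
    IntentSeries
        Zero outside every active window; code x effort inside.
    """
    if effort_mode not in ("modulated", "scalar"):
        raise ValueError(f"unknown effort_mode {effort_mode!r}")
    times = features.times
    if schedule.trials:
        first = schedule.trials[0]
        if times[-1] <= first.start_time + first.prepare_s:
            raise ValueError(
                "feature frame does not reach the schedule's first active window"
            )
    n_ch = features.n_channels
    m = features.values[:, :n_ch].mean(axis=1)  # mean MAV across channels
    values = np.zeros((len(times), 3), dtype=float)
    end = schedule.duration
    for trial in schedule.trials:
        lo, hi = active_window(trial, schedule_end=end)
        mask = (times >= lo) & (times < hi)
        if not np.any(mask):
            continue
        if effort_mode == "scalar":
            effort = np.ones(mask.sum())
        else:
            mw = m[mask]
            mbar = mw.mean()
            if mbar == 0.0:
                warnings.warn(
                    f"trial at t={trial.start_time:.1f}s has zero mean MAV; "
                    "labeling it zero-intent",
                    stacklevel=2,
                )
                continue
            effort = mw / mbar
        if clip_effort:
            effort = np.clip(effort, 0.0, 1.0)
        values[mask] = np.asarray(trial.posture_code, dtype=float) * effort[:, None]
    return IntentSeries(times=times, values=values, bounded=clip_effort)


def schedule_to_frame(schedule: CueSchedule):
    """Tabulate a schedule as a pandas DataFrame (one row per trial)."""
    import pandas as pd

    rows = [
        {
            "trial": i,
            "code_pronation": tr.posture_code[0],
            "code_wrist": tr.posture_code[1],
            "code_aperture": tr.posture_code[2],
            "start_s": tr.start_time,
            "prepare_s": tr.prepare_s,
            "go_s": tr.go_s,
            "rest_s": tr.rest_s,
        }
        for i, tr in enumerate(schedule.trials)
    ]
    return pd.DataFrame(rows)
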