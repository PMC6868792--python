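"""Sliding-window time-domain EMG features (MAV, WFL) and max-normalization.

The decoding front end computes two features per channel from a 200 ms buffer
updated every 50 ms: Mean Absolute Value (MAV, mean rectified amplitude — a
contraction-intensity proxy) and Waveform Length (WFL, cumulative absolute
first difference — mixing amplitude and frequency content).  With 8 channels
this yields a 16-dimensional feature vector per frame, each dimension later
divided by its training-set maximum so training features peak at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: Default analysis window and step (seconds).
WINDOW_S = 0.200
STEP_S = 0.050


class DegenerateChannelError(ValueError):
    """A feature dimension is identically zero where a positive scale is required."""


@dataclass(frozen=True)
class FeatureFrame:
    """Time-indexed feature matrix.

    ``values`` has one row per frame and ``2 * n_channels`` columns: the
    first ``n_channels`` columns are MAV per channel, the last ``n_channels``
    are WFL per channel (channel order preserved).  ``times`` are frame END
    times: the feature at time t summarizes the preceding window (causal,
    matching online use).
    """

    times: np.ndarray
    values: np.ndarray
    window_s: float = WINDOW_S
    step_s: float = STEP_S

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (frames x features)")
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("times/values length mismatch")
        if self.values.shape[1] % 2 != 0:
            raise ValueError("feature column count must be 2 x n_channels")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1] // 2

    def column_labels(self) -> list:
        n = self.n_channels
        return [f"mav_{i}" for i in range(n)] + [f"wfl_{i}" for i in range(n)]


@dataclass(frozen=True)
class FeatureScale:
    """Per-dimension positive divisors (the training-set maxima)."""

    divisors: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.divisors, dtype=float)
        object.__setattr__(self, "divisors", d)
        if np.any(d <= 0) or not np.all(np.isfinite(d)):
            raise ValueError("all divisors must be positive and finite")


def mav(window) -> float:
    """Mean Absolute Value of one window."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("MAV of an empty window is undefined")
    return float(np.mean(np.abs(window)))


def wfl(window) -> float:
    """Waveform Length: sum of absolute first differences within the window."""
    window = np.asarray(window, dtype=float)
    if window.size < 2:
        raise ValueError("WFL needs a window of length >= 2")
    return float(np.sum(np.abs(np.diff(window))))


def _window_step_samples(sample_rate: float, window_s: float, step_s: float):
    win = window_s * sample_rate
    step = step_s * sample_rate
    win_n, step_n = int(round(win)), int(round(step))
    if abs(win - win_n) > 1e-9 or abs(step - step_n) > 1e-9:
        raise ValueError("window and step must be integer numbers of samples")
    if win_n < 1 or step_n < 1:
        raise ValueError("window and step must be >= 1 sample")
    return win_n, step_n


def sliding_windows(
    recording, window_s: float = WINDOW_S, step_s: float = STEP_S
) -> np.ndarray:
    """View a recording as (n_frames, n_channels, window) blocks.

    Frame k covers samples [k*step, k*step + window) (0-based, half-open);
    trailing partial windows are dropped, never zero-padded.
    """
    win_n, step_n = _window_step_samples(recording.sample_rate, window_s, step_s)
    x = recording.samples
    if x.shape[1] < win_n:
        raise ValueError(
            f"recording of {x.shape[1]} samples is shorter than one "
            f"window of {win_n} samples"
        )
    # (n_channels, n_positions, win) -> stride by step -> (frames, channels, win)
    view = sliding_window_view(x, win_n, axis=1)[:, ::step_n, :]
    return np.moveaxis(view, 0, 1)


def extract_features(
    recording, window_s: float = WINDOW_S, step_s: float = STEP_S
) -> FeatureFrame:
    """MAV and WFL per channel over sliding windows.

    Returns a FeatureFrame with columns [mav_0..mav_{C-1}, wfl_0..wfl_{C-1}]
    and times equal to each window's end time in seconds.
    """
    blocks = sliding_windows(recording, window_s, step_s)  # (F, C, W)
    mav_vals = np.mean(np.abs(blocks), axis=2)
    wfl_vals = np.sum(np.abs(np.diff(blocks, axis=2)), axis=2)
    values = np.concatenate([mav_vals, wfl_vals], axis=1)
    win_n, step_n = _window_step_samples(recording.sample_rate, window_s, step_s)
    n_frames = blocks.shape[0]
    times = (np.arange(n_frames) * step_n + win_n) / recording.sample_rate
    return FeatureFrame(times=times, values=values, window_s=window_s, step_s=step_s)


def features_from_window(block: np.ndarray) -> np.ndarray:
    """16-D feature vector from one (n_channels, window) block (online path)."""
    mav_vals = np.mean(np.abs(block), axis=1)
    wfl_vals = np.sum(np.abs(np.diff(block, axis=1)), axis=1)
    return np.concatenate([mav_vals, wfl_vals])


def fit_normalization(train: FeatureFrame) -> FeatureScale:
    """Per-dimension maxima of the training frame, used as divisors."""
    if train.n_frames == 0:
        raise ValueError("cannot fit normalization on an empty feature frame")
    maxima = train.values.max(axis=0)
    bad = np.flatnonzero(maxima <= 0)
    if bad.size:
        labels = np.asarray(train.column_labels())[bad]
        raise DegenerateChannelError(
            f"feature dimension(s) {labels.tolist()} have max 0; cannot normalize"
        )
    return FeatureScale(divisors=maxima)


def apply_normalization(frame: FeatureFrame, scale: FeatureScale) -> FeatureFrame:
    """Divide each dimension by its training maximum (online values may exceed 1)."""
    if frame.values.shape[1] != scale.divisors.shape[0]:
        raise ValueError("feature/scale dimension mismatch")
    return FeatureFrame(
        times=frame.times,
        values=frame.values / scale.divisors,
        window_s=frame.window_s,
        step_s=frame.step_s,
    )
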