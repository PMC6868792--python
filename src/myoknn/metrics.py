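"""Posture-matching performance metrics: success rate, path efficiency, time.

Distances for path efficiency are measured in ROM-normalized coordinates
(each DOF mapped to [0, 1]), so a degree of wrist motion and a percent of
aperture weigh equally.  Path efficiency is the straight-line (minimum)
distance divided by the distance actually traveled, as a percentage; for
successful trials both are measured from the trial's first state to the
point where the winning dwell began, so holding still inside tolerance does
not inflate the traveled distance.
"""

from __future__ import annotations

import numpy as np

from .hand import to_rom_fraction


def path_efficiency(
    trajectory: np.ndarray,
    target,
    arrival_index: int = None,
    include_dwell: bool = False,
) -> float:
    """Percent path efficiency of one trajectory.

    Parameters
    ----------
    trajectory : ndarray (n, 3)
        Physical-unit hand states at a fixed cadence (n >= 2).
    target : array-like (3,) or HandState
        The trial's target posture (used as the minimum-distance endpoint for
        failed trials).
    arrival_index : int or None
        Trajectory index where the success dwell began; None for failures,
        in which case the full trajectory is used and the straight-line
        distance is start -> target.
    include_dwell : bool
        Measure over the whole trajectory even on success.
    """
    traj = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if traj.shape[0] < 2:
        raise ValueError("path efficiency needs a trajectory of >= 2 states")
    if hasattr(target, "as_array"):
        target = target.as_array()
    norm = to_rom_fraction(traj)
    tgt = to_rom_fraction(np.asarray(target, dtype=float))

    if arrival_index is not None and not include_dwell:
        end = int(arrival_index)
        straight = float(np.linalg.norm(norm[end] - norm[0]))
    else:
        end = norm.shape[0] - 1
        if arrival_index is None:
            straight = float(np.linalg.norm(tgt - norm[0]))
        else:
            straight = float(np.linalg.norm(norm[end] - norm[0]))
    steps = np.diff(norm[: end + 1], axis=0)
    traveled = float(np.sum(np.linalg.norm(steps, axis=1)))
    if traveled == 0.0:
        return 100.0 if straight == 0.0 else 0.0
    return 100.0 * straight / traveled


def success_rate(trials) -> float:
    """Percent of trials successful."""
    trials = _trial_list(trials)
    if not trials:
        raise ValueError("success rate of an empty session is undefined")
    return 100.0 * sum(t.success for t in trials) / len(trials)


def trial_time(trial) -> float:
    """Seconds from trial start to dwell completion (30 s for failures)."""
    return float(trial.trial_time_s)


def summarize(trials, include_failures: bool = True) -> dict:
    """Session summary: success rate plus mean/SD path efficiency and time.

    Failed trials contribute their full-trajectory path efficiency and the
    30 s timeout unless ``include_failures`` is False.
    """
    trials = _trial_list(trials)
    if not trials:
        return {"undefined": True, "n_trials": 0}
    kept = trials if include_failures else [t for t in trials if t.success]
    pes = np.array([t.path_efficiency for t in kept]) if kept else np.array([])
    times = np.array([t.trial_time_s for t in kept]) if kept else np.array([])
    return {
        "n_trials": len(trials),
        "success_rate": success_rate(trials),
        "path_efficiency_mean": float(pes.mean()) if pes.size else float("nan"),
        "path_efficiency_sd": float(pes.std(ddof=1)) if pes.size > 1 else 0.0,
        "trial_time_mean": float(times.mean()) if times.size else float("nan"),
        "trial_time_sd": float(times.std(ddof=1)) if times.size > 1 else 0.0,
    }


def _trial_list(trials):
    if hasattr(trials, "trials"):  # SessionResult
        return list(trials.trials)
    return list(trials)
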