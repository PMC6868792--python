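"""Serialization: HDF5 for arrays, CSV for tables, JSON for summaries."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decoder import KnnModel
from .features import FeatureFrame, FeatureScale
from .labeling import IntentSeries
from .synthetic import EmgRecording


def save_recording(path, rec: EmgRecording) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("samples", data=rec.samples, track_times=False)
        d.attrs["sample_rate"] = rec.sample_rate
        d.attrs["labels"] = list(rec.channel_labels)
        d.attrs["condition"] = rec.condition
        if "seed" in rec.meta:
            d.attrs["seed"] = int(rec.meta["seed"])
        if "noise_sigma" in rec.meta:
            f.create_dataset(
                "noise_sigma",
                data=np.asarray(rec.meta["noise_sigma"]),
                track_times=False,
            )


def load_recording(path) -> EmgRecording:
    with h5py.File(path, "r") as f:
        d = f["samples"]
        meta = {}
        if "seed" in d.attrs:
            meta["seed"] = int(d.attrs["seed"])
        if "noise_sigma" in f:
            meta["noise_sigma"] = f["noise_sigma"][...]
        return EmgRecording(
            samples=d[...],
            sample_rate=float(d.attrs["sample_rate"]),
            channel_labels=tuple(str(x) for x in d.attrs["labels"]),
            condition=str(d.attrs["condition"]),
            meta=meta,
        )


def recording_to_csv(path, rec: EmgRecording) -> None:
    """CSV fallback: one column per channel plus a JSON metadata sidecar."""
    df = pd.DataFrame(rec.samples.T, columns=list(rec.channel_labels))
    df.to_csv(path, index=False)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"sample_rate": rec.sample_rate, "condition": rec.condition},
            indent=2,
        )
    )


def features_to_csv(path, frame: FeatureFrame) -> None:
    df = pd.DataFrame(frame.values, columns=frame.column_labels())
    df.insert(0, "time_s", frame.times)
    df.to_csv(path, index=False)


def features_from_csv(path, window_s: float = 0.2, step_s: float = 0.05):
    df = pd.read_csv(path)
    return FeatureFrame(
        times=df["time_s"].to_numpy(),
        values=df.drop(columns=["time_s"]).to_numpy(),
        window_s=window_s,
        step_s=step_s,
    )


def intent_to_csv(path, intent: IntentSeries) -> None:
    df = pd.DataFrame(intent.values, columns=["pronation", "wrist", "aperture"])
    df.insert(0, "time_s", intent.times)
    df.to_csv(path, index=False)


def save_model(path, model: KnnModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "train_features", data=model.train_features, track_times=False
        )
        f.create_dataset(
            "train_targets", data=model.train_targets, track_times=False
        )
        f.attrs["k"] = model.k
        f.attrs["epsilon"] = model.epsilon
        if model.scale is not None:
            f.create_dataset(
                "scale_divisors", data=model.scale.divisors, track_times=False
            )
        if model.trial_ids is not None:
            f.create_dataset("trial_ids", data=model.trial_ids, track_times=False)


def load_model(path) -> KnnModel:
    with h5py.File(path, "r") as f:
        scale = (
            FeatureScale(divisors=f["scale_divisors"][...])
            if "scale_divisors" in f
            else None
        )
        return KnnModel(
            train_features=f["train_features"][...],
            train_targets=f["train_targets"][...],
            k=int(f.attrs["k"]),
            epsilon=float(f.attrs["epsilon"]),
            scale=scale,
            trial_ids=f["trial_ids"][...] if "trial_ids" in f else None,
        )


def session_to_csv(path, result) -> None:
    """One row per trial: block, target triple, outcome, time, efficiency."""
    rows = []
    block_size = result.spec.block_size if result.spec else len(result.trials)
    for i, t in enumerate(result.trials):
        tgt = t.target.as_array()
        rows.append(
            {
                "trial": i,
                "block": i // block_size,
                "target_pronation": tgt[0],
                "target_wrist": tgt[1],
                "target_aperture": tgt[2],
                "success": int(t.success),
                "trial_time_s": t.trial_time_s,
                "path_efficiency": t.path_efficiency,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
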