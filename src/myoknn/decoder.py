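"""Inverse-distance-weighted K-nearest-neighbor velocity regression.

The controller maps a normalized 16-D feature vector to a 3-DOF velocity
intent in [-1, 1]^3: Euclidean distances to every stored training frame are
computed, the K = 100 closest frames are selected (ties at the K-th distance
broken by training-row index, ascending) and their 3-D targets averaged with
weights 1 / (d + epsilon).  A lazy learner: fitting stores the data verbatim.

Offline quality is measured as leave-one-out Variance Accounted For per DOF,
VAF_d = 100 * (1 - var(residual_d) / var(target_d)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureFrame, FeatureScale
from .labeling import IntentSeries


class InsufficientDataError(ValueError):
    """Fewer training frames than neighbors requested."""


class UndefinedVafError(ValueError):
    """A DOF's target variance is zero, so VAF is undefined."""


@dataclass(frozen=True)
class KnnModel:
    """Stored training set plus the neighbor count and feature scale."""

    train_features: np.ndarray
    train_targets: np.ndarray
    k: int = 100
    scale: FeatureScale = None
    epsilon: float = 1e-9
    trial_ids: np.ndarray = None

    def __post_init__(self):
        X = np.asarray(self.train_features, dtype=float)
        T = np.asarray(self.train_targets, dtype=float)
        object.__setattr__(self, "train_features", X)
        object.__setattr__(self, "train_targets", T)
        if X.ndim != 2 or T.ndim != 2 or T.shape[1] != 3:
            raise ValueError("features must be (n, d) and targets (n, 3)")
        if X.shape[0] != T.shape[0]:
            raise ValueError("feature/target row counts differ")
        if X.shape[0] < self.k:
            raise InsufficientDataError(
                f"{X.shape[0]} training frames < k={self.k}"
            )
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(T))):
            raise ValueError("training data must be finite")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def n_train(self) -> int:
        return self.train_features.shape[0]

    @property
    def n_features(self) -> int:
        return self.train_features.shape[1]


def fit(
    features: FeatureFrame,
    intents: IntentSeries,
    k: int = 100,
    scale: FeatureScale = None,
    epsilon: float = 1e-9,
    trial_ids: np.ndarray = None,
) -> KnnModel:
    """Store (normalized) training features and assumed-intent targets.

    No parameters are estimated; the model is the data.  ``scale`` records
    the FeatureScale the features were normalized with so online queries can
    be normalized identically.
    """
    if features.n_frames != intents.n_frames:
        raise ValueError("feature and intent frame counts differ")
    return KnnModel(
        train_features=features.values,
        train_targets=intents.values,
        k=k,
        scale=scale,
        epsilon=epsilon,
        trial_ids=None if trial_ids is None else np.asarray(trial_ids),
    )


def _select_k(d: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest distances, ties broken by index ascending."""
    n = d.shape[0]
    if k >= n:
        return np.arange(n)
    part = np.argpartition(d, k - 1)[:k]
    kth = d[part].max()
    # Re-resolve the boundary so ties at the k-th distance are index-ordered.
    candidates = np.flatnonzero(d <= kth)
    if candidates.size > k:
        order = np.lexsort((candidates, d[candidates]))
        candidates = candidates[order[:k]]
    return candidates


def _predict_one(model: KnnModel, d: np.ndarray) -> np.ndarray:
    idx = _select_k(d, model.k)
    w = 1.0 / (d[idx] + model.epsilon)
    out = (w @ model.train_targets[idx]) / w.sum()
    return np.clip(out, -1.0, 1.0)


def predict(model: KnnModel, x: np.ndarray) -> np.ndarray:
    """Inverse-distance-weighted mean of the k nearest targets, clipped.

    ``x`` may be a single 16-vector or an (m, 16) batch of already-normalized
    queries; returns a 3-vector or an (m, 3) matrix accordingly.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"query has {X.shape[1]} features, model expects {model.n_features}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("query must be finite")
    Xt = model.train_features
    out = np.empty((X.shape[0], 3))
    # Elementwise differences (not the expanded-square GEMM trick): online
    # queries are single frames, and full precision keeps the predictor
    # exactly equivalent to its brute-force definition.
    for lo in range(0, X.shape[0], 32):
        Q = X[lo : lo + 32]
        diffs = Q[:, None, :] - Xt[None, :, :]
        D = np.sqrt(np.einsum("qnd,qnd->qn", diffs, diffs))
        for i in range(Q.shape[0]):
            out[lo + i] = _predict_one(model, D[i])
    return out[0] if single else out


def loo_vaf(
    model: KnnModel, leave_out: str = "sample", chunk: int = 512
) -> np.ndarray:
    """Leave-one-out Variance Accounted For, percent per DOF.

    Each training frame is predicted with itself excluded from the candidate
    set (``leave_out="sample"``); with ``leave_out="trial"`` every frame of
    the same cue trial is excluded (requires ``model.trial_ids``).  VAF may
    be negative for a worse-than-mean predictor.
    """
    n = model.n_train
    if n < model.k + 1:
        raise InsufficientDataError("leave-one-out needs n >= k + 1")
    if leave_out not in ("sample", "trial"):
        raise ValueError("leave_out must be 'sample' or 'trial'")
    if leave_out == "trial" and model.trial_ids is None:
        raise ValueError("leave-one-trial-out requires trial_ids on the model")

    X = model.train_features
    sq_norms = np.einsum("nd,nd->n", X, X)
    preds = np.empty((n, 3))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        block = X[lo:hi]
        d2 = (
            sq_norms[lo:hi, None]
            - 2.0 * block @ X.T
            + sq_norms[None, :]
        )
        D = np.sqrt(np.maximum(d2, 0.0))
        for i in range(hi - lo):
            d = D[i].copy()
            if leave_out == "sample":
                d[lo + i] = np.inf
            else:
                d[model.trial_ids == model.trial_ids[lo + i]] = np.inf
            preds[lo + i] = _predict_one(model, d)

    return vaf(model.train_targets, preds)


def vaf(targets: np.ndarray, predictions: np.ndarray) -> np.ndarray:
    """Variance Accounted For (percent per column) of arbitrary predictions."""
    T = np.asarray(targets, float)
    P = np.asarray(predictions, float)
    var_t = T.var(axis=0)
    # treat numerically-constant columns (variance at rounding level) as zero
    zero = np.flatnonzero(var_t <= np.finfo(float).eps * (1.0 + np.mean(T**2, axis=0)))
    if zero.size:
        raise UndefinedVafError(f"target variance is zero in DOF(s) {zero.tolist()}")
    return 100.0 * (1.0 - (T - P).var(axis=0) / var_t)
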