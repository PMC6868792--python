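"""Session-level stability statistics for the posture-matching metrics.

Temporal stability is assessed with ordinary least squares of a per-trial
metric (path efficiency, or reciprocal trial time to remedy non-normal
errors) on an intercept, a controller indicator (0 = intact-hand position
controller, 1 = KNN) and controller-specific week slopes — no common week
main effect, so each controller carries its own time trend:

    y = b0 + b1 * knn + b2 * week * intact + b3 * week * knn + e

Whether the controller-by-week interaction is retained is decided by a
nested-model F test (ANOVA).  Postural stability across residual-limb
configurations is assessed with tie-corrected Kruskal-Wallis tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

COEF_NAMES = ("Intercept", "C_f", "C_w0", "C_w1")


@dataclass(frozen=True)
class RegressionResult:
    """OLS coefficient table for the stability model."""

    names: tuple
    estimates: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    r_squared: float
    response: str = ""
    transform: str = "none"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.estimates,
                "std_error": self.std_errors,
                "p": self.p_values,
            },
            index=list(self.names),
        )


def _design(table: pd.DataFrame) -> np.ndarray:
    ctrl = table["controller"].astype(str)
    levels = set(ctrl.unique())
    if not levels <= {"intact", "knn"}:
        raise ValueError(f"controller levels must be 'intact'/'knn', got {levels}")
    if len(levels) < 2:
        raise ValueError("both controller levels must be present")
    knn = (ctrl == "knn").to_numpy(dtype=float)
    week = table["week"].to_numpy(dtype=float)
    if np.unique(week).size < 2:
        raise ValueError("need >= 2 distinct weeks")
    X = np.column_stack(
        [np.ones(len(table)), knn, week * (1.0 - knn), week * knn]
    )
    return X


def fit_stability_regression(
    table: pd.DataFrame,
    response: str = "path_efficiency",
    transform: str = "none",
) -> RegressionResult:
    """OLS of a (possibly reciprocal-transformed) metric on the stability design.

    Parameters
    ----------
    table : DataFrame
        Columns ``controller`` ('intact' or 'knn'), ``week`` and the response.
    response : {"path_efficiency", "trial_time"} or any column name
        Metric to model.
    transform : {"none", "reciprocal"}
        ``reciprocal`` fits 1/response (the standard remedy for the
        right-skewed trial-time distribution).
    """
    if transform not in ("none", "reciprocal"):
        raise ValueError(f"unknown transform {transform!r}")
    y = table[response].to_numpy(dtype=float)
    if transform == "reciprocal":
        if np.any(y == 0):
            raise ValueError("reciprocal transform undefined at 0")
        y = 1.0 / y
    X = _design(table)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("stability design matrix is rank-deficient")
    fit = sm.OLS(y, X).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(fit.rsquared)
    if not np.isfinite(r2):  # constant response: TSS = 0
        r2 = 1.0 if fit.ssr <= 1e-12 else float("nan")
    return RegressionResult(
        names=COEF_NAMES,
        estimates=fit.params,
        std_errors=fit.bse,
        p_values=fit.pvalues,
        r_squared=r2,
        response=response,
        transform=transform,
    )


def compare_models_anova(
    table: pd.DataFrame,
    response: str = "path_efficiency",
    transform: str = "none",
    alpha: float = 0.05,
) -> dict:
    """Nested F test: intercept + controller vs. + controller-specific slopes.

    Returns the F statistic, its p value, and which model is selected (the
    interaction model when p < ``alpha``).
    """
    y = table[response].to_numpy(dtype=float)
    if transform == "reciprocal":
        y = 1.0 / y
    X_full = _design(table)
    X_red = X_full[:, :2]
    fit_red = sm.OLS(y, X_red).fit()
    fit_full = sm.OLS(y, X_full).fit()
    f_stat, p_value, _ = fit_full.compare_f_test(fit_red)
    return {
        "F": float(f_stat),
        "p": float(p_value),
        "selected": "interaction" if p_value < alpha else "controller-only",
    }


def kruskal_wallis(groups) -> tuple:
    """Tie-corrected Kruskal-Wallis H and chi-square p across >= 2 groups.

    When every value in every group is identical the statistic degenerates
    to (H=0, p=1) rather than erroring.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    allvals = np.concatenate(groups)
    if np.all(allvals == allvals[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def simulate_stability_table(
    coeffs=(66.9, -21.8, 3.4, 0.6),
    weeks=(0, 2, 4, 6, 8, 10, 12),
    n_per_cell: int = 40,
    noise_sd: float = 15.0,
    seed: int = 0,
    response: str = "path_efficiency",
) -> pd.DataFrame:
    """Synthesize a per-trial stability table with known true coefficients.

    Generates ``n_per_cell`` trials per controller per week from the
    stability model plus Gaussian noise — the ground truth for
    parameter-recovery checks of :func:`fit_stability_regression`.
    """
    b0, b1, b2, b3 = coeffs
    rng = np.random.default_rng(seed)
    rows = []
    for week in weeks:
        for ctrl, knn in (("intact", 0.0), ("knn", 1.0)):
            mu = b0 + b1 * knn + b2 * week * (1 - knn) + b3 * week * knn
            vals = mu + noise_sd * rng.standard_normal(n_per_cell)
            for v in vals:
                rows.append({"controller": ctrl, "week": week, response: v})
    return pd.DataFrame(rows)
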