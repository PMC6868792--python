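"""Signal-quality characterization: crosstalk, SNR, and the associated tests.

Crosstalk between channels is quantified as the zero-lag Pearson correlation
matrix of the band-limited wideband signals; intramuscular electrodes are
expected to show near-zero off-diagonal correlation while a circumferential
surface array shows clear mixing.  Equality of two channel covariance
structures is tested with Box's M; per-channel SNR and duty cycle are
estimated from cyclic contractions by splitting the rectified low-passed
envelope into noise and activity classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from skimage.filters import threshold_otsu


class EstimationError(RuntimeError):
    """The automated SNR estimator could not find activity bursts."""


@dataclass(frozen=True)
class CrosstalkMatrix:
    """Symmetric zero-lag correlation matrix with unit diagonal."""

    values: np.ndarray
    channel_labels: tuple = ()

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", V)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("crosstalk matrix must be square")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SnrReport:
    """Per-channel noise RMS, SNR (dB) and duty cycle."""

    noise_rms: np.ndarray
    snr_db: np.ndarray
    duty_cycle: np.ndarray
    channel_labels: tuple = ()

    def mean_snr_db(self) -> float:
        return float(np.mean(self.snr_db))


def crosstalk_matrix(recording) -> CrosstalkMatrix:
    """Pairwise zero-lag Pearson correlation of the raw channel signals."""
    x = recording.samples
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 channels and >= 2 samples")
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"channel(s) {dead.tolist()} have zero variance")
    return CrosstalkMatrix(
        values=np.corrcoef(x), channel_labels=tuple(recording.channel_labels)
    )


def mean_offdiagonal(matrix: CrosstalkMatrix, absolute: bool = False) -> float:
    """Mean of the strictly off-diagonal correlations (each pair once).

    ``absolute=True`` averages magnitudes instead of signed values; both are
    reported because a signed mean can hide symmetric mixing.
    """
    V = matrix.values
    if V.shape[0] < 2:
        raise ValueError("need >= 2 channels")
    iu = np.triu_indices_from(V, k=1)
    vals = np.abs(V[iu]) if absolute else V[iu]
    return float(vals.mean())


def boxs_m_test(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple:
    """Box's M test for equality of two covariance matrices.

    Returns ``(M_statistic, p_value)`` using the chi-square approximation
    with Box's small-sample correction factor.  Each sample is observations
    x variables and needs at least p + 1 rows.
    """
    A = np.asarray(sample_a, dtype=float)
    B = np.asarray(sample_b, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    p = A.shape[1]
    if B.shape[1] != p:
        raise ValueError("samples must share the number of variables")
    ns = np.array([A.shape[0], B.shape[0]])
    if np.any(ns < p + 1):
        raise ValueError("each sample needs at least p + 1 observations")
    covs = [np.cov(A, rowvar=False), np.cov(B, rowvar=False)]
    covs = [np.atleast_2d(c) for c in covs]
    dfs = ns - 1
    N = dfs.sum()
    pooled = sum(df * c for df, c in zip(dfs, covs)) / N
    sign, logdet_pooled = np.linalg.slogdet(pooled)
    if sign <= 0:
        raise np.linalg.LinAlgError("pooled covariance is singular")
    M = N * logdet_pooled
    for df, c in zip(dfs, covs):
        sign, logdet = np.linalg.slogdet(c)
        if sign <= 0:
            raise np.linalg.LinAlgError("a group covariance is singular")
        M -= df * logdet
    g = 2
    c1 = (2 * p**2 + 3 * p - 1) / (6.0 * (p + 1) * (g - 1))
    c1 *= np.sum(1.0 / dfs) - 1.0 / N
    chi2 = M * (1.0 - c1)
    df_chi = p * (p + 1) * (g - 1) / 2.0
    p_value = float(stats.chi2.sf(chi2, df_chi))
    return float(M), p_value


def estimate_snr(
    recording,
    lowpass_hz: float = 2.0,
    activity_factor: float = 3.0,
    guard_s: float = 0.25,
) -> SnrReport:
    """Automated SNR/noise/duty-cycle estimation from cyclic contractions.

    Per channel: the envelope is the 2 Hz low-passed full-wave-rectified
    signal; an Otsu split of the envelope amplitudes separates a noise mode
    from an activity mode, the noise RMS is taken from the raw signal in the
    lower class, and the activity mask is envelope > ``activity_factor`` x
    noise RMS.  SNR is 20*log10(active RMS / quiet RMS), with a ``guard_s``
    band around every on/off transition excluded from both RMS pools (the
    low-passed envelope smears burst edges over ~1/lowpass_hz, which would
    otherwise bias low-SNR estimates downward); duty cycle is the active
    fraction of the full mask.  Raises :class:`EstimationError` when no
    bursts are detectable (e.g. pure noise input).
    """
    from scipy.ndimage import binary_erosion

    x = recording.samples
    fs = recording.sample_rate
    sos = signal.butter(4, lowpass_hz, btype="lowpass", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, np.abs(x), axis=1)

    noise_rms, snrs, duties = [], [], []
    for ch in range(x.shape[0]):
        e = env[ch]
        thr = threshold_otsu(e)
        quiet_split = e <= thr
        spread = e.max() - e.min()
        if spread <= 0 or quiet_split.all() or not quiet_split.any():
            raise EstimationError(f"channel {ch}: no activity bursts detected")
        guard_n = int(round(guard_s * fs))
        structure = np.ones(2 * guard_n + 1, dtype=bool) if guard_n > 0 else None
        # noise RMS from the core of the Otsu noise class (edges of the
        # smoothed envelope leak burst energy into the lower class)
        quiet_core = (
            binary_erosion(quiet_split, structure=structure)
            if structure is not None
            else quiet_split
        )
        if not quiet_core.any():
            quiet_core = quiet_split
        n_rms = np.sqrt(np.mean(x[ch, quiet_core] ** 2))
        active = e > activity_factor * n_rms
        quiet = ~active
        if not active.any() or not quiet.any():
            raise EstimationError(f"channel {ch}: no activity bursts detected")
        # Guard against an Otsu split of a unimodal (pure noise) envelope:
        # real bursts separate the class means by far more than the spread
        # within the noise class.
        if e[active].mean() < 2.0 * e[quiet_split].mean():
            raise EstimationError(f"channel {ch}: no activity bursts detected")
        if structure is not None:
            core_a = binary_erosion(active, structure=structure)
            core_q = binary_erosion(quiet, structure=structure)
            if core_a.any() and core_q.any():
                active_rms_pool, quiet_rms_pool = core_a, core_q
            else:  # bursts shorter than the guard: fall back to raw classes
                active_rms_pool, quiet_rms_pool = active, quiet
        else:
            active_rms_pool, quiet_rms_pool = active, quiet
        rms_a = np.sqrt(np.mean(x[ch, active_rms_pool] ** 2))
        rms_q = np.sqrt(np.mean(x[ch, quiet_rms_pool] ** 2))
        noise_rms.append(n_rms)
        snrs.append(20.0 * np.log10(rms_a / rms_q))
        duties.append(active.mean())
    return SnrReport(
        noise_rms=np.asarray(noise_rms),
        snr_db=np.asarray(snrs),
        duty_cycle=np.asarray(duties),
        channel_labels=tuple(recording.channel_labels),
    )


def ranksum_test(a, b) -> tuple:
    """Two-sided Wilcoxon rank-sum test with tie correction.

    Returns ``(statistic, p_value)`` where the statistic is the
    Mann–Whitney U of the first sample (equivalent to the rank-sum up to a
    constant shift).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
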