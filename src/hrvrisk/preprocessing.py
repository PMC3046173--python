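"""ECG preprocessing: R-peak detection and ectopic-interval removal.

R peaks are located by a Pan-Tompkins detector fed by a Haar wavelet
detail reconstruction: the signal is decomposed to the requested level,
the approximation is discarded, and the signal rebuilt from detail
coefficients only.  This removes baseline drift (and, at low levels,
leaves high-frequency noise in — the motivation for the level sweep).
Detected fiducials are refined to the local extremum of the *raw* ECG
within +/-50 ms so the NN series is read off the unfiltered trace.

Ectopic intervals are removed with the generalized extreme studentized
deviate (ESD) procedure: Grubbs' single-outlier test iterated Rosner-style
up to a budget of ``k_max`` candidates, each iteration's statistic
``R = max |x - mean| / sd`` compared against a t-distribution critical
value at level ``alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError
from .io import ECGRecord, RRSeries

__all__ = [
    "RPeakSet",
    "DetectionScore",
    "OutlierReport",
    "detect_r_peaks",
    "score_detection",
    "rr_from_peaks",
    "rosner_filter",
]


@dataclass
class RPeakSet:
    """Detected R-peak sample indices for one record."""

    indices: np.ndarray
    fs: float
    level: int = 4

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class DetectionScore:
    """Beat-detection performance: Se = TP/(TP+FN), Ac = TP/(TP+FN+FP)."""

    FP: int
    FN: int
    Se: float
    Ac: float


@dataclass
class OutlierReport:
    """Trace of one generalized-ESD run."""

    removed_indices: list[int] = field(default_factory=list)
    statistics: list[float] = field(default_factory=list)
    critical_values: list[float] = field(default_factory=list)
    alpha: float = 0.05
    k_max: int = 0


def _detail_reconstruction(x: np.ndarray, level: int) -> np.ndarray:
    """Rebuild ``x`` from Haar detail coefficients at levels 1..level only."""
    coeffs = pywt.wavedec(x, "haar", level=level)
    coeffs[0] = np.zeros_like(coeffs[0])  # drop the approximation
    rec = pywt.waverec(coeffs, "haar")
    return rec[: x.size]


def detect_r_peaks(ecg: ECGRecord, level: int = 4) -> RPeakSet:
    """Detect R peaks with a Haar-detail pre-filter and Pan-Tompkins.

    Parameters
    ----------
    ecg : ECGRecord
        Input record; must span at least 2 s.
    level : int
        Wavelet decomposition level (1-4).  The reconstruction keeps
        detail levels 1..level; higher levels retain more of the QRS
        band and reject more noise.
    """
    if level not in (1, 2, 3, 4):
        raise ConfigurationError(f"level must be in 1..4, got {level}")
    fs = float(ecg.fs)
    if fs < 40:
        raise ConfigurationError(
            f"sampling rate {fs} Hz too low for the 5-15 Hz QRS band-pass"
        )
    x = _detail_reconstruction(ecg.samples, level)

    # Pan-Tompkins chain, zero-phase so fiducials stay aligned with the raw R
    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, min(15.0, 0.9 * nyq) / nyq], btype="band")
    filtered = sps.filtfilt(b, a, x)
    deriv = np.gradient(filtered)
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    cand, _ = sps.find_peaks(integrated, distance=max(1, refractory))
    if cand.size == 0 or not np.any(integrated > 0):
        return RPeakSet(indices=np.array([], dtype=int), fs=fs, level=level)

    # adaptive dual threshold (signal/noise running estimates)
    init = integrated[: int(2 * fs)]
    spki = float(init.max())
    npki = 0.5 * float(init.mean())
    threshold = npki + 0.25 * (spki - npki)

    accepted: list[int] = []
    rr_recent: list[float] = []
    last_unaccepted: list[int] = []
    for idx in cand:
        peak = integrated[idx]
        if accepted and idx - accepted[-1] < refractory:
            continue
        if peak > threshold:
            if accepted:
                rr_recent.append(idx - accepted[-1])
                rr_recent = rr_recent[-8:]
            accepted.append(int(idx))
            spki = 0.125 * peak + 0.875 * spki
            last_unaccepted = []
        else:
            # search-back: if we have gone too long without a beat, accept
            # the best sub-threshold candidate above half the threshold
            if rr_recent and accepted:
                mean_rr = float(np.mean(rr_recent))
                if idx - accepted[-1] > 1.66 * mean_rr and last_unaccepted:
                    best = max(last_unaccepted, key=lambda i: integrated[i])
                    if integrated[best] > 0.5 * threshold and best - accepted[-1] >= refractory:
                        rr_recent.append(best - accepted[-1])
                        rr_recent = rr_recent[-8:]
                        accepted.append(int(best))
                        accepted.sort()
                        spki = 0.125 * integrated[best] + 0.875 * spki
                        last_unaccepted = []
                        continue
            last_unaccepted.append(int(idx))
            npki = 0.125 * peak + 0.875 * npki
        threshold = npki + 0.25 * (spki - npki)

    # refine each fiducial to the raw-signal local extremum within +/-50 ms
    half = int(round(0.050 * fs))
    raw = ecg.samples
    refined: list[int] = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(raw.size, idx + half + 1)
        refined.append(lo + int(np.argmax(raw[lo:hi])))
    refined = sorted(set(refined))
    return RPeakSet(indices=np.asarray(refined, dtype=int), fs=fs, level=level)


def score_detection(
    detected: RPeakSet,
    truth: np.ndarray,
    tol_ms: float = 50.0,
) -> DetectionScore:
    """Score detected beats against ground-truth indices.

    Greedy one-to-one matching within ``tol_ms``; Se and Ac in percent.
    """
    if tol_ms <= 0:
        raise ConfigurationError("matching tolerance must be positive")
    truth = np.asarray(truth, dtype=int)
    tol = tol_ms / 1000.0 * detected.fs
    det = detected.indices
    used = np.zeros(det.size, dtype=bool)
    tp = 0
    for t in truth:
        if det.size == 0:
            break
        free = np.nonzero(~used)[0]
        if free.size == 0:
            break
        dist = np.abs(det[free] - t)
        j = free[int(np.argmin(dist))]
        if abs(det[j] - t) <= tol:
            used[j] = True
            tp += 1
    fn = int(truth.size - tp)
    fp = int(det.size - tp)
    se = 100.0 * tp / (tp + fn) if (tp + fn) else 0.0
    ac = 100.0 * tp / (tp + fn + fp) if (tp + fn + fp) else 0.0
    return DetectionScore(FP=fp, FN=fn, Se=se, Ac=ac)


def rr_from_peaks(peaks: RPeakSet, id: str = "") -> RRSeries:
    """Convert R-peak indices to an NN interval series in milliseconds."""
    if len(peaks) < 2:
        raise InsufficientDataError("need at least 2 peaks to form intervals")
    intervals = 1000.0 * np.diff(peaks.indices) / peaks.fs
    return RRSeries(intervals=intervals, id=id)


def _esd_critical_value(n: int, i: int, alpha: float) -> float:
    """Rosner critical value lambda_i for the i-th iteration (1-based)."""
    ni = n - i + 1  # sample size at this iteration
    p = 1.0 - alpha / (2.0 * ni)
    t = stats.t.ppf(p, ni - 2)
    return (ni - 1) * t / np.sqrt((ni - 2 + t**2) * ni)


def rosner_filter(
    rr: RRSeries,
    k_max: int | None = None,
    alpha: float = 0.05,
) -> tuple[RRSeries, OutlierReport]:
    """Remove ectopic intervals with the generalized ESD (Rosner) test.

    Up to ``k_max`` candidates are peeled off one at a time (the most
    extreme point under ``R = max |x - mean|/sd``, sample-sd convention);
    the declared outlier count is the largest iteration whose statistic
    exceeds its t-based critical value.  Declared outliers are dropped,
    order of the surviving intervals preserved.

    Defaults: ``alpha = 0.05``, ``k_max = ceil(0.05 * len(rr))``.
    """
    x = rr.intervals
    n = x.size
    if n < 10:
        raise InsufficientDataError(f"need >= 10 intervals, got {n}")
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if k_max is None:
        k_max = int(np.ceil(0.05 * n))
    if k_max < 0:
        raise ConfigurationError("k_max must be >= 0")
    if k_max >= n / 2:
        raise ConfigurationError(
            f"k_max = {k_max} >= half the series length {n} (degenerate test)"
        )

    report = OutlierReport(alpha=alpha, k_max=k_max)
    if k_max == 0:
        return RRSeries(intervals=x.copy(), id=rr.id), report

    remaining = np.arange(n)
    candidates: list[int] = []
    for i in range(1, k_max + 1):
        sample = x[remaining]
        mean = sample.mean()
        sd = sample.std(ddof=1)
        if sd == 0:
            break  # degenerate dispersion: nothing can be an outlier
        dev = np.abs(sample - mean) / sd
        j = int(np.argmax(dev))
        report.statistics.append(float(dev[j]))
        report.critical_values.append(float(_esd_critical_value(n, i, alpha)))
        candidates.append(int(remaining[j]))
        remaining = np.delete(remaining, j)

    n_out = 0
    for i, (r_stat, lam) in enumerate(
        zip(report.statistics, report.critical_values), start=1
    ):
        if r_stat > lam:
            n_out = i
    report.removed_indices = sorted(candidates[:n_out])
    if report.removed_indices:
        warnings.warn(
            f"series {rr.id!r}: removed {n_out} ectopic interval(s) "
            f"at positions {report.removed_indices}",
            stacklevel=2,
        )
    keep = np.setdiff1d(np.arange(n), report.removed_indices)
    return RRSeries(intervals=x[keep], id=rr.id), report
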