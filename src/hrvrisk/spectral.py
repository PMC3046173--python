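"""Frequency-domain HRV: tachogram resampling, detrending, AR spectrum.

The unevenly sampled NN series is cubic-spline interpolated onto an even
4 Hz grid, detrended with the smoothness-priors method (regularized
least squares with a second-difference penalty), and modelled as an
autoregressive process of order 16 fitted by the covariance
(least-squares) method.  The power spectral density

    P(f) = sigma^2 / fs / |1 + sum_k a_k exp(-i 2 pi f k / fs)|^2

is integrated over the standard short-term bands VLF [0, 0.04), LF
[0.04, 0.15) and HF [0.15, 0.4] Hz; NLF/NHF normalize LF and HF by
LF + HF (VLF excluded), and LF/HF indexes sympathovagal balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.interpolate import CubicSpline
from scipy.sparse.linalg import spsolve

from .errors import ConfigurationError, InsufficientDataError, NumericalError
from .io import RRSeries

__all__ = [
    "Tachogram",
    "PSDEstimate",
    "SpectralFeatures",
    "resample_rr",
    "detrend_sp",
    "ar_psd",
    "band_powers",
    "spectral_features",
]

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


@dataclass
class Tachogram:
    """Evenly resampled NN signal (ms) at rate ``fs_i`` Hz."""

    values: np.ndarray
    fs_i: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class PSDEstimate:
    freqs: np.ndarray
    power: np.ndarray
    order: int
    coeffs: np.ndarray
    noise_var: float


@dataclass
class SpectralFeatures:
    VLF: float
    LF: float
    HF: float
    NLF: float
    NHF: float
    LFHF: float

    def as_dict(self) -> dict[str, float]:
        return {
            "VLF": self.VLF,
            "LF": self.LF,
            "HF": self.HF,
            "NLF": self.NLF,
            "NHF": self.NHF,
            "LFHF": self.LFHF,
        }


def resample_rr(rr: RRSeries, fs_i: float = 4.0) -> Tachogram:
    """Cubic-spline interpolation of the tachogram onto an even grid.

    The NN series is a point process sampled at the beat times
    (cumulative interval sums); the spline is evaluated at ``fs_i`` Hz
    between the first and last beat.
    """
    if rr.intervals.size < 4:
        raise InsufficientDataError("need >= 4 intervals for cubic interpolation")
    if fs_i <= 2 * HF_BAND[1]:
        raise ConfigurationError(
            f"fs_i = {fs_i} Hz must exceed twice the HF upper edge (0.8 Hz)"
        )
    t = np.cumsum(rr.intervals) / 1000.0  # beat times, s
    if np.any(np.diff(t) <= 0):
        raise NumericalError("cumulative beat time is not strictly increasing")
    spline = CubicSpline(t, rr.intervals)
    n = int(np.floor((t[-1] - t[0]) * fs_i)) + 1
    grid = t[0] + np.arange(n) / fs_i
    return Tachogram(values=spline(grid), fs_i=fs_i)


def detrend_sp(tach: Tachogram, lam: float = 500.0) -> Tachogram:
    """Smoothness-priors detrending with penalty weight ``lam``.

    Subtracts the trend ``(I + lam^2 D2' D2)^{-1} z`` (``D2`` the
    second-difference operator), then removes the residual mean.  Acts
    as a high-pass filter whose cutoff decreases with ``lam``;
    ``lam = 500`` at 4 Hz passes the whole LF band essentially intact.
    """
    z = tach.values
    n = z.size
    if n < 10:
        raise InsufficientDataError("need >= 10 samples to detrend")
    if lam <= 0:
        raise ConfigurationError("lam must be positive")
    d2 = sparse.diags_array(
        [np.ones(n - 2), -2 * np.ones(n - 2), np.ones(n - 2)],
        offsets=[0, 1, 2],
        shape=(n - 2, n),
        format="csc",
    )
    a = sparse.eye_array(n, format="csc") + (lam**2) * (d2.T @ d2)
    trend = spsolve(a, z)
    resid = z - trend
    return Tachogram(values=resid - resid.mean(), fs_i=tach.fs_i)


def ar_psd(tach: Tachogram, p: int = 16, n_freqs: int = 1024) -> PSDEstimate:
    """AR(p) power spectral density by the covariance method.

    Coefficients solve the least-squares prediction problem
    ``x[n] = -sum_k a_k x[n-k]`` over all fully determined rows
    (no windowing of the data — the covariance method proper).
    """
    x = tach.values
    fs = tach.fs_i
    if p < 1:
        raise ConfigurationError(f"AR order must be >= 1, got {p}")
    if x.size <= 3 * p:
        raise InsufficientDataError(
            f"need more than 3*p = {3 * p} samples, got {x.size}"
        )
    # design matrix of lagged samples: row n -> [x[n-1], ..., x[n-p]]
    cols = [x[p - k : x.size - k] for k in range(1, p + 1)]
    X = np.column_stack(cols)
    y = x[p:]
    try:
        sol, rss, rank, _ = np.linalg.lstsq(X, y)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise NumericalError(f"AR normal equations failed: {exc}") from exc
    if rank < p or not np.all(np.isfinite(sol)):
        raise NumericalError("AR covariance fit is singular or non-finite")
    a = -sol  # x[n] + sum a_k x[n-k] = e[n]
    resid = y - X @ sol
    noise_var = float(np.mean(resid**2))
    freqs = np.linspace(0.0, fs / 2.0, n_freqs)
    # A(f) = 1 + sum a_k exp(-i 2 pi f k / fs)
    k = np.arange(1, p + 1)
    A = 1.0 + np.exp(-2j * np.pi * np.outer(freqs, k) / fs) @ a.astype(complex)
    power = noise_var / fs / np.abs(A) ** 2
    return PSDEstimate(freqs=freqs, power=power, order=p, coeffs=a, noise_var=noise_var)


def _band_integral(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi] with interpolated edges."""
    inside = (freqs > lo) & (freqs < hi)
    f_band = np.concatenate(([lo], freqs[inside], [hi]))
    p_band = np.concatenate(
        ([np.interp(lo, freqs, power)], power[inside], [np.interp(hi, freqs, power)])
    )
    return float(np.trapezoid(p_band, f_band))


def band_powers(psd: PSDEstimate) -> SpectralFeatures:
    """Integrate the spectrum over VLF / LF / HF and derive the ratios."""
    if psd.freqs[-1] < HF_BAND[1]:
        raise ConfigurationError(
            f"spectrum must cover [0, {HF_BAND[1]}] Hz, ends at {psd.freqs[-1]}"
        )
    vlf = _band_integral(psd.freqs, psd.power, *VLF_BAND)
    lf = _band_integral(psd.freqs, psd.power, *LF_BAND)
    hf = _band_integral(psd.freqs, psd.power, *HF_BAND)
    if lf + hf > 0:
        nlf = 100.0 * lf / (lf + hf)
        nhf = 100.0 * hf / (lf + hf)
    else:
        nlf = nhf = float("nan")
    if hf > 0:
        lfhf = lf / hf
    else:
        warnings.warn("HF power is zero; LF/HF reported as missing", stacklevel=2)
        lfhf = float("nan")
    return SpectralFeatures(VLF=vlf, LF=lf, HF=hf, NLF=nlf, NHF=nhf, LFHF=lfhf)


def spectral_features(
    rr: RRSeries,
    fs_i: float = 4.0,
    lam: float = 500.0,
    order: int = 16,
) -> SpectralFeatures:
    """Full frequency-domain chain: resample -> detrend -> AR(16) -> bands."""
    tach = detrend_sp(resample_rr(rr, fs_i=fs_i), lam=lam)
    return band_powers(ar_psd(tach, p=order))
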