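"""Nonlinear HRV: Poincare-map geometry and complexity measures.

The Poincare map plots each interval against the next.  Rotating the
cloud by pi/4 gives axes along (u) and across (v) the identity line:
SD1 (short-term variability) is the dispersion of v, SD2 (long-term)
the dispersion of u, both population standard deviations so the exact
identities SD1^2 = SDSD_pop^2 / 2 and SD2^2 = 2 SDNN_pop^2 - SDSD_pop^2/2
hold.  The histogram technique summarizes the same cloud by the widths
of the NN-interval, width (v) and length (u) histograms.

Approximate entropy (ApEn, self-matches included) and sample entropy
(SmEn, self-matches excluded) quantify regularity over template length
m with Chebyshev tolerance r = k * SD of the series, k in [0.1, 0.2].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InsufficientDataError
from .io import RRSeries

__all__ = [
    "PoincareFeatures",
    "ComplexityParams",
    "poincare_features",
    "apen",
    "smen",
    "complexity_features",
]

#: conventional HRV histogram bin: 1/128 s
DEFAULT_BIN_MS = 7.8125


@dataclass
class PoincareFeatures:
    SD1: float
    SD2: float
    widthNN: float
    widthW: float
    widthL: float

    def as_dict(self) -> dict[str, float]:
        return {
            "SD1": self.SD1,
            "SD2": self.SD2,
            "widthNN": self.widthNN,
            "widthW": self.widthW,
            "widthL": self.widthL,
        }


@dataclass
class ComplexityParams:
    """Template length m and Chebyshev tolerance r (ms)."""

    m: int
    r: float

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigurationError(f"m must be >= 1, got {self.m}")


def _bin_up(value: float, bin_ms: float) -> float:
    """Round a range up to a whole number of bins (bin_ms = 0: no binning)."""
    if bin_ms <= 0 or value == 0:
        return value
    # tolerate float fuzz at bin boundaries
    return float(np.ceil(value / bin_ms - 1e-9) * bin_ms)


def poincare_features(rr: RRSeries, bin_ms: float = DEFAULT_BIN_MS) -> PoincareFeatures:
    """Ellipse (SD1/SD2) and histogram-width features of the Poincare map."""
    x = rr.intervals
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 intervals, got {x.size}")
    a, b = x[:-1], x[1:]
    u = (b + a) / np.sqrt(2.0)  # along the identity line
    v = (b - a) / np.sqrt(2.0)  # across the identity line
    return PoincareFeatures(
        SD1=float(v.std(ddof=0)),
        SD2=float(u.std(ddof=0)),
        widthNN=_bin_up(float(a.max() - a.min()), bin_ms),
        widthW=_bin_up(float(v.max() - v.min()), bin_ms),
        widthL=_bin_up(float(u.max() - u.min()), bin_ms),
    )


def _check_complexity_input(x: np.ndarray, params: ComplexityParams) -> None:
    if x.size < 10 * params.m:
        warnings.warn(
            f"series length {x.size} below the guideline 10*m = {10 * params.m}; "
            "entropy estimates may be unstable",
            stacklevel=3,
        )
    if params.r <= 0 and np.ptp(x) > 0:
        raise ConfigurationError("tolerance r must be positive for non-constant input")


def _chebyshev_neighbor_counts(x: np.ndarray, m: int, r: float, n_templates: int) -> np.ndarray:
    """For each of the first ``n_templates`` m-length templates, count
    templates (among the same set) within Chebyshev distance r, self
    included."""
    # incremental max over the m lags keeps memory at one (n, n) matrix
    d = np.abs(x[:n_templates, None] - x[None, :n_templates])
    for k in range(1, m):
        np.maximum(d, np.abs(x[k : k + n_templates, None] - x[None, k : k + n_templates]), out=d)
    return (d <= r).sum(axis=1)


def apen(rr: RRSeries | np.ndarray, params: ComplexityParams) -> float:
    """Approximate entropy (Pincus): Phi^m(r) - Phi^{m+1}(r).

    Chebyshev distance, self-matches included,
    ``Phi^m = mean_i ln(C_i^m(r))``.
    """
    x = np.asarray(rr.intervals if isinstance(rr, RRSeries) else rr, dtype=float)
    m, r = params.m, params.r
    if x.size < m + 2:
        raise InsufficientDataError("series too short for the template length")
    if np.ptp(x) == 0:
        return 0.0
    _check_complexity_input(x, params)

    def phi(mm: int) -> float:
        n_templ = x.size - mm + 1
        counts = _chebyshev_neighbor_counts(x, mm, r, n_templ)
        return float(np.mean(np.log(counts / n_templ)))

    return phi(m) - phi(m + 1)


def smen(rr: RRSeries | np.ndarray, params: ComplexityParams) -> float:
    """Sample entropy (Richman-Moorman): -ln(A/B), self-matches excluded.

    A and B count (m+1)- and m-length Chebyshev matches over the same
    N - m templates.  Returns NaN (with a warning) when either count is
    zero — the estimate is undefined rather than infinite.
    """
    x = np.asarray(rr.intervals if isinstance(rr, RRSeries) else rr, dtype=float)
    m, r = params.m, params.r
    if x.size < m + 2:
        raise InsufficientDataError("series too short for the template length")
    if np.ptp(x) == 0:
        return 0.0
    _check_complexity_input(x, params)
    n_templ = x.size - m  # same template count for both lengths
    b_counts = _chebyshev_neighbor_counts(x, m, r, n_templ) - 1  # drop self
    a_counts = _chebyshev_neighbor_counts(x, m + 1, r, n_templ) - 1
    B = int(b_counts.sum())
    A = int(a_counts.sum())
    if A == 0 or B == 0:
        warnings.warn(
            f"sample entropy undefined (A={A}, B={B}) at m={m}, r={r:.4g}; "
            "reporting missing value",
            stacklevel=2,
        )
        return float("nan")
    return float(-np.log(A / B))


def complexity_features(
    rr: RRSeries,
    k: float = 0.2,
    m_max: int = 4,
) -> dict[str, float]:
    """ApEn and SmEn for m = 1..m_max at tolerance r = k * SD of the series."""
    if not 0 < k:
        raise ConfigurationError("k must be positive")
    sd = float(rr.intervals.std(ddof=1))
    out: dict[str, float] = {}
    for m in range(1, m_max + 1):
        if sd == 0:
            out[f"ApEn_m{m}"] = 0.0
            out[f"SmEn_m{m}"] = 0.0
            continue
        params = ComplexityParams(m=m, r=k * sd)
        out[f"ApEn_m{m}"] = apen(rr, params)
        out[f"SmEn_m{m}"] = smen(rr, params)
    return out
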