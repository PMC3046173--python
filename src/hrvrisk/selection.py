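"""Normality checks, two-sample KS feature selection, MinMax scaling.

HRV features are generally far from normal, so group differences are
screened with the distribution-free two-sample Kolmogorov-Smirnov test:
D = sup |ECDF_a - ECDF_b| with an asymptotic p-value at effective size
n_a n_b / (n_a + n_b).  Two alpha levels are used: 0.05 to report a
feature as significant, 0.01 (stricter) to admit it to the classifier
pool.  No multiple-testing correction is applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConfigurationError, InsufficientDataError, LabelingError

__all__ = [
    "SelectionReport",
    "normality_check",
    "ks_two_sample",
    "select_features",
    "minmax_fit_apply",
    "MinMaxBounds",
]

ALPHA_SIGNIFICANT = 0.05
ALPHA_SELECT = 0.01


def normality_check(values: np.ndarray) -> tuple[float, float, bool]:
    """Chi-square and one-sample-KS goodness of fit to a fitted Normal.

    Returns ``(chi2_p, ks1_p, skipped)``.  The chi-square test bins the
    sample into equal-probability bins of the fitted Normal with
    expected counts >= 5 (dof = bins - 3); the KS test compares against
    Normal(sample mean, sample sd).  Zero-variance samples are skipped.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 20:
        raise InsufficientDataError(f"need n >= 20 for the chi-square binning, got {n}")
    mu, sd = float(x.mean()), float(x.std(ddof=1))
    if sd == 0:
        return float("nan"), float("nan"), True
    n_bins = max(4, min(20, n // 5))  # expected count n/n_bins >= 5
    edges = stats.norm.ppf(np.linspace(0, 1, n_bins + 1), loc=mu, scale=sd)
    observed, _ = np.histogram(x, bins=edges)
    expected = np.full(n_bins, n / n_bins)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    dof = n_bins - 1 - 2  # two fitted parameters
    chi2_p = float(stats.chi2.sf(chi2, dof))
    ks1_p = float(stats.kstest(x, "norm", args=(mu, sd)).pvalue)
    return chi2_p, ks1_p, False


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value.

    D is the supremum ECDF difference over the pooled sample; p comes
    from the Kolmogorov distribution at sqrt(n_eff) * D with
    n_eff = |a||b| / (|a| + |b|).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size < 5 or b.size < 5:
        raise InsufficientDataError("each sample needs >= 5 observations")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    n_eff = a.size * b.size / (a.size + b.size)
    p = float(special.kolmogorov(np.sqrt(n_eff) * d))
    return d, min(1.0, p)


@dataclass
class SelectionReport:
    """Per-feature KS results and the selected subset."""

    feature_names: list[str]
    statistics: dict[str, float]
    p_values: dict[str, float]
    ranks: dict[str, int]
    selected: list[str]
    alpha_significant: float = ALPHA_SIGNIFICANT
    alpha_select: float = ALPHA_SELECT
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "alpha_significant": self.alpha_significant,
            "alpha_select": self.alpha_select,
            "selected": self.selected,
            "features": {
                name: {
                    "D": self.statistics[name],
                    "p": self.p_values[name],
                    "rank": self.ranks[name],
                    "significant": self.p_values[name] < self.alpha_significant,
                }
                for name in self.feature_names
            },
            "warnings": self.warnings,
        }


def select_features(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    alpha_select: float = ALPHA_SELECT,
    top_k: int = 5,
    alpha_significant: float = ALPHA_SIGNIFICANT,
) -> SelectionReport:
    """Rank features by two-sample KS p-value between the two label groups.

    Features with p < ``alpha_select`` are eligible; the first ``top_k``
    by ascending p (ties broken by column order) are selected.
    """
    if top_k < 1:
        raise ConfigurationError("top_k must be >= 1")
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise LabelingError(f"need exactly 2 label groups, got {groups.tolist()}")
    mask = labels == groups[0]
    stats_d: dict[str, float] = {}
    pvals: dict[str, float] = {}
    for name in features.columns:
        col = features[name].to_numpy(dtype=float)
        finite = np.isfinite(col)
        a, b = col[finite & mask], col[finite & ~mask]
        if a.size < 5 or b.size < 5:
            stats_d[name], pvals[name] = float("nan"), float("nan")
            continue
        stats_d[name], pvals[name] = ks_two_sample(a, b)
    order = sorted(
        features.columns,
        key=lambda n: (
            np.inf if np.isnan(pvals[n]) else pvals[n],
            list(features.columns).index(n),
        ),
    )
    ranks = {name: i + 1 for i, name in enumerate(order)}
    eligible = [n for n in order if np.isfinite(pvals[n]) and pvals[n] < alpha_select]
    selected = eligible[:top_k]
    warns: list[str] = []
    if len(selected) < top_k:
        msg = (
            f"only {len(selected)} of the requested {top_k} features pass "
            f"p < {alpha_select}"
        )
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)
    return SelectionReport(
        feature_names=list(features.columns),
        statistics=stats_d,
        p_values=pvals,
        ranks=ranks,
        selected=selected,
        alpha_significant=alpha_significant,
        alpha_select=alpha_select,
        warnings=warns,
    )


@dataclass
class MinMaxBounds:
    mins: pd.Series
    maxs: pd.Series
    constant_features: list[str]


def minmax_fit_apply(
    train: pd.DataFrame,
    *others: pd.DataFrame,
) -> tuple[list[pd.DataFrame], MinMaxBounds]:
    """MinMax normalization fitted on the training table only.

    ``x' = (x - min_train) / (max_train - min_train)``; the bounds are
    applied unchanged to the other tables, whose values may legitimately
    fall outside [0, 1].  Constant training features map to 0 and are
    flagged.
    """
    if train.shape[0] == 0:
        raise InsufficientDataError("training table is empty")
    mins = train.min(axis=0)
    maxs = train.max(axis=0)
    span = maxs - mins
    constant = list(span.index[span == 0])
    safe_span = span.replace(0, 1.0)

    def apply(df: pd.DataFrame) -> pd.DataFrame:
        out = (df - mins) / safe_span
        for c in constant:
            out[c] = 0.0
        return out

    bounds = MinMaxBounds(mins=mins, maxs=maxs, constant_features=constant)
    return [apply(df) for df in (train, *others)], bounds
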