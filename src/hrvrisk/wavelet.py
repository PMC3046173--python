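"""Multi-resolution HRV features: wavelet-packet energy and entropy + PCA.

The mean-subtracted NN series is decomposed into a full wavelet-packet
tree (Daubechies-4, periodization, level 5).  Every node over levels
1..5 (2 + 4 + 8 + 16 + 32 = 62 nodes) contributes two features:

* energy  — the mean squared coefficient of the node,
* entropy — Shannon entropy of the node's normalized squared
  coefficients ``p_i = c_i^2 / sum c^2`` (natural log, 0*ln 0 = 0).

The resulting 124-column block is highly redundant; a standard PCA
(covariance eigendecomposition with a deterministic sign convention)
is provided to reduce it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from sklearn.decomposition import PCA as _SkPCA

from .errors import InsufficientDataError, SchemaError
from .io import RRSeries

__all__ = [
    "WaveletPacketFeatures",
    "PCAModel",
    "wp_features",
    "shannon_entropy",
    "fit_pca",
    "pca_project",
]


def shannon_entropy(coeffs: np.ndarray) -> float:
    """Shannon entropy of the normalized squared coefficients of a node."""
    c2 = np.asarray(coeffs, dtype=float) ** 2
    total = c2.sum()
    if total <= 0:
        return 0.0
    p = c2 / total
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


@dataclass
class WaveletPacketFeatures:
    """Per-node energies and entropies over a full packet tree."""

    node_ids: list[tuple[int, int]]  # (level, index within level)
    energies: np.ndarray
    entropies: np.ndarray
    coeff_counts: np.ndarray

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (lvl, idx), e in zip(self.node_ids, self.energies):
            out[f"wpE_L{lvl}N{idx}"] = float(e)
        for (lvl, idx), s in zip(self.node_ids, self.entropies):
            out[f"wpS_L{lvl}N{idx}"] = float(s)
        return out


def wp_features(
    rr: RRSeries,
    wavelet: str = "db4",
    level: int = 5,
) -> WaveletPacketFeatures:
    """Wavelet-packet energy/entropy features of the NN series.

    The input is the raw (un-resampled) interval series in beat-index
    domain, mean-subtracted.  Periodic extension keeps the transform
    orthogonal, so per-level energies sum to the signal energy.
    """
    x = rr.intervals
    if x.size < 2**level * 2:
        raise InsufficientDataError(
            f"need >= {2 ** level * 2} intervals for a level-{level} tree, "
            f"got {x.size}"
        )
    x = x - x.mean()
    wp = pywt.WaveletPacket(data=x, wavelet=wavelet, mode="periodization", maxlevel=level)
    node_ids: list[tuple[int, int]] = []
    energies: list[float] = []
    entropies: list[float] = []
    counts: list[int] = []
    for lvl in range(1, level + 1):
        for idx, node in enumerate(wp.get_level(lvl, order="natural")):
            c = np.asarray(node.data, dtype=float)
            node_ids.append((lvl, idx))
            energies.append(float(np.mean(c**2)))
            entropies.append(shannon_entropy(c))
            counts.append(c.size)
    return WaveletPacketFeatures(
        node_ids=node_ids,
        energies=np.asarray(energies),
        entropies=np.asarray(entropies),
        coeff_counts=np.asarray(counts),
    )


@dataclass
class PCAModel:
    """Centered principal-component model of a feature block."""

    components: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    feature_names: list[str]


def fit_pca(table: pd.DataFrame, n_components: int | None = None) -> PCAModel:
    """Fit PCA on a per-record feature block (records x features).

    Components are sorted by explained variance, with the sign fixed so
    each component's largest-magnitude loading is positive.
    """
    if table.shape[0] < 2:
        raise InsufficientDataError("PCA needs at least 2 records")
    if table.shape[1] < 1:
        raise SchemaError("PCA needs at least 1 feature")
    max_comp = min(table.shape)
    if n_components is not None and n_components > max_comp:
        warnings.warn(
            f"requested {n_components} components but only {max_comp} "
            "are available; truncating",
            stacklevel=2,
        )
        n_components = max_comp
    pca = _SkPCA(n_components=n_components, svd_solver="full")
    pca.fit(table.to_numpy(dtype=float))
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCAModel(
        components=comps,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        mean=pca.mean_.copy(),
        feature_names=list(table.columns),
    )


def pca_project(model: PCAModel, table: pd.DataFrame) -> pd.DataFrame:
    """Project a feature block onto the fitted components (columns PC_k)."""
    if list(table.columns) != model.feature_names:
        if set(table.columns) == set(model.feature_names):
            table = table[model.feature_names]
        else:
            raise SchemaError(
                "feature columns do not match the fitted PCA model"
            )
    centered = table.to_numpy(dtype=float) - model.mean
    proj = centered @ model.components.T
    cols = [f"PC_{k + 1}" for k in range(model.components.shape[0])]
    return pd.DataFrame(proj, index=table.index, columns=cols)
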