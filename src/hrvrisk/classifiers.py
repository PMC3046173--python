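"""Classification schemes and the evaluation protocol.

Three families discriminate normal (N) from cardiovascular-risk (R)
records on a handful of selected, MinMax-normalized HRV features:

* a three-layer perceptron (default 5-200-1: tanh hidden layer,
  logistic output) trained by Levenberg-Marquardt least squares;
* a radial-basis-function network (default 5-3-1): k-means centers,
  Gaussian widths set by each center's influence radius (distance to
  the nearest other center), linear output layer by least squares;
* soft-margin SVMs with linear, polynomial and RBF kernels; the
  "heuristic" hyper-parameter choice is a small grid scored by 3-fold
  cross-validation on the training split.

Evaluation uses a stratified 2/3-1/3 split and reports the confusion
matrix, Se/Sp/Pp/Np/Ac in percent, the ROC curve and its area.  The
risk class is the positive class throughout; the decision threshold is
0.5 on the continuous score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.svm import SVC

from .errors import ConfigurationError, LabelingError, ValidationError

__all__ = [
    "SplitPlan",
    "ClassifierReport",
    "MLPModel",
    "RBFModel",
    "SVMModel",
    "train_mlp",
    "train_rbf",
    "train_svm",
    "make_classifier",
    "evaluate",
    "roc_auc",
    "stratified_split",
    "cross_validate",
    "SCHEMES",
]

SCHEMES = ("mlp", "rbf", "svm-linear", "svm-poly", "svm-rbf")


@dataclass
class SplitPlan:
    """A single stratified train/test partition of record positions."""

    train_ids: np.ndarray
    test_ids: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_ids, self.test_ids).size:
            raise ValidationError("train and test sets overlap")


@dataclass
class ClassifierReport:
    TP: int
    FP: int
    TN: int
    FN: int
    Se: float
    Sp: float
    Pp: float
    Np: float
    Ac: float
    roc: list[tuple[float, float]] = field(default_factory=list)
    auc: float = float("nan")
    n_support_vectors: int | None = None

    def as_dict(self) -> dict:
        out = {
            "confusion": {"TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN},
            "Se": self.Se,
            "Sp": self.Sp,
            "Pp": self.Pp,
            "Np": self.Np,
            "Ac": self.Ac,
            "roc": [[float(f), float(t)] for f, t in self.roc],
            "auc": self.auc,
        }
        if self.n_support_vectors is not None:
            out["n_support_vectors"] = self.n_support_vectors
        return out


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(X)):
        raise ValidationError("features contain non-finite values")
    if np.unique(y).size < 2:
        raise LabelingError("training set contains a single class")
    return X, y


# ---------------------------------------------------------------------------
# multilayer perceptron trained by Levenberg-Marquardt
# ---------------------------------------------------------------------------


class MLPModel:
    """3-layer perceptron: tanh hidden units, logistic output in (0, 1)."""

    def __init__(self, W1: np.ndarray, b1: np.ndarray, w2: np.ndarray, b2: float):
        self.W1, self.b1, self.w2, self.b2 = W1, b1, w2, b2

    def scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        z = np.tanh(X @ self.W1.T + self.b1)
        a = z @ self.w2 + self.b2
        return 1.0 / (1.0 + np.exp(-a))

    def predict(self, X) -> np.ndarray:
        return (self.scores(X) >= 0.5).astype(int)


def _mlp_jacobian(X, W1, b1, w2, b2):
    """Network outputs and the Jacobian d y_i / d theta (row per sample)."""
    z = np.tanh(X @ W1.T + b1)  # (n, h)
    y = 1.0 / (1.0 + np.exp(-(z @ w2 + b2)))  # (n,)
    g = y * (1.0 - y)  # logistic derivative
    dz = 1.0 - z**2  # (n, h)
    n, h = z.shape
    d = X.shape[1]
    # parameter order: W1 (h*d), b1 (h), w2 (h), b2
    J = np.empty((n, h * d + 2 * h + 1))
    hidden = g[:, None] * w2[None, :] * dz  # (n, h): dy/d(pre-activation_j)
    J[:, : h * d] = (hidden[:, :, None] * X[:, None, :]).reshape(n, h * d)
    J[:, h * d : h * d + h] = hidden
    J[:, h * d + h : h * d + 2 * h] = g[:, None] * z
    J[:, -1] = g
    return y, J


def train_mlp(
    X,
    y,
    hidden: int = 200,
    seed: int = 0,
    max_iter: int = 200,
    val_fraction: float = 0.0,
    patience: int = 6,
) -> MLPModel:
    """Train the perceptron by Levenberg-Marquardt on squared error.

    The LM step uses the matrix-inversion identity
    ``(J'J + lam I)^{-1} J' e = J' (J J' + lam I)^{-1} e`` so the linear
    solve is in the sample dimension, which is tiny here.  With
    ``val_fraction > 0`` a held-out slice of the training data stops
    training after ``patience`` consecutive validation-error rises.
    """
    X, y = _as_xy(X, y)
    if hidden < 1:
        raise ConfigurationError("hidden must be >= 1")
    rng = np.random.default_rng(seed)
    n, d = X.shape

    val_X = val_y = None
    if val_fraction > 0:
        n_val = max(1, int(round(val_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        val_X, val_y = X[val_idx], y[val_idx]
        X, y = X[tr_idx], y[tr_idx]
        n = X.shape[0]

    W1 = rng.normal(scale=1.0 / np.sqrt(d), size=(hidden, d))
    b1 = rng.normal(scale=0.1, size=hidden)
    w2 = rng.normal(scale=1.0 / np.sqrt(hidden), size=hidden)
    b2 = 0.0

    def unpack(theta):
        W1_ = theta[: hidden * d].reshape(hidden, d)
        b1_ = theta[hidden * d : hidden * d + hidden]
        w2_ = theta[hidden * d + hidden : hidden * d + 2 * hidden]
        return W1_, b1_, w2_, float(theta[-1])

    theta = np.concatenate([W1.ravel(), b1, w2, [b2]])
    lam = 1e-2
    out, J = _mlp_jacobian(X, *unpack(theta))
    err = out - y
    sse = float(err @ err)
    best_val = np.inf
    rises = 0
    for _ in range(max_iter):
        if sse < 1e-10 or lam > 1e10:
            break
        JJt = J @ J.T
        JJt[np.diag_indices_from(JJt)] += lam
        try:
            step = J.T @ np.linalg.solve(JJt, err)
        except np.linalg.LinAlgError:
            lam *= 10
            continue
        trial = theta - step
        out_t, J_t = _mlp_jacobian(X, *unpack(trial))
        err_t = out_t - y
        sse_t = float(err_t @ err_t)
        if sse_t < sse:
            theta, J, err, sse = trial, J_t, err_t, sse_t
            lam = max(lam / 10, 1e-12)
            if val_X is not None:
                model = MLPModel(*unpack(theta))
                val_err = float(np.mean((model.scores(val_X) - val_y) ** 2))
                if val_err > best_val:
                    rises += 1
                    if rises >= patience:
                        break
                else:
                    best_val = val_err
                    rises = 0
        else:
            lam *= 10
    return MLPModel(*unpack(theta))


# ---------------------------------------------------------------------------
# radial-basis-function network
# ---------------------------------------------------------------------------


class RBFModel:
    """Gaussian-hidden-layer network with a linear (least-squares) readout."""

    def __init__(self, centers: np.ndarray, widths: np.ndarray, weights: np.ndarray):
        self.centers, self.widths, self.weights = centers, widths, weights

    def _design(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        phi = np.exp(-d2 / (2.0 * self.widths**2))
        return np.column_stack([phi, np.ones(X.shape[0])])

    def scores(self, X) -> np.ndarray:
        return self._design(X) @ self.weights

    def predict(self, X) -> np.ndarray:
        return (self.scores(X) >= 0.5).astype(int)


def train_rbf(X, y, centers: int = 3, seed: int = 0) -> RBFModel:
    """Fit k-means centers, influence-radius widths, and a linear readout."""
    X, y = _as_xy(X, y)
    if centers < 1:
        raise ConfigurationError("centers must be >= 1")
    if centers > X.shape[0]:
        raise ConfigurationError("more centers than training records")
    km = KMeans(n_clusters=centers, n_init=10, random_state=seed)
    km.fit(X)
    C = km.cluster_centers_
    if centers == 1:
        widths = np.array([max(float(np.linalg.norm(X - C[0], axis=1).max()), 1e-6)])
    else:
        d = np.linalg.norm(C[:, None, :] - C[None, :, :], axis=2)
        d[np.diag_indices_from(d)] = np.inf
        widths = d.min(axis=1)
        widths[widths <= 0] = max(float(widths[widths > 0].min()) if np.any(widths > 0) else 1.0, 1e-6)
    model = RBFModel(centers=C, widths=widths, weights=np.zeros(centers + 1))
    phi = model._design(X)
    model.weights, *_ = np.linalg.lstsq(phi, y)
    return model


# ---------------------------------------------------------------------------
# support vector machines
# ---------------------------------------------------------------------------


class SVMModel:
    """Thin wrapper around a fitted soft-margin SVM."""

    def __init__(self, svc: SVC, params: dict):
        self.svc = svc
        self.params = params

    @property
    def n_support_vectors(self) -> int:
        return int(self.svc.n_support_.sum())

    def scores(self, X) -> np.ndarray:
        # shift the decision function so the common 0.5 threshold applies
        return self.svc.decision_function(np.asarray(X, dtype=float)) + 0.5

    def predict(self, X) -> np.ndarray:
        return (self.svc.decision_function(np.asarray(X, dtype=float)) >= 0).astype(int)


_SVM_GRID = {
    "linear": [{"C": 1.0}],  # fixed to the conventional default
    "poly": [
        {"C": c, "degree": deg}
        for c in (0.1, 1.0, 10.0, 100.0)
        for deg in (2, 3)
    ],
    "rbf": [
        {"C": c, "gamma": g}
        for c in (0.1, 1.0, 10.0, 100.0)
        for g in (0.01, 0.1, 1.0)
    ],
}


def _cv_accuracy(X, y, kernel, params, seed, folds=3) -> float:
    rng = np.random.default_rng(seed)
    idx = np.arange(X.shape[0])
    # stratified fold assignment
    fold_of = np.empty(idx.size, dtype=int)
    for cls in np.unique(y):
        members = rng.permutation(idx[y == cls])
        fold_of[members] = np.arange(members.size) % folds
    accs = []
    for f in range(folds):
        tr, te = fold_of != f, fold_of == f
        if np.unique(y[tr]).size < 2 or te.sum() == 0:
            continue
        svc = SVC(kernel=kernel, **params)
        svc.fit(X[tr], y[tr])
        accs.append(float(np.mean(svc.predict(X[te]) == y[te])))
    return float(np.mean(accs)) if accs else 0.0


def train_svm(
    X,
    y,
    kernel: str = "linear",
    C: float | None = None,
    seed: int = 0,
    **kernel_params,
) -> SVMModel:
    """Train a soft-margin SVM; unspecified hyper-parameters come from a
    small grid scored by 3-fold CV on the training split."""
    X, y = _as_xy(X, y)
    if kernel not in ("linear", "poly", "rbf"):
        raise ConfigurationError(f"unknown kernel {kernel!r}")
    if C is not None and C <= 0:
        raise ConfigurationError("C must be positive")
    if C is not None or kernel_params:
        params = dict(kernel_params)
        params["C"] = C if C is not None else 1.0
    else:
        grid = _SVM_GRID[kernel]
        scored = [(_cv_accuracy(X, y, kernel, p, seed), -i, p) for i, p in enumerate(grid)]
        params = max(scored)[2]
    svc = SVC(kernel=kernel, tol=1e-3, **params)
    svc.fit(X, y.astype(int))
    return SVMModel(svc=svc, params=params)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den else float("nan")


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) from a threshold sweep and the trapezoid AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise LabelingError("both classes must be present for a ROC curve")
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    points = []
    for th in thresholds:
        pred = scores >= th
        tpr = (pred & (labels == 1)).sum() / n_pos
        fpr = (pred & (labels == 0)).sum() / n_neg
        points.append((float(fpr), float(tpr)))
    pts = np.array(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return [tuple(p) for p in points], auc


def report_from_confusion(
    tp: int, fp: int, tn: int, fn: int,
    roc: list[tuple[float, float]] | None = None,
    auc: float = float("nan"),
    n_support_vectors: int | None = None,
) -> ClassifierReport:
    """Assemble the five performance metrics from a confusion matrix."""
    return ClassifierReport(
        TP=tp, FP=fp, TN=tn, FN=fn,
        Se=_pct(tp, tp + fn),
        Sp=_pct(tn, tn + fp),
        Pp=_pct(tp, tp + fp),
        Np=_pct(tn, tn + fn),
        Ac=_pct(tp + tn, tp + fp + tn + fn),
        roc=roc or [],
        auc=auc,
        n_support_vectors=n_support_vectors,
    )


def evaluate(model, X, y) -> ClassifierReport:
    """Score a fitted model on a labeled set (risk = positive class)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    pred = model.predict(X)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    scores = model.scores(X)
    if np.unique(y).size == 2:
        roc, auc = roc_auc(scores, y)
    else:
        roc, auc = [], float("nan")
    nsv = getattr(model, "n_support_vectors", None)
    return report_from_confusion(tp, fp, tn, fn, roc=roc, auc=auc, n_support_vectors=nsv)


def make_classifier(scheme: str, seed: int = 0, **params):
    """Return a ``fit(X, y) -> model`` callable for a named scheme."""
    if scheme == "mlp":
        return lambda X, y: train_mlp(X, y, seed=seed, **params)
    if scheme == "rbf":
        return lambda X, y: train_rbf(X, y, seed=seed, **params)
    if scheme.startswith("svm-"):
        kernel = {"svm-linear": "linear", "svm-poly": "poly", "svm-rbf": "rbf"}.get(scheme)
        if kernel is None:
            raise ConfigurationError(f"unknown scheme {scheme!r}")
        return lambda X, y: train_svm(X, y, kernel=kernel, seed=seed, **params)
    raise ConfigurationError(f"unknown scheme {scheme!r}")


def stratified_split(labels, train_frac: float = 2 / 3, seed: int = 0) -> SplitPlan:
    """Stratified random train/test partition (positions, not ids)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(labels):
        members = rng.permutation(np.nonzero(labels == cls)[0])
        if members.size < 2:
            raise LabelingError(f"class {cls!r} has fewer than 2 records")
        n_train = int(round(train_frac * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        train_idx.extend(members[:n_train])
        test_idx.extend(members[n_train:])
    return SplitPlan(
        train_ids=np.sort(np.array(train_idx)),
        test_ids=np.sort(np.array(test_idx)),
        seed=seed,
    )


def cross_validate(
    features: pd.DataFrame,
    labels,
    scheme: str = "mlp",
    seed: int = 0,
    repeats: int = 1,
    train_frac: float = 2 / 3,
    normalize: bool = True,
    **params,
) -> list[ClassifierReport]:
    """Repeated stratified 2/3-1/3 evaluation of one classifier scheme.

    Each repeat draws a fresh stratified split (seed + repeat index),
    fits MinMax bounds on the training side only, trains the scheme and
    scores the held-out third.  Returns one report per repeat.
    """
    from .selection import minmax_fit_apply

    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise LabelingError("cross-validation needs a two-class cohort")
    reports = []
    for rep in range(repeats):
        plan = stratified_split(y, train_frac=train_frac, seed=seed + rep)
        tr = features.iloc[plan.train_ids]
        te = features.iloc[plan.test_ids]
        y_tr = (y[plan.train_ids] == y.max()).astype(int) if y.dtype.kind in "OUS" else y[plan.train_ids]
        y_te = (y[plan.test_ids] == y.max()).astype(int) if y.dtype.kind in "OUS" else y[plan.test_ids]
        if normalize:
            (tr, te), _ = minmax_fit_apply(tr, te)
        fit = make_classifier(scheme, seed=seed + rep, **params)
        model = fit(tr.to_numpy(dtype=float), np.asarray(y_tr, dtype=float))
        reports.append(evaluate(model, te.to_numpy(dtype=float), y_te))
    return reports
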