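"""PCA exploration and the PLS-DA baseline classifier.

PCA here is the classical centered SVD with a deterministic sign
convention (each loading's largest-magnitude entry is positive) so score
plots are reproducible run to run.  PLS-DA wraps a NIPALS partial
least squares regression on one-hot class indicators; prediction is the
argmax of the fitted responses, ties resolved toward the lowest class
index.  Both operate on the samples x bands reflectance matrices produced
by the ingest and synthetic modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

__all__ = ["PCAResult", "PLSDA", "pca_fit", "pca_transform", "plsda_fit", "plsda_predict"]


@dataclass
class PCAResult:
    """Scores, orthonormal loadings and explained-variance ratios of a PCA fit."""

    scores: np.ndarray  # samples x k
    loadings: np.ndarray  # bands x k, orthonormal columns
    explained_ratio: np.ndarray  # length k, non-increasing
    cumulative_ratio: np.ndarray  # running sum, <= 1
    center: np.ndarray  # band means
    scaled: bool = False
    scale_: np.ndarray | None = None
    warnings_: list = field(default_factory=list)


def pca_fit(X: np.ndarray, k: int = 3, scale: bool = False) -> PCAResult:
    """Center (optionally unit-variance scale) and eigendecompose the covariance.

    Requesting more components than the data's rank truncates to the rank
    and records a warning instead of fabricating null directions.  Data
    with zero total variance is degenerate and rejected.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 samples")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    center = X.mean(axis=0)
    Xc = X - center
    scale_ = None
    if scale:
        scale_ = Xc.std(axis=0, ddof=1)
        scale_[scale_ == 0] = 1.0
        Xc = Xc / scale_
    total_var = float(np.sum(Xc**2))
    if total_var == 0.0:
        raise ValueError("degenerate data: zero total variance (all rows identical)")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(X.shape) * np.finfo(np.float64).eps
    rank = int(np.sum(s > tol))
    notes = []
    if k > rank:
        notes.append(f"requested k={k} exceeds rank {rank}; truncated")
        warnings.warn(notes[-1], RuntimeWarning, stacklevel=2)
        k = rank
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # sign convention: largest-|entry| of each loading is positive
    flip = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    scores = U * s[None, :]
    ratio = (s**2) / total_var
    return PCAResult(
        scores=scores,
        loadings=Vt.T,
        explained_ratio=ratio,
        cumulative_ratio=np.cumsum(ratio),
        center=center,
        scaled=scale,
        scale_=scale_,
        warnings_=notes,
    )


def pca_transform(result: PCAResult, Xnew: np.ndarray) -> np.ndarray:
    """Project new samples onto the fitted components."""
    Xc = np.asarray(Xnew, dtype=np.float64) - result.center
    if result.scaled:
        Xc = Xc / result.scale_
    return Xc @ result.loadings


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


@dataclass
class PLSDA:
    """Fitted PLS-DA: NIPALS latent variables regressed on one-hot classes."""

    pls: PLSRegression
    classes_: np.ndarray
    n_components: int

    @property
    def x_weights_(self) -> np.ndarray:
        return self.pls.x_weights_

    @property
    def coef_(self) -> np.ndarray:
        return self.pls.coef_


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    Y = np.zeros((y.size, classes.size))
    for i, c in enumerate(classes):
        Y[y == c, i] = 1.0
    return Y


def plsda_fit(
    X: np.ndarray,
    labels: np.ndarray,
    n_components: int | None = None,
    max_components: int = 10,
    cv_folds: int = 5,
    seed: int = 0,
) -> PLSDA:
    """Fit PLS-DA on one-hot responses.

    With ``n_components=None`` the component count is chosen by stratified
    cross-validated accuracy over 1..max_components (capped at the data's
    limit min(samples - 1, bands)).  A single-class training set is an
    error — there is nothing to discriminate.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError(f"PLS-DA needs >= 2 classes, got {classes.size}")
    cap = min(X.shape[0] - 1, X.shape[1])
    if n_components is None:
        best_k, best_acc = 1, -1.0
        counts = np.min(np.bincount(np.searchsorted(classes, labels)))
        folds = int(min(cv_folds, counts))
        if folds < 2:
            n_components = min(max_components, cap)
        else:
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            for k in range(1, min(max_components, cap) + 1):
                correct = 0
                for tr, te in skf.split(X, labels):
                    m = _fit_raw(X[tr], labels[tr], classes, k)
                    correct += int(np.sum(plsda_predict(m, X[te]) == labels[te]))
                acc = correct / X.shape[0]
                if acc > best_acc + 1e-12:
                    best_k, best_acc = k, acc
            n_components = best_k
    if not 1 <= n_components <= cap:
        raise ValueError(f"n_components {n_components} outside 1..{cap}")
    return _fit_raw(X, labels, classes, n_components)


def _fit_raw(X, labels, classes, k) -> PLSDA:
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(X, _one_hot(labels, classes))
    return PLSDA(pls=pls, classes_=classes, n_components=k)


def plsda_predict(model: PLSDA, Xnew: np.ndarray) -> np.ndarray:
    """Argmax of the fitted one-hot responses; ties break to the lowest class index."""
    scores = model.pls.predict(np.asarray(Xnew, dtype=np.float64))
    return model.classes_[np.argmax(scores, axis=1)]  # argmax takes first max on ties


def plsda_accuracy(model: PLSDA, X: np.ndarray, labels: np.ndarray) -> float:
    """Per cent correct predictions."""
    return 100.0 * float(np.mean(plsda_predict(model, X) == np.asarray(labels)))
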