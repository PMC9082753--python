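"""Common spatial patterns (CSP) for multichannel EEG epochs.

CSP finds spatial filters w maximizing the variance ratio between two
classes: the generalized eigenproblem ``S1 w = λ (S1 + S2) w`` on the
average per-class covariance matrices.  Filters from both ends of the
eigenvalue spectrum are kept (maximal variance for one class each), and the
log-variance of the filtered epoch is the feature.  The multi-class case is
handled one-vs-rest with concatenated per-class features.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin


def _trial_cov(x: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance of one epoch (C, T)."""
    c = x @ x.T
    return c / np.trace(c)


def _class_cov(epochs) -> np.ndarray:
    return np.mean([_trial_cov(np.asarray(e, dtype=float)) for e in epochs], axis=0)


def csp_filters(cov_a: np.ndarray, cov_b: np.ndarray, n_components: int,
                reg: float = 1e-10) -> tuple:
    """Solve the two-class CSP eigenproblem.

    Returns ``(filters, eigenvalues)`` where ``filters`` is
    ``(n_components, C)`` holding the ``n_components/2`` eigenvectors from
    each end of the spectrum (rows), and eigenvalues are those of
    ``S_a w = λ (S_a + S_b) w`` for the selected rows.  A rank-deficient
    composite covariance is ridge-regularized with a warning.
    """
    if n_components % 2 or n_components < 2:
        raise ValueError("n_components must be even and >= 2")
    c = cov_a.shape[0]
    if n_components > c:
        raise ValueError(f"n_components={n_components} exceeds {c} channels")
    composite = cov_a + cov_b
    cond = np.linalg.cond(composite)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("rank-deficient covariance; applying ridge regularization",
                      RuntimeWarning, stacklevel=2)
        composite = composite + reg * np.trace(composite) / c * np.eye(c)
    evals, evecs = linalg.eigh(cov_a, composite)
    order = np.argsort(evals)          # ascending
    k = n_components // 2
    sel = np.concatenate([order[-k:][::-1], order[:k]])  # top-k then bottom-k
    return evecs[:, sel].T, evals[sel]


class CSP(BaseEstimator, TransformerMixin):
    """One-vs-rest CSP feature extractor over a list of ``(C, T)`` epochs.

    ``transform`` emits, per class pair, the log-variance of the filtered
    epoch: ``log(var(w_i^T X))`` for each selected filter.  With two classes
    a single filter bank is fit; with k > 2 classes, k one-vs-rest banks are
    fit and their features concatenated.

    Attributes
    ----------
    filters_ : (n_banks, n_components, C) array after ``fit``.
    eigvals_ : (n_banks, n_components) array of selected eigenvalues.
    """

    def __init__(self, n_components: int = 4):
        self.n_components = n_components

    def fit(self, X, y):
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("CSP needs at least two classes")
        for cls in classes:
            if np.sum(y == cls) < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 trials")
        X = [np.asarray(x, dtype=float) for x in X]
        banks, eigs = [], []
        if classes.size == 2:
            pairs = [(classes[0], None)]
        else:
            pairs = [(cls, None) for cls in classes]
        for cls, _ in pairs:
            cov_a = _class_cov([x for x, lab in zip(X, y) if lab == cls])
            cov_b = _class_cov([x for x, lab in zip(X, y) if lab != cls])
            w, ev = csp_filters(cov_a, cov_b, self.n_components)
            banks.append(w)
            eigs.append(ev)
        self.classes_ = classes
        self.filters_ = np.stack(banks)
        self.eigvals_ = np.stack(eigs)
        return self

    def transform(self, X):
        feats = []
        for x in X:
            x = np.asarray(x, dtype=float)
            row = []
            for w in self.filters_:
                z = w @ x
                row.append(np.log(z.var(axis=1) + 1e-20))
            feats.append(np.concatenate(row))
        return np.asarray(feats)
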