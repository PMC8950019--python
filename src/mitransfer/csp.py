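"""Common spatial patterns (CSP) for two-class EEG.

CSP finds spatial filters w that maximize the variance of the projected
signal for one class while minimizing it for the other.  The classical
construction:

1. class mean covariances  C_y = mean_i (X_i X_i^T) / trace(X_i X_i^T),
2. composite covariance    C_c = C_1 + C_2 and its eigendecomposition
   C_c = U_c diag(l_c) U_c^T with eigenvalues sorted descending,
3. whitening               P = diag(l_c)^{-1/2} U_c^T  (so P C_c P^T = I),
4. whitened class covariances S_y = P C_y P^T share eigenvectors B with
   eigenvalue matrices summing to the identity,
5. projection matrix       W = B^T P, rows sorted by the class-1 eigenvalue
   descending; the first and last m rows are the most discriminative pair
   directions and are the ones kept.

Features are the log of each retained row's variance normalized by the sum
over retained rows, so exp of the feature vector sums to one.

Equivalently the filters solve the generalized eigenproblem
C_1 w = lambda (C_1 + C_2) w; the test suite cross-checks the whitening
construction against scipy's generalized eigensolver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .trials import CLASS1, CLASS2, Trial, TrialSet

__all__ = [
    "CSPDecomposition",
    "SpatialFilterBank",
    "class_mean_covariance",
    "fit_csp",
    "project",
    "extract_features",
    "featurize_trialset",
    "CSP",
]


@dataclass
class CSPDecomposition:
    """All intermediate matrices of one CSP fit (for inspection/testing)."""

    C1: np.ndarray
    C2: np.ndarray
    Cc: np.ndarray
    Uc: np.ndarray
    lambda_c: np.ndarray
    P: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    B: np.ndarray
    lambda1: np.ndarray
    lambda2: np.ndarray
    W_full: np.ndarray


@dataclass
class SpatialFilterBank:
    """Retained CSP filters: the first and last ``m_pairs`` rows of W."""

    W: np.ndarray  # (2*m_pairs, M)
    m_pairs: int
    eigvals_class1: np.ndarray  # class-1 eigenvalues of the retained rows
    n_channels: int


def _trace_normalized_cov(x: np.ndarray) -> np.ndarray:
    c = x @ x.T
    tr = np.trace(c)
    if tr <= 0:
        raise ValueError("trial has zero power; cannot trace-normalize")
    return c / tr


def class_mean_covariance(ts, label) -> np.ndarray:
    """Mean trace-normalized covariance over the trials of one class.

    ``ts`` may be a TrialSet (label = class tag) or an (n, M, N) array with a
    boolean/index mask supplied as ``label``.  The result has unit trace.
    """
    if isinstance(ts, TrialSet):
        data = [t.data for t in ts.trials if t.label == label]
        if not data:
            raise ValueError(f"no trials with label {label!r}")
    else:
        arr = np.asarray(ts, dtype=np.float64)
        data = [arr[i] for i in np.atleast_1d(label)]
        if not data:
            raise ValueError("empty class")
    out = np.zeros((data[0].shape[0],) * 2)
    for x in data:
        out += _trace_normalized_cov(x)
    return out / len(data)


def _csp_from_covariances(c1: np.ndarray, c2: np.ndarray, m_pairs: int,
                          eigen_floor_rel: float = 1e-12):
    m = c1.shape[0]
    if 2 * m_pairs > m:
        raise ValueError(f"2*m_pairs = {2 * m_pairs} exceeds {m} channels")
    cc = c1 + c2
    w_c, u_c = np.linalg.eigh(cc)
    # descending eigenvalue order
    order = np.argsort(w_c)[::-1]
    w_c, u_c = w_c[order], u_c[:, order]
    lam_max = w_c[0]
    if lam_max <= 0:
        raise np.linalg.LinAlgError("composite covariance not positive definite")
    floor = eigen_floor_rel * lam_max
    if (w_c < floor).any():
        w_c = np.maximum(w_c, floor)
    p = (u_c / np.sqrt(w_c)).T  # diag(w)^(-1/2) @ Uc.T
    s1 = p @ c1 @ p.T
    s2 = p @ c2 @ p.T
    w1, b = np.linalg.eigh(s1)
    order = np.argsort(-w1, kind="stable")  # descending; stable on ties
    w1, b = w1[order], b[:, order]
    w_full = b.T @ p
    lambda1 = np.diag(w1)
    lambda2 = np.eye(m) - lambda1
    dec = CSPDecomposition(
        C1=c1, C2=c2, Cc=cc, Uc=u_c, lambda_c=w_c, P=p, S1=s1, S2=s2,
        B=b, lambda1=lambda1, lambda2=lambda2, W_full=w_full,
    )
    keep = list(range(m_pairs)) + list(range(m - m_pairs, m))
    bank = SpatialFilterBank(
        W=w_full[keep], m_pairs=m_pairs,
        eigvals_class1=w1[keep], n_channels=m,
    )
    return bank, dec


def fit_csp(ts: TrialSet, m_pairs: int):
    """Fit CSP on a labeled TrialSet.

    Returns (SpatialFilterBank, CSPDecomposition).  Both classes must be
    present and ``2*m_pairs`` may not exceed the channel count.
    """
    labels = set(t.label for t in ts.trials)
    if CLASS1 not in labels or CLASS2 not in labels:
        raise ValueError(
            f"both classes required for CSP; found labels {sorted(labels)}"
        )
    c1 = class_mean_covariance(ts, CLASS1)
    c2 = class_mean_covariance(ts, CLASS2)
    return _csp_from_covariances(c1, c2, m_pairs)


def project(bank: SpatialFilterBank, t) -> np.ndarray:
    """Project a trial through the retained filters: Z = W X."""
    x = t.data if isinstance(t, Trial) else np.asarray(t, dtype=np.float64)
    if x.shape[0] != bank.n_channels:
        raise ValueError(
            f"bank fitted for {bank.n_channels} channels, trial has {x.shape[0]}"
        )
    return bank.W @ x


def extract_features(bank: SpatialFilterBank, t) -> np.ndarray:
    """Normalized log-variance features of one trial.

    x_r = log( var(Z_r) / sum_j var(Z_j) ) over the 2*m_pairs retained rows,
    with the population (1/N, mean-removed) variance.  By construction
    sum_r exp(x_r) = 1.
    """
    z = project(bank, t)
    v = z.var(axis=1)  # population variance, mean removed
    if (v <= 0).any():
        bad = int(np.argmin(v))
        raise FloatingPointError(
            f"projected row {bad} has zero variance; log-feature undefined"
        )
    return np.log(v / v.sum())


def featurize_trialset(bank: SpatialFilterBank, ts: TrialSet):
    """Feature table for a TrialSet: (n_trials, 2*m_pairs) plus label codes."""
    feats = np.empty((len(ts), 2 * bank.m_pairs))
    for i, t in enumerate(ts.trials):
        try:
            feats[i] = extract_features(bank, t)
        except Exception as exc:
            raise type(exc)(f"trial {i}: {exc}") from exc
    return feats, ts.labels


class CSP(TransformerMixin, BaseEstimator):
    """Scikit-learn CSP transformer on (n_trials, n_channels, n_samples).

    ``fit(X, y)`` expects binary labels (the two distinct values present);
    ``transform`` returns normalized log-variance features of shape
    (n_trials, 2 * m_pairs).

    Parameters
    ----------
    m_pairs : int, default 7
        Filter pairs retained (first and last rows of the sorted projection
        matrix).  Must satisfy 2*m_pairs <= n_channels.

    Attributes
    ----------
    filters_ : ndarray (2*m_pairs, M)
        Retained spatial filters (rows).
    decomposition_ : CSPDecomposition
        Full intermediate matrices of the fit.
    classes_ : ndarray
        The two class values, in sorted order (first maps to "class 1").
    """

    def __init__(self, m_pairs: int = 7):
        self.m_pairs = m_pairs

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("expected (n_trials, n_channels, n_samples)")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"CSP is two-class; got classes {classes}")
        c1 = class_mean_covariance(X, np.flatnonzero(y == classes[0]))
        c2 = class_mean_covariance(X, np.flatnonzero(y == classes[1]))
        bank, dec = _csp_from_covariances(c1, c2, self.m_pairs)
        self.classes_ = classes
        self.filters_ = bank.W
        self.eigvals_class1_ = bank.eigvals_class1
        self.decomposition_ = dec
        self.bank_ = bank
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "filters_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("expected (n_trials, n_channels, n_samples)")
        z = np.einsum("fm,imn->ifn", self.filters_, X)
        v = z.var(axis=2)
        if (v <= 0).any():
            raise FloatingPointError("a projected row has zero variance")
        return np.log(v / v.sum(axis=1, keepdims=True))
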