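"""Euclidean-space data alignment (EA).

Cross-subject EEG transfer suffers from domain shift: each subject's trials
occupy a differently oriented region of channel space.  EA removes the
second-order part of that shift by whitening every domain with the inverse
square root of its own mean trial covariance

    R = (1/n) sum_i X_i X_i^T,      X~_i = R^{-1/2} X_i,

after which the mean covariance of each domain's aligned trials is exactly
the identity, so all domains share the same average spatial distribution.
EA is unsupervised: it never reads labels, so it can be applied to an
unlabeled target subject.

The trial covariance here is the plain product ``X X^T`` with no 1/N or
trace normalization — EA is invariant to a global scalar on R, and this
form makes the identity property exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .trials import Trial, TrialSet

__all__ = [
    "AlignmentModel",
    "trial_covariance",
    "fit_alignment",
    "align",
    "EuclideanAlignment",
]


def trial_covariance(t) -> np.ndarray:
    """Spatial covariance of one trial: the exact product X @ X.T.

    Accepts a Trial or a bare (channels x samples) array.  Symmetric
    positive semidefinite by construction.
    """
    x = t.data if isinstance(t, Trial) else np.asarray(t, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("trial data contains non-finite values")
    return x @ x.T


def _inv_sqrt_psd(ref: np.ndarray, eigen_floor_rel: float):
    """Inverse symmetric square root with a relative eigenvalue floor.

    Returns (inv_sqrt, floor_applied).  Eigenvalues below
    eigen_floor_rel * lambda_max are raised to the floor, guarding against
    numerically singular references from small trial counts.
    """
    w, u = np.linalg.eigh(ref)
    lam_max = float(w[-1])
    if lam_max <= 0:
        raise np.linalg.LinAlgError(
            "reference covariance is not positive definite; provide more "
            "or richer trials"
        )
    floor = eigen_floor_rel * lam_max
    w_floored = np.maximum(w, floor)
    inv_sqrt = (u / np.sqrt(w_floored)) @ u.T
    return inv_sqrt, floor


@dataclass
class AlignmentModel:
    """Fitted alignment for one domain.

    ``reference`` is the mean trial covariance R; ``inv_sqrt`` its inverse
    symmetric square root R^{-1/2}; ``eigen_floor`` the smallest eigenvalue
    actually admitted.
    """

    reference: np.ndarray
    inv_sqrt: np.ndarray
    n_trials: int
    eigen_floor: float

    @property
    def n_channels(self) -> int:
        return self.reference.shape[0]


def fit_alignment(ts: TrialSet, eigen_floor_rel: float = 1e-10) -> AlignmentModel:
    """Fit the EA reference matrix on a domain's trials (labels ignored)."""
    if len(ts) == 0:
        raise ValueError("cannot fit alignment on an empty TrialSet")
    m = ts.n_channels
    total_samples = sum(t.n_samples for t in ts.trials)
    if total_samples <= m:
        raise ValueError(
            f"only {total_samples} samples across trials for {m} channels; "
            "the reference covariance would be singular"
        )
    ref = np.zeros((m, m))
    for t in ts.trials:
        ref += trial_covariance(t)
    ref /= len(ts)
    inv_sqrt, floor = _inv_sqrt_psd(ref, eigen_floor_rel)
    return AlignmentModel(
        reference=ref, inv_sqrt=inv_sqrt, n_trials=len(ts), eigen_floor=floor
    )


def align(ts: TrialSet, model: AlignmentModel) -> TrialSet:
    """Left-multiply every trial by R^{-1/2}; metadata unchanged.

    When ``model`` was fitted on ``ts`` itself, the mean covariance of the
    output is the identity matrix.
    """
    if len(ts) and ts.n_channels != model.n_channels:
        raise ValueError(
            f"model has {model.n_channels} channels, trials have {ts.n_channels}"
        )
    out = [replace(t, data=model.inv_sqrt @ t.data) for t in ts.trials]
    return replace(ts, trials=out)


def align_per_subject(ts: TrialSet, eigen_floor_rel: float = 1e-10) -> TrialSet:
    """Fit and apply a separate alignment model for each subject in ``ts``."""
    aligned = {}
    for sid in ts.subject_ids():
        sub = ts.for_subject(sid)
        model = fit_alignment(sub, eigen_floor_rel)
        aligned[sid] = iter(align(sub, model).trials)
    out = [next(aligned[t.subject]) for t in ts.trials]
    return replace(ts, trials=out)


class EuclideanAlignment(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer for EA whitening of trial arrays.

    Operates on 3D arrays (n_trials, n_channels, n_samples).  ``fit``
    estimates the domain reference covariance; ``transform`` whitens trials
    with it.  Fit and transform on the same array realizes the
    self-alignment identity (mean covariance of the output = I).

    Parameters
    ----------
    eigen_floor_rel : float, default 1e-10
        Relative eigenvalue floor applied when inverting the reference.

    Attributes
    ----------
    reference_ : ndarray (M, M)
        Mean trial covariance of the fitted domain.
    inv_sqrt_ : ndarray (M, M)
        Its inverse symmetric square root.
    eigen_floor_ : float
        Absolute eigenvalue floor applied.
    """

    def __init__(self, eigen_floor_rel: float = 1e-10):
        self.eigen_floor_rel = eigen_floor_rel

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("expected (n_trials, n_channels, n_samples)")
        n, m, _ = X.shape
        ref = np.einsum("ijk,ilk->jl", X, X) / n
        self.inv_sqrt_, self.eigen_floor_ = _inv_sqrt_psd(ref, self.eigen_floor_rel)
        self.reference_ = ref
        self.n_features_in_ = m
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("expected (n_trials, n_channels, n_samples)")
        if X.shape[1] != self.inv_sqrt_.shape[0]:
            raise ValueError(
                f"model fitted for {self.inv_sqrt_.shape[0]} channels, "
                f"got {X.shape[1]}"
            )
        return np.einsum("jl,ilk->ijk", self.inv_sqrt_, X)
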