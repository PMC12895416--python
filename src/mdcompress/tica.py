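"""Time-lagged independent component analysis (TICA) and a PCA baseline.

TICA solves the generalized eigenproblem C(tau) v = lambda C(0) v, where
C(0) is the instantaneous and C(tau) the (symmetrized) time-lagged
covariance of mean-free features.  Eigenvalues are autocorrelations of the
corresponding components; lambda close to 1 marks a slow process with
implied relaxation time t = -tau / ln(lambda).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .containers import FeatureMatrix

__all__ = [
    "CovariancePair",
    "estimate_covariances",
    "fit_tica",
    "project",
    "implied_timescale",
    "implied_timescales",
    "fit_pca",
    "TICA",
]


@dataclass
class CovariancePair:
    """Mean, instantaneous and symmetrized time-lagged covariances."""

    mean: np.ndarray
    c00: np.ndarray
    c0t: np.ndarray
    lag_frames: int
    n_pairs: int
    timestep_ns: float = 1.0

    @property
    def lag_ns(self) -> float:
        return self.lag_frames * self.timestep_ns


def _as_traj_list(data):
    if isinstance(data, FeatureMatrix):
        return [data.values], data.timestep_ns
    if isinstance(data, np.ndarray):
        return [data], 1.0
    if isinstance(data, (list, tuple)):
        out, ts = [], 1.0
        for item in data:
            if isinstance(item, FeatureMatrix):
                ts = item.timestep_ns
                out.append(item.values)
            else:
                out.append(np.asarray(item, dtype=np.float64))
        return out, ts
    raise TypeError(f"unsupported trajectory input {type(data)}")


def estimate_covariances(data, lag_frames: int,
                         timestep_ns: float | None = None) -> CovariancePair:
    """Pool time-lagged frame pairs across trajectories and form C00, C0t.

    Pairs (x_t, x_{t+tau}) never straddle trajectory boundaries.  The mean
    is taken over both members of every pair, C00 averages the covariance of
    the head and tail windows, and C0t is symmetrized as (C + C^T)/2 -- the
    standard symmetric (reversible-in-expectation) TICA estimator.
    """
    trajs, ts = _as_traj_list(data)
    if timestep_ns is not None:
        ts = timestep_ns
    if lag_frames < 1:
        raise ValueError("lag must be >= 1 frame")
    heads = [t[:-lag_frames] for t in trajs if t.shape[0] > lag_frames]
    tails = [t[lag_frames:] for t in trajs if t.shape[0] > lag_frames]
    if not heads:
        raise ValueError(
            f"no trajectory is longer than the lag ({lag_frames} frames)")
    X0 = np.concatenate(heads)
    Xt = np.concatenate(tails)
    n = X0.shape[0]
    mean = (X0.sum(axis=0) + Xt.sum(axis=0)) / (2.0 * n)
    X0c = X0 - mean
    Xtc = Xt - mean
    c00 = (X0c.T @ X0c + Xtc.T @ Xtc) / (2.0 * n)
    cross = X0c.T @ Xtc / n
    c0t = 0.5 * (cross + cross.T)
    return CovariancePair(mean, c00, c0t, lag_frames, n, ts)


@dataclass
class TICAModel:
    """Fitted TICA decomposition (eigenvalues descending)."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray        # (N, rank), C00-orthonormal columns
    mean: np.ndarray
    lag_frames: int
    epsilon: float
    timestep_ns: float = 1.0

    @property
    def rank(self) -> int:
        return self.eigenvectors.shape[1]

    def timescales(self) -> np.ndarray:
        """Implied timescales (ns) of all retained components."""
        tau = self.lag_frames * self.timestep_ns
        return implied_timescales(self.eigenvalues, tau)


def fit_tica(cov: CovariancePair, epsilon: float = 1e-6) -> TICAModel:
    """Solve C0t v = lambda C00 v by whitening with an eigenvalue floor.

    Directions whose C00 eigenvalue falls below ``epsilon`` times the
    largest are discarded (rank regularization); the problem is then an
    ordinary symmetric eigenproblem in the whitened basis.
    """
    s, V = scipy.linalg.eigh(cov.c00)
    floor = epsilon * s.max()
    if not np.any(s > floor):
        raise ValueError("C00 has no eigenvalue above the regularization "
                         f"floor {floor:.3g}; data may be constant")
    keep = s > floor
    L = V[:, keep] / np.sqrt(s[keep])
    A = L.T @ cov.c0t @ L
    w, U = scipy.linalg.eigh(0.5 * (A + A.T))
    order = np.argsort(w)[::-1]
    return TICAModel(w[order], L @ U[:, order], cov.mean, cov.lag_frames,
                     epsilon, cov.timestep_ns)


def project(model: TICAModel, data, k: int | None = None) -> np.ndarray:
    """Map mean-free data onto the top-k TICA eigenvectors."""
    trajs, _ = _as_traj_list(data)
    X = np.concatenate(trajs)
    k = model.rank if k is None else k
    if k > model.rank:
        raise ValueError(f"k={k} exceeds retained rank {model.rank}")
    return (X - model.mean) @ model.eigenvectors[:, :k]


def implied_timescale(lam: float, tau: float) -> float:
    """Relaxation time t = -tau / ln(lambda) in the units of tau.

    lambda >= 1 signals a non-decaying process (returns +inf); lambda <= 0
    has no real timescale (returns nan).
    """
    if lam >= 1.0:
        return np.inf
    if lam <= 0.0:
        return np.nan
    return -tau / np.log(lam)


def implied_timescales(lams, tau: float) -> np.ndarray:
    return np.array([implied_timescale(float(l), tau) for l in np.atleast_1d(lams)])


def fit_pca(data, k: int | None = None) -> PCA:
    """PCA baseline: top-k eigenvectors of the instantaneous covariance."""
    trajs, _ = _as_traj_list(data)
    X = np.concatenate(trajs)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    return PCA(n_components=k).fit(X)


class TICA(TransformerMixin, BaseEstimator):
    """scikit-learn style TICA transformer.

    Parameters
    ----------
    lag : int
        Lag time in frames for the time-lagged covariance.
    epsilon : float
        Relative eigenvalue floor for C00 regularization.
    dim : int or None
        Number of components ``transform`` returns (None = full rank).

    Attributes
    ----------
    eigenvalues_ : ndarray, descending autocorrelations of the components
    eigenvectors_ : ndarray (N, rank), C00-orthonormal
    mean_ : ndarray, feature mean over lagged pairs
    covariances_ : CovariancePair
    """

    def __init__(self, lag: int = 1, epsilon: float = 1e-6,
                 dim: int | None = None):
        self.lag = lag
        self.epsilon = epsilon
        self.dim = dim

    def fit(self, X, y=None):
        cov = estimate_covariances(X, self.lag)
        model = fit_tica(cov, self.epsilon)
        self.covariances_ = cov
        self.model_ = model
        self.eigenvalues_ = model.eigenvalues
        self.eigenvectors_ = model.eigenvectors
        self.mean_ = model.mean
        self.n_features_in_ = model.eigenvectors.shape[0]
        return self

    def transform(self, X):
        k = self.dim
        if k is not None:
            k = min(k, self.model_.rank)
        return project(self.model_, X, k)

    def timescales(self) -> np.ndarray:
        return self.model_.timescales()
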