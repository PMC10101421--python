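"""Core data types for Gaussian mixtures and exact density evaluation.

A Gaussian mixture model (GMM) with ``K`` components on ``R^d`` has density

    p(x | Theta) = sum_m alpha_m N(x | mu_m, Sigma_m),

where the mixing proportions ``alpha_m`` are positive and sum to one and
each component is a multivariate normal with mean ``mu_m`` and positive
definite covariance ``Sigma_m``.  This module holds the parameter container
(:class:`GMMParams`), the dataset container (:class:`LabeledDataset`) and
numerically careful density / log-likelihood evaluation.  All density work
goes through a Cholesky factorization of the covariance; positive
definiteness is *defined* operationally as "the symmetric factorization
succeeds", and matrices that fail it are reported to the caller rather than
silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import logsumexp

__all__ = [
    "GMMParams",
    "LabeledDataset",
    "NotPositiveDefiniteError",
    "cholesky_pd",
    "is_positive_definite",
    "component_density",
    "component_log_density",
    "mixture_density",
    "log_likelihood",
    "per_point_log_density",
]

_LOG_2PI = np.log(2.0 * np.pi)


class NotPositiveDefiniteError(ValueError):
    """Raised when a covariance matrix is not symmetric positive definite."""

    def __init__(self, message: str, matrix: np.ndarray | None = None,
                 component: int | None = None):
        super().__init__(message)
        self.matrix = matrix
        self.component = component


def cholesky_pd(cov: np.ndarray, *, component: int | None = None) -> np.ndarray:
    """Lower Cholesky factor of ``cov``, or raise :class:`NotPositiveDefiniteError`.

    Symmetry is checked explicitly (max absolute asymmetry below 1e-10
    relative to scale); positive definiteness is certified by the
    factorization itself.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"covariance must be a square matrix, got shape {cov.shape}")
    scale = max(1.0, float(np.abs(cov).max()))
    if np.abs(cov - cov.T).max() > 1e-10 * scale:
        raise NotPositiveDefiniteError(
            f"covariance matrix is not symmetric"
            + (f" (component {component})" if component is not None else ""),
            matrix=cov, component=component)
    try:
        return linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(
            "covariance matrix is not positive definite"
            + (f" (component {component})" if component is not None else "")
            + f": {exc}", matrix=cov, component=component) from exc


def is_positive_definite(cov: np.ndarray) -> bool:
    """True iff ``cov`` is symmetric and admits a Cholesky factorization."""
    try:
        cholesky_pd(cov)
    except (NotPositiveDefiniteError, ValueError):
        return False
    return True


@dataclass
class GMMParams:
    """Parameters of a K-component Gaussian mixture.

    Attributes
    ----------
    weights : (K,) array
        Mixing proportions; strictly positive, summing to one.
    means : (K, d) array
        Component mean vectors.
    covariances : (K, d, d) array
        Component covariance matrices, symmetric positive definite.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None, :, :]

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def validate(self) -> "GMMParams":
        """Check all invariants; return self or raise ``ValueError``."""
        K, d = self.K, self.d
        if K < 1 or d < 1:
            raise ValueError(f"need K >= 1 and d >= 1, got K={K}, d={d}")
        if self.weights.shape != (K,):
            raise ValueError(f"weights shape {self.weights.shape} != ({K},)")
        if self.covariances.shape != (K, d, d):
            raise ValueError(
                f"covariances shape {self.covariances.shape} != ({K}, {d}, {d})")
        if np.any(self.weights <= 0):
            raise ValueError("all mixing proportions must be strictly positive")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"mixing proportions sum to {self.weights.sum()!r}, not 1")
        for m in range(K):
            cholesky_pd(self.covariances[m], component=m)
        return self

    def copy(self) -> "GMMParams":
        return GMMParams(self.weights.copy(), self.means.copy(),
                         self.covariances.copy())

    def to_dict(self) -> dict:
        """JSON-serializable representation (nested lists)."""
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GMMParams":
        return cls(np.asarray(d["weights"]), np.asarray(d["means"]),
                   np.asarray(d["covariances"]))


@dataclass
class LabeledDataset:
    """An n x d feature matrix with optional integer class labels in 1..K."""

    X: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.n,):
                raise ValueError(
                    f"labels length {self.labels.shape} does not match n={self.n}")
        if self.n < 1:
            raise ValueError("dataset must contain at least one observation")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("dataset contains missing or non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path: str | Path, *, sep: str = ",") -> None:
        """Write one row per observation; optional final integer column ``label``."""
        df = pd.DataFrame(self.X, columns=[f"f{j}" for j in range(self.d)])
        if self.labels is not None:
            df["label"] = self.labels
        df.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, *, sep: str = ",") -> "LabeledDataset":
        """Read a delimited text file with a header row.

        A column named ``label`` (any position) is taken as the integer class
        labels; all remaining columns are features.
        """
        df = pd.read_csv(path, sep=sep)
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy(dtype=int)
        return cls(df.to_numpy(dtype=float), labels)


def component_log_density(X: np.ndarray, mean: np.ndarray,
                          cov: np.ndarray) -> np.ndarray:
    """Log density of N(mean, cov) at the rows of ``X``.

    Evaluated through the Cholesky factor L of the covariance:
    ``log N(x) = -d/2 log(2 pi) - sum(log diag L) - ||L^-1 (x - mu)||^2 / 2``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = np.asarray(mean, dtype=float).ravel()
    L = cholesky_pd(cov)
    dev = linalg.solve_triangular(L, (X - mean).T, lower=True)
    maha_sq = np.einsum("ij,ij->j", dev, dev)
    log_det_half = np.sum(np.log(np.diag(L)))
    return -0.5 * (X.shape[1] * _LOG_2PI + maha_sq) - log_det_half


def component_density(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float | np.ndarray:
    """Multivariate normal density at ``x`` (a point or an array of points)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim <= 1
    out = np.exp(component_log_density(x, mean, cov))
    return float(out[0]) if single else out


def per_point_log_density(X: np.ndarray, params: GMMParams) -> np.ndarray:
    """(n,) vector of log mixture densities, computed by log-sum-exp over
    ``log alpha_m + log N_m(x)`` so small densities do not underflow."""
    log_w = np.log(params.weights)
    comp = np.stack([component_log_density(X, params.means[m], params.covariances[m])
                     for m in range(params.K)], axis=1)
    return logsumexp(comp + log_w, axis=1)


def mixture_density(x: np.ndarray, params: GMMParams) -> float | np.ndarray:
    """Mixture density sum_m alpha_m N(x | mu_m, Sigma_m) at ``x``."""
    x = np.asarray(x, dtype=float)
    single = x.ndim <= 1
    out = np.exp(per_point_log_density(np.atleast_2d(x), params))
    return float(out[0]) if single else out


def log_likelihood(data: LabeledDataset | np.ndarray, params: GMMParams) -> float:
    """Total log-likelihood sum_i log p(x_i | Theta).

    Raises ``FloatingPointError`` naming the first offending observation if
    any per-point log density is non-finite (density exactly zero).
    """
    X = data.X if isinstance(data, LabeledDataset) else np.atleast_2d(data)
    lp = per_point_log_density(X, params)
    bad = ~np.isfinite(lp)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise FloatingPointError(
            f"log-likelihood is non-finite at observation {i} "
            "(mixture density underflowed to zero); consider regularizing "
            "the covariances")
    return float(lp.sum())
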