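"""EM iteration for Gaussian mixtures: E-step, M-step, convergence, fit loop.

The E-step computes responsibilities (posterior component memberships)

    h_m(x_i) = alpha_m N(x_i | mu_m, Sigma_m) / sum_j alpha_j N(x_i | theta_j),

the M-step re-estimates weights, means and covariances by responsibility-
weighted maximum likelihood, and the loop stops when the relative
improvement of the log-likelihood falls below a tolerance.  Responsibilities
are formed in log space (per-row log-sum-exp normalization), so strongly
separated components do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model import (GMMParams, LabeledDataset, NotPositiveDefiniteError,
                    component_log_density, is_positive_definite)

__all__ = ["EMResult", "e_step", "m_step", "has_converged", "run_em",
           "hard_assignment", "default_cov_floor"]

DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = 1000


@dataclass
class EMResult:
    """Outcome of an EM fit.

    ``loglik_trace[0]`` is the log-likelihood of the initial parameters;
    entry ``s`` is the log-likelihood after iteration ``s``.  The trace is
    non-decreasing up to floating-point slack (EM ascent property).
    """

    params: GMMParams
    loglik_trace: list[float]
    n_iter: int
    converged: bool

    @property
    def final_loglik(self) -> float:
        return self.loglik_trace[-1]

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "loglik_trace": [float(v) for v in self.loglik_trace],
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


def _log_resp(X: np.ndarray, params: GMMParams) -> tuple[np.ndarray, np.ndarray]:
    """(n,K) log responsibilities and (n,) per-point log mixture density."""
    log_w = np.log(params.weights)
    comp = np.stack([component_log_density(X, params.means[m], params.covariances[m])
                     for m in range(params.K)], axis=1) + log_w
    norm = logsumexp(comp, axis=1)
    return comp - norm[:, None], norm


def e_step(data: LabeledDataset | np.ndarray, params: GMMParams) -> np.ndarray:
    """Posterior responsibilities, an (n, K) row-stochastic matrix."""
    X = data.X if isinstance(data, LabeledDataset) else np.atleast_2d(data)
    log_r, norm = _log_resp(X, params)
    if not np.all(np.isfinite(norm)):
        i = int(np.flatnonzero(~np.isfinite(norm))[0])
        raise FloatingPointError(
            f"all component densities underflowed at observation {i}; "
            "consider regularizing the covariances")
    return np.exp(log_r)


def m_step(data: LabeledDataset | np.ndarray, resp: np.ndarray, *,
           check_pd: bool = True) -> GMMParams:
    """Responsibility-weighted ML update of weights, means and covariances.

    With hard 0/1 responsibilities this reduces to per-cluster sample means,
    per-cluster MLE covariances and weights equal to cluster fractions.
    ``check_pd=False`` skips the positive-definiteness validation (callers
    that repair degenerate covariances themselves, e.g. :func:`run_em`).
    """
    X = data.X if isinstance(data, LabeledDataset) else np.atleast_2d(data)
    resp = np.asarray(resp, dtype=float)
    n, d = X.shape
    if resp.shape[0] != n:
        raise ValueError("responsibility matrix does not match data length")
    nk = resp.sum(axis=0)
    empty = np.flatnonzero(nk <= 0)
    if empty.size:
        raise ValueError(f"component {int(empty[0]) + 1} has zero total "
                         "responsibility (empty component)")
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    K = resp.shape[1]
    covs = np.empty((K, d, d))
    for m in range(K):
        dev = X - means[m]
        covs[m] = (resp[:, m, None] * dev).T @ dev / nk[m]
        covs[m] = 0.5 * (covs[m] + covs[m].T)
    params = GMMParams(weights, means, covs)
    if check_pd:
        for m in range(K):
            if not is_positive_definite(covs[m]):
                raise NotPositiveDefiniteError(
                    f"M-step produced a non-positive-definite covariance for "
                    f"component {m + 1}", matrix=covs[m], component=m)
    return params


def has_converged(loglik_prev: float, loglik_curr: float,
                  tol: float = DEFAULT_TOL) -> bool:
    """Relative-improvement stopping rule |L_s - L_{s-1}| / |L_{s-1}| < tol.

    The absolute value in the denominator keeps the statistic meaningful
    when log-likelihoods are negative.  A zero previous value degenerates to
    comparing |L_s| with the tolerance.
    """
    if not (np.isfinite(loglik_prev) and np.isfinite(loglik_curr)):
        raise ValueError("log-likelihood values must be finite")
    if loglik_prev == 0.0:
        return abs(loglik_curr) < tol
    return abs(loglik_curr - loglik_prev) / abs(loglik_prev) < tol


def default_cov_floor(X: np.ndarray) -> float:
    """Ridge magnitude for degenerate covariances: 1e-6 x mean feature variance."""
    return 1e-6 * float(np.var(X, axis=0).mean())


def _repair(cov: np.ndarray, floor: float) -> np.ndarray:
    """Add a ridge ``floor * I`` (escalating) until the matrix is PD."""
    d = cov.shape[0]
    ridge = max(floor, np.finfo(float).tiny)
    for _ in range(12):
        candidate = cov + ridge * np.eye(d)
        if is_positive_definite(candidate):
            return candidate
        ridge *= 10.0
    raise NotPositiveDefiniteError(
        "covariance could not be repaired by a diagonal ridge", matrix=cov)


def run_em(data: LabeledDataset | np.ndarray, init: GMMParams, *,
           tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
           cov_floor: float | None = None) -> EMResult:
    """Fit a GMM by EM from the initial parameters ``init``.

    Alternates E and M steps, recording the log-likelihood each iteration,
    until the relative improvement drops below ``tol`` or ``max_iter``
    iterations have run.  A diagonal ridge ``cov_floor * I`` (default 1e-6 x
    the mean per-feature variance of the data) is added to every M-step
    covariance: applied uniformly it bounds the likelihood away from the
    degenerate spikes of collapsing components while perturbing healthy
    covariances negligibly, and keeps the iteration map consistent across
    iterations.  A covariance that is still not positive definite after the
    ridge is repaired by escalation; an unrepairable one raises with the
    iteration number.
    """
    X = data.X if isinstance(data, LabeledDataset) else np.atleast_2d(data)
    init.validate()
    if init.d != X.shape[1]:
        raise ValueError(f"init dimension {init.d} != data dimension {X.shape[1]}")
    if cov_floor is None:
        cov_floor = default_cov_floor(X)

    params = init.copy()
    log_r, norm = _log_resp(X, params)
    trace = [float(norm.sum())]
    converged = False
    n_iter = 0
    for s in range(1, max_iter + 1):
        resp = np.exp(log_r)
        try:
            params = m_step(X, resp, check_pd=False)
        except ValueError as exc:
            raise RuntimeError(f"EM failed at iteration {s}: {exc}") from exc
        params.covariances += cov_floor * np.eye(X.shape[1])
        for m in range(params.K):
            if not is_positive_definite(params.covariances[m]):
                try:
                    params.covariances[m] = _repair(params.covariances[m], cov_floor)
                except NotPositiveDefiniteError as exc:
                    raise RuntimeError(
                        f"degenerate covariance for component {m + 1} at "
                        f"iteration {s}, not repairable by ridge") from exc
        log_r, norm = _log_resp(X, params)
        trace.append(float(norm.sum()))
        n_iter = s
        if has_converged(trace[-2], trace[-1], tol):
            converged = True
            break
    return EMResult(params=params, loglik_trace=trace, n_iter=n_iter,
                    converged=converged)


def hard_assignment(data: LabeledDataset | np.ndarray, params: GMMParams) -> np.ndarray:
    """Maximum-responsibility labels in 1..K for each observation."""
    X = data.X if isinstance(data, LabeledDataset) else np.atleast_2d(data)
    log_r, _ = _log_resp(X, params)
    return np.argmax(log_r, axis=1) + 1
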