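"""Comparator initializers: emEM (short-EM restarts) and RndEM.

Both draw random starting points — component means sampled uniformly
without replacement from the data, the global MLE covariance for every
component, uniform weights — and keep the candidate with the highest
log-likelihood.  emEM refines each candidate with a short, laxly converged
EM run before scoring; RndEM scores the raw starts without any EM
iterations (equivalently, emEM with a zero short-EM budget).
"""

from __future__ import annotations

import numpy as np

from .em import hard_assignment, run_em
from .initialize import InitResult, global_mle, spherical_fallback
from .model import GMMParams, LabeledDataset, is_positive_definite, log_likelihood

__all__ = ["random_start", "emem_init", "rndem_init"]


def random_start(data: LabeledDataset | np.ndarray, K: int,
                 rng_seed: int = 0) -> GMMParams:
    """Random starting parameters: K distinct data points as means, the
    global MLE covariance (spherically repaired if degenerate) for every
    component, uniform weights."""
    X = data.X if isinstance(data, LabeledDataset) else np.atleast_2d(data)
    n, d = X.shape
    if K > n:
        raise ValueError(f"cannot draw K={K} distinct means from n={n} points")
    rng = np.random.default_rng(rng_seed)
    means = X[rng.choice(n, size=K, replace=False)]
    _, cov = global_mle(X)
    if not is_positive_definite(cov):
        cov = spherical_fallback(X, X.mean(axis=0),
                                 var_floor=1e-6 * float(np.var(X, axis=0).mean()))
    covs = np.repeat(cov[None, :, :], K, axis=0)
    return GMMParams(np.full(K, 1.0 / K), means, covs)


def _to_result(data, params: GMMParams, score: float, seed: int,
               vectors: np.ndarray) -> InitResult:
    return InitResult(params=params, partition=hard_assignment(data, params),
                      partition_vectors=vectors, selection_score=float(score),
                      seed=int(seed), criterion="loglik")


def emem_init(data: LabeledDataset | np.ndarray, K: int, *,
              n_starts: int = 10, short_tol: float = 1e-2,
              short_max_iter: int = 20, rng_seed: int = 0) -> InitResult:
    """emEM: short EM from ``n_starts`` random starts, best by log-likelihood.

    Each candidate runs EM with the lax tolerance ``short_tol`` for at most
    ``short_max_iter`` iterations; the candidate with the highest short-run
    final log-likelihood is returned (for the caller's long EM run).  With
    ``short_max_iter=0`` this reduces exactly to :func:`rndem_init`.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be a positive integer")
    best: InitResult | None = None
    failures: list[str] = []
    for j in range(n_starts):
        seed = int(rng_seed) + j
        start = random_start(data, K, rng_seed=seed)
        try:
            if short_max_iter > 0:
                res = run_em(data, start, tol=short_tol, max_iter=short_max_iter)
                params, score = res.params, res.final_loglik
            else:
                params, score = start, log_likelihood(data, start)
        except (RuntimeError, FloatingPointError) as exc:
            failures.append(f"start {j}: {exc}")
            continue
        if best is None or score > best.selection_score:
            best = _to_result(data, params, score, seed, start.means)
    if best is None:
        raise RuntimeError("every short-EM candidate degenerated: "
                           + "; ".join(failures))
    return best


def rndem_init(data: LabeledDataset | np.ndarray, K: int, *,
               n_starts: int = 10, rng_seed: int = 0) -> InitResult:
    """RndEM: score ``n_starts`` random starts by their log-likelihood
    without any EM iterations and return the best."""
    return emem_init(data, K, n_starts=n_starts, short_max_iter=0,
                     rng_seed=rng_seed)
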