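"""Clustering evaluation: adjusted Rand index, var* and replicate summaries.

The adjusted Rand index (ARI) of Hubert and Arabie is the chance-corrected
pair-counting agreement between two partitions of the same n objects: 1 for
identical partitions, about 0 for independent ones, negative for systematic
disagreement.  ``var*`` is the variance of replicate ARI values magnified
by 1000, a convenience scale since ARI variances over replicate benchmark
datasets are otherwise hard to read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RunSummary", "adjusted_rand_index", "var_star", "summarize_runs"]


def adjusted_rand_index(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Hubert-Arabie adjusted Rand index of two labelings.

    Computed from the contingency table of the two partitions:

        ARI = (sum_ij C(n_ij,2) - E) / (0.5 [sum_i C(a_i,2) + sum_j C(b_j,2)] - E)

    with E = sum_i C(a_i,2) sum_j C(b_j,2) / C(n,2).  Invariant under
    relabeling of either partition.  When the adjustment denominator is zero
    (both partitions all singletons or both a single cluster) the index is 1
    if the partitions agree and 0 otherwise.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    n = a.size
    if n < 2:
        raise ValueError("ARI needs at least two objects")

    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    table = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)

    def comb2(x: np.ndarray) -> np.ndarray:
        x = x.astype(np.float64)
        return x * (x - 1.0) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = n * (n - 1.0) / 2.0
    expected = sum_a * sum_b / total
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0.0:
        return 1.0 if np.array_equal(_canon(ai), _canon(bi)) else 0.0
    return float((sum_ij - expected) / denom)


def _canon(labels: np.ndarray) -> np.ndarray:
    """Relabel by order of first occurrence, so partitions compare as set
    partitions rather than as raw label vectors."""
    seen: dict = {}
    return np.array([seen.setdefault(v, len(seen)) for v in labels])


def var_star(values: np.ndarray) -> float:
    """Population variance (divisor n) of replicate values, scaled by 1000."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("var* needs at least two values")
    return float(np.var(values) * 1000.0)


@dataclass
class RunSummary:
    """Replicate-level summary: means and third quartiles of ARI and
    log-likelihood, plus var* of the ARI values (None for a single run)."""

    ari_mean: float
    loglik_mean: float
    ari_q3: float
    loglik_q3: float
    var_star: float | None
    n_runs: int

    def to_dict(self) -> dict:
        return {
            "ari_mean": self.ari_mean,
            "loglik_mean": self.loglik_mean,
            "ari_q3": self.ari_q3,
            "loglik_q3": self.loglik_q3,
            "var_star": self.var_star,
            "n_runs": self.n_runs,
        }


def summarize_runs(aris: np.ndarray, logliks: np.ndarray) -> RunSummary:
    """Means and third quartiles over replicate runs; var* of the ARI list.

    Third quartiles use linear interpolation between order statistics.
    """
    aris = np.asarray(aris, dtype=float).ravel()
    logliks = np.asarray(logliks, dtype=float).ravel()
    if aris.size == 0 or aris.size != logliks.size:
        raise ValueError("need equal-length nonempty ARI and log-likelihood lists")
    return RunSummary(
        ari_mean=float(aris.mean()),
        loglik_mean=float(logliks.mean()),
        ari_q3=float(np.quantile(aris, 0.75)),
        loglik_q3=float(np.quantile(logliks, 0.75)),
        var_star=var_star(aris) if aris.size >= 2 else None,
        n_runs=int(aris.size),
    )
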