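# mripem — iterative max–min initialization for Gaussian mixture EM

Model-based clustering with Gaussian mixture models (GMMs) estimates the
parameters Θ = {α_m, μ_m, Σ_m} of the density

    p(x | Θ) = Σ_{m=1}^{K} α_m N(x | μ_m, Σ_m)

by the EM algorithm.  EM climbs the likelihood monotonically but only to a
local optimum, so the starting point decides the quality of the fit — with
many components, random starts routinely seed two components inside one
cluster and none in another, and EM cannot recover.

This package implements **MRIPEM**, an iterative initialization that builds
the K components one at a time: it starts from the global MLE mean and
covariance of the whole sample, and at each stage draws a small pool of `t`
candidate points, picks the candidate whose minimal squared Mahalanobis
distance to the current component means is largest (a max–min rule that
pushes seeds apart), hard-partitions the sample around the enlarged set of
partition vectors by Euclidean distance, and re-estimates all current
components (with a trace-matching spherical covariance σ²I as the fallback
for degenerate cluster scatters).  The construction is repeated `r` times
and the best run is kept — by adjusted Rand index (ARI) against known
labels in benchmark settings, by log-likelihood otherwise.  Default rules:
`t = K` for K < 5, `t = 5` otherwise; `r = 10`.

Alongside the initializer the package ships everything needed to evaluate
it:

- `mripem.model` — GMM parameter/dataset containers, Cholesky-based density
  and log-likelihood evaluation, CSV I/O;
- `mripem.em` — vectorized EM (log-space E-step, relative-improvement
  stopping rule |ΔlogL|/|logL| < 1e-5);
- `mripem.initialize` — the max–min iterative initializer;
- `mripem.baselines` — the emEM (short-EM restarts) and RndEM (scored raw
  random starts) comparison initializers;
- `mripem.simulate` — a MixSim-style generator of Gaussian mixtures with
  prespecified average (ω̄) and maximum (ω̆) pairwise overlap, the standard
  way to control clustering difficulty in simulation studies;
- `mripem.metrics` — adjusted Rand index (Hubert–Arabie), var\* (ARI
  variance × 1000), replicate summaries;
- `mripem.bench` — the benchmark harness (overlap grid × methods,
  t/r sensitivity scans, user-supplied CSV datasets) and `mripem.cli` — a
  `mripem` command with subcommands `simulate`, `init`, `fit`,
  `bench-table`, `bench-t`, `bench-r`, `real`.

## Worked example

Generate a 2-d mixture of K = 10 components at low overlap, then fit it
with the max–min initializer and with a random-start baseline:

```python
import numpy as np
from mripem import (OverlapSpec, generate_mixture, sample_mixture,
                    mripem_init, rndem_init, run_em, hard_assignment,
                    adjusted_rand_index)

spec = OverlapSpec(omega_bar=1e-3, omega_max=0.04, K=10, p=2)
draw = generate_mixture(spec, rng_seed=4)
data = sample_mixture(draw.params, n_per_component=200, rng_seed=5)
print(f"achieved overlaps: omega_bar={draw.achieved_omega_bar:.4g}, "
      f"omega_max={draw.achieved_omega_max:.4g}")

for name, init in [("max-min", mripem_init(data, 10, rng_seed=0)),
                   ("RndEM  ", rndem_init(data, 10, rng_seed=0))]:
    fit = run_em(data, init.params)
    ari = adjusted_rand_index(data.labels, hard_assignment(data, fit.params))
    print(f"{name}: ARI {ari:.4f}  logL {fit.final_loglik:.2f} "
          f"({fit.n_iter} EM iterations)")
```

Output:

```
achieved overlaps: omega_bar=0.001056, omega_max=0.0408
max-min: ARI 0.9912  logL 6717.60 (6 EM iterations)
RndEM  : ARI 0.8879  logL 6265.09 (59 EM iterations)
```

The generator reports the overlap it actually realized next to the
targets; the ARI line shows the initialization gap that motivates the
method — from the max–min start EM recovers essentially the true
partition, while the best of ten random starts leaves clusters merged.

The same comparison from the shell:

```sh
mripem simulate --k 10 --p 2 --omega-bar 1e-3 --omega-max 0.04 \
    --n-per-component 200 --seed 4 --out mix.csv
mripem fit mix.csv --k 10 --method mripem --seed 0
mripem bench-table --preset benchmark-tables-fast --seed 1 --out-dir results/
```

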