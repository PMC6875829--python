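# chronomix

Modeling, clustering and integration of **longitudinal microbiome and
multi-omics data**.

Time-course studies of microbial communities — an infant gut sampled over
the first months of life, a bioreactor monitored through a degradation
cycle — produce several feature tables (OTU counts, metabolite
intensities, performance measures) observed on the same biological
material at few, possibly unmatched, time points, with substantial
between-replicate variability. `chronomix` provides a complete pipeline
for asking: *which features, within and across omics layers, follow the
same temporal trajectory?*

## Method overview

1. **Compositional preprocessing.** Count tables are filtered (features
   must exceed 0.01% relative abundance in at least one sample), then
   transformed with the centered log-ratio
   `clr(x)_i = log(x_i / G(x))`, where `G(x)` is the sample geometric
   mean. Total-sum scaling is also available.
2. **Mixed-model spline fitting (LMMS).** Each feature's trajectory is
   fitted across biological replicates by four serially nested models:
   a straight line, a penalized spline `f(t) = b0 + b1 t + sum_k u_k B_k(t)`
   with random spline coefficients `u_k ~ N(0, s2_u)` estimated by REML,
   then subject-specific random intercepts and random slopes. A more
   complex model is retained only when its new variance component is
   materially nonzero. The fitted population curves are interpolated onto
   a shared grid, collapsing an `N x P x T` study into a `T x P` matrix.
3. **Profile filtering.** Straight-line fits with heteroscedastic
   residuals (Breusch–Pagan test) or with MSE above the worst spline-fit
   MSE are treated as noise and removed.
4. **Clustering.** PCA or sparse PCA on the modeled matrix; each feature
   joins the component carrying its largest (or only nonzero) loading and
   is sub-clustered by loading sign, giving up to `2H` clusters. The
   number of components and the number of features kept per component
   (keepX) are tuned with the average silhouette under the Spearman
   distance `d = 1 - rho`.
5. **Integration.** Multi-block sparse PLS (sparse generalized CCA)
   maximizes `sum_{q != j} c_qj cov(X^(q) a^(q), X^(j) a^(j))` across
   blocks sharing the time grid, with soft-thresholded loadings and a
   design matrix `C` declaring which blocks should covary.
6. **Proportionality validation.** Within each cluster, the
   composition-safe distance `phi_s(x, y) = var(x - y) / var(x + y)` on
   log-scale profiles is compared within versus outside the cluster
   (Wilcoxon rank-sum), flagging potentially spurious associations.
7. **Simulation benchmark.** Twenty reference profiles in four clusters
   on nine time points, five simulated individuals each, Gaussian noise
   over sigma in {0, ..., 3}: clustering accuracy is measured with and
   without spline modeling, and with 0–4 missing time points.

## Worked example

```python
import numpy as np
from chronomix import (
    SimulationConfig, make_reference_profiles, simulate_dataset,
    run_benchmark,
)

cfg = SimulationConfig(sigma_grid=(0.0, 0.5, 3.0), n_datasets=10, seed=1)
res = run_benchmark(cfg)
print(res.summary[["sigma", "arm", "mean_accuracy", "mean_rand"]])
```

prints

```
   sigma   arm  mean_accuracy  mean_rand
0    0.0  lmms          1.000   1.000000
1    0.5  lmms          0.995   0.991053
2    3.0  lmms          0.820   0.704737
```

Without noise the spline-then-PCA pipeline recovers the four reference
clusters perfectly; accuracy degrades gracefully as the per-observation
noise grows to three times the profile standard deviation, and the
mixed-model fit across five individuals acts as a denoiser relative to
clustering raw single profiles.

The same stages are scriptable from the shell:

```bash
chronomix preprocess --counts counts.tsv --meta meta.tsv --out clr.tsv
chronomix model --input clr.tsv --meta meta.tsv \
    --out-fits fits.json --out-matrix modeled.tsv
chronomix filter --fits fits.json --out-report report.tsv
chronomix cluster --matrix modeled.tsv --h-max 2 \
    --out-assignments assign.tsv
chronomix proportionality --matrix modeled.tsv --assignments assign.tsv \
    --out-prefix prop
chronomix integrate --blocks otus.tsv --blocks metabolites.tsv \
    --h 2 --out-prefix integrated
```

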