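# Methods

This note documents the statistical machinery implemented in `chronomix`,
the defaults it ships with, and the boundaries of what its tests
demonstrate.

## Compositional preprocessing

Sequencing counts are relative: only ratios carry information. The
pipeline therefore works on centered log-ratio (CLR) values,
`clr(x)_i = ln(x_i + c) - mean_j ln(x_j + c)`, computed per sample with a
pseudo-count `c` (default 1) added to the raw counts so zeros are
representable. CLR is invariant to sample-wise rescaling, so total-sum
scaling before CLR is unnecessary (it is exposed separately for users who
want proportions). The low-count filter keeps features whose within-sample
proportion strictly exceeds a threshold (default 1e-4, i.e. 0.01%) in at
least one sample; the strict inequality is deliberate and tested at the
boundary. Natural logarithms are used throughout — the base cancels in
correlations but must be fixed for proportionality distances to be
reproducible.

## Linear mixed-model splines

Each feature is fitted serially with four nested models across replicates
(subjects):

1. straight line by OLS;
2. penalized spline: fixed line plus truncated basis functions whose
   coefficients are iid random effects, `u_k ~ N(0, s2_u)`;
3. model 2 plus subject random intercepts `a_i ~ N(0, s2_a)`;
4. model 3 plus subject random slopes `b_i ~ N(0, s2_b)` (independent of
   the intercepts).

Bases: `cubic_all_inner_knots` places a truncated cubic `(t - k)^3_+` at
every inner observed time (2 + (T_obs - 2) parameters — able to
interpolate when unpenalized, suited to small T); the penalized variants
place `min(floor(T_obs / 2), 7)` knots at interior quantiles of the
observed times, with truncated-line or truncated-cubic functions. Time is
mapped to [0, 1] internally before basis construction for conditioning;
fixed effects are reported on the original scale.

Estimation maximizes the restricted likelihood profiled over the residual
variance, parameterized by log10 variance ratios `s2_c / s2_e` bounded in
[-8, 12]. The criterion is evaluated through a Woodbury factorization of
the q x q random-effect cross-product matrix, so a fit costs one small
Cholesky per evaluation regardless of the number of observations. Two
numerical choices matter:

* the random-effect design is **column-normalized** before estimation
  (the iid-coefficient assumption is placed on the normalized basis);
  the raw truncated-power basis is so badly conditioned that the REML
  ridge cannot approach its smoothing limits in double precision.
  Coefficients are mapped back to the raw basis for prediction;
* when the full unpenalized basis reproduces the data exactly (residual
  MSE below 1e-16 x response variance, with residual degrees of freedom
  present), the fit returns the **minimum-norm interpolant** directly —
  the exact limit of the penalized spline as the variance ratio diverges.
  This makes noiseless recovery exact instead of
  conditioning-limited.

Serial selection follows a variance-collapse rule: model k+1 replaces the
current model only if its newly added variance component exceeds
`1e-8 x var(y)` and the fit's MSE (residuals against fitted values
including predicted random effects) does not increase. This rule is
deliberately liberal: under iid noise the REML estimate of an absent
variance component is frequently small-positive rather than zero, so
classes 3–4 are over-selected relative to the generating process. That
costs nothing downstream — the population curve used for clustering
(fixed effects + spline effects, subject effects zeroed) is essentially
unchanged — but users who want parsimonious class labels can pass
`selection="lrt"`, a REML likelihood-ratio test against the 50:50
chi-square mixture null appropriate for a variance component on the
boundary, at alpha = 0.05. Subjects with a single observation contribute
to the fixed effects only. Prediction outside the observed interval is an
error; interpolation grids default to one point per distinct observed
time, equally spaced.

## Profile filtering

Straight-line fits can signal either genuinely linear dynamics or noise
that defeated the spline. Two filters apply to class-1 fits only: the
Breusch–Pagan test (LM statistic `n R^2` from regressing squared
residuals on time, chi-square with 1 df) removes profiles with
heteroscedastic residuals at alpha = 0.05; optionally, profiles with MSE
above the maximum MSE among spline-fitted features are removed. The MSE
bound defaults to "auto": it engages only when straight lines exceed
half of all fits, where the BP test alone is insufficiently stringent.
The removal direction (significant BP -> removed) and the alpha default
are design choices stated in the filter report header.

## Clustering and tuning

The modeled `T x P` matrix is profile-standardized (each trajectory
centered, unit variance across the grid) so shape, not amplitude, drives
clustering. PCA assigns each feature to the component with its largest
absolute loading; sparse PCA assigns each selected feature to the
component where its loading is nonzero (earlier component on ties).
Clusters split by loading sign, so H components give up to 2H clusters of
co-varying (or mirror-image) trajectories.

Cluster quality uses the silhouette `s(i) = (b(i) - a(i)) / max(a, b)`
with trajectory distance `d = 1 - rho_spearman`, ranging over [0, 2] so
that anticorrelated profiles — which belong to opposite sign clusters —
are maximally distant. The alternative convention `(1 - rho)/2` was
considered and rejected because it halves the separation between sign
clusters. Members of singleton clusters score 0; constant profiles have
undefined rank correlation and are skipped with a warning. Per-profile
silhouettes map to statuses: above 0.5 assigned, in [0, 0.5] uncertain,
negative misassigned; flags are reported, features are never relocated.

The number of components H maximizes the average silhouette over
1..H_max (ties to the smaller H). keepX per sparse component is chosen
along a user grid by a "first sudden decrease" rule: the largest grid
value before the per-cluster average silhouette first drops more than
delta = 0.05 (absolute) below its running maximum.

Sparse PCA and the multi-block factorization enforce sparsity by
soft-thresholding at the (k+1)-th largest absolute gradient entry, which
leaves exactly k nonzeros (ties broken deterministically). The
multi-block iteration updates one block's loading at a time; a sweep that
would decrease the design-weighted covariance objective is rejected and
the iteration stops there, making the objective trace non-decreasing by
construction. Because the sparse problem is non-convex, components are
multi-started from the top three singular vectors (plus, for two-block
problems with keepX <= 2 and a small block, from coordinate vectors, so
the keepX = 1 solution provably reaches the best covariance pair on
small problems). Deflation is symmetric by default — each block is
regressed on its own score — matching the unsupervised framing; a
response-anchored variant (all blocks deflated on a designated block's
score) is available for designs with an outcome block. keepX tuning for
blocks runs coordinate search with two sweeps, so choices made while
other blocks were still dense are revisited once.

## Proportionality validation

Correlations between relative-abundance profiles are prone to spurious
structure. The proportionality distance
`phi_s(x, y) = var(x - y) / var(x + y)` on log-scale profiles is zero
exactly when the raw-scale pair is proportional and is reported per
cluster: median over within-cluster pairs versus median over pairs of one
member with every selected feature outside the cluster, with a two-sided
Wilcoxon rank-sum p-value (exact for small pair sets, normal
approximation with tie correction otherwise, as implemented in SciPy).
Sample (n-1) variances are used; the ratio is invariant to that
convention as long as both variances share it. CLR-modeled profiles are
treated as already log-scale; continuous blocks are logged only on
request. Within-cluster pairs above the 95th percentile of all
within-cluster distances are flagged as candidate spurious associations.

## Simulation benchmark

The generator emulates a four-cluster trajectory study: 20 reference
profiles (4 clusters x 5) on 9 equally spaced time points; per reference,
5 individuals are drawn with iid Gaussian noise at each time point, sigma
ranging over {0, 0.1, 0.2, 0.3, 0.4, 0.5, 1, 1.5, 2, 3}; optionally 0–4
interior time points are removed per individual profile (endpoints kept
so interpolation never extrapolates). The modeling arm fits LMMS per
feature and clusters the 9-point interpolated matrix with PCA (H tuned up
to 2, sign-split, optimal bipartite matching to the truth); the
no-modeling arm clusters one raw simulated profile per reference after
the same per-profile standardization. Accuracy is the per-cluster
confusion-matrix quantity (TP + TN) / (TP + FP + TN + FN) micro-averaged
over true clusters; the Rand index is reported alongside.

Reference shapes are archetypes: rising sigmoid, falling sigmoid,
unimodal peak, unimodal trough, each standardized to mean 0 / sd 1 across
time (so sigma is expressed in units of profile standard deviation — the
sigma = 3 operating point means noise three times the signal scale).
Within-cluster variants jitter the sigmoid steepness and bump width only:
sigmoids are exactly odd and bumps exactly even about the grid midpoint.
This symmetry is an identifiability device — it makes the two temporal
patterns exactly orthogonal after standardization, so the population
covariance is block-diagonal and PCA cannot rotate the two components
into each other even when their variances nearly coincide. Without it,
noiseless clustering would fail sporadically for reasons unrelated to
the method under study. Any alternative reference set can be supplied as
a TSV via the CLI (`simulate --profiles`).

What the benchmark does *not* emulate: compositional count noise (the
simulated values are already continuous, as after CLR), uneven or
subject-specific sampling schedules, subject-level random effects
(individuals differ only by iid noise), and correlated noise across
features. Passing results therefore demonstrate the denoising and
interpolation value of the modeling step under the stated noise model,
not performance on raw sequencing data.

Default problem sizes: 100 simulated datasets per noise level in the
shipped tests and acceptance script, 500 behind a flag (`--n-datasets`),
chosen as the package's standard reduced-size configuration; means are
stable to about +/-0.01 at 100 datasets. All randomness flows from a
single integer seed through spawned generator streams, so every arm and
noise level is independently reproducible.

## Known limitations

* Serial model-class labels over-select subject-effect classes under the
  default variance-collapse rule (see above); use `selection="lrt"` for
  parsimony.
* The sparse multi-block optimum is a multi-started local optimum; for
  keepX far from 1 and many blocks there is no global guarantee.
* Spearman-distance silhouettes are undefined for constant trajectories,
  which are skipped, and insensitive to monotone reparameterizations of
  profiles.
* The Breusch–Pagan filter tests heteroscedasticity against time only;
  variance structure orthogonal to time is not detected.
* No group-differential testing, extrapolation, rarefaction, or
  N-of-1 dynamical modeling; see the non-goals of each module.
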