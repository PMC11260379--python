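# Methods

## Model and procedure

The pipeline relates a subjects × regions brain feature matrix **X** to a
subjects × 6 behavioral design **Y** by Partial Least Squares Correlation.

**Connectivity features.** Each subject's parcellated BOLD series (regions ×
timepoints, sampling period TR) is band-pass filtered with a 4th-order
Butterworth applied forward–backward (`sosfiltfilt`), so the filter is
zero-phase and leaves correlation structure untouched. Defaults 0.01–0.15 Hz
target slow resting-state fluctuations; at TR = 3 s the Nyquist frequency is
1/6 ≈ 0.167 Hz, so the upper edge is valid but close to it, and any band at
or above Nyquist is rejected up front. The FC matrix is the pairwise Pearson
correlation of the filtered series — symmetric, unit diagonal, entries in
[−1, 1] — used *signed*, with no thresholding or absolute value. Eigenvector
centrality is the eigenvector of the largest eigenvalue of FC; since a
correlation matrix is positive semidefinite, that eigenvalue is nonnegative
and λvvᵀ is the best rank-1 symmetric approximation of FC in Frobenius norm.
Constant (zero-variance) regions are rejected with the offending region
named, never imputed.

**Design.** Age, carrier status (any E4-containing genotype) and symptom
status (MCI or AD) are z-scored with the sample standard deviation
(ddof = 1); the three interactions are elementwise products of the z-scored
mains and are deliberately not re-standardized. PLSC outputs are invariant
to column scale of X (z-scored internally) so the ddof choice only affects
the absolute scale of Y's interaction columns, not which components emerge.
Sex is generated in synthetic cohorts but never enters the design.

**PLSC.** With X columns z-scored (ddof = 1), `R = Yᵀ X_z / (n−1)` puts the
main-effect rows of R on an exact Pearson-correlation scale. The SVD
`R = U diag(s) Vᵀ` (K = min(6, regions)) yields behavioral saliences U,
brain saliences V, and singular values s. Sign indeterminacy is fixed per
component by making the largest-|loading| entry of the V column positive.
Latent scores are `Lx = X_z V` and `Ly = Y U`. The aging score of component
k is `Y[:, age-cols] @ U[age-cols, k]` with age-cols = {age, age×E4,
age×symptoms}; when a component's non-age saliences vanish it equals the
Ly column exactly.

## Permutation testing

Significance of each singular value is assessed by permuting subject rows
of Y relative to X (1000 permutations by default) and re-running the SVD,
with the add-one estimator `p_k = (#{s*_k ≥ s_k} + 1)/(B + 1)`, whose floor
is 1/(B+1).

Two reference schemes are provided. The literal same-rank comparison
(`scheme="simple"`) compares each permuted singular value to the observed
one of the same rank. It is exact for component 1 and for fully null data,
but anti-conservative past the true rank: when strong components exist, the
observed rank-k value is the *maximum* noise singular value in their
orthogonal complement, while the permuted reference is only the k-th order
statistic of a null spectrum. Measured on synthetic data with two strong
planted effects, it declared 2–4 components significant depending on the
seed. The default (`scheme="deflate"`) therefore projects each permuted
matrix off the observed leading k−1 singular subspaces (both sides) before
taking its top singular value; the observed statistic is unchanged and the
reference now lives in the same orthogonal complement. The two schemes give
identical p-values for component 1 (asserted in the tests).

Component counting uses sequential stopping by default (stop at the first
rank whose p reaches α), the natural rule for nested rank tests; marginal
counting (every p < α) is also available. α defaults to 0.05.

Known limitation: even deflated, tests past the true rank remain slightly
liberal when the preceding components are strong, because signal–noise
interaction inflates the observed residual spectrum relative to a permuted
null. In calibration runs with two planted effects the sequential count
equaled the true rank in 7–9 of 10 seeds and was the modal outcome in all
seed families tried; fully null calibration of component 1 is exact.

## Bootstrap stability

Subjects are resampled with replacement (1000 resamples by default) and the
PLSC refit per resample, X re-standardized within the resample. Each
resample's (U*, V*) is aligned to the original by one orthogonal Procrustes
rotation of the stacked saliences — without this, sign and component-order
flips across resamples corrupt the standard errors. Elementwise standard
deviations (ddof = 1) give the bootstrap SEs; the bootstrap ratio is the
original salience over its SE, and |BR| > 2 (strict) marks a stable element,
matching the ~95% normal-theory confidence level. SEs are floored at 1e-12
and floored elements flagged, so degenerate data never produce non-finite
ratios. A resample that makes a design column constant (e.g. no carriers
drawn) is redrawn, up to 100 times before erroring.

Randomness discipline: one master seed spawns independent child streams
(`numpy.random.SeedSequence`) for the permutation and bootstrap stages, so
changing one stage's count never perturbs the other's results.

## Synthetic cohorts

The generator emulates the study conditions the package is tested under:
128 subjects (54 APOE4 carriers, 52 symptomatic), ages from a normal
(73.42, 7.59²) truncated to [50, 95] years, 379 regions, 197 timepoints at
TR = 3 s. Carrier and symptomatic sets are drawn independently and honour
the requested counts *exactly*. Genotype marginals are realistic
(carriers: E3/E4 0.85, E4/E4 0.10, E2/E4 0.05; non-carriers: E3/E3 0.85,
E2/E3 0.15) but only the binary carrier flag enters the analysis; the
diagnosis mix within strata follows MCI:AD = 39:13 and CN:SMC = 39:37.

Ground truth is planted as rank-1 effects (unit-norm brain pattern v,
unit-norm behavior pattern u over the six design columns, scalar strength);
distinct effects must be mutually orthogonal so they map onto distinct SVD
components. Two levels are available:

- **Feature-level**: `X = 1μᵀ + Σ_k strength_k (Y u_k) v_kᵀ + N(0, σ²)`,
  for testing the PLSC stage in isolation. Default experiment conditions
  use strength 5 and σ = 1 at n = 128 — strong enough for reliable
  detection, weak enough that recovery is non-trivial (pattern cosine
  ≈ 0.93, not 1).
- **Time-series level**: per subject, target correlation = shared base FC
  plus `coupling · (Y u_k)_i` times the off-diagonal part of v_k v_kᵀ,
  diagonal reset to 1. If the additive bump breaks positive definiteness
  the matrix is repaired by flooring its eigenvalues at 1e-6 and rescaling
  to unit diagonal; the rescaling is a congruence transform, so the result
  is an exact correlation matrix and remains positive definite in a single
  pass (an iterative alternating-projection repair was measured at seconds
  per subject and is unnecessary at this accuracy). Series are zero-mean
  Gaussian draws from the Cholesky factor, so the sample FC of long series
  converges to the target. The end-to-end recovery experiment uses 80
  regions, a uniform base correlation of 0.1, a 16-region planted
  community, and coupling 0.6 — enough to move eigenvector centrality
  beyond the FC sampling noise of 197-timepoint series.

What the generator does *not* emulate: hemodynamics, scanner drift, motion
or physiological artifacts, spatial autocorrelation of real parcellations,
non-Gaussian BOLD marginals, or realistic empirical FC topology. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated generative model, not robustness to fMRI artifacts — the
upstream denoising those artifacts require is out of scope, and the
pipeline assumes it has already happened.

## Numerical choices and degenerate inputs

- Eigen-decomposition via LAPACK `eigh`; a near-tie of the top two FC
  eigenvalues (within 1e-9) logs a warning and is broken deterministically
  by choosing the tied eigenvector whose largest-|loading| sits at the
  lowest region index. Generic data make exact ties measure-zero.
- Centrality sign: entry sum ≥ 0, falling back to a positive
  largest-|entry| element when the sum is exactly 0.
- FC matrices are symmetrized to 1e-10, clipped to [−1, 1], diagonal set to
  exactly 1; validation is strict rather than repairing silently.
- Orthonormality of U and V is asserted to 1e-8 on every fit; singular
  values to Frobenius-energy identity at 1e-10.
- Cohort/pipeline sizes in the validation experiments are chosen so each
  completes in well under a minute of compute: null calibration uses 200
  replicate datasets × 200 permutations (the floor 1/201 is still far below
  α = 0.05); recovery runs use the full default 1000 + 1000 resampling at
  the default 128 × 379 problem size.

## Pipeline runs

`run_pipeline` drives any of four input modes (timeseries / fc / features /
simulate) from one `RunConfig` (YAML round-trippable), writes every table
as CSV/TSV/JSON, and records a manifest with SHA-256 hashes of all outputs,
the seed, the full config and per-stage timings. Group comparisons in the
cohort summary use Kruskal–Wallis across the four carrier × symptom groups;
groups with fewer than two members are skipped with a warning, and
all-identical values yield p = 1 by convention. Aging-score reports fit
ordinary least-squares slopes of score vs age per subgroup (the four cells
and both two-level marginals); the qualitative signature of an age×E4
effect is a carrier/non-carrier slope separation exceeding the
symptomatic/non-symptomatic one.
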