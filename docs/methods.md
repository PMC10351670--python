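# Methods

`hippotex` implements a complete analysis chain for hippocampal MRI texture
across the Alzheimer's continuum: 3D ROI texture extraction, PCA feature
reduction, cross-sectional group inference, a latent disease-time progression
model, trajectory and dual-timescale models on that timeline, and bootstrap
comparison of nested cognitive-decline prediction models. This note records
the models, their assumptions, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Texture extraction

An ROI is a masked 3D intensity grid with voxel spacing in mm. The
preprocessing order is fixed: (1) optional denoising hook (a no-op by
default — non-local-means denoising upstream has been reported not to change
texture characterization appreciably, so the hook only exists for users who
want to plug one in); (2) trimming of in-mask voxels outside mean ± 3 SD,
which limits partial-volume contamination from surrounding CSF; (3)
z-scoring of the remaining in-mask intensities, making texture comparable
across participants; (4) discretization into `G` equal-width bins spanning
the in-mask range (default G = 32; the maximum maps to bin G). Because of
(3) + (4), all downstream features are invariant to affine rescaling of the
raw intensities (verified by test).

Three feature families are computed per hemisphere and averaged element-wise
across hemispheres (volume included; volume = in-mask voxel count × voxel
volume):

* **First-order**: histogram statistics of the in-mask intensities (mean,
  median, SD, variance, skewness and Pearson kurtosis as plain moment
  ratios, min/max/range, energy, G-bin histogram entropy in bits,
  percentiles 5/25/75/95, IQR).
* **GLCM**: co-occurrences of discretized levels at one-voxel distance over
  all 26 3D neighbour offsets. Pairs with either endpoint outside the mask
  are skipped (mask-restricted counting); each per-offset matrix is
  symmetrized, normalized to sum 1, and the 26 matrices are averaged.
  Features: contrast, dissimilarity, homogeneity, inverse difference moment,
  ASM/energy, entropy (bits), correlation, autocorrelation, cluster shade,
  cluster prominence, maximum probability.
* **GLRLM**: maximal same-level runs along the 13 unique 3D directions
  (offset pairs ±d describe the same runs), broken at the mask boundary.
  Features (SRE, LRE, GLN, RLN, RP, low/high grey-level and joint run
  emphases) are computed per direction and averaged.

Both matrix constructions are verified against brute-force pair/run
enumeration on batches of random discretized ROIs. Binning happens per
hemisphere, after trimming and z-scoring of that hemisphere. The feature
catalogue is a documented, compact set of the three families — count parity
with any particular radiomics toolbox is a non-goal.

## Feature reduction

Feature-table cleaning masks cells outside mean ± 3 × IQR of their column
(cell-wise, not row-wise, since isolated outlier measurements should not
discard a whole scan) and drops features with variance below 1e-10. The PCA
rotation is computed only on a designated training subset — baseline visits
of cognitively unimpaired participants — after z-scoring with training
means/SDs, and applied to the entire table. Components explaining ≥ 5% of
training variance are retained (configurable). Component signs follow a
deterministic convention (largest-magnitude loading positive); rows with any
missing feature get missing scores.

## Cross-sectional group models

Each texture component and volume is modelled at baseline as

    y ~ C(group) + age_bl + sex + education + ICV + (1 | site)

with a four-level diagnostic group (CU-Aβ−, CU-Aβ+, MCI-Aβ+, ADD-Aβ+;
reference CU-Aβ−) and a random intercept per scan site, fitted by REML with
an exact profiled solver for the single-random-intercept structure. Term
tests are Wald F statistics with residual denominator degrees of freedom
(n − p); at the cohort sizes this package targets (hundreds of subjects) the
difference from Satterthwaite-type corrections is negligible, and the
type-I-error calibration test (rejection rate within [0.035, 0.065] under a
1000-rep null at n=400) is the explicit check on this choice. Pairwise
post-hoc models refit the same structure on the reference group plus one
other group. Cohen's d is the adjusted contrast divided by the pooled
within-group SD of the raw outcome; Cohen's f is the between/within SD
ratio (equal to d/2 for two equal groups). Multiplicity is handled with the
Holm step-down procedure by default (Benjamini–Hochberg via `method="bh"`);
the family is whatever set of p-values is passed in — the bundled pipeline
pools all variables × contrasts into a single family.

Amyloid status uses CSF Aβ1–42 when available (positive below 980 pg/mL),
otherwise PET centiloid (positive above a configurable threshold; default
24 CL, a synthetic default — no single canonical value exists). Values
within ±5% of the operative threshold are excluded as borderline. Continuous
analysis variables can additionally be screened with a literal
mean ± 1.5 × IQR fence (the conventional quartile fence is available via
`fence="quartile"`). With a degenerate IQR of 0 the mean fence collapses to
the mean, so only values exactly at the mean survive — documented behaviour.

## Latent disease-time model

The core model aligns every subject's visits on a shared latent timeline:

    y_ijk = θ_k(t_ij + s_fixed(i) + s_i) + x_ik + e_ijk

* θ_k — natural cubic spline (9 DoF) per outcome, on its original scale.
  The basis is the truncated-power natural-spline construction with
  analytic derivatives (linear beyond the boundary knots).
* s_fixed(i) — baseline-group offset (reference group fixed at 0) plus a
  linear term in baseline age centred at the cohort mean.
* s_i ~ N(0, ω²) — subject random time shift. No subject-level random
  slopes exist anywhere in the model; individual deviation is carried by
  the shift and the intercepts.
* x_ik — subject × outcome random intercepts with an unstructured K×K
  covariance Σ.
* e_ijk ~ N(0, σ²_k) — independent residuals with per-outcome variances,
  giving a data-driven relative weighting of outcomes.

**Estimation** alternates: (a) given shifts, each outcome's spline,
intercept variance and residual variance are estimated by profiled ML
(random-intercept LMM); Σ's off-diagonals come from the BLUP correlations
scaled to the ML intercept variances (positive semi-definite by
construction); (b) given the curves, each subject's total shift is updated
as the posterior mode (MAP) of its marginal likelihood — with the subject's
intercepts integrated out analytically through Σ — times the N(s_fixed, ω²)
prior, found by a coarse grid (0.5 y) plus bounded 1-D refinement; ties in
the posterior break toward zero shift; (c) group offsets and the age slope
are re-estimated by least squares on the updated shifts, the reference
group is re-anchored at zero, and ω² is updated EM-style as the mean of
squared shifts plus Laplace posterior variances. Spline knots sit at
quantiles of the current shifted times (boundary knots at the 1st/99th
percentiles) and are refreshed for the first 4 iterations, then frozen.

Starting values matter: from a cold start (all shifts zero) the initial
mean curves are nearly flat and the intercepts absorb the staging
variation — a local optimum with collapsed shifts. Fitting therefore starts
from a moment-based alignment: outcomes are z-scored and oriented by the
sign of their pooled within-subject slope, averaged into a composite
severity score, and each subject's mean composite is converted to years via
the pooled within-subject progression rate of that composite.

Convergence is declared when the Laplace-approximate marginal
log-likelihood changes by less than 1e-5 (relative) or the largest shift
update falls below 0.01 y, whichever comes first; the surrogate objective
is not exactly monotone (the variance update and the Laplace approximation
each contribute wobble of order 0.1% near the optimum), so the
package tracks the full trace and the tests assert overall improvement and
stabilization rather than strict monotonicity. Non-convergence raises an
error carrying the trace.

**Identifiability.** With a single outcome whose mean curve is linear, a
time shift is exactly confounded with an intercept offset; the model warns
(`shifts weakly identified`) for K=1. Translation of the whole timeline is
absorbed by the reference-group anchor and, subsequently, by Time-0
anchoring: the running median (window 2 y by default) of staged CSF
Aβ1–42 is scanned from early to late disease time, and the first crossing
of the healthy (Aβ−) group's 95th percentile *in the direction of
abnormality* (the lower-tail raw quantile for a decreasing marker) defines
Time 0, with linear interpolation between evaluation points and ties
resolved to the first crossing.

**Staging.** Predicted disease time is t̃_ij = t_ij + ŝ_fixed(i) + ŝ_i with
ŝ_i the posterior mode under the ML estimates (verified against a dense
0.01-y grid). Subjects with no usable observations get fixed-effect-only
staging with a flag.

## Trajectories over disease time

Each staged variable v_ij follows v_ij = θ(t̃_ij) + x_i + ε_ij with a
subject random intercept (variance τ²) and residual variance σ². The spline
DoF is selected among {3,4,5,6} by BIC under ML (BIC uses the observation
count as effective n, the standard mixed-model convention here), and the
selected model is refitted by REML. The extreme 5% quantiles of disease
time are excluded before fitting — 2.5% per tail by default, with a
per-tail-5% flag since either reading of "extreme 5% quantiles" is
defensible.

Two derived curves:

* **Abnormality** (θ̂(t) − q0.5)/(q0.95 − q0.5): 0 at the healthy-group
  median, 1 at its 95% quantile in the direction of abnormality. The
  direction per outcome is declared in configuration (volume/MMSE lower =
  abnormal; ADAS13/CDR-SB/centiloid higher = abnormal). Healthy quantiles
  use all observations of subjects classified CU-Aβ− at baseline. The
  transform is affine-equivariant: rescaling the outcome rescales the
  quantiles and leaves the curve unchanged.
* **Sensitivity to change** θ̂′(t)/σ̂: slope per residual SD — the per-year
  signal-to-noise for tracking one individual — computed with the analytic
  basis derivative and the REML residual SD (subject intercepts removed).

## Dual-timescale (age × disease) models

Five forms are compared by BIC, all with a subject random intercept:
constant; disease-time spline only; age spline only; additive
θ_d(t̃) + θ_a(a_t0); and interaction, which adds the product of the two
*centred* spline expansions. To avoid counting progressive time twice,
models containing both timescales use age at disease Time 0,
a_t0(i) = within-subject mean of (age at visit − disease time at visit),
which is constant per subject by construction; the age-only model uses
observed age. Spline DoF run 1–6 per timescale (DoF 1 = linear). The
interaction surface is the tensor product of the centred bases with its DoF
tied to the main-effect DoF per timescale: the rank-1 product of two spline
functions is nonlinear in its coefficients, while the tensor product is
linear, contains the rank-1 product as a special case, and keeps the
candidate scan at 85 linear mixed-model fits (1 + 6 + 6 + 36 + 36) instead
of a four-way DoF grid of thousands. Centring the factors before
multiplying reduces collinearity with the main effects. The winning form is
refitted by REML.

## Predicting cognitive decline

For subjects without dementia at baseline, three nested OLS models predict
the cognitive score at the visit nearest 24 months (window ±6 months by
default in the library, ±12 in the bundled small pipeline; distance ties
resolve to the earlier visit): baseline score + age + sex + education +
ICV; plus hippocampal volume; plus the five texture components. Subjects
are resampled with replacement (1000 repetitions by default) — resampling
at subject level, since rows within a subject are not exchangeable — and
each model's adjusted R² is recorded per resample. The three pairwise
comparisons use two-sample t-tests between the bootstrap distributions with
Holm adjustment and Cohen's d of the difference; a paired-test variant is
available behind `paired=True`.

One deliberate calibration choice: on a bootstrap resample the rows are not
independent (on average 63.2% of subjects are distinct), so the usual
row-count adjusted-R² correction under-penalizes extra predictors and a
block of pure-noise predictors *systematically* raises mean adjusted R² —
an effect no test on the resulting distributions can undo. Adjusted R² is
therefore computed with effective n = number of unique subjects in the
resample by default, which restores the degrees-of-freedom fairness the
adjustment exists to provide (measured null rejection of the noise-texture
step ≈ 0.04 at n=500 versus ≈ 0.2–0.33 with the row-count formula). The
row-count variant is available via `effective_n="rows"`.

## Synthetic data generator

The cohort generator emulates an ADNI-like multi-site panel: four baseline
groups (reference CU-Aβ−) with fixed latent-time offsets (defaults 0, 5,
10, 15 y — synthetic values chosen to span an approximately two-decade
continuum; the source cohort's generating process is unknown), Gaussian
subject shifts (default SD 3 y), ages from a normal distribution truncated
to [55, 95] (mean 73, SD 7), monotone outcome mean curves built as PCHIP
interpolants of control points (held flat beyond their support, clipped to
instrument floors/ceilings: MMSE [0,30], ADAS13 [0,85], CDR-SB ≥ 0),
subject random intercepts, i.i.d. residual noise per outcome, monotone
visit-level dropout plus outcome-level MCAR missingness, and a site label.
Default curve shapes are sigmoidal in disease time — near-normal cognition
before amyloid onset (time 0), worsening over the following two decades;
CSF Aβ1–42 declining through 980 pg/mL around time 0 — with noise scales
chosen to look like a realistic amnestic cohort. All draws come from one
seeded generator: identical specs give byte-identical tables, and the true
shifts and intercepts are returned for recovery scoring.

ROI phantoms are ellipsoids in a rectangular grid filled with a constant
base level plus a textured field: seeded hyperintense impulses ("clustered
hyperintensities") and white noise smoothed together with a Gaussian kernel
whose width (`blob_sigma`) is the field's correlation length — larger sigma
gives smoother images and monotonically lower GLCM contrast, which the
tests exploit. `radius_scale` shrinks the ellipsoid to create volume
signal. In the bundled pipeline, blob count, smoothing and ROI size are
tied to the subject's true disease stage so that downstream stages see
genuine (if simplistic) disease signal.

What the generator does **not** emulate: amyloid-PET physics, scanner/site
effects on texture (site enters only as a random intercept on outcomes),
spatially realistic hippocampal anatomy, informative (MNAR) dropout, or
practice effects on cognitive tests. Passing tests therefore demonstrate
correctness of the algorithms and calibration of the inference under the
stated generating model, not performance on real MRI.

## Problem sizes and determinism

The test suite and acceptance script run everything at desk scale, chosen
as the package's own study sizes: texture oracles on ≤ 8³ phantoms;
latent-time recovery on a 400-subject, 4-outcome cohort; BIC selection
recovery over 50 seeds at 500 subjects; inference calibration with
500–1000 simulation replicates and 100–200 bootstrap outer replicates at
n_boot=200; and an end-to-end pipeline fixture of 100 subjects with 14³
phantoms. Every stochastic stage takes an explicit seed; fixed seeds give
identical tables, fits, manifests and bootstrap results.

## Known limitations

* The alternating estimator returns a local optimum; the moment-based
  initialization makes the reported recovery reliable under the generator's
  conditions but global optimality is not guaranteed, and group offsets are
  mildly shrunk toward each other (MAP shrinkage plus flat curve tails).
* Σ's off-diagonals are moment estimates from BLUP correlations, not full
  ML; the diagonal and the residual variances are ML/profiled estimates.
* Wald F tests use residual denominator DoF; with few sites or very small
  n a Satterthwaite/Kenward–Roger correction would be preferable.
* The dual-timescale interaction is a tensor surface with tied DoF, a
  superset of the rank-1 product form; BIC comparisons across forms carry
  the corresponding parameter counts.
* Trajectory standard errors / credible bands are not computed (point
  curves only).
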