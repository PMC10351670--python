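# hippotex

Hippocampal MRI **texture** analysis and **latent disease-time** modelling
across the Alzheimer's continuum.

Structural atrophy is a comparatively late consequence of Alzheimer's
pathology, but microstructural change alters the statistical texture of the
T1-weighted MR signal earlier. This package implements, as a tested and
reusable pipeline, the full analysis chain needed to study that idea:

1. **Texture extraction** (`hippotex.texture`) — first-order, grey-level
   co-occurrence (GLCM) and run-length (GLRLM) features from masked 3D ROIs,
   with μ±3σ trimming, z-scoring, 32-bin discretization, 26-direction
   averaging and hemisphere averaging.
2. **Feature reduction** (`hippotex.features`) — outlier/low-variance
   cleaning and a PCA rotation trained on baseline cognitively unimpaired
   (CU) scans, projected onto everyone.
3. **Cross-sectional inference** (`hippotex.crosssec`) — linear mixed models
   `y ~ group + age + sex + education + ICV + (1|site)` across the four
   baseline groups (CU-Aβ−, CU-Aβ+, MCI-Aβ+, ADD-Aβ+), pairwise post-hocs,
   Holm correction, Cohen's f/d, and amyloid-status classification
   (CSF Aβ1–42 < 980 pg/mL, 5% borderline exclusion).
4. **Disease-time staging** (`hippotex.progression`) — the core model: a
   multivariate nonlinear mixed-effects model
   `y_ijk = θ_k(t_ij + s_fixed(i) + s_i) + x_ik + e_ijk` that aligns every
   subject's visits on a shared latent timeline via 9-DoF natural-spline
   mean trajectories, group+age fixed shifts, Gaussian subject shifts, an
   unstructured intercept covariance across outcomes and per-outcome
   residual variances; MAP staging and Time-0 anchoring at the healthy
   CSF-amyloid bound.
5. **Trajectories** (`hippotex.trajectories`) — spline-over-disease-time
   models (3–6 DoF, BIC/ML selection, REML refit), abnormality curves
   `(θ̂(t) − q0.5)/(q0.95 − q0.5)` against healthy quantiles, sensitivity
   curves `θ̂′(t)/σ̂`, and dual-timescale age × disease models (five forms,
   1–6 DoF per term, BIC).
6. **Prediction comparison** (`hippotex.cogpredict`) — bootstrap comparison
   of adjusted R² across nested regressions predicting 2-year cognitive
   change: covariates vs +hippocampal volume vs +texture components.

A first-class synthetic-data module (`hippotex.simulate`) generates
ADNI-schema-like longitudinal cohorts with *known* latent time shifts and
textured 3D ROI phantoms, so every stage is testable end to end without any
access-controlled data. Modelling follows the statsmodels idiom: a model
class built from a DataFrame whose `fit()` returns a results object with
estimates, variances, curves and a `summary()`.

## Worked example

```python
import numpy as np
from hippotex import (CohortSpec, generate_cohort, ProgressionModel,
                      TrajectoryModel, AbnormalityScale)

table, truth = generate_cohort(CohortSpec(n_per_group=50, seed=11))
fit = ProgressionModel(table, ["adas13", "cdrsb", "mmse", "centiloid"]).fit()
print(fit.summary())
```

```
Latent disease-time model  (K=4 outcomes, spline df=9, iterations=14)
log-likelihood (Laplace): -9161.11
shift SD: 2.982 y   age slope: -0.0472 y/y
group offsets (years):
      CU-Ab-:   +0.000 (reference)
     ADD-Ab+:  +13.730
      CU-Ab+:   +5.282
     MCI-Ab+:   +8.859
residual SDs:
          adas13:    2.431
           cdrsb:    0.665
            mmse:    1.253
       centiloid:    7.071
```

The model recovers the generating structure: the cohort was simulated with
group shifts (0, 5, 10, 15) years, subject-shift SD 3 y and residual SDs
(2.5, 0.7, 1.3, 7.0) — and the estimated subject shifts track the true ones
(`corr = 0.916` against `truth.subjects["s_i"]`). Staging, anchoring and a
trajectory on the estimated timeline:

```python
ab = table[table["outcome"] == "csf_ab42"]
fit.anchor_time_zero(fit.predict_disease_time(ab),
                     ab.loc[ab["group_bl"] == "CU-Ab-", "value"])
staged = fit.predict_disease_time(table)          # adds a disease_time column

vol = staged[staged["outcome"] == "hippo_volume"]
tm = TrajectoryModel(vol, "hippo_volume").fit()
print(tm.summary())
scale = AbnormalityScale.from_healthy(
    vol.loc[vol["group_bl"] == "CU-Ab-", "value"], "hippo_volume", "decreasing")
for t in (0.0, 5.0, 10.0):
    print(f"abnormality at disease time {t:4.1f} y:"
          f" {tm.abnormality_curve(scale, [t])[0]:+.2f}")
```

```
Trajectory of 'hippo_volume': df=3 (reml), tau2=2.497e+05, sigma2=2.214e+04, support=[-15.10, 7.12] y, n=947
abnormality at disease time  0.0 y: +1.52
abnormality at disease time  5.0 y: +2.28
abnormality at disease time 10.0 y: +2.98
```

Time 0 is the point where the running median of staged CSF Aβ1–42 first
crosses the healthy group's bound, so hippocampal volume is already beyond
the healthy 95th percentile (abnormality 1) at amyloid onset in this
synthetic cohort, and grows more abnormal along the continuum. The
`hippotex` command-line tool exposes the same stages
(`simulate / extract / reduce / crosssec / stage / trajectories / predict /
run`); `hippotex run --seed 5 --outdir out/` executes the whole chain on a
bundled synthetic fixture and writes per-stage artifacts plus a manifest.

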