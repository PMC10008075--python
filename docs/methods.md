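# Methods

## The problem and the model

Parosmia — the qualitative distortion of odor perception — has lacked a
graded severity measure that does not require odor exposure. The approach
implemented here scores severity from a survey alone: patients classify a
fixed list of named odors (descriptors) as smelling *normal*,
*qualitatively different* (QD), *odorless* (OL), or *unknown*. The
premise is that odors rarely reported as affected across patients are the
ones affected last, so an affected response on a rarely-affected odor
signals more severe disease.

The pipeline has three statistical layers:

1. **Descriptor affectedness.** Per descriptor `d`, the share of observed
   responses in each category, `qd_d` and `ol_d` (percent), with
   normal-approximation binomial CIs
   `pct ± z_{1−α/2}·100·√(p̂(1−p̂)/n)`, clipped to [0, 100]. Unknown
   responses are treated as missing, so `n` is the count of classified
   cells.

2. **Association models.** Two binary factors are analyzed: QD vs
   (normal, OL) and OL vs (normal, QD). Descriptor-level Pearson
   correlations relate six semantic variables — corpus-derived olfactory
   association (OAI) and specificity (OSI), lexical valence and arousal
   (1–9), and olfactory/gustatory modality ratings (0–5) — to `qd_d` and
   `ol_d`, pairwise-complete, with `p` from
   `t = r√((n−2)/(1−r²))` on `n−2` df. The main models are
   random-intercept logistic regressions over (participant, descriptor)
   cells: ten participant covariates (age, BMI, sex, TDI, impairment
   duration, parosmia degree/intensity/valence, subjective impairment,
   olfactory importance) plus, in separate models to avoid collinearity,
   one semantic variable at a time — 14 fits in total.

3. **Severity index.** A PCA over the descriptor matrix (6 semantic
   variables + `qd_d` + `ol_d`, z-standardized, correlation-matrix
   eigendecomposition) yields scores `s_{p,d}` and variance fractions
   `v_p`. Weighted scores `OLs_{p,d} = s_{p,d}·ρ(s_p, ol)` (QD analogous)
   are min–max normalized per PC, inverted, and combined:
   `OLw_d = Σ_p (1 − norm(OLs)_{p,d})·v_p`. A participant's score is

       ps_i = Σ_{d∈D_i} (OL_{i,d}·OLw_d + QD_{i,d}·QDw_d)
              / Σ_{d∈D_i} max(OLw_d, QDw_d) ∈ [0, 1],

   where `D_i` is the set of descriptors participant `i` classified.
   The index is invariant to PC sign flips and weight rescaling, and
   monotone under normal→affected flips; these are enforced by tests.

## Preprocessing

* **Coding.** normal → (QD=0, OL=0), qualitatively_different → (1, 0),
  odorless → (0, 1); unknown → cell excluded from the observation mask.
* **Parosmia degree** is the weighted sum of intensity (0–10 VAS),
  frequency (daily=1) and significant consequences (0/1). The component
  weights of this composite are not standardized anywhere we know of;
  the default is (1, 1, 1), configurable.
* **Standardization** divides centered continuous predictors by two
  sample SDs (SD becomes 0.5), making their coefficients comparable to
  the ±1 effect-coded sex factor. Semantic predictors are standardized
  across descriptors (their natural unit) before broadcasting to the long
  table; observation-level standardization would weight descriptors by
  response counts and was rejected for that reason.
* **Imputation** follows a bootstrap-additive scheme: for each incomplete
  numeric variable, an additive OLS regression (linear terms plus a
  3-df natural cubic spline on continuous predictors with ≥8 distinct
  values) is fit on each of 10 bootstrap resamples of the rows complete
  for that model; the imputed value is the mean of the 10 predictions.
  Observed cells are never modified. Fewer than 10 complete training
  rows triggers mean-imputation fallback with a warning. Imputation runs
  before standardization, since the models need complete predictors.
  Single imputed values are used downstream (no Rubin's-rules pooling);
  descriptor semantic variables are never imputed for the correlation
  table (pairwise deletion) and only mean-imputed inside the PCA step,
  where incomplete rows would otherwise drop scoring coverage.

## The mixed-model fitter

No maximum-likelihood random-intercept logistic GLMM exists in the Python
stack this package builds on, so one is implemented in `parosim.glmm`:
the random intercept is integrated out by Gauss–Hermite quadrature
(15 nodes by default; 25 in oracle tests), the marginal log-likelihood
and its analytic gradient are vectorized over observations and nodes, and
L-BFGS-B optimizes `(β, log σ)` with `log σ` box-bounded in
[log 1e−4, log 25]. Standard errors come from the central-difference
Hessian of the marginal log-likelihood; inference is Wald (z and
two-sided normal p), matching the reporting convention of the association
tables. A variance estimate at the lower box is flagged as a boundary
fit and the fixed-effect covariance is computed with σ held fixed.
The fitter is validated against dense adaptive quadrature (log-likelihood
agreement ~1e−10) and against `lme4::glmer` with `nAGQ=25` (coefficients,
SEs, intercept SD and log-likelihood within 1e−3 on a 30-group fixture).
Calibration: under null simulations (200 participants, intercept SD 0.8)
the pooled per-term Wald rejection rate at α=.05 is ≈0.056–0.064 —
slightly anticonservative, as expected for Wald tests at this scale.

## The synthetic cohort generator

The generator emulates the study conditions the analysis assumes:

* **Cohort frame:** 48 participants × 38 descriptors.
* **Semantic variables:** a latent 6-variate normal with the published
  correlation matrix (e.g. r(valence, gustatory)=0.639), mapped affinely
  onto each rating scale with clipping; clipping is a >3σ event with the
  default scale maps, so sample correlations track the targets within
  ±0.05 at large n. The matrix is checked for positive semidefiniteness;
  a non-PSD user matrix can be repaired by eigenvalue clipping
  (`repair_psd`).
* **Participants:** age ~ truncated normal(45, 12) on [21, 70];
  P(F) = 30/48; remaining covariates use plausible clinical ranges (BMI
  N(26, 4) on [16, 45], TDI N(20, 8) on [1, 48], PEA threshold
  N(4, 2.5) on [1, 16], duration U(1, 36) months, VAS items uniform or
  clipped normal) — these joint distributions are assumptions, not
  estimates, and are all config-exposed.
* **Responses:** one trinomial draw per cell from the softmax of
  (0, η_QD, η_OL), `η_c = intercept_c + x'β_c + u_i`, with a shared
  per-participant intercept `u_i ~ N(0, 0.8²)` and the published binary
  model coefficients as default slopes on the same 2-SD-standardized
  scale the analysis uses. Using one trinomial mechanism instead of two
  binary ones keeps categories mutually exclusive by construction; the
  binary re-analysis of trinomial data is therefore an approximation,
  and recovery tests assert sign and approximate magnitude (in practice
  the olfactory→QD slope 0.95 is recovered within ~1 empirical SE at
  500 participants). Labels are replaced by "unknown" with probability
  0.02.
* **Missingness:** completely at random per variable — subjective
  impairment 30%, BMI 12.5%, other participant covariates 5%,
  valence/arousal 10%, modality ratings 5% of descriptors. MCAR is
  verified by an aggregate independence test across 50 seeds.
* **Severity coupling:** subjective impairment is linked to the latent
  `u_i` (2 VAS points per SD, plus N(0, 1.5) noise) so that the severity
  index correlates positively with reported impairment, as in patients.
  Null-calibration studies set this coupling to 0 along with the slopes,
  because a covariate correlated with the random intercept is not a null
  configuration for Wald calibration.
* **Reproducibility:** each stage draws from a sub-seed derived from the
  master seed by a fixed `SeedSequence` spawn-key scheme, so stages can
  be re-run independently and identical (config, seed) gives identical
  cohorts.

What the generator does **not** emulate: real descriptor semantics (it
draws exchangeable Gaussian descriptors, not actual words), longitudinal
change, etiology, non-MCAR missingness, and any dependence structure
among participant covariates beyond the impairment–severity link. Tests
passing on synthetic cohorts therefore establish the correctness and
calibration of the statistical machinery under the stated model, not
clinical validity on real patients.

## Numerical and design choices

* PCA retains P=3 components by default (configurable); variance
  fractions are always computed over *all* components, so retained-PC
  weights never sum above 1. Component signs are fixed by making each
  PC's largest-magnitude loading positive; every downstream quantity is
  sign-invariant anyway.
* The min–max normalization in the weight equations is applied per PC by
  default, so each PC contributes on a common [0, 1] scale before
  variance weighting; a global min–max across retained PCs is available
  behind a flag (`per_pc_minmax=False`). A PC whose weighted scores are
  constant contributes the neutral `0.5·v_p` to every descriptor.
* The severity numerator adds the OL and QD products; exclusivity of the
  indicators means each cell contributes at most one term.
* Degenerate binomial CIs (p̂ ∈ {0, 1}) clip to the point estimate.
* Descriptor subset selection uses greedy farthest-point (maximin)
  sampling, deterministic with ties broken by input order. The ½
  approximation guarantee versus the exhaustive optimum is asserted for
  the euclidean metric; cosine dissimilarity (the default for unit-
  normalized word embeddings) is not a metric, so no factor is claimed
  there. The published descriptor list involved manual curation the
  selection endpoint does not attempt to reproduce.
* Problem sizes in the heavy test studies — 200 replicates at 200
  participants for Wald calibration, 20 replicates at 500 participants
  for slope recovery, 10,000 randomized cases for the index property
  sweep — were chosen so Monte-Carlo error is small relative to the
  asserted bands while the whole suite stays interactive (~2 minutes).

## Known limitations

* Wald inference only; no likelihood-ratio or bootstrap CIs for the
  mixed models, no random slopes, no crossed descriptor random effects.
* No multiple-testing correction by default (a Benjamini–Hochberg flag
  would be a natural extension); stars in the correlation table are
  per-cell α=0.05.
* The imputation scheme is a simplified additive-bootstrap analog of
  predictive-mean multiple imputation, not a reimplementation of any
  specific package, and uses the prediction mean rather than
  predictive-mean matching; imputed values can fall outside observed
  ranges on pathological inputs.
* `ps` is undefined for participants who classified nothing (score
  missing with a warning), and the index's clinical cut-offs are out of
  scope.
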