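# Methods

This note documents the statistical machinery of `wqsmix`: the models, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions that affect results.

## Exposure preparation

Urinary concentrations are creatinine-adjusted (µg/L ÷ g/L creatinine =
µg/g creatinine) and recoded per metal into decile ranks 0–9. Cut points
are the nine empirical deciles computed by linear interpolation of order
statistics (the common "type 7" quantile convention); a value equal to a
cut point falls in the lower bin and the top bin is closed. This makes the
coding invariant under strictly increasing transformations and exactly
reproducible from the stored thresholds. Deciles are computed **once on the
full analytic sample** and reused by every training/validation subset:
quantization is a data-preparation step, not a model-fitting step, so
re-coding per split would change the meaning of the index across holdouts.
Heavily tied columns (e.g. a below-LOD point mass under the `zero`
substitution rule) can produce merged bottom bins; the transform warns with
the occupancy vector rather than failing. A constant column is rejected as
degenerate — it cannot be quantized.

Cross-metal association is summarized by the Spearman matrix (average ranks
for ties). A constant column's correlations are reported as missing, never
silently zeroed.

## Limit-of-detection handling

LODs are defined on the unadjusted µg/L scale, so censoring runs through a
creatinine round trip: adjusted values are multiplied by the subject's
creatinine, compared with the metal's LOD, and below-LOD values are
replaced by 0, LOD/√2, or LOD/2 (then re-adjusted). The default is LOD/√2,
the standard single-substitution choice for log-normal biomarkers; the
`zero` rule is provided because the reference cohort's Mn distribution
shows a 25th percentile of exactly 0, which only that rule reproduces. No
claim is made about which rule the reference analysis used; both are
exposed and the choice is a config switch.

## The synthetic cohort generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream property is verified.

* **Exposures.** A Gaussian copula on the log scale with log-normal
  marginals. Each metal's median is fixed at its reference geometric mean
  and the log-SD is solved by bracketed root finding so the log-normal's
  interquartile range matches the reference IQR. The copula's latent
  correlation is obtained from the target Spearman matrix via
  r = 2·sin(πρ/6), so empirical rank correlations converge to the target.
  The default target is exchangeable and weak — 0.15 within the essential
  and toxic groups, 0.05 between — reflecting the reference cohort's lack
  of strong cross-metal correlations (only some pairs above 0.2 in absolute
  value). Any positive semi-definite target matrix can be supplied; a
  non-PSD matrix is rejected with the offending eigenvalue named.
* **Creatinine** is log-normal with median 1.0 g/L and log-SD 0.4, a
  typical spot-urine dilution spread; the reference publication reports no
  creatinine distribution, so this is the package's own choice and is
  configurable.
* **Covariates** (maternal age, BMI, social class, smoking, Mediterranean
  diet score, child sex, feeding mode) are drawn independently from the
  reference marginals, with age and BMI as truncated normals. Binary
  covariates are 0/1 indicators; continuous covariates enter models
  unstandardized.
* **Outcomes** follow the analysis model itself: y = intercept +
  β₁ᵉS_ess + β₂ᵉS_ess² + β₁ᵗS_tox + β₂ᵗS_tox² + covariate terms + Gaussian
  noise, with the indices built from the post-censoring decile matrix and a
  known weight vector per group. Adopting the analysis model as the
  generating process is deliberate: the package's correctness claims are
  about *parameter recovery* under its own assumptions, which requires a
  well-posed truth. WPPSI-type scores default to intercept 100 / residual
  SD 15 and NEPSY-type scores to 10 / 3; one `EffectTruth` drives all
  eleven outcomes, with effects mapped onto the NEPSY scale by the factor
  3/15 so the standardized signal is identical across instruments. A
  residual SD of zero is allowed and produces an exactly affine outcome,
  used by the identifiability tests.

What the generator does **not** emulate: trial arms or supplementation
effects, gestational-age dynamics, attrition and missingness mechanisms,
longitudinal exposure trajectories, inter-covariate dependence, and
outcome-specific covariate effects. Passing tests therefore demonstrate
that the estimator recovers known structure under idealized but calibrated
conditions — not that any specific real-cohort estimate is correct.

## Non-linearity screen

Each metal × outcome pair is fit as `y ~ f(q) + covariates` where f is a
rank-10 cubic B-spline penalized by its exact integrated squared second
derivative. The penalty's null space is precisely the affine functions of
the exposure, so an infinite penalty reproduces the ordinary linear fit and
the smooth's effective degrees of freedom (edf, the trace of its share of
the influence matrix) run from 1 (linear) to 9. The smoothing parameter is
chosen by restricted maximum likelihood — stabler than GCV at n ≈ 200 —
optimized by bounded scalar search on log λ ∈ [−10, 14]; the REML score is
computed in the penalized-regression form and has been verified against the
dense mixed-model restricted likelihood.

The significance of the smooth is an approximate Wald test of the whole
term (linear part included) against the zero function, computed in
fitted-value space: f̂′V_f^{r−}f̂ with V_f the Bayesian covariance of the
fitted smooth, pseudo-inverse rank r = round(edf), referred to
F(r, n − edf_total). Under a null exposure effect the test rejects at close
to its nominal level (simulated rejection ≈ 0.05–0.06 at α = 0.05). Whether
the reference analysis tested smooths against zero or against linearity is
not documented; this package tests against zero and couples it with the
edf threshold, which together target the same "curvilinear" reading.

A pair is flagged when edf ≥ 1.5 **and** p < α (defaults 1.5 and 0.05). The
edf threshold defines "suggests curvature" — reference-reported non-linear
pairs had edf 1.70–1.91 — and is configurable. No multiplicity correction
is applied across the 154 tests by default, matching a plain α = 0.05
screen; a Benjamini–Hochberg option exists. Exposures enter the screen as
decile ranks (the scale every downstream model uses); raw-concentration
screening is a switch. All eleven outcomes receive identical treatment.

Flagged pairs are confirmed with a restricted cubic spline (Harrell's
truncated-power basis, linear beyond the boundary knots by construction).
Knots sit at the conventional quantiles — (0.10, 0.50, 0.90) for 3 knots,
(0.05, 0.35, 0.65, 0.95) for 4 (default), (0.05, 0.275, 0.50, 0.725, 0.95)
for 5; coincident knots are deduplicated and fewer than 3 survivors reject
the fit. The joint F-test of the k−2 non-linear coefficients gives
p_nonlinear, and the fitted curve is exported on a 100-point grid with
pointwise intervals.

The screen's product is the quadratic configuration: an outcome receives a
quadratic **essential**-index term when at least one essential metal is
flagged for it. The configuration is a pure function of the screen table.
Only the essential index is ever quadratic by screen decision (mirroring
the empirical pattern that toxic-metal dose-responses screen linear);
quadratic toxic terms can still be requested explicitly.

## Two-index WQS estimation

**Training objective.** For one bootstrap resample, the estimator minimizes
the profiled Gaussian negative log-likelihood plus a ridge penalty:

    F(w) = (n/2)·log RSS(w) + λ·Σᵢwᵢ²,   w on the simplex,

where RSS(w) is the residual sum of squares of `y ~ β₀ + β₁·(Qw) +
covariates` with β₀, the covariate coefficients, and |β₁| profiled out in
closed form and sign(β₁) constrained to the index direction. When the
unconstrained slope has the wrong sign the profile takes the boundary value
β₁ → 0; the two branches join continuously and differentiably at w′a = 0.
The penalty form is a deliberate interpretation: the reference analysis
states a "penalization term equal to 100" without a functional form, and an
L1 penalty is constant on the simplex, so the quadratic (ridge) form — whose
unique simplex minimum is the uniform weight vector — is the only
informative convex choice. λ is measured against the scale-free log-RSS fit
term, making the penalty invariant to outcome rescaling. Both the form and
λ = 100 (default) are configurable; λ → ∞ drives weights to uniform and
λ = 0 reproduces the unpenalized estimator exactly.

**Optimization.** Weights are parameterized by a softmax over m − 1 free
logits (last logit pinned at zero). Each training step runs three starts —
uniform, proportional to a marginal association prescreen, and random —
as one batched Adam pass (cosine-decayed learning rate, 150 steps by
default) across all bootstrap resamples simultaneously, followed by a
per-resample damped-Newton polish (finite-difference Hessian of the
analytic gradient) to gradient tolerance 1e−8·n. The polished solution has
been verified against a 1001-point profile-least-squares grid sweep of the
two-metal simplex (objective within 1e−6, weight within 0.02) and against a
0.01-step sweep of the three-metal simplex. Interpolating (zero-residual)
fits are treated as converged; a training step in which fewer than 10% of
bootstraps converge fails loudly.

**Aggregation.** Converged bootstrap weight vectors are averaged with
mixing proportions equal to their squared β₁ Wald statistics (a bootstrap
that found signal speaks louder), then renormalized. The reference analysis
does not state its aggregation rule; uniform averaging is available, and a
zero-signal situation (every bootstrap at the sign boundary) falls back to
uniform with a logged warning.

**Validation.** Both indices enter one OLS model on the held-out rows,
with squared index terms per the quadratic configuration and all
covariates. Quadratic terms appear in validation only: training stays
linear in the index because a sign constraint on β₁ alone does not
identify a direction for a quadratic training objective. Rank-deficient
validation designs are rejected with the offending column named;
validation sets smaller than `min_validation_n` (default 20) fail that
holdout.

**Repeated holdout.** Each of `n_holdout` (default 100) repetitions draws
a fresh simple-random 60/40 split (no stratification — none is specified
for the reference procedure), trains each index separately, and validates
jointly. Point estimates are means over holdout repetitions (median
optional) and 95% intervals are the 2.5/97.5 percentiles of the holdout
distribution; mean-Wald intervals are recorded alongside for comparison.
A term is significant when its percentile interval excludes zero (a
degenerate interval touching zero is not significant). Failed holdouts are
skipped and counted; more than 20% failures aborts with diagnostics.
Percentile intervals over correlated holdout estimates are conservative
for cohort-level sampling error — simulated type-I error of the toxic
index at n = 201 is ≈ 0.06 at the nominal 0.05 — which is the standard
behavior of repeated-holdout summaries, not a defect.

**Direction selection.** With `auto_aic` (default), every sign combination
of the auto indices is evaluated by a reduced repeated-holdout pre-pass
(default 20 holdouts × 20 bootstraps) and the combination with the lowest
mean validation AIC wins; the AIC table is kept in the fit provenance.
Selection happens once, before the full run — not per holdout, which would
mix directions within one summarized distribution. AIC ties within 1e−6
deterministically prefer the negative (adverse-effect) direction and are
logged.

## Determinism

Every stochastic stage consumes an explicit seed. Cohort generation spawns
independent substreams (exposures, creatinine, covariates, outcomes) from
one master seed; repeated holdout spawns one substream per holdout
(driving its split and its bootstrap resamples); the pipeline derives one
seed per outcome from the run seed. Identical configuration + seed gives
byte-identical report bundles.

## Problem sizes in the test suite

The statistical acceptance checks run at deliberately reduced repetition
counts (n_boot = 20, n_holdout = 20, against reference defaults of
100/100): type-I error over 200 null cohorts at the reference n = 201,
recovery and direction selection over 20 cohorts at n = 500, and screen
power over 100 seeds at n = 500. These sizes give stable Monte-Carlo
verdicts for the properties being checked while keeping the suite
routinely runnable; the estimator itself is identical at full settings.

## Known limitations

* The ridge interpretation of the weight penalty is the package's own
  reading of an under-specified procedure; results at λ = 100 shrink
  weights noticeably toward uniform, so weight *rankings* are more
  trustworthy than weight magnitudes.
* Gaussian outcomes only; no binomial/Poisson families, no survival or
  count outcomes, and no interaction between the two indices.
* Each index is trained with only its own index in the model; training
  with the other index frozen is a plausible alternative reading of
  "estimated separately" that is not implemented.
* The GAM smooth applies to the exposure only; covariates enter linearly,
  and no tensor/interaction smooths are provided.
* Maternal psychological distress was measured in the reference cohort but
  is absent from its adjustment set; it is likewise excluded here rather
  than guessed into the model.
* Complete-case handling is per outcome; no imputation is provided.
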