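# Methods

`trimtrack` analyses repeated complete-blood-count (CBC) measures through
pregnancy and their relation to postpartum hemorrhage (PPH).  Because
suitable clinical cohorts are access-restricted, the package pairs every
analysis stage with a synthetic-cohort generator whose true parameters are
known, so recovery, calibration and exactness can be verified end to end.

## Data model

Long-format records hold one row per blood draw per woman: gestational week
(0–42), the 14 CBC measures (ERY, HT, MCH, MCHC, MCV, HB, RDW, PLATE, MPV,
LEUC, EOSI, LYMPH, MONO, NEUT), maternal age, country-of-origin category,
delivery mode and postpartum blood loss in ml.  Weeks 0–13, 14–27 and 28–42
(inclusive integer bounds at both ends) define trimesters 1–3, coded
t = 0, 1, 2.  Draws within a trimester — including same-day draws — are
averaged arithmetically, giving each woman up to three repeated measures per
CBC variable.  PPH is a pure threshold: blood loss ≥ 500 ml after a vaginal
birth.  Cesarean deliveries and women without a blood-loss record are
excluded from outcome analyses but remain eligible for growth modelling;
growth modelling additionally requires at least one draw in every trimester.

## Synthetic cohort generator

Per woman *i* and measure *k* the generator draws a latent intercept/slope
pair (π0, π1) from a bivariate normal with mean (μ0, μ1) and covariance
Ψ = [[ψ00, ψ01], [ψ01, ψ11]], and emits, for each of `draws_per_trimester`
draws at integer weeks uniform within the trimester bin,

    Y_ij = π0 + π1 t_j + ε_ij,   ε_ij ~ N(0, θ_j),   t = (0, 1, 2).

Covariates shift the latent intercept: age (centred at its mean of 30.65
years, truncated normal SD 5 on [18, 48]) and a four-level origin category
with a 68% majority class; both effects are expressed in units of the
within-measure intercept SD so one default serves all measures.  The PPH
indicator is Bernoulli with logit equal to an intercept (default
logit(119/1012) ≈ −2.0, i.e. 11.8% prevalence when no measure contributes)
plus Σ_k γ_k·(trimester means of measure k).  By default the trimester
means entering the outcome are z-scored across the cohort so γ values are
log-odds per SD and comparable across measures; a raw-scale option exists
because either convention is defensible.  Recorded blood loss is drawn
conditionally on the PPH indicator (below/above 500 ml), so the downstream
threshold recovers the simulated outcome exactly.

Default per-measure means, variances and trends are stylized clinical
values, not reference ranges: the red-cell-index/platelet group (MCH, MCHC,
MCV, RDW, PLATE, MPV) carries non-zero slope variance ψ11 (women genuinely
differ in their trajectories) while the remaining measures have ψ11 = 0.
Default non-zero outcome coefficients are given to ERY, PLATE and MPV with
the sign pattern risk-increasing in trimester 1 and protective in
trimester 3.  What the generator deliberately omits: measures are
independent of one another given covariates (real CBC panels are strongly
cross-correlated), noise is Gaussian, trends are linear, and missingness is
driven only by observed age.  Passing tests therefore demonstrate
correctness of the estimators under the assumed model, not robustness to
real-data violations of it.

Missingness is injected missing-at-random: each measure cell is blanked
with probability proportional to a smooth function of the woman's observed
age, normalised to the requested marginal rate (≤ 0.15), and any column
whose realised fraction would exceed 15% has cells restored, so the cap
holds by construction.

## Growth model

For each measure the three trimester averages follow the random-coefficient
(latent growth) model Y = Λη + ε with Λ = [[1,0],[1,1],[1,2]],
η ~ N(A x, Ψ) where x holds an intercept and centred covariates (age,
origin dummies), and occasion-specific residuals ε_j ~ N(0, θ_j) (a
homoscedastic option constrains θ equal).  Estimation is maximum likelihood
under multivariate normality.  The mean regression A is profiled out in
closed form by generalised least squares at every objective evaluation, so
the optimisation runs over at most six variance parameters on sufficient
statistics and its cost is independent of sample size.  Variances are
parameterised on a log/Cholesky scale (Ψ positive semi-definite and θ ≥ 0
by construction); the response is standardized by its overall SD before
optimisation and estimates rescaled afterwards; a 1e-10 diagonal ridge on
the implied covariance keeps the objective bounded when θ → 0 (exactly
linear data).  L-BFGS-B with up to three jittered restarts is used;
solutions at an active bound are accepted when the projected gradient
vanishes.  Standard errors come from the observed information
(finite-difference Hessian) with the delta method mapping to the natural
parameters.

Variance decomposition: phenotypic variance is defined as the average over
t ∈ {0,1,2} of the model-implied occasion variance
ψ00 + t²ψ11 + 2tψ01 + θ_t.  Repeatability is ψ00 / phenotypic variance;
"change" is the slope share mean(t²)·ψ11 / phenotypic; the covariance share
mean(2t)·ψ01 / phenotypic and the residual share close the decomposition to
1 exactly.  Averaging occasion variances is a convention — no single
denominator is canonical for a model whose variance grows with t — and
repeatability figures depend on it.

Among-women slope variation is tested by a likelihood-ratio comparison of
the intercept-only model (ψ11 = ψ01 = 0) against the full model: LRT =
2·Δloglik on 2 df.  Because ψ11 sits on the boundary of its space, the
naive χ²₂ p-value is conservative; the 0.5·χ²₁ + 0.5·χ²₂ mixture p-value is
reported alongside, but the naive p drives the α = 0.001 significance flag,
matching common practice.

## Multiple imputation

Remaining variable-level gaps are filled by chained equations on the
per-woman wide matrix (imputing after trimester aggregation; imputing the
raw draws first would be the main alternative and is not implemented).
Each incomplete numeric variable is regressed on all others; coefficients
are drawn from their approximate posterior (normal around the
least-squares fit with a scaled-inverse-χ² residual-variance draw) before
predicting with added Gaussian noise; ten cycles are run and the whole
procedure repeated independently m = 3 times.  Categorical covariates are
never imputed — rows missing them are dropped with a logged count.
Downstream results are pooled by simple averaging (odds ratios on the log
scale); Rubin's-rules variance pooling is available but off by default, as
averaging is the convention the rest of the package follows.  No
predictive-mean matching and no multilevel imputation models.

## Bayesian path model

For one measure, three jointly specified equations relate the standardized
trimester values z1, z2, z3 and PPH:

    z2  = γ1 z1 + covariates + ε2
    z3  = γ2 z1 + γ3 z2 + covariates + ε3
    PPH ~ Bernoulli(logit⁻¹(γ4 z1 + γ5 z2 + γ6 z3 + covariates))

a recursive system whose coefficient matrix over (z1, z2, z3, PPH) is
strictly lower triangular.  γ4 is the baseline trimester-1 association; γ5
and γ6 are the trimester-2 and trimester-3 associations adjusted for all
earlier trimesters.  Covariate (age, origin) coefficients are per-equation
by default — the natural reading of a system in which each equation has its
own scale — with a `shared_covariates` option tying them across equations.
Priors are weakly informative: Normal(0, 10²) on standardized coefficients
and half-Cauchy(0, 5) on residual SDs.  Because predictors are standardized
internally, the reported odds ratios are per SD of the trimester value.

Sampling uses 3 chains of 2500 iterations with the first 1000 discarded.
The kernel is an independence Metropolis step from a multivariate-t
(df 7) proposal centred at the posterior mode with 1.2× the Laplace
covariance, interleaved every 20 iterations with a component-wise
random-walk sweep that keeps the kernel irreducible where the Laplace
approximation is poor.  For these near-Gaussian regression posteriors this
yields effective sample sizes in the thousands.  The contract is the
converged posterior, not the algorithm: split-R̂ and ESS are computed with
ArviZ and any R̂ > 1.05 raises an error.  With unshared covariates the
posterior factorises over equations and each is sampled separately; the
shared option samples the coupled system jointly.  An association is
flagged when the equal-tailed 95% credible interval of exp(γ) excludes 1.

## Prediction experiment

On the outcome-eligible cohort, each replicate removes a stratified holdout
of 200 women (25 PPH, 175 non-PPH), fits five Bayesian logistic models on
the remainder — baseline (age + origin), tri1/tri2/tri3 (baseline plus that
trimester's 14 CBC averages) and tracking (baseline plus all 42) — and
scores all five on the same held-out women, so the comparison is paired.
The baseline covariates are included in every model for comparability.
Coefficient priors are Normal(0, 2) — "variance two" read as variance, so
SD √2, configurable because the alternative reading (SD 2) is plausible.
Features are standardized with training-set statistics only.  Predicted
risk is the full posterior mean of the logistic link, not a plug-in at the
posterior-mean coefficients.  AUC uses the rank-sum (Mann–Whitney)
formulation with average ranks, so ties count one half; the experiment
reports each model's mean AUC across 10 replicates and the standard error
sample SD/√10 (no single SE definition is canonical for overlapping
training sets).

## Pipeline and reproducibility

`run_all` derives all stage seeds from one master seed via
`SeedSequence.spawn` in a fixed order (simulation, imputation, path,
prediction), runs every stage per measure over each completed dataset,
pools, and writes the variance-component table, the OR table, the AUC
summary and a manifest (versions, seeds, config hash — no timestamps), so
identical configurations produce byte-identical reports.  When the input
has no missing cells the m imputed copies would be identical, so a single
copy is analysed and the manifest records the effective m.

## Problem sizes used in the checks

Simulation-based checks follow the cohort scale throughout: n = 1457 for
growth-model recovery and the 500-replicate LRT calibration, n = 1012 with
~12% events for the 100-replicate credible-interval coverage study,
n = 5000 where a single dataset must pin parameters tightly, 50 mask
replicates for imputation, and 10 holdout replicates for prediction.  The
acceptance script runs the full 14-measure pipeline once at n = 1457 with
5% missingness and m = 3 imputations.

## Known limitations

Only linear growth over exactly three occasions is supported.  The
imputation model is a plain linear chained-equation scheme.  The path model
is per-measure; no multivariate (all measures jointly) extension.  Bayesian
credible intervals in the ~120-event logistic regime show mild frequentist
undercoverage (~0.92–0.95 observed for nominal 0.95), a known property of
weakly-informative-prior logistic inference at this event count, not a
sampler defect.  The generator's independence across measures makes the
"tracking" prediction advantage cleaner than it would be on real,
cross-correlated CBC panels.
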