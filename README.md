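# trimtrack

Repeated-measures analysis of complete-blood-count (CBC) trajectories
through pregnancy and their association with postpartum hemorrhage (PPH).

Blood counts change through pregnancy, and women differ both in their
starting values and in how their values change.  `trimtrack` is for
biostatisticians and perinatal epidemiologists who want to quantify those
individual differences from routine repeated CBC draws and relate them to a
delivery outcome.  It implements three linked analyses on per-woman
trimester averages (gestational weeks 0–13, 14–27, 28–42; t = 0, 1, 2):

1. **Latent growth model.**  For each measure, Y = Λη + ε with loadings
   Λ = [[1,0],[1,1],[1,2]], latent intercept/slope η ~ N(Aξ, Ψ) (covariates
   age and origin), and occasion residuals ε_j ~ N(0, θ_j), fit by maximum
   likelihood.  Phenotypic variance (the average model-implied occasion
   variance) is decomposed into *repeatability* ψ00/σ²_P, among-women
   *change* mean(t²)ψ11/σ²_P, an intercept–slope covariance share and a
   residual share; among-women slope variation is tested by a 2-df
   likelihood-ratio test at α = 0.001.
2. **Bayesian recursive path model.**  Jointly specified equations
   z2 = γ1 z1 + …, z3 = γ2 z1 + γ3 z2 + …, and
   PPH ~ Bernoulli(logit⁻¹(γ4 z1 + γ5 z2 + γ6 z3 + …)) with a strictly
   lower-triangular coefficient matrix, giving trimester-specific odds
   ratios per SD: γ4 at baseline, γ5 adjusted for trimester 1, γ6 adjusted
   for trimesters 1 and 2.  MCMC with 3 chains, 1000 burn-in of 2500
   iterations; associations flagged when the 95% credible interval of
   exp(γ) excludes 1.
3. **Held-out prediction.**  Ten stratified holdouts of 200 women (25 PPH /
   175 non-PPH); Bayesian logistic models with Normal(0, 2) priors —
   baseline (age + origin), one per trimester, and a "tracking" model using
   all three trimesters — compared by paired AUC.

PPH is blood loss ≥ 500 ml after vaginal birth; cesarean deliveries are
excluded from outcome analyses.  Missing values (≤ 15% per variable) are
multiply imputed by chained equations (m = 3) and results averaged.
Because suitable clinical cohorts are access-restricted, the package
includes a synthetic-cohort generator with the exact statistical structure
the analyses assume; every stage is validated against it.  See
`docs/methods.md` for models, conventions and limitations.

## Worked example

```bash
trimtrack simulate --n-women 800 --seed 42 --out cohort.csv
trimtrack growth cohort.csv --measure PLATE
```

```json
{
  "measure": "PLATE",
  "n": 800,
  "repeatability": 0.7141821415954762,
  "change": 0.15232139636540182,
  "cov": 0.007714247385217552,
  "residual": 0.12578221465390454,
  "phenotypic_variance": 3501.216957652949,
  "lrt": 82.46647719677276,
  "p_naive": 1.2377473515236207e-18,
  "slope_variation_significant": true
}
```

71% of platelet-count variance is attributable to stable among-women
differences (values are well correlated across trimesters) and 15% to
among-women differences in the *rate of change*; the likelihood-ratio test
rejects the model without slope variation decisively — as it should, since
the generator gives platelets a non-zero slope variance.

```bash
trimtrack path cohort.csv --measure PLATE --seed 7
```

```text
measure trimester    log_or       or    lower    upper  associated
  PLATE      tri1  0.167771 1.182666 0.831190 1.689047       False
  PLATE      tri2  0.350810 1.420217 0.925508 2.253795       False
  PLATE      tri3 -0.412484 0.662003 0.442683 0.976345        True
```

Higher third-trimester platelet counts (adjusted for trimesters 1 and 2)
are protective here — OR 0.66 per SD with a 95% credible interval excluding
1 — matching the generator's built-in effect (true trimester-3 OR 0.85,
trimester-1 OR 1.20, at n = 800 only the larger adjusted effect reaches the
flag).  Other subcommands: `validate`, `impute`, `predict`, and `run-all`
(full pipeline from a YAML config; identical master seeds give
byte-identical reports).

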