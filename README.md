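# mrkit

Two-sample and multivariable Mendelian randomization (MR) from GWAS summary
statistics, with Bayesian model averaging for risk-factor prioritization.

`mrkit` is aimed at genetic epidemiologists who want to estimate the causal
effects of one or more heritable risk factors (e.g. lipid fractions, BMI,
smoking, years of schooling) on a disease outcome such as Alzheimer's
disease, using only published per-SNP association results. The package
covers the whole workflow: instrument selection, allele harmonization,
estimation, pleiotropy and directionality diagnostics, and risk-factor
ranking — plus a fully specified synthetic-data generator so every stage
can be validated against a known causal truth.

## The model

For SNP *j* and exposure *k*, let β̂_Xjk (SE σ_Xjk) be the per-allele effect
on the exposure and β̂_Yj (SE σ_Yj) the effect on the outcome. Under the
instrumental-variable assumptions, the structural model is

    β_Yj = Σ_k θ_k β_Xjk + α_j ,

where θ_k is the causal effect of exposure k and α_j (ideally 0) is a
direct, pleiotropic effect on the outcome. The estimators:

- **IVW fixed effects** — θ̂ = Σ_j w_j β̂_Xj β̂_Yj / Σ_j w_j β̂_Xj², with
  w_j = σ_Yj⁻²; equivalently weighted least squares of β̂_Y on β̂_X
  through the origin.
- **Maximum likelihood** — profile likelihood of the joint normal model
  β̂_Xj ~ N(ξ_j, σ_Xj²), β̂_Yj ~ N(θ ξ_j, σ_Yj²), which also accounts for
  exposure-side sampling error.
- **Weighted median** — the 50th weighted percentile of the per-SNP ratios
  β̂_Yj/β̂_Xj; consistent when ≥50 % of the weight comes from valid
  instruments. SE by parametric bootstrap.
- **MR-Egger** — weighted regression with a free intercept; a nonzero
  intercept estimates directional pleiotropy.
- **Multivariable IVW** — θ̂ = (XᵀWX)⁻¹XᵀWy with X the J×K exposure-beta
  matrix, isolating each factor's direct effect.
- **MR-BMA** — every subset γ of exposures is scored by a closed-form
  Gaussian marginal likelihood on the σ_Y-standardized scale, combined with
  a Bernoulli inclusion prior; factors are ranked by marginal inclusion
  probability (MIP) and summarized by the model-averaged causal estimate
  (MACE).
- **Steiger test** — compares instrument variance explained, recovered from
  the association statistics as r² = t²/(t² + n − 2), between exposure and
  outcome to orient the causal direction.

For a binary outcome, effects are log-odds ratios and every estimate is
also reported as an odds ratio with a normal 95 % CI.

## Worked example

Simulate a three-exposure study (true effects θ = 0.25, −0.25, 0) and run
the univariable estimators, the Steiger test, and MR-BMA:

```bash
$ mrkit simulate --n-snps 200 --n-exposures 3 --seed 11 --outdir sim
wrote 3 exposure tables + outcome + truth to sim/

$ mrkit mr sim/exposure_1.tsv sim/outcome.tsv --seed 11
IVW fixed effects     nsnp=199  OR=1.327 (1.289-1.367)  p=6.735e-81
Maximum likelihood    nsnp=199  OR=1.343 (1.303-1.384)  p=1.382e-81
Weighted median       nsnp=199  OR=1.33 (1.262-1.401)   p=1.451e-26

$ mrkit steiger sim/exposure_1.tsv sim/outcome.tsv
r2.exposure=0.06099  r2.outcome=0.01163  correct_direction=True  p=2.01e-245

$ mrkit bma sim/exposure_1.tsv sim/exposure_2.tsv sim/exposure_3.tsv \
      --outcome sim/outcome.tsv
1  exposure_1  MIP=1.000  MACE=0.2619
2  exposure_2  MIP=1.000  MACE=-0.2207
3  exposure_3  MIP=0.007  MACE=-4.391e-05
```

Reading the output: the first exposure's odds ratio per SD, ~1.33, matches
its generating effect (e^0.25 ≈ 1.28 plus sampling noise); the Steiger test
confirms the instruments explain far more variance in the exposure than in
the outcome, so the assumed direction is supported; and MR-BMA gives the
two truly causal factors marginal inclusion probabilities of 1.0 while the
null factor drops to 0.007, with model-averaged estimates close to the
generating ±0.25.

The same analyses run from Python (`mrkit.simulate_dataset`,
`mrkit.harmonize`, `mrkit.ivw_fixed_effects`, `mrkit.mvmr_ivw`,
`mrkit.run_bma`, ...), and `mrkit run-all config.yaml` executes the whole
pipeline — selection, harmonization, all estimators, Egger, bi-directional
MR, Steiger, multivariable IVW and BMA — writing one TSV per stage plus a
structured run log.

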