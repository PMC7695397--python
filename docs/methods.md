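# Methods

This note records the statistical model behind `mrkit`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Structural model and estimators

All analyses consume harmonized summary statistics: for SNP *j* (J
instruments, assumed mutually independent after LD pruning) and exposure
*k* (K exposures), the observed effects are

    β̂_Xjk ~ N(b_jk, σ_Xjk²),   β̂_Yj ~ N(Σ_k θ_k b_jk + α_j, σ_Yj²),

with θ the causal effects of the exposures on the outcome and α_j a direct
(pleiotropic) SNP–outcome effect that violates the exclusion restriction
when nonzero.

**IVW fixed effects.** θ̂ = Σ w_j β̂_Xj β̂_Yj / Σ w_j β̂_Xj², w_j = σ_Yj⁻²,
se = (Σ w_j β̂_Xj²)^(−1/2). This treats β̂_X as known (the NOME
approximation) and assumes no overdispersion. A multiplicative
random-effects variant (`ivw(..., random_effects=True)`) scales the SE by
√(Q/(J−1)) floored at 1, where Q is Cochran's heterogeneity statistic.

**Maximum likelihood.** The per-SNP true exposure effects ξ_j are profiled
out analytically, leaving the scalar profile log-likelihood
−½ Σ (β̂_Yj − θβ̂_Xj)²/(σ_Yj² + θ²σ_Xj²), maximised by Newton iteration
from the IVW start. The SE is the inverse square root of the numerical
curvature at the optimum. Convergence requires |gradient| ≤ 1e−8 (or a
Newton step below machine precision, which is the same stationarity
statement up to floating-point resolution); failure raises rather than
returning a dubious estimate. Unlike IVW, this estimator is not attenuated
by exposure-side sampling error.

**Weighted median.** Per-SNP ratios θ_j = β̂_Yj/β̂_Xj with normalized
weights w_j ∝ β̂_Xj²/σ_Yj² (the inverse ratio variance under NOME). With
ratios sorted and breakpoints p_j = S_j − w_j/2 (S_j the cumulative
weight), the estimate interpolates θ against p at p = 0.5; outside the
breakpoint range the nearest ratio is returned. SNPs with β̂_X exactly 0
are excluded (their ratio is undefined) with a warning. The SE is the
standard deviation of the estimate over parametric resamples of
(β̂_X, β̂_Y) from their reported sampling distributions — 1000 resamples
by default, always seeded. The bootstrap was chosen over the original
estimator's percentile method because it propagates exposure-side error
with no extra assumptions.

**MR-Egger.** SNPs are first re-signed so β̂_Xj ≥ 0, then β̂_Y is
regressed on β̂_X with an unconstrained intercept, weights σ_Yj⁻².
Intercept and slope p-values use t with J−2 degrees of freedom. When the
fit is numerically exact (weighted residual sum of squares below 1e−24 of
the response scale) the intercept t-statistic is 0/0 rounding noise, so
the intercept p is reported as 1.

**Multivariable IVW.** θ̂ = (XᵀWX)⁻¹XᵀWy with X the J×K matrix of
exposure betas (no intercept), W = diag(σ_Y⁻²); covariance (XᵀWX)⁻¹. A
SNP missing from one exposure enters with beta 0 and weight-zero SE (+inf
marker), the convention that an instrument need only associate with at
least one factor. Rank deficiency — smallest singular value of W^½X below
1e−10 of the largest — is fatal and names the collinear exposures, because
silently regularizing algebraically related exposures (e.g. HDL/LDL/total
cholesterol) would misattribute effects. The smallest singular value is
always exposed as a conditioning diagnostic. `residual_scale=True`
multiplies the covariance by the residual mean square (floored at 1); this
is the variant to use when exposure-side noise or pleiotropy is
non-negligible, since the fixed-effects SEs then undercover (see
"Calibration" below).

**MR-BMA.** On the standardized scale ỹ_j = β̂_Yj/σ_Yj,
X̃_jk = β̂_Xjk/σ_Yj the residual variance is 1, and each factor subset γ
is scored by the closed-form marginal likelihood of ỹ under
θ_γ ~ N(0, σ_prior² I) with no intercept — a Gaussian effect prior
parameterized directly by the prior effect SD, evaluated via the matrix
determinant lemma and Woodbury identity so only |γ|×|γ| systems are
solved. Model posterior: PP(γ) ∝ p^|γ|(1−p)^(K−|γ|) · m(ỹ|γ), normalized
over the enumerated models. MIP_k = Σ_{γ∋k} PP(γ);
MACE_k = Σ_γ PP(γ)·θ̂_kγ with θ̂_kγ the posterior-mean effect (0 when
k ∉ γ). Defaults p = 0.1 (sparsity: few factors are truly causal) and
σ_prior = 0.25, the originating method's published values; both are echoed
in every output because MIPs are prior-sensitive. Exact enumeration of all
nonempty subsets is the default up to K = 20 (511 models at K = 9); the
stochastic mode runs a seeded Metropolis add/remove/swap walk, scores each
distinct model once, and renormalizes over the visited set, so at small K
with enough iterations it coincides with exact enumeration. Rank-deficient
subsets get zero posterior weight and a log entry.

**Steiger directionality.** Per-SNP variance explained is recovered from
the association statistic, r_j² = t_j²/(t_j² + n − 2), and summed over
instruments per trait; this needs no allele frequency and applies
(approximately, on the observed scale) to binary traits. The alternative
2β̂²·MAF(1−MAF) formula for standardized continuous traits is available
via `method="maf"`. The p-value compares the aggregate correlations √r²
through Fisher's z with the two GWAS treated as independent cohorts. The
log p-value is carried exactly; table output prints underflowed values as
"<1e-300" rather than 0. A summed r² ≥ 1 is fatal — it means the
instruments are not independent or the inputs are corrupt.

## Harmonization

The first exposure table holding a SNP defines the reference orientation;
every other record is aligned to it: exact allele match → keep; swapped
alleles → negate beta, eaf → 1−eaf; complementary-strand pair → complement
then re-compare (attempted before declaring incompatibility, so records
are kept "where possible"); incompatible pairs → drop. Palindromic SNPs
(A/T, C/G) are aligned nominally by allele labels and then checked against
the effect-allele frequencies: frequencies on opposite sides of 0.5 flip
the sign; either frequency inside the ambiguity window, or missing, drops
the SNP. The window default (0.42, 0.58) is the de-facto community
default — the underlying workflow description says only that allele
frequency infers the strand — and is exposed as a parameter because it is
a genuine sensitivity knob. Every SNP carries exactly one action tag
(kept-as-is / sign-flipped / strand-complemented / palindromic-aligned /
dropped+reason), making harmonization idempotent and fully auditable.

Proxy search (`find_proxies`) is off by default and purely local: it needs
a user-supplied r² table and returns the highest-r² candidate at
r² ≥ 0.8, ties broken by smaller p then lexicographic ID. No remote LD
service is ever queried.

## Instrument selection

Candidates at p < 5e−8 are clumped greedily best-p-first at r² ≤ 0.001
(both thresholds exposed); within any correlated pair the SNP with the
smaller p survives, and best-p-first is the unique order-independent
reading of that rule. Ties break lexicographically so output is invariant
to row order. Missing LD pairs count as r² = 0, matching the
post-pruning independence convention. Both per-exposure clumping (the
default) and pooled clumping across all exposures' candidates are
provided, since workflows differ on whether pruning is done within or
across traits.

## Synthetic data: what it emulates, what it does not

`simulate_dataset` reproduces the structure of a multi-consortium
two-sample MR study: J independent SNPs, true SNP–exposure effects drawn
from a zero-mean multivariate normal with configurable scale and
cross-exposure correlation, outcome effects from the structural model with
optional pleiotropy α_j ~ N(mean, sd²) on a configurable fraction of SNPs,
and observed effects with SE = 1/√(2·MAF·(1−MAF)·n) — the standardized-
trait GWAS standard error, which keeps the generator closed-form. A
configurable fraction of SNPs are decoys (zero true effect) that the
significance filter must remove; fractions of records are emitted
palindromic and/or allele-swapped to exercise harmonization. One master
seed spawns independent per-trait streams, so outputs are byte-identical
across runs and adding an exposure does not perturb the others.

Defaults emulate a nine-risk-factor Alzheimer's-type study: K = 9
exposures with two truly causal effects (±0.25 on the log-odds scale),
exposure GWAS of 2×10⁵, outcome GWAS of 74 046, MAF uniform on
(0.05, 0.45), 20 % palindromic SNPs, 10 % swapped records, 30 % decoys.

Not emulated: LD between SNPs (the estimators are applied after pruning to
near-independence, and that is the regime simulated), case-control
ascertainment, winner's-curse selection of instruments, sample overlap
between the two GWAS, and population stratification. Passing tests
therefore certify the estimators and pipeline under the model's own
assumptions, not robustness to those real-data pathologies.

Because every SNP draws effects on all K exposures, instruments are shared
across factors — precisely the regime multivariable MR and MR-BMA are
built for. A corollary visible in pipeline output: univariable IVW on a
null factor can reject too often there, because the other factors' effects
act as correlated pleiotropy; the joint fit isolates direct effects
correctly. This is a feature of the generator, not a bug of the tests.

## Calibration choices in the validation suite

- Parameter recovery (K = 3, θ = (0.5, −0.2, 0), J = 200, n = 10⁵, 500
  replicates) uses per-SNP effect scale 0.5 so instruments are strong and
  weak-instrument attenuation (of order se_X²/scale²) is negligible
  against Monte-Carlo error. Coverage is assessed with the residual-scaled
  covariance: at these sample sizes the exposure-side noise contributes
  θ²σ_X² to the residual variance, which fixed-effects SEs ignore
  (observed coverage ≈ 91 %); the residual-scaled variant absorbs it and
  restores ≈ 95 %.
- Type-I error (1000 replicates, J = 50) uses balanced pleiotropy with
  sd 0.001 against an outcome SE of ≈ 0.006: the weak-pleiotropy regime in
  which fixed-effects tests remain nominally calibrated (large balanced
  pleiotropy inflates fixed-effects test sizes by construction; the
  random-effects variants exist for that case).
- MR-BMA validation: exact enumeration is compared to an independent
  brute force that evaluates each subset's dense J×J Gaussian marginal
  directly; ranking recovery uses 2 causal factors of 9, J = 150, 100
  replicates.
- Problem sizes throughout (J of 50–450, replicate counts of 100–1000)
  were chosen so each check is statistically decisive — binomial 99 %
  bounds for size, ±2 % bands for coverage — while the whole suite runs in
  well under a minute.

## Numerical details

- 95 % CIs use the normal multiplier 1.959964 throughout; Egger p-values
  use t(J−2), IVW/ML/multivariable use the normal.
- Profile-likelihood Newton steps are damped to |step| ≤ 1 + |θ| and fall
  back to gradient ascent if the local curvature is not negative.
- BMA posterior normalization goes through log-sum-exp; MIPs are clipped
  to [0, 1] against float-summation overshoot.
- TSV output writes floats via `repr` (shortest round-trip form) and reads
  them back with round-trip precision, so write→read is exact; missing
  optional fields are empty cells, never 0.
- P-values are floored at the smallest positive double on simulation
  output; Steiger p-values are additionally carried in log space.

## Known limitations

- No LD-aware estimation: a correlated-instrument mode (block-LD
  simulation and generalized weighted least squares with an LD matrix) is
  deliberately out of scope.
- The weighted-median bootstrap ignores correlation between β̂_X and β̂_Y
  induced by sample overlap (the two-sample design assumes none).
- Binary-trait variance explained in the Steiger test is an
  observed-scale approximation; comparisons against liability-scale
  figures need care.
- MR-BMA p-value calibration by permutation is not implemented; MIPs and
  PPs are reported as posterior quantities under the stated prior only.
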