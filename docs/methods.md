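# Methods

## Model

The package analyses a longitudinal outcome measured on `n` unrelated
subjects at a handful of occasions with the random-intercept-and-slope
linear mixed model

    y_ij = x_ij' β + b_0i + b_1i t_ij + ε_ij,
    (b_0i, b_1i)' ~ N(0, D),   ε_ij ~ N(0, σ²),  independent across i and j,

where the fixed-effect row `x_ij` contains an intercept, time, optional
covariates and — in the full (per-SNP) model — the dosage `s_i` and its
product with time.  Assumptions baked in: a linear time trend per subject,
homoscedastic independent measurement errors (`Σ_i = σ² I`), independent
subjects (no kinship), and two-dimensional random effects.  None of these
are relaxed; crossed or higher-dimensional random effects, serial
correlation and relatedness are out of scope.

## Estimation

**Variance components.** `LongitudinalLMM.fit()` maximizes the REML
likelihood, profiling both `β` (GLS) and `σ²` analytically and optimizing
only the three log-Cholesky parameters of `A = D/σ²`.  Every evaluation
needs only per-subject 2×2 sufficient statistics (`S_i = Z_i'W_iZ_i`,
`R_i = Z_i'W_iX_i`, `r_i = Z_i'W_iy_i`, plus the global cross-products),
via the Woodbury identity `(I + Z_iAZ_i')⁻¹ = I − Z_iA(I + S_iA)⁻¹Z_i'`
and `|I + Z_iAZ_i'| = |I + S_iA|`, so one fit is O(n) with small
constants.  REML (not ML) matches the convention of the standard
mixed-model packages this estimator is validated against; the test suite
requires agreement with an independent implementation (statsmodels
`MixedLM`) to 1e-4 relative.

The optimizer is Nelder-Mead with multiple starts — a method-of-moments
seed built from per-subject OLS lines plus two fixed fallbacks — because
the profiled surface can have a boundary-trapped local optimum in which
the weakly identified intercept variance collapses to zero; the best probe
is polished with a fresh simplex (`xatol` 1e-8, `fatol` 1e-9; the
criterion itself is flat to ~1e-9 near the optimum, so tighter tolerances
cannot be met).  A fit whose `D̂` lands numerically on the boundary of the
positive-definite cone is flagged (`boundary`), optionally raised, and
given a minimal ridge so downstream scoring stays defined.

**Per-SNP scoring.** With `(D̂, σ̂²)` frozen at the SNP-free fit, joint
estimation of fixed and random effects is the penalized least-squares
(Henderson) system with per-subject penalty `P* = (D̂/σ̂²)⁻¹`.  The
per-subject rotation `Φ_i = Ω_i^{-1/2}U_i'` (eigendecomposition of
`S_i + P*`) whitens the random-effect block; eigenvalues are taken
ascending and eigenvector signs are unconstrained — all downstream
quantities are invariant to the convention, and a test asserts exactly
that rather than pinning a convention.  Subjects with a single
observation are retained: `S_i` is singular but `S_i + P*` is PD.

Adding a SNP borders the system with the two columns `s_i Z_i`.  Block
elimination of the (factorized-once) core leaves, per SNP,

    C = Σ s_i² F_i − a M⁻¹ a',  a = Σ s_i E_i,  c = Σ s_i g_i,
    β_SNP = C⁻¹ c,  SE = σ̂ √diag(C⁻¹),

with reduced-model features `E_i = R_i − K_i'Ã_i`, `F_i = S_i − K_i'K_i`,
`g_i = r_i − R_iβ* − K_i'θ_i` (`K_i = Φ_iS_i`, `Ã_i = Φ_iR_i`).  A block
of m SNPs is two matrix products (weights `s` and `s²`) against an
n×(2p+6) feature table; peak scratch memory is one n×m buffer (for `s²`),
never the O(n·k·m) row expansion.  The identity with the dense weighted
Henderson solve of the full model is exact algebra; the test suite holds
it to 1e-8 relative (observed ~1e-12) and uses the dense solve as the
oracle everywhere.

**Inference.** Wald tests against the standard normal: `z = β/SE`,
`p = 2(1 − Φ(|z|))`.  At GWAS sample sizes the normal and the t reference
are indistinguishable, and the refit comparator in the accuracy study uses
the same convention so the comparison isolates the variance-component
approximation.  −log₁₀ p is computed through the scaled complementary
error function so statistics with |z| ≳ 38 (where the p-value itself
underflows) remain finite.

**What the approximation costs.** Omitting a SNP with effects (β₂, β₃)
inflates the reduced model's random-effect covariance by
`var(s)·(β₂,β₃)'(β₂,β₃)` (`predict_variance_inflation`; verified by
simulation).  Scores are therefore exact under the null and conservative
— never anti-conservative beyond Monte-Carlo noise — for strong effects;
the accuracy study quantifies the gap and calibrates the scan threshold
needed to capture every refit-significant SNP.

## Missing data

Phenotype rows with a missing outcome, time or covariate get weight 0,
which replaces the row by zeros in every cross-product — algebraically
identical to deleting it.  Segment sums are computed as cumulative-sum
differences (a strictly sequential scan) so zero-weighted and deleted rows
give bit-identical estimates, not merely close ones; subjects with no
valid rows are dropped.  A strict mode errors instead.  Missing dosages
are mean-imputed per SNP (flagged) or the SNP is skipped; SNPs with
dosage variance below 1e-8 are flagged monomorphic, and any SNP whose 2×2
system has condition number above 1e12 is returned as NA with a status
rather than a number.

## Synthetic data

`SimulationConfig` defaults define the reference study design: n = 2000
subjects, k = 4 occasions at times uniform on (0, 10), q = 3 independent
time-varying covariates ~ N(2, 0.5²) (0.5 read as an SD; switchable to a
variance), fixed intercept −2.6 and slope −1.9, covariate coefficients
drawn once per dataset from N(0, 1), D = [[1, −0.2], [−0.2, 1]], error SD
σ = 2.5, and continuous dosages uniform on (0, 2) (imputed-genotype
convention; a Binomial(2, maf) hard-call law is available).  In the
accuracy study the cross-sectional and longitudinal effect sizes each
take `n_replicates` equally spaced values on [0, 1], paired by two
independent random permutations, one SNP per dataset.  MCAR missingness
can be injected at a given rate.

The generator reproduces the stated moments (tested) but deliberately
omits linkage disequilibrium, population structure, informative
missingness and non-linear trends: green tests certify the algebra and
calibration under the model's own assumptions, not robustness to their
violation.

## Accuracy study

`run_accuracy_study` simulates one dataset per grid point, scores its SNP
with the fast scan and with a full REML refit of the SNP model (the
"in-doubt" exact analysis; refit non-convergence is recorded and the
point excluded), and reports paired estimates, SEs and −log₁₀ p, the
threshold calibration τ (the smallest fast-scan −log₁₀ p among points
whose refit exceeds a cut, default 7.3), and R² accounting with
R² = 1 − ‖y−ŷ‖²/‖y−ȳ‖².

Two R² conventions are recorded.  With mixed-model fitted values
(fixed effects + BLUPs, the `lmer fitted()` convention) the full/reduced
difference is ~1e-4 at most: a subject-constant SNP effect lies in the
span of each subject's `[1, t]`, so the reduced model's random effects
absorb it almost entirely.  The headline "SNP contribution to R²"
therefore uses fixed-effects-only fitted values (the marginal R², the
variance the SNP terms explain beyond the other fixed effects), which is
the quantity that actually moves along the effect grid — up to ~24% at
the top of the default grid, where the SNP-by-time term `β₃ t s` rivals
the random-slope variance.  `AccuracyReport.max_r2_contribution()`
exposes both via the `marginal` flag.

## Problem sizes and numerical choices

The package's own validation runs at deliberate scales: the dense-oracle
equivalence at n = 500 with 200 SNPs; null calibration on 5000 SNPs at
n = 1000 (type-I error within the 99% binomial band at α = 0.05, and
Kolmogorov–Smirnov uniformity of null p-values); the scan-vs-refit study
at the full n = 2000 design with 120 replicates in the test suite and the
complete 200 in `scripts/acceptance.py`; variance-component recovery over
50 null replicates.  Tolerances: 1e-10 for the rotation identity, 1e-8
relative for all solver equivalences, exact equality for
zero-weight-vs-deletion, Monte-Carlo bands elsewhere.  Reproducibility:
every stochastic routine takes a seed or `numpy.random.Generator`;
replicate streams come from `SeedSequence.spawn`, and identical inputs
yield byte-identical result files.

## Known limitations

- Variance components are estimated once; for SNPs with very large
  effects the scan's SEs are inflated and its p-values pessimistic (by
  design — rescreen top hits with the built-in refit, `--oracle`).
- The REML estimate of the intercept variance `D₀₀` is weakly identified
  at k = 4 with σ²/D₀₀ ≈ 6: its per-dataset sampling SD is large (~0.25
  on a true value of 1 in the reference design) with a long left tail
  (individual datasets can legitimately have their REML optimum near
  0.3), so replicate averages of `D̂₀₀` wander far more than the other
  components; slope-variance, covariance and σ estimates are tightly
  recovered.
- Wald/normal inference only; no score or likelihood-ratio tests, no
  small-sample df corrections.
- Dosage coding is additive; dominance and multi-allelic codings are not
  supported.
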