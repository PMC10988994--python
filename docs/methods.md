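# Methods

## Problem and estimands

The package estimates two per-person annual quantities for a binary disease
exposure (the motivating case is site-specific cancer): the causal effect
on total health care costs (GBP/year) and on QALYs. QALY effects are
reported ×100, as percentage points of a QALY per year; they are averages
over follow-up, not cumulative totals. These feed a cost-effectiveness
simulation of a hypothetical population-wide preventative drug against a
do-nothing comparator.

## Instrumented estimation

A polygenic risk score is the single excluded instrument for the disease in
just-identified two-stage least squares. The coefficient is computed by the
IV closed form `(Z'X)⁻¹Z'y` (identical to the two-stage projection in the
just-identified case), with `Z = [1, PRS, C]` and `X = [1, disease, C]`.
Interpretation follows the additive structural mean model: a constant
average effect of the disease on each outcome.

Numerical and inferential choices:

- **Robust covariance.** HC1 sandwich
  `(Z'X)⁻¹ Z'diag(e²)Z (X'Z)⁻¹ · n/(n−k)` where `e` are second-stage
  residuals formed with the *observed* exposure. No generated-regressor
  correction beyond the IV sandwich is applied; with a binary exposure and
  a strong instrument this is the standard treatment.
- **First-stage F.** The squared HC1 t-ratio of the instrument in the
  stage-1 regression (single instrument, so robust F = t²).
- **Default covariates.** Age, sex, the cohort's principal components
  (synthetic default 10) and recruitment-centre indicators (one-hot, first
  level dropped). Sex is dropped automatically inside single-sex strata.
- **Degenerate input handling.** Zero-variance instruments, rank-deficient
  designs and non-finite outcomes raise immediately rather than returning
  NaN estimates.
- **PRS weighting.** Default scheme `beta` (weights are the GWAS log-odds
  ratios) — the convention under which 2SLS with a PRS instrument is the
  usual PRS-MR estimator. A `precision` scheme (`β/se²`) is available for
  users who read "weighted by precision" literally. Scores are left
  unstandardised: just-identified 2SLS point estimates and SEs are
  invariant to affine instrument rescaling (verified to 1e-9 relative in
  tests), so standardisation is cosmetic.
- **Harmonisation.** Weight tables and dosage columns are matched on
  variant id; an opposite effect/other orientation recodes dosage
  `d → 2−d`. Strand-ambiguous (A/T, C/G) variants are accepted unchanged
  but logged — strand cannot be resolved from a weight table alone.

The Hausman endogeneity test contrasts 2SLS with multivariable OLS:
`(β_iv − β_ols)²/(se_iv² − se_ols²)` on χ²(1). With robust SEs the variance
difference can be non-positive in finite samples; it is then clamped to
statistic 0 (p = 1) with a warning. Simulation at the default study
conditions shows type-I error compatible with 0.05 and power above 0.5
against strong confounding at n = 20,000.

**Per-variant sensitivity analysis.** Exposure and outcome are regressed on
each variant's dosage plus covariates (computed by Frisch–Waugh
residualisation, one vectorised pass); Wald ratios use first-order
delta-method SEs `se_out/|β_exp|`, ignoring first-stage uncertainty — the
standard two-sample convention. Pooling is fixed-effect IVW; heterogeneity
is Cochran's Q on χ²(n−1). Variants whose exposure association is below
1e-12 are excluded with a warning. An MR-Egger intercept regression is
provided as an optional extra; it is not part of the default pipeline
because directional-pleiotropy testing with 10–20 variants is
underpowered.

**Missing costs.** Primary-care-style missingness is handled by a simple
noise-injected regression imputation: a linear model of observed costs on
covariates and disease status predicts the missing values, plus residuals
resampled with replacement; m completed sets are analysed and pooled by
Rubin's rules (`W + (1+1/m)B`). This is deliberately lighter than full
chained-equations imputation; it is proper enough for the MAR mechanism
the generator produces (missingness depends on centre only, and centre is
in the imputation model).

## Synthetic cohort generator

The generator emulates the data structure the estimators assume, not any
particular population:

- **Genotypes.** Independent biallelic variants, dosages Binomial(2, f).
  No linkage disequilibrium — deliberately, so per-variant analyses have a
  clean null.
- **Liability.** `L = Gβ + c_L·U + Logistic(0,1)` with `U ~ N(0,1)` a
  latent confounder. Logistic noise makes each `β_j` a genuine per-allele
  log-odds ratio, matching GWAS effect-size semantics. Disease is `L`
  above the *empirical* within-sample quantile for the target prevalence
  (analytic thresholds drift at small n; the empirical quantile keeps
  realised prevalence on target, within 0.5 pp at n = 10⁵ by test). For
  sex-specific cancers the threshold is taken within the eligible sex and
  the other sex is always unaffected.
- **Costs.** Linear age/sex baseline + true effect ×disease + confounder
  loading + lognormal(σ = 1) noise scaled to a target SD, truncated at
  zero. The lognormal tail reproduces the right skew of annual cost data
  (median well below mean) without modelling hospital coding.
- **QALYs.** Linear age baseline − |effect|×disease + confounder loading +
  Gaussian noise, clamped to [0, 1].
- **Missingness.** Bernoulli per person with centre-specific rates
  spanning [0.5, 1.5]× the target rate — missing at random given centre,
  mirroring linkage-driven missingness of primary-care data.
- **Weight tables.** Observed GWAS betas are the true log-ORs plus normal
  noise at per-variant SEs drawn from `gwas_se_range`, so instrument
  weights carry realistic estimation error.

Default study conditions (chosen once): 20 variants with per-allele
log-ORs 0.10–0.20 and frequencies 0.10–0.50 (≈5% of liability variance; a
strong-PRS cancer), prevalence 4.3%, true effects +£800/year on costs and
−5 QALY percentage points/year, confounder loadings (0.5, £400, −0.04),
cost noise SD £1,200 (median total cost lands near £600–£800), QALY noise
SD 0.15 (median ≈0.78), sex ratio 46.3% male, 8 centres, 10 PCs, follow-up
≈ N(8.1, 0.8) years. Missingness defaults to zero and is switched on
(0.3–0.62) where imputation is exercised.

What passing tests on this generator do **not** show about real data: no
LD, no age-dependent incidence, no survival/censoring process, no
cost–QALY dependence beyond the shared confounder and disease, and
population structure only via exchangeable PCs. The estimators' robustness
to those features is untested here by design.

## Intervention simulation

Per draw: log-OR ~ N(ln OR, (ln U − ln L)/3.92); baseline proportion ~
N(p, √(p(1−p)/N)) truncated to (0,1) and rescaled to counts; risk
difference `RD = nOR/(N−n+nOR) − n/N` from the drawn values; cost and QALY
effects ~ N(point, CI-width/3.92), drawn independently (no correlation is
specified for them). Then `ΔCost = price + RD×cost`, `ΔQALY = RD×qaly`
(percentage points; positive when preventing disease raises QALYs),
`NMB = λ·ΔQALY/100 − ΔCost`. Medians and 2.5/97.5 percentiles summarise
the draws. Because NMB draws translate one-for-one with price, the
break-even annual price is `price + median NMB`; the implementation
re-runs at that price and verifies |median NMB| ≤ £1. Costs and QALYs are
not discounted; effects are per average year of follow-up.

Design choices worth flagging:

- The binomial SE uses the square root, `√(p(1−p)/N)`; the formula is
  sometimes typeset without it, which yields absurd magnitudes.
- OR uncertainty is drawn on the log scale by default so draws stay
  positive; natural-scale drawing is available (`or_scale="natural"`).
- The "all" scenario uses overall counts, not an aggregate of age-band
  runs.
- The drug price is carried at full precision (£470.40/year from
  £39.20×12) and rounded only for display.

**Known divergence.** With the published prostate inputs the deterministic
point-estimate oracle is NMB ≈ −£450 (RD −3.0% × £134 ⇒ −£4.0/year of
cost offset, × −2.68 pp ⇒ +0.080 pp of QALYs). The simulation's published
medians (total cost £463.45, QALY +0.13 pp, NMB −£438, break-even ≈£32)
sit a few pounds away from both the oracle and this implementation's
medians (≈£466.8, +0.08 pp, −£451, break-even ≈£19 at seed 1), because the
median of a product of noisy draws is scheme-dependent and the exact
published draw scheme is not fully specified. Both the oracle and this
package's stochastic medians are documented; agreement is at the
few-percent level and no parameter is tuned to force it closer.

## Pipeline and reproducibility

Stages `simulate → prs → mr → sensitivity → cea` are individually
re-runnable; a single global seed spawns named per-stage substreams
(CRC32-keyed SeedSequence), so rerunning one stage reproduces its output
byte-for-byte. Output tables are delimiter-explicit (TSV for genetic
matrices, CSV for results), UTF-8, with a header comment carrying package
version, seed and config hash. Failing stages delete their partial
outputs.

Problem sizes used by the test and acceptance suites — cohorts of
4,000–20,000 individuals, 10–20 variants, 100–500 replicates, 10,000
simulation draws — were chosen as the smallest at which the targeted
asymptotics (CI coverage, χ² calibration of Q and Hausman, F linearity)
are expected to hold cleanly; they run in about a minute end to end.

## Limitations

Single-instrument 2SLS only (no weak-instrument-robust inference, no
LATE/ATE decomposition); fixed-effect IVW without correlated instruments;
no clumping or p-value thresholding of variants; TSV/CSV I/O only (no
VCF/BGEN); lifetime extrapolation, discounting, adverse events and Markov
modelling are out of scope for the simulation.
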