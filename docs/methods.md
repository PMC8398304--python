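# Methods

## Model and estimators

The package implements two-sample Mendelian randomization with a single
diallelic instrument. Inputs are summary statistics: a variant–exposure
coefficient β<sub>GX</sub> (exposure units per effect allele) with standard
error, and per-study variant–outcome coefficients β<sub>GY</sub> (log-odds
per effect allele) with standard errors, estimated in non-overlapping
samples.

**Per-allele scale.** The published scale of the packaged analysis is the
per-allele odds ratio exp(β<sub>GY</sub>) with interval
exp(β<sub>GY</sub> ± z·se<sub>GY</sub>) and a two-sided normal p for
β<sub>GY</sub>/se<sub>GY</sub>. z is the exact normal quantile
(1.959963985… at 95%), not 1.96; at two printed decimals the choice is
immaterial, at full precision it makes runs reproducible.

**Wald ratio.** The causal log-odds per exposure unit is
β<sub>GY</sub>/β<sub>GX</sub>. The default standard error is first-order,
se<sub>GY</sub>/|β<sub>GX</sub>|, because per-allele reporting carries only
outcome uncertainty; the second-order delta-method form
√(se<sub>GY</sub>²/β<sub>GX</sub>² + β<sub>GY</sub>²se<sub>GX</sub>²/β<sub>GX</sub>⁴)
is used whenever the denominator is itself estimated (notably throughout
the simulation recovery experiment). The second-order term is nonnegative,
so the second-order se is never smaller than the first-order one.

**Meta-analysis.** Diseases with two independent outcome samples are
combined by fixed-effects inverse-variance weighting; the model is fixed
effects unconditionally — no random-effects fallback is attempted when
I² > 0, because with k = 2 members a between-study variance estimate is
essentially noise; instead Q, its chi-square p at k−1 df, and I² are always
reported (including when I² floors at exactly 0, i.e. whenever Q ≤ df) and
the command-line layer warns when I² > 0. The Parkinson's pair in the
packaged table is visibly heterogeneous (member betas 0.048 vs 0.117,
I² ≈ 82%); the package computes and flags this rather than suppressing the
combination.

**Normal reference.** All intervals and p-values use the standard normal,
never Student's t: the contributing samples have 10⁴–10⁵ participants.
Two-sided p-values are floored at the smallest subnormal double so the
p ∈ (0, 1] contract survives extreme z-scores.

## Harmonization

Outcome records are aligned to the instrument's effect allele before any
estimation. Non-palindromic pairs resolve uniquely into one of: unchanged,
sign flip (beta negated, eaf → 1−eaf), strand flip (complement both
alleles), strand+sign flip, or incompatible (dropped with a note, not an
exception — batch runs must survive odd rows). Palindromic pairs (A/T,
C/G) are strand-ambiguous; they are oriented by allele frequency only when
both sides report one and both are farther than a threshold (default 0.08,
the conventional margin) from 0.5, and dropped otherwise. The packaged
rs4988235 analysis is T/C and never triggers the palindromic path; the
logic exists for general reuse. The report's six counters partition the
input exactly, a property the tests enforce.

## Instrument strength

Under Hardy–Weinberg equilibrium the allele count has variance 2p(1−p), so
R² = 2p(1−p)β<sub>GX</sub>²/σ<sub>X</sub>² with σ<sub>X</sub> the total
exposure SD, and F = R²(n−k−1)/(k(1−R²)). Externally reported R²/F values
are carried verbatim with `source="reported"` and are deliberately not
forced to be mutually consistent: for the packaged instrument the reported
R² = 0.02 at n = 73,715 implies F ≈ 1504, not the reported 515 — the two
published numbers evidently come from different underlying regressions, and
the package preserves both while exposing the discrepancy through
`f_statistic`.

## Synthetic data generator

`SimScenario` emulates exactly the structure the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `eaf` | 0.7 | instrument effect-allele frequency (European-like placeholder; the source studies publish none) |
| `beta_gx` | 17.1 | exposure units (g/day milk) per allele |
| `exposure_sd` | 120 | residual exposure SD, g/day |
| `theta` | 0 | causal log-odds per exposure unit |
| `alpha` | −2 | baseline log-odds (≈12% marginal case probability) |
| `n_exposure_sample` | 20,000 | exposure cohort size (first-stage F ≈ 170) |
| `n_cases`, `n_controls` | 1,500 / 1,500 | outcome case-control quotas |
| `pleiotropy_beta` | 0 | direct variant→outcome log-odds per allele |

Genotypes are Binomial(2, eaf) (HWE); the exposure is linear in allele
count with Gaussian residuals; outcome-sample individuals become cases with
probability logistic(α + θX + pleiotropy·G) and are drawn in batches until
both quotas fill (rejection sampling, matching how case-control GWAS
ascertain; a 10⁸-draw cap guards impossible scenarios). The exposure beta
comes from closed-form OLS; the outcome beta from a logistic regression of
status on dosage fitted by IRLS (statsmodels GLM, tolerance 1e-10, max 50
iterations) on the genotype-collapsed 2×3 table, which is sufficient for
this model and keeps 500-replicate experiments in seconds. Non-convergence
raises with separation named as the likely cause.

**Non-collapsibility.** The marginal per-allele log-OR is *not*
θ·β<sub>GX</sub>: the odds ratio is non-collapsible over the residual
exposure distribution, and case-control ascertainment adds a second
distortion. `marginal_log_or_per_allele` therefore computes the exact
estimand of the fitted two-parameter logistic model: genotype-conditional
case probabilities by Gauss–Hermite quadrature (61 nodes), genotype
distributions among sampled cases and controls from Bayes' rule and the
quota ratio, and the maximizer of the expected log-likelihood by BFGS. All
recovery-bias claims are judged against this integrated truth, not the
naive product (at θ = 0.005 per g/day the attenuation is ≈ 6%).

**Randomness.** One scenario seed expands to per-replicate streams via
`SeedSequence([seed, replicate, stream])` (stream 0 = exposure sample,
1 = outcome sample), making replicates independent and every summary
bit-for-bit reproducible.

**What the generator does not emulate:** linkage disequilibrium, covariates
and population stratification, overlapping samples, genotype uncertainty,
non-linear exposure effects. Passing recovery tests therefore validate the
estimator's statistical logic under its own assumptions; they say nothing
about assumption violations in real data beyond the pleiotropy scenario
built for that purpose.

## Numerical and validation choices

- Summary-statistic validation treats a reported p that disagrees with
  |beta|/se as a warning, never an error, and compares on the z scale with
  10% relative tolerance: published tables round beta and se to three
  decimals, which can shift p by ~20% while moving z by ~2%.
- Odds-ratio input columns are log-transformed at load (with a warning):
  all internal arithmetic lives on the log-odds scale.
- Written tables serialise floats with `repr`, so write→read is the exact
  identity; absent optional fields round-trip as empty cells.
- The packaged table stores betas/SEs at their published three decimals.
  One consequence: the MS GWAS upper confidence bound computes to 0.99501,
  landing on the 0.995 two-decimal rounding boundary, where a value derived
  from unrounded source statistics prints 0.99. Recomputed p-values
  similarly match published ones only to order of magnitude; tests
  therefore pin ORs/CIs at two decimals, I² exactly, and p-values at
  |log10 ratio| ≤ 0.25.
- Replicate counts in the shipped experiments (500 for coverage and bias,
  300 for the pleiotropy demonstration) put the Monte-Carlo SE of a
  coverage estimate near 0.01 and of the mean bias near 2% of the truth —
  small enough to resolve the claims being tested, at a few seconds per
  experiment.

## Known limitations

- Single-instrument only: no IVW across variants, MR-Egger or
  weighted-median estimators, and hence no within-analysis pleiotropy
  diagnostics — the simulator's violation scenario is the only probe.
- Fixed-effects combination assumes one common true effect; the PD pair
  shows when that assumption is strained.
- No reference-panel strand inference; palindromic resolution relies
  entirely on allele frequencies.
- Non-linear dose-response cannot be addressed with summary statistics of
  this form.
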