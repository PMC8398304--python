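# snpmr — single-variant two-sample Mendelian randomization

`snpmr` estimates the causal effect of an exposure on a disease from GWAS
summary statistics when exactly **one** genetic variant serves as the
instrumental variable. The worked dataset packaged with the library asks
whether habitual milk intake affects the risk of four neurodegenerative
diseases (multiple sclerosis, Alzheimer's disease, Parkinson's disease,
amyotrophic lateral sclerosis), instrumented by the lactase-persistence
variant rs4988235 (*LCT*-13910 C>T), whose T allele raises milk consumption
in Europeans.

## The method

With instrument G, exposure X and outcome Y, and summary coefficients
β̂<sub>GX</sub> (exposure units per allele) and β̂<sub>GY</sub> (log-odds per
allele), the **Wald ratio** estimate of the causal effect is

```
β̂_IV = β̂_GY / β̂_GX ,   se_first = se_GY / |β̂_GX| ,
se_second = sqrt( se_GY²/β̂_GX² + β̂_GY² · se_GX² / β̂_GX⁴ )
```

Per-allele odds ratios are `exp(β̂_GY)` with normal-theory intervals
`exp(β̂ ± z·se)`. Where a disease has two non-overlapping outcome samples,
estimates are combined by **fixed-effects inverse-variance meta-analysis**
(weights w<sub>i</sub> = 1/se<sub>i</sub>²) with Cochran's Q, its chi-square
p at k−1 df, and I² = max(0, (Q−df)/Q)·100%. Instrument strength is
summarized by R² = 2p(1−p)β²/σ² and F = R²(n−k−1)/(k(1−R²)).

The validity of any single-instrument analysis rests on the three IV
assumptions — relevance, independence from confounders, and the exclusion
restriction (no direct variant→outcome path). The last two are untestable
with one variant, so the package ships a synthetic two-sample generator
(`snpmr.simulate`) that can deliberately violate the exclusion restriction
and show the resulting bias.

## Worked example

```python
from snpmr import builtin_study_fixture, per_allele_estimate, fixed_effects_meta

table = builtin_study_fixture()           # seven packaged studies
ms = [per_allele_estimate(table[l]) for l in ("MS GWAS", "MS Immunochip")]
combined = fixed_effects_meta(ms, "Multiple sclerosis")
print(f"OR {combined.or_point:.2f} ({combined.ci_low:.2f}-{combined.ci_high:.2f}) "
      f"p={combined.p:.3g} I2={combined.i2_percent:.0f}%")
```

prints

```
OR 0.94 (0.91-0.97) p=0.000139 I2=0%
```

i.e. each additional milk-intake-increasing T allele is associated with 6%
lower odds of multiple sclerosis, the two samples agreeing within sampling
error (I² = 0%). Running the whole packaged analysis from the shell:

```
snpmr reproduce --out-dir results/
```

emits an eleven-row forest table (seven studies, three combined rows, one
single-study summary). `examples/` holds one short script per capability:
per-study odds ratios, meta-analysis, per-unit Wald ratios, and simulation
recovery.

Combined per-allele results from the packaged table: multiple sclerosis
OR 0.94 (0.91–0.97), Alzheimer's disease 0.97 (0.94–0.99), Parkinson's
disease 1.09 (1.06–1.12), ALS 0.97 (0.94–1.01, single sample).

A note on display rounding: the packaged betas/SEs carry three decimals, so
a confidence bound can land exactly on a two-decimal rounding boundary (the
MS GWAS upper bound computes to 0.99501); full precision is always kept in
the JSON outputs and such bounds may display one unit off versions computed
from unrounded source statistics.

## Layout

- `snpmr.summary_io` — delimited-text I/O, validation, the packaged table
- `snpmr.harmonize` — allele alignment (sign/strand flips, palindromes)
- `snpmr.mr_core` — per-allele ORs, Wald ratio, rescaling
- `snpmr.meta` — fixed-effects combination, Q / I² / heterogeneity p
- `snpmr.instrument` — R², F, round-trips between them
- `snpmr.simulate` — synthetic two-sample generator and recovery experiment
- `snpmr.report` / `snpmr.cli` — forest tables and the `snpmr` command

See `docs/methods.md` for the statistical details and design choices.
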