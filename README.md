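# ivmr

Two-sample Mendelian randomization (MR) from GWAS summary statistics:
instrument selection, allele harmonization, the standard estimator family
(IVW, MR-Egger, simple/weighted/penalized-weighted median, multivariable
MR), sensitivity diagnostics, a reproducible end-to-end pipeline, and a
synthetic-GWAS generator for validating all of it against known truth.

## The problem

Mendelian randomization uses genetic variants as instrumental variables to
estimate the causal effect of an exposure (say, a blood-cell count) on an
outcome (say, a disease) from observational data. In the two-sample
summary-data setting, only per-variant association estimates from two
separate GWAS are needed. For each variant j:

    γ̂_j ~ N(γ_j, σ_Xj²)          (variant–exposure association)
    Γ̂_j ~ N(β·γ_j + α_j, σ_Yj²)  (variant–outcome association)

β is the causal effect of interest — exp(β) is an odds ratio for binary
outcomes — and α_j is the direct (pleiotropic) effect of variant j, zero
for a valid instrument. Each variant gives a Wald ratio β̂_j = Γ̂_j/γ̂_j;
the estimators combine the ratios under different robustness assumptions,
and the diagnostics probe whether the instruments behave like instruments.
See `docs/methods.md` for the full model, conventions and caveats.

## Worked example

Simulate a 20-variant panel with true causal effect β = 0.3
(OR ≈ 1.35) and run the full pipeline on it:

```sh
ivmr simulate --n-snps 20 --true-beta 0.3 --seed 7 \
    --out-exposure exposure.tsv --out-outcome outcome.tsv --out-truth truth.tsv
ivmr run --exposure exposure.tsv --outcome outcome.tsv --seed 1 --out results/
```

Output:

```
report written to results/report.json
ivw_fixed: OR=1.38663 (95% CI 1.10307-1.74308), p=0.005103, J=19
egger_slope: OR=1.62849 (95% CI 0.939953-2.8214), p=0.1001, J=19
simple_median: OR=1.32629 (95% CI 0.947391-1.85673), p=0.09994, J=19
weighted_median: OR=1.33221 (95% CI 0.972909-1.82421), p=0.07366, J=19
penalized_weighted_median: OR=1.33221 (95% CI 0.957057-1.85442), p=0.08915, J=19
```

Every estimator brackets the true OR of 1.35. One of the 20 variants fell
below genome-wide significance (P < 5×10⁻⁸) and was excluded, leaving
J = 19. `results/report.json` carries the rest: the instrument funnel
(`loaded 20 → significant 19 → clumped 19 → harmonized 19 → screened 19`),
mean instrument F-statistic 399.8, Cochran's Q = 12.67 on 18 df
(p = 0.81, no heterogeneity), and an Egger intercept of −0.0167
(p = 0.55, no directional-pleiotropy flag). Per-variant TSVs
(`estimates.tsv`, `instruments.tsv`, `loo.tsv`, `funnel.tsv`,
`heterogeneity.tsv`) land next to it.

The same workflow runs on real summary statistics: `ivmr validate` checks
a file's schema and the internal consistency of its (beta, se, p) triples,
`--ld` supplies an r² matrix or pair list for clumping, and `ivmr run`
accepts multiple `--exposure` files plus `--methods mvmr` for
multivariable MR. The parser reads tab-separated files with common header
synonyms, including published-table dialects with typographic exponents
(`6.22 × 10⁻¹⁰`), unicode minus signs and thousands separators.

As a library:

```python
from ivmr.simulate import ScenarioConfig, simulate_instrument_set
from ivmr.estimators import ivw, egger

hset, truth = simulate_instrument_set(ScenarioConfig(n_snps=50, true_beta=0.3, seed=1))
print(ivw(hset))   # MREstimate(method='ivw_fixed', beta_hat=0.2014..., se=0.0649..., ...)
slope, intercept = egger(hset)
```

## Layout

- `src/ivmr/io.py` — summary-statistics reading/writing/validation
- `src/ivmr/simulate.py` — synthetic GWAS generator with known truth
- `src/ivmr/harmonize.py` — significance filter, LD clumping, allele
  harmonization, F-statistics
- `src/ivmr/estimators.py` — IVW, MR-Egger, median family, MVMR
- `src/ivmr/diagnostics.py` — Cochran's Q, Egger intercept test,
  leave-one-out, funnel data
- `src/ivmr/pipeline.py`, `src/ivmr/cli.py` — end-to-end pipeline and the
  `ivmr` command-line tool
- `docs/methods.md` — model, assumptions, defaults and limitations
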