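# Methods note

This note records the statistical model behind `ivmr`, the conventions and
defaults the implementation commits to, what the synthetic-GWAS generator
does and does not emulate, and the numerical and design choices a user
should know about before trusting a result.

## 1. Structural model and assumptions

`ivmr` implements two-sample summary-data Mendelian randomization (MR).
For each of J independent genetic variants we observe

- γ̂_j — the estimated variant–exposure association, with standard error
  σ_Xj, from the exposure GWAS;
- Γ̂_j — the estimated variant–outcome association, with standard error
  σ_Yj, from a non-overlapping outcome GWAS.

The working model is

    γ̂_j ~ N(γ_j, σ_Xj²)
    Γ̂_j ~ N(β·γ_j + α_j, σ_Yj²)

where β is the causal effect of the exposure on the outcome (on the
log-odds scale for binary outcomes, so exp(β) is an odds ratio) and α_j is
the direct (pleiotropic) effect of variant j on the outcome. A variant is
a *valid instrument* when α_j = 0.

Assumptions carried throughout:

- **Two-sample independence.** γ̂_j and Γ̂_j are independent across samples,
  and variants are independent of each other (LD pruning is the user's or
  the clumping stage's job).
- **NOME (NO Measurement Error) for ratio SEs.** The first-order standard
  error of the Wald ratio β̂_j = Γ̂_j/γ̂_j is taken as σ_Yj/|γ̂_j|, ignoring
  uncertainty in γ̂_j. This is the standard convention when instruments are
  genome-wide significant; the F-statistic screen exists to keep users in
  the regime where it is defensible.
- **InSIDE for MR-Egger.** The Egger intercept consistently estimates the
  mean direct effect only when instrument strength γ_j is independent of
  the direct effects α_j.

## 2. Estimators

- **IVW**: weighted mean of the ratio estimates with weights
  w_j = γ̂_j²/σ_Yj², identical to the zero-intercept weighted least-squares
  slope of Γ̂ on γ̂. `fixed` (default) uses SE = (Σw_j)^(−1/2); `mre`
  (multiplicative random effects) inflates it by max(1, √(Q/(J−1))).
- **MR-Egger**: weighted regression of Γ̂_j on γ̂_j *with* an intercept,
  after orienting every variant so γ̂_j ≥ 0 (orientation affects only the
  fit, never the stored data). Slope = causal effect robust to directional
  pleiotropy under InSIDE; intercept = mean direct effect. Default
  weighting is inverse-variance (σ_Yj⁻²); `unweighted` is plain OLS, whose
  slope is exactly cov(Γ̂, γ̂)/var(γ̂). SEs use the residual-scaled
  regression covariance and p-values use t with J−2 df.
- **Median family**: order the ratio estimates; give estimate s_j the
  percentile p_j = 100·(s_j − w_j/2) where s_j is the cumulative
  normalized weight, and linearly interpolate to p = 50. Simple median
  uses equal weights, weighted median uses IVW weights, and the penalized
  weighted median multiplies each weight by min(1, 20·q_j), where q_j is
  the upper χ²₁ tail of that variant's Cochran-Q contribution. Standard
  errors come from a parametric bootstrap (default 2000 replicates)
  resampling both γ̂_j and Γ̂_j from their reported SEs, recomputing
  weights in each replicate.
- **MVMR**: multivariable MR — zero-intercept WLS of Γ̂ on the J×K matrix
  of exposure associations, requiring J > K. The default covariance is the
  unscaled fixed-effect (XᵀWX)⁻¹, which makes the K = 1 case agree exactly
  with `ivw(fixed)`; an `mre` option scales SEs by max(1, √(RSS/(J−K))).
  p-values use t with J−K df.

## 3. Diagnostics

Cochran's Q about the IVW estimate (df J−1, χ² p-value, with per-variant
decomposition Q_j), the Egger intercept test (flagging p < 0.05 as
evidence of directional pleiotropy), leave-one-out IVW (reporting the
variant whose removal moves the estimate most), and funnel data (ratio
estimate vs precision 1/se_j, with a precision-weighted signed-deviation
asymmetry score that should be near zero under balanced pleiotropy).

## 4. Instrument selection defaults and why

- `p_threshold = 5e-8` (strict `<`): genome-wide significance, the
  standard instrument-inclusion criterion.
- `window_kb = 10_000`, `r2_max = 0.001`: conventional strict clumping for
  MR, where residual LD between instruments biases estimates and inflates
  precision. Published analyses of this design are not always internally
  consistent about r² (0.001–0.05 appear in the literature for the same
  pipelines), so every run logs the value it used. The clumping rule is
  greedy on ascending p-value (ties broken by chromosome, position, then
  variant id) and discards a candidate only when it is **both** within the
  window **and** at r² ≥ r2_max with an already-kept variant; with no LD
  source supplied, nothing conflicts and clumping is a no-op.
- Palindromic variants (A/T, C/G): default policy `infer_by_eaf` aligns
  strands using allele frequency, dropping variants whose frequency falls
  in the ambiguity window (0.42, 0.58) where inference is unreliable;
  `drop` and `keep` are available for sensitivity analysis.
- `f_floor = 10`: the conventional weak-instrument threshold for the
  per-variant approximation F_j ≈ (γ̂_j/σ_Xj)². Weak instruments are
  flagged by default and removed only with `remove_weak = true`, because
  silent removal changes the estimand.

## 5. What the generator emulates, and what it does not

`ivmr.simulate` draws summary statistics directly from the structural
model above: per-variant effects γ_j from a folded normal
(mean 0.1, sd 0.05, floored at 0.02), observation noise at σ_X = 0.005
and σ_Y = 0.05 with ±20% per-variant jitter on the reported SEs, and
pleiotropy modes `none`, `balanced`, `directional` and `inside_violating`
with a configurable invalid fraction. These scales put per-variant
F-statistics in the hundreds and ratio-estimate SEs near 0.5 — the regime
of well-powered blood-cell-trait GWAS instrumenting a disease outcome.
Defaults are study conditions, fixed in code, not tuned per run.

The generator does **not** simulate individual-level genotypes, realistic
LD maps (LD blocks are idealized constant-r² blocks, 10 kb spacing within
a block, cycled over chromosomes 1–22), case-control ascertainment or the
liability scale, allele-frequency-dependent effect sizes, sample overlap
between the two GWAS, or winner's curse from in-sample instrument
selection. Effects live on an abstract linear scale; odds ratios are
obtained by exponentiation, not by simulating a binary outcome.

## 6. Numerical choices

- Zero-noise scenarios (σ = 0) emit SE = 1e-12 rather than 0 so that
  record invariants (se > 0) and inverse-variance weights stay defined.
- p-values are clamped below at the minimum positive float; a perfect
  Egger fit (zero residual) yields SE 0 and the clamped minimum p rather
  than a division error.
- Confidence intervals use the fixed critical value 1.96 throughout
  (normal approximation), including for bootstrap SEs.
- Wald consistency checking (reported p vs 2Φ(−|β/se|)) compares on the
  log10 scale with default tolerance 0.15, and treats two p-values both
  below 10⁻³⁰⁰ as consistent to sidestep float underflow.
- The weighted-median interpolation clamps to the extreme order statistics
  when p = 50 falls outside [p_1, p_J].
- The Egger regression is fit with `statsmodels` WLS; IVW, MVMR and the
  median family are closed-form `numpy` computations (MVMR stays in closed
  form so its fixed-effect covariance and the K = 1 ≡ IVW identity hold
  exactly). Tail probabilities come from `scipy.stats`.
- All randomness (simulation, bootstrap) flows through
  `numpy.random.default_rng` with explicit seeds; a pipeline run with a
  fixed config and seed is byte-identical on re-run.

## 7. Design choices

- The pipeline treats the first exposure file as primary: univariable
  methods and diagnostics run on it; `mvmr` uses all exposures with a
  union (default) or intersection rule for combining their clumped
  instrument sets.
- Instrument-set failures name the stage that emptied the set
  (significance filter, clumping, harmonization), because "no variants"
  has very different remedies at each stage.
- Reports serialize to JSON with the full config echoed, so an output file
  is self-describing.

## 8. Known limitations and caveats

- **Penalized-median caveat.** The weight penalty is computed against the
  IVW estimate. A single *large* outlier drags that reference toward
  itself, so Cochran contributions of valid variants on the far side grow
  and they — not the outlier alone — get penalized, which can *increase*
  bias. The penalty behaves as designed when outliers are a minority of
  moderate magnitude; with one dominant outlier, leave-one-out is the more
  reliable diagnostic.
- The weighted median's 50% breakdown point is an asymptotic property (in
  GWAS sample size). At finite per-variant noise, directional pleiotropy
  below the breakdown fraction still shifts the estimate by an amount
  proportional to the per-variant ratio-estimate SD; the estimator is
  unbiased relative to its own sampling variability, not exactly unbiased
  in the mean.
- NOME-based ratio SEs understate uncertainty when instruments are weak;
  the F screen mitigates but does not remove this.
- MR-Egger pays a large variance cost and is sensitive to InSIDE
  violations; its intercept test has low power at small J.
- The statistical validation in the test suite uses Monte-Carlo designs of
  300–500 replicates at J = 50 instruments; conclusions are calibrated to
  those problem sizes.
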