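"""Causal-effect estimators for summary-level Mendelian randomization.

All estimators consume a :class:`~ivmr.harmonize.HarmonizedInstrumentSet`
of per-variant exposure effects γ̂_j (SE σ_Xj) and outcome effects Γ̂_j
(SE σ_Yj) and return an :class:`MREstimate` on the beta scale together
with the odds-ratio presentation exp(β̂) and its 95% CI.

Methods
-------
* per-variant Wald ratios β̂_j = Γ̂_j/γ̂_j with first-order SEs σ_Yj/|γ̂_j|
  (exposure error ignored — the NOME convention);
* inverse-variance-weighted (IVW) pooling, β̂ = Σw_jβ̂_j/Σw_j with
  w_j = γ̂_j²/σ_Yj², equivalently the zero-intercept weighted
  least-squares slope of Γ̂ on γ̂; fixed-effect or multiplicative
  random-effects SEs;
* MR-Egger regression Γ̂_j = β₀ + β₁γ̂_j, whose intercept estimates the
  average directional pleiotropy under the InSIDE assumption;
* the median family — simple, weighted, and heterogeneity-penalized
  weighted median (weights w*_j = w_j·min(1, 20·q_j) with q_j the χ²₁
  upper-tail probability of the variant's Cochran component), with
  parametric-bootstrap standard errors;
* multivariable MR: zero-intercept weighted regression of Γ̂ on the J×K
  matrix of exposure effects, giving direct effects per exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .harmonize import HarmonizedInstrumentSet, MultiExposureSet

__all__ = [
    "MREstimate",
    "EggerIntercept",
    "ratio_estimates",
    "ivw",
    "egger",
    "simple_median",
    "weighted_median",
    "penalized_weighted_median",
    "mvmr",
    "to_odds_ratio",
]

_Z95 = 1.96  # all intervals are 95%
_TINY_P = np.finfo(float).tiny


@dataclass
class MREstimate:
    """A causal-effect estimate with its odds-ratio presentation."""

    method: str
    beta_hat: float
    se: float
    pval: float
    n_snps: int
    extras: dict = field(default_factory=dict)

    @property
    def or_hat(self) -> float:
        return float(np.exp(self.beta_hat))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta_hat - _Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta_hat + _Z95 * self.se))

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta_hat,
            "se": self.se,
            "or": self.or_hat,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
        }
        d.update(self.extras)
        return d


@dataclass
class EggerIntercept:
    """MR-Egger intercept: the average directional pleiotropy estimate."""

    intercept_hat: float
    se: float
    pval: float  # two-sided, t with J-2 df

    def to_dict(self) -> dict:
        return {
            "egger_intercept": self.intercept_hat,
            "egger_intercept_se": self.se,
            "egger_intercept_pval": self.pval,
        }


def _norm_p(beta: float, se: float) -> float:
    if se == 0.0:
        return _TINY_P if beta != 0.0 else 1.0
    return float(max(2.0 * stats.norm.sf(abs(beta) / se), _TINY_P))


def _t_p(stat: float, df: int) -> float:
    if not np.isfinite(stat):
        return _TINY_P
    return float(max(2.0 * stats.t.sf(abs(stat), df), _TINY_P))


def to_odds_ratio(beta_hat: float, se: float):
    """Odds-ratio presentation: exp(β̂) and exp(β̂ ∓ 1.96·SE)."""
    if se < 0:
        raise ValueError("se must be >= 0")
    return (
        float(np.exp(beta_hat)),
        float(np.exp(beta_hat - _Z95 * se)),
        float(np.exp(beta_hat + _Z95 * se)),
    )


def ratio_estimates(hset: HarmonizedInstrumentSet):
    """Per-variant Wald ratios and first-order SEs.

    β̂_j = Γ̂_j/γ̂_j, se_j = σ_Yj/|γ̂_j|.  A zero exposure effect makes the
    ratio undefined and raises, naming the variant.
    """
    g = hset.gamma_hat
    if (g == 0.0).any():
        bad = hset.snp[g == 0.0][0]
        raise ValueError(f"zero exposure effect for {bad}: Wald ratio undefined")
    return hset.Gamma_hat / g, hset.se_y / np.abs(g)


def _ivw_weights(hset: HarmonizedInstrumentSet) -> np.ndarray:
    return hset.gamma_hat**2 / hset.se_y**2


def _ivw_beta(hset: HarmonizedInstrumentSet) -> float:
    b, _ = ratio_estimates(hset)
    w = _ivw_weights(hset)
    return float(np.sum(w * b) / np.sum(w))


def ivw(hset: HarmonizedInstrumentSet, model: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``fixed``: SE = (Σw_j)^(-1/2).  ``mre`` (multiplicative random
    effects): the fixed SE inflated by max(1, √(Q/(J−1))), Q the Cochran
    statistic about the IVW estimate; requires J ≥ 2.  p-values use the
    normal reference.  With J = 1 the fixed model collapses to the single
    Wald ratio.
    """
    if model not in ("fixed", "mre"):
        raise ValueError(f"unknown IVW model {model!r}")
    J = hset.n_snps
    if model == "mre" and J < 2:
        raise ValueError("random-effects IVW needs at least 2 instruments")
    b, _ = ratio_estimates(hset)
    w = _ivw_weights(hset)
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    label = "ivw_fixed"
    if model == "mre":
        q = float(np.sum(w * (b - beta) ** 2))
        se *= max(1.0, np.sqrt(q / (J - 1)))
        label = "ivw_mre"
    return MREstimate(label, beta, se, _norm_p(beta, se), J)


def _orient_positive(hset: HarmonizedInstrumentSet):
    """Re-express variants so every γ̂_j ≥ 0 (flip both betas).

    Wald ratios are invariant to this recoding; the Egger regression is
    not, so it is applied there only.
    """
    sign = np.where(hset.gamma_hat < 0, -1.0, 1.0)
    return sign * hset.gamma_hat, sign * hset.Gamma_hat


def egger(hset: HarmonizedInstrumentSet, weighting: str = "inverse_variance"):
    """MR-Egger regression: slope = causal effect, intercept = pleiotropy.

    Fits Γ̂_j = β₀ + β₁·γ̂_j after orienting all variants to γ̂_j ≥ 0.
    ``inverse_variance`` (default) weights by σ_Yj⁻²; ``unweighted`` is
    ordinary least squares, whose slope is exactly cov(Γ̂, γ̂)/var(γ̂).
    SEs come from the (weighted) regression; p-values from t with J−2 df.
    A perfect fit (zero residual) yields SE 0 and the minimum-positive p.
    """
    if weighting not in ("unweighted", "inverse_variance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    J = hset.n_snps
    if J < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    g, G = _orient_positive(hset)
    w = (
        np.ones(J)
        if weighting == "unweighted"
        else 1.0 / hset.se_y**2
    )
    X = sm.add_constant(g)
    fit = sm.WLS(G, X, weights=w).fit()
    coef = fit.params
    df = J - 2
    se0, se1 = float(fit.bse[0]), float(fit.bse[1])
    intercept = EggerIntercept(
        float(coef[0]),
        se0,
        _t_p(coef[0] / se0 if se0 > 0 else np.inf * np.sign(coef[0]), df)
        if coef[0] != 0 or se0 > 0
        else 1.0,
    )
    slope_p = _t_p(coef[1] / se1 if se1 > 0 else np.inf, df)
    slope = MREstimate(
        "egger_slope",
        float(coef[1]),
        se1,
        slope_p,
        J,
        extras=intercept.to_dict(),
    )
    return slope, intercept


def _weighted_median_core(beta_j: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median.

    Sort estimates ascending with normalized weights w_j; with cumulative
    sums s_j, each estimate sits at percentile p_j = 100·(s_j − w_j/2);
    the estimate at p = 50 is found by linear interpolation, clamping to
    the extreme order statistics when 50 falls outside [p_1, p_J].
    """
    order = np.argsort(beta_j, kind="mergesort")
    b = beta_j[order]
    w = weights[order] / weights[order].sum()
    s = np.cumsum(w)
    p = 100.0 * (s - w / 2.0)
    return float(np.interp(50.0, p, b))


def _bootstrap_median_se(
    hset: HarmonizedInstrumentSet,
    weight_fn,
    n_boot: int,
    seed: int,
) -> float:
    """Parametric bootstrap SE of a median-family estimator.

    Resamples γ̂*_j ~ N(γ̂_j, σ_Xj²) and Γ̂*_j ~ N(Γ̂_j, σ_Yj²) and
    recomputes the estimator (including its weights) on each replicate.
    """
    rng = np.random.default_rng(seed)
    g0, G0 = hset.gamma_hat, hset.Gamma_hat
    sx, sy = hset.se_x, hset.se_y
    J = hset.n_snps
    out = np.empty(n_boot)
    for i in range(n_boot):
        g = rng.normal(g0, sx)
        G = rng.normal(G0, sy)
        g = np.where(g == 0.0, 1e-300, g)
        b = G / g
        w = weight_fn(g, G, sy)
        out[i] = _weighted_median_core(b, w)
    return float(out.std(ddof=1))


def simple_median(
    hset: HarmonizedInstrumentSet, n_boot: int = 2000, seed: int = 0
) -> MREstimate:
    """Simple median of the per-variant Wald ratios.

    Odd J takes the middle order statistic, even J the mean of the two
    middle ones (equal-weight special case of the weighted median).
    Consistent when at least half the instruments are valid.  SE by
    parametric bootstrap.
    """
    b, _ = ratio_estimates(hset)
    beta = _weighted_median_core(b, np.ones(hset.n_snps))
    se = _bootstrap_median_se(
        hset, lambda g, G, sy: np.ones(len(g)), n_boot, seed
    )
    return MREstimate("simple_median", beta, se, _norm_p(beta, se), hset.n_snps)


def weighted_median(
    hset: HarmonizedInstrumentSet,
    weights: np.ndarray | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> MREstimate:
    """Weighted median of the Wald ratios (default IVW weights γ̂²/σ_Y²).

    Consistent when valid instruments carry at least half the total
    weight.  SE by parametric bootstrap.
    """
    if hset.n_snps < 2:
        raise ValueError("weighted median needs at least 2 instruments")
    b, _ = ratio_estimates(hset)
    w = _ivw_weights(hset) if weights is None else np.asarray(weights, float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    beta = _weighted_median_core(b, w)
    if weights is None:
        weight_fn = lambda g, G, sy: g**2 / sy**2  # noqa: E731
    else:
        weight_fn = lambda g, G, sy: w  # noqa: E731
    se = _bootstrap_median_se(hset, weight_fn, n_boot, seed)
    return MREstimate(
        "weighted_median", beta, se, _norm_p(beta, se), hset.n_snps
    )


def _penalized_weights(b, w, penalty_factor, q_cutoff):
    """Cochran-component penalty: w*_j = w_j·min(1, penalty·q_j).

    q_j is the upper-tail χ²₁ probability of Q_j = w_j(β̂_j − β̂_IVW)²;
    with the default penalty factor 20, weights are untouched whenever
    q_j > 1/20 = q_cutoff and shrink proportionally to q_j below it.
    """
    beta_ivw = float(np.sum(w * b) / np.sum(w))
    Qj = w * (b - beta_ivw) ** 2
    qj = stats.chi2.sf(Qj, df=1)
    return w * np.minimum(1.0, penalty_factor * qj), qj


def penalized_weighted_median(
    hset: HarmonizedInstrumentSet,
    penalty_factor: float = 20.0,
    q_cutoff: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> MREstimate:
    """Weighted median with heterogeneity-penalized weights.

    Down-weights variants whose Wald ratio is an outlier relative to the
    IVW estimate (w*_j = w_j·min(1, 20·q_j)), then takes the weighted
    median under the penalized weights.  Homogeneous panels are left
    untouched (all q_j near 1).
    """
    if hset.n_snps < 2:
        raise ValueError("penalized weighted median needs >= 2 instruments")
    b, _ = ratio_estimates(hset)
    w = _ivw_weights(hset)
    w_star, _ = _penalized_weights(b, w, penalty_factor, q_cutoff)
    if np.all(w_star == 0.0):
        raise ValueError(
            "all penalized weights are zero; inspect heterogeneity before "
            "trusting any pooled estimate on this panel"
        )

    def weight_fn(g, G, sy):
        wb = g**2 / sy**2
        ws, _ = _penalized_weights(G / g, wb, penalty_factor, q_cutoff)
        return np.where(ws > 0, ws, np.finfo(float).tiny)

    beta = _weighted_median_core(b[w_star > 0], w_star[w_star > 0])
    se = _bootstrap_median_se(hset, weight_fn, n_boot, seed)
    return MREstimate(
        "penalized_weighted_median", beta, se, _norm_p(beta, se), hset.n_snps
    )


def mvmr(mset: MultiExposureSet, model: str = "fixed") -> list[MREstimate]:
    """Multivariable MR: direct effects of K exposures jointly.

    Zero-intercept weighted least squares of Γ̂ on the J×K exposure-effect
    matrix with weights σ_Yj⁻².  Requires J > K (more instruments than
    exposures) and a full-rank exposure matrix.  SEs from the
    fixed-effect covariance (XᵀWX)⁻¹ — for K = 1 this reproduces
    univariable fixed-effect IVW exactly; ``mre`` scales by
    max(1, √(RSS/(J−K))).  p-values use t with J−K df.
    """
    J, K = mset.n_snps, mset.n_exposures
    if J <= K:
        raise ValueError(
            f"multivariable MR needs more instruments than exposures "
            f"(J={J}, K={K})"
        )
    X = mset.gamma_hat
    if np.linalg.matrix_rank(X) < K:
        raise ValueError("exposure-effect matrix is rank deficient")
    w = 1.0 / mset.se_y**2
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ mset.Gamma_hat)
    cov = np.linalg.inv(xtwx)
    if model == "mre":
        resid = mset.Gamma_hat - X @ coef
        rss = float(np.sum(w * resid**2))
        cov = cov * max(1.0, rss / (J - K))
    elif model != "fixed":
        raise ValueError(f"unknown MVMR model {model!r}")
    out = []
    for k, label in enumerate(mset.exposures):
        se = float(np.sqrt(cov[k, k]))
        tstat = coef[k] / se if se > 0 else np.inf
        out.append(
            MREstimate(
                "mvmr",
                float(coef[k]),
                se,
                _t_p(tstat, J - K),
                J,
                extras={"exposure": label},
            )
        )
    return out
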