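"""Sensitivity suite: heterogeneity, pleiotropy intercept, leave-one-out,
and funnel data.

Together these probe the instrumental-variable assumptions that the point
estimators cannot check on their own: Cochran's Q asks whether the
per-variant Wald ratios are mutually consistent; the Egger intercept asks
whether pleiotropy has a directional component; leave-one-out asks whether
any single variant drives the pooled estimate; the funnel table exposes
small-instrument asymmetry (plot-ready, no rendering here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    EggerIntercept,
    MREstimate,
    _ivw_weights,
    egger,
    ivw,
    ratio_estimates,
)
from .harmonize import HarmonizedInstrumentSet

__all__ = [
    "HeterogeneityResult",
    "cochran_q",
    "egger_intercept_test",
    "leave_one_out",
    "funnel_data",
]


@dataclass
class HeterogeneityResult:
    """Cochran's Q with its per-variant decomposition.

    Q = Σ_j Q_j with Q_j = w_j(β̂_j − β̂)², w_j = γ̂_j²/σ_Yj² and β̂ the
    reference (IVW by default).  Under homogeneity Q ~ χ² with J−1 df;
    each Q_j is referred to χ²₁, giving the per-variant tail
    probabilities q_j that the penalized weighted median reuses.
    """

    Q: float
    df: int
    pval: float
    Q_j: np.ndarray
    q_j: np.ndarray

    def to_dict(self) -> dict:
        return {"Q": self.Q, "df": self.df, "pval": self.pval}


def cochran_q(
    hset: HarmonizedInstrumentSet, reference_beta: float | None = None
) -> HeterogeneityResult:
    """Cochran's Q about ``reference_beta`` (default: fixed-effect IVW)."""
    if hset.n_snps < 2:
        raise ValueError("Cochran's Q needs at least 2 instruments")
    b, _ = ratio_estimates(hset)
    w = _ivw_weights(hset)
    ref = (
        float(np.sum(w * b) / np.sum(w))
        if reference_beta is None
        else float(reference_beta)
    )
    Qj = w * (b - ref) ** 2
    Q = float(Qj.sum())
    df = hset.n_snps - 1
    return HeterogeneityResult(
        Q=Q,
        df=df,
        pval=float(stats.chi2.sf(Q, df)),
        Q_j=Qj,
        q_j=stats.chi2.sf(Qj, 1),
    )


def egger_intercept_test(hset: HarmonizedInstrumentSet, alpha: float = 0.05):
    """Directional-pleiotropy test via the MR-Egger intercept.

    Returns ``(EggerIntercept, flag)``; the flag is raised when the
    two-sided intercept p-value falls below ``alpha`` — evidence that the
    average direct effect of the instruments differs from zero.
    """
    _, intercept = egger(hset)
    return intercept, bool(intercept.pval < alpha)


def leave_one_out(hset: HarmonizedInstrumentSet, model: str = "fixed"):
    """Recompute IVW J times, each time omitting one variant.

    Returns a DataFrame (snp dropped, beta, se, or, ci_low, ci_high,
    pval, deviation from the full-set estimate) plus the id and size of
    the largest absolute deviation.  With J = 2 each row is the retained
    variant's single-SNP Wald ratio.
    """
    J = hset.n_snps
    if J < 2:
        raise ValueError("leave-one-out needs at least 2 instruments")
    full = ivw(hset, model="fixed" if J - 1 >= 1 else model)
    rows = []
    for j in range(J):
        mask = np.ones(J, bool)
        mask[j] = False
        est = ivw(hset.subset(mask), model="fixed")
        rows.append(
            {
                "snp_dropped": hset.snp[j],
                "beta": est.beta_hat,
                "se": est.se,
                "or": est.or_hat,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "deviation": est.beta_hat - full.beta_hat,
            }
        )
    table = pd.DataFrame(rows)
    imax = int(table["deviation"].abs().idxmax())
    return table, str(table.loc[imax, "snp_dropped"]), float(
        abs(table.loc[imax, "deviation"])
    )


def funnel_data(hset: HarmonizedInstrumentSet):
    """Plot-ready funnel table plus a numeric asymmetry score.

    One row per variant: Wald ratio β̂_j and its precision 1/se_j.
    Reference lines are the IVW and (when J ≥ 3) Egger estimates.  The
    asymmetry score is the precision-weighted mean signed deviation of
    the ratios from the IVW estimate — near zero for a symmetric funnel
    (it is *not* identically zero, because funnel precisions 1/se_j are
    not the IVW weights).
    """
    b, se = ratio_estimates(hset)
    table = pd.DataFrame(
        {"snp": hset.snp, "beta": b, "precision": 1.0 / se}
    )
    est = ivw(hset) if hset.n_snps >= 1 else None
    refs = {"ivw": est.beta_hat}
    if hset.n_snps >= 3:
        slope, _ = egger(hset)
        refs["egger"] = slope.beta_hat
    prec = table["precision"].to_numpy()
    asym = float(np.sum(prec * (b - est.beta_hat)) / prec.sum())
    return table, refs, asym
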