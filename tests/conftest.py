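"""Shared fixtures and independent oracles for the test suite.

The oracle functions here deliberately avoid the package's own code paths:
brute-force grid searches, two-pass covariance formulas, erfc-based tail
probabilities, and exhaustive subset enumeration, so that agreement with
the implementation is evidence and not tautology.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from ivmr.harmonize import HarmonizedInstrumentSet

DATA = Path(__file__).parent / "data"

_ALLELES = [("A", "G"), ("C", "T"), ("G", "T"), ("A", "C")]


def make_hset(gamma, se_x, Gamma, se_y, chrom=None, pos=None):
    """Build a harmonized set directly from aligned effect vectors."""
    J = len(gamma)
    return HarmonizedInstrumentSet(
        pd.DataFrame(
            {
                "snp": [f"rs{j + 1}" for j in range(J)],
                "effect_allele": [_ALLELES[j % 4][0] for j in range(J)],
                "other_allele": [_ALLELES[j % 4][1] for j in range(J)],
                "gamma_hat": np.asarray(gamma, float),
                "se_x": np.asarray(se_x, float),
                "Gamma_hat": np.asarray(Gamma, float),
                "se_y": np.asarray(se_y, float),
                "eaf": 0.3,
                "chrom": "1" if chrom is None else chrom,
                "pos": np.arange(J) * 20_000_000 + 1 if pos is None else pos,
                "flipped": False,
                "palindromic": False,
            }
        )
    )


@pytest.fixture
def table3_path():
    return DATA / "table3_basophil.tsv"


@pytest.fixture
def three_snp_set():
    """The 3-variant desk fixture: γ̂=(0.1,0.2,0.3), Γ̂=(0.05,0.08,0.2)."""
    return make_hset(
        gamma=[0.1, 0.2, 0.3],
        se_x=[0.01, 0.01, 0.01],
        Gamma=[0.05, 0.08, 0.2],
        se_y=[0.01, 0.02, 0.03],
    )


# ---------------------------------------------------------------- oracles


def oracle_normal_sf(z: float) -> float:
    """Upper-tail standard normal probability via erfc (no scipy)."""
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def oracle_chi2_1_sf(x: float) -> float:
    """Upper-tail χ²₁ probability via erfc: P(χ²₁ > x) = erfc(√(x/2))."""
    return math.erfc(math.sqrt(x / 2.0))


def oracle_ivw_grid(beta_j, w, lo=-5.0, hi=5.0, n=2_000_001) -> float:
    """Grid minimizer of Σ w_j (β̂_j − β)² (the IVW objective)."""
    grid = np.linspace(lo, hi, n)
    loss = (w[:, None] * (beta_j[:, None] - grid[None, :]) ** 2).sum(axis=0)
    return float(grid[np.argmin(loss)])


def oracle_cov_var_slope(x, y):
    """Two-pass unweighted regression slope cov(y, x)/var(x) + intercept."""
    xbar, ybar = np.mean(x), np.mean(y)
    cov = np.sum((x - xbar) * (y - ybar)) / (len(x) - 1)
    var = np.sum((x - xbar) ** 2) / (len(x) - 1)
    slope = cov / var
    return slope, ybar - slope * xbar


def oracle_weighted_median_dense(beta_j, w, n_grid=2_000_001) -> float:
    """Dense inversion of the percentile curve p(β) at 50.

    Builds the (β_(j), p_j) polyline with p_j = 100(s_j − w_j/2) and scans
    a dense β grid for the point whose interpolated percentile is closest
    to 50.
    """
    order = np.argsort(beta_j)
    b = np.asarray(beta_j, float)[order]
    wn = np.asarray(w, float)[order]
    wn = wn / wn.sum()
    p = 100.0 * (np.cumsum(wn) - wn / 2.0)
    if 50.0 <= p[0]:
        return float(b[0])
    if 50.0 >= p[-1]:
        return float(b[-1])
    grid = np.linspace(b[0], b[-1], n_grid)
    pg = np.interp(grid, b, p)
    return float(grid[np.argmin(np.abs(pg - 50.0))])


def _conflicts(row_a, row_b, ld, window_kb, r2_max) -> bool:
    if str(row_a["chrom"]) != str(row_b["chrom"]):
        return False
    close = abs(int(row_a["pos"]) - int(row_b["pos"])) <= window_kb * 1000
    key = frozenset((row_a["snp"], row_b["snp"]))
    r2 = ld.get(key, 0.0)
    return close and r2 >= r2_max


def oracle_clump_subsets(df, ld_pairs, window_kb, r2_max):
    """Exhaustive clumping oracle over all subsets (≤ ~15 variants).

    The greedy survivor set is the unique subset S that is (a) admissible
    — no two members conflict — and (b) greedy-consistent: every excluded
    variant conflicts with a member that precedes it in (p, chrom, pos,
    snp) priority order.  Enumerates every subset and returns the unique
    one satisfying both.
    """
    rows = df.to_dict("records")
    n = len(rows)
    priority = sorted(
        range(n),
        key=lambda i: (
            rows[i]["pval"],
            str(rows[i]["chrom"]),
            rows[i]["pos"],
            rows[i]["snp"],
        ),
    )
    rank = {i: r for r, i in enumerate(priority)}
    solutions = []
    for mask in range(1 << n):
        S = [i for i in range(n) if mask >> i & 1]
        ok = all(
            not _conflicts(rows[a], rows[b], ld_pairs, window_kb, r2_max)
            for ai, a in enumerate(S)
            for b in S[ai + 1:]
        )
        if not ok:
            continue
        maximal = all(
            any(
                rank[s] < rank[x]
                and _conflicts(rows[x], rows[s], ld_pairs, window_kb, r2_max)
                for s in S
            )
            for x in range(n)
            if x not in S
        )
        if maximal:
            solutions.append(S)
    assert len(solutions) == 1, "clumping oracle: solution not unique"
    return sorted(df.iloc[solutions[0]]["snp"])


def ld_matrix_to_pairs(ld: pd.DataFrame) -> dict:
    """Square r² frame → {frozenset(snp_a, snp_b): r²} for the oracle."""
    out = {}
    for a in ld.index:
        for b in ld.columns:
            if a != b and ld.loc[a, b] > 0:
                out[frozenset((a, b))] = float(ld.loc[a, b])
    return out
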