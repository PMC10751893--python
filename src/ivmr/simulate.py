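"""Synthetic GWAS summary statistics with known causal ground truth.

The generator realizes the structural model behind summary-level Mendelian
randomization.  For variant j with true variant–exposure effect γ_j and
direct (pleiotropic) outcome effect α_j, under causal effect β:

    γ̂_j ~ Normal(γ_j, σ_Xj²)            (exposure GWAS estimate)
    Γ̂_j ~ Normal(β·γ_j + α_j, σ_Yj²)    (outcome GWAS estimate)

Valid instruments have α_j = 0.  The pleiotropy regimes mirror the failure
modes the estimator family is designed to handle:

``none``
    all α_j = 0 — every variant a valid instrument.
``balanced``
    invalid variants draw α_j with mean zero (pleiotropy cancels on
    average; undetectable by the Egger intercept).
``directional``
    invalid variants draw α_j with a common non-zero mean, independent of
    γ_j (InSIDE holds; the Egger intercept estimates the mean).
``inside_violating``
    α_j is generated proportional to γ_j plus noise, so instrument
    strength and direct effect correlate (InSIDE broken; Egger biased).

Exposure and outcome noise are drawn independently (two-sample design, no
sample overlap).  γ_j magnitudes come from a folded normal with a floor,
so instrument strength — and hence per-variant F statistics — is
controllable.  Allele frequencies are Uniform(0.05, 0.95); a configurable
fraction of variants receive palindromic allele pairs (A/T or C/G) with
frequencies near 0.5, to exercise harmonization policies.  Positions are
laid out so that variants within an LD block fall inside a clumping window
while unrelated variants are distant or on other chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CANONICAL_COLUMNS, wald_pvalues

__all__ = [
    "ScenarioConfig",
    "SimTruth",
    "simulate_panel",
    "simulate_instrument_set",
    "simulate_ld_matrix",
]

_MODES = ("none", "balanced", "directional", "inside_violating")

# se floor so that σ = 0 (noise-free limit) still yields legal records
_SE_FLOOR = 1e-12


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    Attributes
    ----------
    n_snps
        Number of variants J.
    true_beta
        Causal effect β of exposure on outcome (beta scale).
    gamma_mean, gamma_sd, gamma_floor
        True γ_j magnitudes are ``max(|Normal(gamma_mean, gamma_sd)|,
        gamma_floor)``.  Defaults give strong instruments (F ≈ 400 at the
        default σ_x), in line with effect/SE scales seen in large blood
        cell-count GWAS.
    sigma_x, sigma_y
        SE scale of exposure and outcome estimates.  Per-variant SEs are
        jittered ±20% around the scale unless the scale is 0 (noise-free
        limit, in which case SEs are a representational floor and the
        estimates are exact).
    pleiotropy_mode
        One of ``none | balanced | directional | inside_violating``.
    pleiotropy_mean, pleiotropy_sd
        Moments of the direct effects α_j for invalid variants.
    invalid_fraction
        Fraction of variants (rounded to a count) receiving nonzero α_j.
    palindromic_fraction
        Fraction of variants given A/T or C/G allele pairs with eaf near
        0.5 (harmonization stress test).
    ld_blocks
        Optional list of ``(block_size, r2)`` pairs describing
        block-diagonal LD; blocks are laid out within the clumping window.
    seed
        RNG seed; a fixed seed gives bit-identical panels.
    """

    n_snps: int = 50
    true_beta: float = 0.3
    gamma_mean: float = 0.1
    gamma_sd: float = 0.05
    gamma_floor: float = 0.02
    sigma_x: float = 0.005
    sigma_y: float = 0.05
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    palindromic_fraction: float = 0.0
    ld_blocks: list[tuple[int, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("invalid_fraction must be in [0, 1]")
        if self.pleiotropy_mode not in _MODES:
            raise ValueError(
                f"pleiotropy_mode must be one of {_MODES}, "
                f"got {self.pleiotropy_mode!r}"
            )
        for name in ("gamma_sd", "sigma_x", "sigma_y", "pleiotropy_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ld_blocks is not None:
            if sum(size for size, _ in self.ld_blocks) != self.n_snps:
                raise ValueError("ld_blocks sizes must sum to n_snps")
            for _, r2 in self.ld_blocks:
                if not 0.0 <= r2 <= 1.0:
                    raise ValueError("block r2 must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of a simulated panel, for recovery tests."""

    true_beta: float
    gamma: np.ndarray          # true γ_j
    alpha: np.ndarray          # true direct effects α_j
    is_valid: np.ndarray       # α_j == 0
    snp: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp,
                "gamma": self.gamma,
                "alpha": self.alpha,
                "is_valid": self.is_valid.astype(int),
            }
        )


_NON_PALINDROMIC = [("A", "G"), ("A", "C"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("C", "G")]


def _positions(config: ScenarioConfig, rng: np.random.Generator):
    """Chromosome/position layout honouring the LD-block structure.

    Each block (or singleton) is placed on its own chromosome arm slot,
    far from other blocks; within a block, variants sit 10 kb apart so a
    10,000 kb clumping window always spans the block.
    """
    blocks = config.ld_blocks or [(1, 0.0)] * config.n_snps
    chroms, poss = [], []
    for b, (size, _) in enumerate(blocks):
        chrom = str(b % 22 + 1)
        base = 1_000_000 + (b // 22) * 50_000_000
        for k in range(size):
            chroms.append(chrom)
            poss.append(base + 10_000 * k)
    return chroms, poss


def _alleles(config: ScenarioConfig, rng: np.random.Generator):
    J = config.n_snps
    n_pal = int(round(config.palindromic_fraction * J))
    is_pal = np.zeros(J, bool)
    is_pal[rng.choice(J, n_pal, replace=False)] = True
    ea, oa, eaf = [], [], np.empty(J)
    for j in range(J):
        if is_pal[j]:
            a = _PALINDROMIC[rng.integers(len(_PALINDROMIC))]
            eaf[j] = rng.uniform(0.44, 0.56)
        else:
            a = _NON_PALINDROMIC[rng.integers(len(_NON_PALINDROMIC))]
            eaf[j] = rng.uniform(0.05, 0.95)
        if rng.random() < 0.5:
            a = (a[1], a[0])
            eaf[j] = 1.0 - eaf[j]
        ea.append(a[0])
        oa.append(a[1])
    return ea, oa, eaf


def _direct_effects(config: ScenarioConfig, gamma: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    J = config.n_snps
    alpha = np.zeros(J)
    if config.pleiotropy_mode == "none":
        return alpha
    n_invalid = int(round(config.invalid_fraction * J))
    invalid = rng.choice(J, n_invalid, replace=False)
    if config.pleiotropy_mode == "balanced":
        alpha[invalid] = rng.normal(0.0, config.pleiotropy_sd, n_invalid)
    elif config.pleiotropy_mode == "directional":
        alpha[invalid] = rng.normal(
            config.pleiotropy_mean, config.pleiotropy_sd, n_invalid
        )
    else:  # inside_violating: α tracks instrument strength
        scale = config.pleiotropy_mean / max(config.gamma_mean, 1e-12)
        alpha[invalid] = scale * gamma[invalid] + rng.normal(
            0.0, config.pleiotropy_sd, n_invalid
        )
    return alpha


def _ses(scale: float, J: int, rng: np.random.Generator) -> np.ndarray:
    if scale == 0.0:
        return np.full(J, _SE_FLOOR)
    return scale * rng.uniform(0.8, 1.2, J)


def simulate_panel(config: ScenarioConfig):
    """Simulate one exposure/outcome summary-statistics pair.

    Returns
    -------
    (exposure, outcome, truth)
        Two canonical summary-statistics frames sharing variant ids,
        alleles, frequencies and positions, plus the :class:`SimTruth`.
        Both frames use the same effect-allele convention (harmonization
        on them is the identity).
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_snps

    gamma = np.abs(rng.normal(config.gamma_mean, config.gamma_sd, J))
    gamma = np.maximum(gamma, config.gamma_floor)
    alpha = _direct_effects(config, gamma, rng)

    se_x = _ses(config.sigma_x, J, rng)
    se_y = _ses(config.sigma_y, J, rng)
    gamma_hat = gamma + (rng.normal(0.0, 1.0, J) * se_x
                         if config.sigma_x > 0 else 0.0)
    mu_y = config.true_beta * gamma + alpha
    Gamma_hat = mu_y + (rng.normal(0.0, 1.0, J) * se_y
                        if config.sigma_y > 0 else 0.0)

    snp = [f"rs{j + 1:06d}" for j in range(J)]
    ea, oa, eaf = _alleles(config, rng)
    chroms, poss = _positions(config, rng)

    def frame(beta, se):
        return pd.DataFrame(
            {
                "snp": snp,
                "effect_allele": ea,
                "other_allele": oa,
                "beta": beta,
                "se": se,
                "eaf": eaf,
                "chrom": chroms,
                "pos": poss,
                "pval": wald_pvalues(beta, se),
            },
            columns=CANONICAL_COLUMNS,
        )

    truth = SimTruth(
        true_beta=config.true_beta,
        gamma=gamma,
        alpha=alpha,
        is_valid=(alpha == 0.0),
        snp=snp,
    )
    return frame(gamma_hat, se_x), frame(Gamma_hat, se_y), truth


def simulate_instrument_set(config: ScenarioConfig):
    """Simulate a panel and return it as a ready harmonized instrument set.

    The generator emits exposure and outcome on a single effect-allele
    convention, so harmonization on its output is the identity; this
    shortcut skips the per-variant allele bookkeeping, which matters in
    replication loops (hundreds of panels).  Returns ``(hset, truth)``.
    """
    from .harmonize import HarmonizedInstrumentSet

    exposure, outcome, truth = simulate_panel(config)
    data = pd.DataFrame(
        {
            "snp": exposure["snp"],
            "effect_allele": exposure["effect_allele"],
            "other_allele": exposure["other_allele"],
            "gamma_hat": exposure["beta"].to_numpy(float),
            "se_x": exposure["se"].to_numpy(float),
            "Gamma_hat": outcome["beta"].to_numpy(float),
            "se_y": outcome["se"].to_numpy(float),
            "eaf": exposure["eaf"].to_numpy(float),
            "chrom": exposure["chrom"],
            "pos": exposure["pos"],
            "flipped": False,
            "palindromic": False,
        }
    )
    return HarmonizedInstrumentSet(data), truth


def simulate_ld_matrix(config: ScenarioConfig) -> pd.DataFrame:
    """Block-diagonal pairwise r² matrix aligned to the panel's SNP order.

    Unit diagonal; within a block every off-diagonal entry equals the
    block's r²; zero across blocks.
    """
    if config.ld_blocks is None:
        raise ValueError("config.ld_blocks is required for an LD matrix")
    J = config.n_snps
    mat = np.zeros((J, J))
    start = 0
    for size, r2 in config.ld_blocks:
        mat[start:start + size, start:start + size] = r2
        start += size
    np.fill_diagonal(mat, 1.0)
    snp = [f"rs{j + 1:06d}" for j in range(J)]
    return pd.DataFrame(mat, index=snp, columns=snp)
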