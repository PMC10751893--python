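"""Instrument selection and harmonization of exposure/outcome statistics.

The selection funnel mirrors standard two-sample MR practice: keep
genome-wide-significant variants (P < 5×10⁻⁸), clump them to approximate
mutual independence (distance window + LD r² ceiling, greedy by p-value),
align outcome statistics to the exposure's effect-allele convention, and
screen instrument strength with per-variant F statistics.

Allele harmonization resolves three situations:

* swapped alleles (outcome effect/other alleles reversed) — flip the sign
  of the outcome beta and mirror its eaf;
* strand flips (alleles reported on the opposite strand) — complement,
  then align as above;
* palindromic variants (A/T or C/G), where strand cannot be inferred from
  the alleles alone — resolved by the configured policy: drop them, infer
  orientation from allele frequencies (dropping those inside an ambiguity
  band around 0.5), or assume both studies report the same strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HarmonizedInstrumentSet",
    "MultiExposureSet",
    "filter_significant",
    "clump",
    "harmonize",
    "harmonize_multi",
    "f_statistics",
]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class HarmonizedInstrumentSet:
    """Per-variant aligned effect estimates ready for estimation.

    ``data`` has one row per instrument, ordered by (chrom, pos), with
    columns: snp, gamma_hat (exposure beta), se_x, Gamma_hat (outcome
    beta), se_y, eaf, chrom, pos, flipped (outcome re-expressed onto the
    exposure's effect allele), palindromic (allele pair is its own
    reverse complement).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("harmonized set is empty")
        if (self.data["se_x"] <= 0).any() or (self.data["se_y"] <= 0).any():
            raise ValueError("harmonized set contains non-positive SEs")

    @property
    def n_snps(self) -> int:
        return len(self.data)

    @property
    def snp(self) -> np.ndarray:
        return self.data["snp"].to_numpy()

    @property
    def gamma_hat(self) -> np.ndarray:
        return self.data["gamma_hat"].to_numpy(float)

    @property
    def se_x(self) -> np.ndarray:
        return self.data["se_x"].to_numpy(float)

    @property
    def Gamma_hat(self) -> np.ndarray:
        return self.data["Gamma_hat"].to_numpy(float)

    @property
    def se_y(self) -> np.ndarray:
        return self.data["se_y"].to_numpy(float)

    def subset(self, mask) -> "HarmonizedInstrumentSet":
        return HarmonizedInstrumentSet(self.data.loc[mask].reset_index(drop=True))


@dataclass
class MultiExposureSet:
    """Instruments aligned across K exposures and one outcome (MVMR input).

    ``gamma_hat`` / ``se_x`` are J×K arrays (column k = exposure k);
    ``Gamma_hat`` / ``se_y`` length-J vectors; ``exposures`` the K labels.
    """

    snp: np.ndarray
    gamma_hat: np.ndarray
    se_x: np.ndarray
    Gamma_hat: np.ndarray
    se_y: np.ndarray
    exposures: list[str]

    def __post_init__(self) -> None:
        self.gamma_hat = np.atleast_2d(np.asarray(self.gamma_hat, float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, float))
        if self.gamma_hat.shape != self.se_x.shape:
            raise ValueError("gamma_hat and se_x shapes differ")
        if self.gamma_hat.shape[0] != len(self.Gamma_hat):
            raise ValueError("exposure and outcome lengths differ")

    @property
    def n_snps(self) -> int:
        return self.gamma_hat.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.gamma_hat.shape[1]


def filter_significant(df: pd.DataFrame, threshold: float = 5e-8) -> pd.DataFrame:
    """Keep variants with p strictly below the genome-wide threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    return df.loc[df["pval"] < threshold].reset_index(drop=True)


def _r2_lookup(ld, snp_a: str, snp_b: str) -> float:
    """Pairwise r²; absent pairs count as 0 (unlinked)."""
    if ld is None:
        return 0.0
    if isinstance(ld, pd.DataFrame):
        if snp_a in ld.index and snp_b in ld.columns:
            return float(ld.loc[snp_a, snp_b])
        return 0.0
    # dict keyed by frozenset or ordered tuple
    return float(
        ld.get((snp_a, snp_b), ld.get((snp_b, snp_a), 0.0))
    )


def clump(
    df: pd.DataFrame,
    ld=None,
    window_kb: float = 10_000.0,
    r2_max: float = 0.001,
) -> pd.DataFrame:
    """Greedy p-value clumping with a distance window and an r² ceiling.

    Variants are visited by ascending p (ties broken by chrom, pos, snp).
    A variant is kept unless some already-kept variant on the same
    chromosome lies within ``window_kb`` *and* has r² ≥ ``r2_max`` with
    it — both conditions must hold for a conflict.  ``ld`` may be a
    square r² DataFrame (index/columns = snp ids), a dict of pairwise
    values, or None (all pairs unlinked).
    """
    if len(df) == 0:
        return df.reset_index(drop=True)
    order = df.reset_index(drop=True).sort_values(
        ["pval", "chrom", "pos", "snp"], kind="mergesort"
    )
    kept_rows: list[int] = []
    kept: list[tuple[str, str, int]] = []  # (snp, chrom, pos)
    for idx, row in order.iterrows():
        conflict = False
        for ksnp, kchrom, kpos in kept:
            if str(row["chrom"]) != kchrom:
                continue
            close = abs(int(row["pos"]) - kpos) <= window_kb * 1_000
            linked = _r2_lookup(ld, row["snp"], ksnp) >= r2_max
            if close and linked:
                conflict = True
                break
        if not conflict:
            kept_rows.append(idx)
            kept.append((row["snp"], str(row["chrom"]), int(row["pos"])))
    out = df.reset_index(drop=True).loc[sorted(kept_rows)]
    return out.reset_index(drop=True)


def _is_palindromic(ea: str, oa: str) -> bool:
    return (ea, oa) in _PALINDROMIC_PAIRS


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_policy: str = "infer_by_eaf",
    eaf_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedInstrumentSet:
    """Align outcome statistics to the exposure's effect alleles.

    Variants are intersected on id; for each, the outcome record is
    re-expressed on the exposure's effect allele (direct match, allele
    swap, strand complement, or complement+swap).  Palindromic variants
    are resolved per ``palindrome_policy``:

    ``drop``
        remove them;
    ``infer_by_eaf``
        orient by matching which side of 0.5 each study's effect-allele
        frequency falls on; drop variants whose exposure or outcome eaf
        lies inside ``eaf_window`` (too close to 0.5 to call), or whose
        eaf is missing;
    ``keep``
        assume both studies report the same strand.

    Unresolvable allele pairs are dropped with a logged reason.
    """
    if palindrome_policy not in ("drop", "infer_by_eaf", "keep"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    exp = exposure.drop_duplicates("snp").set_index("snp")
    out = outcome.drop_duplicates("snp").set_index("snp")
    common = exp.index.intersection(out.index)

    rows = []
    for snp in common:
        e, o = exp.loc[snp], out.loc[snp]
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        pal = _is_palindromic(ea_e, oa_e)
        beta_o, eaf_o = float(o["beta"]), float(o["eaf"])
        flipped = False

        if pal:
            if palindrome_policy == "drop":
                log.debug("%s dropped: palindromic (policy=drop)", snp)
                continue
            # for a palindrome the complement equals the swap, so only
            # direct match vs swap are distinguishable from alleles
            if (ea_o, oa_o) == (ea_e, oa_e):
                pass
            elif (ea_o, oa_o) == (oa_e, ea_e):
                beta_o, eaf_o, flipped = -beta_o, 1.0 - eaf_o, True
            else:
                log.debug("%s dropped: allele mismatch", snp)
                continue
            if palindrome_policy == "infer_by_eaf":
                eaf_e = float(e["eaf"])
                lo, hi = eaf_window
                if np.isnan(eaf_e) or np.isnan(eaf_o):
                    log.debug("%s dropped: palindromic, eaf missing", snp)
                    continue
                if lo <= eaf_e <= hi or lo <= eaf_o <= hi:
                    log.debug("%s dropped: palindromic, eaf ambiguous", snp)
                    continue
                if (eaf_e < 0.5) != (eaf_o < 0.5):
                    # frequencies disagree on side: outcome is on the
                    # opposite strand, i.e. effectively allele-swapped
                    beta_o, eaf_o = -beta_o, 1.0 - eaf_o
                    flipped = not flipped
        else:
            comp = (_COMPLEMENT[ea_o], _COMPLEMENT[oa_o])
            if (ea_o, oa_o) == (ea_e, oa_e):
                pass
            elif (ea_o, oa_o) == (oa_e, ea_e):
                beta_o, eaf_o, flipped = -beta_o, 1.0 - eaf_o, True
            elif comp == (ea_e, oa_e):
                pass  # strand complement, same orientation
            elif comp == (oa_e, ea_e):
                beta_o, eaf_o, flipped = -beta_o, 1.0 - eaf_o, True
            else:
                log.debug("%s dropped: allele mismatch", snp)
                continue

        rows.append(
            {
                "snp": snp,
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "gamma_hat": float(e["beta"]),
                "se_x": float(e["se"]),
                "Gamma_hat": beta_o,
                "se_y": float(o["se"]),
                "eaf": float(e["eaf"]),
                "chrom": str(e["chrom"]),
                "pos": int(e["pos"]),
                "flipped": flipped,
                "palindromic": pal,
            }
        )
    if not rows:
        raise ValueError("no variants could be harmonized")
    data = (
        pd.DataFrame(rows)
        .sort_values(["chrom", "pos", "snp"], kind="mergesort")
        .reset_index(drop=True)
    )
    return HarmonizedInstrumentSet(data)


def harmonize_multi(
    exposures: dict[str, pd.DataFrame],
    outcome: pd.DataFrame,
    snp_ids,
    palindrome_policy: str = "infer_by_eaf",
    eaf_window: tuple[float, float] = (0.42, 0.58),
) -> MultiExposureSet:
    """Align K exposures and one outcome on a common instrument list.

    ``snp_ids`` is the candidate instrument list (e.g. the union or
    intersection of per-exposure significant, clumped sets); variants
    missing from any exposure file are dropped (every exposure beta is
    required for multivariable estimation).
    """
    labels = list(exposures)
    per_exp = {
        k: harmonize(df, outcome, palindrome_policy, eaf_window).data.set_index("snp")
        for k, df in exposures.items()
    }
    snp_ids = [s for s in snp_ids if all(s in per_exp[k].index for k in labels)]
    if not snp_ids:
        raise ValueError("no variant present in all exposure files")
    first = per_exp[labels[0]]
    gamma = np.column_stack(
        [per_exp[k].loc[snp_ids, "gamma_hat"].to_numpy(float) for k in labels]
    )
    se_x = np.column_stack(
        [per_exp[k].loc[snp_ids, "se_x"].to_numpy(float) for k in labels]
    )
    return MultiExposureSet(
        snp=np.array(snp_ids),
        gamma_hat=gamma,
        se_x=se_x,
        Gamma_hat=first.loc[snp_ids, "Gamma_hat"].to_numpy(float),
        se_y=first.loc[snp_ids, "se_y"].to_numpy(float),
        exposures=labels,
    )


def f_statistics(
    hset: HarmonizedInstrumentSet,
    floor: float = 10.0,
    remove_weak: bool = False,
):
    """Per-variant instrument-strength F statistics, F_j = (γ̂_j/σ_Xj)².

    Returns ``(f_values, mean_f, weak_mask[, screened_set])``; variants
    with F_j below ``floor`` are flagged as weak and, when
    ``remove_weak``, removed (an all-weak panel raises).
    """
    f = (hset.gamma_hat / hset.se_x) ** 2
    weak = f < floor
    mean_f = float(f.mean())
    if not remove_weak:
        return f, mean_f, weak
    if weak.all():
        raise ValueError("all instruments are weak (F below floor)")
    return f, mean_f, weak, hset.subset(~weak)
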