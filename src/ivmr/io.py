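"""Reading, validating and writing GWAS summary statistics.

Summary statistics are held as a :class:`pandas.DataFrame` with one variant
per row and the canonical columns :data:`CANONICAL_COLUMNS`.  Two text
dialects are supported:

``tsv``
    Plain tab/whitespace-separated text with a header naming the canonical
    columns (case-insensitive; common synonyms accepted).

``table3``
    The dialect of published association tables: columns
    ``SNP, EA, OA, Beta, eaf, chr, pos, se, pval`` (order- and
    case-insensitive), numbers possibly typeset with a unicode minus sign,
    thousands separators in positions ("9,953,097"), and exponents written
    as ``6.22 × 10^−10`` or with superscript digits rather than e-notation.

Effect sizes (``beta``) are per effect-allele copy; ``se`` is the standard
error of ``beta``; ``eaf`` the effect-allele frequency (may be missing);
positions are 1-based.
"""

from __future__ import annotations

import math
import re
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CANONICAL_COLUMNS",
    "SchemaError",
    "ParseError",
    "read_summary_stats",
    "write_summary_stats",
    "validate_summary_stats",
    "check_wald_consistency",
]

#: canonical column order of a summary-statistics frame
CANONICAL_COLUMNS = [
    "snp",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "eaf",
    "chrom",
    "pos",
    "pval",
]

_VALID_ALLELES = {"A", "C", "G", "T"}


class SchemaError(ValueError):
    """A mandatory column is missing or the header cannot be interpreted."""


class ParseError(ValueError):
    """A data cell could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


# header synonyms -> canonical names (lower-cased, punctuation stripped)
_HEADER_MAP = {
    "snp": "snp",
    "snpid": "snp",
    "rsid": "snp",
    "ea": "effect_allele",
    "effectallele": "effect_allele",
    "a1": "effect_allele",
    "oa": "other_allele",
    "otherallele": "other_allele",
    "a2": "other_allele",
    "beta": "beta",
    "b": "beta",
    "se": "se",
    "stderr": "se",
    "eaf": "eaf",
    "af": "eaf",
    "freq": "eaf",
    "chr": "chrom",
    "chrom": "chrom",
    "chromosome": "chrom",
    "pos": "pos",
    "bp": "pos",
    "position": "pos",
    "pval": "pval",
    "p": "pval",
    "pvalue": "pval",
}

_SUPERSCRIPTS = str.maketrans("⁰¹²³⁴⁵⁶⁷⁸⁹⁻⁺", "0123456789-+")


def _normalize_number(text: str) -> str:
    """Normalize a typeset numeric token to plain float syntax.

    Handles unicode minus, superscript exponents, ``a × 10^b`` scientific
    notation and thousands separators.
    """
    s = text.strip()
    s = s.replace("−", "-").replace("–", "-")  # − and – to -
    s = s.translate(_SUPERSCRIPTS)
    # "6.22 × 10^-10", "6.22 x 10^-10", "2.13 × 10^8", "6.22×10-10"
    m = re.fullmatch(
        r"\s*(-?[\d.,]+)\s*[×x*]\s*10\s*(?:\^|\*\*)?\s*\(?(-?\d+)\)?\s*",
        s,
    )
    if m:
        mantissa = m.group(1).replace(",", "")
        return f"{mantissa}e{m.group(2)}"
    # plain number, possibly with thousands separators
    if re.fullmatch(r"-?[\d,]+(\.\d*)?([eE][-+]?\d+)?", s):
        return s.replace(",", "")
    return s


def _parse_float(text: str, line: int, column: str) -> float:
    try:
        return float(_normalize_number(text))
    except ValueError:
        raise ParseError(f"cannot parse {column!r} value {text!r}", line) from None


def _canonical_header(names: Iterable[str]) -> dict[str, str]:
    """Map raw header names onto canonical columns; raise on missing ones."""
    mapping: dict[str, str] = {}
    for raw in names:
        key = re.sub(r"[\s_.\-]", "", raw.strip().lower())
        if key in _HEADER_MAP:
            canon = _HEADER_MAP[key]
            if canon not in mapping.values():
                mapping[raw] = canon
    mandatory = {"snp", "effect_allele", "other_allele", "beta", "se", "pval"}
    missing = mandatory - set(mapping.values())
    if missing:
        raise SchemaError(
            "missing mandatory column(s): " + ", ".join(sorted(missing))
        )
    return mapping


def read_summary_stats(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read GWAS summary statistics into the canonical frame.

    Parameters
    ----------
    path
        Text file, tab- or whitespace-separated, first row a header.
    dialect
        ``"tsv"`` or ``"table3"`` (see module docstring).  Both are parsed
        by the same tolerant reader; the name records intent.

    Returns
    -------
    pandas.DataFrame
        Columns :data:`CANONICAL_COLUMNS`; row order preserved; alleles
        upper-cased.  Duplicate variant ids are kept (with a warning) —
        deduplication is an instrument-selection concern.
    """
    if dialect not in ("tsv", "table3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise SchemaError(f"{path}: empty file, no header")

    def split(line: str) -> list[str]:
        return line.split("\t") if "\t" in line else line.split()

    header = split(lines[0])
    mapping = _canonical_header(header)
    idx = {mapping[name]: i for i, name in enumerate(header) if name in mapping}

    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = split(line)
        if len(cells) < len(header):
            raise ParseError(
                f"expected {len(header)} fields, found {len(cells)}", lineno
            )

        def cell(canon: str) -> str | None:
            i = idx.get(canon)
            return cells[i] if i is not None else None

        ea = (cell("effect_allele") or "").upper()
        oa = (cell("other_allele") or "").upper()
        eaf_raw = cell("eaf")
        eaf = (
            math.nan
            if eaf_raw in (None, "", "NA", "nan", ".")
            else _parse_float(eaf_raw, lineno, "eaf")
        )
        pos_raw = cell("pos")
        pos = (
            -1
            if pos_raw in (None, "", "NA", ".")
            else int(round(_parse_float(pos_raw, lineno, "pos")))
        )
        rows.append(
            {
                "snp": cell("snp"),
                "effect_allele": ea,
                "other_allele": oa,
                "beta": _parse_float(cell("beta"), lineno, "beta"),
                "se": _parse_float(cell("se"), lineno, "se"),
                "eaf": eaf,
                "chrom": str(cell("chrom")) if cell("chrom") is not None else "",
                "pos": pos,
                "pval": _parse_float(cell("pval"), lineno, "pval"),
            }
        )
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    dup = df["snp"].duplicated()
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate variant id(s) in {path}; all kept",
            stacklevel=2,
        )
    validate_summary_stats(df)
    return df


def write_summary_stats(df: pd.DataFrame, path, dialect: str = "tsv") -> None:
    """Write a canonical frame as tab-separated text.

    ``table3`` uses the published header names (SNP, EA, OA, Beta, eaf,
    chr, pos, se, pval); ``tsv`` uses the canonical names.  Numbers are
    written in full repr precision so a read–write round trip is the
    identity to better than 1e-12.
    """
    out = df.copy()
    if dialect == "table3":
        out = out[CANONICAL_COLUMNS].rename(
            columns={
                "snp": "SNP",
                "effect_allele": "EA",
                "other_allele": "OA",
                "beta": "Beta",
                "chrom": "chr",
            }
        )
    elif dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


def validate_summary_stats(df: pd.DataFrame) -> None:
    """Raise ``ValueError`` on violated record invariants.

    Checks: se > 0; eaf in [0,1] when present; pval in (0,1]; alleles in
    {A,C,G,T} and effect != other.  p-values are *not* required to be
    Wald-consistent with (beta, se) — real files drift; use
    :func:`check_wald_consistency` to audit that.
    """
    if (df["se"] <= 0).any():
        bad = df.loc[df["se"] <= 0, "snp"].iloc[0]
        raise ValueError(f"non-positive se (first offender: {bad})")
    eaf = df["eaf"].dropna()
    if ((eaf < 0) | (eaf > 1)).any():
        raise ValueError("eaf outside [0, 1]")
    if ((df["pval"] <= 0) | (df["pval"] > 1)).any():
        bad = df.loc[(df["pval"] <= 0) | (df["pval"] > 1), "snp"].iloc[0]
        raise ValueError(f"pval outside (0, 1] (first offender: {bad})")
    alleles_ok = df["effect_allele"].isin(_VALID_ALLELES) & df[
        "other_allele"
    ].isin(_VALID_ALLELES)
    if not alleles_ok.all():
        bad = df.loc[~alleles_ok, "snp"].iloc[0]
        raise ValueError(f"allele not in A/C/G/T (first offender: {bad})")
    if (df["effect_allele"] == df["other_allele"]).any():
        raise ValueError("effect allele equals other allele")


def check_wald_consistency(beta: float, se: float, pval: float,
                           tol: float = 0.15) -> bool:
    """Does the reported p-value match the two-sided normal Wald p?

    Compares ``2·Φ(−|beta/se|)`` with ``pval`` on the log10 scale; ``tol``
    is the allowed absolute difference in log10 units.  Extremely small
    values that underflow on both sides compare equal.
    """
    z = abs(beta / se)
    log10p = (stats.norm.logsf(z) + math.log(2)) / math.log(10)
    if pval <= 0:
        return False
    log10rep = math.log10(pval)
    if log10p < -300 and log10rep < -300:
        return True
    return abs(log10p - log10rep) <= tol


def wald_pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Two-sided normal Wald p-values, clamped into (0, 1]."""
    z = np.abs(np.asarray(beta, float) / np.asarray(se, float))
    p = 2.0 * stats.norm.sf(z)
    tiny = np.finfo(float).tiny
    return np.clip(p, tiny, 1.0)
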