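"""End-to-end orchestration: files in → harmonized instruments → estimates
→ diagnostics → report.

The funnel of filters is: load → genome-wide significance → clumping →
harmonization → instrument-strength screen.  Stage counts are recorded in
the report and are non-increasing by construction.  Every configuration
field — notably the clumping r² ceiling, for which published criteria are
often inconsistent — is echoed verbatim into the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import cochran_q, egger_intercept_test, funnel_data, leave_one_out
from .estimators import (
    egger,
    ivw,
    mvmr,
    penalized_weighted_median,
    simple_median,
    weighted_median,
)
from .harmonize import (
    clump,
    f_statistics,
    filter_significant,
    harmonize,
    harmonize_multi,
)
from .io import read_summary_stats

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_ld"]

log = logging.getLogger(__name__)

ALL_METHODS = (
    "ivw",
    "egger",
    "simple-median",
    "weighted-median",
    "penalized-weighted-median",
    "mvmr",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (defaults are the study criteria:
    P < 5×10⁻⁸, clump window 10,000 kb, clump r² < 0.001)."""

    exposure_paths: list[str] = field(default_factory=list)
    outcome_path: str = ""
    ld_path: str | None = None
    p_threshold: float = 5e-8
    window_kb: float = 10_000.0
    r2_max: float = 0.001
    palindrome_policy: str = "infer_by_eaf"
    eaf_window: tuple[float, float] = (0.42, 0.58)
    methods: list[str] = field(
        default_factory=lambda: ["ivw", "egger", "simple-median",
                                 "weighted-median",
                                 "penalized-weighted-median"]
    )
    ivw_model: str = "fixed"
    n_boot: int = 2000
    seed: int = 0
    f_floor: float = 10.0
    remove_weak: bool = False
    mvmr_snp_rule: str = "union"
    out_dir: str | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.eaf_window, list):
            cfg.eaf_window = tuple(cfg.eaf_window)
        return cfg


@dataclass
class RunReport:
    """Everything a run produced, serializable to JSON."""

    config: dict
    version: str
    stage_counts: dict
    estimates: list[dict]
    egger_intercept: dict | None
    pleiotropy_flag: bool | None
    heterogeneity: dict | None
    loo: list[dict]
    loo_max_snp: str | None
    loo_max_deviation: float | None
    funnel: list[dict]
    funnel_refs: dict
    funnel_asymmetry: float | None
    instruments: list[dict]
    mean_f: float | None

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def load_ld(path) -> pd.DataFrame | dict:
    """Load an LD r² source: square matrix TSV (header row and first
    column are variant ids) or a 3-column pairwise file (snp_a, snp_b, r2)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    cols = [c.lower() for c in header]
    if cols[:3] == ["snp_a", "snp_b", "r2"]:
        pairs = pd.read_csv(path, sep="\t")
        return {
            (str(a), str(b)): float(r)
            for a, b, r in zip(pairs["snp_a"], pairs["snp_b"], pairs["r2"])
        }
    return pd.read_csv(path, sep="\t", index_col=0)


def _select_instruments(df, ld, cfg):
    sig = filter_significant(df, cfg.p_threshold)
    clumped = clump(sig, ld, cfg.window_kb, cfg.r2_max)
    return sig, clumped


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full workflow and (optionally) write report files.

    Raises ``ValueError`` with the emptying stage named if any filter
    removes every instrument, and a condition-count error when
    multivariable MR is requested with J ≤ K.
    """
    if not config.exposure_paths:
        raise ValueError("at least one exposure file is required")
    exposures = {
        Path(p).stem: read_summary_stats(p) for p in config.exposure_paths
    }
    outcome = read_summary_stats(config.outcome_path)
    ld = load_ld(config.ld_path) if config.ld_path else None

    primary_label = next(iter(exposures))
    primary = exposures[primary_label]

    n_loaded = len(primary)
    sig, clumped = _select_instruments(primary, ld, config)
    if len(sig) == 0:
        raise ValueError("no instruments: significance filter emptied the set")
    if len(clumped) == 0:
        raise ValueError("no instruments: clumping emptied the set")
    try:
        hset = harmonize(
            clumped, outcome, config.palindrome_policy, config.eaf_window
        )
    except ValueError as exc:
        raise ValueError(f"no instruments: harmonization emptied the set ({exc})")

    fvals, mean_f, weak, *rest = f_statistics(
        hset, config.f_floor, config.remove_weak
    )
    if config.remove_weak:
        hset = rest[0]
    n_screened = hset.n_snps

    stage_counts = {
        "loaded": n_loaded,
        "significant": len(sig),
        "clumped": len(clumped),
        "harmonized": len(fvals),
        "screened": n_screened,
    }
    log.info("instrument funnel: %s (r2_max=%g)", stage_counts, config.r2_max)

    estimates: list[dict] = []
    egger_block = None
    pleio_flag = None
    methods = list(config.methods)
    for m in methods:
        if m not in ALL_METHODS:
            raise ValueError(f"unknown method {m!r}")

    if "ivw" in methods:
        estimates.append(ivw(hset, model=config.ivw_model).to_dict())
    if "egger" in methods and hset.n_snps >= 3:
        slope, intercept = egger(hset)
        estimates.append(slope.to_dict())
        intercept_res, pleio_flag = egger_intercept_test(hset)
        egger_block = intercept_res.to_dict()
    if "simple-median" in methods:
        estimates.append(
            simple_median(hset, config.n_boot, config.seed).to_dict()
        )
    if "weighted-median" in methods and hset.n_snps >= 2:
        estimates.append(
            weighted_median(hset, None, config.n_boot, config.seed).to_dict()
        )
    if "penalized-weighted-median" in methods and hset.n_snps >= 2:
        estimates.append(
            penalized_weighted_median(
                hset, n_boot=config.n_boot, seed=config.seed
            ).to_dict()
        )
    if "mvmr" in methods:
        if len(exposures) < 2:
            raise ValueError("mvmr requires at least two exposure files")
        snp_sets = []
        for label, df in exposures.items():
            _, cl = _select_instruments(df, ld, config)
            snp_sets.append(set(cl["snp"]))
        if config.mvmr_snp_rule == "union":
            snps = sorted(set.union(*snp_sets))
        elif config.mvmr_snp_rule == "intersection":
            snps = sorted(set.intersection(*snp_sets))
        else:
            raise ValueError(f"unknown mvmr_snp_rule {config.mvmr_snp_rule!r}")
        mset = harmonize_multi(
            exposures, outcome, snps,
            config.palindrome_policy, config.eaf_window,
        )
        for est in mvmr(mset):
            estimates.append(est.to_dict())

    het = cochran_q(hset).to_dict() if hset.n_snps >= 2 else None
    if hset.n_snps >= 2:
        loo_table, loo_snp, loo_dev = leave_one_out(hset)
        loo_records = loo_table.to_dict("records")
    else:
        loo_records, loo_snp, loo_dev = [], None, None
    funnel_table, funnel_refs, asym = funnel_data(hset)

    inst = hset.data.copy()
    inst["f_stat"] = (hset.gamma_hat / hset.se_x) ** 2
    inst["weak"] = inst["f_stat"] < config.f_floor

    cfg_dict = asdict(config)
    cfg_dict["eaf_window"] = list(config.eaf_window)
    report = RunReport(
        config=cfg_dict,
        version=__version__,
        stage_counts=stage_counts,
        estimates=estimates,
        egger_intercept=egger_block,
        pleiotropy_flag=pleio_flag,
        heterogeneity=het,
        loo=loo_records,
        loo_max_snp=loo_snp,
        loo_max_deviation=loo_dev,
        funnel=funnel_table.to_dict("records"),
        funnel_refs=funnel_refs,
        funnel_asymmetry=asym,
        instruments=inst.to_dict("records"),
        mean_f=mean_f,
    )

    if config.out_dir:
        _write_outputs(report, hset, config)
    return report


def _write_outputs(report: RunReport, hset, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    pd.DataFrame(report.estimates).to_csv(
        out / "estimates.tsv", sep="\t", index=False, float_format="%.17g"
    )
    pd.DataFrame(report.instruments).to_csv(
        out / "instruments.tsv", sep="\t", index=False, float_format="%.17g"
    )
    pd.DataFrame(report.loo).to_csv(
        out / "loo.tsv", sep="\t", index=False, float_format="%.17g"
    )
    pd.DataFrame(report.funnel).to_csv(
        out / "funnel.tsv", sep="\t", index=False, float_format="%.17g"
    )
    het = report.heterogeneity or {}
    pd.DataFrame([het]).to_csv(
        out / "heterogeneity.tsv", sep="\t", index=False, float_format="%.17g"
    )
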