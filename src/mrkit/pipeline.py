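"""One-command orchestration of the full MR study workflow.

`run_study` executes, from a single declarative :class:`RunConfig`:
instrument construction with a full audit trail, the primary (all-instrument)
and secondary (named-subset) causal analyses, genetic-risk-score validation
and the observational association when an individual-level cohort is given,
the analytic power block, and the between-study heterogeneity/meta block when
per-study outcome statistics are given.  The result is a :class:`StudyReport`
that serialises to deterministic JSON (same config + seed → byte-identical
report) and renders to a human-readable summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from . import __version__, estimators, meta as meta_mod, power as power_mod, score
from .instruments import (
    DEFAULT_CLUMP_R2,
    DEFAULT_P_THRESHOLD,
    DEFAULT_PALINDROME_MAF,
    DEFAULT_PROXY_R2,
    harmonise,
)
from .model import MRModel
from .sumstats import LDReference, SummaryStatsSet, read_ld, read_sumstats

__all__ = ["RunConfig", "StudyReport", "run_study", "render_report"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one study run (YAML-loadable)."""

    exposure_path: str
    outcome_path: str
    ld_path: str | None = None
    cohort_path: str | None = None
    per_study_paths: dict[str, str] = field(default_factory=dict)
    # instrument thresholds (paper defaults)
    p_threshold: float = DEFAULT_P_THRESHOLD
    clump_r2: float = DEFAULT_CLUMP_R2
    proxy_r2: float = DEFAULT_PROXY_R2
    palindrome_maf: float = DEFAULT_PALINDROME_MAF
    # estimation
    methods: tuple[str, ...] = ("ivw", "weighted_median")
    ivw_model: str = "multiplicative_random"
    n_boot: int = 10_000
    subset_rsids: tuple[str, ...] = ()
    # GRS / observational
    trait_sd: float = 1.0
    grs_scale_unit: float = 1.4
    r2_boot: int = 2000
    # power
    power_r2: tuple[float, ...] = ()
    target_power: float = 0.8
    alpha: float = 0.05
    outcome_n_cases: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("methods", "subset_rsids", "power_r2"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("methods", "subset_rsids", "power_r2"):
            d[key] = list(d[key])
        return d


@dataclass
class StudyReport:
    """Structured results of one study run; every number traces to one
    operation's output."""

    audit: dict
    primary: dict
    secondary: dict | None
    grs: dict | None
    power: dict
    meta: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, allow_nan=False)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "StudyReport":
        return cls(**{f.name: d[f.name] for f in dataclasses.fields(cls)})


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _fit_methods(model: MRModel, config: RunConfig, seed_offset: int) -> dict:
    out: dict[str, dict] = {}
    for method in config.methods:
        res = model.fit(
            method,
            ivw_model=config.ivw_model,
            n_boot=config.n_boot,
            seed=config.seed + seed_offset,
        )
        out[method] = res.estimate.to_dict()
    return out


def run_study(
    config: RunConfig,
    outdir: str | Path | None = None,
) -> StudyReport:
    """Execute every configured stage in order and assemble the report.

    Stage order: instruments → primary MR → secondary MR (named subset) →
    GRS/R² and observational OR (if a cohort is given) → power → between-study
    meta (if per-study outcome paths are given).  A subset variant absent from
    the instrument table triggers a warning and is listed in the report.
    """
    exposure = read_sumstats(config.exposure_path, trait_label="exposure")
    outcome = read_sumstats(
        config.outcome_path, trait_label="outcome", trait_type="binary",
        n_cases=config.outcome_n_cases,
    )
    ld = read_ld(config.ld_path) if config.ld_path else LDReference()

    model = MRModel.from_summary_stats(
        exposure,
        outcome,
        ld,
        p_threshold=config.p_threshold,
        clump_r2=config.clump_r2,
        proxy_r2=config.proxy_r2,
        palindrome_maf=config.palindrome_maf,
    )
    audit = model.audit.to_dict()

    primary = _fit_methods(model, config, seed_offset=1)

    secondary = None
    subset_missing: list[str] = []
    if config.subset_rsids:
        have = {i.rsid for i in model.instruments}
        subset_missing = [r for r in config.subset_rsids if r not in have]
        present = [r for r in config.subset_rsids if r in have]
        if subset_missing:
            warnings.warn(
                f"secondary subset variant(s) missing from instruments: {subset_missing}",
                stacklevel=2,
            )
        if len(present) >= 1:
            sub_model = model.subset(present)
            secondary = {
                "subset_rsids": list(present),
                "subset_missing": subset_missing,
                "estimates": _fit_methods(sub_model, config, seed_offset=2),
            }
        else:
            secondary = {
                "subset_rsids": [],
                "subset_missing": subset_missing,
                "estimates": {},
            }

    # summary-level variance explained by the final instruments
    instrument_rsids = [i.rsid for i in model.instruments]
    summary = score.summary_r2(
        [exposure.get(r) for r in instrument_rsids],
        trait_sd=config.trait_sd,
        seed=config.seed + 3,
        n_boot=config.r2_boot,
    )

    grs_block = None
    if config.cohort_path:
        cohort = score.read_cohort(config.cohort_path)
        usable = [r for r in instrument_rsids if r in cohort.data.columns]
        cohort = score.CohortTable(
            data=cohort.data, variant_ids=usable,
            eaf=np.array([exposure.get(r).eaf for r in usable]),
        )
        weights = {
            i.rsid: i.beta_exposure for i in model.instruments if i.rsid in set(usable)
        }
        scores = score.compute_grs(cohort, weights)
        r2_ind = score.grs_r2(
            cohort, scores, seed=config.seed + 4, n_boot=config.r2_boot
        )
        obs_or, obs_lo, obs_hi = score.observational_or(cohort, config.grs_scale_unit)
        grs_block = {
            "n_individuals": len(cohort),
            "n_score_variants": len(usable),
            "individual_r2": dataclasses.asdict(r2_ind),
            "observational_or": {
                "scale_unit": config.grs_scale_unit,
                "or_per_unit": obs_or,
                "ci_low": obs_lo,
                "ci_high": obs_hi,
            },
        }

    # power block: analytic power at the estimated instrument strength
    n_total = outcome.n_total
    case_fraction = (outcome.n_cases / n_total) if outcome.n_cases else 0.5
    r2_values = [summary.r2, *config.power_r2]
    power_block: dict[str, Any] = {
        "n_total": n_total,
        "case_fraction": case_fraction,
        "alpha": config.alpha,
        "target_power": config.target_power,
        "summary_r2": dataclasses.asdict(summary),
        "min_detectable_or": {
            f"{r2:.6g}": power_mod.min_detectable_or(
                n_total, case_fraction, r2, config.target_power, config.alpha
            )
            for r2 in r2_values
        },
    }
    ivw_or = primary.get("ivw", {}).get("or_causal")
    if ivw_or and not math.isclose(ivw_or, 1.0):
        ratio = (1.0 - case_fraction) / case_fraction
        power_block["required_cases_at_ivw_or"] = {
            "or_causal": ivw_or,
            "control_to_case_ratio": ratio,
            "n_cases": power_mod.required_cases(
                ivw_or, summary.r2, ratio, config.target_power, config.alpha
            ),
        }

    meta_block = None
    if config.per_study_paths:
        pruned = {i.rsid for i in model.instruments}
        exposure_final = [exposure.get(r) for r in instrument_rsids]
        per_study_instr = {}
        for label, path in config.per_study_paths.items():
            study_outcome = read_sumstats(path, trait_label=label, trait_type="binary")
            instr, _ = harmonise(
                exposure_final, study_outcome, ld,
                maf_max=config.palindrome_maf, r2_min=config.proxy_r2,
            )
            per_study_instr[label] = instr
        studies = meta_mod.per_study_estimates(per_study_instr)
        q, df, p = meta_mod.meta_q(studies)
        pooled = meta_mod.random_effects_pool(studies)
        meta_block = {
            "studies": [dataclasses.asdict(s) for s in studies],
            "q": q,
            "df": df,
            "p": p,
            "pooled": pooled.to_dict(),
        }

    report = StudyReport(
        audit=audit,
        primary=primary,
        secondary=secondary,
        grs=grs_block,
        power=power_block,
        meta=meta_block,
        provenance={
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "mrkit_version": __version__,
        },
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.to_json() + "\n")
        (outdir / "report.md").write_text(render_report(report))
        logger.info("report written to %s", outdir)
    return report


def _estimate_rows(estimates: Mapping[str, Mapping[str, Any]]) -> list[str]:
    rows = [
        "| method | OR | 95% CI | beta | se | p | Q (df) | Q p |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for method, e in estimates.items():
        qcell = f"{e['q']:.2f} ({e['q_df']})" if e.get("q") is not None else "-"
        qp = f"{e['q_p']:.2f}" if e.get("q_p") is not None else "-"
        rows.append(
            f"| {method} | {e['or_causal']:.3f} | "
            f"({e['or_low']:.3f}, {e['or_high']:.3f}) | {e['beta_causal']:.4f} | "
            f"{e['se']:.4f} | {e['pvalue']:.3g} | {qcell} | {qp} |"
        )
    return rows


def render_report(report: StudyReport) -> str:
    """Human-readable markdown rendering; empty blocks are omitted."""
    a = report.audit
    lines = ["# MR study report", "", "## Instrument audit", ""]
    lines += [
        "| stage | count |",
        "|---|---|",
        f"| genome-wide significant | {a['n_significant']} |",
        f"| independent after LD pruning | {a['n_independent']} |",
        f"| palindromic dropped | {a['n_palindromic_dropped']} |",
        f"| absent from outcome | {a['n_absent']} |",
        f"| recovered by proxy | {a['n_proxied']} |",
        f"| unmatched (no proxy) | {a['n_unmatched']} |",
        f"| irreconcilable alleles | {a['n_irreconcilable']} |",
        f"| final instruments | {a['n_final']} |",
        "",
        "## Primary analysis",
        "",
    ]
    lines += _estimate_rows(report.primary)
    if report.secondary and report.secondary.get("estimates"):
        lines += ["", "## Secondary analysis (subset)", ""]
        lines.append(f"Subset: {', '.join(report.secondary['subset_rsids'])}")
        if report.secondary["subset_missing"]:
            lines.append(
                f"Missing from instruments: {', '.join(report.secondary['subset_missing'])}"
            )
        lines.append("")
        lines += _estimate_rows(report.secondary["estimates"])
    if report.grs:
        g = report.grs
        r2 = g["individual_r2"]
        obs = g["observational_or"]
        lines += [
            "",
            "## Genetic risk score and observational association",
            "",
            f"- score variants: {g['n_score_variants']}, individuals: {g['n_individuals']}",
            f"- individual-level R²: {r2['r2']:.4f} "
            f"(95% CI {r2['ci_low']:.4f}–{r2['ci_high']:.4f})",
            f"- observational OR per {obs['scale_unit']} unit RDW: "
            f"{obs['or_per_unit']:.3f} (95% CI {obs['ci_low']:.3f}–{obs['ci_high']:.3f})",
        ]
    p = report.power
    lines += [
        "",
        "## Power",
        "",
        f"- summary-level instrument R²: {p['summary_r2']['r2']:.4f} "
        f"(95% CI {p['summary_r2']['ci_low']:.4f}–{p['summary_r2']['ci_high']:.4f})",
    ]
    for r2key, mdor in p["min_detectable_or"].items():
        lines.append(
            f"- minimum detectable OR at {p['target_power']:.0%} power, R²={r2key}: {mdor:.3f}"
        )
    if "required_cases_at_ivw_or" in p:
        rc = p["required_cases_at_ivw_or"]
        lines.append(
            f"- cases required to detect OR {rc['or_causal']:.3f} at "
            f"{p['target_power']:.0%} power (1:{rc['control_to_case_ratio']:.1f} "
            f"cases:controls): {rc['n_cases']}"
        )
    if report.meta:
        m = report.meta
        lines += ["", "## Between-study heterogeneity", ""]
        lines += ["| study | beta | se |", "|---|---|---|"]
        for s in m["studies"]:
            lines.append(f"| {s['study']} | {s['beta']:.4f} | {s['se']:.4f} |")
        pooled = m["pooled"]
        lines += [
            "",
            f"Cochran's Q = {m['q']:.2f}, df = {m['df']}, p = {m['p']:.2f}; "
            f"random-effects pooled beta = {pooled['beta_pooled']:.4f} "
            f"(se {pooled['se_pooled']:.4f}, tau² = {pooled['tau2']:.4g})",
        ]
    lines.append("")
    return "\n".join(lines)
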