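"""Synthetic GWAS-like data generation under a specified causal model.

Generates every input the MR pipeline consumes without any download:

* an exposure GWAS: per-allele effects in trait-SD units for ``n_variants``
  independent loci, jointly explaining a configurable R², observed with
  sampling noise se = 1/sqrt(2f(1−f)·N),
* an outcome (binary-trait) GWAS under a causal log-odds effect ``b`` per SD
  of exposure, optionally with balanced or directional pleiotropy, observed
  with se = 1/sqrt(2f(1−f)·N·K(1−K)) and noise independent of the exposure
  draw (the two-sample property),
* an r²-only LD reference (block structure plus proxy pairs),
* an individual-level cohort (Hardy–Weinberg dosages, exposure driven by the
  genetic score to a target R², logistic case status) for the genetic-risk-
  score and observational stages.

All randomness flows from one root seed through a fixed
``numpy.random.SeedSequence`` splitting scheme (variant structure, exposure
draw, outcome draw, cohort, per-study draws, pleiotropy), so every stage is
independently reproducible.  Scaling of the true effects to the target R² is
deterministic: the construction identity Σ 2f(1−f)β² = R² holds exactly.

True exposure effects are oriented positive, i.e. the reported effect allele
is the trait-increasing allele, matching common GWAS reporting practice; this
also makes directional pleiotropy genuinely directional on the Wald-ratio
scale.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import estimators
from .instruments import harmonise
from .score import CohortTable
from .sumstats import (
    COMPLEMENT,
    MIN_PVALUE,
    LDReference,
    SummaryStatsSet,
    VariantAssociation,
)

__all__ = [
    "ScenarioConfig",
    "SimTruth",
    "SimulatedStudy",
    "gen_exposure_gwas",
    "gen_outcome_gwas",
    "gen_ld_reference",
    "gen_cohort",
    "scenario_preset",
    "simulate_study",
    "run_mr_replicates",
]

#: PAH GWAS shape: 2085 cases among 11 744 individuals
PAH_N = 11_744
PAH_CASES = 2085

#: the four case-control studies contributing to the outcome GWAS
FOUR_STUDIES: tuple[tuple[str, int, int], ...] = (
    ("NIHRBR", 847, 5048),
    ("PAHB", 694, 1560),
    ("PHAAR", 269, 1068),
    ("BHFPAH", 275, 1983),
)

#: variants acting on systemic iron status, used as the secondary instrument
IRON_SUBSET: tuple[tuple[str, str], ...] = (
    ("rs1800562", "HFE"),
    ("rs1799945", "HFE"),
    ("rs855791", "TMPRSS6"),
    ("rs3804141", "TFRC"),
    ("rs7385804", "TFR2"),
)

_NON_PALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one simulated MR study."""

    # variant panel
    n_variants: int = 150
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_fraction: float = 0.0
    palindrome_maf_range: tuple[float, float] | None = None
    ld_blocks: tuple[tuple[int, float], ...] = ()
    # exposure GWAS
    r2_target: float = 0.12
    n_exposure: int = 170_000
    effect_dist: str = "normal"  # "normal" | "offset_normal"
    ensure_significant: bool = False
    sig_threshold: float = 8.31e-9
    subset_size: int = 0
    subset_r2: float | None = None
    # outcome GWAS
    n_outcome: int = PAH_N
    case_fraction: float = PAH_CASES / PAH_N
    causal_log_or: float = 0.0
    pleiotropy: str = "none"  # "none" | "balanced" | "directional"
    pleiotropy_fraction: float = 0.0
    pleiotropy_scale: float = 0.2
    n_missing_outcome: int = 0
    n_proxy_recoverable: int = 0
    proxy_r2: float = 0.9
    allele_swap_fraction: float = 0.3
    strand_flip_fraction: float = 0.2
    study_split: tuple[tuple[str, int, int], ...] = ()
    # individual-level cohort
    cohort_n: int = 0
    cohort_case_fraction: float = 0.0
    grs_r2_target: float = 0.026
    rdw_mean: float = 13.60
    rdw_sd: float = 1.40
    obs_log_or_per_sd: float = math.log(1.90)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        if not (0.0 < self.r2_target < 1.0):
            raise ValueError("r2_target must be in (0,1)")
        if self.subset_size and (self.subset_r2 is None or not 0 < self.subset_r2 < self.r2_target):
            raise ValueError("subset_r2 must lie in (0, r2_target) when subset_size > 0")
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            raise ValueError("palindromic_fraction must be in [0,1]")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            raise ValueError("pleiotropy_fraction must be in [0,1]")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy setting {self.pleiotropy!r}")
        if self.effect_dist not in ("normal", "offset_normal"):
            raise ValueError(f"unknown effect_dist {self.effect_dist!r}")
        if self.n_proxy_recoverable > self.n_missing_outcome:
            raise ValueError("n_proxy_recoverable cannot exceed n_missing_outcome")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class SimTruth:
    """Ground truth underlying one simulated scenario."""

    config: ScenarioConfig
    rsids: list[str]
    chrom: list[str]
    pos: np.ndarray
    effect_allele: list[str]
    other_allele: list[str]
    eaf: np.ndarray
    beta_x_true: np.ndarray
    beta_x_obs: np.ndarray
    se_x: np.ndarray
    direct_effects: np.ndarray  # pleiotropic path to the outcome
    beta_y_true: np.ndarray
    palindromic: np.ndarray  # bool mask
    subset_rsids: list[str]
    subset_genes: dict[str, str]
    missing_rsids: list[str]
    proxy_map: dict[str, str]  # instrument rsid -> proxy rsid in the outcome
    swap_mask: np.ndarray
    flip_mask: np.ndarray

    @property
    def causal_log_or(self) -> float:
        return self.config.causal_log_or

    def index(self, rsid: str) -> int:
        return self.rsids.index(rsid)


def _children(cfg: ScenarioConfig) -> list[np.random.SeedSequence]:
    # fixed split order: variants, exposure, outcome, cohort, studies, pleiotropy
    return np.random.SeedSequence(cfg.seed).spawn(6)


def _draw_shapes(rng: np.random.Generator, n: int, dist: str) -> np.ndarray:
    if dist == "normal":
        return np.abs(rng.standard_normal(n))
    # offset_normal keeps every effect bounded away from zero so that a panel
    # scaled to a genome-wide-significant R2 stays genome-wide significant
    return 1.0 + 0.3 * np.abs(rng.standard_normal(n))


def gen_exposure_gwas(cfg: ScenarioConfig) -> tuple[SummaryStatsSet, SimTruth]:
    """Exposure GWAS summary statistics plus the generating truth.

    True per-allele effects are drawn as shapes, then scaled so that
    Σ 2f(1−f)β² equals ``r2_target`` exactly (the subset, when configured, is
    scaled separately to ``subset_r2``).  Observed effects add independent
    normal noise at the analytic SE; p-values are two-sided Wald.
    """
    ss_var, ss_exp, _, _, _, ss_pleio = _children(cfg)
    rng_var = np.random.default_rng(ss_var)
    rng_exp = np.random.default_rng(ss_exp)
    n = cfg.n_variants

    maf = rng_var.uniform(*cfg.maf_range, size=n)
    n_pal = int(round(cfg.palindromic_fraction * n))
    pal_idx = rng_var.choice(n, size=n_pal, replace=False) if n_pal else np.array([], dtype=int)
    palindromic = np.zeros(n, dtype=bool)
    palindromic[pal_idx] = True
    if cfg.palindrome_maf_range is not None and n_pal:
        maf[pal_idx] = rng_var.uniform(*cfg.palindrome_maf_range, size=n_pal)
    side = rng_var.random(n) < 0.5
    eaf = np.where(side, maf, 1.0 - maf)

    alleles = []
    for j in range(n):
        pool = _PALINDROMIC_PAIRS if palindromic[j] else _NON_PALINDROMIC_PAIRS
        alleles.append(pool[rng_var.integers(len(pool))])
    effect_allele = [a for a, _ in alleles]
    other_allele = [b for _, b in alleles]

    rsids = [f"rs{1_000_000 + 13 * j}" for j in range(n)]
    chrom = [str(1 + j % 22) for j in range(n)]
    pos = np.array([1_000_000 + 50_000 * j for j in range(n)], dtype=int)

    subset_rsids: list[str] = []
    subset_genes: dict[str, str] = {}
    if cfg.subset_size:
        if cfg.subset_size > len(IRON_SUBSET):
            raise ValueError(f"subset_size > {len(IRON_SUBSET)} not supported")
        eligible = np.flatnonzero(~palindromic)
        chosen = rng_var.choice(eligible, size=cfg.subset_size, replace=False)
        for k, j in enumerate(sorted(chosen)):
            rsid, gene = IRON_SUBSET[k]
            rsids[j] = rsid
            subset_rsids.append(rsid)
            subset_genes[rsid] = gene

    # scale true effects to the target variance explained, subset separately
    het = 2.0 * eaf * (1.0 - eaf)
    shapes = _draw_shapes(rng_exp, n, cfg.effect_dist)
    beta_true = shapes.copy()
    in_subset = np.array([r in set(subset_rsids) for r in rsids])
    groups: list[tuple[np.ndarray, float]] = []
    if cfg.subset_size:
        groups.append((in_subset, cfg.subset_r2))
        groups.append((~in_subset, cfg.r2_target - cfg.subset_r2))
    else:
        groups.append((np.ones(n, dtype=bool), cfg.r2_target))
    for mask, target in groups:
        raw = float(np.sum(het[mask] * shapes[mask] ** 2))
        beta_true[mask] = shapes[mask] * math.sqrt(target / raw)

    se_x = 1.0 / np.sqrt(het * cfg.n_exposure)
    beta_obs = beta_true + rng_exp.normal(size=n) * se_x
    if cfg.ensure_significant:
        z_crit = float(stats.norm.isf(cfg.sig_threshold / 2.0))
        for j in range(n):
            tries = 0
            while abs(beta_obs[j] / se_x[j]) <= z_crit and tries < 500:
                beta_obs[j] = beta_true[j] + rng_exp.normal() * se_x[j]
                tries += 1
    pvals = np.maximum(2.0 * stats.norm.sf(np.abs(beta_obs / se_x)), MIN_PVALUE)

    # pleiotropic direct effects on the outcome (part of the scenario truth)
    rng_pleio = np.random.default_rng(ss_pleio)
    direct = np.zeros(n)
    if cfg.pleiotropy != "none" and cfg.pleiotropy_fraction > 0:
        n_invalid = int(round(cfg.pleiotropy_fraction * n))
        invalid = rng_pleio.choice(n, size=n_invalid, replace=False)
        if cfg.pleiotropy == "balanced":
            direct[invalid] = rng_pleio.normal(0.0, cfg.pleiotropy_scale / 2.0, n_invalid)
        else:  # directional: one-signed direct effects
            direct[invalid] = rng_pleio.uniform(0.0, cfg.pleiotropy_scale, n_invalid)
    beta_y_true = cfg.causal_log_or * beta_true + direct

    # which variants the outcome panel lacks, and which of those have a proxy
    missing_rsids: list[str] = []
    proxy_map: dict[str, str] = {}
    if cfg.n_missing_outcome:
        eligible = np.flatnonzero(~palindromic & ~in_subset)
        if len(eligible) < cfg.n_missing_outcome:
            raise ValueError("not enough non-palindromic variants to remove from the outcome")
        removed = sorted(rng_var.choice(eligible, size=cfg.n_missing_outcome, replace=False))
        missing_rsids = [rsids[j] for j in removed]
        for j in removed[: cfg.n_proxy_recoverable]:
            proxy_map[rsids[j]] = f"{rsids[j]}px"

    swap_mask = rng_var.random(n) < cfg.allele_swap_fraction
    flip_mask = rng_var.random(n) < cfg.strand_flip_fraction

    records = [
        VariantAssociation(
            rsid=rsids[j], chrom=chrom[j], pos=int(pos[j]),
            effect_allele=effect_allele[j], other_allele=other_allele[j],
            eaf=float(eaf[j]), beta=float(beta_obs[j]), se=float(se_x[j]),
            pvalue=float(pvals[j]), n=cfg.n_exposure,
        )
        for j in range(n)
    ]
    exposure = SummaryStatsSet(
        trait_label="RDW", trait_type="continuous", records=records, n_total=cfg.n_exposure
    )
    truth = SimTruth(
        config=cfg, rsids=rsids, chrom=chrom, pos=pos,
        effect_allele=effect_allele, other_allele=other_allele, eaf=eaf,
        beta_x_true=beta_true, beta_x_obs=beta_obs, se_x=se_x,
        direct_effects=direct, beta_y_true=beta_y_true, palindromic=palindromic,
        subset_rsids=subset_rsids, subset_genes=subset_genes,
        missing_rsids=missing_rsids, proxy_map=proxy_map,
        swap_mask=swap_mask, flip_mask=flip_mask,
    )
    return exposure, truth


def _outcome_record(
    truth: SimTruth, j: int, rsid: str, pos: int, beta_true: float,
    se: float, noise: float, n: int, swap: bool, flipstrand: bool,
) -> VariantAssociation:
    ea, oa = truth.effect_allele[j], truth.other_allele[j]
    eaf = float(truth.eaf[j])
    beta = beta_true + noise * se
    if flipstrand:
        ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
    if swap:
        ea, oa = oa, ea
        beta, eaf = -beta, 1.0 - eaf
    z = abs(beta / se)
    return VariantAssociation(
        rsid=rsid, chrom=truth.chrom[j], pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=float(beta), se=float(se),
        pvalue=float(max(2.0 * stats.norm.sf(z), MIN_PVALUE)), n=n,
    )


def gen_outcome_gwas(
    cfg: ScenarioConfig,
    truth: SimTruth,
    n_outcome: int | None = None,
    case_fraction: float | None = None,
    seed_seq: np.random.SeedSequence | None = None,
    study_label: str = "PAH",
) -> SummaryStatsSet:
    """Outcome GWAS summary statistics on the log-odds scale.

    True outcome effects are b·β_x plus any pleiotropic direct effect (fixed
    in ``truth``); the observation noise is drawn independently of the
    exposure noise.  Variants listed in ``truth.missing_rsids`` are absent;
    those with a proxy contribute an LD-attenuated (√r²·β) proxy record
    instead.
    """
    n_out = cfg.n_outcome if n_outcome is None else n_outcome
    k = cfg.case_fraction if case_fraction is None else case_fraction
    if seed_seq is None:
        seed_seq = _children(cfg)[2]
    rng = np.random.default_rng(seed_seq)
    missing = set(truth.missing_rsids)
    records: list[VariantAssociation] = []
    scale = n_out * k * (1.0 - k)
    for j, rsid in enumerate(truth.rsids):
        het = 2.0 * truth.eaf[j] * (1.0 - truth.eaf[j])
        se = 1.0 / math.sqrt(het * scale)
        if rsid in missing:
            proxy = truth.proxy_map.get(rsid)
            if proxy is None:
                continue
            beta_true = math.sqrt(cfg.proxy_r2) * truth.beta_y_true[j]
            records.append(
                _outcome_record(
                    truth, j, proxy, int(truth.pos[j]) + 500, beta_true, se,
                    rng.standard_normal(), n_out,
                    swap=bool(truth.swap_mask[j]), flipstrand=bool(truth.flip_mask[j]),
                )
            )
            continue
        records.append(
            _outcome_record(
                truth, j, rsid, int(truth.pos[j]), float(truth.beta_y_true[j]), se,
                rng.standard_normal(), n_out,
                swap=bool(truth.swap_mask[j]), flipstrand=bool(truth.flip_mask[j]),
            )
        )
    return SummaryStatsSet(
        trait_label=study_label, trait_type="binary", records=records,
        n_total=n_out, n_cases=int(round(n_out * k)),
    )


def gen_study_outcomes(cfg: ScenarioConfig, truth: SimTruth) -> dict[str, SummaryStatsSet]:
    """One outcome GWAS per contributing study, independent noise per study."""
    if not cfg.study_split:
        raise ValueError("config has no study_split")
    children = _children(cfg)[4].spawn(len(cfg.study_split))
    out: dict[str, SummaryStatsSet] = {}
    for (label, n_cases, n_controls), child in zip(cfg.study_split, children):
        n_total = n_cases + n_controls
        out[label] = gen_outcome_gwas(
            cfg, truth, n_outcome=n_total, case_fraction=n_cases / n_total,
            seed_seq=child, study_label=label,
        )
    return out


def gen_ld_reference(cfg: ScenarioConfig, truth: SimTruth | None = None) -> LDReference:
    """Block-diagonal LD: constant r² within configured blocks, zero across,
    plus the proxy pairs of the scenario (index variant ↔ proxy, r² =
    ``cfg.proxy_r2``)."""
    ref = LDReference()
    if truth is not None:
        idx = 0
        for size, r2 in cfg.ld_blocks:
            block = truth.rsids[idx: idx + size]
            for a_i in range(len(block)):
                for b_i in range(a_i + 1, len(block)):
                    ref.add(block[a_i], block[b_i], r2)
            idx += size
        for index_rsid, proxy_rsid in truth.proxy_map.items():
            ref.add(index_rsid, proxy_rsid, cfg.proxy_r2)
    return ref


def _solve_intercept(linear: np.ndarray, target: float) -> float:
    def deficit(a: float) -> float:
        return float(np.mean(special.expit(a + linear))) - target

    return float(optimize.brentq(deficit, -30.0, 30.0, xtol=1e-12))


def gen_cohort(
    cfg: ScenarioConfig,
    truth: SimTruth,
    rsids: Sequence[str] | None = None,
    weights: Mapping[str, float] | None = None,
) -> CohortTable:
    """Individual-level cohort for GRS validation and the observational stage.

    Dosages are Binomial(2, f) per variant (Hardy–Weinberg, independent
    loci).  The exposure is built so the *population* R² of the weighted
    score equals ``grs_r2_target``; case status follows a logistic model in
    standardised exposure, age and sex with the intercept solved numerically
    for the target case fraction.
    """
    if cfg.cohort_n <= 0:
        raise ValueError("cfg.cohort_n must be positive to generate a cohort")
    rng = np.random.default_rng(_children(cfg)[3])
    if rsids is None:
        rsids = [r for r in truth.rsids]
    idx = [truth.index(r) for r in rsids]
    f = truth.eaf[idx]
    if weights is None:
        w = truth.beta_x_obs[idx]
    else:
        w = np.array([weights[r] for r in rsids], dtype=float)
    n = cfg.cohort_n

    dos = rng.binomial(2, f, size=(n, len(idx))).astype(float)
    grs = dos @ w
    mu = float(np.sum(w * 2.0 * f))
    sd = math.sqrt(float(np.sum(w**2 * 2.0 * f * (1.0 - f))))
    g_std = (grs - mu) / sd
    r2g = cfg.grs_r2_target
    noise = rng.standard_normal(n)
    rdw_z = math.sqrt(r2g) * g_std + math.sqrt(1.0 - r2g) * noise
    rdw = cfg.rdw_mean + cfg.rdw_sd * rdw_z

    age = np.clip(rng.normal(60.0, 12.0, n), 18.0, 90.0)
    sex = rng.integers(0, 2, n).astype(float)
    if cfg.cohort_case_fraction > 0:
        linear = (
            cfg.obs_log_or_per_sd * rdw_z
            + 0.01 * (age - age.mean())
            + 0.1 * (sex - sex.mean())
        )
        a = _solve_intercept(linear, cfg.cohort_case_fraction)
        is_case = (rng.random(n) < special.expit(a + linear)).astype(int)
    else:
        is_case = np.zeros(n, dtype=int)

    data = pd.DataFrame(
        {
            "id": [f"S{i:06d}" for i in range(n)],
            "rdw": rdw,
            "age": age,
            "sex": sex,
            "is_case": is_case,
            "study": "VUMC",
        }
    )
    data = pd.concat(
        [data, pd.DataFrame(dos, columns=list(rsids), index=data.index)], axis=1
    )
    return CohortTable(data=data, variant_ids=list(rsids), eaf=f.copy())


# ---------------------------------------------------------------------------
# presets and scenario bundles


def scenario_preset(name: str, seed: int = 0) -> ScenarioConfig:
    """Named, fully seeded study scenarios.

    ``paper_shape`` mimics the dimensions of the motivating study: 212
    independent exposure QTL jointly explaining R²=12.7% (5 of them an
    iron-status subset at 1.7%), 13 strand-ambiguous palindromes at
    intermediate frequency, 32 instruments absent from the outcome panel of
    which 12 are proxy-recoverable (yielding 179 final instruments), an
    outcome GWAS of 11 744 with 2085 cases split over four studies, and a
    16 531-person cohort (642 cases) whose score explains 2.6% of the
    exposure.  The remaining presets are estimator-calibration scenarios.
    """
    if name == "null":
        return ScenarioConfig(seed=seed)
    if name == "causal":
        return ScenarioConfig(
            n_variants=50, r2_target=0.026, causal_log_or=math.log(1.5), seed=seed
        )
    if name == "directional_pleiotropy":
        return ScenarioConfig(
            pleiotropy="directional", pleiotropy_fraction=0.3, pleiotropy_scale=0.2,
            seed=seed,
        )
    if name == "four_study":
        return ScenarioConfig(
            causal_log_or=math.log(1.07), study_split=FOUR_STUDIES, seed=seed
        )
    if name == "paper_shape":
        return ScenarioConfig(
            n_variants=212,
            palindromic_fraction=13 / 212,
            palindrome_maf_range=(0.455, 0.499),
            r2_target=0.127,
            subset_size=5,
            subset_r2=0.017,
            effect_dist="offset_normal",
            ensure_significant=True,
            n_missing_outcome=32,
            n_proxy_recoverable=12,
            causal_log_or=0.0,
            study_split=FOUR_STUDIES,
            cohort_n=16_531,
            cohort_case_fraction=642 / 16_531,
            grs_r2_target=0.026,
            seed=seed,
        )
    raise ValueError(f"unknown scenario preset {name!r}")


@dataclass
class SimulatedStudy:
    """Everything one simulated MR study needs, generated from one config."""

    config: ScenarioConfig
    exposure: SummaryStatsSet
    outcome: SummaryStatsSet
    ld: LDReference
    truth: SimTruth
    per_study: dict[str, SummaryStatsSet] = field(default_factory=dict)
    cohort: CohortTable | None = None


def simulate_study(cfg: ScenarioConfig, with_cohort: bool = True) -> SimulatedStudy:
    exposure, truth = gen_exposure_gwas(cfg)
    outcome = gen_outcome_gwas(cfg, truth)
    ld = gen_ld_reference(cfg, truth)
    per_study = gen_study_outcomes(cfg, truth) if cfg.study_split else {}
    cohort = gen_cohort(cfg, truth) if (with_cohort and cfg.cohort_n > 0) else None
    return SimulatedStudy(
        config=cfg, exposure=exposure, outcome=outcome, ld=ld, truth=truth,
        per_study=per_study, cohort=cohort,
    )


def run_mr_replicates(
    cfg: ScenarioConfig,
    n_reps: int,
    seed: int,
    with_weighted_median: bool = False,
    wm_boot: int = 200,
) -> pd.DataFrame:
    """Generate ``n_reps`` independent datasets from ``cfg`` and estimate each.

    Each replicate regenerates the scenario under a child seed, harmonises the
    generated instrument panel against the outcome (no re-selection on
    significance: the panel *is* the instrument set by construction) and fits
    fixed-effect IVW, optionally also the weighted median.  Returns one row
    per replicate with the estimates, SEs and p-values.
    """
    rep_seeds = np.random.SeedSequence(seed).generate_state(2 * n_reps) & 0x7FFFFFFF
    rows = []
    for i in range(n_reps):
        cfg_i = replace(cfg, seed=int(rep_seeds[i]))
        exposure, truth = gen_exposure_gwas(cfg_i)
        outcome = gen_outcome_gwas(cfg_i, truth)
        ld = gen_ld_reference(cfg_i, truth)
        instruments, _ = harmonise(exposure.records, outcome, ld)
        est = estimators.ivw(instruments, model="fixed")
        row = {
            "beta_ivw": est.beta_causal,
            "se_ivw": est.se,
            "p_ivw": est.pvalue,
            "n_instruments": est.n_instruments,
        }
        if with_weighted_median:
            wm = estimators.weighted_median(
                instruments, n_boot=wm_boot, seed=int(rep_seeds[n_reps + i])
            )
            row.update({"beta_wm": wm.beta_causal, "se_wm": wm.se})
        rows.append(row)
    return pd.DataFrame(rows)
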