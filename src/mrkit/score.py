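"""Genetic risk scores, variance explained, and the observational
case-control association.

Three validation stages of an MR study live here:

* the beta-weighted genetic risk score (GRS) of each individual
  (:func:`compute_grs`) and the exposure variance it explains in an
  individual-level cohort (:func:`grs_r2`),
* the summary-level variance explained Σ 2f(1−f)β²/σ² for independent
  variants (:func:`summary_r2`), which needs only the discovery GWAS, and
* the observational exposure-outcome association: a logistic regression of
  case status on the exposure (per chosen standard unit) adjusted for age and
  sex (:func:`observational_or`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .estimators import Z95
from .sumstats import VariantAssociation

__all__ = [
    "CohortTable",
    "R2Result",
    "SeparationError",
    "compute_grs",
    "grs_r2",
    "summary_r2",
    "observational_or",
    "read_cohort",
    "write_cohort",
]

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Logistic fit diverged — the data are (quasi-)completely separated."""


@dataclass
class CohortTable:
    """Individual-level cohort: genotype dosages, exposure, covariates.

    ``data`` must carry columns ``id``, ``rdw`` (percent units, > 0), ``age``,
    ``sex`` (binary code), ``is_case`` and ``study``, plus one dosage column
    (values in [0,2], NaN for missing) per entry of ``variant_ids``.  ``eaf``
    (aligned to ``variant_ids``) enables 2·eaf mean-imputation of missing
    dosages.
    """

    data: pd.DataFrame
    variant_ids: list[str]
    eaf: np.ndarray | None = None

    def __post_init__(self) -> None:
        required = {"id", "rdw", "age", "sex", "is_case", "study"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table lacks column(s) {sorted(missing)}")
        absent = [v for v in self.variant_ids if v not in self.data.columns]
        if absent:
            raise ValueError(f"cohort table lacks dosage column(s) {absent[:5]}")
        if (self.data["rdw"] <= 0).any():
            raise ValueError("rdw must be positive (percent units)")
        dos = self.data[self.variant_ids].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(dos, initial=0.0) < 0.0 or np.nanmax(dos, initial=0.0) > 2.0:
                raise ValueError("dosages must lie in [0,2]")
        if self.eaf is not None:
            self.eaf = np.asarray(self.eaf, dtype=float)
            if self.eaf.shape != (len(self.variant_ids),):
                raise ValueError("eaf must align with variant_ids")

    def __len__(self) -> int:
        return len(self.data)

    def dosages(self) -> np.ndarray:
        return self.data[self.variant_ids].to_numpy(dtype=float)


@dataclass(frozen=True)
class R2Result:
    """Proportion of trait variance explained, with a bootstrap 95% CI."""

    r2: float
    ci_low: float
    ci_high: float
    source: str  # "individual" | "summary"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.r2 <= self.ci_high):
            raise ValueError("R² CI must bracket the estimate")


def compute_grs(
    cohort: CohortTable, weights: Sequence[float] | Mapping[str, float]
) -> np.ndarray:
    """Per-individual beta-weighted genetic risk score Σ_j dosage_ij · w_j.

    ``weights`` is aligned to ``cohort.variant_ids`` (a mapping is reindexed
    by rsid).  Missing dosages are mean-imputed at 2·eaf; per-variant
    missingness is logged.
    """
    if isinstance(weights, Mapping):
        try:
            w = np.array([weights[v] for v in cohort.variant_ids], dtype=float)
        except KeyError as e:
            raise ValueError(f"no weight for cohort variant {e.args[0]!r}") from e
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (len(cohort.variant_ids),):
        raise ValueError(
            f"weight vector length {w.shape} does not match "
            f"{len(cohort.variant_ids)} dosage columns"
        )
    dos = cohort.dosages()
    miss = np.isnan(dos)
    if miss.any():
        if cohort.eaf is None:
            raise ValueError("missing dosages require cohort.eaf for imputation")
        rates = miss.mean(axis=0)
        for v, rate in zip(cohort.variant_ids, rates):
            if rate > 0:
                logger.info("dosage missingness %.2f%% at %s (mean-imputed)", 100 * rate, v)
        fill = np.broadcast_to(2.0 * cohort.eaf, dos.shape)
        dos = np.where(miss, fill, dos)
    return dos @ w


def grs_r2(
    cohort: CohortTable,
    scores: np.ndarray,
    *,
    seed: int,
    n_boot: int = 2000,
) -> R2Result:
    """Variance in the exposure explained by the score: squared sample
    correlation of rdw and GRS, with a nonparametric bootstrap percentile CI
    over individuals."""
    scores = np.asarray(scores, dtype=float)
    rdw = cohort.data["rdw"].to_numpy(dtype=float)
    if len(scores) != len(rdw):
        raise ValueError("scores must align with the cohort rows")
    if len(rdw) < 3:
        raise ValueError("R² needs at least 3 individuals")
    if np.ptp(scores) == 0.0:
        raise ValueError("constant score vector: R² undefined")
    r2 = float(np.corrcoef(rdw, scores)[0, 1] ** 2)
    rng = np.random.default_rng(seed)
    n = len(rdw)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        s = scores[idx]
        if np.ptp(s) == 0.0:
            boots[b] = np.nan
            continue
        boots[b] = np.corrcoef(rdw[idx], s)[0, 1] ** 2
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    # percentile bounds can exclude the point estimate only through Monte-Carlo
    # noise in degenerate cohorts; clamp to preserve the container invariant
    return R2Result(r2=r2, ci_low=min(float(lo), r2), ci_high=max(float(hi), r2),
                    source="individual")


def summary_r2(
    variants: Sequence[VariantAssociation],
    trait_sd: float = 1.0,
    *,
    seed: int,
    n_boot: int = 2000,
) -> R2Result:
    """Summary-level variance explained by mutually independent variants.

    R² = Σ_j 2 f_j (1−f_j) β_j² / trait_sd², the variance of the additive
    genetic score under Hardy–Weinberg and linkage equilibrium.  ``trait_sd``
    converts per-allele effects reported in raw trait units to the SD scale
    (leave at 1 for effects already in SD units).  The CI is a seeded
    parametric bootstrap resampling each β_j ~ N(β_j, se_j).
    """
    if trait_sd <= 0:
        raise ValueError("trait_sd must be positive")
    if not variants:
        return R2Result(r2=0.0, ci_low=0.0, ci_high=0.0, source="summary")
    f = np.array([v.eaf for v in variants])
    beta = np.array([v.beta for v in variants])
    se = np.array([v.se for v in variants])
    het = 2.0 * f * (1.0 - f)
    r2 = float(np.sum(het * beta**2) / trait_sd**2)
    rng = np.random.default_rng(seed)
    betas = rng.normal(beta, se, size=(n_boot, len(beta)))
    boots = (het * betas**2).sum(axis=1) / trait_sd**2
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return R2Result(r2=r2, ci_low=min(float(lo), r2), ci_high=max(float(hi), r2),
                    source="summary")


def observational_or(
    cohort: CohortTable, scale_unit: float = 1.4
) -> tuple[float, float, float]:
    """Odds of being a case per ``scale_unit`` increase in RDW, adjusted for
    age and sex.

    Logistic regression (binomial GLM, iteratively reweighted least squares,
    deviance tolerance 1e-8, max 50 iterations) of case status on
    rdw/scale_unit + age + sex; returns the exponentiated RDW coefficient with
    its Wald 95% CI.  The default unit, 1.4% RDW, is one standard deviation in
    a common-disease control population.
    """
    if scale_unit <= 0:
        raise ValueError("scale_unit must be positive")
    y = cohort.data["is_case"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("cohort must contain both cases and controls")
    X = pd.DataFrame(
        {
            "rdw_scaled": cohort.data["rdw"].to_numpy(dtype=float) / scale_unit,
            "age": cohort.data["age"].to_numpy(dtype=float),
            "sex": cohort.data["sex"].to_numpy(dtype=float),
        }
    )
    X = sm.add_constant(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50, tol=1e-8)
    except PerfectSeparationWarning as e:
        raise SeparationError(str(e)) from e
    except Exception as e:  # statsmodels raises PerfectSeparationError subclasses
        raise SeparationError(str(e)) from e
    coef = float(res.params["rdw_scaled"])
    se = float(res.bse["rdw_scaled"])
    if not np.isfinite(coef) or not np.isfinite(se) or abs(coef) > 30:
        raise SeparationError("diverging RDW coefficient: complete separation suspected")
    return (
        float(np.exp(coef)),
        float(np.exp(coef - Z95 * se)),
        float(np.exp(coef + Z95 * se)),
    )


_COHORT_META_COLS = ("id", "rdw", "age", "sex", "is_case", "study")


def read_cohort(path, variant_ids: Sequence[str] | None = None,
                eaf: Sequence[float] | None = None) -> CohortTable:
    """Read a tab-delimited cohort table; dosage columns are named by rsid.

    When ``variant_ids`` is omitted, every non-metadata column is treated as a
    dosage column, in file order.
    """
    df = pd.read_csv(path, sep="\t")
    if variant_ids is None:
        variant_ids = [c for c in df.columns if c not in _COHORT_META_COLS]
    return CohortTable(
        data=df,
        variant_ids=list(variant_ids),
        eaf=None if eaf is None else np.asarray(eaf, dtype=float),
    )


def write_cohort(cohort: CohortTable, path) -> None:
    cols = list(_COHORT_META_COLS) + cohort.variant_ids
    cohort.data[cols].to_csv(path, sep="\t", index=False)
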