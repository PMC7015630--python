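"""Between-study heterogeneity and random-effects pooling of causal estimates.

When the outcome GWAS is a meta-analysis of several case-control studies with
differently ascertained controls, the causal effect can be estimated within
each study and compared across them: Cochran's Q with n_studies − 1 degrees of
freedom tests homogeneity, and a DerSimonian–Laird random-effects model pools
the per-study effects with weights 1/(se² + tau²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
from scipy import stats

from . import estimators
from .instruments import HarmonisedInstrument

__all__ = [
    "StudyEstimate",
    "MetaResult",
    "per_study_estimates",
    "meta_q",
    "q_pvalue",
    "random_effects_pool",
]


def q_pvalue(q: float, df: int) -> float:
    """Upper-tail chi-square probability of a Cochran's Q statistic."""
    if q < 0 or df < 1:
        raise ValueError("Q must be >= 0 and df >= 1")
    return float(stats.chi2.sf(q, df))

_Z95 = estimators.Z95


@dataclass(frozen=True)
class StudyEstimate:
    study: str
    beta: float  # causal log-odds per SD exposure
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.study}: standard error must be positive")


@dataclass(frozen=True)
class MetaResult:
    q: float
    df: int
    p: float
    tau2: float
    beta_pooled: float
    se_pooled: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "q", "df", "p", "tau2", "beta_pooled", "se_pooled", "ci_low", "ci_high"
        )}


def per_study_estimates(
    per_study_instruments: Mapping[str, Sequence[HarmonisedInstrument]],
    ivw_model: str = "fixed",
) -> list[StudyEstimate]:
    """IVW causal estimate within each study.

    Studies with no usable instrument are excluded with a warning; at least
    two populated studies are required for any between-study comparison.
    """
    out: list[StudyEstimate] = []
    for study, instruments in per_study_instruments.items():
        if not instruments:
            warnings.warn(f"study {study!r} has no instruments; excluded", stacklevel=2)
            continue
        est = estimators.ivw(list(instruments), model=ivw_model)
        out.append(StudyEstimate(study=study, beta=est.beta_causal, se=est.se))
    if len(out) < 2:
        raise ValueError("between-study analysis requires at least 2 populated studies")
    return out


def _fixed_effect(betas: np.ndarray, ses: np.ndarray) -> tuple[float, np.ndarray]:
    w = 1.0 / ses**2
    return float(np.sum(w * betas) / np.sum(w)), w


def meta_q(estimates: Sequence[StudyEstimate]) -> tuple[float, int, float]:
    """Cochran's Q across study estimates with fixed-effect weights 1/se²."""
    if len(estimates) < 2:
        raise ValueError("meta_q requires at least 2 estimates")
    betas = np.array([e.beta for e in estimates])
    ses = np.array([e.se for e in estimates])
    beta_fe, w = _fixed_effect(betas, ses)
    q = float(np.sum(w * (betas - beta_fe) ** 2))
    df = len(estimates) - 1
    return q, df, float(stats.chi2.sf(q, df))


def random_effects_pool(estimates: Sequence[StudyEstimate]) -> MetaResult:
    """DerSimonian–Laird random-effects pooled estimate.

    tau² = max(0, (Q − df) / (Σw − Σw²/Σw)) with fixed-effect weights w;
    the pooled effect uses weights 1/(se² + tau²).  When Q ≤ df the moment
    estimator truncates at zero and the pool equals the fixed-effect result.
    """
    q, df, p = meta_q(estimates)
    betas = np.array([e.beta for e in estimates])
    ses = np.array([e.se for e in estimates])
    w = 1.0 / ses**2
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (ses**2 + tau2)
    beta_pooled = float(np.sum(w_re * betas) / np.sum(w_re))
    se_pooled = math.sqrt(1.0 / float(np.sum(w_re)))
    return MetaResult(
        q=q,
        df=df,
        p=p,
        tau2=tau2,
        beta_pooled=beta_pooled,
        se_pooled=se_pooled,
        ci_low=beta_pooled - _Z95 * se_pooled,
        ci_high=beta_pooled + _Z95 * se_pooled,
    )
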