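"""Causal-effect estimators for two-sample Mendelian randomisation.

Given harmonised per-variant effects (exposure in SD units, outcome in
log-odds), each variant j provides a Wald ratio

    theta_j = beta_yj / beta_xj,    se(theta_j) = se_yj / |beta_xj|

(first-order delta method, exposure uncertainty ignored).  The inverse-
variance-weighted (IVW) estimate combines the ratios with weights
w_j = beta_xj^2 / se_yj^2, equivalently a zero-intercept weighted regression
of outcome on exposure effects.  The weighted median interpolates the
weight-ordered ratios at cumulative weight 1/2 and is consistent when at
least half the weight comes from valid instruments.  Cochran's Q over the
ratios diagnoses instrument heterogeneity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .instruments import HarmonisedInstrument

__all__ = [
    "MREstimate",
    "UndefinedRatioError",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "cochran_q",
    "to_odds_scale",
]

Z95 = float(stats.norm.isf(0.025))  # 1.959963985...


class UndefinedRatioError(ValueError):
    """Wald ratio requested for an instrument with zero exposure effect."""


@dataclass(frozen=True)
class MREstimate:
    """A causal log-odds effect per SD of exposure, with 95% CI on both the
    log-odds and the odds-ratio scale, and (for IVW) Cochran's Q diagnostics."""

    method: str  # ivw_fixed | ivw_mre | weighted_median
    beta_causal: float
    se: float
    ci_low: float
    ci_high: float
    or_causal: float
    or_low: float
    or_high: float
    pvalue: float
    n_instruments: int
    q: float | None = None
    q_df: int | None = None
    q_p: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("estimate standard error must be positive")
        if not self.ci_low < self.beta_causal < self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "method", "beta_causal", "se", "ci_low", "ci_high",
            "or_causal", "or_low", "or_high", "pvalue", "n_instruments",
            "q", "q_df", "q_p",
        )}


def _make_estimate(method: str, beta: float, se: float, n: int,
                   q: float | None = None, q_df: int | None = None,
                   q_p: float | None = None) -> MREstimate:
    lo, hi = beta - Z95 * se, beta + Z95 * se
    p = 2.0 * float(stats.norm.sf(abs(beta) / se))
    return MREstimate(
        method=method, beta_causal=beta, se=se, ci_low=lo, ci_high=hi,
        or_causal=math.exp(beta), or_low=math.exp(lo), or_high=math.exp(hi),
        pvalue=p, n_instruments=n, q=q, q_df=q_df, q_p=q_p,
    )


def wald_ratio(instr: HarmonisedInstrument) -> tuple[float, float]:
    """Per-variant causal estimate and its first-order standard error."""
    if instr.beta_exposure == 0:
        raise UndefinedRatioError(f"{instr.rsid}: zero exposure effect")
    return (
        instr.beta_outcome / instr.beta_exposure,
        instr.se_outcome / abs(instr.beta_exposure),
    )


def _ratio_arrays(instruments: Sequence[HarmonisedInstrument]) -> tuple[np.ndarray, np.ndarray]:
    ratios = np.empty(len(instruments))
    ses = np.empty(len(instruments))
    for j, ins in enumerate(instruments):
        ratios[j], ses[j] = wald_ratio(ins)
    return ratios, ses


def cochran_q(
    instruments: Sequence[HarmonisedInstrument], beta_ref: float
) -> tuple[float, int, float]:
    """Cochran's Q of the Wald ratios around ``beta_ref``.

    Q = sum_j (theta_j − beta_ref)^2 / se(theta_j)^2, chi-square with n−1
    degrees of freedom under homogeneity.
    """
    if len(instruments) < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    ratios, ses = _ratio_arrays(instruments)
    q = float(np.sum(((ratios - beta_ref) / ses) ** 2))
    df = len(instruments) - 1
    return q, df, float(stats.chi2.sf(q, df))


def ivw(
    instruments: Sequence[HarmonisedInstrument],
    model: str = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance-weighted causal estimate.

    beta = sum(bx*by/se_y^2) / sum(bx^2/se_y^2): the zero-intercept weighted
    regression of outcome on exposure effects.  ``model="fixed"`` takes
    se^2 = 1/sum(bx^2/se_y^2); ``"multiplicative_random"`` inflates the fixed
    SE by max(1, sqrt(Q/df)), reducing to the fixed model when the instruments
    are homogeneous.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    if not instruments:
        raise ValueError("IVW requires at least one instrument")
    bx = np.array([i.beta_exposure for i in instruments])
    by = np.array([i.beta_outcome for i in instruments])
    sy = np.array([i.se_outcome for i in instruments])
    if np.any(bx == 0):
        raise UndefinedRatioError("IVW requires non-zero exposure effects")
    w = 1.0 / sy**2
    denom = float(np.sum(bx**2 * w))
    beta = float(np.sum(bx * by * w)) / denom
    se = math.sqrt(1.0 / denom)
    method = "ivw_fixed"
    q = q_df = q_p = None
    if len(instruments) >= 2:
        q, q_df, q_p = cochran_q(instruments, beta)
    if model == "multiplicative_random":
        if len(instruments) == 1:
            warnings.warn(
                "multiplicative random effects undefined for a single instrument; "
                "falling back to the fixed-effect model",
                stacklevel=2,
            )
        else:
            se *= max(1.0, math.sqrt(q / q_df))
            method = "ivw_mre"
    return _make_estimate(method, beta, se, len(instruments), q, q_df, q_p)


def _interp_weighted_median(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Cumulative-weight-interpolated weighted median, vectorised over rows."""
    ratios = np.atleast_2d(ratios)
    weights = np.atleast_2d(weights)
    order = np.argsort(ratios, axis=1)
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(w, axis=1) - w / 2.0
    # index of the first midpoint at or above 1/2
    k = (s < 0.5).sum(axis=1)
    n = r.shape[1]
    out = np.empty(r.shape[0])
    for i in range(r.shape[0]):  # cheap: rows are bootstrap replicates
        ki = k[i]
        if ki == 0:
            out[i] = r[i, 0]
        elif ki == n:
            out[i] = r[i, -1]
        else:
            s0, s1 = s[i, ki - 1], s[i, ki]
            out[i] = r[i, ki - 1] + (r[i, ki] - r[i, ki - 1]) * (0.5 - s0) / (s1 - s0)
    return out


def weighted_median(
    instruments: Sequence[HarmonisedInstrument],
    n_boot: int = 10_000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Ratios are ordered ascending with normalised weights w_j = bx_j^2/se_yj^2;
    the estimate interpolates between the ratios whose half-step cumulative
    weights bracket 1/2.  The SE is the standard deviation of the estimate over
    ``n_boot`` parametric resamples of (beta_x, beta_y) from normal
    distributions with their reported SEs.
    """
    if len(instruments) < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    if n_boot < 100:
        raise ValueError("n_boot < 100 gives an unstable bootstrap SE")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    bx = np.array([i.beta_exposure for i in instruments])
    by = np.array([i.beta_outcome for i in instruments])
    sx = np.array([i.se_exposure for i in instruments])
    sy = np.array([i.se_outcome for i in instruments])
    if np.any(bx == 0):
        raise UndefinedRatioError("weighted median requires non-zero exposure effects")
    point = float(_interp_weighted_median(by / bx, bx**2 / sy**2)[0])
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, len(bx)))
    bys = rng.normal(by, sy, size=(n_boot, len(by)))
    bxs = np.where(bxs == 0.0, np.finfo(float).eps, bxs)
    boots = _interp_weighted_median(bys / bxs, bxs**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    if se == 0.0:
        se = float(np.finfo(float).eps)  # degenerate identical-ratio input
    return _make_estimate("weighted_median", point, se, len(instruments))


def to_odds_scale(estimate: MREstimate) -> MREstimate:
    """Recompute the odds-ratio fields from the log-odds fields (idempotent)."""
    return replace(
        estimate,
        or_causal=math.exp(estimate.beta_causal),
        or_low=math.exp(estimate.ci_low),
        or_high=math.exp(estimate.ci_high),
    )
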