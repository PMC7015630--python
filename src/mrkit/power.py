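"""Analytic power and sample-size calculations for two-sample MR with a
binary outcome.

The causal test statistic is approximated by its non-centrality: with total
outcome sample size N, case fraction K, instrument variance explained R² and
causal odds ratio OR per SD of exposure,

    z = sqrt(N * R² * K(1−K)) * |ln OR|
    power = Phi(z − z_{1−α/2})

which inverts in closed form for the minimum detectable OR and the required
sample size.  The approximation ignores the sub-alpha/2 lower-tail rejection
region, so power at OR=1 equals Phi(−z_{1−α/2}) (= 0.025 at α=0.05), not α.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerSpec",
    "mr_power",
    "min_detectable_or",
    "required_cases",
    "power_curve",
]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the non-centrality power approximation.

    ``case_fraction`` may be built from a case:control ratio 1:c as
    K = 1/(1+c) (:meth:`from_ratio`) or from realised counts
    (:meth:`from_counts`).
    """

    n_total: int
    case_fraction: float
    r2: float
    or_causal: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0,1)")
        if not (0.0 < self.r2 < 1.0):
            raise ValueError("r2 must be in (0,1)")
        if self.or_causal <= 0.0:
            raise ValueError("or_causal must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0,1)")

    @classmethod
    def from_counts(
        cls, n_total: int, n_cases: int, r2: float, or_causal: float, alpha: float = 0.05
    ) -> "PowerSpec":
        return cls(n_total, n_cases / n_total, r2, or_causal, alpha)

    @classmethod
    def from_ratio(
        cls, n_total: int, control_to_case_ratio: float, r2: float,
        or_causal: float, alpha: float = 0.05,
    ) -> "PowerSpec":
        return cls(n_total, 1.0 / (1.0 + control_to_case_ratio), r2, or_causal, alpha)


def _ncp_scale(n_total: float, case_fraction: float, r2: float) -> float:
    return math.sqrt(n_total * r2 * case_fraction * (1.0 - case_fraction))


def mr_power(spec: PowerSpec) -> float:
    """Power of the two-sided causal test under the NCP approximation."""
    z_crit = float(stats.norm.isf(spec.alpha / 2.0))
    z = _ncp_scale(spec.n_total, spec.case_fraction, spec.r2) * abs(math.log(spec.or_causal))
    return float(stats.norm.cdf(z - z_crit))


def min_detectable_or(
    n_total: int,
    case_fraction: float,
    r2: float,
    target_power: float = 0.8,
    alpha: float = 0.05,
) -> float:
    """Smallest OR > 1 detectable at ``target_power`` — closed-form inversion.

    mr_power at the returned OR equals ``target_power`` exactly (to the
    precision of the normal quantile function).
    """
    if not (alpha < target_power < 1.0):
        raise ValueError("target_power must be in (alpha, 1)")
    z_crit = float(stats.norm.isf(alpha / 2.0))
    z_pow = float(stats.norm.ppf(target_power))
    return math.exp((z_crit + z_pow) / _ncp_scale(n_total, case_fraction, r2))


def required_cases(
    or_causal: float,
    r2: float,
    control_to_case_ratio: float,
    target_power: float = 0.8,
    alpha: float = 0.05,
) -> int:
    """Number of cases needed to detect ``or_causal`` at ``target_power``.

    With K = 1/(1+c), N = (z_{1−α/2}+z_power)² / (R² K(1−K) ln²OR) and the
    case count is ceil(N·K).
    """
    if or_causal == 1.0:
        raise ValueError("or_causal = 1 requires an infinite sample")
    if not (alpha < target_power < 1.0):
        raise ValueError("target_power must be in (alpha, 1)")
    k = 1.0 / (1.0 + control_to_case_ratio)
    z_crit = float(stats.norm.isf(alpha / 2.0))
    z_pow = float(stats.norm.ppf(target_power))
    n_total = (z_crit + z_pow) ** 2 / (r2 * k * (1.0 - k) * math.log(or_causal) ** 2)
    return math.ceil(n_total * k)


def power_curve(
    n_total: int,
    case_fraction: float,
    r2_values,
    or_grid=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Power against OR for several instrument-R² values.

    Returns a long-format table (or_causal, r2, power) for the standard
    power-versus-effect-size figure; default OR grid 1.00–2.20 by 0.01.
    """
    if or_grid is None:
        or_grid = np.round(np.arange(1.0, 2.2 + 1e-9, 0.01), 10)
    rows = []
    for r2 in np.atleast_1d(r2_values):
        base = PowerSpec(n_total, case_fraction, float(r2), 1.5, alpha)
        for orv in np.atleast_1d(or_grid):
            rows.append(
                {
                    "or_causal": float(orv),
                    "r2": float(r2),
                    "power": mr_power(replace(base, or_causal=float(orv))),
                }
            )
    return pd.DataFrame(rows)
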