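"""Model/Results interface over the two-sample MR estimators.

`MRModel` holds a harmonised instrument table (built directly, from a
DataFrame, or from raw exposure/outcome summary statistics via the full
instrument pipeline); `fit()` returns an `MRResults` carrying the causal
estimate, its uncertainty, the heterogeneity diagnostics and a printable
summary table.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import estimators
from .estimators import MREstimate
from .instruments import (
    DEFAULT_CLUMP_R2,
    DEFAULT_P_THRESHOLD,
    DEFAULT_PALINDROME_MAF,
    DEFAULT_PROXY_R2,
    HarmonisedInstrument,
    InstrumentAudit,
    build_instruments,
)
from .sumstats import LDReference, SummaryStatsSet

__all__ = ["MRModel", "MRResults"]


class MRModel:
    """Two-sample Mendelian randomisation model for a binary outcome.

    Parameters
    ----------
    instruments
        Harmonised instruments: exposure effects in SD units, outcome effects
        in log-odds, both aligned to a shared effect allele.
    exposure_name, outcome_name
        Labels used in summaries.

    Examples
    --------
    >>> model = MRModel(instruments, exposure_name="RDW", outcome_name="PAH")
    >>> res = model.fit(method="ivw")
    >>> res.odds_ratio, res.conf_int_or()
    """

    def __init__(
        self,
        instruments: Sequence[HarmonisedInstrument],
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
        audit: InstrumentAudit | None = None,
    ) -> None:
        if not instruments:
            raise ValueError("MRModel requires at least one instrument")
        self.instruments = list(instruments)
        self.exposure_name = exposure_name
        self.outcome_name = outcome_name
        self.audit = audit

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> "MRModel":
        """Build from a table with columns rsid, beta_exposure, se_exposure,
        beta_outcome, se_outcome, eaf (optionally is_proxy, proxy_r2)."""
        instruments = [
            HarmonisedInstrument(
                rsid=str(row["rsid"]),
                beta_exposure=float(row["beta_exposure"]),
                se_exposure=float(row["se_exposure"]),
                beta_outcome=float(row["beta_outcome"]),
                se_outcome=float(row["se_outcome"]),
                eaf=float(row["eaf"]),
                is_proxy=bool(row.get("is_proxy", False)),
                proxy_r2=(None if pd.isna(row.get("proxy_r2", np.nan)) else float(row["proxy_r2"])),
                proxy_rsid=(row.get("proxy_rsid") or None),
            )
            for _, row in df.iterrows()
        ]
        return cls(instruments, exposure_name, outcome_name)

    @classmethod
    def from_summary_stats(
        cls,
        exposure: SummaryStatsSet,
        outcome: SummaryStatsSet,
        ld: LDReference | None = None,
        p_threshold: float = DEFAULT_P_THRESHOLD,
        clump_r2: float = DEFAULT_CLUMP_R2,
        proxy_r2: float = DEFAULT_PROXY_R2,
        palindrome_maf: float = DEFAULT_PALINDROME_MAF,
    ) -> "MRModel":
        """Run the full instrument pipeline on raw summary statistics."""
        instruments, audit = build_instruments(
            exposure, outcome, ld, p_threshold, clump_r2, proxy_r2, palindrome_maf
        )
        return cls(instruments, exposure.trait_label, outcome.trait_label, audit=audit)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [i.rsid for i in self.instruments],
                "beta_exposure": [i.beta_exposure for i in self.instruments],
                "se_exposure": [i.se_exposure for i in self.instruments],
                "beta_outcome": [i.beta_outcome for i in self.instruments],
                "se_outcome": [i.se_outcome for i in self.instruments],
                "eaf": [i.eaf for i in self.instruments],
                "is_proxy": [i.is_proxy for i in self.instruments],
                "proxy_r2": [i.proxy_r2 for i in self.instruments],
                "proxy_rsid": [i.proxy_rsid for i in self.instruments],
            }
        )

    @property
    def wald_ratios(self) -> pd.DataFrame:
        """Per-instrument Wald ratios and their delta-method SEs."""
        rows = []
        for ins in self.instruments:
            ratio, se = estimators.wald_ratio(ins)
            rows.append({"rsid": ins.rsid, "ratio": ratio, "se": se})
        return pd.DataFrame(rows)

    def subset(self, rsids: Sequence[str]) -> "MRModel":
        wanted = set(rsids)
        kept = [i for i in self.instruments if i.rsid in wanted]
        if not kept:
            raise ValueError("subset contains no instrument of this model")
        return MRModel(kept, self.exposure_name, self.outcome_name)

    def fit(
        self,
        method: str = "ivw",
        ivw_model: str = "multiplicative_random",
        n_boot: int = 10_000,
        seed: int | None = None,
    ) -> "MRResults":
        """Fit the causal model.

        ``method`` is ``"ivw"`` (with ``ivw_model`` fixed or multiplicative
        random effects) or ``"weighted_median"`` (parametric bootstrap SE;
        ``seed`` mandatory).
        """
        if method == "ivw":
            est = estimators.ivw(self.instruments, model=ivw_model)
        elif method == "weighted_median":
            est = estimators.weighted_median(self.instruments, n_boot=n_boot, seed=seed)
        else:
            raise ValueError(f"unknown method {method!r}")
        return MRResults(self, est)

    def fit_all(
        self,
        methods: Sequence[str] = ("ivw", "weighted_median"),
        ivw_model: str = "multiplicative_random",
        n_boot: int = 10_000,
        seed: int | None = None,
    ) -> dict[str, "MRResults"]:
        return {
            m: self.fit(m, ivw_model=ivw_model, n_boot=n_boot, seed=seed) for m in methods
        }


class MRResults:
    """Results of a fitted MR model; thin value wrapper around MREstimate."""

    def __init__(self, model: MRModel, estimate: MREstimate) -> None:
        self.model = model
        self.estimate = estimate

    # -- statsmodels-flavoured accessors ------------------------------------
    @property
    def method(self) -> str:
        return self.estimate.method

    @property
    def beta(self) -> float:
        """Causal log-odds effect per SD of exposure."""
        return self.estimate.beta_causal

    @property
    def bse(self) -> float:
        return self.estimate.se

    @property
    def pvalue(self) -> float:
        return self.estimate.pvalue

    @property
    def odds_ratio(self) -> float:
        return self.estimate.or_causal

    @property
    def nobs(self) -> int:
        return self.estimate.n_instruments

    def conf_int(self) -> tuple[float, float]:
        return self.estimate.ci_low, self.estimate.ci_high

    def conf_int_or(self) -> tuple[float, float]:
        return self.estimate.or_low, self.estimate.or_high

    def summary(self) -> str:
        e = self.estimate
        m = self.model
        lines = [
            "Two-sample Mendelian randomisation",
            "=" * 58,
            f"Exposure: {m.exposure_name}   Outcome: {m.outcome_name}",
            f"Method: {e.method}   Instruments: {e.n_instruments}",
            "-" * 58,
            f"{'':<18}{'estimate':>10}{'se':>8}{'[95% CI]':>20}",
            f"{'log-odds / SD':<18}{e.beta_causal:>10.4f}{e.se:>8.4f}"
            f"{'[' + format(e.ci_low, '.4f') + ', ' + format(e.ci_high, '.4f') + ']':>20}",
            f"{'odds ratio / SD':<18}{e.or_causal:>10.4f}{'':>8}"
            f"{'[' + format(e.or_low, '.4f') + ', ' + format(e.or_high, '.4f') + ']':>20}",
            f"{'p-value':<18}{e.pvalue:>10.3g}",
        ]
        if e.q is not None:
            lines.append("-" * 58)
            lines.append(
                f"Cochran's Q: {e.q:.3f}  df: {e.q_df}  p: {e.q_p:.3f}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        e = self.estimate
        return (
            f"<MRResults {e.method} OR={e.or_causal:.3f} "
            f"CI=({e.or_low:.3f}, {e.or_high:.3f}) n={e.n_instruments}>"
        )
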