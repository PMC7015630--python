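"""Genetic-instrument construction for two-sample Mendelian randomisation.

The instrument pipeline turns an exposure GWAS into a harmonised instrument
table usable for causal estimation:

1. genome-wide-significance filter (:func:`select_significant`),
2. greedy LD pruning to mutual independence (:func:`ld_prune`),
3. exclusion of strand-ambiguous palindromic variants at intermediate allele
   frequency (:func:`drop_palindromic`),
4. proxy substitution for instruments absent from the outcome GWAS
   (:func:`find_proxy`), and
5. allele harmonisation of the exposure and outcome effects to one shared
   effect allele (:func:`harmonise`).

Every input variant ends up in exactly one disposition category of the
:class:`InstrumentAudit`, so the stage counts reconcile exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .sumstats import (
    COMPLEMENT,
    LDReference,
    SummaryStatsSet,
    VariantAssociation,
)

__all__ = [
    "HarmonisedInstrument",
    "InstrumentAudit",
    "Disposition",
    "select_significant",
    "ld_prune",
    "drop_palindromic",
    "find_proxy",
    "harmonise",
    "build_instruments",
]

logger = logging.getLogger(__name__)

# paper-default thresholds for the whole pipeline
DEFAULT_P_THRESHOLD = 8.31e-9
DEFAULT_CLUMP_R2 = 0.01
DEFAULT_PROXY_R2 = 0.8
DEFAULT_PALINDROME_MAF = 0.45


@dataclass(frozen=True)
class HarmonisedInstrument:
    """Exposure and outcome effects of one variant, aligned to a shared
    effect allele.

    ``beta_exposure`` is in exposure-SD units, ``beta_outcome`` in log-odds.
    When the outcome effect comes from an LD proxy rather than the variant
    itself, ``is_proxy`` is set and ``proxy_r2``/``proxy_rsid`` identify it.
    """

    rsid: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float
    is_proxy: bool = False
    proxy_r2: float | None = None
    proxy_rsid: str | None = None

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError(f"{self.rsid}: standard errors must be positive")
        if self.is_proxy and (self.proxy_r2 is None or self.proxy_r2 <= 0):
            raise ValueError(f"{self.rsid}: proxy instruments require proxy_r2")


@dataclass(frozen=True)
class Disposition:
    rsid: str
    status: str  # kept | kept_proxy | dropped_palindromic | dropped_unmatched | dropped_irreconcilable
    detail: str = ""


@dataclass
class InstrumentAudit:
    """Stage-by-stage bookkeeping of instrument construction.

    ``n_significant`` and ``n_independent`` are populated by
    :func:`build_instruments`; :func:`harmonise` alone fills the harmonisation
    counts.  ``check()`` asserts the conservation identity
    ``n_final = n_independent − n_palindromic_dropped − n_unmatched
    − n_irreconcilable`` (proxied variants are counted inside ``n_final``).
    """

    n_significant: int | None = None
    n_independent: int | None = None
    n_palindromic_dropped: int = 0
    n_absent: int = 0
    n_proxied: int = 0
    n_unmatched: int = 0
    n_irreconcilable: int = 0
    n_final: int = 0
    dispositions: list[Disposition] = field(default_factory=list)

    def check(self) -> None:
        n_input = self.n_independent if self.n_independent is not None else len(self.dispositions)
        if n_input != len(self.dispositions):
            raise AssertionError("audit dispositions do not cover the input")
        if self.n_final != (
            n_input - self.n_palindromic_dropped - self.n_unmatched - self.n_irreconcilable
        ):
            raise AssertionError("audit stage counts do not reconcile")
        if self.n_unmatched != self.n_absent - self.n_proxied:
            raise AssertionError("proxy bookkeeping does not reconcile")

    def to_dict(self) -> dict:
        return {
            "n_significant": self.n_significant,
            "n_independent": self.n_independent,
            "n_palindromic_dropped": self.n_palindromic_dropped,
            "n_absent": self.n_absent,
            "n_proxied": self.n_proxied,
            "n_unmatched": self.n_unmatched,
            "n_irreconcilable": self.n_irreconcilable,
            "n_final": self.n_final,
            "dispositions": [
                {"rsid": d.rsid, "status": d.status, "detail": d.detail} for d in self.dispositions
            ],
        }


def select_significant(
    sumset: SummaryStatsSet, threshold: float = DEFAULT_P_THRESHOLD
) -> list[VariantAssociation]:
    """Records with p strictly below ``threshold``, input order preserved."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("significance threshold must be in (0,1)")
    return [r for r in sumset.records if r.pvalue < threshold]


def ld_prune(
    variants: Sequence[VariantAssociation],
    ld: LDReference,
    r2_max: float = DEFAULT_CLUMP_R2,
) -> list[VariantAssociation]:
    """Greedy p-ordered clumping to mutual independence.

    Variants are visited in ascending p-value (ties broken by rsid, making the
    result invariant to input order) and accepted iff their r² with every
    already-accepted variant is below ``r2_max``.  Variants absent from the LD
    reference are treated as unlinked.
    """
    accepted: list[VariantAssociation] = []
    for v in sorted(variants, key=lambda v: (v.pvalue, v.rsid)):
        if all(ld.r2(v.rsid, a.rsid) < r2_max for a in accepted):
            accepted.append(v)
    return accepted


def drop_palindromic(
    variants: Sequence[VariantAssociation], maf_max: float = DEFAULT_PALINDROME_MAF
) -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """Split off palindromic variants with intermediate allele frequency.

    A variant is dropped iff it is palindromic (A/T or C/G) *and* its minor
    allele frequency exceeds ``maf_max``: near 50% frequency cannot resolve
    the strand, so such variants cannot be harmonised reliably.  Palindromic
    variants below the threshold are retained for frequency alignment.
    """
    if not (0.0 < maf_max <= 0.5):
        raise ValueError("maf_max must be in (0, 0.5]")
    kept, dropped = [], []
    for v in variants:
        if v.is_palindromic and v.maf > maf_max:
            dropped.append(v)
        else:
            kept.append(v)
    return kept, dropped


def find_proxy(
    missing: VariantAssociation,
    outcome: SummaryStatsSet,
    ld: LDReference,
    r2_min: float = DEFAULT_PROXY_R2,
) -> tuple[str, float] | None:
    """Best available LD proxy in the outcome set for a missing instrument.

    Among outcome variants with r² ≥ ``r2_min`` to ``missing``, returns the
    highest-r² candidate; ties are broken by smaller basepair distance, then
    lexicographic rsid.  Returns None when no candidate qualifies.
    """
    if not (0.0 < r2_min <= 1.0):
        raise ValueError("r2_min must be in (0,1]")
    candidates: list[tuple[float, float, str]] = []
    for rsid, r2 in ld.neighbours(missing.rsid, r2_min):
        rec = outcome.get(rsid)
        if rec is None or rsid == missing.rsid:
            continue
        dist = abs(rec.pos - missing.pos) if rec.chrom == missing.chrom else float("inf")
        candidates.append((-r2, dist, rsid))
    if not candidates:
        return None
    neg_r2, _, rsid = min(candidates)
    return rsid, -neg_r2


def _align_outcome(
    exp: VariantAssociation, out: VariantAssociation
) -> tuple[float, float, str] | None:
    """Align an outcome record to the exposure's effect allele.

    Returns ``(beta_outcome, eaf_outcome, mode)`` with the outcome effect
    expressed per copy of the exposure effect allele, or None when the allele
    pairs are irreconcilable.  Palindromic pairs are aligned by allele
    frequency (letters carry no strand information for them).
    """
    exp_pair = frozenset((exp.effect_allele, exp.other_allele))
    out_pair = frozenset((out.effect_allele, out.other_allele))
    if exp.is_palindromic:
        if out_pair != exp_pair:
            return None
        # match the minor allele of each study; ambiguous exactly at 0.5
        same_side = (exp.eaf < 0.5) == (out.eaf < 0.5)
        if same_side:
            return out.beta, out.eaf, "palindromic_freq"
        return -out.beta, 1.0 - out.eaf, "palindromic_freq_flip"
    if out_pair == exp_pair:
        if out.effect_allele == exp.effect_allele:
            return out.beta, out.eaf, "aligned"
        return -out.beta, 1.0 - out.eaf, "swap"
    comp_pair = frozenset(COMPLEMENT[a] for a in out_pair)
    if comp_pair == exp_pair:
        # strand flip: complement the outcome alleles, then the swap rule
        if COMPLEMENT[out.effect_allele] == exp.effect_allele:
            return out.beta, out.eaf, "strand_flip"
        return -out.beta, 1.0 - out.eaf, "strand_flip_swap"
    return None


def _freq_align_proxy(
    exp: VariantAssociation, proxy: VariantAssociation
) -> tuple[float, float, str]:
    # no phase information in an r²-only LD reference: align the proxy's
    # effect allele to the exposure effect allele by frequency side
    if (exp.eaf < 0.5) == (proxy.eaf < 0.5):
        return proxy.beta, proxy.eaf, "proxy_freq"
    return -proxy.beta, 1.0 - proxy.eaf, "proxy_freq_flip"


def harmonise(
    exposure: Sequence[VariantAssociation],
    outcome: SummaryStatsSet,
    ld: LDReference | None = None,
    maf_max: float = DEFAULT_PALINDROME_MAF,
    r2_min: float = DEFAULT_PROXY_R2,
) -> tuple[list[HarmonisedInstrument], InstrumentAudit]:
    """Harmonise exposure and outcome effects to the exposure effect allele.

    ``exposure`` must already be significance-filtered and LD-pruned.  For
    each exposure variant: intermediate-frequency palindromes are dropped;
    variants absent from the outcome are proxied through ``ld`` when a proxy
    with r² ≥ ``r2_min`` exists, otherwise dropped; outcome effects reported
    for the other allele or the other strand are sign- and frequency-flipped;
    variants whose allele pairs cannot be reconciled are dropped.  The audit
    lists each input variant under exactly one disposition.
    """
    seen: set[str] = set()
    for v in exposure:
        if v.rsid in seen:
            raise ValueError(f"duplicate rsid {v.rsid!r} in exposure instrument list")
        seen.add(v.rsid)

    audit = InstrumentAudit()
    instruments: list[HarmonisedInstrument] = []
    for exp in exposure:
        if exp.is_palindromic and exp.maf > maf_max:
            audit.n_palindromic_dropped += 1
            audit.dispositions.append(
                Disposition(exp.rsid, "dropped_palindromic", f"maf={exp.maf:.3f}>{maf_max}")
            )
            continue
        out = outcome.get(exp.rsid)
        if out is None:
            audit.n_absent += 1
            proxy = find_proxy(exp, outcome, ld, r2_min) if ld is not None else None
            if proxy is None:
                audit.n_unmatched += 1
                audit.dispositions.append(
                    Disposition(exp.rsid, "dropped_unmatched", "absent from outcome, no proxy")
                )
                continue
            proxy_rsid, proxy_r2 = proxy
            proxy_rec = outcome.get(proxy_rsid)
            beta_out, eaf_out, mode = _freq_align_proxy(exp, proxy_rec)
            logger.info(
                "proxy %s (r2=%.3f) frequency-aligned for %s: lower-confidence alignment",
                proxy_rsid, proxy_r2, exp.rsid,
            )
            audit.n_proxied += 1
            audit.n_final += 1
            audit.dispositions.append(
                Disposition(exp.rsid, "kept_proxy", f"{proxy_rsid} r2={proxy_r2:.3f} {mode}")
            )
            instruments.append(
                HarmonisedInstrument(
                    rsid=exp.rsid,
                    beta_exposure=exp.beta,
                    se_exposure=exp.se,
                    beta_outcome=beta_out,
                    se_outcome=proxy_rec.se,
                    eaf=exp.eaf,
                    is_proxy=True,
                    proxy_r2=proxy_r2,
                    proxy_rsid=proxy_rsid,
                )
            )
            continue
        aligned = _align_outcome(exp, out)
        if aligned is None:
            audit.n_irreconcilable += 1
            audit.dispositions.append(
                Disposition(
                    exp.rsid,
                    "dropped_irreconcilable",
                    f"{exp.effect_allele}/{exp.other_allele} vs {out.effect_allele}/{out.other_allele}",
                )
            )
            continue
        beta_out, _, mode = aligned
        audit.n_final += 1
        audit.dispositions.append(Disposition(exp.rsid, "kept", mode))
        instruments.append(
            HarmonisedInstrument(
                rsid=exp.rsid,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=beta_out,
                se_outcome=out.se,
                eaf=exp.eaf,
            )
        )
    audit.n_independent = len(exposure)
    audit.check()
    return instruments, audit


def build_instruments(
    exposure: SummaryStatsSet,
    outcome: SummaryStatsSet,
    ld: LDReference | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    clump_r2: float = DEFAULT_CLUMP_R2,
    proxy_r2: float = DEFAULT_PROXY_R2,
    palindrome_maf: float = DEFAULT_PALINDROME_MAF,
) -> tuple[list[HarmonisedInstrument], InstrumentAudit]:
    """Full instrument pipeline: significance → LD pruning → harmonisation."""
    significant = select_significant(exposure, p_threshold)
    independent = ld_prune(significant, ld or LDReference(), clump_r2)
    instruments, audit = harmonise(independent, outcome, ld, palindrome_maf, proxy_r2)
    audit.n_significant = len(significant)
    audit.n_independent = len(independent)
    logger.info(
        "instruments: %d significant -> %d independent -> %d harmonised "
        "(%d palindromic dropped, %d proxied, %d unmatched, %d irreconcilable)",
        audit.n_significant, audit.n_independent, audit.n_final,
        audit.n_palindromic_dropped, audit.n_proxied, audit.n_unmatched,
        audit.n_irreconcilable,
    )
    return instruments, audit
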