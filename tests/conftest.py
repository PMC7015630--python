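import numpy as np
import pytest

from mrkit.instruments import HarmonisedInstrument
from mrkit.sumstats import SummaryStatsSet, VariantAssociation


def make_variant(
    rsid="rs1",
    chrom="1",
    pos=1000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pvalue=1e-12,
    n=10_000,
) -> VariantAssociation:
    return VariantAssociation(
        rsid=rsid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pvalue=pvalue, n=n,
    )


def make_sumset(records, trait_label="trait", trait_type="continuous",
                n_total=None, n_cases=None) -> SummaryStatsSet:
    if n_total is None:
        n_total = max((r.n for r in records), default=1)
    return SummaryStatsSet(
        trait_label=trait_label, trait_type=trait_type, records=list(records),
        n_total=n_total, n_cases=n_cases,
    )


def make_instr(rsid="rs1", bx=0.1, sex=0.01, by=0.05, sey=0.02,
               eaf=0.3, **kw) -> HarmonisedInstrument:
    return HarmonisedInstrument(
        rsid=rsid, beta_exposure=bx, se_exposure=sex,
        beta_outcome=by, se_outcome=sey, eaf=eaf, **kw,
    )


def random_instruments(rng: np.random.Generator, n: int) -> list[HarmonisedInstrument]:
    """A well-behaved random instrument panel for property tests."""
    bx = rng.uniform(0.02, 0.2, n) * rng.choice([-1.0, 1.0], n)
    return [
        make_instr(
            rsid=f"rs{j}", bx=float(bx[j]), sex=float(rng.uniform(0.002, 0.01)),
            by=float(rng.normal(0, 0.05)), sey=float(rng.uniform(0.01, 0.1)),
            eaf=float(rng.uniform(0.05, 0.95)),
        )
        for j in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
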