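"""Validated containers and tab-delimited I/O for GWAS summary statistics.

The whole package works from two kinds of boundary objects defined here:

* :class:`SummaryStatsSet` — one trait's GWAS summary statistics, a list of
  per-variant :class:`VariantAssociation` records.  For a continuous trait the
  effects are per-allele, in trait-standard-deviation units; for a binary trait
  they are per-allele log-odds.
* :class:`LDReference` — pairwise linkage-disequilibrium r² between variants,
  used for pruning to independence and for proxy lookup.

All validation happens at this boundary: a row of an input file is either
converted into a valid record or rejected with exactly one primary reason, so
downstream code never re-checks field invariants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "SummaryStatsSet",
    "LDReference",
    "RejectedRow",
    "DialectError",
    "EmptyInputError",
    "DEFAULT_DIALECT",
    "read_sumstats",
    "write_sumstats",
    "read_ld",
    "write_ld",
]

VALID_BASES = frozenset("ACGT")
_PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: smallest positive normal double; p-values that underflow are clamped here
MIN_PVALUE = float(np.finfo(np.float64).tiny)

#: canonical field -> default file column name
DEFAULT_DIALECT: dict[str, str] = {
    "rsid": "rsid",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "n",
}


class DialectError(ValueError):
    """A mandatory column is missing from an input file."""


class EmptyInputError(ValueError):
    """No valid rows survived validation."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's per-allele association with one trait.

    ``beta`` is the effect of each copy of ``effect_allele`` (trait-SD units
    for continuous traits, log-odds for binary traits); ``eaf`` is the
    effect-allele frequency, mandatory because palindrome handling and
    summary-level R² are undefined without it.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def __post_init__(self) -> None:
        reason = validation_error(
            self.effect_allele, self.other_allele, self.eaf, self.se, self.pvalue, self.n
        )
        if reason is not None:
            raise ValueError(f"{self.rsid}: {reason}")

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G variant — strand cannot be inferred from alleles alone."""
        return frozenset((self.effect_allele, self.other_allele)) in _PALINDROMIC_PAIRS

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    def flipped(self) -> "VariantAssociation":
        """The same association reported for the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


def validation_error(
    effect_allele: str,
    other_allele: str,
    eaf: float,
    se: float,
    pvalue: float,
    n: int,
) -> str | None:
    """First violated field invariant, or None if the record is valid.

    The order of the checks defines the single *primary* reason reported for a
    rejected input row.
    """
    if effect_allele not in VALID_BASES or other_allele not in VALID_BASES:
        return "invalid allele (must be a single base A/C/G/T)"
    if effect_allele == other_allele:
        return "identical effect and other allele"
    if not (0.0 < eaf < 1.0):
        return "effect-allele frequency outside (0,1)"
    if not se > 0.0:
        return "non-positive standard error"
    if not (0.0 < pvalue <= 1.0):
        return "p-value outside (0,1]"
    if not n > 0:
        return "non-positive sample size"
    return None


@dataclass(frozen=True)
class RejectedRow:
    row: int
    rsid: str
    reason: str


@dataclass
class SummaryStatsSet:
    """GWAS summary statistics for one trait."""

    trait_label: str
    trait_type: str  # "continuous" | "binary"
    records: list[VariantAssociation]
    n_total: int
    n_cases: int | None = None
    rejected: list[RejectedRow] = field(default_factory=list)
    _index: dict[str, VariantAssociation] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.n_cases is not None and self.n_cases >= self.n_total:
            raise ValueError("n_cases must be smaller than n_total")
        index: dict[str, VariantAssociation] = {}
        for rec in self.records:
            if rec.rsid in index:
                raise ValueError(f"duplicate rsid {rec.rsid!r} in {self.trait_label!r}")
            index[rec.rsid] = rec
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def get(self, rsid: str) -> VariantAssociation | None:
        return self._index.get(rsid)

    def to_frame(self) -> pd.DataFrame:
        cols = list(DEFAULT_DIALECT)
        data = {c: [getattr(r, c) for r in self.records] for c in cols}
        return pd.DataFrame(data)


class LDReference:
    """Symmetric pairwise r² between variants; unlisted pairs are r²=0.

    Stored sparsely as an adjacency map, which supports both membership
    queries (pruning) and neighbour enumeration (proxy search).
    """

    def __init__(self, pairs: Iterable[tuple[str, str, float]] = ()) -> None:
        self._adj: dict[str, dict[str, float]] = {}
        for a, b, r2 in pairs:
            self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        r2 = float(r2)
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r² outside [0,1] for pair ({a}, {b}): {r2}")
        if a == b:
            if r2 != 1.0:
                raise ValueError(f"diagonal r² must be 1, got {r2} for {a}")
            return  # diagonal is implicit
        self._adj.setdefault(a, {})[b] = r2
        self._adj.setdefault(b, {})[a] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._adj.get(a, {}).get(b, 0.0)

    def neighbours(self, a: str, r2_min: float = 0.0) -> list[tuple[str, float]]:
        """Variants with stored r² ≥ ``r2_min`` to ``a``."""
        return [(b, r2) for b, r2 in self._adj.get(a, {}).items() if r2 >= r2_min]

    def ids(self) -> list[str]:
        return sorted(self._adj)

    def to_pairs(self) -> list[tuple[str, str, float]]:
        out = []
        for a, nbrs in self._adj.items():
            for b, r2 in nbrs.items():
                if a < b:
                    out.append((a, b, r2))
        return sorted(out)


# ---------------------------------------------------------------------------
# file I/O


def _parse_row(
    raw: Mapping[str, str], dialect: Mapping[str, str]
) -> tuple[VariantAssociation | None, str | None]:
    vals: dict[str, object] = {}
    for canon, col in dialect.items():
        cell = raw[col]
        text = "" if cell is None else str(cell).strip()
        if text == "" or text.upper() in ("NA", "NAN"):
            return None, f"missing value in mandatory field '{canon}'"
        vals[canon] = text
    try:
        pos = int(float(vals["pos"]))  # tolerate "123.0"
        eaf = float(vals["eaf"])
        beta = float(vals["beta"])
        se = float(vals["se"])
        pvalue = float(vals["pvalue"])
        n = int(float(vals["n"]))
    except ValueError:
        return None, "unparseable numeric field"
    if not (math.isfinite(eaf) and math.isfinite(beta) and math.isfinite(se) and math.isfinite(pvalue)):
        return None, "non-finite numeric field"
    if 0.0 <= pvalue < MIN_PVALUE:
        warnings.warn(
            f"p-value underflow for {vals['rsid']}; clamped to {MIN_PVALUE:.3e}",
            stacklevel=3,
        )
        pvalue = MIN_PVALUE
    ea = str(vals["effect_allele"]).upper()
    oa = str(vals["other_allele"]).upper()
    reason = validation_error(ea, oa, eaf, se, pvalue, n)
    if reason is not None:
        return None, reason
    return (
        VariantAssociation(
            rsid=str(vals["rsid"]),
            chrom=str(vals["chrom"]),
            pos=pos,
            effect_allele=ea,
            other_allele=oa,
            eaf=eaf,
            beta=beta,
            se=se,
            pvalue=pvalue,
            n=n,
        ),
        None,
    )


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    trait_label: str = "trait",
    trait_type: str = "continuous",
    n_cases: int | None = None,
) -> SummaryStatsSet:
    """Read tab-delimited GWAS summary statistics.

    ``dialect`` maps canonical field names to the file's column names (defaults
    in :data:`DEFAULT_DIALECT`).  Rows violating a field invariant are dropped
    and reported in ``SummaryStatsSet.rejected`` with one primary reason each.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [col for col in dialect.values() if col not in df.columns]
    if missing:
        raise DialectError(f"missing mandatory column(s) {missing} in {path}")
    records: list[VariantAssociation] = []
    rejected: list[RejectedRow] = []
    for i, raw in enumerate(df.to_dict("records")):
        rec, reason = _parse_row(raw, dialect)
        if rec is None:
            rejected.append(RejectedRow(row=i, rsid=str(raw.get(dialect["rsid"], "?")), reason=reason))
        else:
            records.append(rec)
    if not records:
        raise EmptyInputError(f"no valid summary-statistic rows in {path}")
    n_total = max(r.n for r in records)
    return SummaryStatsSet(
        trait_label=trait_label,
        trait_type=trait_type,
        records=records,
        n_total=n_total,
        n_cases=n_cases,
        rejected=rejected,
    )


def write_sumstats(sumset: SummaryStatsSet, path) -> None:
    """Write canonical tab-delimited output; inverse of :func:`read_sumstats`.

    Numerics are written with 17 significant digits so the round trip is exact
    to double precision.
    """
    cols = list(DEFAULT_DIALECT.values())
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in sumset.records:
            fh.write(
                "\t".join(
                    (
                        r.rsid,
                        r.chrom,
                        str(r.pos),
                        r.effect_allele,
                        r.other_allele,
                        f"{r.eaf:.17g}",
                        f"{r.beta:.17g}",
                        f"{r.se:.17g}",
                        f"{r.pvalue:.17g}",
                        str(r.n),
                    )
                )
                + "\n"
            )


def read_ld(path) -> LDReference:
    """Read an LD reference, long format (id_a, id_b, r2) or square matrix.

    A file whose header is exactly ``id_a  id_b  r2`` is read as long format;
    anything else is treated as a square matrix with variant ids in the first
    column and the header row.
    """
    head = pd.read_csv(path, sep="\t", nrows=0)
    if list(head.columns) == ["id_a", "id_b", "r2"]:
        df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str, "r2": float})
        return LDReference(df.itertuples(index=False, name=None))
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if list(mat.index) != list(mat.columns):
        raise ValueError("LD matrix rows and columns must list the same variants in order")
    ref = LDReference()
    arr = mat.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("LD matrix is not symmetric")
    if not np.allclose(np.diag(arr), 1.0):
        raise ValueError("LD matrix diagonal must be 1")
    ids = list(mat.index)
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            if arr[i, j] != 0.0:
                ref.add(a, ids[j], arr[i, j])
    return ref


def write_ld(ref: LDReference, path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tr2\n")
        for a, b, r2 in ref.to_pairs():
            fh.write(f"{a}\t{b}\t{r2:.17g}\n")
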