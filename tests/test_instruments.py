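"""Instrument selection, LD pruning, proxies and allele harmonisation."""

import itertools

import numpy as np
import pytest

from mrkit.instruments import (
    drop_palindromic,
    find_proxy,
    harmonise,
    ld_prune,
    select_significant,
)
from mrkit.sumstats import LDReference, VariantAssociation

from conftest import make_sumset, make_variant


class TestSelectSignificant:
    def test_boundary_is_strict(self):
        thr = 8.31e-9
        at = make_variant(rsid="at", pvalue=thr)
        below = make_variant(rsid="below", pvalue=1e-10)
        out = select_significant(make_sumset([at, below]), thr)
        assert [v.rsid for v in out] == ["below"]

    def test_empty_set_allowed(self):
        ss = make_sumset([make_variant(pvalue=0.5)])
        assert select_significant(ss, 1e-8) == []

    def test_input_order_preserved(self):
        vs = [make_variant(rsid=f"rs{j}", pvalue=1e-12 * (5 - j)) for j in range(4)]
        assert select_significant(make_sumset(vs), 1e-9) == vs


def _all_valid_subsets(variants, ld, r2_max):
    """Brute-force oracle: every subset whose pairwise r² all stay below r2_max."""
    valid = []
    for k in range(len(variants) + 1):
        for combo in itertools.combinations(variants, k):
            if all(
                ld.r2(a.rsid, b.rsid) < r2_max
                for a, b in itertools.combinations(combo, 2)
            ):
                valid.append(set(v.rsid for v in combo))
    return valid


class TestLDPrune:
    def test_linked_triplet_keeps_smallest_p(self):
        vs = [
            make_variant(rsid="a", pvalue=1e-12),
            make_variant(rsid="b", pvalue=1e-10),
            make_variant(rsid="c", pvalue=1e-9),
        ]
        ld = LDReference([(x, y, 0.9) for x, y in itertools.combinations("abc", 2)])
        kept = ld_prune(vs, ld, 0.01)
        assert [v.rsid for v in kept] == ["a"]
        # exhaustive check: the greedy result is a valid subset and contains
        # the most significant variant of every maximal valid subset it touches
        assert {"a"} in _all_valid_subsets(vs, ld, 0.01)

    def test_greedy_matches_bruteforce_validity(self, rng):
        # random LD graph over 7 variants: the greedy output must always be a
        # *maximal* valid subset (no remaining variant could be added)
        vs = [make_variant(rsid=f"v{j}", pvalue=float(rng.uniform(1e-12, 1e-6)))
              for j in range(7)]
        pairs = [
            (a.rsid, b.rsid, float(rng.choice([0.0, 0.05, 0.5, 0.95])))
            for a, b in itertools.combinations(vs, 2)
        ]
        ld = LDReference([p for p in pairs if p[2] > 0])
        kept = ld_prune(vs, ld, 0.1)
        kept_ids = {v.rsid for v in kept}
        assert kept_ids in _all_valid_subsets(vs, ld, 0.1)
        for v in vs:
            if v.rsid not in kept_ids:
                assert any(ld.r2(v.rsid, k) >= 0.1 for k in kept_ids)

    def test_unlinked_input_returned_whole(self):
        vs = [make_variant(rsid=f"v{j}", pvalue=1e-10) for j in range(5)]
        assert len(ld_prune(vs, LDReference(), 0.01)) == 5

    def test_single_variant(self):
        v = make_variant()
        assert ld_prune([v], LDReference(), 0.01) == [v]

    def test_invariant_to_input_order(self, rng):
        vs = [make_variant(rsid=f"v{j}", pvalue=float(rng.uniform(1e-12, 1e-8)))
              for j in range(6)]
        ld = LDReference([("v0", "v1", 0.9), ("v2", "v3", 0.9), ("v4", "v5", 0.3)])
        reference = ld_prune(vs, ld, 0.5)
        for perm_seed in range(5):
            perm = list(np.random.default_rng(perm_seed).permutation(len(vs)))
            assert ld_prune([vs[i] for i in perm], ld, 0.5) == reference


class TestDropPalindromic:
    @pytest.mark.parametrize(
        "ea,oa,eaf,dropped",
        [
            ("A", "T", 0.50, True),   # intermediate palindrome
            ("A", "T", 0.10, False),  # palindrome, clear minor allele
            ("A", "C", 0.50, False),  # intermediate but not palindromic
            ("C", "G", 0.54, True),
            ("A", "T", 0.45, False),  # boundary: maf not strictly above 0.45
        ],
    )
    def test_drop_rule(self, ea, oa, eaf, dropped):
        v = make_variant(ea=ea, oa=oa, eaf=eaf)
        kept, drop = drop_palindromic([v], 0.45)
        assert (v in drop) is dropped
        assert kept + drop == [v]

    def test_partition_is_exact(self, rng):
        vs = [
            make_variant(
                rsid=f"v{j}",
                ea="A", oa="T" if j % 2 else "G",
                eaf=float(rng.uniform(0.05, 0.95)),
            )
            for j in range(20)
        ]
        kept, dropped = drop_palindromic(vs, 0.45)
        assert sorted(v.rsid for v in kept + dropped) == sorted(v.rsid for v in vs)


class TestFindProxy:
    def _outcome(self):
        return make_sumset(
            [
                make_variant(rsid="p1", pos=6000),
                make_variant(rsid="p2", pos=51_000),
                make_variant(rsid="p3", pos=2000),
            ],
            trait_type="binary",
            n_cases=100,
        )

    def test_highest_r2_wins(self):
        miss = make_variant(rsid="m", pos=1000)
        ld = LDReference([("m", "p1", 0.85), ("m", "p2", 0.95)])
        assert find_proxy(miss, self._outcome(), ld, 0.8) == ("p2", 0.95)

    def test_below_threshold_returns_none(self):
        miss = make_variant(rsid="m", pos=1000)
        ld = LDReference([("m", "p1", 0.79)])
        assert find_proxy(miss, self._outcome(), ld, 0.8) is None

    def test_tie_broken_by_distance(self):
        miss = make_variant(rsid="m", pos=1000)
        ld = LDReference([("m", "p1", 0.9), ("m", "p2", 0.9)])  # 5 kb vs 50 kb
        assert find_proxy(miss, self._outcome(), ld, 0.8) == ("p1", 0.9)

    def test_tie_broken_by_rsid(self):
        miss = make_variant(rsid="m", pos=1000)
        outcome = make_sumset(
            [make_variant(rsid="pb", pos=2000), make_variant(rsid="pa", pos=2000)]
        )
        ld = LDReference([("m", "pa", 0.9), ("m", "pb", 0.9)])
        assert find_proxy(miss, outcome, ld, 0.8) == ("pa", 0.9)

    def test_candidate_must_be_in_outcome(self):
        miss = make_variant(rsid="m", pos=1000)
        ld = LDReference([("m", "absent", 0.99)])
        assert find_proxy(miss, self._outcome(), ld, 0.8) is None


class TestHarmonise:
    def test_already_aligned_unchanged(self):
        exp = [make_variant(ea="A", oa="G", beta=0.1)]
        out = make_sumset([make_variant(ea="A", oa="G", beta=0.05)])
        instr, audit = harmonise(exp, out)
        assert instr[0].beta_outcome == 0.05
        assert audit.n_final == 1

    def test_allele_swap_negates(self):
        exp = [make_variant(ea="A", oa="G", beta=0.1)]
        out = make_sumset([make_variant(ea="G", oa="A", beta=0.05, eaf=0.3)])
        instr, _ = harmonise(exp, out)
        assert instr[0].beta_outcome == -0.05

    def test_strand_complement(self):
        exp = [make_variant(ea="A", oa="G", beta=0.1)]
        out = make_sumset([make_variant(ea="T", oa="C", beta=0.05)])
        instr, _ = harmonise(exp, out)
        assert instr[0].beta_outcome == 0.05

    def test_strand_complement_and_swap(self):
        exp = [make_variant(ea="A", oa="G", beta=0.1)]
        out = make_sumset([make_variant(ea="C", oa="T", beta=0.05, eaf=0.3)])
        instr, _ = harmonise(exp, out)
        assert instr[0].beta_outcome == -0.05

    def test_palindrome_frequency_alignment(self):
        exp = [make_variant(ea="A", oa="T", eaf=0.2, beta=0.1)]
        same = make_sumset([make_variant(ea="T", oa="A", eaf=0.22, beta=0.05)])
        instr, _ = harmonise(exp, same)
        # outcome minor-frequency allele listed first: same side, keep sign
        assert instr[0].beta_outcome == 0.05
        other = make_sumset([make_variant(ea="A", oa="T", eaf=0.78, beta=0.05)])
        instr, _ = harmonise(exp, other)
        assert instr[0].beta_outcome == -0.05

    def test_intermediate_palindrome_dropped(self):
        exp = [make_variant(ea="A", oa="T", eaf=0.5)]
        out = make_sumset([make_variant(ea="A", oa="T", eaf=0.5)])
        instr, audit = harmonise(exp, out)
        assert instr == [] and audit.n_palindromic_dropped == 1

    def test_irreconcilable_alleles_dropped(self):
        exp = [make_variant(ea="A", oa="G", beta=0.1)]
        out = make_sumset([make_variant(ea="A", oa="C", beta=0.05)])
        instr, audit = harmonise(exp, out)
        assert instr == [] and audit.n_irreconcilable == 1

    def test_absent_without_proxy_dropped(self):
        exp = [make_variant(rsid="x")]
        out = make_sumset([make_variant(rsid="y")])
        instr, audit = harmonise(exp, out, LDReference())
        assert instr == [] and audit.n_unmatched == 1 and audit.n_absent == 1

    def test_absent_with_proxy_recovered(self):
        exp = [make_variant(rsid="x", eaf=0.3, beta=0.1)]
        out = make_sumset([make_variant(rsid="y", eaf=0.31, beta=0.07)])
        ld = LDReference([("x", "y", 0.92)])
        instr, audit = harmonise(exp, out, ld)
        assert audit.n_proxied == 1 and audit.n_final == 1
        ins = instr[0]
        assert ins.is_proxy and ins.proxy_rsid == "y" and ins.proxy_r2 == 0.92
        assert ins.beta_outcome == 0.07  # same frequency side: sign kept
        assert ins.beta_exposure == 0.1  # exposure record of the index variant

    def test_duplicate_exposure_rsid_is_input_error(self):
        exp = [make_variant(rsid="x"), make_variant(rsid="x")]
        with pytest.raises(ValueError, match="duplicate"):
            harmonise(exp, make_sumset([make_variant(rsid="x")]))

    def test_idempotence(self, rng):
        exposure, outcome = _random_pair(rng, 25)
        instr1, _ = harmonise(exposure, outcome)
        # re-express the harmonised pairs as a new aligned exposure/outcome set
        exp2 = []
        out2 = []
        exp_by_id = {e.rsid: e for e in exposure}
        for ins in instr1:
            e = exp_by_id[ins.rsid]
            exp2.append(e)
            out2.append(
                make_variant(
                    rsid=ins.rsid, ea=e.effect_allele, oa=e.other_allele,
                    eaf=e.eaf, beta=ins.beta_outcome, se=ins.se_outcome,
                )
            )
        instr2, _ = harmonise(exp2, make_sumset(out2))
        assert [(i.rsid, i.beta_exposure, i.beta_outcome) for i in instr2] == [
            (i.rsid, i.beta_exposure, i.beta_outcome) for i in instr1
        ]

    def test_sign_consistency_under_joint_reallele_flip(self, rng):
        exposure, outcome = _random_pair(rng, 25)
        base, _ = harmonise(exposure, outcome)
        for k in range(len(exposure)):
            exp_f = list(exposure)
            exp_f[k] = exp_f[k].flipped()
            out_recs = [
                (r.flipped() if r.rsid == exposure[k].rsid else r)
                for r in outcome.records
            ]
            flipped, _ = harmonise(exp_f, make_sumset(out_recs))
            pairs_base = {(i.rsid): (i.beta_exposure * i.beta_outcome) for i in base}
            pairs_flip = {(i.rsid): (i.beta_exposure * i.beta_outcome) for i in flipped}
            # the causal-relevant product beta_x*beta_y is allele-labelling free
            for rsid in pairs_base:
                assert pairs_flip[rsid] == pytest.approx(pairs_base[rsid], rel=1e-12)

    def test_audit_conservation(self, rng):
        exposure, outcome = _random_pair(rng, 40, drop_fraction=0.2)
        instr, audit = harmonise(exposure, outcome, LDReference())
        audit.check()
        assert len(audit.dispositions) == len(exposure)
        assert audit.n_final == len(instr)


def _random_pair(rng, n, drop_fraction=0.0):
    """Random exposure list plus an outcome set exercising every alignment mode."""
    from mrkit.sumstats import COMPLEMENT

    non_pal = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
    exposure = []
    out_records = []
    for j in range(n):
        pal = j % 5 == 0
        ea, oa = ("A", "T") if pal else non_pal[j % 4]
        eaf = float(rng.uniform(0.05, 0.4))
        exp = make_variant(
            rsid=f"rs{j}", ea=ea, oa=oa, eaf=eaf,
            beta=float(rng.normal(0.1, 0.02)), pos=1000 + j,
        )
        exposure.append(exp)
        if drop_fraction and rng.random() < drop_fraction:
            continue  # absent from the outcome
        beta_y = float(rng.normal(0, 0.05))
        o_ea, o_oa, o_eaf = ea, oa, eaf + float(rng.uniform(-0.02, 0.02))
        if not pal and rng.random() < 0.5:  # strand flip
            o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        if rng.random() < 0.5:  # allele swap
            o_ea, o_oa = o_oa, o_ea
            beta_y, o_eaf = -beta_y, 1 - o_eaf
        out_records.append(
            make_variant(rsid=f"rs{j}", ea=o_ea, oa=o_oa, eaf=o_eaf,
                         beta=beta_y, se=0.02, pos=1000 + j)
        )
    return exposure, make_sumset(out_records, trait_type="binary", n_cases=100)
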