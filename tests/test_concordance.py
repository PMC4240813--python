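"""Call-set concordance, match predicates, and multiple-signature detection."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from indelqc import (
    CallSet,
    DictReference,
    IndelCall,
    compare_callsets,
    left_normalize,
    match_exact,
    match_position,
    match_validation,
    mean_concordance,
    multiple_signatures,
    union_callset,
)
from indelqc.concordance import EXACT, POSITION


def _call(chrom="chr1", pos=100, ref="A", alt="AT", normalized=True, **kw):
    c = IndelCall(chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt, **kw)
    c.normalized = normalized
    return c


def _random_callset(rng, n, label):
    calls = {}
    while len(calls) < n:
        pos = int(rng.integers(1, 40))
        ref, alt = ("AC", "A") if rng.random() < 0.5 else ("A", "AG")
        calls[(pos, ref, alt)] = _call(pos=pos, ref=ref, alt=alt)
    return CallSet(label=label, calls=list(calls.values()))


def brute_force_compare(a: CallSet, b: CallSet, mode: str):
    """O(n*m) all-pairs matcher, counting per the partition-of-union rule."""
    if mode == EXACT:
        n_int = sum(1 for ca in a.calls if any(ca.key == cb.key for cb in b.calls))
        n_a = len(a.calls) - n_int
        n_b = sum(1 for cb in b.calls if not any(ca.key == cb.key for ca in a.calls))
        return n_int, n_a, n_b
    positions = {c.position_key for c in a.calls} | {c.position_key for c in b.calls}
    n_int = n_a = n_b = 0
    for p in positions:
        ka = len({c.key for c in a.calls if c.position_key == p})
        kb = len({c.key for c in b.calls if c.position_key == p})
        if ka and kb:
            n_int += 1
            n_a += ka - 1
            n_b += kb - 1
        else:
            n_a += ka
            n_b += kb
    return n_int, n_a, n_b


class TestMatchPredicates:
    def test_identical_records_match_everywhere(self):
        a, b = _call(), _call()
        assert match_position(a, b) and match_exact(a, b) and match_validation(a, b)

    def test_same_position_different_change(self):
        deletion = _call(ref="AT", alt="A")
        insertion = _call(ref="A", alt="AT")
        assert match_position(deletion, insertion)
        assert not match_exact(deletion, insertion)
        assert not match_validation(deletion, insertion)  # type differs

    def test_validation_match_same_type_different_alleles(self):
        a = _call(ref="A", alt="AT")
        b = _call(ref="A", alt="AGG")
        assert match_validation(a, b) and not match_exact(a, b)

    def test_unnormalized_inputs_rejected(self):
        a = _call(normalized=False)
        with pytest.raises(ValueError):
            match_exact(a, _call())

    def test_equivalent_raw_representations_exact_match_after_normalization(self):
        seq = "GGCACACACATT"
        ref = DictReference({"c": seq})
        raw1 = IndelCall(chrom="c", pos=3, ref_allele="CAC", alt_allele="C")
        raw2 = IndelCall(chrom="c", pos=8, ref_allele="ACA", alt_allele="A")
        n1, n2 = left_normalize(raw1, ref), left_normalize(raw2, ref)
        assert match_exact(n1, n2)


class TestCompareCallsets:
    def test_identical_sets_fully_concordant(self):
        cs = CallSet(label="a", calls=[_call(pos=p) for p in (5, 10, 15)])
        r = compare_callsets(cs, cs, mode=EXACT)
        assert (r.n_intersection, r.n_a_specific, r.n_b_specific) == (3, 0, 0)
        assert r.rate_concordant == 100.0

    def test_disjoint_sets_zero_concordant(self):
        a = CallSet(label="a", calls=[_call(pos=5)])
        b = CallSet(label="b", calls=[_call(pos=500)])
        r = compare_callsets(a, b, mode=EXACT)
        assert r.rate_concordant == 0.0 and r.n_a_specific == r.n_b_specific == 1

    def test_worked_rates_over_union_of_100(self):
        shared = [_call(pos=1000 + i) for i in range(50)]
        a = CallSet(label="a", calls=shared + [_call(pos=5000 + i) for i in range(30)])
        b = CallSet(label="b", calls=shared + [_call(pos=9000 + i) for i in range(20)])
        r = compare_callsets(a, b, mode=EXACT)
        assert (r.rate_concordant, r.rate_a_specific, r.rate_b_specific) == (50.0, 30.0, 20.0)

    def test_rates_partition_the_union(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = _random_callset(rng, int(rng.integers(1, 40)), "a")
            b = _random_callset(rng, int(rng.integers(1, 40)), "b")
            for mode in (EXACT, POSITION):
                r = compare_callsets(a, b, mode=mode)
                total = r.rate_concordant + r.rate_a_specific + r.rate_b_specific
                assert total == pytest.approx(100.0, abs=0.3)

    def test_agrees_with_brute_force_matcher_on_random_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = _random_callset(rng, int(rng.integers(1, 50)), "a")
            b = _random_callset(rng, int(rng.integers(1, 50)), "b")
            for mode in (EXACT, POSITION):
                r = compare_callsets(a, b, mode=mode)
                assert (r.n_intersection, r.n_a_specific, r.n_b_specific) == \
                    brute_force_compare(a, b, mode)

    def test_exact_intersection_never_exceeds_position_intersection(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            a = _random_callset(rng, 25, "a")
            b = _random_callset(rng, 25, "b")
            re = compare_callsets(a, b, mode=EXACT)
            rp = compare_callsets(a, b, mode=POSITION)
            assert re.n_intersection <= rp.n_intersection

    def test_depth_floor_excludes_low_depth_loci_in_either_set(self):
        a = CallSet(label="a", calls=[_call(pos=10), _call(pos=20)])
        b = CallSet(label="b", calls=[_call(pos=10), _call(pos=30)])
        depth_a = {("chr1", 10): 50, ("chr1", 20): 5, ("chr1", 30): 50}
        depth_b = {("chr1", 10): 50, ("chr1", 20): 50, ("chr1", 30): 2}
        r = compare_callsets(a, b, mode=EXACT, depth_a=depth_a, depth_b=depth_b,
                             depth_floor=20)
        # pos 20 (shallow in a) and pos 30 (shallow in b) both drop
        assert (r.n_intersection, r.n_a_specific, r.n_b_specific) == (1, 0, 0)

    def test_depth_floor_without_maps_rejected(self):
        a = CallSet(label="a", calls=[_call()])
        with pytest.raises(ValueError):
            compare_callsets(a, a, depth_floor=20)

    def test_missing_locus_in_depth_map_treated_as_zero(self):
        a = CallSet(label="a", calls=[_call(pos=10)])
        r = compare_callsets(a, a, mode=EXACT, depth_a={}, depth_b={}, depth_floor=1)
        assert r.n_union == 0


class TestMeanConcordance:
    def _result(self, conc, a_spec, b_spec):
        from indelqc.concordance import ConcordanceResult
        return ConcordanceResult(0, 0, 0, conc, a_spec, b_spec, mode=EXACT)

    def test_identical_samples_sd_zero(self):
        out = mean_concordance([self._result(53.0, 34.0, 13.0)] * 3)
        assert out["rate_concordant"] == (53.0, 0.0)

    def test_two_sample_mean_and_sd(self):
        out = mean_concordance([self._result(52, 30, 18), self._result(54, 28, 18)])
        mean, sd = out["rate_concordant"]
        assert mean == 53.0 and sd == pytest.approx(1.41, abs=0.01)

    def test_single_sample_sd_undefined(self):
        out = mean_concordance([self._result(52, 30, 18)])
        assert out["rate_concordant"] == (52.0, None)


class TestMultipleSignatures:
    def test_no_shared_positions_empty(self):
        cs = CallSet(label="u", calls=[_call(pos=10), _call(pos=20)])
        assert multiple_signatures(cs) == []

    def test_two_alternates_at_one_position(self):
        cs = CallSet(label="u", calls=[
            _call(pos=10, ref="A", alt="AT"),
            _call(pos=10, ref="A", alt="ATT"),
            _call(pos=99, ref="AC", alt="A"),
        ])
        loci = multiple_signatures(cs)
        assert len(loci) == 1
        assert loci[0].pos == 10 and len(loci[0].signatures) == 2

    def test_planted_loci_recovered_exactly(self):
        rng = np.random.default_rng(23)
        k = 7
        planted = rng.choice(np.arange(100, 1000, 10), size=k, replace=False)
        calls = []
        for p in planted:
            calls.append(_call(pos=int(p), ref="A", alt="AT"))
            calls.append(_call(pos=int(p), ref="AC", alt="A"))
        calls += [_call(pos=int(p)) for p in range(2000, 2300, 10)]
        loci = multiple_signatures(CallSet(label="u", calls=calls))
        assert sorted(l.pos for l in loci) == sorted(int(p) for p in planted)

    def test_union_callset_deduplicates(self):
        a = CallSet(label="a", calls=[_call(pos=10)])
        b = CallSet(label="b", calls=[_call(pos=10), _call(pos=20)])
        assert len(union_callset(a, b)) == 2
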