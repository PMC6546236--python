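import math
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edconsensus.callers import (DEFAULT_FILTER_ORDER, FilterParams,
                                 hardfilter_call, island_call, mi_call,
                                 mi_score, site_in_homopolymer,
                                 strand_bias_test)
from edconsensus.io_formats import GenomeRef, KnownSnpCatalog
from edconsensus.pileup import CandidateVariant

# Plug-in MI of joint counts [[40,10],[10,40]], computed independently as
# 0.8*log2(1.6) + 0.2*log2(0.4) bits.
MI_40_10 = 0.27807190511263774


def make_candidate(pos=10, ref="A", alt="G", alt_count=6, coverage=20,
                   alt_plus=None, alt_minus=None, jdist=100.0, contig="c1",
                   read_alleles=None, **flags):
    ap = alt_count // 2 if alt_plus is None else alt_plus
    am = alt_count - ap if alt_minus is None else alt_minus
    ref_n = coverage - alt_count
    c = CandidateVariant(contig, pos, ref, alt, alt_count, coverage,
                         ap, am, ref_n // 2, ref_n - ref_n // 2, jdist,
                         read_alleles)
    for k, v in flags.items():
        setattr(c, k, v)
    return c


class TestHomopolymer:
    GENOME = GenomeRef({"c1": "CCCAAAAACGCCCAAAACC"})
    # run of 5 A's at [3,8); run of 4 A's at [13,17)

    @pytest.mark.parametrize("pos", [3, 4, 5, 6, 7])
    def test_inside_five_run(self, pos):
        assert site_in_homopolymer(self.GENOME, ("c1", pos))

    @pytest.mark.parametrize("pos", [2, 8])
    def test_adjacent_to_five_run(self, pos):
        assert site_in_homopolymer(self.GENOME, ("c1", pos))

    @pytest.mark.parametrize("pos", [1, 9, 14, 15])
    def test_four_run_and_distant_positions_clean(self, pos):
        assert not site_in_homopolymer(self.GENOME, ("c1", pos))

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError):
            site_in_homopolymer(self.GENOME, ("c1", 99))


def fisher_two_sided_oracle(a, b, c, d):
    """Exact conditional two-sided p by enumerating all tables with the
    observed margins (hypergeometric probabilities via math.comb)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


class TestStrandBias:
    def test_balanced_split_passes(self):
        assert strand_bias_test(5, 5, 55, 55) == pytest.approx(1.0)

    def test_fully_biased_alt_fails_at_alpha(self):
        p = strand_bias_test(10, 0, 35, 25)
        assert p < 0.01
        assert p == pytest.approx(fisher_two_sided_oracle(10, 0, 25, 25),
                                  abs=1e-9)

    @pytest.mark.parametrize("table", [(3, 7, 20, 18), (0, 5, 12, 9),
                                       (6, 6, 6, 6), (9, 1, 10, 30)])
    def test_matches_exact_enumeration(self, table):
        ap, am, rp, rm = table
        p = strand_bias_test(ap, am, ap + rp, am + rm)
        assert p == pytest.approx(fisher_two_sided_oracle(ap, am, rp, rm),
                                  abs=1e-9)

    def test_zero_coverage_raises(self):
        with pytest.raises(ValueError):
            strand_bias_test(0, 0, 0, 0)


@pytest.fixture
def crafted_candidates(toy_bundle):
    """Ten candidates: one designed violation per cascade filter + 4 clean."""
    return {
        "known_snp": make_candidate(pos=350),
        "simple_repeat": make_candidate(pos=250),
        "homopolymer": make_candidate(pos=304),
        "strand_bias": make_candidate(pos=30, alt_count=10, coverage=60,
                                      alt_plus=10, alt_minus=0),
        "vaf_high": make_candidate(pos=40, alt_count=39, coverage=40),
        "junction": make_candidate(pos=137, jdist=3.0),
        "clean1": make_candidate(pos=10),
        "clean2": make_candidate(pos=20),
        "clean3": make_candidate(pos=50),
        "clean4": make_candidate(pos=60),
    }


class TestHardFilter:
    def test_fixture_survivors_and_provenance(self, toy_bundle, crafted_candidates):
        cands = crafted_candidates
        calls = hardfilter_call(list(cands.values()), toy_bundle, FilterParams())
        assert calls.sites() == {("c1", p) for p in (10, 20, 50, 60)}
        for name in ("known_snp", "simple_repeat", "homopolymer",
                     "strand_bias", "vaf_band", "junction"):
            key = {"vaf_band": "vaf_high"}.get(name, name)
            assert cands[key].failed_filters() == [name]
        for key in ("clean1", "clean2", "clean3", "clean4"):
            assert cands[key].failed_filters() == []

    def test_vaf_bounds_inclusive(self, toy_bundle):
        at_low = make_candidate(pos=10, alt_count=2, coverage=20)   # VAF 0.10
        at_low.alt_count, at_low.coverage = 2, 20
        ok = hardfilter_call([make_candidate(pos=10, alt_count=19, coverage=20)],
                             toy_bundle, FilterParams())
        # VAF 0.95 exactly: inclusive pass
        assert ("c1", 10) in ok

    def test_vaf_low_rejected(self, toy_bundle):
        calls = hardfilter_call(
            [make_candidate(pos=10, alt_count=3, coverage=40)],  # VAF 0.075
            toy_bundle, FilterParams())
        assert len(calls) == 0

    def test_filter_order_invariance_of_survivors(self, toy_bundle,
                                                  crafted_candidates):
        import copy

        a = copy.deepcopy(list(crafted_candidates.values()))
        b = copy.deepcopy(list(crafted_candidates.values()))
        s1 = hardfilter_call(a, toy_bundle, FilterParams(),
                             order=DEFAULT_FILTER_ORDER)
        s2 = hardfilter_call(b, toy_bundle, FilterParams(),
                             order=tuple(reversed(DEFAULT_FILTER_ORDER)))
        assert s1.sites() == s2.sites()


class TestMiScore:
    def test_perfect_linkage_one_bit(self):
        x = {f"r{i}": i % 2 for i in range(20)}
        assert mi_score(x, dict(x)) == pytest.approx(1.0)

    def test_independence_zero_bits(self):
        # joint counts exactly the product of marginals
        x, y = {}, {}
        k = 0
        for xi, yi, n in [(0, 0, 25), (0, 1, 25), (1, 0, 25), (1, 1, 25)]:
            for _ in range(n):
                x[f"r{k}"], y[f"r{k}"] = xi, yi
                k += 1
        assert mi_score(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_known_table_value(self):
        x, y = {}, {}
        k = 0
        for xi, yi, n in [(0, 0, 40), (0, 1, 10), (1, 0, 10), (1, 1, 40)]:
            for _ in range(n):
                x[f"r{k}"], y[f"r{k}"] = xi, yi
                k += 1
        assert mi_score(x, y) == pytest.approx(MI_40_10, abs=1e-9)

    def test_insufficient_overlap_returns_none(self):
        x = {"a": 0, "b": 1}
        assert mi_score(x, x, min_shared=5) is None

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=5, max_size=60))
    def test_symmetry_nonnegativity_and_entropy_bound(self, pairs):
        x = {f"r{i}": a for i, (a, _) in enumerate(pairs)}
        y = {f"r{i}": b for i, (_, b) in enumerate(pairs)}
        mxy, myx = mi_score(x, y), mi_score(y, x)
        assert mxy == pytest.approx(myx, abs=1e-12)
        assert mxy >= 0

        def entropy(d):
            p = sum(d.values()) / len(d)
            if p in (0, 1):
                return 0.0
            return -p * math.log2(p) - (1 - p) * math.log2(1 - p)

        assert mxy <= min(entropy(x), entropy(y)) + 1e-9


def _linked_alleles(n=30, flip=False):
    """Reads r0..r(n-1); haplotype = parity. Perfect phase linkage."""
    return {f"r{i}": (i % 2) ^ int(flip) for i in range(n)}


def _independent_alleles(n=30, rate=0.3):
    # deterministic pattern uncorrelated with parity
    return {f"r{i}": int((i // 2) % 10 < 10 * rate) for i in range(n)}


class TestMiCall:
    def _anchor(self, pos):
        return make_candidate(pos=pos, alt_count=15, coverage=30,
                              read_alleles=[(f"r{i}", "G" if i % 2 else "A")
                                            for i in range(30)])

    def test_linked_candidate_rejected_independent_called(self):
        anchors = [self._anchor(p) for p in (100, 150, 200)]
        linked = make_candidate(pos=120, alt_count=15, coverage=30,
                                read_alleles=[(f"r{i}", "G" if i % 2 else "A")
                                              for i in range(30)])
        indep = make_candidate(
            pos=130, alt_count=9, coverage=30,
            read_alleles=[(f"r{i}", "G" if (i // 2) % 10 < 3 else "A")
                          for i in range(30)])
        catalog = KnownSnpCatalog({("c1", p, "A", "G") for p in (100, 150, 200)})
        calls = mi_call(anchors + [linked, indep], catalog, FilterParams())
        assert ("c1", 130) in calls
        assert ("c1", 120) not in calls

    def test_no_anchors_falls_back_to_vaf_band(self, caplog):
        cand_mid = make_candidate(pos=10, alt_count=6, coverage=20)
        cand_high = make_candidate(pos=30, alt_count=39, coverage=40)
        with caplog.at_level("WARNING"):
            calls = mi_call([cand_mid, cand_high], KnownSnpCatalog(set()),
                            FilterParams())
        assert ("c1", 10) in calls and ("c1", 30) not in calls


class TestIslandCall:
    def test_three_close_sites_form_island(self, toy_bundle):
        cands = [make_candidate(pos=p, jdist=100.0) for p in (10, 30, 50)]
        calls, islands = island_call(cands, toy_bundle, FilterParams())
        assert len(islands) == 1 and islands[0].n_sites == 3
        assert calls.sites() == {("c1", 10), ("c1", 30), ("c1", 50)}

    def test_distant_sites_no_island(self, toy_bundle):
        cands = [make_candidate(pos=10), make_candidate(pos=70)]
        _, islands = island_call(cands, toy_bundle, FilterParams())
        assert islands == []

    def test_isolated_site_needs_hardfilter_pass(self, toy_bundle):
        clean = make_candidate(pos=10)
        in_repeat = make_candidate(pos=250)
        calls, _ = island_call([clean, in_repeat], toy_bundle, FilterParams())
        assert ("c1", 10) in calls and ("c1", 250) not in calls

    def test_island_members_bypass_cascade(self, toy_bundle):
        # three sites inside the simple repeat still form an island
        cands = [make_candidate(pos=p) for p in (242, 248, 254)]
        calls, islands = island_call(cands, toy_bundle, FilterParams())
        assert len(islands) == 1 and len(calls) == 3

    def test_known_snps_excluded_before_clustering(self, toy_bundle):
        cands = [make_candidate(pos=p) for p in (340, 360)]
        cands.append(make_candidate(pos=350))  # known SNP position
        _, islands = island_call(cands, toy_bundle, FilterParams())
        assert islands == []
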