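import pytest

from edconsensus import io_formats as io
from edconsensus.pileup import (CandidateVariant, build_pileup,
                                call_candidates, dedupe_reads)
from edconsensus.simdata import SimConfig, generate_reference, plant_variants, simulate_reads
from edconsensus.io_formats import (GenomeRef, SpliceJunctionSet)
from tests.conftest import sam_record


def _read(name="r1", pos=0, strand="+", cigar="4M", bases="ACGT", q=40,
          contig="c1"):
    return io.AlignedRead(name, contig, pos, strand, cigar, bases,
                          [q] * len(bases))


class TestDedupe:
    def test_identical_locus_collapsed_to_one(self):
        reads = [_read("b"), _read("a")]
        kept = dedupe_reads(reads)
        assert len(kept) == 1 and kept[0].name == "a"

    def test_different_cigar_both_kept(self):
        reads = [_read("a", cigar="4M"), _read("b", cigar="2M1N2M")]
        assert len(dedupe_reads(reads)) == 2

    def test_different_strand_both_kept(self):
        reads = [_read("a", strand="+"), _read("b", strand="-")]
        assert len(dedupe_reads(reads)) == 2

    def test_empty_input(self):
        assert dedupe_reads([]) == []

    def test_idempotent(self):
        reads = [_read("a"), _read("b"), _read("c", pos=2),
                 _read("d", pos=2, strand="-")]
        once = dedupe_reads(reads)
        assert dedupe_reads(once) == once


class TestBuildPileup:
    GENOME = GenomeRef({"c1": "AAAAACCCCC" * 10})

    def test_mismatch_counts_and_coverage(self):
        reads = [_read(f"r{i}", pos=0, bases="GAAA") for i in range(3)]
        pls = list(build_pileup(reads, self.GENOME, SpliceJunctionSet()))
        at0 = [p for p in pls if p.pos == 0][0]
        assert at0.count("G") == 3 and at0.coverage == 3
        assert sorted(b for _, b in at0.read_alleles) == ["G", "G", "G"]

    def test_n_gap_contributes_nothing(self):
        reads = [_read("r", pos=0, cigar="2M5N2M", bases="AACC")]
        pls = {p.pos: p for p in build_pileup(reads, self.GENOME,
                                              SpliceJunctionSet())}
        assert set(pls) == {0, 1, 7, 8}

    def test_low_quality_bases_excluded(self):
        reads = [_read("hi", bases="GAAA", q=40), _read("lo", bases="GAAA", q=10)]
        pls = [p for p in build_pileup(reads, self.GENOME, SpliceJunctionSet())
               if p.pos == 0]
        assert pls[0].count("G") == 1

    def test_junction_distance(self):
        juncs = SpliceJunctionSet({("c1", 5)})
        reads = [_read("r", pos=0, bases="GAAA")]
        (p0,) = [p for p in build_pileup(reads, self.GENOME, juncs) if p.pos == 0]
        # site at 0, junction at 5 -> hand-checked distance 5
        assert p0.junction_distance == 5
        (p2,) = [p for p in build_pileup(reads, self.GENOME, juncs) if p.pos == 2]
        assert p2.junction_distance == 3

    def test_read_overrunning_contig_raises(self):
        genome = GenomeRef({"c1": "AAAA"})
        reads = [_read("r", pos=2, bases="ACGT")]
        with pytest.raises(ValueError, match="r"):
            list(build_pileup(reads, genome, SpliceJunctionSet()))

    def test_mismatch_mode_emits_only_variant_sites(self):
        reads = [_read("r", pos=0, bases="GAAA")]
        pls = list(build_pileup(reads, self.GENOME, SpliceJunctionSet(),
                                emit="mismatch"))
        assert [p.pos for p in pls] == [0]


class TestCallCandidates:
    def _pileups(self, cov, alt):
        reads = [_read(f"a{i}", pos=0, bases="GAAA") for i in range(alt)]
        reads += [_read(f"b{i}", pos=0, bases="AAAA") for i in range(cov - alt)]
        return build_pileup(reads, TestBuildPileup.GENOME, SpliceJunctionSet())

    def test_coverage_below_floor_rejected(self):
        assert call_candidates(self._pileups(4, 3)) == []

    def test_alt_below_floor_rejected(self):
        assert call_candidates(self._pileups(10, 2)) == []

    def test_thresholds_met_candidate_emitted(self):
        (cand,) = [c for c in call_candidates(self._pileups(10, 3))
                   if c.pos == 0]
        assert (cand.ref, cand.alt, cand.alt_count, cand.coverage) == ("A", "G", 3, 10)
        assert cand.vaf == pytest.approx(0.3)

    def test_triallelic_majority_alt_with_tie_break(self):
        reads = [_read(f"g{i}", pos=0, bases="G") for i in range(3)]
        reads += [_read(f"t{i}", pos=0, bases="T") for i in range(3)]
        reads += [_read(f"r{i}", pos=0, bases="A") for i in range(4)]
        # make loci distinct so dedupe is not triggered
        for i, r in enumerate(reads):
            r.cigar = "1M"
        (cand,) = call_candidates(
            build_pileup(reads, TestBuildPileup.GENOME, SpliceJunctionSet()))
        assert cand.alt == "G"  # tie between G and T broken alphabetically


class TestTruthOracle:
    def test_error_free_candidates_are_exactly_thresholded_planted_sites(self, tmp_path):
        """With zero sequencing error, candidate sites must coincide with
        planted variants whose (independently counted) alt depth passes the
        floors."""
        cfg = SimConfig(seed=21, contig_length=20_000, n_genes=4,
                        exon_length=150, intron_length=200, alu_count=6,
                        island_count=3, n_isolated_sites=10, n_snps=15,
                        simple_repeat_count=1, homopolymer_count=1,
                        n_cell_lines=1, adar_activity=(1.0,), n_replicates=1,
                        coverage=15, error_rate=0.0)
        genome, bundle = generate_reference(cfg)
        truth = plant_variants(genome, bundle, cfg)
        sam = str(tmp_path / "r.sam")
        simulate_reads(genome, truth, cfg, 0, 1, sam)

        reads = dedupe_reads(io.read_alignments(sam))
        cands = call_candidates(build_pileup(reads, genome, bundle.junctions,
                                             emit="mismatch"))
        got = {c.site for c in cands}

        # independent naive counter over the same deduped reads
        expected = set()
        planted = {(s.contig, s.pos): s.alt for s in truth.snps}
        planted.update({(s.contig, s.pos): s.alt for s in truth.editing_sites})
        for (contig, pos), alt in planted.items():
            cov = alt_n = 0
            for read in reads:
                for rs, re_, qoff in read.aligned_blocks():
                    if rs <= pos < re_:
                        cov += 1
                        if read.bases[qoff + pos - rs] == alt:
                            alt_n += 1
            if cov >= 5 and alt_n >= 3:
                expected.add((contig, pos))
        assert got == expected
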