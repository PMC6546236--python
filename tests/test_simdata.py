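import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from edconsensus import io_formats as io
from edconsensus import simdata
from edconsensus.simdata import (EditSiteTruth, SimConfig, SimTruth, SnpTruth,
                                 generate_expression, generate_reference,
                                 plant_variants, simulate_reads)

SMALL = dict(contig_length=30_000, n_genes=6, exon_length=150,
             intron_length=200, alu_count=8, island_count=4,
             n_isolated_sites=15, n_snps=25, simple_repeat_count=2,
             homopolymer_count=2, n_cell_lines=2, adar_activity=(1.0, 0.6),
             n_replicates=2, coverage=15)


@pytest.fixture(scope="module")
def small_world():
    cfg = SimConfig(seed=11, **SMALL)
    genome, bundle = generate_reference(cfg)
    truth = plant_variants(genome, bundle, cfg)
    return cfg, genome, bundle, truth


class TestReference:
    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        cfg = SimConfig(seed=1, **SMALL)
        paths = []
        for i in range(2):
            genome, _ = generate_reference(cfg)
            p = tmp_path / f"g{i}.fa"
            io.write_fasta(genome, str(p))
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_alu_track_count(self, small_world):
        cfg, _, bundle, _ = small_world
        alus = [r for r in bundle.repeats if r.label == "Alu"]
        assert len(alus) == cfg.alu_count

    def test_exon_boundaries_subset_of_junctions(self, small_world):
        _, _, bundle, _ = small_world
        for gene in bundle.genes:
            assert {(gene.contig, j) for j in gene.junctions()} <= \
                bundle.junctions.positions

    def test_alu_copies_written_into_sequence(self, small_world):
        # planted Alu intervals should resemble each other far more than
        # random sequence (shared consensus, 5-15% divergence)
        _, genome, bundle, _ = small_world
        alus = [r for r in bundle.repeats if r.label == "Alu"][:2]
        seqs = []
        for iv in alus:
            s = genome.sequences[iv.contig][iv.start:iv.end]
            if iv.strand == "-":
                s = s.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            seqs.append(s)
        ident = np.mean([a == b for a, b in zip(*seqs)])
        assert ident > 0.6


class TestPlanting:
    def test_zero_adar_activity_zeroes_levels(self):
        cfg = SimConfig(seed=2, adar_activity=0.0, n_cell_lines=1, **{
            k: v for k, v in SMALL.items()
            if k not in {"adar_activity", "n_cell_lines"}})
        genome, bundle = generate_reference(cfg)
        truth = plant_variants(genome, bundle, cfg)
        assert all(lv == 0.0 for s in truth.editing_sites for lv in s.levels)

    def test_island_sites_inside_alu_and_islands(self, small_world):
        _, _, bundle, truth = small_world
        alus = [r for r in bundle.repeats if r.label == "Alu"]
        for site in truth.editing_sites:
            if site.island_id is None:
                continue
            island = truth.islands[site.island_id]
            assert island.start <= site.pos < island.end
            assert any(a.contig == site.contig and a.contains(site.pos)
                       for a in alus)
        for island in truth.islands:
            assert any(a.contig == island.contig and a.start <= island.start
                       and island.end <= a.end for a in alus)

    def test_editing_and_snp_sites_disjoint(self, small_world):
        _, _, _, truth = small_world
        assert not truth.snp_positions() & truth.editing_positions()

    def test_levels_respect_floor_and_activity(self, small_world):
        cfg, _, _, truth = small_world
        for s in truth.editing_sites:
            assert s.base_level >= cfg.editing_level_min
            for li, lv in enumerate(s.levels):
                assert lv in (0.0, pytest.approx(s.base_level * cfg.adar_activity[li]))

    def test_deg_independent_of_editing_when_enrichment_1(self):
        # planted labels should show no association across 20 seeds
        n_sig = 0
        for seed in range(20):
            cfg = SimConfig(seed=seed, deg_edited_enrichment=1.0, **SMALL)
            genome, bundle = generate_reference(cfg)
            truth = plant_variants(genome, bundle, cfg)
            edited = truth.edited_genes()
            table = np.zeros((2, 2))
            for g in truth.genes:
                table[int(g.gene_id in edited), int(g.gene_id in truth.deg_genes)] += 1
            if table.min() >= 1:
                _, p = stats.fisher_exact(table)
                n_sig += p < 0.01
        assert n_sig <= 2


def _single_site_world(level=0.3, het_snp=False, depth=1000, error=0.0):
    """1 kb genome with exactly one planted feature at position 500."""
    cfg = SimConfig(seed=9, contig_length=1000, n_genes=0, alu_count=0,
                    island_count=0, n_isolated_sites=0, n_snps=0,
                    simple_repeat_count=0, homopolymer_count=0,
                    n_cell_lines=1, adar_activity=(1.0,), n_replicates=1,
                    coverage=depth, error_rate=error, duplicate_fraction=0.0,
                    spliced_fraction=0.0)
    genome, bundle = generate_reference(cfg)
    seq = list(genome.sequences["chr1"])
    seq[500] = "A"
    genome = io.GenomeRef({"chr1": "".join(seq)})
    snps, sites = [], []
    if het_snp:
        snps = [SnpTruth("chr1", 500, "A", "G", "het", 0)]
    else:
        sites = [EditSiteTruth("chr1", 500, "A", "G", ".", None, level, (level,))]
    truth = SimTruth(cfg, snps, sites, [], [], set(),
                     pd.DataFrame(index=pd.Index([], name="gene_id")))
    return cfg, genome, truth


def _allele_fractions_at(path, pos):
    counts = {}
    for read in io.read_alignments(path):
        for rs, re_, qoff in read.aligned_blocks():
            if rs <= pos < re_:
                b = read.bases[qoff + pos - rs]
                counts[b] = counts.get(b, 0) + 1
    total = sum(counts.values())
    return counts, total


class TestReads:
    def test_error_free_reads_match_reference(self, tmp_path):
        cfg, genome, truth = _single_site_world(level=0.0, depth=5)
        truth = dataclasses.replace(truth, editing_sites=[])
        path = str(tmp_path / "r.sam")
        simulate_reads(genome, truth, cfg, 0, 1, path)
        for read in io.read_alignments(path):
            for rs, re_, qoff in read.aligned_blocks():
                assert read.bases[qoff:qoff + re_ - rs] == \
                    genome.sequences[read.contig][rs:re_]

    def test_het_snp_allele_fraction_near_half(self, tmp_path):
        cfg, genome, truth = _single_site_world(het_snp=True)
        path = str(tmp_path / "r.sam")
        simulate_reads(genome, truth, cfg, 0, 1, path)
        counts, total = _allele_fractions_at(path, 500)
        # binomial 99% interval around 0.5 at ~1000x
        assert abs(counts.get("G", 0) / total - 0.5) < 0.05

    def test_editing_level_recovered_in_g_fraction(self, tmp_path):
        cfg, genome, truth = _single_site_world(level=0.3)
        path = str(tmp_path / "r.sam")
        simulate_reads(genome, truth, cfg, 0, 1, path)
        counts, total = _allele_fractions_at(path, 500)
        assert abs(counts.get("G", 0) / total - 0.3) < 0.04

    def test_same_seed_identical_sam_bytes(self, tmp_path):
        cfg = SimConfig(seed=4, **SMALL)
        genome, bundle = generate_reference(cfg)
        truth = plant_variants(genome, bundle, cfg)
        blobs = []
        for i in range(2):
            p = tmp_path / f"r{i}.sam"
            simulate_reads(genome, truth, cfg, 0, 1, str(p))
            blobs.append(p.read_bytes())
        assert blobs[0] == blobs[1]

    def test_spliced_reads_skip_introns(self, tmp_path):
        cfg = SimConfig(seed=4, **SMALL)
        genome, bundle = generate_reference(cfg)
        truth = plant_variants(genome, bundle, cfg)
        p = str(tmp_path / "r.sam")
        simulate_reads(genome, truth, cfg, 0, 1, p)
        spliced = [r for r in io.read_alignments(p) if "N" in r.cigar]
        assert spliced
        junctions = bundle.junctions.positions
        for read in spliced[:20]:
            blocks = read.aligned_blocks()
            # every internal block boundary must be a known splice junction
            for (s1, e1, _), (s2, e2, _) in zip(blocks, blocks[1:]):
                assert (read.contig, e1) in junctions
                assert (read.contig, s2) in junctions


class TestExpression:
    def test_zero_noise_replicates_identical(self, small_world):
        cfg, _, _, truth = small_world
        cfg0 = dataclasses.replace(cfg, expr_noise_sd=0.0)
        expr = generate_expression(truth, cfg0)
        for line in cfg.cell_lines:
            cols = [c for c in expr.columns if c.startswith(line + "_")]
            assert (expr[cols].nunique(axis=1) == 1).all()

    def test_non_deg_log_ratio_near_zero(self, small_world):
        cfg, _, _, truth = small_world
        expr = generate_expression(truth, cfg)
        non_deg = [g.gene_id for g in truth.genes if g.gene_id not in truth.deg_genes]
        a = np.log2(expr.loc[non_deg, [c for c in expr.columns if c.startswith("line1_")]]).mean(axis=1)
        b = np.log2(expr.loc[non_deg, [c for c in expr.columns if c.startswith("line2_")]]).mean(axis=1)
        bound = 3 * cfg.expr_noise_sd / np.sqrt(cfg.n_replicates)
        assert (np.abs(a - b) < 2 * bound + 1e-9).mean() > 0.9

    def test_truth_tables_roundtrip(self, small_world, tmp_path):
        _, _, _, truth = small_world
        simdata.write_truth_tables(truth, str(tmp_path))
        back = simdata.load_truth_tables(str(tmp_path))
        assert back.snp_positions() == truth.snp_positions()
        assert back.editing_positions() == truth.editing_positions()
        assert back.editing_positions(1) == truth.editing_positions(1)
        assert back.cell_lines == truth.config.cell_lines
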