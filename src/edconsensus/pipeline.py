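"""End-to-end orchestration: simulate -> call -> consensus -> annotate ->
enrich -> evaluate, with a manifest of per-stage counts.

Every stage reads and writes plain-text artifacts (FASTA/SAM/VCF/TSV), so
any single stage can be re-run from cached upstream outputs and reproduce
downstream outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import annotate as ann
from . import consensus as cons
from . import enrich as enr
from . import io_formats as io
from . import simdata
from .callers import (EditingCallSet, EditingIsland, FilterParams,
                      hardfilter_call, island_call, mi_call)
from .pileup import build_pileup, call_candidates, dedupe_reads

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    filters: FilterParams = field(default_factory=FilterParams)
    min_replicate_support: int = 1
    deg_fc_threshold: float = 2.0
    deg_alpha: float = 0.05
    snv_genes: list[str] = field(default_factory=list)  # genes for SNV counting; default: all
    out_dir: str = "edconsensus_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str, seed: int | None = None,
                  out_dir: str | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_kwargs = raw.pop("sim", {}) or {}
        filt_kwargs = raw.pop("filters", {}) or {}
        for sub_name, sub_cls, kwargs in (("sim", simdata.SimConfig, sim_kwargs),
                                          ("filters", FilterParams, filt_kwargs)):
            bad = set(kwargs) - {f.name for f in dataclasses.fields(sub_cls)}
            if bad:
                raise ValueError(f"unknown {sub_name} config keys: {sorted(bad)}")
        cfg = cls(sim=simdata.SimConfig(**sim_kwargs),
                  filters=FilterParams(**filt_kwargs), **raw)
        if seed is not None:
            cfg.sim = dataclasses.replace(cfg.sim, seed=seed)
        if out_dir is not None:
            cfg.out_dir = out_dir
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps({
            "sim": dataclasses.asdict(self.sim),
            "filters": dataclasses.asdict(self.filters),
            "min_replicate_support": self.min_replicate_support,
            "deg_fc_threshold": self.deg_fc_threshold,
            "deg_alpha": self.deg_alpha,
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage: simulate
# ---------------------------------------------------------------------------

def simulate_dataset(config: simdata.SimConfig, out_dir: str):
    """Generate and write the full synthetic dataset; returns the in-memory
    objects alongside the file manifest."""
    os.makedirs(out_dir, exist_ok=True)
    truth_dir = os.path.join(out_dir, "truth")
    os.makedirs(truth_dir, exist_ok=True)

    genome, bundle = simdata.generate_reference(config)
    truth = simdata.plant_variants(genome, bundle, config)

    paths = {
        "reference": os.path.join(out_dir, "reference.fa"),
        "genes": os.path.join(out_dir, "genes.gff"),
        "repeats": os.path.join(out_dir, "repeats.bed"),
        "known_snps": os.path.join(out_dir, "known_snps.vcf"),
        "dna_snvs": os.path.join(out_dir, "dna_snvs.vcf"),
        "expression": os.path.join(out_dir, "expression.tsv"),
        "sam": {},
    }
    io.write_fasta(genome, paths["reference"])
    io.write_gff_lite(bundle.genes, paths["genes"])
    io.write_bed(bundle.repeats, paths["repeats"])
    simdata.write_known_snp_vcf(truth, genome, paths["known_snps"])
    simdata.write_dna_vcf(truth, genome, paths["dna_snvs"])
    simdata.write_truth_tables(truth, truth_dir)

    expr = simdata.generate_expression(truth, config)
    expr.round(4).to_csv(paths["expression"], sep="\t")

    for li, line in enumerate(config.cell_lines):
        for rep in range(1, config.n_replicates + 1):
            sam = os.path.join(out_dir, f"reads_{line}_rep{rep}.sam")
            simdata.simulate_reads(genome, truth, config, li, rep, sam)
            paths["sam"][(line, rep)] = sam

    catalog = io.read_variant_catalog(paths["known_snps"], genome, source="known")
    bundle = dataclasses.replace(bundle, snp_catalog=catalog)
    return genome, bundle, truth, expr, paths


def load_annotation(ref_path: str, genes_path: str, repeats_path: str,
                    known_snp_vcf: str | None) -> io.AnnotationBundle:
    genome = io.read_fasta(ref_path)
    genes = io.read_intervals(genes_path, "gff-lite")
    repeats = io.read_intervals(repeats_path, "BED")
    junctions = io.SpliceJunctionSet.from_gene_models(genes)
    catalog = (io.read_variant_catalog(known_snp_vcf, genome, source="known")
               if known_snp_vcf else io.KnownSnpCatalog(set()))
    return io.AnnotationBundle(genome, genes, repeats, junctions, catalog)


# ---------------------------------------------------------------------------
# stage: per-replicate calling
# ---------------------------------------------------------------------------

@dataclass
class ReplicateCalls:
    replicate: int
    candidates: list
    by_caller: dict[str, EditingCallSet]
    islands: list[EditingIsland]
    intersection: EditingCallSet


def call_replicate(sam_path: str, bundle: io.AnnotationBundle,
                   params: FilterParams, replicate: int) -> ReplicateCalls:
    reads = dedupe_reads(io.read_alignments(sam_path))
    pileups = build_pileup(reads, bundle.genome, bundle.junctions,
                           min_base_quality=params.min_base_quality,
                           emit="mismatch")
    candidates = call_candidates(pileups, params.min_cov, params.min_alt)
    hard = hardfilter_call(candidates, bundle, params, replicate)
    mi = mi_call(candidates, bundle.snp_catalog, params, replicate)
    island, islands = island_call(candidates, bundle, params, replicate)
    inter = cons.intersect_methods(hard, mi, island)
    return ReplicateCalls(replicate, candidates,
                          {"hardfilter": hard, "mi": mi, "island": island},
                          islands, inter)


@dataclass
class LineResult:
    cell_line: str
    replicates: list[ReplicateCalls]
    consensus: cons.ConsensusEditingSet       # after A-to-I restriction
    consensus_raw: cons.ConsensusEditingSet   # before A-to-I restriction

    def candidate_sites(self) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for rc in self.replicates:
            out |= {c.site for c in rc.candidates}
        return out

    def island_sites(self) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for rc in self.replicates:
            for isl in rc.islands:
                out |= set(isl.members)
        return out


def call_cell_line(sam_paths: list[str], bundle: io.AnnotationBundle,
                   params: FilterParams, cell_line: str,
                   min_replicate_support: int = 1) -> LineResult:
    reps = [call_replicate(p, bundle, params, i + 1)
            for i, p in enumerate(sam_paths)]
    combined = cons.combine_replicates([rc.intersection for rc in reps],
                                       cell_line, min_replicate_support)
    final = cons.restrict_a_to_i(combined, bundle.genes)
    return LineResult(cell_line, reps, final, combined)


# ---------------------------------------------------------------------------
# stage: evaluation against planted truth
# ---------------------------------------------------------------------------

@dataclass
class TruthScore:
    cell_line: str
    sensitivity: float
    precision: float | None
    n_eligible: int
    n_called: int
    fp_breakdown: dict[str, int]
    island_site_recovery: float
    alu_fraction_called: float
    alu_fraction_planted: float


def score_against_truth(result: LineResult, truth: simdata.SimTruth,
                        line_index: int,
                        bundle: io.AnnotationBundle) -> TruthScore:
    """Sensitivity/precision of the consensus set against planted truth.

    The sensitivity denominator is restricted to planted editing sites that
    actually met the coverage/alt-read floor in at least one replicate
    (i.e. appeared among raw candidates), so it measures the callers rather
    than sampling depth.
    """
    called = result.consensus.site_keys()
    planted_line = truth.editing_positions(line_index)
    snp_pos = truth.snp_positions()
    unknown_contigs = {c for c, _ in called} - set(bundle.genome.sequences)
    if unknown_contigs:
        raise ValueError(f"calls on contigs absent from truth genome: {sorted(unknown_contigs)}")
    candidates = result.candidate_sites()
    eligible = planted_line & candidates
    tp = called & planted_line
    sensitivity = len(tp & eligible) / len(eligible) if eligible else float("nan")
    precision = len(tp) / len(called) if called else None
    fp = called - planted_line
    breakdown = {"SNP": 0, "error": 0, "other": 0}
    editing_any = truth.editing_positions(None)
    for site in fp:
        if site in snp_pos:
            breakdown["SNP"] += 1
        elif site in editing_any:
            breakdown["other"] += 1   # planted editing, inactive in this line
        else:
            breakdown["error"] += 1

    island_truth = {
        (s.contig, s.pos) for s in truth.editing_sites
        if s.island_id is not None and s.levels[line_index] > 0
    } & eligible
    recovered = result.island_sites()
    island_recovery = (len(island_truth & recovered) / len(island_truth)
                       if island_truth else float("nan"))

    alu_called = sum(1 for (c, p) in called if bundle.alu_at(c, p))
    alu_planted = sum(1 for (c, p) in planted_line if bundle.alu_at(c, p))
    return TruthScore(
        result.cell_line,
        sensitivity,
        precision,
        len(eligible),
        len(called),
        breakdown,
        island_recovery,
        alu_called / len(called) if called else float("nan"),
        alu_planted / len(planted_line) if planted_line else float("nan"),
    )


def alu_fraction_within_ci(score: TruthScore, level: float = 0.99) -> bool:
    """Is the Alu fraction of calls inside the binomial CI implied by the
    planted Alu fraction at the observed call count?"""
    n, p0 = score.n_called, score.alu_fraction_planted
    if n == 0 or np.isnan(p0):
        return False
    lo = stats.binom.ppf((1 - level) / 2, n, p0) / n
    hi = stats.binom.ppf(1 - (1 - level) / 2, n, p0) / n
    return lo <= score.alu_fraction_called <= hi


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole analysis on a freshly simulated dataset.

    Returns the manifest (also written as ``manifest.json``) with per-stage
    counts: per-caller and intersection counts per replicate, per-line union
    and A-to-I counts, Venn partitions, enrichment results and truth scores.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = config.out_dir
    os.makedirs(out_dir, exist_ok=True)
    sim = config.sim

    genome, bundle, truth, expr, paths = simulate_dataset(sim, out_dir)
    sample_map = simdata.sample_map(sim)

    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": sim.seed,
        "cell_lines": {},
    }

    results: dict[str, LineResult] = {}
    for li, line in enumerate(sim.cell_lines):
        sams = [paths["sam"][(line, r)] for r in range(1, sim.n_replicates + 1)]
        res = call_cell_line(sams, bundle, config.filters, line,
                             config.min_replicate_support)
        results[line] = res
        line_info = {"replicates": {}, "union": len(res.consensus_raw),
                     "a_to_i": len(res.consensus)}
        for rc in res.replicates:
            line_info["replicates"][str(rc.replicate)] = {
                "candidates": len(rc.candidates),
                "hardfilter": len(rc.by_caller["hardfilter"]),
                "mi": len(rc.by_caller["mi"]),
                "island": len(rc.by_caller["island"]),
                "intersection": len(rc.intersection),
            }
        manifest["cell_lines"][line] = line_info

        _write_line_outputs(res, bundle, out_dir)

    # cross-line specific sites and Venn partition
    specificity = ann.specific_sites({l: r.consensus for l, r in results.items()},
                              bundle.genes)
    manifest["venn"] = {"+".join(k): v for k, v in specificity.venn_counts.items()}
    manifest["union_all_lines"] = specificity.union_size
    _write_venn(specificity, out_dir)

    # enrichment: line1 (reference line) vs each transformed line
    universe = enr.expressed_universe(expr, sample_map)
    enrich_rows = []
    lines = sim.cell_lines
    for other in lines[1:]:
        deg = enr.simple_deg(expr, sample_map, lines[0], other,
                             config.deg_fc_threshold, config.deg_alpha)
        edited_tbl = ann.assign_genes(results[other].consensus, bundle.genes)
        edited = set(edited_tbl["gene_id"]) & universe
        if not edited:
            log.warning("no edited genes in universe for %s; enrichment skipped", other)
            continue
        er = enr.hypergeom_enrichment(universe, deg & universe, edited)
        enrich_rows.append((lines[0], other, er.N, er.K, er.n, er.k,
                            er.p_value, er.fold_enrichment))
    enrich_df = pd.DataFrame(enrich_rows, columns=[
        "line_a", "line_b", "N", "K", "n", "k", "p_value", "fold_enrichment"])
    enrich_df.to_csv(os.path.join(out_dir, "enrichment.tsv"), sep="\t",
                     index=False, float_format="%.6g")
    manifest["enrichment"] = enrich_df.to_dict("records")

    # genomic SNVs per gene (DNA call set vs known catalog)
    dna = io.read_variant_catalog(paths["dna_snvs"], genome, source="dna")
    known = bundle.snp_catalog
    snv_rows = []
    gene_sel = config.snv_genes or [g.gene_id for g in bundle.genes]
    for gid in gene_sel:
        g = ann.gene_by_id(bundle.genes, gid)
        span_c, exon_c, novel_c = ann.count_snvs_per_gene(dna, g, known)
        snv_rows.append((gid, span_c, exon_c, novel_c))
    pd.DataFrame(snv_rows, columns=["gene_id", "span_snvs", "exon_snvs",
                                    "novel_snvs"]).to_csv(
        os.path.join(out_dir, "snv_per_gene.tsv"), sep="\t", index=False)
    manifest["snv_per_gene_total"] = int(sum(r[1] for r in snv_rows))
    manifest["novel_snvs_total"] = int(sum(r[3] for r in snv_rows))

    # evaluation against planted truth
    score_rows = []
    manifest["scores"] = {}
    for li, line in enumerate(lines):
        sc = score_against_truth(results[line], truth, li, bundle)
        manifest["scores"][line] = {
            "sensitivity": sc.sensitivity,
            "precision": sc.precision,
            "n_eligible": sc.n_eligible,
            "n_called": sc.n_called,
            "island_site_recovery": sc.island_site_recovery,
            "alu_fraction_called": sc.alu_fraction_called,
            "alu_fraction_planted": sc.alu_fraction_planted,
            "fp_breakdown": sc.fp_breakdown,
        }
        score_rows.append((line, sc.sensitivity,
                           sc.precision if sc.precision is not None else "NA",
                           sc.n_eligible, sc.n_called, sc.island_site_recovery,
                           sc.alu_fraction_called, sc.alu_fraction_planted))
    pd.DataFrame(score_rows, columns=[
        "cell_line", "sensitivity", "precision", "n_eligible", "n_called",
        "island_site_recovery", "alu_fraction_called", "alu_fraction_planted",
    ]).to_csv(os.path.join(out_dir, "scores.tsv"), sep="\t", index=False,
              float_format="%.6g")

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_line_outputs(res: LineResult, bundle: io.AnnotationBundle,
                        out_dir: str) -> None:
    line = res.cell_line
    io.write_editing_vcf(cons.consensus_to_vcf_rows(res.consensus),
                         os.path.join(out_dir, f"consensus_{line}.vcf"),
                         bundle.genome.lengths)
    rows = []
    for (contig, pos), site in sorted(res.consensus.sites.items()):
        rows.append((contig, pos + 1, site.ref, site.alt, site.strand,
                     len(site.replicates),
                     ",".join(str(r) for r in site.replicates),
                     f"{site.mean_level:.4f}"))
    pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "strand",
                                "n_replicates", "replicates", "mean_level"]
                 ).to_csv(os.path.join(out_dir, f"consensus_{line}.tsv"),
                          sep="\t", index=False)
    ann.region_table(res.consensus, bundle.repeats, bundle.genes).to_csv(
        os.path.join(out_dir, f"regions_{line}.tsv"), sep="\t", index=False)
    ann.assign_genes(res.consensus, bundle.genes).to_csv(
        os.path.join(out_dir, f"edited_genes_{line}.tsv"), sep="\t", index=False)
    for rc in res.replicates:
        for name, cs in rc.by_caller.items():
            crows = [(c, p + 1, call.ref, call.alt, f"{call.vaf:.4f}")
                     for (c, p), call in sorted(cs.calls.items())]
            pd.DataFrame(crows, columns=["contig", "pos", "ref", "alt", "vaf"]
                         ).to_csv(os.path.join(
                             out_dir, f"calls_{line}_rep{rc.replicate}_{name}.tsv"),
                             sep="\t", index=False)
        prov_rows = []
        for cand in sorted(rc.candidates, key=lambda c: (c.contig, c.pos)):
            chain = ";".join(f"{n}={'pass' if ok else 'FAIL'}"
                             for n, ok in cand.provenance)
            prov_rows.append((cand.contig, cand.pos + 1, cand.ref, cand.alt,
                              f"{cand.vaf:.4f}", chain))
        pd.DataFrame(prov_rows, columns=["contig", "pos", "ref", "alt", "vaf",
                                         "provenance"]).to_csv(
            os.path.join(out_dir, f"candidates_{line}_rep{rc.replicate}.tsv"),
            sep="\t", index=False)


def _write_venn(specificity: ann.SpecificityResult, out_dir: str) -> None:
    rows = [("+".join(combo), count)
            for combo, count in sorted(specificity.venn_counts.items())]
    pd.DataFrame(rows, columns=["lines", "sites"]).to_csv(
        os.path.join(out_dir, "venn_sites.tsv"), sep="\t", index=False)
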