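"""Synthetic RNA-seq study generator with planted ground truth.

Emulates, at desk scale, the design of a multi-cell-line bulk RNA-seq
editing study: several cell lines sequenced in three biological replicates
over a shared genome, with

* A-to-I editing sites clustered into "islands" inside Alu-like inverted
  repeats plus isolated sites elsewhere,
* genomic SNPs (het and hom-alt, phased onto two haplotypes) acting as
  confounders for editing detection,
* a per-cell-line ADAR-activity scalar that multiplies every site's editing
  level (modelling reduced ADAR expression in some lines), and
* a two-condition expression matrix in which differential expression is
  enriched among edited genes by a configurable odds multiplier.

All randomness flows through numpy Generators derived from ``SimConfig.seed``
via ``SeedSequence`` spawn keys, so every artifact (FASTA/SAM/VCF/TSV) is
byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .callers import site_in_homopolymer
from .io_formats import (
    AnnotationBundle,
    GeneModel,
    GenomeRef,
    GenomicInterval,
    KnownSnpCatalog,
    SpliceJunctionSet,
)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults describe a single 200 kb contig carrying 40 genes and 40
    Alu-like repeats, three cell lines with decreasing ADAR activity, three
    replicates each at 30x coverage — small enough to run on a laptop while
    preserving the statistical structure the consensus pipeline relies on.
    """

    seed: int = 0
    # genome
    n_contigs: int = 1
    contig_length: int = 200_000
    n_genes: int = 40
    exons_per_gene: int = 3
    exon_length: int = 250
    intron_length: int = 500
    alu_count: int = 40
    alu_length: int = 300
    alu_divergence: tuple[float, float] = (0.05, 0.15)
    simple_repeat_count: int = 10
    simple_repeat_length: int = 40
    homopolymer_count: int = 12
    homopolymer_length: tuple[int, int] = (6, 10)
    # variants
    n_snps: int = 150
    het_fraction: float = 0.67
    known_snp_fraction: float = 0.95
    n_isolated_sites: int = 100
    island_count: int = 20
    island_sites: tuple[int, int] = (3, 6)
    island_max_gap: int = 50
    editing_level_alpha: float = 2.0
    editing_level_beta: float = 5.0
    editing_level_min: float = 0.2
    private_site_fraction: float = 0.2
    # sequencing
    coverage: float = 30.0
    read_length: int = 100
    error_rate: float = 0.001
    base_quality: int = 37
    duplicate_fraction: float = 0.05
    spliced_fraction: float = 0.10
    n_replicates: int = 3
    # cell lines
    n_cell_lines: int = 3
    adar_activity: tuple[float, ...] = (1.0, 0.7, 0.45)
    # expression
    deg_fraction: float = 0.2
    deg_edited_enrichment: float = 4.0
    deg_fold_change: float = 4.0
    expr_noise_sd: float = 0.15
    expr_mean_log2: float = 5.0
    expr_mean_log2_sd: float = 1.5

    def __post_init__(self) -> None:
        if isinstance(self.adar_activity, (int, float)):
            self.adar_activity = (float(self.adar_activity),) * self.n_cell_lines
        self.adar_activity = tuple(self.adar_activity)
        if len(self.adar_activity) < self.n_cell_lines:
            raise ValueError("adar_activity must give one value per cell line")
        if not all(0.0 <= a <= 1.0 for a in self.adar_activity):
            raise ValueError("adar_activity values must lie in [0, 1]")
        if self.read_length > self.contig_length:
            raise ValueError("read length exceeds contig length")
        for p in (self.het_fraction, self.known_snp_fraction, self.error_rate,
                  self.deg_fraction, self.private_site_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability parameter out of [0,1]: {p}")

    @property
    def cell_lines(self) -> list[str]:
        return [f"line{i + 1}" for i in range(self.n_cell_lines)]

    def rng(self, *key: int) -> np.random.Generator:
        return np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(self.seed, spawn_key=key))
        )


@dataclass(frozen=True)
class SnpTruth:
    contig: str
    pos: int
    ref: str
    alt: str
    genotype: str  # "het" | "hom"
    phase: int     # haplotype carrying the alt allele (het only)


@dataclass(frozen=True)
class EditSiteTruth:
    contig: str
    pos: int
    ref: str            # plus-strand reference base (A, or T for minus-strand genes)
    alt: str            # plus-strand observed variant base (G, or C)
    strand: str
    island_id: int | None
    base_level: float
    levels: tuple[float, ...]  # per cell line, after ADAR-activity scaling


@dataclass
class SimTruth:
    """Planted ground truth, sufficient to score any caller."""

    config: SimConfig
    snps: list[SnpTruth]
    editing_sites: list[EditSiteTruth]
    islands: list[GenomicInterval]
    genes: list[GeneModel]
    deg_genes: set[str]
    expr_means: pd.DataFrame  # genes x cell lines

    def snp_positions(self) -> set[tuple[str, int]]:
        return {(s.contig, s.pos) for s in self.snps}

    def editing_positions(self, line: int | None = None) -> set[tuple[str, int]]:
        sites = self.editing_sites
        if line is not None:
            sites = [s for s in sites if s.levels[line] > 0]
        return {(s.contig, s.pos) for s in sites}

    def edited_genes(self, line: int | None = None) -> set[str]:
        positions = self.editing_positions(line)
        out = set()
        for g in self.genes:
            if any(
                c == g.contig and g.span.start <= p < g.span.end
                for c, p in positions
            ):
                out.add(g.gene_id)
        return out

    def site_class(self, contig: str, pos: int) -> str:
        if (contig, pos) in self.snp_positions():
            return "SNP"
        if (contig, pos) in self.editing_positions():
            return "editing"
        return "clean"


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _place_nonoverlapping(rng, length: int, count: int, contig_len: int,
                          occupied: list[tuple[int, int]], margin: int = 5,
                          max_tries: int = 20_000) -> list[int]:
    """Rejection-sample `count` starts of `length` avoiding `occupied`."""
    starts: list[int] = []
    taken = sorted(occupied)
    for _ in range(max_tries):
        if len(starts) == count:
            break
        s = int(rng.integers(0, contig_len - length))
        if all(s + length + margin <= a or b + margin <= s for a, b in taken):
            starts.append(s)
            taken.append((s, s + length))
            taken.sort()
    if len(starts) < count:
        raise ValueError(
            f"could not place {count} features of length {length}; contig too crowded"
        )
    return starts


def generate_reference(config: SimConfig) -> tuple[GenomeRef, AnnotationBundle]:
    """Random genome with planted genes, Alu-like inverted repeats,
    simple repeats and homopolymer runs.

    Alu copies derive from one random consensus per genome; each copy is
    mutated by 5-15% and half the copies are inserted in inverted (reverse
    complement) orientation, mimicking the inverted Alu pairs that form the
    double-stranded RNA substrate of ADAR.
    """
    rng = config.rng(1)
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    repeats: list[GenomicInterval] = []

    gene_len = (config.exons_per_gene * config.exon_length
                + (config.exons_per_gene - 1) * config.intron_length)
    alu_consensus = "".join(rng.choice(list(BASES), size=config.alu_length))

    for ci in range(config.n_contigs):
        contig = f"chr{ci + 1}"
        L = config.contig_length
        seq = rng.integers(0, 4, size=L)

        # genes in evenly spaced slots with jitter, non-overlapping
        occupied: list[tuple[int, int]] = []
        slot = L // max(config.n_genes, 1)
        if config.n_genes and slot < gene_len + 10:
            raise ValueError("contig too short for requested gene count/size")
        for gi in range(config.n_genes):
            start = gi * slot + int(rng.integers(0, max(slot - gene_len, 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            for ei in range(config.exons_per_gene):
                es = start + ei * (config.exon_length + config.intron_length)
                exons.append(GenomicInterval(contig, es, es + config.exon_length, strand))
            gid = f"g{ci + 1:02d}{gi + 1:03d}"
            span = GenomicInterval(contig, start, start + gene_len, strand, gid)
            genes.append(GeneModel(gid, span, [
                dataclasses.replace(e, label=gid) for e in exons], strand))
            occupied.append((start, start + gene_len))

        exon_iv = [(e.start, e.end) for g in genes if g.contig == contig for e in g.exons]

        # Alu-like repeats: anywhere outside exons
        alu_starts = _place_nonoverlapping(
            rng, config.alu_length, config.alu_count // config.n_contigs,
            L, exon_iv)
        for s in alu_starts:
            copy = list(alu_consensus)
            n_mut = int(rng.uniform(*config.alu_divergence) * config.alu_length)
            for i in rng.choice(config.alu_length, size=n_mut, replace=False):
                copy[i] = BASES[(_CODE[copy[i]] + int(rng.integers(1, 4))) % 4]
            inserted = "".join(copy)
            strand = "+"
            if rng.random() < 0.5:
                inserted = _revcomp(inserted)
                strand = "-"
            seq[s:s + config.alu_length] = [_CODE[b] for b in inserted]
            repeats.append(GenomicInterval(contig, s, s + config.alu_length, strand, "Alu"))

        taken = exon_iv + [(r.start, r.end) for r in repeats if r.contig == contig]

        # simple repeats (dinucleotide tracts)
        sr_starts = _place_nonoverlapping(
            rng, config.simple_repeat_length,
            config.simple_repeat_count // config.n_contigs, L, taken)
        for s in sr_starts:
            unit = "".join(rng.choice(list(BASES), size=2, replace=False))
            tract = (unit * config.simple_repeat_length)[: config.simple_repeat_length]
            seq[s:s + len(tract)] = [_CODE[b] for b in tract]
            repeats.append(GenomicInterval(contig, s, s + len(tract), ".", "simple_repeat"))
            taken.append((s, s + len(tract)))

        # homopolymer runs
        hp_max = config.homopolymer_length[1]
        hp_starts = _place_nonoverlapping(
            rng, hp_max, config.homopolymer_count // config.n_contigs, L, taken)
        for s in hp_starts:
            n = int(rng.integers(config.homopolymer_length[0], hp_max + 1))
            b = int(rng.integers(0, 4))
            seq[s:s + n] = b

        sequences[contig] = "".join(BASES[c] for c in seq)

    genome = GenomeRef(sequences)
    junctions = SpliceJunctionSet.from_gene_models(genes)
    bundle = AnnotationBundle(genome, genes, repeats, junctions, KnownSnpCatalog(set()))
    return genome, bundle


# ---------------------------------------------------------------------------
# variant planting
# ---------------------------------------------------------------------------

def _editable_positions(genome: GenomeRef, bundle: AnnotationBundle,
                        contig: str, start: int, end: int) -> list[tuple[int, str, str]]:
    """Positions in [start,end) where an editing site can be planted cleanly.

    Clean means: the plus-strand base is A (for +/intergenic context) or T
    (inside a minus-strand gene), outside simple repeats, not in or adjacent
    to a homopolymer run of >=5, and >4 nt from any splice junction — so the
    planted truth is recoverable in principle and recovery scores measure
    the callers rather than the artifact filters (which are exercised by the
    SNP confounders and dedicated fixtures).
    """
    seq = genome.sequences[contig]
    out = []
    for pos in range(start, end):
        in_genes = bundle.genes_at(contig, pos)
        strand = in_genes[0].strand if in_genes else "."
        want = "T" if strand == "-" else "A"
        if seq[pos] != want:
            continue
        if bundle.simple_repeat_at(contig, pos):
            continue
        if site_in_homopolymer(genome, (contig, pos), 5):
            continue
        if bundle.junction_distance(contig, pos) <= 4:
            continue
        alt = "C" if want == "T" else "G"
        out.append((pos, want, alt))
    return out


def _truncated_beta(rng, a: float, b: float, lo: float) -> float:
    for _ in range(10_000):
        x = float(rng.beta(a, b))
        if x >= lo:
            return x
    return lo


def plant_variants(genome: GenomeRef, bundle: AnnotationBundle,
                   config: SimConfig) -> SimTruth:
    """Plant SNPs, editing sites (islands + isolated), DEG labels and
    per-gene expression means.

    Editing levels are Beta(alpha, beta) draws truncated at
    ``editing_level_min``, multiplied per cell line by that line's ADAR
    activity; a ``private_site_fraction`` of sites is active in a single
    cell line only.  DEG labels are drawn so that
    P(DEG | edited) = enrichment x P(DEG | not edited), capped at 1.
    """
    rng = config.rng(2)
    contigs = list(genome.sequences)
    islands: list[GenomicInterval] = []
    editing: list[EditSiteTruth] = []
    used: set[tuple[str, int]] = set()

    # --- island-resident sites inside Alu repeats
    alus = [r for r in bundle.repeats if r.label == "Alu"]
    if config.island_count > len(alus):
        raise ValueError("island_count exceeds Alu count")
    chosen = rng.choice(len(alus), size=config.island_count, replace=False)
    island_id = 0
    for ai in sorted(int(i) for i in chosen):
        alu = alus[ai]
        eligible = _editable_positions(genome, bundle, alu.contig, alu.start, alu.end)
        k = int(rng.integers(config.island_sites[0], config.island_sites[1] + 1))
        member = _pick_clustered(rng, eligible, k, config.island_max_gap)
        if member is None or len(member) < 3:
            raise ValueError(
                f"insufficient editable A positions in Alu {alu.start}-{alu.end}"
            )
        positions = [p for p, _, _ in member]
        islands.append(GenomicInterval(
            alu.contig, min(positions), max(positions) + 1, alu.strand,
            f"island{island_id}"))
        for pos, ref, alt in member:
            editing.append(_make_site(rng, config, alu.contig, pos, ref, alt,
                                      bundle, island_id))
            used.add((alu.contig, pos))
        island_id += 1

    # --- isolated sites outside Alus, well separated from other sites
    per_contig = config.n_isolated_sites // len(contigs)
    for contig in contigs:
        L = len(genome.sequences[contig])
        placed = 0
        for _ in range(200_000):
            if placed == per_contig:
                break
            pos = int(rng.integers(0, L))
            if (contig, pos) in used or bundle.alu_at(contig, pos):
                continue
            cand = _editable_positions(genome, bundle, contig, pos, pos + 1)
            if not cand:
                continue
            if any((contig, q) in used
                   for q in range(pos - config.island_max_gap,
                                  pos + config.island_max_gap + 1)):
                continue
            p, ref, alt = cand[0]
            editing.append(_make_site(rng, config, contig, p, ref, alt, bundle, None))
            used.add((contig, p))
            placed += 1
        if placed < per_contig:
            raise ValueError("insufficient A positions for isolated editing sites")

    # --- SNPs, uniform, disjoint from editing sites
    snps: list[SnpTruth] = []
    while len(snps) < config.n_snps:
        contig = contigs[int(rng.integers(0, len(contigs)))]
        pos = int(rng.integers(0, len(genome.sequences[contig])))
        if (contig, pos) in used:
            continue
        ref = genome.base(contig, pos)
        if ref == "N":
            continue
        alt = BASES[(_CODE[ref] + int(rng.integers(1, 4))) % 4]
        genotype = "het" if rng.random() < config.het_fraction else "hom"
        phase = int(rng.integers(0, 2))
        snps.append(SnpTruth(contig, pos, ref, alt, genotype, phase))
        used.add((contig, pos))

    # --- DEG labels enriched among edited genes
    edited_any = set()
    for g in bundle.genes:
        if any(s.contig == g.contig and g.span.start <= s.pos < g.span.end
               for s in editing):
            edited_any.add(g.gene_id)
    n_genes = len(bundle.genes)
    n_e = len(edited_any)
    r = config.deg_edited_enrichment
    denom = (n_genes - n_e) + r * n_e
    p_ne = config.deg_fraction * n_genes / denom if denom else 0.0
    p_e = min(1.0, r * p_ne)
    deg_genes = set()
    for g in bundle.genes:
        p = p_e if g.gene_id in edited_any else p_ne
        if rng.random() < p:
            deg_genes.add(g.gene_id)

    # --- per-gene expression means per cell line
    gene_ids = [g.gene_id for g in bundle.genes]
    base = 2.0 ** rng.normal(config.expr_mean_log2, config.expr_mean_log2_sd,
                             size=n_genes)
    means = np.tile(base[:, None], (1, config.n_cell_lines))
    for i, gid in enumerate(gene_ids):
        if gid in deg_genes:
            direction = 1.0 if rng.random() < 0.5 else -1.0
            for li in range(1, config.n_cell_lines):
                means[i, li] = base[i] * config.deg_fold_change ** direction
    expr_means = pd.DataFrame(means, index=gene_ids, columns=config.cell_lines)

    editing.sort(key=lambda s: (s.contig, s.pos))
    snps.sort(key=lambda s: (s.contig, s.pos))
    return SimTruth(config, snps, editing, islands, bundle.genes, deg_genes,
                    expr_means)


def _pick_clustered(rng, eligible, k, max_gap):
    """First window of >=3 (ideally k) eligible positions with gaps <= max_gap."""
    if not eligible:
        return None
    best = None
    runs, run = [], [eligible[0]]
    for item in eligible[1:]:
        if item[0] - run[-1][0] <= max_gap:
            run.append(item)
        else:
            runs.append(run)
            run = [item]
    runs.append(run)
    runs.sort(key=len, reverse=True)
    cluster = runs[0]
    if len(cluster) < 3:
        return None
    k = min(k, len(cluster))
    start = int(rng.integers(0, len(cluster) - k + 1))
    best = cluster[start:start + k]
    # keep gaps within bound after subsetting (contiguous slice, so they are)
    return best


def _make_site(rng, config: SimConfig, contig: str, pos: int, ref: str, alt: str,
               bundle: AnnotationBundle, island_id: int | None) -> EditSiteTruth:
    genes = bundle.genes_at(contig, pos)
    strand = genes[0].strand if genes else "."
    base_level = _truncated_beta(rng, config.editing_level_alpha,
                                 config.editing_level_beta,
                                 config.editing_level_min)
    levels = [base_level * a for a in config.adar_activity]
    # island sites are conserved across lines (Alu editing is); only isolated
    # sites may be private to one line
    if island_id is None and rng.random() < config.private_site_fraction:
        owner = int(rng.integers(0, config.n_cell_lines))
        levels = [levels[i] if i == owner else 0.0
                  for i in range(config.n_cell_lines)]
    return EditSiteTruth(contig, pos, ref, alt, strand, island_id,
                         base_level, tuple(levels))


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(genome: GenomeRef, truth: SimTruth, config: SimConfig,
                   cell_line: int, replicate: int, path: str) -> str:
    """Write one replicate's pre-aligned single-end reads as SAM.

    Reads are drawn uniformly over the genome plus a ``spliced_fraction`` of
    transcript reads that skip introns (N CIGAR ops).  Each read samples one
    of two haplotypes; het SNP alleles follow the haplotype phase, editing
    sites convert A->G (T->C on the minus strand) independently per read with
    probability equal to the site's cell-line editing level, and sequencing
    errors strike each base independently.  A ``duplicate_fraction`` of reads
    is re-emitted verbatim under a new name to exercise duplicate removal.
    """
    import pysam

    rng = config.rng(3, cell_line, replicate)
    names = list(genome.sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(genome.sequences[n])} for n in names],
    }

    # per-contig lookup arrays
    lookup = {}
    for contig, seq in genome.sequences.items():
        L = len(seq)
        ref_codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        code = np.full(256, 4, dtype=np.int8)
        for b, i in _CODE.items():
            code[ord(b)] = i
        ref_arr = code[ref_codes]
        snp_type = np.zeros(L, dtype=np.int8)   # 0 none, 1 het, 2 hom
        snp_alt = np.zeros(L, dtype=np.int8)
        snp_phase = np.zeros(L, dtype=np.int8)
        for s in truth.snps:
            if s.contig != contig:
                continue
            snp_type[s.pos] = 1 if s.genotype == "het" else 2
            snp_alt[s.pos] = _CODE[s.alt]
            snp_phase[s.pos] = s.phase
        edit_prob = np.zeros(L, dtype=np.float64)
        edit_alt = np.zeros(L, dtype=np.int8)
        for s in truth.editing_sites:
            if s.contig != contig:
                continue
            edit_prob[s.pos] = s.levels[cell_line]
            edit_alt[s.pos] = _CODE[s.alt]
        lookup[contig] = (ref_arr, snp_type, snp_alt, snp_phase, edit_prob, edit_alt)

    genes_by_contig: dict[str, list[GeneModel]] = {}
    for g in truth.genes:
        genes_by_contig.setdefault(g.contig, []).append(g)

    with pysam.AlignmentFile(path, "w", header=header) as out:
        read_idx = 0
        for contig in names:
            L = len(genome.sequences[contig])
            n_reads = int(np.ceil(config.coverage * L / config.read_length))
            n_spliced = int(config.spliced_fraction * n_reads)
            genes = genes_by_contig.get(contig, [])
            emitted: list[pysam.AlignedSegment] = []
            for i in range(n_reads):
                spliced = i < n_spliced and genes
                if spliced:
                    gene = genes[int(rng.integers(0, len(genes)))]
                    blocks = _transcript_read_blocks(rng, gene, config.read_length)
                else:
                    start = int(rng.integers(0, L - config.read_length + 1))
                    blocks = [(start, start + config.read_length)]
                if blocks is None:
                    start = int(rng.integers(0, L - config.read_length + 1))
                    blocks = [(start, start + config.read_length)]
                seg = _make_read(rng, config, lookup[contig], contig, blocks,
                                 f"r{cell_line}_{replicate}_{read_idx}", out.header)
                emitted.append(seg)
                read_idx += 1
            # exact duplicates
            n_dup = int(config.duplicate_fraction * len(emitted))
            if n_dup:
                for j in rng.choice(len(emitted), size=n_dup, replace=False):
                    src = emitted[int(j)]
                    dup = pysam.AlignedSegment(out.header)
                    dup.query_name = src.query_name + "_dup"
                    dup.flag = src.flag
                    dup.reference_id = src.reference_id
                    dup.reference_start = src.reference_start
                    dup.mapping_quality = src.mapping_quality
                    dup.cigarstring = src.cigarstring
                    dup.query_sequence = src.query_sequence
                    dup.query_qualities = src.query_qualities
                    emitted.append(dup)
            for seg in emitted:
                out.write(seg)
    return path


def _transcript_read_blocks(rng, gene: GeneModel, read_len: int):
    """Genomic blocks of a read drawn from the gene's mature transcript."""
    exon_lens = [len(e) for e in gene.exons]
    translen = sum(exon_lens)
    if translen < read_len:
        return None
    toff = int(rng.integers(0, translen - read_len + 1))
    blocks = []
    remaining, cursor = read_len, toff
    for exon in gene.exons:
        elen = len(exon)
        if cursor >= elen:
            cursor -= elen
            continue
        take = min(elen - cursor, remaining)
        blocks.append((exon.start + cursor, exon.start + cursor + take))
        remaining -= take
        cursor = 0
        if remaining == 0:
            break
    return blocks


def _make_read(rng, config: SimConfig, arrays, contig: str, blocks,
               name: str, header):
    import pysam

    ref_arr, snp_type, snp_alt, snp_phase, edit_prob, edit_alt = arrays
    positions = np.concatenate([np.arange(s, e) for s, e in blocks])
    codes = ref_arr[positions].astype(np.int8)
    hap = int(rng.integers(0, 2))
    # genomic SNPs
    st = snp_type[positions]
    hom = st == 2
    codes[hom] = snp_alt[positions][hom]
    het = (st == 1) & (snp_phase[positions] == hap)
    codes[het] = snp_alt[positions][het]
    # RNA editing, independent per read
    ep = edit_prob[positions]
    if ep.any():
        edited = rng.random(len(positions)) < ep
        codes[edited] = edit_alt[positions][edited]
    # sequencing errors
    if config.error_rate > 0:
        err = rng.random(len(positions)) < config.error_rate
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum())).astype(np.int8)
            codes[err] = (codes[err] + shift) % 4
    bases = "".join(BASES[c] for c in codes)

    cigar_parts = []
    for k, (s, e) in enumerate(blocks):
        if k > 0:
            cigar_parts.append(f"{s - blocks[k - 1][1]}N")
        cigar_parts.append(f"{e - s}M")

    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.flag = 16 if rng.random() < 0.5 else 0
    seg.reference_id = header.get_tid(contig)
    seg.reference_start = int(blocks[0][0])
    seg.mapping_quality = 60
    seg.cigarstring = "".join(cigar_parts)
    seg.query_sequence = bases
    seg.query_qualities = pysam.qualitystring_to_array(
        chr(config.base_quality + 33) * len(bases))
    return seg


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def generate_expression(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Expression matrix (genes x cell_line/replicate samples).

    Log-normal multiplicative noise around the per-cell-line means, so
    replicates of one line are highly correlated while DEG genes differ
    between lines by the configured fold change.
    """
    rng = config.rng(4)
    cols, data = [], []
    for li, line in enumerate(config.cell_lines):
        for rep in range(1, config.n_replicates + 1):
            cols.append(f"{line}_rep{rep}")
            noise = 2.0 ** rng.normal(0.0, config.expr_noise_sd,
                                      size=len(truth.expr_means))
            data.append(truth.expr_means.iloc[:, li].to_numpy() * noise)
    mat = pd.DataFrame(np.column_stack(data), index=truth.expr_means.index,
                       columns=cols)
    mat.index.name = "gene_id"
    return mat


def sample_map(config: SimConfig) -> dict[str, tuple[str, int]]:
    return {
        f"{line}_rep{rep}": (line, rep)
        for line in config.cell_lines
        for rep in range(1, config.n_replicates + 1)
    }


# ---------------------------------------------------------------------------
# truth / annotation emission
# ---------------------------------------------------------------------------

def write_truth_tables(truth: SimTruth, directory: str) -> None:
    import os

    cfg = truth.config
    snp_df = pd.DataFrame(
        [(s.contig, s.pos, s.ref, s.alt, s.genotype, s.phase) for s in truth.snps],
        columns=["contig", "pos", "ref", "alt", "genotype", "phase"])
    snp_df.to_csv(os.path.join(directory, "truth_snps.tsv"), sep="\t", index=False)
    ed_rows = []
    for s in truth.editing_sites:
        row = [s.contig, s.pos, s.ref, s.alt, s.strand,
               s.island_id if s.island_id is not None else "NA",
               f"{s.base_level:.4f}"]
        row += [f"{lv:.4f}" for lv in s.levels]
        ed_rows.append(row)
    ed_df = pd.DataFrame(ed_rows, columns=(
        ["contig", "pos", "ref", "alt", "strand", "island_id", "base_level"]
        + [f"level_{ln}" for ln in cfg.cell_lines]))
    ed_df.to_csv(os.path.join(directory, "truth_editing.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [(iv.contig, iv.start, iv.end, iv.label) for iv in truth.islands],
        columns=["contig", "start", "end", "island"],
    ).to_csv(os.path.join(directory, "truth_islands.tsv"), sep="\t", index=False)
    gene_df = pd.DataFrame({
        "gene_id": [g.gene_id for g in truth.genes],
        "edited": [g.gene_id in truth.edited_genes() for g in truth.genes],
        "deg": [g.gene_id in truth.deg_genes for g in truth.genes],
    })
    gene_df.to_csv(os.path.join(directory, "truth_genes.tsv"), sep="\t", index=False)


@dataclass
class TruthTables:
    """Read-back view of written truth tables, duck-typing the parts of
    :class:`SimTruth` that scoring needs."""

    snps: list[SnpTruth]
    editing_sites: list[EditSiteTruth]
    islands: list[GenomicInterval]
    cell_lines: list[str]

    snp_positions = SimTruth.snp_positions
    editing_positions = SimTruth.editing_positions
    site_class = SimTruth.site_class


def load_truth_tables(directory: str) -> TruthTables:
    import os

    snp_df = pd.read_csv(os.path.join(directory, "truth_snps.tsv"), sep="\t")
    snps = [SnpTruth(r.contig, int(r.pos), r.ref, r.alt, r.genotype, int(r.phase))
            for r in snp_df.itertuples()]
    ed_df = pd.read_csv(os.path.join(directory, "truth_editing.tsv"), sep="\t")
    level_cols = [c for c in ed_df.columns if c.startswith("level_")]
    cell_lines = [c[len("level_"):] for c in level_cols]
    sites = []
    for r in ed_df.itertuples():
        island = None if pd.isna(r.island_id) or r.island_id == "NA" else int(r.island_id)
        levels = tuple(float(getattr(r, c)) for c in level_cols)
        sites.append(EditSiteTruth(r.contig, int(r.pos), r.ref, r.alt, r.strand,
                                   island, float(r.base_level), levels))
    isl_df = pd.read_csv(os.path.join(directory, "truth_islands.tsv"), sep="\t")
    islands = [GenomicInterval(r.contig, int(r.start), int(r.end), ".", r.island)
               for r in isl_df.itertuples()]
    return TruthTables(snps, sites, islands, cell_lines)


def _write_simple_vcf(rows, genome: GenomeRef, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DB,Number=0,Type=Flag,Description='
                 '"Catalog membership">\n')
        fh.write('##INFO=<ID=GT,Number=1,Type=String,Description='
                 '"Simulated genotype">\n')
        for name, seq in genome.sequences.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for contig, pos, ref, alt, info in sorted(rows):
            fh.write(f"{contig}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")


def write_known_snp_vcf(truth: SimTruth, genome: GenomeRef, path: str) -> None:
    """Known-SNP catalog: a ``known_snp_fraction`` subset of planted SNPs,
    modelling dbSNP incompleteness."""
    rng = truth.config.rng(5)
    rows = []
    for s in truth.snps:
        if rng.random() < truth.config.known_snp_fraction:
            rows.append((s.contig, s.pos, s.ref, s.alt, "DB"))
    _write_simple_vcf(rows, genome, path)


def write_dna_vcf(truth: SimTruth, genome: GenomeRef, path: str) -> None:
    """DNA-seq variant calls: all planted SNPs with genotype annotation."""
    rows = [(s.contig, s.pos, s.ref, s.alt, f"GT={'0/1' if s.genotype == 'het' else '1/1'}")
            for s in truth.snps]
    _write_simple_vcf(rows, genome, path)
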