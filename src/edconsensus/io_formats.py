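"""Readers and writers for the standard formats the pipeline touches.

Every reader converts to a single internal coordinate convention:
0-based, half-open intervals on the forward strand of the reference.
SAM, VCF and the GFF-lite gene-model dialect are all 1-based on disk;
the conversion happens here and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")
CIGAR_OPS = "MIDNSHP=X"
#: CIGAR ops this pipeline understands (soft-clip, match, intron skip).
SUPPORTED_CIGAR_OPS = set("MNS=X")
#: ops that consume reference bases
REF_CONSUMING = set("MDN=X")
#: ops that consume read bases
READ_CONSUMING = set("MIS=X")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeRef:
    """Reference genome held in memory (toy scale, uppercase)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r} contains non-nucleotide characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def base(self, contig: str, pos: int) -> str:
        return self.sequences[contig][pos]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval]
    strand: str

    def __post_init__(self) -> None:
        prev_end = None
        for exon in self.exons:
            if exon.start < self.span.start or exon.end > self.span.end:
                raise FormatError(
                    f"exon {exon.start}-{exon.end} outside span of gene {self.gene_id}"
                )
            if prev_end is not None and exon.start < prev_end:
                raise FormatError(f"overlapping/unsorted exons in gene {self.gene_id}")
            prev_end = exon.end

    @property
    def contig(self) -> str:
        return self.span.contig

    def junctions(self) -> set[int]:
        """Internal exon boundaries (splice donor/acceptor coordinates)."""
        sites: set[int] = set()
        for exon in self.exons:
            if exon.start != self.span.start:
                sites.add(exon.start)
            if exon.end != self.span.end:
                sites.add(exon.end)
        return sites


@dataclass
class SpliceJunctionSet:
    """Positions of known splice junctions, as (contig, 0-based boundary)."""

    positions: set[tuple[str, int]] = field(default_factory=set)

    @classmethod
    def from_gene_models(cls, genes: list[GeneModel]) -> "SpliceJunctionSet":
        positions = {
            (g.contig, j) for g in genes for j in g.junctions()
        }
        return cls(positions)

    def by_contig(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for contig, pos in self.positions:
            out.setdefault(contig, []).append(pos)
        for v in out.values():
            v.sort()
        return out


@dataclass
class KnownSnpCatalog:
    """Catalog of genomic SNPs (e.g. dbSNP or a DNA-seq call set)."""

    entries: set[tuple[str, int, str, str]] = field(default_factory=set)
    source: str = ""

    @property
    def positions(self) -> set[tuple[str, int]]:
        return {(c, p) for c, p, _, _ in self.entries}

    def __contains__(self, site: tuple[str, int]) -> bool:
        return site in self.positions

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class AlignedRead:
    """A mapped single-end read (0-based leftmost position)."""

    name: str
    contig: str
    pos: int
    strand: str
    cigar: str
    bases: str
    quals: list[int]
    is_duplicate: bool = False

    def cigar_tuples(self) -> list[tuple[str, int]]:
        out = []
        n = ""
        for ch in self.cigar:
            if ch.isdigit():
                n += ch
            else:
                out.append((ch, int(n)))
                n = ""
        return out

    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar_tuples() if op in REF_CONSUMING)

    def aligned_blocks(self) -> list[tuple[int, int, int]]:
        """(ref_start, ref_end, read_offset) for each M/=/X block."""
        blocks = []
        rpos, qpos = self.pos, 0
        for op, n in self.cigar_tuples():
            if op in "M=X":
                blocks.append((rpos, rpos + n, qpos))
                rpos += n
                qpos += n
            elif op == "N":
                rpos += n
            elif op == "S":
                qpos += n
        return blocks


@dataclass
class AnnotationBundle:
    """Reference plus every annotation track, with interval indexes."""

    genome: GenomeRef
    genes: list[GeneModel]
    repeats: list[GenomicInterval]
    junctions: SpliceJunctionSet
    snp_catalog: KnownSnpCatalog

    def __post_init__(self) -> None:
        self._repeat_index: dict[str, IntervalTree] = {}
        for iv in self.repeats:
            self._repeat_index.setdefault(iv.contig, IntervalTree()).addi(
                iv.start, iv.end, iv
            )
        self._gene_index: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._gene_index.setdefault(g.contig, IntervalTree()).addi(
                g.span.start, g.span.end, g
            )
        self._junctions_by_contig = self.junctions.by_contig()

    def repeats_at(self, contig: str, pos: int) -> list[GenomicInterval]:
        tree = self._repeat_index.get(contig)
        if tree is None:
            return []
        return [hit.data for hit in tree[pos]]

    def alu_at(self, contig: str, pos: int) -> bool:
        return any(iv.label == "Alu" for iv in self.repeats_at(contig, pos))

    def simple_repeat_at(self, contig: str, pos: int) -> bool:
        return any(
            iv.label == "simple_repeat" for iv in self.repeats_at(contig, pos)
        )

    def genes_at(self, contig: str, pos: int) -> list[GeneModel]:
        tree = self._gene_index.get(contig)
        if tree is None:
            return []
        return [hit.data for hit in tree[pos]]

    def genes_overlapping(self, contig: str, start: int, end: int) -> list[GeneModel]:
        tree = self._gene_index.get(contig)
        if tree is None:
            return []
        return [hit.data for hit in tree[start:end]]

    def junction_distance(self, contig: str, pos: int) -> float:
        sites = self._junctions_by_contig.get(contig)
        if not sites:
            return float("inf")
        import bisect

        i = bisect.bisect_left(sites, pos)
        best = float("inf")
        if i < len(sites):
            best = min(best, abs(sites[i] - pos))
        if i > 0:
            best = min(best, abs(sites[i - 1] - pos))
        return best


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> GenomeRef:
    """Load a FASTA file into a :class:`GenomeRef` (sequences uppercased)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate contig name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    return GenomeRef(sequences)


def write_fasta(genome: GenomeRef, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignments(path: str):
    """Stream mapped primary reads from a SAM file as :class:`AlignedRead`.

    Unmapped, secondary and supplementary records are skipped.  Records with
    CIGAR operations outside M/N/S/=/X are rejected with a warning (the
    pipeline does not model indels or hard clips).
    """
    with pysam.AlignmentFile(path, "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            ops = {CIGAR_OPS[op] for op, _ in rec.cigartuples or []}
            if not ops <= SUPPORTED_CIGAR_OPS:
                log.warning(
                    "read %s rejected: unsupported CIGAR %s", rec.query_name, rec.cigarstring
                )
                continue
            yield AlignedRead(
                name=rec.query_name,
                contig=rec.reference_name,
                pos=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                cigar=rec.cigarstring,
                bases=rec.query_sequence,
                quals=list(rec.query_qualities),
                is_duplicate=rec.is_duplicate,
            )


def read_intervals(path: str, format: str = "BED"):
    """Read an interval track.

    ``BED`` (3-6 columns) yields ``GenomicInterval`` with the BED name column
    as label.  ``GFF-lite`` — tab-separated ``contig source type start end
    score strand frame gene_id=<id>`` with type in {gene, exon}, 1-based
    inclusive coordinates — yields assembled ``GeneModel`` objects.
    """
    if format.upper() == "BED":
        return _read_bed(path)
    if format.lower() in {"gff-lite", "gff_lite", "gff"}:
        return _read_gff_lite(path)
    raise ValueError(f"unknown interval format {format!r}")


def _read_bed(path: str) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}: line {lineno}: BED needs >=3 columns")
            contig, start, end = cols[0], int(cols[1]), int(cols[2])
            label = cols[3] if len(cols) > 3 else ""
            strand = cols[5] if len(cols) > 5 else "."
            out.append(GenomicInterval(contig, start, end, strand, label))
    return out


def _read_gff_lite(path: str) -> list[GeneModel]:
    spans: dict[str, tuple[str, int, int, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: line {lineno}: GFF-lite needs 9 columns")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            if not attrs.startswith("gene_id="):
                raise FormatError(f"{path}: line {lineno}: missing gene_id attribute")
            gid = attrs[len("gene_id="):]
            start0, end0 = int(start) - 1, int(end)  # 1-based inclusive -> half-open
            if ftype == "gene":
                spans[gid] = (contig, start0, end0, strand)
                order.append(gid)
            elif ftype == "exon":
                exons.setdefault(gid, []).append((start0, end0))
            else:
                raise FormatError(f"{path}: line {lineno}: unknown feature type {ftype!r}")
    genes = []
    for gid in order:
        contig, s, e, strand = spans[gid]
        gene_exons = sorted(exons.get(gid, []))
        for es, ee in gene_exons:
            if es < s or ee > e:
                raise FormatError(f"exon outside gene span for gene {gid}")
        genes.append(
            GeneModel(
                gene_id=gid,
                span=GenomicInterval(contig, s, e, strand, gid),
                exons=[GenomicInterval(contig, es, ee, strand, gid) for es, ee in gene_exons],
                strand=strand,
            )
        )
    return genes


def write_bed(intervals: list[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.label}\t.\t{iv.strand}\n")


def write_gff_lite(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.contig}\tedconsensus\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t"
                f"{g.strand}\t.\tgene_id={g.gene_id}\n"
            )
            for exon in g.exons:
                fh.write(
                    f"{g.contig}\tedconsensus\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{g.strand}\t.\tgene_id={g.gene_id}\n"
                )


def read_variant_catalog(path: str, genome: GenomeRef | None = None,
                         source: str = "") -> KnownSnpCatalog:
    """Read SNVs from a VCF into a :class:`KnownSnpCatalog`.

    Multi-allelic records are split; records whose ref or alt allele is not a
    single base are skipped (count logged).  When a genome is supplied the
    reference allele of every kept record is checked against it.
    """
    entries: set[tuple[str, int, str, str]] = set()
    skipped = 0
    mismatches = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            pos0 = rec.pos - 1
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt == "*":
                    skipped += 1
                    continue
                if genome is not None and genome.base(rec.chrom, pos0) != rec.ref:
                    mismatches.append((rec.chrom, pos0, rec.ref))
                    continue
                entries.add((rec.chrom, pos0, rec.ref.upper(), alt.upper()))
    if mismatches:
        raise FormatError(
            f"{path}: REF allele mismatches vs genome at {mismatches[:10]}"
            + ("..." if len(mismatches) > 10 else "")
        )
    if skipped:
        log.info("%s: skipped %d non-SNV allele records", path, skipped)
    return KnownSnpCatalog(entries, source=source or path)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=EDLEV,Number=1,Type=Float,Description="Editing level (variant allele fraction)">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at site">
##INFO=<ID=AD,Number=R,Type=Integer,Description="Read counts for ref and alt alleles">
##INFO=<ID=METHODS,Number=.,Type=String,Description="Callers supporting the site">
##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Number of supporting replicates">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_editing_vcf(calls, path: str, contig_lengths: dict[str, int] | None = None) -> None:
    """Write editing calls as VCF 4.2.

    ``calls`` is an iterable of objects/dicts with contig, pos (0-based), ref,
    alt, editing level, depth, alt count, and the list of supporting callers.
    Calls are sorted by coordinate before writing.
    """
    rows = []
    for c in calls:
        get = c.get if isinstance(c, dict) else lambda k, _c=c: getattr(_c, k)
        rows.append(
            (
                get("contig"), get("pos"), get("ref"), get("alt"),
                float(get("editing_level")), int(get("depth")), int(get("alt_count")),
                list(get("methods")), int(get("support", 1) if isinstance(c, dict) else getattr(c, "support", 1)),
            )
        )
    if rows != sorted(rows, key=lambda r: (r[0], r[1])):
        log.info("write_editing_vcf: sorting %d unsorted calls", len(rows))
        rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        header = _VCF_HEADER
        if contig_lengths:
            contig_lines = "".join(
                f"##contig=<ID={name},length={length}>\n"
                for name, length in contig_lengths.items()
            )
            header = header.replace("#CHROM", contig_lines + "#CHROM", 1)
        fh.write(header)
        for contig, pos, ref, alt, lev, dp, ad, methods, supp in rows:
            info = (
                f"EDLEV={lev:.4f};DP={dp};AD={max(dp - ad, 0)},{ad};"
                f"METHODS={','.join(methods)};SUPP={supp}"
            )
            fh.write(f"{contig}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")
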