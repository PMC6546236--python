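"""From aligned reads to per-site observations and raw candidate variants.

PCR duplicates are collapsed first (locus-based definition: identical
position, strand and CIGAR), bases below a quality floor are masked, and
candidate variant sites are then nominated wherever enough reads disagree
with the reference.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .io_formats import AlignedRead, GenomeRef, SpliceJunctionSet

log = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}

#: minimum base quality for a base to enter the pileup
DEFAULT_MIN_BASE_QUALITY = 20


@dataclass
class SitePileup:
    """Summary of all read observations at one reference position."""

    contig: str
    pos: int
    ref: str
    counts_plus: dict[str, int]
    counts_minus: dict[str, int]
    junction_distance: float
    #: (read name, observed base) for every contributing read; populated for
    #: sites carrying at least one non-reference base (and for every site when
    #: the pileup is built in ``emit="covered"`` mode on small inputs).
    read_alleles: list[tuple[str, str]] | None = None

    @property
    def coverage(self) -> int:
        return sum(self.counts_plus.values()) + sum(self.counts_minus.values())

    def count(self, base: str) -> int:
        return self.counts_plus.get(base, 0) + self.counts_minus.get(base, 0)


@dataclass
class CandidateVariant:
    """An RNA-level mismatch site that met the coverage/alt-read floor."""

    contig: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    coverage: int
    alt_plus: int
    alt_minus: int
    ref_plus: int
    ref_minus: int
    junction_distance: float
    read_alleles: list[tuple[str, str]] | None = None
    in_simple_repeat: bool | None = None
    in_homopolymer: bool | None = None
    known_snp: bool | None = None
    provenance: list[tuple[str, bool]] = field(default_factory=list)

    @property
    def vaf(self) -> float:
        return self.alt_count / self.coverage

    @property
    def site(self) -> tuple[str, int]:
        return (self.contig, self.pos)

    def record(self, filter_name: str, passed: bool) -> None:
        self.provenance.append((filter_name, passed))

    def failed_filters(self) -> list[str]:
        return [name for name, ok in self.provenance if not ok]


def dedupe_reads(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Collapse PCR duplicates.

    Reads sharing (contig, leftmost position, strand, CIGAR) are considered
    duplicates of one fragment; the lexicographically smallest read name is
    kept as a deterministic tie-break.
    """
    best: dict[tuple, AlignedRead] = {}
    total = 0
    for read in reads:
        total += 1
        key = (read.contig, read.pos, read.strand, read.cigar)
        cur = best.get(key)
        if cur is None or read.name < cur.name:
            best[key] = read
    kept = sorted(best.values(), key=lambda r: (r.contig, r.pos, r.strand, r.cigar))
    if total:
        log.info("dedupe_reads: retained %d of %d reads", len(kept), total)
    return kept


def build_pileup(reads: Iterable[AlignedRead], genome: GenomeRef,
                 junctions: SpliceJunctionSet,
                 min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
                 emit: str = "covered") -> Iterator[SitePileup]:
    """Build per-site pileups from (deduplicated) reads.

    N CIGAR gaps contribute nothing; bases below ``min_base_quality`` are
    excluded.  ``emit="covered"`` yields every position with at least one
    surviving base (with full per-read allele lists — intended for small
    inputs); ``emit="mismatch"`` yields only positions carrying at least one
    non-reference base, which is all downstream candidate calling needs and
    stays cheap at genome scale.
    """
    if emit not in {"covered", "mismatch"}:
        raise ValueError(f"unknown emit mode {emit!r}")
    by_contig: dict[str, list[AlignedRead]] = {}
    for read in reads:
        if read.contig not in genome.sequences:
            raise ValueError(f"read {read.name}: unknown contig {read.contig}")
        end = read.pos + read.reference_span()
        if end > len(genome.sequences[read.contig]):
            raise ValueError(f"read {read.name} overruns end of {read.contig}")
        by_contig.setdefault(read.contig, []).append(read)

    junc = junctions.by_contig() if junctions is not None else {}

    for contig in sorted(by_contig):
        seq = genome.sequences[contig]
        L = len(seq)
        ref_arr = np.full(L, 4, dtype=np.int8)
        code = np.full(256, 4, dtype=np.int8)
        for b, i in _CODE.items():
            code[ord(b)] = i
        ref_arr[:] = code[np.frombuffer(seq.encode(), dtype=np.uint8)]

        counts = np.zeros((L, 4, 2), dtype=np.int32)
        creads = by_contig[contig]
        for read in creads:
            quals = np.asarray(read.quals)
            sidx = 0 if read.strand == "+" else 1
            for rs, re_, qoff in read.aligned_blocks():
                n = re_ - rs
                seg = read.bases[qoff:qoff + n]
                codes = code[np.frombuffer(seg.encode(), dtype=np.uint8)]
                mask = (quals[qoff:qoff + n] >= min_base_quality) & (codes < 4)
                if not mask.any():
                    continue
                positions = np.arange(rs, re_)[mask]
                np.add.at(counts, (positions, codes[mask], sidx), 1)

        total = counts.sum(axis=(1, 2))
        ref_count = np.zeros(L, dtype=np.int64)
        valid = ref_arr < 4
        ref_count[valid] = counts[np.arange(L)[valid], ref_arr[valid]].sum(axis=1)
        if emit == "covered":
            sites = np.flatnonzero(total > 0)
        else:
            sites = np.flatnonzero(total - ref_count > 0)
        site_set = set(int(p) for p in sites)

        alleles: dict[int, list[tuple[str, str]]] = {p: [] for p in site_set}
        if site_set:
            for read in creads:
                quals = read.quals
                for rs, re_, qoff in read.aligned_blocks():
                    for p in range(rs, re_):
                        if p in site_set and quals[qoff + p - rs] >= min_base_quality:
                            b = read.bases[qoff + p - rs]
                            if b in _CODE:
                                alleles[p].append((read.name, b))

        jpos = junc.get(contig, [])
        for p in sorted(site_set):
            jd = _nearest_distance(jpos, p)
            cp = {b: int(counts[p, i, 0]) for b, i in _CODE.items() if counts[p, i, 0]}
            cm = {b: int(counts[p, i, 1]) for b, i in _CODE.items() if counts[p, i, 1]}
            yield SitePileup(contig, p, seq[p], cp, cm, jd, alleles[p])


def _nearest_distance(sorted_positions: list[int], pos: int) -> float:
    if not sorted_positions:
        return float("inf")
    i = bisect.bisect_left(sorted_positions, pos)
    best = float("inf")
    if i < len(sorted_positions):
        best = min(best, abs(sorted_positions[i] - pos))
    if i > 0:
        best = min(best, abs(sorted_positions[i - 1] - pos))
    return best


def call_candidates(pileups: Iterable[SitePileup], min_cov: int = 5,
                    min_alt: int = 3) -> list[CandidateVariant]:
    """Nominate candidate variants from pileups.

    A site qualifies when total coverage >= ``min_cov`` and the most frequent
    non-reference base is seen in >= ``min_alt`` reads.  Tri-allelic sites
    keep only the majority alt (alphabetical tie-break).
    """
    out: list[CandidateVariant] = []
    for sp in pileups:
        if sp.ref not in _CODE:
            continue
        cov = sp.coverage
        if cov < min_cov:
            continue
        non_ref = [(sp.count(b), b) for b in BASES if b != sp.ref and sp.count(b) > 0]
        if not non_ref:
            continue
        non_ref.sort(key=lambda t: (-t[0], t[1]))
        alt_count, alt = non_ref[0]
        if alt_count < min_alt:
            continue
        out.append(
            CandidateVariant(
                contig=sp.contig,
                pos=sp.pos,
                ref=sp.ref,
                alt=alt,
                alt_count=alt_count,
                coverage=cov,
                alt_plus=sp.counts_plus.get(alt, 0),
                alt_minus=sp.counts_minus.get(alt, 0),
                ref_plus=sp.counts_plus.get(sp.ref, 0),
                ref_minus=sp.counts_minus.get(sp.ref, 0),
                junction_distance=sp.junction_distance,
                read_alleles=sp.read_alleles,
            )
        )
    return out
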