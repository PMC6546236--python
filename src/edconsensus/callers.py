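"""Three independent editing-calling strategies over a shared candidate list.

* ``hardfilter_call`` — a strict filtering cascade: drop known SNPs, simple
  repeats, homopolymer context, strand-biased sites, extreme variant allele
  fractions and junction-proximal sites; the survivors are the calls.
* ``mi_call`` — allelic-linkage scoring: a genomic variant co-segregates with
  nearby heterozygous SNPs on the same reads (high mutual information),
  whereas RNA editing strikes reads independently of haplotype (low MI).
  Candidates whose mean MI against known-SNP anchors falls below a low
  quantile of the SNP-SNP null distribution are called as editing.
* ``island_call`` — editing-island clustering: dense clusters of candidate
  sites (the signature of ADAR acting on double-stranded Alu regions) are
  called wholesale; isolated candidates must pass the full hard-filter
  cascade instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import AnnotationBundle, GenomeRef, GenomicInterval
from .pileup import CandidateVariant

log = logging.getLogger(__name__)


@dataclass
class FilterParams:
    """Thresholds of the filtering cascade and caller knobs."""

    min_cov: int = 5
    min_alt: int = 3
    homopolymer_len: int = 5
    vaf_low: float = 0.10
    vaf_high: float = 0.95
    junction_dist: int = 4
    strand_bias_alpha: float = 0.01
    min_base_quality: int = 20
    # MI caller
    mi_min_shared_reads: int = 5
    mi_null_quantile: float = 0.05
    mi_anchor_window: int = 2000
    mi_anchor_min_minor: int = 2
    # island caller
    island_gap: int = 50
    island_min_sites: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.vaf_low < self.vaf_high <= 1:
            raise ValueError("require 0 <= vaf_low < vaf_high <= 1")
        if self.homopolymer_len < 2 or self.junction_dist < 0:
            raise ValueError("invalid homopolymer_len or junction_dist")


@dataclass(frozen=True)
class Call:
    ref: str
    alt: str
    vaf: float
    alt_count: int
    coverage: int


@dataclass
class EditingCallSet:
    """Accepted editing sites from one caller on one replicate."""

    caller: str
    replicate: int
    calls: dict[tuple[str, int], Call] = field(default_factory=dict)

    def sites(self) -> set[tuple[str, int]]:
        return set(self.calls)

    def add(self, cand: CandidateVariant) -> None:
        self.calls[cand.site] = Call(cand.ref, cand.alt, cand.vaf,
                                     cand.alt_count, cand.coverage)

    def __len__(self) -> int:
        return len(self.calls)

    def __contains__(self, site: tuple[str, int]) -> bool:
        return site in self.calls


@dataclass
class EditingIsland:
    interval: GenomicInterval
    members: list[tuple[str, int]]

    @property
    def n_sites(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def site_in_homopolymer(genome: GenomeRef, site: tuple[str, int], L: int = 5) -> bool:
    """True iff the site lies within, or immediately adjacent to (+/- 1 bp),
    a maximal run of >= L identical reference bases."""
    contig, pos = site
    seq = genome.sequences[contig]
    if not 0 <= pos < len(seq):
        raise ValueError(f"site {pos} outside contig {contig}")
    for q in (pos - 1, pos, pos + 1):
        if not 0 <= q < len(seq):
            continue
        b = seq[q]
        lo = q
        while lo > 0 and seq[lo - 1] == b:
            lo -= 1
        hi = q
        while hi + 1 < len(seq) and seq[hi + 1] == b:
            hi += 1
        if hi - lo + 1 >= L:
            return True
    return False


def strand_bias_test(alt_plus: int, alt_minus: int,
                     cov_plus: int, cov_minus: int) -> float:
    """Two-sided Fisher exact p-value for alt vs ref reads split by strand."""
    if cov_plus + cov_minus == 0:
        raise ValueError("zero total coverage")
    ref_plus, ref_minus = cov_plus - alt_plus, cov_minus - alt_minus
    if min(ref_plus, ref_minus) < 0:
        raise ValueError("alt count exceeds coverage on a strand")
    _, p = stats.fisher_exact([[alt_plus, alt_minus], [ref_plus, ref_minus]],
                              alternative="two-sided")
    return float(p)


def _ensure_flags(cand: CandidateVariant, bundle: AnnotationBundle,
                  params: FilterParams) -> None:
    if cand.known_snp is None:
        cand.known_snp = cand.site in bundle.snp_catalog
    if cand.in_simple_repeat is None:
        cand.in_simple_repeat = bundle.simple_repeat_at(cand.contig, cand.pos)
    if cand.in_homopolymer is None:
        cand.in_homopolymer = site_in_homopolymer(bundle.genome, cand.site,
                                                  params.homopolymer_len)
    if cand.junction_distance is None or cand.junction_distance < 0:
        cand.junction_distance = bundle.junction_distance(cand.contig, cand.pos)


def filter_verdicts(cand: CandidateVariant, bundle: AnnotationBundle,
                    params: FilterParams,
                    order: Sequence[str] | None = None) -> list[tuple[str, bool]]:
    """Evaluate every cascade predicate on one candidate.

    Each filter is a pure predicate, so the surviving set does not depend on
    evaluation order; the order only shapes the provenance listing.
    """
    _ensure_flags(cand, bundle, params)
    sb_p = strand_bias_test(cand.alt_plus, cand.alt_minus,
                            cand.alt_plus + cand.ref_plus,
                            cand.alt_minus + cand.ref_minus)
    checks = {
        "known_snp": not cand.known_snp,
        "simple_repeat": not cand.in_simple_repeat,
        "homopolymer": not cand.in_homopolymer,
        "strand_bias": sb_p >= params.strand_bias_alpha,
        "vaf_band": params.vaf_low <= cand.vaf <= params.vaf_high,
        "junction": cand.junction_distance > params.junction_dist,
    }
    order = order or list(checks)
    return [(name, checks[name]) for name in order]


DEFAULT_FILTER_ORDER = ("known_snp", "simple_repeat", "homopolymer",
                        "strand_bias", "vaf_band", "junction")


def hardfilter_call(candidates: Sequence[CandidateVariant],
                    bundle: AnnotationBundle, params: FilterParams,
                    replicate: int = 0,
                    order: Sequence[str] = DEFAULT_FILTER_ORDER) -> EditingCallSet:
    """Strict filtering cascade; survivors become editing calls.

    Every verdict is recorded in the candidate's provenance, so rejected
    candidates name the filter(s) responsible.
    """
    if bundle.snp_catalog is None:
        raise ValueError("hardfilter_call requires a known-SNP catalog")
    out = EditingCallSet("hardfilter", replicate)
    for cand in candidates:
        verdicts = filter_verdicts(cand, bundle, params, order)
        for name, ok in verdicts:
            cand.record(name, ok)
        if all(ok for _, ok in verdicts):
            out.add(cand)
    return out


# ---------------------------------------------------------------------------
# mutual-information caller
# ---------------------------------------------------------------------------

def mi_score(alleles_x: Mapping[str, int], alleles_y: Mapping[str, int],
             min_shared: int = 5) -> float | None:
    """Plug-in mutual information (bits) between two sites' read alleles.

    Inputs map read name -> binarized allele (0 = ref, 1 = alt).  Returns
    ``None`` when fewer than ``min_shared`` reads cover both sites.
    """
    shared = alleles_x.keys() & alleles_y.keys()
    if len(shared) < min_shared:
        return None
    n = np.zeros((2, 2))
    for r in shared:
        n[alleles_x[r], alleles_y[r]] += 1
    N = n.sum()
    p = n / N
    px, py = p.sum(axis=1), p.sum(axis=0)
    mi = 0.0
    for i in (0, 1):
        for j in (0, 1):
            if p[i, j] > 0:
                mi += p[i, j] * math.log2(p[i, j] / (px[i] * py[j]))
    return max(mi, 0.0)


def binarize_alleles(cand_or_site) -> dict[str, int]:
    """Read-name -> {0 ref, 1 alt} map from a candidate's per-read alleles."""
    out = {}
    for name, base in cand_or_site.read_alleles or []:
        if base == cand_or_site.ref:
            out[name] = 0
        elif base == cand_or_site.alt:
            out[name] = 1
    return out


def mi_call(candidates: Sequence[CandidateVariant], catalog,
            params: FilterParams, replicate: int = 0) -> EditingCallSet:
    """Call editing by allelic linkage against known-SNP anchors.

    Anchors are candidates at known-SNP positions with both alleles
    observed.  The null MI distribution comes from anchor-anchor pairs; a
    candidate is called editing when its mean MI against pairable anchors
    falls below the ``mi_null_quantile`` of that null.  Candidates with no
    pairable anchor (or an empty null) fall back to the variant-allele-
    fraction band of the hard filter.
    """
    out = EditingCallSet("mi", replicate)
    anchors = [
        c for c in candidates
        if c.site in catalog and c.read_alleles
        and min(c.alt_count, c.coverage - c.alt_count) >= params.mi_anchor_min_minor
    ]
    if not anchors:
        log.warning("mi_call: no usable known-SNP anchors; "
                    "all candidates routed to VAF fallback")
    anchor_alleles = [binarize_alleles(a) for a in anchors]
    anchor_pos = [(a.contig, a.pos) for a in anchors]

    null: list[float] = []
    for i in range(len(anchors)):
        for j in range(i + 1, len(anchors)):
            if anchor_pos[i][0] != anchor_pos[j][0]:
                continue
            if abs(anchor_pos[i][1] - anchor_pos[j][1]) > params.mi_anchor_window:
                continue
            mi = mi_score(anchor_alleles[i], anchor_alleles[j],
                          params.mi_min_shared_reads)
            if mi is not None:
                null.append(mi)
    threshold = (float(np.quantile(null, params.mi_null_quantile))
                 if null else None)

    for cand in candidates:
        cand_alleles = binarize_alleles(cand)
        scores: list[float] = []
        if threshold is not None:
            for k, anchor in enumerate(anchors):
                if anchor.contig != cand.contig or anchor.site == cand.site:
                    continue
                if abs(anchor.pos - cand.pos) > params.mi_anchor_window:
                    continue
                mi = mi_score(cand_alleles, anchor_alleles[k],
                              params.mi_min_shared_reads)
                if mi is not None:
                    scores.append(mi)
        if scores:
            called = float(np.mean(scores)) < threshold
        else:
            called = params.vaf_low <= cand.vaf <= params.vaf_high
        if called:
            out.add(cand)
    return out


# ---------------------------------------------------------------------------
# island caller
# ---------------------------------------------------------------------------

def island_call(candidates: Sequence[CandidateVariant],
                bundle: AnnotationBundle, params: FilterParams,
                replicate: int = 0) -> tuple[EditingCallSet, list[EditingIsland]]:
    """Cluster candidates into editing islands; call island members wholesale.

    Known-SNP candidates are excluded first.  Single-linkage clustering with
    inter-site gap <= ``island_gap``; clusters of >= ``island_min_sites``
    become islands whose members are all called.  Isolated candidates are
    called only if they pass the full hard-filter cascade.
    """
    out = EditingCallSet("island", replicate)
    islands: list[EditingIsland] = []
    eligible = []
    for cand in candidates:
        if cand.known_snp is None:
            cand.known_snp = cand.site in bundle.snp_catalog
        if not cand.known_snp:
            eligible.append(cand)
    by_contig: dict[str, list[CandidateVariant]] = {}
    for cand in eligible:
        by_contig.setdefault(cand.contig, []).append(cand)

    for contig in sorted(by_contig):
        cands = sorted(by_contig[contig], key=lambda c: c.pos)
        cluster: list[CandidateVariant] = []
        for cand in cands:
            if cluster and cand.pos - cluster[-1].pos > params.island_gap:
                _flush_cluster(cluster, bundle, params, out, islands)
                cluster = []
            cluster.append(cand)
        if cluster:
            _flush_cluster(cluster, bundle, params, out, islands)
    return out, islands


def _flush_cluster(cluster, bundle, params, out, islands) -> None:
    if len(cluster) >= params.island_min_sites:
        for cand in cluster:
            out.add(cand)
        islands.append(EditingIsland(
            GenomicInterval(cluster[0].contig, cluster[0].pos,
                            cluster[-1].pos + 1, ".", "island"),
            [c.site for c in cluster]))
    else:
        for cand in cluster:
            verdicts = filter_verdicts(cand, bundle, params)
            if all(ok for _, ok in verdicts):
                out.add(cand)
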