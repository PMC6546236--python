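"""Region classification, edited-gene assignment, cell-line-specific
partitions and per-gene genomic-SNV counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .consensus import ConsensusEditingSet
from .io_formats import GeneModel, GenomicInterval, KnownSnpCatalog


@dataclass(frozen=True)
class RegionClass:
    alu_flag: str    # "Alu" | "nonAlu"
    locus_flag: str  # "genebody" | "intergenic"


def _build_trees(intervals: Sequence[GenomicInterval],
                 label: str | None = None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        if label is not None and iv.label != label:
            continue
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _gene_trees(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.contig, IntervalTree()).addi(g.span.start, g.span.end, g)
    return trees


def classify_region(site: tuple[str, int],
                    repeat_track: Sequence[GenomicInterval],
                    gene_models: Sequence[GeneModel]) -> RegionClass:
    """Alu iff the site overlaps an Alu-labelled repeat interval; genebody
    iff it lies within any gene span (either strand); otherwise intergenic."""
    contig, pos = site
    alu = any(iv.label == "Alu" and iv.contains(pos)
              for iv in repeat_track if iv.contig == contig)
    genic = any(g.contig == contig and g.span.contains(pos) for g in gene_models)
    return RegionClass("Alu" if alu else "nonAlu",
                       "genebody" if genic else "intergenic")


def region_table(cset: ConsensusEditingSet,
                 repeat_track: Sequence[GenomicInterval],
                 gene_models: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-site region classes for one cell line (indexed fast version)."""
    alu_trees = _build_trees(repeat_track, "Alu")
    gtrees = _gene_trees(gene_models)
    rows = []
    for (contig, pos), site in sorted(cset.sites.items()):
        alu = bool(alu_trees.get(contig) and alu_trees[contig][pos])
        genic = bool(gtrees.get(contig) and gtrees[contig][pos])
        rows.append((contig, pos, site.ref, site.alt, site.strand,
                     "Alu" if alu else "nonAlu",
                     "genebody" if genic else "intergenic"))
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "strand",
                                       "alu_class", "locus_class"])


def assign_genes(cset: ConsensusEditingSet,
                 gene_models: Sequence[GeneModel]) -> pd.DataFrame:
    """Interval-join of consensus sites onto gene spans.

    A gene is "edited" when at least one consensus site overlaps its span;
    a site falling in the overlap of two genes counts for both.  Returns one
    row per edited gene with its site count.
    """
    gtrees = _gene_trees(gene_models)
    counts: dict[str, int] = {}
    for (contig, pos) in cset.sites:
        tree = gtrees.get(contig)
        if not tree:
            continue
        for hit in tree[pos]:
            gid = hit.data.gene_id
            counts[gid] = counts.get(gid, 0) + 1
    df = pd.DataFrame(sorted(counts.items()), columns=["gene_id", "edited_sites"])
    return df


@dataclass
class SpecificityResult:
    """Per-cell-line specific sites/genes and the full Venn partition."""

    specific_sites: dict[str, set[tuple[str, int]]]
    specific_genes: dict[str, set[str]]
    venn_counts: dict[tuple[str, ...], int]
    union_size: int


def specific_sites(consensus_sets: Mapping[str, ConsensusEditingSet],
                   gene_models: Sequence[GeneModel] | None = None
                   ) -> SpecificityResult:
    """Partition sites by the exact combination of cell lines carrying them.

    A line-specific site is present in that line and absent from all others;
    a line-specific gene is a gene containing at least one such site.  Venn
    region counts over all line combinations sum to the union size.
    """
    if len(consensus_sets) < 2:
        raise ValueError("need >=2 cell lines to compute specific sites")
    lines = sorted(consensus_sets)
    membership: dict[tuple[str, int], tuple[str, ...]] = {}
    for key in set().union(*(consensus_sets[l].site_keys() for l in lines)):
        present = tuple(l for l in lines if key in consensus_sets[l])
        membership[key] = present
    venn: dict[tuple[str, ...], int] = {}
    for r in range(1, len(lines) + 1):
        for combo in combinations(lines, r):
            venn[combo] = 0
    for present in membership.values():
        venn[present] += 1
    specific = {
        line: {k for k, present in membership.items() if present == (line,)}
        for line in lines
    }
    specific_genes: dict[str, set[str]] = {line: set() for line in lines}
    if gene_models is not None:
        gtrees = _gene_trees(gene_models)
        for line in lines:
            for contig, pos in specific[line]:
                tree = gtrees.get(contig)
                if tree:
                    specific_genes[line] |= {h.data.gene_id for h in tree[pos]}
    return SpecificityResult(specific, specific_genes, venn, len(membership))


def gene_by_id(gene_models: Sequence[GeneModel], gene_id: str) -> GeneModel:
    for g in gene_models:
        if g.gene_id == gene_id:
            return g
    raise KeyError(f"gene_id {gene_id!r} not found in gene models")


def count_snvs_per_gene(snv_catalog: KnownSnpCatalog, gene_model: GeneModel,
                        known_catalog: KnownSnpCatalog | None = None
                        ) -> tuple[int, int, int]:
    """(span_count, exon_count, novel_count) of genomic SNVs in one gene.

    ``novel_count`` is the number of span SNVs absent from ``known_catalog``
    (0 when no known catalog is supplied).  Half-open interval convention: an
    SNV exactly at an exon start is inside the exon; one at the exon end is
    not.
    """
    span = gene_model.span
    in_span = [
        (c, p, r, a) for (c, p, r, a) in snv_catalog.entries
        if c == gene_model.contig and span.start <= p < span.end
    ]
    exon_count = sum(
        1 for (_, p, _, _) in in_span
        if any(e.start <= p < e.end for e in gene_model.exons)
    )
    if known_catalog is not None:
        novel = sum(1 for (c, p, _, _) in in_span
                    if (c, p) not in known_catalog.positions)
    else:
        novel = 0
    return len(in_span), exon_count, novel
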