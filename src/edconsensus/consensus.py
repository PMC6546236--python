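"""Set algebra combining callers and replicates into per-cell-line
A-to-I editing sets.

Per replicate, only sites detected by all three callers are kept (consensus
trades sensitivity for precision); per cell line, the replicate consensus
sets are unioned; finally only canonical A-to-I changes survive — A>G on the
plus strand, T>C where the site falls in a minus-strand gene (inosine pairs
as guanosine, so editing always reads as A>G on the edited strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .callers import Call, EditingCallSet
from .io_formats import GeneModel


@dataclass(frozen=True)
class ConsensusSite:
    ref: str            # plus-strand reference base
    alt: str            # plus-strand variant base
    strand: str         # resolved gene strand, '.' when intergenic
    replicates: tuple[int, ...]
    mean_level: float
    depth: int = 0
    alt_count: int = 0


@dataclass
class ConsensusEditingSet:
    """Per-cell-line editing sites supported by all callers in >=1 replicate."""

    cell_line: str
    sites: dict[tuple[str, int], ConsensusSite] = field(default_factory=dict)

    def site_keys(self) -> set[tuple[str, int]]:
        return set(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.sites


def intersect_methods(set_hard: EditingCallSet, set_mi: EditingCallSet,
                      set_island: EditingCallSet) -> EditingCallSet:
    """Per-replicate intersection of the three callers' site sets.

    The hard-filter caller is the canonical source of the per-site VAF (it
    alone guarantees the coverage/alt-read floors on the reported counts).
    """
    reps = {set_hard.replicate, set_mi.replicate, set_island.replicate}
    if len(reps) != 1:
        raise ValueError(f"call sets come from different replicates: {sorted(reps)}")
    keys = set_hard.sites() & set_mi.sites() & set_island.sites()
    out = EditingCallSet("consensus", set_hard.replicate)
    for key in keys:
        out.calls[key] = set_hard.calls[key]
    return out


def combine_replicates(per_replicate_sets: Sequence[EditingCallSet],
                       cell_line: str = "",
                       min_replicate_support: int = 1) -> ConsensusEditingSet:
    """Union of per-replicate consensus sets for one cell line.

    Records which replicates support each site and the mean editing level
    (VAF) across supporting replicates.  Sites supported by fewer than
    ``min_replicate_support`` replicates are dropped.
    """
    if not per_replicate_sets:
        raise ValueError("need at least one replicate set")
    support: dict[tuple[str, int], list[tuple[int, Call]]] = {}
    for cs in per_replicate_sets:
        for key, call in cs.calls.items():
            support.setdefault(key, []).append((cs.replicate, call))
    out = ConsensusEditingSet(cell_line)
    for key in sorted(support):
        entries = support[key]
        if len(entries) < min_replicate_support:
            continue
        reps = tuple(sorted(r for r, _ in entries))
        mean_level = sum(c.vaf for _, c in entries) / len(entries)
        first = entries[0][1]
        out.sites[key] = ConsensusSite(first.ref, first.alt, ".", reps,
                                       mean_level, first.coverage, first.alt_count)
    return out


def restrict_a_to_i(cset: ConsensusEditingSet,
                    gene_models: Sequence[GeneModel]) -> ConsensusEditingSet:
    """Keep only canonical A-to-I changes after strand resolution.

    Genic sites take the strand of the overlapping gene model: A>G on a
    plus-strand gene, or T>C (the plus-strand image of A>G) on a minus-strand
    gene.  Intergenic sites have no strand; either plus-strand A>G or T>C is
    accepted and reported with strand '.'.
    """
    by_contig: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_contig.setdefault(g.contig, []).append(g)

    out = ConsensusEditingSet(cset.cell_line)
    for (contig, pos), site in cset.sites.items():
        strands = {
            g.strand for g in by_contig.get(contig, [])
            if g.span.start <= pos < g.span.end
        }
        keep, strand = False, "."
        if (site.ref, site.alt) == ("A", "G"):
            if "+" in strands:
                keep, strand = True, "+"
            elif not strands:
                keep = True
        elif (site.ref, site.alt) == ("T", "C"):
            if "-" in strands:
                keep, strand = True, "-"
            elif not strands:
                keep = True
        if keep:
            out.sites[(contig, pos)] = ConsensusSite(
                site.ref, site.alt, strand, site.replicates, site.mean_level,
                site.depth, site.alt_count)
    return out


def consensus_to_vcf_rows(cset: ConsensusEditingSet):
    """Rows for :func:`edconsensus.io_formats.write_editing_vcf`."""
    rows = []
    for (contig, pos), site in sorted(cset.sites.items()):
        rows.append({
            "contig": contig, "pos": pos, "ref": site.ref, "alt": site.alt,
            "editing_level": site.mean_level, "depth": site.depth,
            "alt_count": site.alt_count,
            "methods": ["hardfilter", "mi", "island"],
            "support": len(site.replicates),
        })
    return rows
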