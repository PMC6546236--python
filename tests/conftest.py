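import textwrap

import pytest

from edconsensus.io_formats import (AnnotationBundle, GeneModel, GenomeRef,
                                    GenomicInterval, KnownSnpCatalog,
                                    SpliceJunctionSet)


def write(path, content: str) -> str:
    path.write_text(textwrap.dedent(content))
    return str(path)


@pytest.fixture
def sam_factory(tmp_path):
    """Write a SAM file from header contigs and raw record lines."""

    def _make(records, contigs={"c1": 1000}, name="reads.sam"):
        lines = ["@HD\tVN:1.6\tSO:unsorted"]
        lines += [f"@SQ\tSN:{c}\tLN:{n}" for c, n in contigs.items()]
        lines += records
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n")
        return str(p)

    return _make


def sam_record(name="r1", flag=0, contig="c1", pos1=1, cigar="4M",
               seq="ACGT", qual=None, mapq=60):
    qual = qual if qual is not None else "I" * len(seq)
    return (f"{name}\t{flag}\t{contig}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0"
            f"\t{seq}\t{qual}")


@pytest.fixture
def toy_bundle():
    """Hand-crafted annotation bundle exercising every filter context.

    Layout on a 400 bp contig (0-based):
      - gene G1 [100,220) on '+', exons [100,140) and [180,220)
        -> splice junctions at 140 and 180
      - simple repeat [240,260)
      - homopolymer AAAAAA at [300,306) (written into the sequence)
      - known SNP at 350
    """
    # alternating background: no homopolymer runs except the planted one
    seq = ["CG"[i % 2] for i in range(400)]
    for i in range(300, 306):
        seq[i] = "A"
    # reference A's at positions used for candidates
    for p in (10, 20, 30, 40, 50, 60, 137, 250, 350, 70, 340, 342, 344,
              346, 348, 352, 354, 356, 358, 360, 242, 248, 254):
        if not 300 <= p < 306:
            seq[p] = "A"
    genome = GenomeRef({"c1": "".join(seq)})
    gene = GeneModel(
        "G1",
        GenomicInterval("c1", 100, 220, "+", "G1"),
        [GenomicInterval("c1", 100, 140, "+", "G1"),
         GenomicInterval("c1", 180, 220, "+", "G1")],
        "+",
    )
    repeats = [
        GenomicInterval("c1", 240, 260, ".", "simple_repeat"),
    ]
    junctions = SpliceJunctionSet.from_gene_models([gene])
    catalog = KnownSnpCatalog({("c1", 350, "A", "G")})
    return AnnotationBundle(genome, [gene], repeats, junctions, catalog)
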