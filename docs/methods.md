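# Methods

## Overview

`edconsensus` identifies A-to-I RNA-editing sites from aligned RNA-seq
reads by requiring agreement between three calling strategies with
unrelated failure modes, then interprets the resulting site sets
(annotation, edited genes, cell-line specificity, DEG enrichment). This
note records the model behind each stage, the parameters that matter, what
the synthetic-data generator does and does not emulate, and the design
choices made where the design was genuinely open.

## Candidate nomination

Reads are parsed from SAM (mapped primary records only; CIGAR restricted to
M/N/S/=/X — the pipeline does not model indels). PCR duplicates are
collapsed by mapping identity — (contig, leftmost position, strand, CIGAR) —
keeping the lexicographically smallest read name as a deterministic
tie-break. Pileups count bases with quality ≥ Q20 (a fixed floor standing
in for full base-quality recalibration, which is out of scope;
configurable). A site becomes a candidate when total coverage ≥ 5 and the
most frequent non-reference base is seen in ≥ 3 reads; tri-allelic sites
keep only the majority alternative allele (alphabetical tie-break). These
floors are applied uniformly upstream of all three callers.

## The three callers

**Hard-filter cascade.** Six pure predicates, each recorded in the
candidate's provenance: known-SNP membership; simple-repeat overlap
(annotation track, no de-novo repeat finding); homopolymer context — the
site lies within or immediately adjacent (±1 bp) to a maximal run of ≥ 5
identical reference bases; strand bias — two-sided Fisher exact test on
[[alt⁺, alt⁻], [ref⁺, ref⁻]] with rejection at p < 0.01 (the standard
FisherStrand-style quantification of "substantially biased"); variant
allele fraction outside [0.10, 0.95], bounds inclusive-pass (the exclusion
is of *strictly* more extreme values); distance ≤ 4 nt to a known splice
junction (junction = internal exon boundary of a gene model). Because each
predicate is pure, the surviving set is invariant to evaluation order; the
order only shapes provenance listings.

**Mutual-information linkage.** Per-read alleles at two sites, binarized to
ref/alt, give a 2×2 joint count over shared reads; the plug-in MI
I(X;Y) = Σ p(x,y) log₂ p(x,y)/(p(x)p(y)) (0·log 0 = 0) is computed when ≥ 5
reads cover both sites. Anchors are candidates at known-SNP positions with
minor-allele count ≥ 2 (a homozygous site carries no linkage information).
The null distribution is MI over anchor–anchor pairs within a 2 kb window;
a candidate is called editing when its mean MI against pairable anchors
falls below the empirical 5% quantile of that null. Candidates with no
pairable anchor fall back to the VAF band. The published MI-based caller
couples MI to a trained classifier whose details are not reproducible from
its description; the empirical-quantile rule implements the stated
principle (haplotype linkage separates genomic variants from editing) with
an explicit, auditable threshold.

**Editing islands.** Known-SNP candidates are removed, the rest are
single-linkage clustered per contig with inter-site gap ≤ 50 bp, and
clusters of ≥ 3 sites are called wholesale as islands — the signature of
ADAR acting processively on double-stranded Alu RNA. Isolated candidates
are called only if they pass the full hard-filter cascade. The gap and
minimum-size parameters are package defaults (exposed in `FilterParams`);
the island concept fixes neither, and recovery is insensitive to the exact
values at the simulated island geometry (sites a few bp apart inside
~300 bp repeats).

## Consensus set algebra

Per replicate, the three call sets are intersected by site key; the
hard-filter caller is the canonical VAF source since it alone guarantees
the count floors behind the reported fractions. Per cell line, replicate
intersections are **unioned** (supporting replicates recorded; mean editing
level across them); a minimum replicate support is configurable and
defaults to 1. Finally only canonical A-to-I changes survive strand
resolution: A>G within plus-strand genes, T>C within minus-strand genes
(the plus-strand image of A>G), and either orientation — reported
unstranded — for intergenic sites, where no gene model fixes the template.

## Annotation and enrichment

Region classes are total functions: Alu iff the site overlaps an
Alu-labelled repeat interval; gene body iff it falls in any gene span
(either strand, introns included — configurable to exon-only). A gene is
edited when ≥ 1 consensus site overlaps its span; sites in gene overlaps
count for every overlapping gene (interval-join semantics). Cell-line-
specific sites are those present in exactly one line; Venn-region counts
partition the union exactly.

Genomic SNVs from a DNA-seq VCF are counted per gene over the span, over
exons (half-open convention: a variant at an exon start is inside), and as
"novel" when absent from the known catalog.

The DEG stand-in is Welch's t-test on log₂(x+1) per gene across replicates,
Benjamini–Hochberg across genes, DEG iff adjusted p ≤ 0.05 and |log₂ FC| ≥ 1.
It is deliberately minimal — the scientific question downstream is the
enrichment one — and an externally computed DEG list is accepted equally.
Enrichment of DEGs among edited genes uses the exact hypergeometric upper
tail P(X ≥ k) (scipy's log-space implementation, verified against subset
enumeration to 1e-12 in the test suite). The universe is genes with nonzero
mean expression in ≥ 1 line (conservative; configurable), and all tested
sets are intersected with it.

## The synthetic study generator

The generator emulates the statistical structure the analysis assumes, at
desk scale: multiple cell lines × 3 replicates over one shared genome;
editing clustered in Alu-like repeats plus isolated sites; genomic SNPs as
confounders; an ADAR-activity scalar per line; and an expression matrix
whose DEG labels are enriched among edited genes.

* **Genome** (default one 200 kb contig): uniform random sequence with 40
  non-overlapping 3-exon genes (250 bp exons, 500 bp introns, random
  strand), 40 copies of a single random 300 bp Alu-like consensus (each
  mutated 5–15%, half inserted reverse-complemented, placed outside exons),
  10 dinucleotide simple-repeat tracts and 12 homopolymer runs of 6–10 nt.
* **Variants**: 150 SNPs placed uniformly (67% heterozygous, phased onto
  one of two haplotypes; the rest hom-alt); 20 editing islands of 3–6 sites
  inside distinct Alus plus 100 isolated sites elsewhere, all at reference
  A on the local gene strand (T on the plus strand inside minus-strand
  genes). Editing sites are planted only in recoverable contexts — outside
  simple repeats, homopolymer runs and the 4 nt junction windows — so
  recovery scores measure the callers rather than the artifact filters,
  which are exercised by the SNP confounders and dedicated fixtures.
  Per-site editing levels are Beta(2, 5) draws truncated at ≥ 0.2 (mass in
  the 20–50% range where detection is nontrivial), multiplied by the line's
  ADAR activity (default 1.0 / 0.7 / 0.45, a declining-activity series);
  20% of isolated sites are private to one line. Island sites are shared
  across lines, reflecting the conservation of Alu editing; at toy island
  sizes per-line private island sites would mostly measure cluster-size
  attrition rather than calling behaviour.
* **Reads**: single-end 100 bp, pre-aligned at their true origin (alignment
  is out of scope; a position-jitter option is deliberately absent from the
  default design), drawn uniformly over the genome plus 10% spliced
  transcript reads carrying N CIGAR ops; each read samples a haplotype,
  het SNP alleles follow phase, editing converts the base independently per
  read with probability equal to the site's level, errors strike each base
  at 1e-3, 5% of reads are re-emitted verbatim as PCR duplicates. The
  known-SNP catalog VCF contains 95% of planted SNPs, modelling catalog
  incompleteness; the DNA-seq VCF contains them all.
* **Expression**: per-gene log-normal means (log₂ mean 5, sd 1.5), DEG
  genes shifted 4-fold between line 1 and the others in a random direction,
  multiplicative log-normal replicate noise (sd 0.15 log₂ units). DEG
  labels satisfy P(DEG | edited) = 4 × P(DEG | not edited) by default.

All randomness flows through numpy `SeedSequence` spawn keys derived from
one seed, so every artifact is byte-identical across runs — the test suite
asserts this at file level.

**What the simulator does not emulate** — and hence what passing recovery
tests do not show about real data: mapping ambiguity and misalignment
(reads are placed at their true origin), indels and structural variation,
realistic base-quality distributions, coverage non-uniformity from
expression levels (reads are uniform over the genome rather than
transcript-weighted), hyper-edited reads that fail alignment, and
hg19-scale repeat content. Recovery numbers are therefore upper bounds on
real-data performance; the pipeline's robustness to those effects rests on
the filters, not on these tests.

## Problem sizes and numerical choices

The default study design (200 kb, 30×, 3 replicates) keeps a full
three-line analysis under a minute on one CPU while every stage operates in
the regime it is designed for (hundreds of candidates, dozens of anchors
and islands). The test suite runs its end-to-end recovery fixture at two
cell lines and the enrichment behaviour at 500 genes on an 800 kb contig —
the gene count, not the read depth, powers the hypergeometric test, so that
study omits read simulation entirely.

Degenerate inputs are handled explicitly: empty call sets intersect and
union to empty; an empty known-SNP catalog routes all MI candidates to the
VAF fallback with a warning; zero coverage in the strand-bias test, a
single-replicate line in the DEG test, and an empty edited-gene set in the
enrichment test raise errors rather than returning numbers. Precision on an
empty call set is reported as NA. Ties are broken deterministically
everywhere (read names in dedup, alphabetical alt alleles, sorted outputs),
and floats are written with fixed formats so identical runs produce
identical bytes.

## Known limitations

* The MI caller needs heterozygous anchors within read distance; in
  anchor-poor regions it degenerates to the VAF band and adds little
  specificity beyond the cascade.
* Island calling at toy scale uses small clusters (3–6 sites); real Alu
  islands are larger, so the min-sites floor matters less in practice than
  here.
* The A-to-I restriction cannot orient intergenic sites; plus-strand T>C
  intergenic calls are accepted as A-to-I without strand evidence.
* The DEG stand-in ignores count noise models (negative binomial) and
  isoform structure; it is a labelled placeholder for any external DE
  engine.
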