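# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind mitokit's four analysis stages and its synthetic-data
generators.

## Coordinates and sequence model

All public coordinates are 1-based inclusive, matching mitogenome annotation
tables and GFF3. Genomes are circular molecules, and the topology flag is
stored, but sequence indexing never wraps the replication origin: no
annotated feature in the target genomes spans the junction, so
origin-spanning features and origin-wrapping SSR scans are rejected rather
than silently handled. Sequences are DNA over {A,C,G,T,N}; N is "missing"
everywhere (excluded from GC numerators, barred from repeats, ignored in
consensus building and distances).

GC content is `100·(G+C)/length` with N counted in the denominator only.
Translation uses the mold/protozoan mitochondrial code (NCBI transl_table 4;
TGA → Trp), the code of fungal mitochondria; it is a per-run parameter, and
codons containing N translate to X. The codon table itself is taken from
Biopython; the translation and codon-effect logic is local.

## SSR scanner

A repeat is reported when it is **perfect** (exact copies), **maximal**
(extendable by no base on either side at its period), **left-anchored**
(the start is the first base of the first full copy; the reported span
covers whole copies only, with any trailing partial copy recorded
separately), and **primitive-united** (`ATAT × k` is re-expressed as
`AT × 2k`). The scan is a single pass per unit length u = 1…10 over the
self-comparison `seq[j] == seq[j+u]`, O(10·n) overall.

Classification follows the three-tier organelle-SSR scheme: units 1–6 bp
are normal SSRs when the run totals ≥ 10 bp, except penta/hexa units at
exactly 2 copies, which form the potential tier; units 7–10 bp at ≥ 2
copies are extended SSRs. Two conventions deserve note:

- The 10 bp total-length threshold is applied as **≥ 10**, not > 10:
  published catalogs of these genomes contain 10-bp records (T×10,
  five-copy dinucleotides), so ≥ is the behavior consistent with practice.
  The threshold is configurable (`SSRConfig.min_total_length_normal`).
- The unit is reported in its **first observed phase** (leftmost), with no
  rotational or lexicographic canonicalization: catalogs list both `TA` and
  `AT` units, and we preserve that.

Overlap and nesting among accepted records are resolved deterministically:
a record wholly contained in another accepted record's span is suppressed,
and remaining conflicts are settled greedily by longer total length, then
smaller unit length, then leftmost start. Surviving records are mutually
non-overlapping, which makes counts reproducible from the record list. Ids
are assigned per unit-length prefix in start order (`M`, `D`, `T`, `Te`,
`P`, `H`, `cHp`, `O`, and by extension `N`, `De`), zero-padded to seven
digits, mirroring published catalog naming.

## Positional classification

Overlap is **any-overlap**: one shared base attributes an interval to a
gene (published catalogs attribute an SSR overlapping a gene's final base
to that gene). Classes in precedence order: genic (≥ 1 exon base of a
top-level feature), intronic ORF (overlap with a CDS nested in another
gene's intron — typically a LAGLIDADG homing endonuclease), intronic,
intergenic. tRNA and rRNA features count as genic. Nesting is taken from
the explicit `nested_in` annotation field when present; otherwise a CDS
whose span lies inside another feature's span but outside that feature's
exons is inferred nested. Published gene tables for these genomes give exon
*counts* but not exon *coordinates*; without exon detail the classifier
degrades to a two-class genic/intergenic mode (gene spans act as exonic)
and marks results `approximate=True` rather than guessing intron
structure.

## Variant caller

The reference for polarity is the per-column **majority consensus**; ties
break toward a designated reference strain (default: the first row), then
alphabetically. This matches the convention of alignment-viewer variant
tables in which an insertion carried by a minority of strains is reported
as `- to CC` against the gapped consensus. Per column:

- gap-free polymorphic columns yield one SNP event per distinct minority
  allele (multi-allelic columns produce several events);
- maximal runs of columns with the same polymorphic gap pattern and carrier
  set merge into a single insertion or deletion event; two adjacent indel
  events therefore always differ in type or carriers.

Summary coverage percentages use alignment columns as the denominator:
`snp_coverage = 100·n_SNPs/aligned_length`, and the INDEL count in the
summary is the number of gap-bearing polymorphic **columns** (a 10-column
insertion counts 10), which is the column-like quantity whose ratios match
published species-panel tables; the event count is reported alongside
(`n_indel_events`). Values are kept at full precision and rounded only in
report writers.

Effect annotation maps alignment columns to reference coordinates by
skipping reference gaps, classifies the site positionally, and for a SNP in
a CDS recomputes the affected codon in transcript orientation (reverse-
strand alleles complemented) under transl_table 4, reporting
`X to Y in <gene>` or `synonymous in <gene>`. Aligning itself is out of
scope: the input contract is an externally computed aligned multi-FASTA.

## Phylogeny

Supermatrices are column-wise concatenations of per-gene alignment blocks
with gap padding for taxa missing from a block and an explicit partition
table; slicing a partition returns the original block. The default
conserved-gene set is ATP8, COX2, NAD2, NAD3, NAD4L — the genes reliably
annotated across Ophiocordycipitaceae mitogenomes — and is a runtime
parameter (gene symbols are normalized, e.g. CO2 → COX2, before lookup; a
taxon lacking a gene is dropped from that block only, with a warning).

Distances are p-distances by default, with JC69 as an option; the source
workflow used a GUI package's defaults and never stated the NJ distance
model, so the simplest model is the default and both are exposed. Gap/N
sites are excluded pairwise (complete deletion available); a pair with zero
comparable sites is an error, and JC69 is an error at p ≥ 0.75.

Neighbor joining is the canonical Saitou–Nei agglomeration on the
Q-criterion, with ties broken by the smallest index pair (deterministic),
negative branch lengths clamped to zero, and an unrooted trifurcation at
the last join (two taxa: each leaf gets d/2). Bootstrap resamples columns
with replacement using a seeded generator; support on each internal edge of
the full-data tree is the percentage of replicate trees containing the same
bipartition, so a fixed seed reproduces supports bit-for-bit. Monophyly is
judged on the unrooted tree relative to an outgroup leaf: a taxon set is
monophyletic iff its split exists and the outgroup is on the other side.
Maximum-likelihood and Bayesian searches are out of scope; the supermatrix
exports to PHYLIP/NEXUS for external tools.

## Synthetic data

The generators emulate the statistical shape of endosymbiont mitogenome
data: i.i.d. bases at a target GC (default 0.307, the GC ratio of these
genomes; realized GC is within ±1 percentage point of target for ≥ 10 kb),
genome lengths tens of kilobases, short planted SSRs, and five-strain
panels carrying a handful of events (the study-panel preset plants exactly
2 SNPs + 3 insertions + 2 deletions with insertion lengths {2, 10, 1} and
deletion lengths {2, 3} at the published alignment columns).

**SSR planting and screening.** Specs are written at random collision-free
positions with ≥ 12 bp flanks, then the whole sequence is screened: the
scanner runs, and any hit that is not a planted record has its span (plus
one base of margin, minus planted positions) re-sampled; this repeats until
a full scan detects exactly the planted set, within a retry budget
(default 100). Span-level re-sampling is used instead of whole-sequence
rejection because at ~30% GC a random sequence contains a potential
penta/hexa SSR roughly every 500 bp, so whole-fixture rejection would
essentially never converge at mitogenome scale. The guarantee is the same:
scanner precision = recall = 1.0 on generator output, which is what the
recovery tests assert.

**Panels.** Events are specified in alignment coordinates, so the true
alignment is constructed directly and exactly — no aligner is involved, and
aligner ambiguity (which real pipelines inherit) is deliberately
side-stepped. Carrier sets must be strict minorities so the column-majority
consensus equals the ancestor; specs that would merge on calling (adjacent,
same type, same carriers) are rejected at construction, making recovery an
exact set comparison.

**Supermatrices.** Sequence evolution is Jukes–Cantor along the given tree
(per-edge change probability `(3/4)(1 − e^{−4rt/3})`, replacement uniform
over the other three bases), gap-free, per block. Multifurcating trees are
accepted — a star tree with zero branch lengths is the degenerate case that
yields identical rows. Indel-aware and codon models are out of scope.

What passing tests on synthetic data do **not** show: real mitogenomes are
not i.i.d. base streams (codon structure, strand-asymmetric composition,
AT-rich intergenic tracts), real alignments contain aligner-induced gap
placement ambiguity, and real annotations carry errors. The synthetic
results validate the algorithms' correctness against known truth, not their
robustness to those artefacts.

## Problem sizes used in the test suite

The suite runs on one CPU in well under a minute: scanner/brute-force
equivalence on 100 random sequences ≤ 2 kb, variant recovery on 100 random
five-strain panels of 1.2 kb plus the full 55.4 kb study panel, NJ recovery
on additive matrices of ≤ 8 taxa and on 100 simulated 250-column
supermatrices, and bootstrap runs of 100–200 replicates on 6–8 taxa.
These sizes were chosen to exercise every code path at full fidelity while
keeping the suite fast to iterate on; nothing in the algorithms is
specific to them.

## Known discrepancies in the published tables

Surfaced here because the package intentionally does not reproduce them:

- The per-genome summary table reports 16 tRNAs while the gene list and the
  text give 12; the gene list (12) is followed.
- The abstract says two insertions and three deletions; the variant table
  and results text give three insertions and two deletions, which the
  package's preset follows.
- The variant table prints an 11-column span (27,476–27,486) for a 10 bp
  insertion; the allele length is taken as authoritative.
- A few SSR catalog rows print unit sequences truncated relative to their
  span (e.g. a "PentaSSR" with a 4-bp printed unit over a 10-bp span); the
  span identity is taken as authoritative.
- The SSR positional percentages are quoted against a 191-record
  denominator while the count table sums to 169 per genome; the package
  reports raw counts and fractions over its own totals.
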