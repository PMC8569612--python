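# Methods

This note documents the models, conventions, and design choices behind
`plantelements`, in the spirit of a statistical-software methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and window conventions

Genomic coordinates are 1-based inclusive (GFF3/SAM convention);
offsets inside extracted windows and designed elements are 0-based
half-open. "−U..+D of an anchor" is interpreted as U bases strictly
upstream of the anchor plus D bases starting at and including the
anchor, so a window has length U+D and its anchor sits at offset U
(promoters: 1000+50 = 1050 nt with the TSS at offset 1000; terminators:
400+200 = 600 nt with the polyA site at offset 400). Windows that would
cross a chromosome end are skipped, not truncated, so every record in a
training set is length-aligned for column-wise statistics. Minus-strand
windows are reverse-complemented into transcription orientation.
Ambiguity codes other than N are rejected at input. No filter excludes
windows that overlap neighboring genes; callers who need one should
curate the gene list.

For splice coordinates, the donor is the **first intronic base** and the
acceptor the **last intronic base**: a read whose alignment blocks end
at position *e* and resume at *s* supports the junction (*e*+1, *s*−1).
This convention makes junction keys directly comparable to intron
annotations.

## Positional word enrichment

The enrichment layer follows position-restricted word-counting motif
discovery. Words of length *k* (default 6) are assigned to positional
bins of width 25 by their start offset; counting is presence/absence per
sequence, which keeps the 2×2 test margins equal to the number of
sequences and stabilizes the statistic on repetitive sequence. The
enrichment p-value for a (word, bin) pair is the one-sided
hypergeometric tail (Fisher exact test) of foreground vs background
sequence counts, computed with `scipy.stats.hypergeom`; q-values are
Benjamini–Hochberg across all tested pairs (`statsmodels`). Words never
seen in the foreground are not tested. Fold enrichment uses the
Haldane–Anscombe +0.5 correction so it stays finite when the background
count is zero. Significant words are merged greedily: seed with the most
significant unassigned word, absorb same-bin words at Hamming distance
≤ 1, take the per-position IUPAC union as consensus. All sort orders
have lexicographic tie-breaks, so results are order-invariant.

The background is an explicit input. A dinucleotide-preserving shuffle
(random Eulerian-walk construction with a last-edge arborescence check,
fixed seed) is provided for null backgrounds; windows from a random gene
sample work equally.

Word length, bin width, test level, and merging radius are parameters,
not claims: the original motif-discovery runs behind the published
elements used unpublished training genomes and settings, and this
package does not attempt to reproduce their motif lists.

## Positional profiles and the generative designer

The published elements were produced by an undisclosed machine-learning
generator; this package substitutes a documented generative sampler so
the surrounding pipeline is complete and testable. A positional profile
is the column-wise base frequency matrix of a training set with additive
pseudocount smoothing (default 1.0; N bases excluded from counts). A
design is produced by:

1. sampling every position independently from the profile columns,
   aligned so the element's anchor (predicted TSS for promoters, donor
   for introns, distal cleavage site for terminators) maps to the
   profile's anchor offset;
2. stamping one concrete realization of each enriched motif at a random
   offset inside its bin (skipped if it would overwrite a fixed
   structural motif — stamped positions are locked);
3. writing the class's structural motifs (locked);
4. local repair: bases participating in a constraint violation are
   resampled from the profile (excluding the offending base) up to 10
   rounds; if violations persist the attempt is rejected and the whole
   element resampled, up to 1,000 attempts, after which a hard error
   names the unsatisfiable constraint.

Everything is driven by one `numpy` Generator per call, so a fixed
(inputs, seed) pair yields byte-identical output.

Class defaults (all config-exposed):

| parameter | default | rationale |
|---|---|---|
| promoter length / leader | 500 bp / 50 bp | element sizes follow the ~500/300/300 bp class targets; the leader is "short" by design and 50 bp is a placeholder within that description |
| TATA→TSS spacing | exactly 30 bp | transcription initiates ~30 bp downstream of the TATA box in plant promoters; fixed rather than ranged so the hallmark is testable |
| initiator at TSS | YA with TSS = A | a pyrimidine/purine initiator-like dinucleotide; the exact plant Inr consensus used by the original authors is unpublished, so this minimal form is a placeholder |
| intron length / flanks | 300 bp / 5 bp | flanking exonic bases support splicing; 5 bp matches the training-window convention |
| forbidden interior patterns | `GTAAG`; `CAG` preceded by ≥6 pyrimidines | donor-like and acceptor-like sequences between the intended splice sites risk alternative splicing |
| IME motif | `TTNGATYTG` | **placeholder** assembled from published IME-associated composition; real designs should supply project-specific motifs. Placement window: intron offsets 10–150 |
| terminator sites | 2 cleavage sites, 60 bp apart, distal 40 bp from the end | two-site architecture with ~60 bp separation mirrors effective two-site 3′ UTRs |
| NUE spacing | AATAAA ending 10–30 bp upstream of each cleavage site | canonical near-upstream element geometry (a 17 bp gap, one observed configuration, lies inside this range) |
| T-rich tract | ≥8 T's ending at the distal site | T-rich tracts adjoin plant cleavage sites; 8 is a conservative run length that the validator can check exactly |

The validator re-derives every constraint from the sequence and feature
annotations alone, never throws on content, and reports all violations
with intervals; designer outputs pass it by construction (a tested
round-trip property).

## Novelty screen

The screen's statistic is the longest run of continuous identity between
an element and any reference sequence or its reverse complement,
computed exactly by a row-streamed dynamic program (O(nm) time, O(m)
memory, numpy-vectorized rows) with deterministic leftmost witnesses.
The default ceiling of 22 bp treats the published "longest continuous
identity ≤ 22 bp" observation as a configurable screen threshold, not as
a reproduction of BLAST statistics — alignment scores and E-values
against full crop genomes are out of scope. A Smith–Waterman local
alignment score (match +1, mismatch −1, gap −2; `Bio.Align`) is
available for context and carries no threshold. The ORF scanner reports
every ATG-initiated frame to its first in-frame stop (or sequence end)
with at least a minimum codon count, on both strands.

## Transversion knockouts

Motif ablation replaces each base of a named feature interval with its
transversion partner under A↔C, G↔T. Among the transversion pairings,
this one is an involution (applying a knockout twice restores the
original — useful for verification) and maps AT-rich motifs to GC-rich
sequence, which is the intended effect for TATA-box knockouts. The
A↔T/G↔C alternative is also a transversion but would leave AT-content
unchanged, so it is not offered.

## Transcript metrics

SAM parsing is delegated to `pysam`; blocks are rebuilt from CIGAR with
M/=/X and D consuming reference within a block, N opening a junction
gap, and I/S/H consuming no reference. Unique mapping means MAPQ ≥ 1
(configurable) and not secondary/supplementary; multiple SAM inputs are
pooled. Adapter provenance is a configurable tag (default `XA`, values
`5`, `3`, `53`), with assume-all escape hatches for pre-filtered
libraries.

At each intended splice position, reads are categorized as expected
(junction uses both intended coordinates), unexpected (junction shares
that coordinate only), or unspliced (one block contiguously covers the
two bases flanking the boundary). Reads ending exactly at a boundary are
uninformative there and excluded from the denominator. Percentages are
rounded half-up to one decimal in reports (site distributions to two);
unrounded values are retained internally, and category percentages at a
position sum to 100.0 within rounding error (±0.1). Junctions touching
neither intended coordinate are listed without percentages. The minimum
read support for reporting a junction defaults to 1 and is
configurable.

TSS (polyA) distributions use the first (last) aligned base of
5′- (3′-) adapter reads; the dominant site is the modal position with
smallest-coordinate tie-break, and the best-window statistic reports the
maximal summed percentage over contiguous windows of a given width
(leftmost on ties, scanned from the smallest observed position).

Read-through is quantified per sample as
100·2^−(ΔCt(readthrough) − ΔCt(GUS)) with ΔCt against the mean of the
sample's normalizer targets; the normalizer cancels within a sample but
the per-target 2^−ΔCt relative expressions are kept for cross-sample
comparison.

## Read simulator and toy genome

The simulator draws each read independently: a TSS, one splice outcome
per intended intron (expected / retained / named alternative junction),
and a polyA site, all categorical; it then emits an error-free,
exact-match alignment anchored at the transcript 5′ end (5′-adapter
reads) or 3′ end (3′-adapter reads), with M/N CIGARs, the adapter tag,
and a truth table of all latent variables. Reads longer than their
transcript are truncated with the truth noting it. What it deliberately
does **not** model: sequencing errors and indels (the downstream
statistics consume junction and end coordinates, which an error model
would only blur), PCR duplication, adapter mis-ligation, and alignment
ambiguity. Passing recovery tests on simulated data therefore
demonstrates the correctness of the accounting, not robustness to real
library artifacts — real pipelines still need their own trimming and
alignment QC upstream.

The toy-genome generator lays out 2–3-exon genes with canonical GT..AG
introns on random strands with enough intergenic room for all window
classes, optionally planting a motif at a fixed TSS-relative offset with
configurable penetrance, giving ground truth for enrichment-recovery
tests.

## Problem sizes and numerical choices

Stochastic test suites use 10,000 simulated reads (recovery within 3
binomial standard errors), 100 seeds per designer class, 200 training
windows for planted-motif recovery, and 100 random query/reference pairs
(200 nt vs 5 kb) for screen-oracle equivalence; the Fisher tail is
checked exhaustively on all 2×2 tables with group sizes ≤ 28 plus 2,000
random tables up to size 60. These sizes were chosen to make the checks
statistically meaningful while keeping the whole suite fast enough to
run routinely. Percent rounding uses decimal half-up (not banker's
rounding) to match how report tables are conventionally printed.

## Known limitations

* The designer is a transparent positional-profile sampler, not a
  learned generative model; it recapitulates positional motif content
  and hard constraints but makes no claim about expression level or
  tissue specificity of its outputs.
* Expression-based clustering to define co-expressed training sets, and
  EST-based annotation adjustment, are upstream of this package: gene
  lists are inputs.
* The IME motif default and the initiator pattern are placeholders, and
  the exact intervals mutated in published knockout variants are not
  bundled; variants here operate on each element's own annotations.
* One published splice-usage cell (the At.GSI21 junction (723, 814) at
  the 3′ site) prints 5.7% where the denominator convention that
  reproduces every other cell yields 5.0%; the discrepancy is noted
  rather than rationalized, and the computation here reports 5.0.
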