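# plantelements

Computational derivation, screening, and molecular characterization of
synthetic plant expression elements: promoters with 5′ UTR leaders,
introns, and 3′ UTR terminators.

Transgene expression cassettes in crops need diversified regulatory
elements — a promoter/leader, optionally an intron, and a 3′ UTR — that
drive predictable expression while sharing as little sequence as
possible with the host genome and with other stacked traits. This
package implements the desk side of that engineering loop for scientists
building and validating such elements:

1. **Training windows** — extract anchored, strand-resolved sequence
   windows from an annotated genome around the landmarks that define
   each element class: −1000..+50 of the transcription start site (TSS)
   for promoters, introns with 5 bp exonic flanks, and −400..+200 of the
   polyadenylation site for 3′ UTRs.
2. **Positional motifs** — position-restricted *k*-mer enrichment of a
   foreground training set against a background (e.g. a
   dinucleotide-shuffled copy), scored per (word, positional bin) with a
   one-sided Fisher exact test and Benjamini–Hochberg control, then
   greedily merged into IUPAC consensus motifs; plus per-offset
   nucleotide profiles.
3. **Element design** — sample candidate sequences from the positional
   profile, stamp enriched motifs at bin-consistent offsets, and
   rejection-sample against hard structural constraints: a TATA box
   exactly 30 bp upstream of the predicted TSS and an ATG-free leader
   (promoters, ~500 bp); canonical GT..AG boundaries, a clean interior,
   and an intron-mediated-enhancement (IME) motif (introns, ~300 bp);
   two YA cleavage sites each with an AATAAA near-upstream element
   10–30 bp upstream and a T-rich tract at the distal site
   (terminators, ~300 bp). A validator independently reports every
   constraint violation.
4. **Novelty screening** — exact longest run of continuous identity
   between an element and a reference genome (both strands; default
   ceiling 22 bp) and a 6-frame unintended-ORF scan.
5. **Motif knockouts** — transversion variants (A↔C, G↔T, an involution
   that maps TATAAA → GCGCCC) of any annotated feature interval.
6. **Transcript metrics** — from SAM alignments to a cassette:
   splice-junction usage accounting (expected / unspliced / unexpected
   per intended splice position), TSS and polyA-site distributions from
   5′/3′-adapter-tagged reads, and qPCR read-through by the
   2^−ΔΔCt method.
7. **Read simulation** — adapter-tagged RACE-style reads with known TSS
   distribution, per-intron splice outcomes, and polyA sites, emitted as
   SAM/FASTQ with a truth table, so the metrics are testable end to end.

## The central statistic

For an intended intron with donor *d* (first intronic base) and acceptor
*a* (last intronic base), reads informative at the 5′ splice position
are those spliced at *d* (to any acceptor) plus those covering the
boundary (*d*−1, *d*) contiguously (unspliced). The expected-splicing
percentage at the 5′ site is

```
pct_expected_5 = 100 · n(d→a) / [ n(d→a) + n_unspliced(d) + Σ_{a'≠a} n(d→a') ]
```

rounded half-up to one decimal; the 3′ side mirrors this with junctions
sharing the acceptor. Junctions using neither intended position are
reported but enter no denominator.

## Worked example

```bash
python examples/characterize_transcripts.py
```

simulates 10,000 reads of a single-intron reporter cassette (intron at
511–814, splice outcomes 93% expected / 3% retained / 4% alternative
acceptor at 827) and characterizes them:

```
pooled 10000 uniquely mapped reads
intended junction (511, 814):
  expected splicing    9298  93.0% (5')  96.9% (3')
  unspliced             295 (5'), 295 (3')  3.0% / 3.1%
  unexpected (511, 827): 407 reads, 4.1% at 5'
dominant TSS at 481 (90.81% of 5'-adapter reads); 100.0% of initiation inside the 10-bp window starting at 481
polyA sites: 3126 (59.26%), 3186 (40.74%)
```

The splice percentages recover the generating probabilities (the 3′
expected share is higher because the alternative junction does not use
the intended acceptor and so leaves its denominator); the TSS and polyA
distributions recover their categorical truths. The other examples
(`design_elements.py`, `screen_and_variants.py`, `readthrough_qpcr.py`)
walk the design, screening, and qPCR capabilities the same way.

A `plantelements` command-line tool wraps the same library for shell
pipelines (`extract`, `motifs`, `design`, `screen`, `variant`,
`simulate`, `characterize`, `readthrough`); see `plantelements --help`.

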