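"""Extraction of anchored, strand-resolved training windows from a genome.

Training sets for element design are fixed-geometry sequence windows cut
around three kinds of anchors in annotated genes:

* promoters + leaders: 1,000 bp strictly upstream of the transcription
  start site (TSS) through 50 bp starting at the TSS (1,050 nt total);
* introns: the sequence between the 5' and 3' splice sites plus 5 bp of
  flanking exon on each side;
* 3' UTR terminators: 400 bp strictly upstream of the polyadenylation
  site through 200 bp starting at the site (600 nt total).

All windows are reported in transcription orientation (minus-strand
windows are reverse complemented) with the anchor base at a fixed offset,
so that positional statistics can be computed column-wise across genes.
Windows that would run off a chromosome end are skipped (with a logged
warning) rather than truncated, keeping every record length-aligned.

Coordinates are 1-based inclusive (GFF3 convention) on the genomic side;
offsets inside a window are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from ._seq import check_alphabet, revcomp

logger = logging.getLogger(__name__)


class Anchor(str, Enum):
    TSS = "TSS"
    SPLICE5 = "SPLICE5"
    SPLICE3 = "SPLICE3"
    POLYA = "POLYA"


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry relative to an anchor base.

    ``upstream`` bases lie strictly upstream of the anchor; the
    ``downstream`` stretch starts at and includes the anchor base, so the
    total window length is ``upstream + downstream`` and the anchor sits
    at 0-based offset ``upstream``.
    """

    anchor: Anchor
    upstream: int
    downstream: int

    def __post_init__(self):
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window margins must be non-negative")
        if self.upstream + self.downstream <= 0:
            raise ValueError("window must have positive length")

    @property
    def length(self) -> int:
        return self.upstream + self.downstream


PROMOTER_SPEC = WindowSpec(Anchor.TSS, 1000, 50)
TERMINATOR_SPEC = WindowSpec(Anchor.POLYA, 400, 200)


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene structure: ordered exons on one strand.

    ``exons`` are 1-based inclusive genomic intervals sorted in
    transcription order (descending genomic coordinate on the minus
    strand). The TSS is the first transcribed base and the polyA site the
    last transcribed base; both are derived from the exon list.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        for start, end in self.exons:
            if start > end or start < 1:
                raise ValueError(f"{self.gene_id}: bad exon interval {start}..{end}")
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError(f"{self.gene_id}: exons not in transcription order")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            lo1, hi1 = min(s1, e1), max(s1, e1)
            lo2, hi2 = min(s2, e2), max(s2, e2)
            if not (hi1 < lo2 or hi2 < lo1):
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def tss(self) -> int:
        """1-based coordinate of the first transcribed base."""
        first = self.exons[0]
        return first[0] if self.strand == "+" else first[1]

    @property
    def polya_site(self) -> int:
        """1-based coordinate of the last transcribed base."""
        last = self.exons[-1]
        return last[1] if self.strand == "+" else last[0]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic (start, end) of each intron, start <= end, transcription order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return out


@dataclass(frozen=True)
class WindowRecord:
    """One extracted window, oriented 5'->3' along transcription."""

    gene_id: str
    chrom: str
    start: int      # 1-based inclusive genomic interval of the window
    end: int
    strand: str
    anchor_offset: int
    sequence: str
    donor_offset: int | None = None      # intron windows only
    acceptor_offset: int | None = None
    canonical: bool | None = None


@dataclass
class TrainingSet:
    """A collection of anchored windows sharing one geometry.

    For TSS/polyA-anchored sets every record has identical length
    ``window_spec.length``; intron sets (``window_spec is None``) vary in
    length with the introns themselves.
    """

    records: list[WindowRecord] = field(default_factory=list)
    window_spec: WindowSpec | None = None

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def validate(self) -> None:
        if self.window_spec is not None:
            L = self.window_spec.length
            for r in self.records:
                if len(r.sequence) != L:
                    raise ValueError(
                        f"{r.gene_id}: window length {len(r.sequence)} != {L}"
                    )
                if r.anchor_offset != self.window_spec.upstream:
                    raise ValueError(f"{r.gene_id}: anchor offset mismatch")
        for r in self.records:
            check_alphabet(r.sequence, r.gene_id)


def _require_genes(gene_models: Mapping[str, GeneModel], gene_ids: Iterable[str]) -> list[GeneModel]:
    out = []
    for gid in gene_ids:
        if gid not in gene_models:
            raise KeyError(f"unknown gene id: {gid!r}")
        out.append(gene_models[gid])
    return out


def _chrom_seq(genome: Mapping[str, str], chrom: str) -> str:
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not present in genome")
    return genome[chrom]


def _extract_anchored(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    spec: WindowSpec,
    anchor_of,
) -> TrainingSet:
    ts = TrainingSet(window_spec=spec)
    for gene in genes:
        seq = _chrom_seq(genome, gene.chrom)
        anchor = anchor_of(gene)
        if gene.strand == "+":
            start = anchor - spec.upstream
            end = anchor + spec.downstream - 1
        else:
            start = anchor - spec.downstream + 1
            end = anchor + spec.upstream
        if start < 1 or end > len(seq):
            logger.warning(
                "%s: %s window %d..%d exceeds chromosome %s bounds; record skipped",
                gene.gene_id, spec.anchor.value, start, end, gene.chrom,
            )
            continue
        window = seq[start - 1:end]
        if gene.strand == "-":
            window = revcomp(window)
        ts.records.append(
            WindowRecord(
                gene_id=gene.gene_id, chrom=gene.chrom, start=start, end=end,
                strand=gene.strand, anchor_offset=spec.upstream, sequence=window,
            )
        )
    ts.validate()
    return ts


def extract_promoter_windows(
    genome: Mapping[str, str],
    gene_models: Mapping[str, GeneModel],
    gene_ids: Iterable[str],
    spec: WindowSpec = PROMOTER_SPEC,
) -> TrainingSet:
    """Cut promoter+leader windows around each gene's TSS.

    Default geometry: 1,000 bp strictly upstream of the TSS plus 50 bp
    starting at the TSS (anchor offset 1000, window length 1050).
    Unknown gene ids raise; out-of-bounds windows are skipped with a
    warning so all surviving records are length-aligned.
    """
    if spec.anchor is not Anchor.TSS:
        raise ValueError("promoter windows must be TSS-anchored")
    genes = _require_genes(gene_models, gene_ids)
    return _extract_anchored(genome, genes, spec, lambda g: g.tss)


def extract_terminator_windows(
    genome: Mapping[str, str],
    gene_models: Mapping[str, GeneModel],
    gene_ids: Iterable[str],
    spec: WindowSpec = TERMINATOR_SPEC,
) -> TrainingSet:
    """Cut 3' UTR windows around each gene's polyadenylation site
    (default 400 bp upstream + 200 bp starting at the site)."""
    if spec.anchor is not Anchor.POLYA:
        raise ValueError("terminator windows must be polyA-anchored")
    genes = _require_genes(gene_models, gene_ids)
    return _extract_anchored(genome, genes, spec, lambda g: g.polya_site)


def extract_intron_windows(
    genome: Mapping[str, str],
    gene_models: Mapping[str, GeneModel],
    gene_ids: Iterable[str],
    flank: int = 5,
) -> TrainingSet:
    """Cut each intron plus ``flank`` exonic bases on either side.

    Single-exon genes contribute nothing. A flank longer than the
    adjoining exon is truncated with a warning. Each record carries the
    0-based offsets of the first (donor) and last (acceptor) intronic
    base inside the window and a flag for the canonical GT..AG
    dinucleotides.
    """
    genes = _require_genes(gene_models, gene_ids)
    ts = TrainingSet(window_spec=None)
    for gene in genes:
        if len(gene.exons) < 2:
            continue
        seq = _chrom_seq(genome, gene.chrom)
        for idx, (istart, iend) in enumerate(gene.introns):
            up_exon = gene.exons[idx]
            down_exon = gene.exons[idx + 1]
            f5 = min(flank, up_exon[1] - up_exon[0] + 1)
            f3 = min(flank, down_exon[1] - down_exon[0] + 1)
            if f5 < flank or f3 < flank:
                logger.warning(
                    "%s intron %d: flank truncated to %d/%d by short exon",
                    gene.gene_id, idx + 1, f5, f3,
                )
            if gene.strand == "+":
                start, end = istart - f5, iend + f3
                donor = f5
            else:
                start, end = istart - f3, iend + f5
                donor = f5
            if start < 1 or end > len(seq):
                logger.warning(
                    "%s intron %d: window out of bounds; skipped", gene.gene_id, idx + 1
                )
                continue
            window = seq[start - 1:end]
            if gene.strand == "-":
                window = revcomp(window)
            acceptor = len(window) - f3 - 1
            canonical = (
                window[donor:donor + 2] == "GT"
                and window[acceptor - 1:acceptor + 1] == "AG"
            )
            if not canonical:
                logger.warning("%s intron %d: non-canonical splice sites", gene.gene_id, idx + 1)
            ts.records.append(
                WindowRecord(
                    gene_id=f"{gene.gene_id}.i{idx + 1}", chrom=gene.chrom,
                    start=start, end=end, strand=gene.strand,
                    anchor_offset=donor, sequence=window,
                    donor_offset=donor, acceptor_offset=acceptor,
                    canonical=canonical,
                )
            )
    ts.validate()
    return ts
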