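"""Simulation of adapter-tagged RACE/amplicon reads with known truth.

Reads are drawn from a generative model of the characterization assay:
each read independently samples a TSS from a categorical start-site
distribution, a splice outcome per intended intron (expected splicing,
intron retention, or a named alternative junction), and a polyA site.
The resulting transcript block structure on the cassette is emitted as
an error-free SAM alignment (plus FASTQ) anchored at the transcript 5'
end for 5'-adapter reads or the 3' end for 3'-adapter reads, with the
adapter recorded in a SAM tag. A truth table records every read's
sampled latent variables so estimates can be checked against the
generating parameters. Everything is deterministic for a fixed seed.

A companion toy-genome generator emits a random annotated genome
(FASTA + GFF3 + gene list) with canonical GT..AG introns and optionally
planted positional motifs, serving as input for window extraction and
motif-enrichment runs.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._seq import revcomp
from .transcript_metrics import CassetteModel, DEFAULT_ADAPTER_TAG

EXPECTED = "EXPECTED"
UNSPLICED = "UNSPLICED"


@dataclass(frozen=True)
class SpliceOutcome:
    """One categorical outcome for an intron: expected, retained, or an
    alternative junction ALT(donor, acceptor)."""

    kind: str                      # EXPECTED | UNSPLICED | ALT
    junction: tuple[int, int] | None = None

    @staticmethod
    def alt(donor: int, acceptor: int) -> "SpliceOutcome":
        return SpliceOutcome("ALT", (donor, acceptor))

    def label(self) -> str:
        if self.kind == "ALT":
            return f"ALT({self.junction[0]},{self.junction[1]})"
        return self.kind


@dataclass
class SimulationParams:
    cassette: CassetteModel
    tss_dist: Mapping[int, float]
    splice_outcomes: list[Mapping[SpliceOutcome, float]]   # one map per intron
    polya_dist: Mapping[int, float]
    n_reads: int = 1000
    read_length: int = 150
    fraction_5prime_adapter: float = 0.5
    fraction_3prime_adapter: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.fraction_5prime_adapter + self.fraction_3prime_adapter > 1 + 1e-9:
            raise ValueError("adapter fractions exceed 1")
        if len(self.splice_outcomes) != len(self.cassette.intended_junctions):
            raise ValueError("one splice-outcome distribution required per intended intron")
        for dist in [self.tss_dist, self.polya_dist, *self.splice_outcomes]:
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"categorical distribution sums to {total}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError("negative probability")


def random_cassette_sequence(cassette: CassetteModel, seed: int = 0) -> str:
    """Deterministic random ACGT sequence for a cassette model."""
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, cassette.length))


def _draw(rng: np.random.Generator, dist: Mapping) -> object:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _transcript_blocks(
    tss: int, polya: int, removed: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Cassette blocks of the mature transcript from TSS to polyA with
    the sampled introns spliced out."""
    blocks = [(tss, polya)]
    for d, a in sorted(removed):
        new: list[tuple[int, int]] = []
        for s, e in blocks:
            if a < s or d > e:
                new.append((s, e))
                continue
            if s <= d - 1:
                new.append((s, d - 1))
            if a + 1 <= e:
                new.append((a + 1, e))
        blocks = new
    return blocks


def _clip_blocks(blocks, read_length, from_start: bool):
    """First (or last) ``read_length`` transcript bases as cassette blocks."""
    remaining = read_length
    out = []
    seq = blocks if from_start else [(s, e) for s, e in reversed(blocks)]
    for s, e in seq:
        span = e - s + 1
        take = min(span, remaining)
        if from_start:
            out.append((s, s + take - 1))
        else:
            out.append((e - take + 1, e))
        remaining -= take
        if remaining == 0:
            break
    return out if from_start else out[::-1]


def _cigar(blocks) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            gap = s - blocks[i - 1][1] - 1
            parts.append(f"{gap}N")
        parts.append(f"{e - s + 1}M")
    return "".join(parts)


def simulate_reads(
    params: SimulationParams,
    cassette_sequence: str | None = None,
    adapter_tag: str = DEFAULT_ADAPTER_TAG,
) -> tuple[str, str, pd.DataFrame]:
    """Draw reads per the generative model; returns (SAM text, FASTQ
    text, truth table). Reads longer than their transcript are truncated
    to the transcript with the truth table noting it.
    """
    cassette = params.cassette
    if cassette_sequence is None:
        cassette_sequence = random_cassette_sequence(cassette, params.seed)
    if len(cassette_sequence) != cassette.length:
        raise ValueError("cassette sequence length mismatch")
    rng = np.random.default_rng(params.seed)
    sam = _io.StringIO()
    fastq = _io.StringIO()
    sam.write("@HD\tVN:1.6\tSO:unsorted\n")
    sam.write(f"@SQ\tSN:{cassette.cassette_id}\tLN:{cassette.length}\n")
    sam.write("@PG\tID:plantelements\tPN:plantelements\n")
    truth_rows = []
    f5 = params.fraction_5prime_adapter
    f3 = params.fraction_3prime_adapter
    for i in range(params.n_reads):
        read_id = f"sim{i:06d}"
        tss = int(_draw(rng, params.tss_dist))
        polya = int(_draw(rng, params.polya_dist))
        outcomes: list[SpliceOutcome] = []
        removed: list[tuple[int, int]] = []
        for intron_idx, dist in enumerate(params.splice_outcomes):
            outcome = _draw(rng, dist)
            if outcome.kind == EXPECTED:
                removed.append(cassette.intended_junctions[intron_idx])
            elif outcome.kind == "ALT":
                removed.append(outcome.junction)
            outcomes.append(outcome)
        blocks = _transcript_blocks(tss, polya, removed)
        transcript_len = sum(e - s + 1 for s, e in blocks)
        u = rng.random()
        adapter = "5" if u < f5 else ("3" if u < f5 + f3 else "")
        truncated = params.read_length > transcript_len
        if adapter == "3":
            read_blocks = _clip_blocks(blocks, min(params.read_length, transcript_len), False)
        else:
            read_blocks = _clip_blocks(blocks, min(params.read_length, transcript_len), True)
        seq = "".join(cassette_sequence[s - 1:e] for s, e in read_blocks)
        flag = 0
        tags = f"\t{adapter_tag}:Z:{adapter}" if adapter else ""
        sam.write(
            f"{read_id}\t{flag}\t{cassette.cassette_id}\t{read_blocks[0][0]}\t60\t"
            f"{_cigar(read_blocks)}\t*\t0\t0\t{seq}\t{'I' * len(seq)}{tags}\n"
        )
        fastq.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
        truth_rows.append({
            "read_id": read_id, "tss": tss, "polya": polya,
            "outcomes": ";".join(o.label() for o in outcomes),
            "adapter": adapter, "truncated": truncated,
        })
    return sam.getvalue(), fastq.getvalue(), pd.DataFrame(truth_rows)


# ------------------------------------------------------- toy genome

@dataclass
class ToyGenome:
    fasta: str
    gff3: str
    gene_ids: list[str]


def make_toy_genome(
    seed: int = 0,
    n_genes: int = 20,
    chrom_length: int = 120_000,
    planted_motif: str | None = None,
    motif_offset: int = -30,          # relative to the TSS
    penetrance: float = 0.8,
    chrom: str = "chr1",
) -> ToyGenome:
    """Random annotated toy genome with canonical GT..AG introns.

    Genes (2-3 exons) are laid out left to right with enough intergenic
    room for promoter and terminator windows; strands are random. If a
    ``planted_motif`` is given, it is written at ``motif_offset`` from
    the TSS (in transcription orientation) in a ``penetrance`` fraction
    of genes, providing ground truth for enrichment recovery. Output is
    deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, chrom_length))
    margin = 1100                    # room for promoter/terminator windows
    gap = 600
    gff_lines = ["##gff-version 3"]
    gene_ids = []
    cursor = margin
    for g in range(n_genes):
        n_exons = int(rng.integers(2, 4))
        exon_lens = [int(rng.integers(150, 301)) for _ in range(n_exons)]
        intron_lens = [int(rng.integers(200, 401)) for _ in range(n_exons - 1)]
        span = sum(exon_lens) + sum(intron_lens)
        if cursor + span + margin > chrom_length:
            raise ValueError(
                f"genes do not fit: need > {cursor + span + margin} bp, "
                f"chromosome is {chrom_length} bp"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene{g + 1:03d}"
        gene_ids.append(gene_id)
        gstart, gend = cursor, cursor + span - 1      # 1-based inclusive
        # genomic exon intervals, left to right
        exons = []
        pos = gstart
        for k, elen in enumerate(exon_lens):
            exons.append((pos, pos + elen - 1))
            pos += elen
            if k < len(intron_lens):
                istart, iend = pos, pos + intron_lens[k] - 1
                if strand == "+":
                    seq[istart - 1:istart + 1] = ["G", "T"]
                    seq[iend - 2:iend] = ["A", "G"]
                else:
                    # transcription runs right to left: donor at the right end
                    seq[iend - 2:iend] = ["A", "C"]
                    seq[istart - 1:istart + 1] = ["C", "T"]
                pos += intron_lens[k]
        tss = gstart if strand == "+" else gend
        if planted_motif is not None and rng.random() < penetrance:
            if strand == "+":
                mstart = tss + motif_offset          # motif_offset < 0: upstream
                seq[mstart - 1:mstart - 1 + len(planted_motif)] = list(planted_motif)
            else:
                mend = tss - motif_offset
                rc = revcomp(planted_motif)
                seq[mend - len(planted_motif):mend] = list(rc)
        gff_lines.append(
            f"{chrom}\ttoy\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gene_id}"
        )
        for k, (es, ee) in enumerate(exons):
            gff_lines.append(
                f"{chrom}\ttoy\texon\t{es}\t{ee}\t.\t{strand}\t.\t"
                f"ID={gene_id}.e{k + 1};Parent={gene_id}"
            )
        cursor = gend + 1 + margin + int(rng.integers(0, gap))
    body = "".join(seq)
    fasta_lines = [f">{chrom}"]
    fasta_lines += [body[i:i + 70] for i in range(0, len(body), 70)]
    return ToyGenome(
        fasta="\n".join(fasta_lines) + "\n",
        gff3="\n".join(gff_lines) + "\n",
        gene_ids=gene_ids,
    )
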