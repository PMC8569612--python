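"""Window extraction: coordinate arithmetic, strand symmetry, boundaries."""

import numpy as np
import pytest

from plantelements._seq import revcomp
from plantelements.genome_windows import (
    Anchor, GeneModel, WindowSpec,
    extract_intron_windows, extract_promoter_windows, extract_terminator_windows,
)
from plantelements import io as pio
from plantelements.race_simulator import make_toy_genome


def test_plus_strand_promoter_window_coordinates(tiny_genome):
    genome, models = tiny_genome
    ts = extract_promoter_windows(genome, models, ["gplus"])
    assert len(ts) == 1
    rec = ts.records[0]
    # tss=1500: window covers genomic 500..1549, anchor at offset 1000
    assert (rec.start, rec.end) == (500, 1549)
    assert len(rec.sequence) == 1050
    assert rec.anchor_offset == 1000
    assert rec.sequence == genome["chr1"][499:1549]
    assert rec.sequence[1000] == genome["chr1"][1499]   # anchor base is the TSS


def test_minus_strand_promoter_window_is_reverse_complement(tiny_genome):
    genome, models = tiny_genome
    ts = extract_promoter_windows(genome, models, ["gminus"])
    rec = ts.records[0]
    # tss=1500 on '-': genomic 1451..2500 reverse-complemented
    assert (rec.start, rec.end) == (1451, 2500)
    assert rec.sequence == revcomp(genome["chr1"][1450:2500])
    assert len(rec.sequence) == 1050


def test_out_of_bounds_window_skipped_with_warning(tiny_genome, caplog):
    genome, models = tiny_genome
    models = dict(models)
    models["gshort"] = GeneModel("gshort", "chr1", "+", ((800, 900), (1000, 1100)))
    with caplog.at_level("WARNING"):
        ts = extract_promoter_windows(genome, models, ["gshort", "gplus"])
    assert [r.gene_id for r in ts.records] == ["gplus"]
    assert any("skipped" in m for m in caplog.messages)


def test_unknown_gene_id_is_hard_error(tiny_genome):
    genome, models = tiny_genome
    with pytest.raises(KeyError, match="nosuchgene"):
        extract_promoter_windows(genome, models, ["nosuchgene"])


def test_intron_window_geometry_and_canonical_flag(tiny_genome):
    genome, models = tiny_genome
    ts = extract_intron_windows(genome, models, ["gplus"], flank=5)
    assert len(ts) == 1
    rec = ts.records[0]
    # intron 1701..2000, flank 5 -> genomic 1696..2005, length 310
    assert (rec.start, rec.end) == (1696, 2005)
    assert len(rec.sequence) == 310
    assert rec.donor_offset == 5
    assert rec.acceptor_offset == 304
    is_gt_ag = rec.sequence[5:7] == "GT" and rec.sequence[303:305] == "AG"
    assert rec.canonical == is_gt_ag


def test_single_exon_gene_contributes_no_intron_records(tiny_genome):
    genome, models = tiny_genome
    models = dict(models)
    models["mono"] = GeneModel("mono", "chr1", "+", ((100, 400),))
    ts = extract_intron_windows(genome, models, ["mono"])
    assert len(ts) == 0


def test_terminator_window_coordinates(tiny_genome):
    genome, models = tiny_genome
    ts = extract_terminator_windows(genome, models, ["gplus"])
    rec = ts.records[0]
    # polya_site=2300: genomic 1900..2499, anchor offset 400
    assert (rec.start, rec.end) == (1900, 2499)
    assert len(rec.sequence) == 600
    assert rec.anchor_offset == 400
    assert rec.sequence[400] == genome["chr1"][2299]


def test_minus_strand_intron_matches_brute_force_on_reverse_complement(tiny_genome):
    """Extracting a minus-strand intron equals extracting the mirrored
    plus-strand intron from the fully reverse-complemented chromosome."""
    genome, models = tiny_genome
    n = len(genome["chr1"])
    ts_minus = extract_intron_windows(genome, models, ["gminus"], flank=5)
    # gminus exons (1300,1500),(900,1100) -> intron genomic 1101..1299
    flipped_genome = {"chr1": revcomp(genome["chr1"])}
    flip = lambda s, e: (n - e + 1, n - s + 1)
    flipped_models = {
        "gminus": GeneModel("gminus", "chr1", "+", (flip(1300, 1500), flip(900, 1100))),
    }
    ts_flip = extract_intron_windows(flipped_genome, flipped_models, ["gminus"], flank=5)
    assert ts_minus.records[0].sequence == ts_flip.records[0].sequence
    assert ts_minus.records[0].donor_offset == ts_flip.records[0].donor_offset


def test_plus_minus_symmetry_on_toy_genome(toy):
    """Promoter windows from a genome equal those from its reverse
    complement with strands and coordinates flipped."""
    genome = {"chr1": "".join(
        line for line in toy.fasta.splitlines() if not line.startswith(">")
    )}
    n = len(genome["chr1"])
    models = {}
    for line in toy.gff3.splitlines():
        if "\tgene\t" in line:
            cols = line.split("\t")
            models.setdefault(cols[8].split("=")[1], [cols[6], []])
        elif "\texon\t" in line:
            cols = line.split("\t")
            gid = cols[8].split("Parent=")[1]
            models[gid][1].append((int(cols[3]), int(cols[4])))
    gene_models = {}
    flipped_models = {}
    for gid, (strand, exons) in models.items():
        exons.sort(reverse=(strand == "-"))
        gene_models[gid] = GeneModel(gid, "chr1", strand, tuple(exons))
        fstrand = "-" if strand == "+" else "+"
        fexons = tuple((n - e + 1, n - s + 1) for s, e in exons)
        flipped_models[gid] = GeneModel(gid, "chr1", fstrand, fexons)
    flipped = {"chr1": revcomp(genome["chr1"])}
    ts = extract_promoter_windows(genome, gene_models, toy.gene_ids)
    ts_flip = extract_promoter_windows(flipped, flipped_models, toy.gene_ids)
    assert [r.sequence for r in ts.records] == [r.sequence for r in ts_flip.records]


def test_anchor_round_trip_recovers_genomic_coordinate(toy, tmp_path):
    """Mapping a window's anchor offset through its genomic interval
    recovers the gene's TSS on both strands; FASTA round trip preserves it."""
    fa = tmp_path / "g.fa"
    gff = tmp_path / "g.gff3"
    fa.write_text(toy.fasta)
    gff.write_text(toy.gff3)
    genome = pio.read_genome(fa)
    gene_models = pio.read_gene_models(gff)
    ts = extract_promoter_windows(genome, gene_models, toy.gene_ids)
    assert len(ts) == len(toy.gene_ids)
    for rec in ts.records:
        if rec.strand == "+":
            anchor_genomic = rec.start + rec.anchor_offset
        else:
            anchor_genomic = rec.end - rec.anchor_offset
        assert anchor_genomic == gene_models[rec.gene_id].tss
    out = tmp_path / "ts.fa"
    pio.write_training_set(ts, out, tmp_path / "ts.tsv")
    back = pio.read_training_set(out)
    assert [r.sequence for r in back.records] == [r.sequence for r in ts.records]
    assert back.window_spec is not None and back.window_spec.length == 1050


def test_ambiguity_codes_rejected(tmp_path):
    fa = tmp_path / "bad.fa"
    fa.write_text(">chr1\nACGTRYACGT\n")
    with pytest.raises(ValueError, match="unsupported characters"):
        pio.read_genome(fa)


def test_window_spec_invariants():
    with pytest.raises(ValueError):
        WindowSpec(Anchor.TSS, 0, 0)
    with pytest.raises(ValueError):
        WindowSpec(Anchor.TSS, -1, 5)
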