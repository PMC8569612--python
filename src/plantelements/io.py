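"""File-format boundaries: FASTA, GFF3, gene lists, TSV reports, YAML config.

Genomes are multi-record FASTA (wrapped or unwrapped, case-insensitive);
annotations are a GFF3 subset with ``gene`` and ``exon`` features carrying
ID/Parent attributes; gene lists are one id per line with ``#`` comments.
Training sets round-trip through FASTA whose headers carry the genomic
provenance as key=value pairs, plus a TSV index.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO

from ._seq import check_alphabet
from .genome_windows import GeneModel, TrainingSet, WindowRecord, WindowSpec, Anchor


# ---------------------------------------------------------------- genome

def read_genome(path) -> dict[str, str]:
    """Load a FASTA genome into memory, upper-cased and alphabet-checked."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        check_alphabet(seq, f"chromosome {rec.id}")
        genome[rec.id] = seq
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def read_gene_models(path) -> dict[str, GeneModel]:
    """Parse gene and exon features from a GFF3 subset into GeneModels."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        exons = [(e.start, e.end) for e in db.children(gene, featuretype="exon")]
        if not exons:
            raise ValueError(f"gene {gene.id} has no exon features")
        exons.sort()
        if gene.strand == "-":
            exons = exons[::-1]
        elif gene.strand != "+":
            raise ValueError(f"gene {gene.id}: strand is required in the annotation")
        models[gene.id] = GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            exons=tuple(exons),
        )
    if not models:
        raise ValueError(f"no gene features found in {path}")
    return models


def read_gene_list(path) -> list[str]:
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.append(line)
    return ids


# ---------------------------------------------------------- training sets

def write_training_set(ts: TrainingSet, fasta_path, tsv_path=None) -> None:
    """Emit a TrainingSet as annotated FASTA (+ optional TSV index)."""
    with open(fasta_path, "w") as fh:
        for r in ts.records:
            attrs = [
                f"interval={r.chrom}:{r.start}-{r.end}",
                f"strand={r.strand}",
                f"anchor_offset={r.anchor_offset}",
            ]
            if r.donor_offset is not None:
                attrs.append(f"donor={r.donor_offset}")
                attrs.append(f"acceptor={r.acceptor_offset}")
                attrs.append(f"canonical={int(bool(r.canonical))}")
            fh.write(f">{r.gene_id} {' '.join(attrs)}\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i:i + 70] + "\n")
    if tsv_path is not None:
        rows = [
            {
                "record_id": r.gene_id, "chrom": r.chrom, "start": r.start,
                "end": r.end, "strand": r.strand,
                "anchor_offset": r.anchor_offset, "length": len(r.sequence),
            }
            for r in ts.records
        ]
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_training_set(fasta_path) -> TrainingSet:
    """Read back a TrainingSet FASTA written by :func:`write_training_set`."""
    records: list[WindowRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        chrom, interval = fields["interval"].split(":")
        start, end = (int(x) for x in interval.split("-"))
        seq = str(rec.seq).upper()
        check_alphabet(seq, rec.id)
        records.append(
            WindowRecord(
                gene_id=rec.id, chrom=chrom, start=start, end=end,
                strand=fields["strand"], anchor_offset=int(fields["anchor_offset"]),
                sequence=seq,
                donor_offset=int(fields["donor"]) if "donor" in fields else None,
                acceptor_offset=int(fields["acceptor"]) if "acceptor" in fields else None,
                canonical=bool(int(fields["canonical"])) if "canonical" in fields else None,
            )
        )
    lengths = {len(r.sequence) for r in records}
    offsets = {r.anchor_offset for r in records}
    spec = None
    if len(lengths) == 1 and len(offsets) == 1 and records[0].donor_offset is None:
        up = records[0].anchor_offset
        spec = WindowSpec(Anchor.TSS, up, len(records[0].sequence) - up)
    return TrainingSet(records=records, window_spec=spec)


# ----------------------------------------------------------- elements

def write_elements_fasta(elements, path) -> None:
    with open(path, "w") as fh:
        for el in elements:
            fh.write(f">{el.element_id} class={el.element_class} seed={el.provenance.get('seed')}\n")
            for i in range(0, len(el.sequence), 70):
                fh.write(el.sequence[i:i + 70] + "\n")


def write_features_gff3(elements, path) -> None:
    """Element features as GFF3; internal 0-based half-open intervals are
    converted to the file's 1-based inclusive convention."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for el in elements:
            fh.write(
                f"{el.element_id}\tplantelements\tregion\t1\t{len(el.sequence)}\t.\t+\t.\t"
                f"ID={el.element_id};class={el.element_class}\n"
            )
            for i, feat in enumerate(el.features):
                fh.write(
                    f"{el.element_id}\tplantelements\t{feat.name}\t{feat.start + 1}\t{feat.end}\t.\t+\t.\t"
                    f"ID={el.element_id}.f{i}\n"
                )


def read_element(fasta_path, gff3_path):
    """Load one designed element (sequence + features) back from disk."""
    from .element_designer import DesignedElement, FeatureAnnotation

    recs = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(recs) != 1:
        raise ValueError("expected exactly one element record")
    rec = recs[0]
    fields = dict(kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv)
    features = []
    for line in Path(gff3_path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split("\t")
        if cols[0] != rec.id or cols[2] == "region":
            continue
        features.append(FeatureAnnotation(cols[2], int(cols[3]) - 1, int(cols[4])))
    return DesignedElement(
        element_id=rec.id, element_class=fields.get("class", "UNKNOWN"),
        sequence=str(rec.seq).upper(), features=features,
        provenance={"seed": fields.get("seed")},
    )


# ----------------------------------------------------------- cassette / qPCR

def read_cassette(yaml_path):
    """Cassette model from a YAML sidecar (id, length, parts, intended sites)."""
    from .transcript_metrics import CassetteModel

    data = yaml.safe_load(Path(yaml_path).read_text())
    return CassetteModel(
        cassette_id=data["cassette_id"],
        length=int(data["length"]),
        parts=[(p["name"], int(p["start"]), int(p["end"])) for p in data.get("parts", [])],
        intended_tss=int(data["intended_tss"]),
        intended_junctions=[(int(j[0]), int(j[1])) for j in data.get("intended_junctions", [])],
        intended_polya_sites=[int(s) for s in data.get("intended_polya_sites", [])],
    )


def read_qpcr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "target", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    return df


def load_config(path) -> dict:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, Mapping):
        raise ValueError("config file must contain a key-value mapping")
    return dict(data)
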