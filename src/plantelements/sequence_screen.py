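"""Novelty screening of designed elements against source genomes.

The screen formalizes "no significant identity to the source genome" as
the length of the longest run of continuous sequence identity between an
element and any reference sequence (either strand), with a default
ceiling of 22 bp. An optional Smith-Waterman local-alignment score
(match +1 / mismatch -1 / gap -2) is reported for context only and
carries no threshold. A standalone ORF scanner covers the
unintended-coding-sequence check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from ._seq import revcomp

DEFAULT_MAX_RUN = 22


@dataclass(frozen=True)
class IdentityRunReport:
    query_id: str
    reference_id: str
    max_run_length: int
    query_interval: tuple[int, int]        # 0-based half-open
    reference_interval: tuple[int, int]    # on the forward reference strand
    strand: str                            # strand of the reference match
    passed: bool | None = None


@dataclass(frozen=True)
class OrfRecord:
    strand: str
    frame: int
    start: int            # 0-based half-open interval on the forward strand
    stop: int
    length_codons: int
    has_stop: bool


def _lcs_one(query: str, ref: str) -> tuple[int, int, int]:
    """Longest common substring length with leftmost witness ends.

    Row-streamed dynamic programming: run[j] = length of the common
    suffix of query[:i+1] and ref[:j+1]. Returns (length, query_end,
    ref_end) with ends inclusive; leftmost-in-query then
    leftmost-in-reference on ties. O(n*m) time, O(m) memory.
    """
    if not query or not ref:
        return 0, -1, -1
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    n_pos = ord("N")
    prev = np.zeros(len(r) + 1, dtype=np.int32)
    best, best_qe, best_re = 0, -1, -1
    for i in range(len(q)):
        match = (r == q[i]) & (r != n_pos) & (q[i] != n_pos)
        cur = np.zeros(len(r) + 1, dtype=np.int32)
        cur[1:] = np.where(match, prev[:-1] + 1, 0)
        row_max = int(cur.max())
        if row_max > best:
            best = row_max
            best_qe = i
            best_re = int(cur.argmax()) - 1
        prev = cur
    return best, best_qe, best_re


def longest_shared_substring(
    query: str,
    references: Mapping[str, str] | Sequence[str],
    query_id: str = "query",
) -> IdentityRunReport:
    """Exact longest common substring between the query and any reference
    or its reverse complement, with one witness location per side.

    Deterministic tie-breaking: longer runs win; then forward strand over
    reverse; then reference input order; then leftmost-in-query,
    leftmost-in-reference (guaranteed by the row scan order).
    """
    if not query:
        raise ValueError("empty query")
    if isinstance(references, Mapping):
        items = list(references.items())
    else:
        items = [(f"ref{i}", s) for i, s in enumerate(references)]
    if not items:
        raise ValueError("empty reference set")
    best: IdentityRunReport | None = None
    for ref_id, ref in items:
        for strand in "+-":
            target = ref if strand == "+" else revcomp(ref)
            length, qe, te = _lcs_one(query, target)
            if length == 0:
                q_iv, r_iv = (0, 0), (0, 0)
            else:
                qs, ts = qe - length + 1, te - length + 1
                q_iv = (qs, qe + 1)
                if strand == "+":
                    r_iv = (ts, te + 1)
                else:
                    r_iv = (len(ref) - (te + 1), len(ref) - ts)
            cand = IdentityRunReport(
                query_id=query_id, reference_id=ref_id, max_run_length=length,
                query_interval=q_iv, reference_interval=r_iv, strand=strand,
            )
            if best is None or cand.max_run_length > best.max_run_length:
                best = cand
    assert best is not None
    return best


def screen_diversity(
    query: str,
    references: Mapping[str, str] | Sequence[str],
    max_run: int = DEFAULT_MAX_RUN,
    query_id: str = "query",
) -> IdentityRunReport:
    """Pass/fail novelty screen: passes iff the longest identity run
    against every reference (either strand) is <= ``max_run`` bp."""
    report = longest_shared_substring(query, references, query_id=query_id)
    from dataclasses import replace

    return replace(report, passed=report.max_run_length <= max_run)


_STOPS = {"TAA", "TAG", "TGA"}


def _scan_strand(seq: str, strand: str, n_forward: int, min_codons: int) -> list[OrfRecord]:
    out = []
    for i in range(len(seq) - 2):
        if seq[i:i + 3] != "ATG":
            continue
        codons = 0
        has_stop = False
        j = i
        while j + 3 <= len(seq):
            codon = seq[j:j + 3]
            if codon in _STOPS and j > i:
                has_stop = True
                break
            codons += 1
            j += 3
        end = j + 3 if has_stop else j
        if codons < min_codons:
            continue
        if strand == "+":
            start_f, stop_f = i, end
        else:
            start_f, stop_f = n_forward - end, n_forward - i
        out.append(
            OrfRecord(
                strand=strand, frame=i % 3, start=start_f, stop=stop_f,
                length_codons=codons, has_stop=has_stop,
            )
        )
    return out


def scan_orfs(sequence: str, min_codons: int = 10, both_strands: bool = True) -> list[OrfRecord]:
    """All ATG-initiated open reading frames to the first in-frame stop
    (or the element end), with at least ``min_codons`` codons excluding
    the stop. Intervals are reported on the forward strand, sorted by
    start offset.
    """
    sequence = sequence.upper()
    records = _scan_strand(sequence, "+", len(sequence), min_codons)
    if both_strands:
        records += _scan_strand(revcomp(sequence), "-", len(sequence), min_codons)
    records.sort(key=lambda r: (r.start, r.strand, r.frame))
    return records


def local_alignment_score(query: str, reference: str) -> float:
    """Smith-Waterman score (match +1, mismatch -1, gap -2), best of the
    two reference strands. Context metric only; no pass/fail threshold."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return float(max(aligner.score(reference, query), aligner.score(revcomp(reference), query)))
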