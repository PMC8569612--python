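"""Position-sensitive word enrichment between foreground and background
training sets, in the spirit of position-restricted word-clustering motif
finders, plus the positional nucleotide profile used by the designer.

Words of length ``k`` are counted per positional bin (a word belongs to the
bin containing its start offset). Counting is presence/absence per sequence,
which keeps the test stable on repetitive sequence. Enrichment is scored
with a one-sided hypergeometric (Fisher) test of foreground vs background
sequence counts, adjusted by Benjamini-Hochberg across all tested
(word, bin) pairs. Significant words in the same bin are then greedily
merged (Hamming distance <= 1 from the most significant seed) into IUPAC
consensus motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._seq import iupac_union
from .genome_windows import TrainingSet

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class PositionalWordCount:
    word: str
    bin: tuple[int, int]          # half-open offset interval
    count: int                    # sequences with >=1 occurrence in the bin
    n: int                        # sequences in the set


@dataclass(frozen=True)
class EnrichedWord:
    word: str
    bin: tuple[int, int]
    fg_count: int
    fg_n: int
    bg_count: int
    bg_n: int
    p_value: float
    q_value: float
    fold_enrichment: float


@dataclass
class PositionalMotif:
    consensus: str
    bin: tuple[int, int]
    member_words: list[str]
    p_value: float
    q_value: float
    fold_enrichment: float


@dataclass
class PositionalProfile:
    """Per-offset nucleotide frequencies of a length-aligned training set."""

    matrix: np.ndarray            # shape (window_length, 4), rows sum to 1
    pseudocount: float
    anchor_offset: int | None = None

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def _uniform_length(ts: TrainingSet) -> int:
    if not ts.records:
        raise ValueError("empty training set")
    lengths = {len(s) for s in ts.sequences()}
    if len(lengths) != 1:
        raise ValueError("positional statistics require length-aligned windows")
    return lengths.pop()


def count_positional_words(ts: TrainingSet, k: int = 6, bin_width: int = 25) -> list[PositionalWordCount]:
    """Count, per (word, bin), the number of sequences containing the word
    starting inside the bin. Bins tile the window as [0,w), [w,2w), ...;
    words containing N are skipped.
    """
    L = _uniform_length(ts)
    if k > L:
        raise ValueError("word length exceeds window length")
    if bin_width < k:
        raise ValueError("bin width must be at least the word length")
    n = len(ts.records)
    counts: dict[tuple[str, tuple[int, int]], int] = {}
    for seq in ts.sequences():
        seen: set[tuple[str, tuple[int, int]]] = set()
        for off in range(L - k + 1):
            word = seq[off:off + k]
            if "N" in word:
                continue
            b0 = (off // bin_width) * bin_width
            seen.add((word, (b0, min(b0 + bin_width, L))))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    return [
        PositionalWordCount(word=w, bin=b, count=c, n=n)
        for (w, b), c in sorted(counts.items(), key=lambda kv: (kv[0][1][0], kv[0][0]))
    ]


def _one_sided_p(fg_count: int, fg_n: int, bg_count: int, bg_n: int) -> float:
    """P[X >= fg_count] for X ~ Hypergeom(N=fg_n+bg_n, K=fg+bg, n=fg_n):
    the one-sided Fisher exact tail for enrichment in the foreground."""
    return float(hypergeom.sf(fg_count - 1, fg_n + bg_n, fg_count + bg_count, fg_n))


def score_enrichment(
    fg: list[PositionalWordCount],
    bg: list[PositionalWordCount],
    alpha: float = 0.05,
) -> list[EnrichedWord]:
    """One-sided Fisher enrichment of foreground over background per
    (word, bin), BH-adjusted across all tested pairs; only q <= alpha is
    returned, sorted by p ascending with lexicographic (word, bin start)
    tie-breaking. Words absent from the foreground are never reported.
    """
    if not fg:
        raise ValueError("empty foreground counts")
    fg_n = fg[0].n
    bg_n = bg[0].n if bg else 0
    fg_bins = {c.bin[1] - c.bin[0] for c in fg}
    bg_map = {(c.word, c.bin): c.count for c in bg}
    for c in bg:
        if (c.bin[1] - c.bin[0]) > max(fg_bins):
            raise ValueError("foreground/background binning mismatch")
    tested = [c for c in fg if c.count > 0]
    pvals = np.array([
        _one_sided_p(c.count, fg_n, bg_map.get((c.word, c.bin), 0), bg_n)
        for c in tested
    ])
    if len(pvals) == 0:
        return []
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = []
    for c, p, q in zip(tested, pvals, qvals):
        if q > alpha:
            continue
        b = bg_map.get((c.word, c.bin), 0)
        # Haldane-Anscombe correction keeps the fold finite when bg_count=0
        fold = ((c.count + 0.5) / (fg_n + 1)) / ((b + 0.5) / (bg_n + 1))
        out.append(
            EnrichedWord(
                word=c.word, bin=c.bin, fg_count=c.count, fg_n=fg_n,
                bg_count=b, bg_n=bg_n, p_value=float(p), q_value=float(q),
                fold_enrichment=fold,
            )
        )
    out.sort(key=lambda e: (e.p_value, e.word, e.bin[0]))
    return out


def merge_words_to_motifs(enriched: list[EnrichedWord]) -> list[PositionalMotif]:
    """Greedy agglomeration of enriched words into IUPAC consensus motifs.

    Seeds with the most significant unassigned word, absorbs unassigned
    same-bin words at Hamming distance <= 1 from the seed, and takes the
    per-position IUPAC union as the consensus. Deterministic given the
    sorted enrichment list.
    """
    if not enriched:
        raise ValueError("no enriched words to merge")
    pool = sorted(enriched, key=lambda e: (e.p_value, e.word, e.bin[0]))
    assigned: set[tuple[str, tuple[int, int]]] = set()
    motifs: list[PositionalMotif] = []
    for seed in pool:
        key = (seed.word, seed.bin)
        if key in assigned:
            continue
        members = [seed]
        assigned.add(key)
        for cand in pool:
            ck = (cand.word, cand.bin)
            if ck in assigned or cand.bin != seed.bin:
                continue
            dist = sum(a != b for a, b in zip(seed.word, cand.word))
            if dist <= 1:
                members.append(cand)
                assigned.add(ck)
        consensus = "".join(
            iupac_union({m.word[i] for m in members}) for i in range(len(seed.word))
        )
        motifs.append(
            PositionalMotif(
                consensus=consensus, bin=seed.bin,
                member_words=sorted(m.word for m in members),
                p_value=seed.p_value, q_value=seed.q_value,
                fold_enrichment=seed.fold_enrichment,
            )
        )
    return motifs


def build_positional_profile(
    ts: TrainingSet, pseudocount: float = 1.0
) -> PositionalProfile:
    """Column-wise base frequencies with additive smoothing; N bases are
    excluded from the counts at their offset."""
    L = _uniform_length(ts)
    counts = np.zeros((L, 4), dtype=float)
    for seq in ts.sequences():
        for i, base in enumerate(seq):
            if base != "N":
                counts[i, _BASE_INDEX[base]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    freq = (counts + pseudocount) / (totals + 4 * pseudocount)
    anchor = ts.window_spec.upstream if ts.window_spec is not None else None
    return PositionalProfile(matrix=freq, pseudocount=pseudocount, anchor_offset=anchor)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (random Eulerian walk on the
    first-order transition multigraph), used to build null backgrounds."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    start, term = seq[0], seq[-1]
    # Altschul-Erickson: draw a random "last edge" per non-terminal vertex
    # until those edges form an arborescence into the terminal vertex, then
    # shuffle the remaining edges freely; the walk is then Eulerian.
    verts = list(edges)
    while True:
        last = {
            v: edges[v][int(rng.integers(len(edges[v])))]
            for v in verts if v != term
        }
        ok = True
        for v in last:
            cur, hops = v, 0
            while cur != term:
                if cur not in last or hops > 4:
                    ok = False
                    break
                cur = last[cur]
                hops += 1
            if not ok:
                break
        if ok:
            break
    order: dict[str, list[str]] = {}
    for v in verts:
        rest = list(edges[v])
        if v in last:
            rest.remove(last[v])
        rest = [rest[i] for i in rng.permutation(len(rest))]
        if v in last:
            rest.append(last[v])
        order[v] = rest
    out = [start]
    cur = start
    for _ in range(len(seq) - 1):
        cur = order[cur].pop(0)
        out.append(cur)
    return "".join(out)


def shuffle_training_set(ts: TrainingSet, seed: int = 0) -> TrainingSet:
    """Dinucleotide-shuffled copy of a training set (fixed seed) for use
    as an explicit enrichment background."""
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    records = [replace(r, sequence=dinucleotide_shuffle(r.sequence, rng)) for r in ts.records]
    return TrainingSet(records=records, window_spec=ts.window_spec)


def motifs_to_frame(motifs: list[PositionalMotif]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "consensus": m.consensus, "bin_start": m.bin[0], "bin_end": m.bin[1],
                "p_value": m.p_value, "q_value": m.q_value,
                "fold_enrichment": m.fold_enrichment,
                "members": ",".join(m.member_words),
            }
            for m in motifs
        ]
    )


def profile_to_frame(profile: PositionalProfile) -> pd.DataFrame:
    df = pd.DataFrame(profile.matrix, columns=list(BASES))
    df.insert(0, "offset", np.arange(profile.length))
    return df
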