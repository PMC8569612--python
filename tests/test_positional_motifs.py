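"""Positional word counting, Fisher enrichment, motif merging, profiles."""

import math

import numpy as np
import pytest

from plantelements.genome_windows import TrainingSet, WindowRecord, WindowSpec, Anchor
from plantelements.positional_motifs import (
    EnrichedWord, build_positional_profile, count_positional_words,
    dinucleotide_shuffle, merge_words_to_motifs, score_enrichment,
    shuffle_training_set, _one_sided_p,
)


def _ts(seqs, upstream=None):
    spec = None
    if upstream is not None:
        spec = WindowSpec(Anchor.TSS, upstream, len(seqs[0]) - upstream)
    records = [
        WindowRecord(f"g{i}", "chr1", 1, len(s), "+", upstream or 0, s)
        for i, s in enumerate(seqs)
    ]
    return TrainingSet(records=records, window_spec=spec)


def brute_force_counts(seqs, k, bin_width):
    """Independent oracle: scan every sequence at every offset."""
    L = len(seqs[0])
    counts = {}
    for seq in seqs:
        seen = set()
        for off in range(L - k + 1):
            w = seq[off:off + k]
            if "N" in w:
                continue
            b0 = (off // bin_width) * bin_width
            seen.add((w, (b0, min(b0 + bin_width, L))))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    return counts


def fisher_tail_oracle(a, n1, b, n2):
    """Exact one-sided tail: sum hypergeometric pmf over x >= a with
    margins (n1 draws, K = a+b successes, N = n1+n2)."""
    N, K = n1 + n2, a + b
    denom = math.comb(N, n1)
    total = 0
    for x in range(a, min(n1, K) + 1):
        if K - x > n2:
            continue
        total += math.comb(K, x) * math.comb(N - K, n1 - x)
    return total / denom


def test_single_sequence_single_word():
    ts = _ts(["TATATA"])
    counts = count_positional_words(ts, k=6, bin_width=6)
    assert {(c.word, c.bin): c.count for c in counts} == {("TATATA", (0, 6)): 1}


def test_presence_absence_counting_within_bin():
    # AAAA at offsets 0 and 2 inside one bin -> still count 1
    ts = _ts(["AAAAAAAT"])
    counts = count_positional_words(ts, k=4, bin_width=8)
    by_key = {(c.word, c.bin): c.count for c in counts}
    assert by_key[("AAAA", (0, 8))] == 1


def test_counts_match_brute_force_scan(rng):
    seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 60)) for _ in range(50)]
    ts = _ts(seqs)
    got = {(c.word, c.bin): c.count for c in count_positional_words(ts, k=5, bin_width=25)}
    assert got == brute_force_counts(seqs, 5, 25)


def test_fg_identical_to_bg_yields_nothing():
    seqs = ["ACGTACGTAC"] * 10
    fg = count_positional_words(_ts(seqs), k=4, bin_width=10)
    bg = count_positional_words(_ts(seqs), k=4, bin_width=10)
    assert score_enrichment(fg, bg, alpha=0.99) == []


def test_fisher_p_matches_exact_tail_sum():
    # the 2x2 table (40,10 / 10,40)
    p = _one_sided_p(40, 50, 10, 50)
    assert p == pytest.approx(fisher_tail_oracle(40, 50, 10, 50), rel=1e-10)


@pytest.mark.parametrize("n1,n2", [(8, 8), (12, 5), (20, 20)])
def test_fisher_p_exhaustive_small_tables(n1, n2):
    for a in range(n1 + 1):
        for b in range(n2 + 1):
            got = _one_sided_p(a, n1, b, n2)
            want = fisher_tail_oracle(a, n1, b, n2)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12), (a, n1, b, n2)


def test_word_absent_from_foreground_never_reported():
    fg = count_positional_words(_ts(["CCCCCC"] * 5), k=6, bin_width=6)
    bg = count_positional_words(_ts(["TATATA"] * 5), k=6, bin_width=6)
    hits = score_enrichment(fg, bg, alpha=1.0)
    assert all(h.word != "TATATA" for h in hits)


def test_bh_qvalues_monotone_in_p_rank(rng):
    seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 40)) for _ in range(30)]
    planted = [("TATAAA" + s[6:]) if i < 20 else s for i, s in enumerate(seqs)]
    fg = count_positional_words(_ts(planted), k=6, bin_width=20)
    bg = count_positional_words(_ts(seqs), k=6, bin_width=20)
    hits = score_enrichment(fg, bg, alpha=1.0)
    ps = [h.p_value for h in hits]
    qs = [h.q_value for h in hits]
    assert ps == sorted(ps)
    order = np.argsort(ps, kind="stable")
    assert all(qs[i] >= ps[i] for i in range(len(hits)))
    assert list(np.array(qs)[order]) == sorted(qs)


def test_merge_iupac_union_and_bin_separation():
    mk = lambda w, b, p: EnrichedWord(w, b, 10, 10, 0, 10, p, p, 10.0)
    motifs = merge_words_to_motifs([mk("TATAAA", (0, 25), 1e-8), mk("TATATA", (0, 25), 1e-6)])
    assert len(motifs) == 1
    assert motifs[0].consensus == "TATAWA"
    assert motifs[0].member_words == ["TATAAA", "TATATA"]
    # same word in non-adjacent bins stays two motifs
    motifs2 = merge_words_to_motifs([mk("TATAAA", (0, 25), 1e-8), mk("TATAAA", (50, 75), 1e-8)])
    assert len(motifs2) == 2


def test_merge_is_order_invariant_for_equal_p():
    mk = lambda w, b: EnrichedWord(w, b, 10, 10, 0, 10, 1e-6, 1e-6, 10.0)
    words = [mk("TATAAA", (0, 25)), mk("TATATA", (0, 25)), mk("GGGCCC", (0, 25))]
    a = merge_words_to_motifs(words)
    b = merge_words_to_motifs(words[::-1])
    assert [(m.consensus, m.bin) for m in a] == [(m.consensus, m.bin) for m in b]


def test_profile_one_hot_and_pseudocount_limits():
    prof0 = build_positional_profile(_ts(["ACGT"]), pseudocount=0)
    assert np.allclose(prof0.matrix, np.eye(4))
    profN = build_positional_profile(_ts(["NNNN"]), pseudocount=1)
    assert np.allclose(profN.matrix, 0.25)


def test_profile_columns_sum_to_one(rng):
    seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 30)) for _ in range(100)]
    prof = build_positional_profile(_ts(seqs))
    assert np.allclose(prof.matrix.sum(axis=1), 1.0, atol=1e-9)


def test_dinucleotide_shuffle_preserves_dinucleotide_counts(rng):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
    shuf = dinucleotide_shuffle(seq, rng)
    count = lambda s: {
        (a, b): sum(1 for x, y in zip(s, s[1:]) if (x, y) == (a, b))
        for a in "ACGT" for b in "ACGT"
    }
    assert count(shuf) == count(seq)
    assert shuf != seq   # 500 nt: astronomically unlikely to be identical


def test_planted_motif_recovered_in_top_motifs(rng):
    """A 6-mer planted at one offset in 80% of 200 windows against a
    shuffled background lands in the top-5 motifs with a covering bin."""
    L, offset, word = 150, 62, "GATCGA"
    seqs = []
    for i in range(200):
        s = list("".join("ACGT"[j] for j in rng.integers(0, 4, L)))
        if i < 160:
            s[offset:offset + 6] = list(word)
        seqs.append("".join(s))
    fg_ts = _ts(seqs)
    bg_ts = shuffle_training_set(fg_ts, seed=123)
    fg = count_positional_words(fg_ts, k=6, bin_width=25)
    bg = count_positional_words(bg_ts, k=6, bin_width=25)
    hits = score_enrichment(fg, bg, alpha=0.05)
    motifs = merge_words_to_motifs(hits)
    top5 = motifs[:5]
    covering = [
        m for m in top5
        if word in m.member_words and m.bin[0] <= offset < m.bin[1]
    ]
    assert covering, [(m.consensus, m.bin) for m in top5]


def test_empty_training_set_is_hard_error():
    with pytest.raises(ValueError, match="empty"):
        count_positional_words(TrainingSet(records=[]), k=4, bin_width=10)
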