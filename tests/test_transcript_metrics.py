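"""Alignment parsing, junction accounting, site distributions, ddCt."""

import math

import pandas as pd
import pytest

from plantelements.transcript_metrics import (
    AlignedRead, CassetteModel, extract_junctions, parse_alignments,
    polya_distribution, readthrough_percent, round_half_up, splice_usage,
    splice_usage_from_counts, tss_distribution, window_fraction,
)


def _sam(cassette, body_lines):
    return (
        "@HD\tVN:1.6\n"
        f"@SQ\tSN:{cassette.cassette_id}\tLN:{cassette.length}\n"
        + "".join(line + "\n" for line in body_lines)
    )


@pytest.fixture
def small_cassette():
    return CassetteModel("cas", 1200, intended_tss=100,
                         intended_junctions=[(461, 780)],
                         intended_polya_sites=[1100])


def test_cigar_block_semantics(small_cassette, tmp_path):
    lines = [
        "r1\t0\tcas\t100\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*",
        "r2\t0\tcas\t461\t60\t20M300N30M\t*\t0\t0\t" + "A" * 50 + "\t*",
        "r3\t0\tcas\t100\t60\t5S45M\t*\t0\t0\t" + "A" * 50 + "\t*",
        "r4\t0\tcas\t100\t60\t20M5D20M\t*\t0\t0\t" + "A" * 40 + "\t*",
        "r5\t0\tcas\t100\t60\t20M5I20M\t*\t0\t0\t" + "A" * 45 + "\t*",
    ]
    p = tmp_path / "a.sam"
    p.write_text(_sam(small_cassette, lines))
    reads = {r.read_id: r for r in parse_alignments(p, small_cassette)}
    assert reads["r1"].blocks == ((100, 149),)
    assert reads["r2"].blocks == ((461, 480), (781, 810))
    assert reads["r2"].junctions == [(481, 780)]
    assert reads["r3"].blocks == ((100, 144),)      # soft clip keeps POS
    assert reads["r4"].blocks == ((100, 144),)      # D consumes ref in-block
    assert reads["r5"].blocks == ((100, 139),)      # I consumes read only


def test_non_unique_and_low_mapq_reads_excluded(small_cassette, tmp_path):
    lines = [
        "ok\t0\tcas\t100\t60\t30M\t*\t0\t0\t" + "A" * 30 + "\t*",
        "sec\t256\tcas\t100\t60\t30M\t*\t0\t0\t" + "A" * 30 + "\t*",
        "supp\t2048\tcas\t100\t60\t30M\t*\t0\t0\t" + "A" * 30 + "\t*",
        "mapq0\t0\tcas\t100\t0\t30M\t*\t0\t0\t" + "A" * 30 + "\t*",
    ]
    p = tmp_path / "a.sam"
    p.write_text(_sam(small_cassette, lines))
    reads = parse_alignments(p, small_cassette)
    assert [r.read_id for r in reads] == ["ok"]


def test_unknown_reference_is_hard_error(small_cassette, tmp_path):
    p = tmp_path / "a.sam"
    p.write_text(
        "@SQ\tSN:other\tLN:500\nr\t0\tother\t10\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n"
    )
    with pytest.raises(ValueError, match="unknown reference"):
        parse_alignments(p, small_cassette)


def test_adapter_tag_parsing(small_cassette, tmp_path):
    lines = [
        "a5\t0\tcas\t100\t60\t30M\t*\t0\t0\t" + "A" * 30 + "\t*\tXA:Z:5",
        "a3\t0\tcas\t100\t60\t30M\t*\t0\t0\t" + "A" * 30 + "\t*\tXA:Z:3",
        "a53\t0\tcas\t100\t60\t30M\t*\t0\t0\t" + "A" * 30 + "\t*\tXA:Z:53",
        "none\t0\tcas\t100\t60\t30M\t*\t0\t0\t" + "A" * 30 + "\t*",
    ]
    p = tmp_path / "a.sam"
    p.write_text(_sam(small_cassette, lines))
    reads = {r.read_id: r for r in parse_alignments(p, small_cassette)}
    assert reads["a5"].has_5prime_adapter and not reads["a5"].has_3prime_adapter
    assert reads["a3"].has_3prime_adapter and not reads["a3"].has_5prime_adapter
    assert reads["a53"].has_5prime_adapter and reads["a53"].has_3prime_adapter
    assert not reads["none"].has_5prime_adapter


def test_extract_junctions_counts_every_gap(rng):
    reads = [
        AlignedRead("r1", ((461, 510), (854, 903))),
        AlignedRead("r2", ((461, 510), (854, 903))),
        AlignedRead("multi", ((1, 50), (101, 150), (301, 350))),
        AlignedRead("contig", ((1, 100),)),
    ]
    table = extract_junctions(reads)
    assert table[(511, 853)] == 2
    assert table[(51, 100)] == 1 and table[(151, 300)] == 1
    assert (1, 100) not in table


def test_extract_junctions_matches_per_read_brute_force(rng):
    reads = []
    for i in range(1000):
        n_blocks = int(rng.integers(1, 4))
        pos = int(rng.integers(1, 100))
        blocks = []
        for _ in range(n_blocks):
            length = int(rng.integers(10, 60))
            blocks.append((pos, pos + length - 1))
            pos += length + int(rng.integers(2, 50))
        reads.append(AlignedRead(f"r{i}", tuple(blocks)))
    got = extract_junctions(reads)
    want: dict = {}
    for read in reads:
        for (s1, e1), (s2, e2) in zip(read.blocks, read.blocks[1:]):
            key = (e1 + 1, s2 - 1)
            want[key] = want.get(key, 0) + 1
    assert got == want


TABLE_CELLS = [
    # (intended, junction counts, unspliced5, unspliced3, checks)
    ((511, 853), {(511, 853): 5432}, 65, 80,
     {"pct_expected_5": 98.8, "pct_expected_3": 98.5,
      "pct_unspliced_5": 1.2, "pct_unspliced_3": 1.5}),
    ((511, 805), {(511, 805): 52618, (511, 818): 2304}, 1599, 1809,
     {"pct_expected_5": 93.1, "pct_expected_3": 96.7, "pct_unspliced_3": 3.3}),
    ((511, 814),
     {(511, 814): 17324, (511, 673): 1385, (688, 814): 187, (723, 814): 1036},
     2269, 2212,
     {"pct_expected_5": 82.6, "pct_expected_3": 83.5,
      "pct_unspliced_5": 10.8, "pct_unspliced_3": 10.7}),
]


@pytest.mark.parametrize("intended,junctions,u5,u3,checks", TABLE_CELLS)
def test_splice_usage_reproduces_printed_percentages(intended, junctions, u5, u3, checks):
    report = splice_usage_from_counts([intended], junctions, u5, u3)
    usage = report.usage(intended)
    for attr, want in checks.items():
        assert getattr(usage, attr) == want, attr


def test_unexpected_junction_percentages_and_category_sum():
    report = splice_usage_from_counts(
        [(511, 814)],
        {(511, 814): 17324, (511, 673): 1385, (688, 814): 187, (723, 814): 1036},
        2269, 2212,
    )
    u = report.usage((511, 814))
    assert u.pct_unexpected_5((511, 673)) == 6.6
    assert u.pct_unexpected_3((688, 814)) == 0.9
    total5 = u.pct_expected_5 + u.pct_unspliced_5 + sum(
        u.pct_unexpected_5(j) for j in u.unexpected_5
    )
    total3 = u.pct_expected_3 + u.pct_unspliced_3 + sum(
        u.pct_unexpected_3(j) for j in u.unexpected_3
    )
    assert math.isclose(total5, 100.0, abs_tol=0.1 + 1e-9)
    assert math.isclose(total3, 100.0, abs_tol=0.1 + 1e-9)


def test_zero_expected_splicing_reports_full_intron_retention():
    report = splice_usage_from_counts(
        [(511, 814)],
        {(580, 673): 704, (580, 827): 165, (633, 827): 146, (723, 827): 716},
        6746, 5768,
    )
    u = report.usage((511, 814))
    assert u.pct_unspliced_5 == 100.0 and u.pct_unspliced_3 == 100.0
    assert u.pct_expected_5 == 0.0 and u.pct_expected_3 == 0.0
    # junctions touching neither intended position are listed, unassigned
    assert set(report.other_junctions) == {(580, 673), (580, 827), (633, 827), (723, 827)}


def test_zero_informative_reads_reported_as_undefined():
    report = splice_usage_from_counts([(100, 200)], {}, 0, 0)
    u = report.usage((100, 200))
    assert u.pct_expected_5 is None and u.pct_unspliced_3 is None


def test_read_based_usage_counts_boundary_coverage(small_cassette):
    p5, p3 = 461, 780
    reads = [
        AlignedRead("spliced", ((400, 460), (781, 900))),       # expected
        AlignedRead("unspl", ((400, 500),)),                    # covers 460/461
        AlignedRead("ends_at_boundary", ((400, 460),)),         # uninformative
        AlignedRead("alt", ((400, 460), (801, 900))),           # donor 461, alt acceptor
        AlignedRead("unspl3", ((700, 800),)),                   # covers 780/781
    ]
    report = splice_usage(reads, small_cassette)
    u = report.usage((p5, p3))
    assert u.expected_count == 1
    assert u.unspliced5_count == 1
    assert u.unspliced3_count == 1
    assert u.unexpected_5 == {(461, 800): 1}
    assert u.denominator_5 == 3


def test_rounding_is_half_up():
    assert round_half_up(0.05, 1) == 0.1
    assert round_half_up(83.45, 1) == 83.5
    assert round_half_up(2.25, 1) == 2.3
    assert round_half_up(1.0049, 2) == 1.0


def test_tss_distribution_and_window_fraction(small_cassette):
    reads = (
        [AlignedRead(f"a{i}", ((481, 700),), has_5prime_adapter=True) for i in range(18)]
        + [AlignedRead(f"b{i}", ((483, 700),), has_5prime_adapter=True) for i in range(2)]
        + [AlignedRead("untagged", ((490, 700),))]
    )
    dist = tss_distribution(reads, small_cassette)
    assert dist.total == 20
    assert dist.pct[481] == 90.0 and dist.pct[483] == 10.0
    assert dist.dominant_site == 481
    start, frac = window_fraction(dist, width=10)
    assert (start, frac) == (474, 100.0) or frac == 100.0


def test_uniform_distribution_window_fraction():
    reads = [
        AlignedRead(f"r{i}", ((100 + i, 300),), has_5prime_adapter=True)
        for i in range(20)
    ]
    cas = CassetteModel("cas", 400, intended_tss=100)
    dist = tss_distribution(reads, cas)
    start, frac = window_fraction(dist, width=10)
    assert frac == 50.0
    assert start == 100     # leftmost tie


def test_polya_distribution_uses_last_block_end(small_cassette):
    reads = [
        AlignedRead("j", ((900, 1000), (1050, 1100)), has_3prime_adapter=True),
        AlignedRead("p", ((950, 1160),), has_3prime_adapter=True),
        AlignedRead("p2", ((950, 1160),), has_3prime_adapter=True),
        AlignedRead("no_tag", ((950, 1160),)),
    ]
    dist = polya_distribution(reads, small_cassette)
    assert dist.counts == {1100: 1, 1160: 2}
    assert dist.dominant_site == 1160


def test_distribution_requires_informative_reads(small_cassette):
    with pytest.raises(ValueError, match="informative"):
        tss_distribution([AlignedRead("r", ((1, 50),))], small_cassette)


def test_readthrough_percent_ddct():
    rows = []
    # five samples with known fold differences; two normalizers
    truth = {}
    for i, delta in enumerate([0.0, 2.0, -1.0, 3.321928, 0.5]):
        sid = f"s{i}"
        rows += [
            {"sample_id": sid, "target": "GUS", "ct": 20.0},
            {"sample_id": sid, "target": "READTHROUGH", "ct": 20.0 + delta},
            {"sample_id": sid, "target": "NORMALIZER_ef1a", "ct": 18.0},
            {"sample_id": sid, "target": "NORMALIZER_ubq", "ct": 19.0},
        ]
        truth[sid] = 100.0 * 2.0 ** (-delta)
    out = readthrough_percent(pd.DataFrame(rows)).set_index("sample_id")
    for sid, want in truth.items():
        assert out.loc[sid, "pct_readthrough"] == pytest.approx(want, rel=1e-6)
    assert out.loc["s0", "pct_readthrough"] == pytest.approx(100.0)
    assert out.loc["s1", "pct_readthrough"] == pytest.approx(25.0)


def test_readthrough_missing_target_is_hard_error():
    df = pd.DataFrame([
        {"sample_id": "s", "target": "GUS", "ct": 20.0},
        {"sample_id": "s", "target": "NORMALIZER_1", "ct": 18.0},
    ])
    with pytest.raises(ValueError, match="READTHROUGH"):
        readthrough_percent(df)
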