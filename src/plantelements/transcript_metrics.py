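"""Transcript-level characterization of an expression cassette from
aligned reads: splice-junction usage accounting, TSS and polyadenylation
site distributions from adapter-tagged reads, and qPCR read-through.

Coordinate conventions (all 1-based on the cassette, whose promoter
5'-most base is position 1):

* a junction is keyed (donor, acceptor) where the donor is the first
  intronic base and the acceptor the last intronic base of the gap a
  spliced read spans;
* an unspliced ("exon-intron junction") read at a splice site is one
  whose single aligned block contiguously covers the two bases flanking
  the boundary; reads ending exactly at the boundary are uninformative;
* percentages at an intended splice position use as denominator all
  reads informative at that position: expected + unspliced + unexpected
  junctions sharing that position. Junctions touching neither intended
  position appear in the report but enter no denominator.

Report percentages are rounded half-up to one decimal (site
distributions to two); unrounded values are retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

DEFAULT_ADAPTER_TAG = "XA"
DEFAULT_MIN_MAPQ = 1


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding as used in printed report tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CassetteModel:
    """Ordered cassette parts with intended transcription landmarks."""

    cassette_id: str
    length: int
    parts: list[tuple[str, int, int]] = field(default_factory=list)
    intended_tss: int = 1
    intended_junctions: list[tuple[int, int]] = field(default_factory=list)
    intended_polya_sites: list[int] = field(default_factory=list)

    def __post_init__(self):
        for p5, p3 in self.intended_junctions:
            if not (1 <= p5 < p3 <= self.length):
                raise ValueError(f"bad intended junction ({p5},{p3})")
        for coord in [self.intended_tss, *self.intended_polya_sites]:
            if not (1 <= coord <= self.length):
                raise ValueError(f"coordinate {coord} outside cassette")


@dataclass(frozen=True)
class AlignedRead:
    read_id: str
    blocks: tuple[tuple[int, int], ...]   # 1-based inclusive, sorted
    has_5prime_adapter: bool = False
    has_3prime_adapter: bool = False
    unique: bool = True

    def __post_init__(self):
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 <= e1 + 1:
                raise ValueError(f"{self.read_id}: blocks overlap or have no gap")

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """(donor, acceptor) for each gap between consecutive blocks."""
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:])
        ]

    def covers_contiguously(self, pos1: int, pos2: int) -> bool:
        """True if one aligned block covers both positions."""
        return any(s <= pos1 and pos2 <= e for s, e in self.blocks)


def parse_alignments(
    sam_source,
    cassette: CassetteModel,
    adapter_tag: str = DEFAULT_ADAPTER_TAG,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    assume_all_5prime: bool = False,
    assume_all_3prime: bool = False,
) -> list[AlignedRead]:
    """Read a SAM file (or list of files, pooled) into AlignedReads.

    CIGAR semantics: M/=/X and D consume reference within a block, N
    opens a junction gap, I/S/H do not consume reference. Reads that are
    unmapped, secondary, supplementary, or below ``min_mapq`` are
    excluded (the unique-mapping criterion). Adapter provenance comes
    from the configurable SAM tag (values '5', '3', or '53'), unless one
    of the assume-all escape hatches is set for pre-filtered inputs.
    """
    if isinstance(sam_source, (list, tuple)):
        sources = list(sam_source)
    else:
        sources = [sam_source]
    reads: list[AlignedRead] = []
    for src in sources:
        with pysam.AlignmentFile(str(src), "r", check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                if aln.mapping_quality < min_mapq:
                    continue
                if aln.reference_name != cassette.cassette_id:
                    raise ValueError(
                        f"read {aln.query_name} aligned to unknown reference "
                        f"{aln.reference_name!r} (expected {cassette.cassette_id!r})"
                    )
                blocks = _blocks_from_cigar(aln)
                tag = ""
                if aln.has_tag(adapter_tag):
                    tag = str(aln.get_tag(adapter_tag))
                reads.append(
                    AlignedRead(
                        read_id=aln.query_name,
                        blocks=blocks,
                        has_5prime_adapter=assume_all_5prime or "5" in tag,
                        has_3prime_adapter=assume_all_3prime or "3" in tag,
                        unique=True,
                    )
                )
    return reads


def _blocks_from_cigar(aln) -> tuple[tuple[int, int], ...]:
    pos = aln.reference_start + 1        # to 1-based
    blocks: list[tuple[int, int]] = []
    start = pos
    consumed = 0
    for op, length in aln.cigartuples:
        if op in (0, 7, 8, 2):           # M, =, X, D consume reference in-block
            consumed += length
        elif op == 3:                    # N: close the block, open a gap
            if consumed:
                blocks.append((start, start + consumed - 1))
            start = start + consumed + length
            consumed = 0
        elif op in (1, 4, 5, 6):         # I, S, H, P: no reference
            continue
        else:
            raise ValueError(f"read {aln.query_name}: unsupported CIGAR op {op}")
    if consumed:
        blocks.append((start, start + consumed - 1))
    return tuple(blocks)


def extract_junctions(reads: Iterable[AlignedRead]) -> dict[tuple[int, int], int]:
    """Tally (donor, acceptor) junction usage; multi-gap reads contribute
    one count per gap."""
    table: dict[tuple[int, int], int] = {}
    for read in reads:
        for key in read.junctions:
            table[key] = table.get(key, 0) + 1
    return table


# ------------------------------------------------------- splice usage

@dataclass
class JunctionUsage:
    """Per-intended-junction accounting mirroring the printed read table."""

    intended: tuple[int, int]
    expected_count: int
    unspliced5_count: int
    unspliced3_count: int
    unexpected_5: dict[tuple[int, int], int]   # share the intended donor
    unexpected_3: dict[tuple[int, int], int]   # share the intended acceptor
    denominator_5: int = 0
    denominator_3: int = 0

    def __post_init__(self):
        self.denominator_5 = (
            self.expected_count + self.unspliced5_count + sum(self.unexpected_5.values())
        )
        self.denominator_3 = (
            self.expected_count + self.unspliced3_count + sum(self.unexpected_3.values())
        )

    def _pct(self, count: int, denom: int) -> float | None:
        if denom == 0:
            return None
        return round_half_up(100.0 * count / denom, 1)

    @property
    def pct_expected_5(self) -> float | None:
        return self._pct(self.expected_count, self.denominator_5)

    @property
    def pct_expected_3(self) -> float | None:
        return self._pct(self.expected_count, self.denominator_3)

    @property
    def pct_unspliced_5(self) -> float | None:
        return self._pct(self.unspliced5_count, self.denominator_5)

    @property
    def pct_unspliced_3(self) -> float | None:
        return self._pct(self.unspliced3_count, self.denominator_3)

    def pct_unexpected_5(self, junction: tuple[int, int]) -> float | None:
        return self._pct(self.unexpected_5.get(junction, 0), self.denominator_5)

    def pct_unexpected_3(self, junction: tuple[int, int]) -> float | None:
        return self._pct(self.unexpected_3.get(junction, 0), self.denominator_3)


@dataclass
class SpliceUsageReport:
    junctions: list[JunctionUsage]
    other_junctions: dict[tuple[int, int], int]   # touch no intended position

    def usage(self, intended: tuple[int, int]) -> JunctionUsage:
        for u in self.junctions:
            if u.intended == intended:
                return u
        raise KeyError(f"no intended junction {intended}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for u in self.junctions:
            p5, p3 = u.intended
            rows.append({
                "junction_5": p5, "junction_3": p3, "category": "expected",
                "count": u.expected_count,
                "pct_5": u.pct_expected_5, "pct_3": u.pct_expected_3,
            })
            rows.append({
                "junction_5": p5, "junction_3": p3, "category": "unspliced",
                "count": f"{u.unspliced5_count} (5'), {u.unspliced3_count} (3')",
                "pct_5": u.pct_unspliced_5, "pct_3": u.pct_unspliced_3,
            })
            for (d, a), c in sorted(u.unexpected_5.items()):
                rows.append({
                    "junction_5": d, "junction_3": a, "category": "unexpected",
                    "count": c, "pct_5": u.pct_unexpected_5((d, a)), "pct_3": None,
                })
            for (d, a), c in sorted(u.unexpected_3.items()):
                rows.append({
                    "junction_5": d, "junction_3": a, "category": "unexpected",
                    "count": c, "pct_5": None, "pct_3": u.pct_unexpected_3((d, a)),
                })
        for (d, a), c in sorted(self.other_junctions.items()):
            rows.append({
                "junction_5": d, "junction_3": a, "category": "unexpected",
                "count": c, "pct_5": None, "pct_3": None,
            })
        return pd.DataFrame(rows)


def splice_usage_from_counts(
    intended_junctions: Sequence[tuple[int, int]],
    junction_counts: Mapping[tuple[int, int], int],
    unspliced_5: Mapping[int, int] | int,
    unspliced_3: Mapping[int, int] | int,
    min_junction_support: int = 1,
) -> SpliceUsageReport:
    """Build the splice-usage report directly from junction/unspliced
    read counts (as printed in a characterization table).

    ``unspliced_5``/``unspliced_3`` map the intended donor/acceptor
    coordinate to its unspliced read count (a bare int is accepted for
    single-intron cassettes).
    """
    if not intended_junctions:
        raise ValueError("cassette has no intended junctions")
    if isinstance(unspliced_5, int):
        unspliced_5 = {intended_junctions[0][0]: unspliced_5}
    if isinstance(unspliced_3, int):
        unspliced_3 = {intended_junctions[0][1]: unspliced_3}
    junction_counts = {
        k: v for k, v in junction_counts.items() if v >= min_junction_support
    }
    usages = []
    claimed: set[tuple[int, int]] = set()
    for p5, p3 in intended_junctions:
        unexpected_5 = {
            (d, a): c for (d, a), c in junction_counts.items()
            if d == p5 and a != p3
        }
        unexpected_3 = {
            (d, a): c for (d, a), c in junction_counts.items()
            if a == p3 and d != p5
        }
        claimed.add((p5, p3))
        claimed.update(unexpected_5)
        claimed.update(unexpected_3)
        usages.append(
            JunctionUsage(
                intended=(p5, p3),
                expected_count=junction_counts.get((p5, p3), 0),
                unspliced5_count=unspliced_5.get(p5, 0),
                unspliced3_count=unspliced_3.get(p3, 0),
                unexpected_5=unexpected_5,
                unexpected_3=unexpected_3,
            )
        )
    other = {k: v for k, v in junction_counts.items() if k not in claimed}
    return SpliceUsageReport(junctions=usages, other_junctions=other)


def splice_usage(
    reads: Iterable[AlignedRead],
    cassette: CassetteModel,
    junctions: Mapping[tuple[int, int], int] | None = None,
    min_junction_support: int = 1,
) -> SpliceUsageReport:
    """Categorize reads at each intended splice position.

    A read is assigned at the 5' position to the junction it uses if it
    splices at the intended donor; otherwise it counts as unspliced at
    that position if one of its blocks contiguously covers the boundary
    (donor-1, donor). Mirror definitions apply at the 3' position.
    """
    reads = list(reads)
    if junctions is None:
        junctions = extract_junctions(reads)
    unspliced_5: dict[int, int] = {}
    unspliced_3: dict[int, int] = {}
    for p5, p3 in cassette.intended_junctions:
        n5 = n3 = 0
        for read in reads:
            donors = {d for d, _ in read.junctions}
            acceptors = {a for _, a in read.junctions}
            if p5 not in donors and read.covers_contiguously(p5 - 1, p5):
                n5 += 1
            if p3 not in acceptors and read.covers_contiguously(p3, p3 + 1):
                n3 += 1
        unspliced_5[p5] = n5
        unspliced_3[p3] = n3
    return splice_usage_from_counts(
        cassette.intended_junctions, junctions, unspliced_5, unspliced_3,
        min_junction_support=min_junction_support,
    )


# ------------------------------------------------- site distributions

@dataclass
class SiteDistribution:
    kind: str                              # "TSS" or "POLYA"
    total: int
    counts: dict[int, int]
    pct: dict[int, float] = field(default_factory=dict)       # rounded, 2 dp
    raw_pct: dict[int, float] = field(default_factory=dict)   # unrounded

    def __post_init__(self):
        if not self.pct:
            self.raw_pct = {p: 100.0 * c / self.total for p, c in self.counts.items()}
            self.pct = {p: round_half_up(v, 2) for p, v in self.raw_pct.items()}

    @property
    def dominant_site(self) -> int:
        best = max(self.counts.values())
        return min(p for p, c in self.counts.items() if c == best)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"position": p, "count": self.counts[p], "pct": self.pct[p]}
                for p in sorted(self.counts)
            ]
        )


def tss_distribution(reads: Iterable[AlignedRead], cassette: CassetteModel) -> SiteDistribution:
    """TSS usage from 5'-adapter reads: the start site is the first
    aligned base of the first block."""
    counts: dict[int, int] = {}
    for read in reads:
        if not (read.has_5prime_adapter and read.unique):
            continue
        site = read.blocks[0][0]
        counts[site] = counts.get(site, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no informative 5'-adapter reads")
    return SiteDistribution(kind="TSS", total=total, counts=counts)


def polya_distribution(reads: Iterable[AlignedRead], cassette: CassetteModel) -> SiteDistribution:
    """Polyadenylation-site usage from 3'-adapter reads: the site is the
    last aligned base of the last block."""
    counts: dict[int, int] = {}
    for read in reads:
        if not (read.has_3prime_adapter and read.unique):
            continue
        site = read.blocks[-1][1]
        counts[site] = counts.get(site, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no informative 3'-adapter reads")
    return SiteDistribution(kind="POLYA", total=total, counts=counts)


def window_fraction(dist: SiteDistribution, width: int = 10) -> tuple[int, float]:
    """Best contiguous window of ``width`` positions by summed unrounded
    percentage (leftmost on ties). Returns (window_start, fraction_pct)."""
    if width < 1:
        raise ValueError("window width must be >= 1")
    positions = sorted(dist.counts)
    best_start, best_frac = positions[0], -1.0
    for start in range(positions[0], positions[-1] + 1):
        frac = sum(
            dist.raw_pct.get(p, 0.0) for p in range(start, start + width)
        )
        if frac > best_frac + 1e-12:
            best_start, best_frac = start, frac
    return best_start, round_half_up(best_frac, 2)


# ------------------------------------------------------------- qPCR

def readthrough_percent(
    qpcr: pd.DataFrame,
    gus_target: str = "GUS",
    readthrough_target: str = "READTHROUGH",
    normalizer_prefix: str = "NORMALIZER",
) -> pd.DataFrame:
    """Per-sample read-through as a percentage of the main transcript,
    via the 2^-ddCt method.

    dCt(target) = Ct(target) - mean Ct(normalizers);
    %readthrough = 100 * 2^-(dCt(readthrough) - dCt(GUS)). The normalizer
    terms cancel inside a sample but the per-target relative expression
    (2^-dCt) is retained for cross-sample comparison.
    """
    required = {"sample_id", "target", "ct"}
    if not required <= set(qpcr.columns):
        raise ValueError(f"qPCR table must have columns {sorted(required)}")
    if (qpcr["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    rows = []
    for sample_id, grp in qpcr.groupby("sample_id", sort=True):
        ct = dict(zip(grp["target"], grp["ct"].astype(float)))
        norms = [v for t, v in ct.items() if str(t).startswith(normalizer_prefix)]
        for target in (gus_target, readthrough_target):
            if target not in ct:
                raise ValueError(f"sample {sample_id!r}: missing target {target!r}")
        if not norms:
            raise ValueError(f"sample {sample_id!r}: no normalizer targets")
        ref = sum(norms) / len(norms)
        d_gus = ct[gus_target] - ref
        d_rt = ct[readthrough_target] - ref
        rows.append({
            "sample_id": sample_id,
            "rel_expr_gus": 2.0 ** (-d_gus),
            "rel_expr_readthrough": 2.0 ** (-d_rt),
            "pct_readthrough": 100.0 * 2.0 ** (-(d_rt - d_gus)),
        })
    return pd.DataFrame(rows)
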