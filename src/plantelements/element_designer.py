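"""Generative design of synthetic plant expression elements.

Three element classes are produced, each built by sampling bases from a
positional nucleotide profile of the training set, stamping enriched
positional motifs at bin-consistent offsets, writing the class's fixed
structural motifs, and rejection-sampling against hard constraints:

* promoter + 5' UTR leader (~500 bp): a TATA box exactly
  ``tata_to_tss_spacing`` (default 30) bp upstream of the predicted TSS,
  an initiator-like pyrimidine/A dinucleotide at the TSS, and a leader
  with no ATG at or downstream of the TSS;
* intron (~300 bp) with short exonic flanks: canonical GT donor and AG
  acceptor, no donor/acceptor-like sequence in the interior, and at
  least one intron-mediated-enhancement (IME) motif placed inside a
  configurable window;
* 3' UTR terminator (~300 bp): a configurable number of cleavage sites
  (default 2), each an A in a YA dinucleotide with an AATAAA
  near-upstream element (NUE) 10-30 bp upstream, and a T-rich tract
  running up to the distal cleavage site.

Every design is deterministic for a fixed (inputs, seed) pair, and every
design op's output passes :func:`validate_element` by construction; a
rejection budget exhausts with a hard error naming the failing
constraint. The validator is independent of the samplers and never
raises on sequence content: it returns a report listing all violations.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from ._seq import IUPAC_TO_SET, matches_iupac
from .positional_motifs import BASES, PositionalMotif, PositionalProfile

PROMOTER = "PROMOTER"
INTRON = "INTRON"
TERMINATOR = "TERMINATOR"

FEATURE_NAMES = {
    "TATA_BOX", "PREDICTED_TSS", "LEADER", "EXON_FLANK_5", "DONOR_SITE",
    "ACCEPTOR_SITE", "IME_MOTIF", "EXON_FLANK_3", "NUE", "CLEAVAGE_SITE",
    "T_RICH_TRACT",
}

# Acceptor-like interior pattern: CAG preceded by a >=6 nt pyrimidine run.
_ACCEPTOR_LIKE = re.compile(r"[CT]{6}CAG")
_ATG = re.compile(r"(?=ATG)")

DEFAULT_MAX_ATTEMPTS = 1000
_LOCAL_REPAIRS = 10


@dataclass(frozen=True)
class FeatureAnnotation:
    """Named feature at a 0-based half-open interval within an element."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if self.name not in FEATURE_NAMES:
            raise ValueError(f"unknown feature name {self.name!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.name}: bad interval {self.start}..{self.end}")
        if self.name in ("DONOR_SITE", "ACCEPTOR_SITE") and self.end - self.start != 2:
            raise ValueError(f"{self.name} must span exactly 2 bases")
        if self.name == "CLEAVAGE_SITE" and self.end - self.start != 1:
            raise ValueError("CLEAVAGE_SITE must span exactly 1 base")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class PromoterConstraints:
    element_class: str = PROMOTER
    target_length: int = 500
    length_tolerance: int = 0
    tata_pattern: str = "TATAAA"
    tata_to_tss_spacing: int = 30
    leader_length: int = 50
    # Initiator-like dinucleotide: pyrimidine then the TSS base itself (A).
    inr_pattern: str = "YA"


@dataclass
class IntronConstraints:
    element_class: str = INTRON
    target_length: int = 300      # intron proper, excluding exonic flanks
    length_tolerance: int = 0
    flank_length: int = 5
    donor_consensus: str = "GT"
    acceptor_consensus: str = "AG"
    forbidden_internal_patterns: tuple[str, ...] = ("GTAAG",)
    forbid_acceptor_like: bool = True
    # Placeholder motif assembled from published IME-associated sequence
    # composition; supply project-specific motifs in real designs.
    ime_motifs: tuple[str, ...] = ("TTNGATYTG",)
    ime_window: tuple[int, int] = (10, 150)   # offsets within the intron


@dataclass
class TerminatorConstraints:
    element_class: str = TERMINATOR
    target_length: int = 300
    length_tolerance: int = 0
    n_polya_sites: int = 2
    nue_pattern: str = "AATAAA"
    nue_to_cleavage_spacing: tuple[int, int] = (10, 30)
    t_tract_min_run: int = 8
    site_spacing: int = 60        # distance between consecutive cleavage sites
    distal_offset_from_end: int = 40


DesignConstraints = PromoterConstraints | IntronConstraints | TerminatorConstraints


@dataclass
class DesignedElement:
    element_id: str
    element_class: str
    sequence: str
    features: list[FeatureAnnotation]
    provenance: dict = field(default_factory=dict)

    def feature(self, name: str) -> FeatureAnnotation:
        hits = [f for f in self.features if f.name == name]
        if not hits:
            raise KeyError(f"element has no {name} feature")
        return hits[0]

    def features_named(self, name: str) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.name == name]


@dataclass
class ConstraintReport:
    violations: list[tuple[str, tuple[int, int], str]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def add(self, name: str, interval: tuple[int, int], message: str) -> None:
        self.violations.append((name, interval, message))


# ------------------------------------------------------------ sampling

def _profile_columns(profile: PositionalProfile | None, n: int, anchor_at: int | None) -> np.ndarray:
    """Slice (or synthesize) ``n`` per-offset base distributions.

    If the profile carries an anchor, the element offset ``anchor_at`` is
    aligned to it; otherwise the slice is right-aligned. With no profile,
    or one too short, the column-averaged composition is tiled.
    """
    if profile is None:
        return np.full((n, 4), 0.25)
    mat = profile.matrix
    if mat.shape[0] >= n:
        if profile.anchor_offset is not None and anchor_at is not None:
            start = profile.anchor_offset - anchor_at
            start = min(max(start, 0), mat.shape[0] - n)
        else:
            start = mat.shape[0] - n
        return mat[start:start + n]
    mean = mat.mean(axis=0)
    return np.tile(mean / mean.sum(), (n, 1))


def _sample_bases(cols: np.ndarray, rng: np.random.Generator) -> list[str]:
    cum = np.cumsum(cols, axis=1)
    u = rng.random(cols.shape[0])
    idx = (u[:, None] > cum).sum(axis=1)
    return [BASES[i] for i in idx]


def _realize_iupac(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        sorted(IUPAC_TO_SET[c])[int(rng.integers(len(IUPAC_TO_SET[c])))]
        for c in consensus
    )


def _stamp_motifs(
    seq: list[str], locked: np.ndarray, motifs: Sequence[PositionalMotif],
    offset_shift: int, rng: np.random.Generator,
) -> None:
    """Write enriched motifs at bin-consistent element offsets.

    ``offset_shift`` maps training-window offsets to element offsets
    (element = window - shift). Motifs falling outside the element or
    onto locked positions are skipped.
    """
    n = len(seq)
    for motif in motifs:
        lo = motif.bin[0] - offset_shift
        hi = motif.bin[1] - offset_shift - 1     # word start stays inside the bin
        lo = max(lo, 0)
        hi = min(hi, n - len(motif.consensus))
        if hi < lo:
            continue
        pos = lo if hi == lo else int(rng.integers(lo, hi + 1))
        if locked[pos:pos + len(motif.consensus)].any():
            continue
        word = _realize_iupac(motif.consensus, rng)
        seq[pos:pos + len(word)] = list(word)
        locked[pos:pos + len(word)] = True


def _write(seq: list[str], locked: np.ndarray, pos: int, text: str) -> None:
    seq[pos:pos + len(text)] = list(text)
    locked[pos:pos + len(text)] = True


def _constraints_hash(constraints) -> str:
    return hashlib.sha1(repr(asdict(constraints)).encode()).hexdigest()[:12]


def _provenance(constraints, seed: int, attempts: int, profile, motifs) -> dict:
    return {
        "seed": seed,
        "attempts": attempts,
        "constraints_hash": _constraints_hash(constraints),
        "profile_length": None if profile is None else profile.length,
        "n_motifs": 0 if motifs is None else len(motifs),
    }


# ------------------------------------------------------------ designers

def design_promoter(
    profile: PositionalProfile | None,
    motifs: Sequence[PositionalMotif] | None,
    constraints: PromoterConstraints | None = None,
    seed: int = 0,
    element_id: str = "promoter",
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
) -> DesignedElement:
    """Sample a promoter + leader element satisfying the hard constraints.

    Layout 5'->3': profile-sampled upstream region with motif stamps, the
    TATA box, exactly ``tata_to_tss_spacing`` bases, the predicted TSS
    carrying the initiator-like dinucleotide, and an ATG-free leader of
    ``leader_length`` ending the element.
    """
    c = constraints or PromoterConstraints()
    L = c.target_length
    tss = L - c.leader_length
    tata_start = tss - c.tata_to_tss_spacing - len(c.tata_pattern)
    if tata_start < 0:
        raise ValueError("target length too short for TATA/TSS/leader layout")
    rng = np.random.default_rng(seed)
    cols = _profile_columns(profile, L, anchor_at=tss)
    failure = "sampling"
    for attempt in range(1, max_attempts + 1):
        seq = _sample_bases(cols, rng)
        locked = np.zeros(L, dtype=bool)
        _write(seq, locked, tata_start, c.tata_pattern)
        inr = _realize_iupac(c.inr_pattern, rng)
        _write(seq, locked, tss - (len(c.inr_pattern) - 1), inr)
        if motifs and profile is not None and profile.anchor_offset is not None:
            _stamp_motifs(seq, locked, motifs, profile.anchor_offset - tss, rng)
        ok = _repair_atg_free(seq, locked, tss, cols, rng)
        if not ok:
            failure = "ATG_FREE_LEADER"
            continue
        features = [
            FeatureAnnotation("TATA_BOX", tata_start, tata_start + len(c.tata_pattern)),
            FeatureAnnotation("PREDICTED_TSS", tss, tss + 1),
            FeatureAnnotation("LEADER", tss, L),
        ]
        element = DesignedElement(
            element_id=element_id, element_class=PROMOTER,
            sequence="".join(seq), features=features,
            provenance=_provenance(c, seed, attempt, profile, motifs),
        )
        report = validate_element(element.sequence, element.features, c)
        if report.passed:
            return element
        failure = report.violations[0][0]
    raise RuntimeError(
        f"promoter design failed after {max_attempts} attempts "
        f"(unsatisfiable constraint: {failure})"
    )


def _repair_atg_free(
    seq: list[str], locked: np.ndarray, tss: int,
    cols: np.ndarray, rng: np.random.Generator,
) -> bool:
    """Locally resample until no ATG starts at or downstream of the TSS."""
    for _ in range(_LOCAL_REPAIRS):
        text = "".join(seq)
        hits = [m.start() for m in _ATG.finditer(text, max(tss - 2, 0)) if m.start() >= tss]
        hits = [h for h in hits if h >= tss]
        if not hits:
            return True
        for h in hits:
            free = [i for i in range(h, min(h + 3, len(seq))) if not locked[i]]
            if not free:
                return False
            i = free[int(rng.integers(len(free)))]
            forbidden = "ATG"[i - h]
            probs = cols[i].copy()
            probs[BASES.index(forbidden)] = 0.0
            if probs.sum() <= 0:
                probs = np.array([b != forbidden for b in BASES], dtype=float)
            probs = probs / probs.sum()
            seq[i] = BASES[int((rng.random() > np.cumsum(probs)).sum())]
    return not any(
        m.start() >= tss for m in _ATG.finditer("".join(seq))
    )


def design_intron(
    profile: PositionalProfile | None,
    motifs: Sequence[PositionalMotif] | None,
    constraints: IntronConstraints | None = None,
    seed: int = 0,
    element_id: str = "intron",
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
) -> DesignedElement:
    """Sample an intron with exonic flanks: GT..AG boundaries, a clean
    interior (no donor/acceptor-like patterns), and >=1 IME motif."""
    c = constraints or IntronConstraints()
    L = c.target_length + 2 * c.flank_length
    donor = c.flank_length                       # first intronic base
    acceptor = c.flank_length + c.target_length - 1   # last intronic base
    if not c.ime_motifs:
        raise ValueError("at least one IME motif is required")
    ime = max(c.ime_motifs, key=len)
    win_lo = max(c.ime_window[0], len(c.donor_consensus))
    win_hi = min(c.ime_window[1], c.target_length - len(c.acceptor_consensus) - len(ime))
    if win_hi < win_lo:
        raise ValueError("IME placement window does not fit inside the intron")
    rng = np.random.default_rng(seed)
    cols = _profile_columns(profile, L, anchor_at=donor)
    failure = "sampling"
    for attempt in range(1, max_attempts + 1):
        seq = _sample_bases(cols, rng)
        locked = np.zeros(L, dtype=bool)
        _write(seq, locked, donor, c.donor_consensus)
        _write(seq, locked, acceptor - 1, c.acceptor_consensus)
        ime_pos = donor + int(rng.integers(win_lo, win_hi + 1))
        ime_word = _realize_iupac(ime, rng)
        _write(seq, locked, ime_pos, ime_word)
        if motifs and profile is not None:
            _stamp_motifs(seq, locked, motifs, 0, rng)
        if not _repair_forbidden(seq, locked, donor, acceptor, c, cols, rng):
            failure = "FORBIDDEN_INTERNAL"
            continue
        features = [
            FeatureAnnotation("EXON_FLANK_5", 0, c.flank_length),
            FeatureAnnotation("DONOR_SITE", donor, donor + 2),
            FeatureAnnotation("IME_MOTIF", ime_pos, ime_pos + len(ime_word)),
            FeatureAnnotation("ACCEPTOR_SITE", acceptor - 1, acceptor + 1),
            FeatureAnnotation("EXON_FLANK_3", acceptor + 1, L),
        ]
        element = DesignedElement(
            element_id=element_id, element_class=INTRON,
            sequence="".join(seq), features=features,
            provenance=_provenance(c, seed, attempt, profile, motifs),
        )
        report = validate_element(element.sequence, element.features, c)
        if report.passed:
            return element
        failure = report.violations[0][0]
    raise RuntimeError(
        f"intron design failed after {max_attempts} attempts "
        f"(unsatisfiable constraint: {failure})"
    )


def _interior_matches(seq_text: str, donor: int, acceptor: int, c: IntronConstraints):
    """Occurrences of forbidden patterns strictly between the splice sites."""
    interior_lo = donor + len(c.donor_consensus)
    interior_hi = acceptor + 1 - len(c.acceptor_consensus)
    region = seq_text[interior_lo:interior_hi]
    hits = []
    for pat in c.forbidden_internal_patterns:
        start = 0
        while True:
            i = region.find(pat, start)
            if i < 0:
                break
            hits.append((interior_lo + i, interior_lo + i + len(pat), pat))
            start = i + 1
    if c.forbid_acceptor_like:
        for m in _ACCEPTOR_LIKE.finditer(region):
            hits.append((interior_lo + m.start(), interior_lo + m.end(), "acceptor-like"))
    return hits


def _repair_forbidden(
    seq: list[str], locked: np.ndarray, donor: int, acceptor: int,
    c: IntronConstraints, cols: np.ndarray, rng: np.random.Generator,
) -> bool:
    for _ in range(_LOCAL_REPAIRS):
        hits = _interior_matches("".join(seq), donor, acceptor, c)
        if not hits:
            return True
        for lo, hi, _pat in hits:
            free = [i for i in range(lo, hi) if not locked[i]]
            if not free:
                return False
            i = free[int(rng.integers(len(free)))]
            probs = cols[i].copy()
            probs[BASES.index(seq[i])] = 0.0
            if probs.sum() <= 0:
                probs = np.array([b != seq[i] for b in BASES], dtype=float)
            probs = probs / probs.sum()
            seq[i] = BASES[int((rng.random() > np.cumsum(probs)).sum())]
    return not _interior_matches("".join(seq), donor, acceptor, c)


def design_terminator(
    profile: PositionalProfile | None,
    motifs: Sequence[PositionalMotif] | None,
    constraints: TerminatorConstraints | None = None,
    seed: int = 0,
    element_id: str = "terminator",
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
) -> DesignedElement:
    """Sample a 3' UTR terminator with ``n_polya_sites`` cleavage sites.

    Each cleavage site is an A in a YA dinucleotide with an AATAAA NUE
    ending 10-30 bp upstream; a T-rich tract of at least
    ``t_tract_min_run`` T's runs up to the distal (last) site.
    """
    c = constraints or TerminatorConstraints()
    L = c.target_length
    distal = L - 1 - c.distal_offset_from_end
    sites = [distal - i * c.site_spacing for i in range(c.n_polya_sites)][::-1]
    lo_sp, hi_sp = c.nue_to_cleavage_spacing
    nue_len = len(c.nue_pattern)
    if sites[0] - hi_sp - nue_len < 0:
        raise ValueError("target length too short for the polyA site layout")
    if c.site_spacing <= hi_sp + nue_len:
        raise ValueError("cleavage sites too close for independent NUEs")
    rng = np.random.default_rng(seed)
    cols = _profile_columns(profile, L, anchor_at=distal)
    failure = "sampling"
    for attempt in range(1, max_attempts + 1):
        seq = _sample_bases(cols, rng)
        locked = np.zeros(L, dtype=bool)
        features: list[FeatureAnnotation] = []
        for site in sites:
            is_distal = site == sites[-1]
            if is_distal:
                run = c.t_tract_min_run
                _write(seq, locked, site - run, "T" * run)
                features.append(FeatureAnnotation("T_RICH_TRACT", site - run, site))
            else:
                _write(seq, locked, site - 1, "CT"[int(rng.integers(2))])
            _write(seq, locked, site, "A")
            spacing = int(rng.integers(lo_sp, hi_sp + 1))
            nue_start = site - spacing - nue_len
            _write(seq, locked, nue_start, c.nue_pattern)
            features.append(FeatureAnnotation("NUE", nue_start, nue_start + nue_len))
            features.append(FeatureAnnotation("CLEAVAGE_SITE", site, site + 1))
        if motifs and profile is not None and profile.anchor_offset is not None:
            _stamp_motifs(seq, locked, motifs, profile.anchor_offset - distal, rng)
        element = DesignedElement(
            element_id=element_id, element_class=TERMINATOR,
            sequence="".join(seq), features=features,
            provenance=_provenance(c, seed, attempt, profile, motifs),
        )
        report = validate_element(element.sequence, element.features, c)
        if report.passed:
            return element
        failure = report.violations[0][0]
    raise RuntimeError(
        f"terminator design failed after {max_attempts} attempts "
        f"(unsatisfiable constraint: {failure})"
    )


# ------------------------------------------------------------ validation

def validate_element(
    sequence: str,
    features: Iterable[FeatureAnnotation],
    constraints: DesignConstraints,
) -> ConstraintReport:
    """Check a sequence + feature annotation against its class constraints.

    Validation never raises on content; every violated constraint is
    reported with the offending interval.
    """
    report = ConstraintReport()
    features = list(features)
    n = len(sequence)
    bad = set(sequence) - set("ACGT")
    if bad:
        report.add("ALPHABET", (0, n), f"unsupported characters {sorted(bad)}")
        return report
    for f in features:
        if f.end > n:
            report.add("FEATURE_BOUNDS", f.interval, f"{f.name} outside element")
            return report

    def named(name):
        return [f for f in features if f.name == name]

    cls = constraints.element_class
    if cls == PROMOTER:
        c: PromoterConstraints = constraints
        expected = c.target_length
        if abs(n - expected) > c.length_tolerance:
            report.add("LENGTH", (0, n), f"length {n} outside {expected}±{c.length_tolerance}")
        tatas, tsss, leaders = named("TATA_BOX"), named("PREDICTED_TSS"), named("LEADER")
        if not (tatas and tsss and leaders):
            report.add("STRUCTURE", (0, n), "TATA_BOX, PREDICTED_TSS and LEADER required")
            return report
        tata, tss, leader = tatas[0], tsss[0], leaders[0]
        if sequence[tata.start:tata.end] != c.tata_pattern:
            report.add("TATA_PATTERN", tata.interval, "TATA box sequence mismatch")
        if tss.start - tata.end != c.tata_to_tss_spacing:
            report.add(
                "TATA_TSS_SPACING", (tata.end, tss.start),
                f"spacing {tss.start - tata.end} != {c.tata_to_tss_spacing}",
            )
        inr_start = tss.start - (len(c.inr_pattern) - 1)
        if inr_start < 0 or not matches_iupac(
            sequence[inr_start:inr_start + len(c.inr_pattern)], c.inr_pattern
        ):
            report.add("INR_PATTERN", (max(inr_start, 0), tss.end), "initiator-like pattern absent at TSS")
        if leader.end - leader.start != c.leader_length:
            report.add("LEADER_LENGTH", leader.interval, "leader length mismatch")
        for m in _ATG.finditer(sequence):
            if m.start() >= tss.start:
                report.add("ATG_FREE_LEADER", (m.start(), m.start() + 3), "ATG at/after predicted TSS")
    elif cls == INTRON:
        ci: IntronConstraints = constraints
        expected = ci.target_length + 2 * ci.flank_length
        if abs(n - expected) > ci.length_tolerance:
            report.add("LENGTH", (0, n), f"length {n} outside {expected}±{ci.length_tolerance}")
        donors, acceptors = named("DONOR_SITE"), named("ACCEPTOR_SITE")
        if not (donors and acceptors):
            report.add("STRUCTURE", (0, n), "DONOR_SITE and ACCEPTOR_SITE required")
            return report
        donor, acceptor = donors[0], acceptors[0]
        if sequence[donor.start:donor.end] != ci.donor_consensus:
            report.add("DONOR_CONSENSUS", donor.interval, f"donor is not {ci.donor_consensus}")
        if sequence[acceptor.start:acceptor.end] != ci.acceptor_consensus:
            report.add("ACCEPTOR_CONSENSUS", acceptor.interval, f"acceptor is not {ci.acceptor_consensus}")
        for lo, hi, pat in _interior_matches(sequence, donor.start, acceptor.end - 1, ci):
            report.add("FORBIDDEN_INTERNAL", (lo, hi), f"forbidden pattern {pat} inside intron")
        imes = named("IME_MOTIF")
        in_window = [
            f for f in imes
            if ci.ime_window[0] <= f.start - donor.start
            and f.end - donor.start <= ci.ime_window[1] + max(len(m) for m in ci.ime_motifs)
        ]
        ok_ime = any(
            any(matches_iupac(sequence[f.start:f.end], m) for m in ci.ime_motifs)
            for f in in_window
        )
        if not ok_ime:
            report.add("IME_PRESENT", (donor.start, acceptor.end), "no IME motif inside placement window")
    elif cls == TERMINATOR:
        ct: TerminatorConstraints = constraints
        if abs(n - ct.target_length) > ct.length_tolerance:
            report.add("LENGTH", (0, n), f"length {n} outside {ct.target_length}±{ct.length_tolerance}")
        sites = sorted(named("CLEAVAGE_SITE"), key=lambda f: f.start)
        if len(sites) != ct.n_polya_sites:
            report.add("N_POLYA_SITES", (0, n), f"{len(sites)} cleavage sites != {ct.n_polya_sites}")
        lo_sp, hi_sp = ct.nue_to_cleavage_spacing
        nues = named("NUE")
        for site in sites:
            s = site.start
            if sequence[s] != "A" or s == 0 or sequence[s - 1] not in "CT":
                report.add("CLEAVAGE_YA", (max(s - 1, 0), s + 1), "cleavage site is not a YA dinucleotide")
            matched = False
            for nue in nues:
                if sequence[nue.start:nue.end] != ct.nue_pattern:
                    continue
                gap = s - nue.end
                if lo_sp <= gap <= hi_sp:
                    matched = True
                    break
            if not matched:
                report.add(
                    "NUE_SPACING", (s, s + 1),
                    f"no {ct.nue_pattern} ending {lo_sp}-{hi_sp} bp upstream of cleavage site",
                )
        if sites:
            distal = sites[-1].start
            run = 0
            i = distal - 1
            while i >= 0 and sequence[i] == "T":
                run += 1
                i -= 1
            if run < ct.t_tract_min_run:
                report.add(
                    "T_RICH_TRACT", (max(distal - run, 0), distal),
                    f"T-run of {run} < {ct.t_tract_min_run} adjoining the distal site",
                )
    else:
        report.add("ELEMENT_CLASS", (0, n), f"unknown element class {cls!r}")
    return report
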