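"""Small shared DNA-sequence helpers.

All sequences in this package are upper-case strings over {A,C,G,T,N}.
Ambiguity codes other than N are rejected at the I/O boundary.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")
UNAMBIGUOUS = frozenset("ACGT")

# IUPAC nucleotide codes keyed by the sorted base set they stand for.
_SET_TO_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R",
    frozenset("AT"): "W", frozenset("CG"): "S",
    frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}
IUPAC_TO_SET = {code: set(bases) for bases, code in _SET_TO_IUPAC.items()}


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_alphabet(seq: str, where: str = "sequence") -> None:
    """Hard error on any character outside {A,C,G,T,N}."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(
            f"{where} contains unsupported characters {sorted(bad)}; "
            "only A/C/G/T/N are accepted"
        )


def iupac_union(bases) -> str:
    """IUPAC code covering a set of concrete bases, e.g. {A,T} -> W."""
    key = frozenset(bases)
    if key not in _SET_TO_IUPAC:
        raise ValueError(f"not a valid base set: {sorted(key)}")
    return _SET_TO_IUPAC[key]


def matches_iupac(word: str, consensus: str) -> bool:
    """True if every base of ``word`` is covered by the IUPAC ``consensus``."""
    if len(word) != len(consensus):
        return False
    return all(b in IUPAC_TO_SET[c] for b, c in zip(word, consensus))
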