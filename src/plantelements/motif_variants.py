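"""Motif knockouts by transversion of annotated feature intervals.

Key functional motifs (TATA box, splice sites, IME motifs, NUE, T-rich
tracts) are ablated by replacing every base of the named feature interval
with its transversion partner under the involutive map A<->C, G<->T.
This pairing maps AT-rich motifs to GC-rich sequence (TATAAA -> GCGCCC),
mirroring how TATA boxes are replaced with GC-rich sequence in knockout
promoter variants, and applying the map twice restores the original.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .element_designer import DesignedElement

_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}
_TRANS_TABLE = str.maketrans(_TRANSVERSION)


@dataclass(frozen=True)
class TransversionEdit:
    feature_name: str
    interval: tuple[int, int]     # 0-based half-open
    before: str
    after: str


def transversion_map(base: str) -> str:
    """Involutive transversion of a single base: A<->C, G<->T."""
    if base not in _TRANSVERSION:
        raise ValueError(f"cannot transvert base {base!r}; expected one of A/C/G/T")
    return _TRANSVERSION[base]


def transvert(seq: str) -> str:
    """Transvert every base of a sequence."""
    for b in set(seq) - set("ACGT"):
        raise ValueError(f"cannot transvert base {b!r}; expected one of A/C/G/T")
    return seq.translate(_TRANS_TABLE)


def make_variant(
    element: DesignedElement, feature_names: set[str] | list[str]
) -> tuple[DesignedElement, list[TransversionEdit]]:
    """Knock out the named features of an element by transversion.

    Exactly the named features' intervals are rewritten; all other bases
    are untouched and the length is unchanged. The variant's id is the
    original id suffixed with the joined feature names. Unknown feature
    names are a hard error listing what is available.
    """
    available = {f.name for f in element.features}
    requested = sorted(set(feature_names))
    unknown = [n for n in requested if n not in available]
    if unknown:
        raise KeyError(
            f"unknown feature(s) {unknown}; element has {sorted(available)}"
        )
    seq = list(element.sequence)
    edits: list[TransversionEdit] = []
    for feat in element.features:
        if feat.name not in requested:
            continue
        before = element.sequence[feat.start:feat.end]
        after = transvert(before)
        seq[feat.start:feat.end] = list(after)
        edits.append(
            TransversionEdit(
                feature_name=feat.name, interval=feat.interval,
                before=before, after=after,
            )
        )
    variant = replace(
        element,
        element_id=element.element_id + "_" + "_".join(requested),
        sequence="".join(seq),
        provenance={**element.provenance, "variant_of": element.element_id,
                    "knocked_out": requested},
    )
    return variant, edits
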