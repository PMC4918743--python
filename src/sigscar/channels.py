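"""The 96-class substitution-in-context alphabet.

Every single-base substitution is reported on the pyrimidine strand: the six
substitution classes C>A, C>G, C>T, T>A, T>C and T>G, combined with the bases
immediately 5' and 3' of the mutated base, give 96 mutation channels.
Purine-referenced representations are reverse-complemented (ref and alt
complemented, flanks complemented and swapped) so each channel is reachable
from exactly two strand representations.

Channel ordering follows the COSMIC convention: substitution classes in the
order above, then 5' flank, then 3' flank, each A,C,G,T.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTION_CLASSES = (
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
)


class ParseError(ValueError):
    """A field of a variant or channel failed validation."""


@dataclass(frozen=True, order=True)
class MutationChannel:
    """One of the 96 pyrimidine-centric substitution-in-context classes."""

    ref: str
    alt: str
    flank5: str
    flank3: str

    def __post_init__(self) -> None:
        if self.ref not in PYRIMIDINES:
            raise ParseError(f"channel ref must be a pyrimidine, got {self.ref!r}")
        for field in ("alt", "flank5", "flank3"):
            value = getattr(self, field)
            if value not in BASES:
                raise ParseError(f"channel {field} must be one of A/C/G/T, got {value!r}")
        if self.alt == self.ref:
            raise ParseError(f"channel alt equals ref ({self.ref!r})")

    @property
    def label(self) -> str:
        return f"{self.flank5}[{self.ref}>{self.alt}]{self.flank3}"

    @property
    def trinucleotide(self) -> str:
        """Pyrimidine-centric trinucleotide context (5' flank, ref, 3' flank)."""
        return self.flank5 + self.ref + self.flank3

    @classmethod
    def from_label(cls, label: str) -> "MutationChannel":
        if len(label) != 7 or label[1] != "[" or label[3] != ">" or label[5] != "]":
            raise ParseError(f"malformed channel label {label!r}")
        return cls(ref=label[2], alt=label[4], flank5=label[0], flank3=label[6])


def classify_substitution(ref: str, alt: str, flank5: str, flank3: str) -> MutationChannel:
    """Map a raw substitution with context onto its pyrimidine-strand channel.

    If ``ref`` is a purine the whole local context is reverse-complemented:
    ref and alt are complemented and the flanks are complemented and swapped.

    Raises
    ------
    ParseError
        If any argument is not a single A/C/G/T base, or ref == alt.
    """
    for name, value in (("ref", ref), ("alt", alt), ("flank5", flank5), ("flank3", flank3)):
        if value not in BASES:
            raise ParseError(f"{name} must be a single A/C/G/T base, got {value!r}")
    if ref == alt:
        raise ParseError(f"ref and alt are identical ({ref!r})")
    if ref in PYRIMIDINES:
        return MutationChannel(ref=ref, alt=alt, flank5=flank5, flank3=flank3)
    return MutationChannel(
        ref=COMPLEMENT[ref],
        alt=COMPLEMENT[alt],
        flank5=COMPLEMENT[flank3],
        flank3=COMPLEMENT[flank5],
    )


def _build_channels() -> tuple[MutationChannel, ...]:
    return tuple(
        MutationChannel(ref=ref, alt=alt, flank5=f5, flank3=f3)
        for (ref, alt) in SUBSTITUTION_CLASSES
        for f5, f3 in product(BASES, BASES)
    )


#: The 96 channels in canonical (COSMIC) order.
CHANNELS: tuple[MutationChannel, ...] = _build_channels()

#: Canonical labels, e.g. "A[C>A]A", in channel order.
CHANNEL_LABELS: tuple[str, ...] = tuple(c.label for c in CHANNELS)

#: Label -> index in canonical order.
CHANNEL_INDEX: dict[str, int] = {c.label: i for i, c in enumerate(CHANNELS)}

#: The 32 pyrimidine-centric trinucleotides, in first-appearance channel order.
PYRIMIDINE_TRINUCLEOTIDES: tuple[str, ...] = tuple(
    dict.fromkeys(c.trinucleotide for c in CHANNELS)
)


def channel_index(ref: str, alt: str, flank5: str, flank3: str) -> int:
    """Canonical index of the channel for a raw substitution with context."""
    return CHANNEL_INDEX[classify_substitution(ref, alt, flank5, flank3).label]


def reverse_complement(seq: str) -> str:
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ParseError(f"non-ACGT base {exc.args[0]!r} in sequence {seq!r}") from None


def collapse_trinucleotide(trinuc: str) -> str:
    """Collapse a raw trinucleotide to its pyrimidine-centric representative."""
    if len(trinuc) != 3:
        raise ParseError(f"expected a trinucleotide, got {trinuc!r}")
    if trinuc[1] in PYRIMIDINES:
        return trinuc
    return reverse_complement(trinuc)
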