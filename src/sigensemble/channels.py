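"""SBS96 channel grammar and trinucleotide-context canonicalization.

A single-base substitution is classified by the substituted pyrimidine
(C or T on the pyrimidine strand), the mutant base, and the two flanking
bases, written ``X[R>A]Y`` (e.g. ``A[C>T]G``).  Purine-strand events are
reverse-complemented onto the pyrimidine strand, so exactly 96 channels
exist: 6 substitutions x 16 flank pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_LABEL_RE = re.compile(r"^([ACGT])\[([CT])>([ACGT])\]([ACGT])$")


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True, order=True)
class Sbs96Channel:
    """One of the 96 pyrimidine-strand trinucleotide substitution classes."""

    substitution: str
    five_prime: str
    three_prime: str

    def __post_init__(self) -> None:
        if self.substitution not in SUBSTITUTIONS:
            raise ValueError(f"invalid substitution {self.substitution!r}")
        if self.five_prime not in BASES or self.three_prime not in BASES:
            raise ValueError(
                f"invalid flanking bases {self.five_prime!r}/{self.three_prime!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.substitution}]{self.three_prime}"

    @classmethod
    def parse(cls, label: str) -> "Sbs96Channel":
        m = _LABEL_RE.match(label)
        if m is None:
            raise ValueError(f"unparseable SBS96 channel label {label!r}")
        five, ref, alt, three = m.groups()
        if ref == alt:
            raise ValueError(f"reference equals alternate in {label!r}")
        return cls(substitution=f"{ref}>{alt}", five_prime=five, three_prime=three)


# Canonical order: substitutions grouped C>A, C>G, C>T, T>A, T>C, T>G; within
# each group the 16 flank pairs lexicographic with the 5' base varying slowest.
CANONICAL_CHANNELS: tuple[Sbs96Channel, ...] = tuple(
    Sbs96Channel(sub, five, three)
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
CANONICAL_LABELS: tuple[str, ...] = tuple(c.label for c in CANONICAL_CHANNELS)
_LABEL_TO_INDEX = {lab: i for i, lab in enumerate(CANONICAL_LABELS)}


def channel_index(label: str) -> int:
    """Position of a channel label in the canonical SBS96 ordering."""
    try:
        return _LABEL_TO_INDEX[label]
    except KeyError:
        # normalize through the parser so e.g. whitespace fails loudly
        return _LABEL_TO_INDEX[Sbs96Channel.parse(label).label]


def canonical_label(ref: str, alt: str, five_prime: str, three_prime: str) -> str:
    """Map a stranded SNV plus plus-strand flanks to its SBS96 channel.

    If the reference base is a purine the substitution and both flanks are
    reverse-complemented onto the pyrimidine strand, which swaps and
    complements the flanks.
    """
    ref, alt = ref.upper(), alt.upper()
    five_prime, three_prime = five_prime.upper(), three_prime.upper()
    for b in (ref, alt, five_prime, three_prime):
        if b not in _COMPLEMENT:
            raise ValueError(f"non-ACGT base {b!r}")
    if ref == alt:
        raise ValueError("reference equals alternate")
    if ref in PURINES:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five_prime, three_prime = _COMPLEMENT[three_prime], _COMPLEMENT[five_prime]
    return Sbs96Channel(f"{ref}>{alt}", five_prime, three_prime).label
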