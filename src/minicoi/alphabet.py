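"""IUPAC nucleotide ambiguity codes extended with inosine.

Degenerate PCR primers are written over the 15 IUPAC codes plus inosine
(``I``), a base analog that pairs with all four nucleotides.  Duplex
stability of inosine pairs is not uniform (I-C > I-A > I-T ≈ I-G), but
following the conservative convention used in primer-coverage work we
score inosine as a universal match; the stability ranking is carried as
metadata only and never changes a match/mismatch verdict.
"""

from __future__ import annotations

import enum
from typing import FrozenSet

__all__ = [
    "ALPHABET",
    "IUPAC_SETS",
    "InosinePolicy",
    "INOSINE_STABILITY_RANKING",
    "AlphabetError",
    "allowed_bases",
    "bases_compatible",
    "reverse_complement",
    "count_ambiguities",
]

# Concrete-base sets represented by each symbol.  Inosine is listed with
# the full set under the universal convention.
IUPAC_SETS: dict[str, FrozenSet[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "I": frozenset("ACGT"),
}

ALPHABET: FrozenSet[str] = frozenset(IUPAC_SETS)

# Complement table over the full alphabet.  Inosine complements to
# itself (it has no unique Watson-Crick partner); ambiguity codes follow
# the IUPAC convention (complement of the represented set).
_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNI",
    "TGCAYRSWMKVHDBNI",
)

#: Duplex-stability ordering of inosine pairs, most to least stable.
#: Metadata only; all four pairings count as matches.
INOSINE_STABILITY_RANKING: tuple[str, ...] = ("I-C", "I-A", "I-T", "I-G")


class InosinePolicy(enum.Enum):
    """How inosine is treated when scoring primer/template pairs.

    Both policies score inosine as matching A, C, G and T; ``RANKED``
    additionally exposes the stability ordering as report metadata.
    """

    UNIVERSAL = "universal"
    RANKED = "ranked"

    @property
    def stability_ranking(self) -> tuple[str, ...] | None:
        if self is InosinePolicy.RANKED:
            return INOSINE_STABILITY_RANKING
        return None


class AlphabetError(ValueError):
    """A symbol outside the IUPAC+inosine alphabet."""

    def __init__(self, symbol: str):
        super().__init__(
            f"symbol {symbol!r} is not an IUPAC nucleotide code or inosine "
            f"(allowed: {''.join(sorted(ALPHABET))})"
        )
        self.symbol = symbol


def normalize(seq: str) -> str:
    """Upper-case a sequence and map U to T.

    Templates derived from mRNA/cDNA may arrive as RNA; everything
    downstream works on the DNA alphabet.
    """
    return seq.upper().replace("U", "T")


def allowed_bases(
    code: str, policy: InosinePolicy = InosinePolicy.UNIVERSAL
) -> FrozenSet[str]:
    """Concrete bases {A,C,G,T} represented by one alphabet symbol.

    Inosine returns the full set under both policies.
    """
    try:
        return IUPAC_SETS[code.upper()]
    except KeyError:
        raise AlphabetError(code) from None


def bases_compatible(
    primer_code: str,
    template_code: str,
    policy: InosinePolicy = InosinePolicy.UNIVERSAL,
) -> bool:
    """True iff the two symbols share at least one concrete base.

    The template side may itself be ambiguous (e.g. N in a reference
    sequence); intersection semantics then make it compatible with any
    primer code, which callers flag rather than count as a mismatch.
    """
    return bool(allowed_bases(primer_code, policy) & allowed_bases(template_code, policy))


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full alphabet (I ↔ I, W ↔ W, Y ↔ R, ...)."""
    seq = normalize(seq)
    for ch in seq:
        if ch not in ALPHABET:
            raise AlphabetError(ch)
    return seq.translate(_COMPLEMENT)[::-1]


def count_ambiguities(sequence: str) -> int:
    """Number of positions whose symbol is not a concrete base.

    Inosine counts as ambiguous (it represents all four bases).
    """
    seq = normalize(sequence)
    n = 0
    for ch in seq:
        if ch not in ALPHABET:
            raise AlphabetError(ch)
        if ch not in "ACGT":
            n += 1
    return n
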