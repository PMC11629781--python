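"""Registry of miniCOI primers and named primer combinations.

The most widely used primers for the ~313-bp miniCOI metabarcoding
fragment are the Leray forward primer mlCOIintF paired with one of three
reverse primers of increasing degeneracy (HCO2198, dgHCO2198,
jgHCO2198), plus the "Leray XT" pair in which the forward primer also
carries extra ambiguities and two inosines.  The registry ships these
sequences verbatim; users may load a different registry file with the
same schema.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .alphabet import ALPHABET, count_ambiguities, normalize

__all__ = [
    "DegeneratePrimer",
    "PrimerCombination",
    "PrimerRegistry",
    "default_registry",
    "get_primer",
    "get_combination",
]


@dataclass(frozen=True)
class DegeneratePrimer:
    """A 5′→3′ primer over IUPAC codes plus inosine."""

    name: str
    sequence: str
    direction: str  # "forward" | "reverse"

    def __post_init__(self):
        seq = normalize(self.sequence)
        object.__setattr__(self, "sequence", seq)
        bad = sorted(set(seq) - ALPHABET)
        if bad:
            raise ValueError(f"primer {self.name}: invalid symbols {bad}")
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name}: direction must be forward|reverse")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_ambiguities(self) -> int:
        return count_ambiguities(self.sequence)


@dataclass(frozen=True)
class PrimerCombination:
    """A named forward/reverse primer pair."""

    name: str
    forward: DegeneratePrimer
    reverse: DegeneratePrimer


class PrimerLookupError(KeyError):
    def __init__(self, name: str, registered: Iterable[str]):
        super().__init__(
            f"unknown name {name!r}; registered: {', '.join(sorted(registered))}"
        )


@dataclass
class PrimerRegistry:
    """Primers and combinations loaded from a tab-separated table."""

    primers: dict[str, DegeneratePrimer] = field(default_factory=dict)
    combinations: dict[str, PrimerCombination] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path_or_text) -> "PrimerRegistry":
        if isinstance(path_or_text, (str, Path)):
            text = Path(path_or_text).read_text(encoding="utf-8")
        else:
            text = path_or_text.read()
        reg = cls()
        lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
        reader = csv.DictReader(lines, delimiter="\t")
        pending: list[tuple[str, str, str]] = []  # (combo, forward, reverse)
        for row in reader:
            name = row["name"].strip()
            primer = DegeneratePrimer(
                name=name,
                sequence=row["sequence"].strip(),
                direction=row["direction"].strip(),
            )
            if name in reg.primers and reg.primers[name].sequence != primer.sequence:
                raise ValueError(f"conflicting sequences for primer {name}")
            reg.primers.setdefault(name, primer)
            combo = (row.get("combination") or "").strip()
            if combo:
                partner = (row.get("forward_partner") or "").strip()
                if not partner:
                    raise ValueError(f"combination {combo}: missing forward_partner")
                pending.append((combo, partner, name))
        for combo, fwd, rev in pending:
            if fwd not in reg.primers:
                raise ValueError(f"combination {combo}: unknown forward {fwd}")
            reg.combinations[combo] = PrimerCombination(
                name=combo, forward=reg.primers[fwd], reverse=reg.primers[rev]
            )
        return reg

    def get_primer(self, name: str) -> DegeneratePrimer:
        try:
            return self.primers[name]
        except KeyError:
            raise PrimerLookupError(name, self.primers) from None

    def get_combination(self, name: str) -> PrimerCombination:
        try:
            return self.combinations[name]
        except KeyError:
            raise PrimerLookupError(name, self.combinations) from None


_DEFAULT: PrimerRegistry | None = None


def default_registry() -> PrimerRegistry:
    """The packaged miniCOI registry (loaded once, cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("minicoi.data").joinpath("primers.tsv")
        _DEFAULT = PrimerRegistry.from_tsv(io.StringIO(ref.read_text(encoding="utf-8")))
    return _DEFAULT


def get_primer(name: str) -> DegeneratePrimer:
    """Look up a primer in the packaged registry by name."""
    return default_registry().get_primer(name)


def get_combination(name: str) -> PrimerCombination:
    """Look up a primer combination in the packaged registry by name."""
    return default_registry().get_combination(name)
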