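"""Reconstruction of published primer-region datasets as concrete sequences.

The review's tables print, for each sequence or haplotype lineage, only
the bases at the non-conserved positions of the 26-nt forward
primer-binding region; every unlisted position is conserved, i.e.
compatible with both forward primers.  ``build_region`` realizes a full
26-nt concrete region from such a row by filling conserved positions
with a base drawn from the intersection of both forward primers' allowed
sets (lexicographically smallest by default) — a fill that can never
create a mismatch for either primer, so recomputed mismatch totals
depend only on the printed states.

Registered datasets:

``oithona_similis``
    14 haplotype lineages (#I–#XIV) over 8 variable positions; the
    per-lineage multiplicity ``n`` sums to the 247 aligned sequences.
``appendicularia``
    21 sequences / 14 species over 14 variable positions, with per-
    species poly-T insert flags.
``thaliacea``
    15 sequences / 12 species over 13 variable positions.
``oithona_nana_partial`` and ``microsetella_norvegica_partial``
    reserved names: their haplotype bases were published only in
    supplementary figures and are not transcribed here (no rows ship).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from functools import lru_cache

from .alphabet import allowed_bases
from .mismatch import TemplateRegion
from .primers import DegeneratePrimer, get_primer

__all__ = [
    "FixtureRow",
    "FixtureSpec",
    "conserved_fill",
    "build_region",
    "expand_fixture",
    "get_fixture",
    "FIXTURE_NAMES",
]

REGION_LENGTH = 26

FIXTURE_NAMES = (
    "oithona_similis",
    "appendicularia",
    "thaliacea",
    "oithona_nana_partial",
    "microsetella_norvegica_partial",
)

# Datasets whose rows exist only in untranscribed supplementary figures.
_RESERVED_EMPTY = {
    "oithona_nana_partial": "O. nana haplotypes A/B (16 sequences)",
    "microsetella_norvegica_partial": "M. norvegica (24 sequences)",
}


@dataclass(frozen=True)
class FixtureRow:
    """One table row: a lineage or accession with its variable-site states."""

    label: str
    states: dict[int, str]  # 1-based primer position -> concrete base
    n: int = 1
    species: str | None = None
    area: str | None = None
    polyT: bool = False
    expected: dict[str, int] = field(default_factory=dict)  # published totals (oracle)


@dataclass(frozen=True)
class FixtureSpec:
    dataset: str
    variable_positions: tuple[int, ...]
    rows: tuple[FixtureRow, ...]

    @property
    def total_n(self) -> int:
        return sum(r.n for r in self.rows)


def conserved_fill(position: int, primers: tuple[DegeneratePrimer, ...] | None = None) -> str:
    """Mismatch-neutral fill base for a conserved position (1-based).

    Lexicographically smallest base in the intersection of the forward
    primers' allowed sets at that position; arbitrary but deterministic,
    and by construction never a mismatch for either primer.
    """
    if primers is None:
        primers = (get_primer("mlCOIintF"), get_primer("mlCOIintF-XT"))
    sets = [allowed_bases(p.sequence[position - 1]) for p in primers]
    inter = frozenset.intersection(*sets)
    if not inter:
        raise ValueError(
            f"no mismatch-neutral fill exists at position {position} "
            f"for primers {[p.name for p in primers]}"
        )
    return min(inter)


def build_region(row: FixtureRow, primer: DegeneratePrimer | None = None) -> TemplateRegion:
    """Realize a full-length concrete region from a table row.

    ``primer`` only sets the region length/orientation context; the
    default is the 26-nt forward-primer region.
    """
    length = primer.length if primer is not None else REGION_LENGTH
    bases = []
    for pos in range(1, length + 1):
        if pos in row.states:
            bases.append(row.states[pos])
        else:
            bases.append(conserved_fill(pos))
    return TemplateRegion(
        source_id=row.label,
        bases="".join(bases),
        start=None,
        covered="full",
        orientation_note="fixture-built forward primer region",
    )


def expand_fixture(spec: FixtureSpec, with_multiplicity: bool = False) -> list[TemplateRegion]:
    """Regions for every row; optionally replicated ``n`` times per row.

    Replicated ids are suffixed ``/1 .. /n`` so the 14 *O. similis*
    lineages expand to the 247 aligned sequences.
    """
    regions: list[TemplateRegion] = []
    for row in spec.rows:
        base = build_region(row)
        if with_multiplicity:
            for k in range(1, row.n + 1):
                regions.append(
                    TemplateRegion(
                        source_id=f"{row.label}/{k}",
                        bases=base.bases,
                        covered="full",
                        orientation_note=base.orientation_note,
                    )
                )
        else:
            regions.append(base)
    return regions


def _read_rows(filename: str) -> list[dict[str, str]]:
    text = resources.files("minicoi.data").joinpath(filename).read_text(encoding="utf-8")
    # comment lines start "# "; data labels like "#I" must survive
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("# ")]
    return list(csv.DictReader(io.StringIO("\n".join(lines)), delimiter="\t"))


def _states_from(raw: dict[str, str]) -> dict[int, str]:
    states: dict[int, str] = {}
    for key, val in raw.items():
        if key.startswith("p") and key[1:].isdigit() and (val or "").strip():
            states[int(key[1:])] = val.strip().upper()
    return states


@lru_cache(maxsize=None)
def get_fixture(name: str) -> FixtureSpec:
    """Load a registered dataset by name."""
    if name in _RESERVED_EMPTY:
        return FixtureSpec(dataset=name, variable_positions=(), rows=())
    if name == "oithona_similis":
        rows = []
        for raw in _read_rows("oithona_similis.tsv"):
            rows.append(
                FixtureRow(
                    label=raw["label"],
                    states=_states_from(raw),
                    n=int(raw["n"]),
                    area=raw["area"],
                    expected={
                        "mlCOIintF": int(raw["expected_ml"]),
                        "mlCOIintF-XT": int(raw["expected_xt"]),
                    },
                )
            )
    elif name in ("appendicularia", "thaliacea"):
        rows = []
        for raw in _read_rows(f"{name}.tsv"):
            rows.append(
                FixtureRow(
                    label=raw["accession"],
                    states=_states_from(raw),
                    n=1,
                    species=raw["species"],
                    polyT=(raw.get("polyT") or "").strip().upper() == "X",
                    expected={
                        "mlCOIintF": int(raw["expected_ml"]),
                        "mlCOIintF-XT": int(raw["expected_xt"]),
                    },
                )
            )
    else:
        raise KeyError(
            f"unknown fixture {name!r}; registered: {', '.join(FIXTURE_NAMES)}"
        )
    positions = tuple(sorted({p for r in rows for p in r.states}))
    spec = FixtureSpec(dataset=name, variable_positions=positions, rows=tuple(rows))
    # fail fast on fill impossibility (cannot occur for the shipped primers)
    for pos in range(1, REGION_LENGTH + 1):
        conserved_fill(pos)
    return spec
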