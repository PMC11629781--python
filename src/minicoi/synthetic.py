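"""Synthetic COI-like templates for end-to-end and property testing.

``synthesize_fasta`` embeds fixture-derived (or arbitrary) forward
primer-binding regions in longer templates laid out like a real miniCOI
amplicon context::

    5'-flank | forward region | spacer [| poly-T insert | spacer] | reverse
    binding target | flank-3'

The reverse binding target is an exact concrete complement target of the
chosen reverse primer, so both locator directions are exercised.  Poly-T
insert lengths follow a geometric distribution with configurable mean
(default 140 nt, the published average for *O. dioica*) truncated at a
maximum (default 500 nt, the published upper bound); placement is inside
the amplicon so an insert always disrupts it.  Every record is fully
determined by the seed, and the layout is recorded in the FASTA
description.

``random_region`` draws concrete regions with an exact, known number of
mismatching positions against a primer — the generator half of
generator/profiler cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import allowed_bases, reverse_complement
from .mismatch import TemplateRegion
from .primers import DegeneratePrimer, get_primer

__all__ = ["SyntheticSequenceConfig", "synthesize_fasta", "random_region"]

_BASES = "ACGT"


@dataclass(frozen=True)
class PolyTConfig:
    """Insert model: shifted geometric with a floor.

    Published inserts are tens to hundreds of nt; lengths are drawn as
    ``min_length - 1 + Geometric`` with the geometric mean chosen so the
    untruncated mean equals ``mean_length``, then truncated at
    ``max_length``.
    """

    enabled: bool = False
    mean_length: int = 140
    max_length: int = 500
    min_length: int = 10

    def __post_init__(self):
        if not self.min_length <= self.mean_length <= self.max_length:
            raise ValueError("poly-T lengths must satisfy min <= mean <= max")


@dataclass(frozen=True)
class SyntheticSequenceConfig:
    flank_length: int = 80
    spacer_length: int = 60
    polyT: PolyTConfig = field(default_factory=PolyTConfig)
    reverse_primer: str = "jgHCO2198"
    seed: int = 0

    def __post_init__(self):
        if self.flank_length < 0 or self.spacer_length < 0:
            raise ValueError("flank/spacer lengths must be >= 0")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=n)])


def _polyt_length(rng: np.random.Generator, cfg: PolyTConfig) -> int:
    geom_mean = cfg.mean_length - cfg.min_length + 1
    draw = cfg.min_length - 1 + int(rng.geometric(1.0 / geom_mean))
    return min(draw, cfg.max_length)


def _concrete_target(primer: DegeneratePrimer, rng: np.random.Generator) -> str:
    """A concrete coding-strand binding target matching the reverse primer.

    Drawn uniformly from the primer's expansion set, then reverse
    complemented into coding-strand orientation.
    """
    expansion = "".join(
        sorted(allowed_bases(c))[rng.integers(0, len(allowed_bases(c)))]
        for c in primer.sequence
    )
    return reverse_complement(expansion)


def synthesize_fasta(
    regions: list[TemplateRegion],
    config: SyntheticSequenceConfig,
) -> list[SeqRecord]:
    """One synthetic template per input region, deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    rev = get_primer(config.reverse_primer)
    records = []
    for region in regions:
        parts = [_random_dna(rng, config.flank_length), region.bases]
        desc = [f"fwd_start={config.flank_length}", f"seed={config.seed}"]
        insert_len = 0
        if config.polyT.enabled:
            half = config.spacer_length // 2
            insert_len = _polyt_length(rng, config.polyT)
            parts += [_random_dna(rng, half), "T" * insert_len,
                      _random_dna(rng, config.spacer_length - half)]
            desc.append(
                f"polyT_start={config.flank_length + len(region.bases) + half}"
            )
            desc.append(f"polyT_len={insert_len}")
        else:
            parts.append(_random_dna(rng, config.spacer_length))
        rev_start = sum(len(p) for p in parts)
        parts += [_concrete_target(rev, rng), _random_dna(rng, config.flank_length)]
        desc.append(f"rev_start={rev_start}")
        records.append(
            SeqRecord(
                Seq("".join(parts)),
                id=region.source_id.replace(" ", "_"),
                description=" ".join(desc),
            )
        )
    return records


def random_region(
    primer: DegeneratePrimer,
    k_mismatches: int,
    terminal: bool = False,
    seed: int = 0,
    source_id: str = "random",
) -> TemplateRegion:
    """A concrete region with exactly ``k_mismatches`` vs the primer.

    Mismatching positions draw a base outside the primer's allowed set
    (impossible where the primer code is N/I — those positions are never
    chosen); matching positions draw from inside it.  ``terminal=True``
    forces one mismatch into the last three positions.
    """
    rng = np.random.default_rng(seed)
    L = primer.length
    if not 0 <= k_mismatches <= L:
        raise ValueError("k_mismatches outside 0..primer length")
    mismatchable = [
        i for i in range(L) if len(allowed_bases(primer.sequence[i])) < 4
    ]
    if k_mismatches > len(mismatchable):
        raise ValueError(
            f"only {len(mismatchable)} positions of {primer.name} can mismatch"
        )
    chosen: list[int] = []
    if terminal:
        if k_mismatches == 0:
            raise ValueError("terminal=True requires k_mismatches >= 1")
        term = [i for i in mismatchable if i >= L - 3]
        if not term:
            raise ValueError("no mismatchable position in the terminal window")
        chosen.append(int(rng.choice(term)))
    pool = [i for i in mismatchable if i not in chosen]
    extra = rng.choice(len(pool), size=k_mismatches - len(chosen), replace=False)
    chosen += [pool[int(e)] for e in extra]
    bases = []
    for i in range(L):
        allowed = sorted(allowed_bases(primer.sequence[i]))
        if i in chosen:
            outside = sorted(set(_BASES) - set(allowed))
            bases.append(outside[rng.integers(0, len(outside))])
        else:
            bases.append(allowed[rng.integers(0, len(allowed))])
    return TemplateRegion(
        source_id=source_id,
        bases="".join(bases),
        covered="full",
        orientation_note=f"random region, k={k_mismatches}, terminal={terminal}",
    )
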