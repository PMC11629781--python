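"""Haplotype-lineage grouping of primer-binding regions and summary statistics.

Given a set of aligned, full-length primer-binding regions, the variable
(non-conserved) positions are the columns showing more than one concrete
base.  Sequences sharing an identical tuple of bases at those positions
form a haplotype lineage; profiling one representative per lineage
against each forward primer gives the per-lineage mismatch totals, and
multiplicity-weighted summaries give the statistics reported for
*O. similis* (mismatch ranges, count of lineages with a 3′-terminal
mismatch, percent of sequences affected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .alphabet import InosinePolicy, allowed_bases
from .mismatch import (
    MismatchProfile,
    TemplateRegion,
    profile_mismatches,
)
from .primers import DegeneratePrimer

__all__ = [
    "HaplotypeGroup",
    "VariablePositionReport",
    "LineageSummary",
    "find_variable_positions",
    "group_by_haplotype",
    "per_position_mismatch_counts",
    "summarize_lineages",
    "p_distance",
    "ROMAN",
]


def _roman(k: int) -> str:
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
            (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
            (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for v, s in vals:
        while k >= v:
            out.append(s)
            k -= v
    return "".join(out)


ROMAN = _roman


@dataclass
class HaplotypeGroup:
    """A lineage: one combination of bases at the variable positions."""

    label: str
    states: dict[int, str]
    members: list[str]
    totals: dict[str, int] = field(default_factory=dict)  # primer name -> total
    terminal3_hit: dict[str, bool] = field(default_factory=dict)
    representative: TemplateRegion | None = None

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class VariablePositionReport:
    position: int  # 1-based primer coordinate
    observed_states: frozenset[str]
    mismatch_count_per_primer: dict[str, int]  # n-weighted sequence counts
    shared_degeneracy: bool


@dataclass(frozen=True)
class LineageSummary:
    n_groups: int
    total_sequences: int
    min_total: dict[str, int]
    max_total: dict[str, int]
    terminal_lineages: dict[str, int]
    terminal_percent: dict[str, int]  # n-weighted, round-half-up


def find_variable_positions(regions: Sequence[TemplateRegion]) -> list[int]:
    """1-based positions whose column holds more than one concrete base.

    N is treated as "no information" and never creates variability on
    its own.  All regions must be full-length and of equal length.
    """
    if not regions:
        return []
    lengths = {len(r) for r in regions}
    if len(lengths) != 1:
        raise ValueError(f"regions of mixed lengths: {sorted(lengths)}")
    (L,) = lengths
    out = []
    for i in range(L):
        column = {r.bases[i] for r in regions} & set("ACGT")
        if len(column) > 1:
            out.append(i + 1)
    return out


def group_by_haplotype(
    regions: Sequence[TemplateRegion],
    positions: Sequence[int],
    primers: Sequence[DegeneratePrimer] = (),
    policy: InosinePolicy = InosinePolicy.UNIVERSAL,
    sort_input: bool = True,
) -> list[HaplotypeGroup]:
    """Partition regions by their base tuple at the given positions.

    Groups are labelled #I, #II, ... in first-seen order after a
    deterministic sort of the input by source id (so shuffling the input
    can only relabel, never recount).  Pass ``sort_input=False`` when
    the input already carries a documented order — e.g. fixture rows in
    table order — so labels follow that order.  Per-group mismatch
    totals come from profiling one representative per group; all
    members are asserted identical at every position so the
    representative stands for the group.
    """
    if not regions:
        return []
    L = len(regions[0])
    if positions and max(positions) > L:
        raise ValueError(f"position {max(positions)} beyond region length {L}")
    ordered = sorted(regions, key=lambda r: r.source_id) if sort_input else list(regions)
    groups: dict[tuple[str, ...], HaplotypeGroup] = {}
    for reg in ordered:
        if len(reg) != L:
            raise ValueError("regions of mixed lengths")
        key = tuple(reg.bases[p - 1] for p in positions)
        grp = groups.get(key)
        if grp is None:
            grp = HaplotypeGroup(
                label=f"#{_roman(len(groups) + 1)}",
                states=dict(zip(positions, key)),
                members=[],
                representative=reg,
            )
            groups[key] = grp
        else:
            # the partition key covers the variable positions; any other
            # column is conserved by definition, so the representative
            # must agree with every member there too
            assert grp.representative is not None
            if grp.representative.bases != reg.bases:
                diff = [
                    i + 1
                    for i, (a, b) in enumerate(zip(grp.representative.bases, reg.bases))
                    if a != b and a in "ACGT" and b in "ACGT"
                ]
                if any(d not in positions for d in diff):
                    raise ValueError(
                        f"members of group {grp.label} differ outside the "
                        f"variable positions (at {diff}); re-run "
                        "find_variable_positions on this input"
                    )
        grp.members.append(reg.source_id)
    result = list(groups.values())
    for grp in result:
        assert grp.representative is not None
        for primer in primers:
            prof = profile_mismatches(primer, grp.representative, policy)
            grp.totals[primer.name] = prof.total
            grp.terminal3_hit[primer.name] = prof.terminal3_hit
    return result


def per_position_mismatch_counts(
    groups: Sequence[HaplotypeGroup],
    primers: Sequence[DegeneratePrimer],
    policy: InosinePolicy = InosinePolicy.UNIVERSAL,
) -> list[VariablePositionReport]:
    """n-weighted per-position mismatch counts for each primer.

    ``shared_degeneracy`` is true where all compared primers have the
    same allowed-base set, which structurally forces equal counts.
    """
    if not groups:
        return []
    positions = sorted(groups[0].states)
    reports = []
    for pos in positions:
        observed = frozenset(g.states[pos] for g in groups)
        counts: dict[str, int] = {}
        for primer in primers:
            allowed = allowed_bases(primer.sequence[pos - 1], policy)
            counts[primer.name] = sum(
                g.n for g in groups if g.states[pos] in "ACGT" and g.states[pos] not in allowed
            )
        sets = {allowed_bases(p.sequence[pos - 1], policy) for p in primers}
        reports.append(
            VariablePositionReport(
                position=pos,
                observed_states=observed,
                mismatch_count_per_primer=counts,
                shared_degeneracy=len(sets) == 1,
            )
        )
    return reports


def _percent_round_half_up(num: int, den: int) -> int:
    return int(math.floor(100 * num / den + 0.5))


def summarize_lineages(groups: Sequence[HaplotypeGroup]) -> LineageSummary:
    """Per-primer mismatch ranges and 3′-terminal statistics.

    ``terminal_percent`` is the multiplicity-weighted share of sequences
    whose lineage carries a mismatch in the primer's last three
    positions, rounded half-up to an integer percent.
    """
    if not groups:
        raise ValueError("no groups to summarize")
    primer_names = list(groups[0].totals)
    total_n = sum(g.n for g in groups)
    min_t, max_t, term_lin, term_pct = {}, {}, {}, {}
    for name in primer_names:
        totals = [g.totals[name] for g in groups]
        min_t[name] = min(totals)
        max_t[name] = max(totals)
        hit = [g for g in groups if g.terminal3_hit[name]]
        term_lin[name] = len(hit)
        term_pct[name] = _percent_round_half_up(sum(g.n for g in hit), total_n)
    return LineageSummary(
        n_groups=len(groups),
        total_sequences=total_n,
        min_total=min_t,
        max_total=max_t,
        terminal_lineages=term_lin,
        terminal_percent=term_pct,
    )


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites between two equal-length sequences.

    Sites where either sequence is not a concrete base (N, gaps already
    removed by the caller) are excluded from the denominator.
    """
    if len(a) != len(b):
        raise ValueError("p-distance requires equal-length sequences")
    a, b = a.upper(), b.upper()
    compared = diff = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            compared += 1
            if x != y:
                diff += 1
    if compared == 0:
        raise ValueError("no comparable sites")
    return diff / compared
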