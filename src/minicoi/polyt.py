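"""Homopolymer (poly-T) run detection in COI-region sequences.

Several appendicularian species carry intron-like homopolymeric poly-T
inserts in the coding strand of their mitochondrial COI (poly-A on the
non-coding strand), tens to hundreds of thymines long (mean ~140 nt, up
to ~500 nt in *O. dioica*, ~1 500 nt in *O. vanhoeffeni*), excised at
the mRNA level.  Such runs disrupt PCR amplification and sequencing of
genomic DNA, so an amplicon overlapping one is effectively lost.

The default threshold ``min_len=10`` operationalizes "tens of
consecutive Ts" as the floor for calling an insert; it is a stated
convention of this package, not a published cutoff, and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alphabet import normalize, reverse_complement

__all__ = [
    "HomopolymerRun",
    "PolyTReport",
    "find_runs",
    "scan_polyT",
    "DEFAULT_MIN_RUN",
]

DEFAULT_MIN_RUN = 10


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of one base: 0-based start, length in nt."""

    base: str
    start: int
    length: int

    @property
    def end(self) -> int:  # half-open
        return self.start + self.length


@dataclass(frozen=True)
class PolyTReport:
    template_id: str
    runs: tuple[HomopolymerRun, ...]
    within_amplicon: bool | None = None  # None when no span was supplied

    @property
    def present(self) -> bool:
        return bool(self.runs)

    @property
    def max_run(self) -> int:
        return max((r.length for r in self.runs), default=0)


def find_runs(seq: str, base: str = "T", min_len: int = DEFAULT_MIN_RUN) -> list[HomopolymerRun]:
    """All maximal runs of ``base`` of length >= min_len, by start.

    Runs are maximal (not extendable in either direction) and therefore
    separated by at least one other character.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    base = base.upper()
    seq = normalize(seq)
    runs: list[HomopolymerRun] = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            if j - i >= min_len:
                runs.append(HomopolymerRun(base=base, start=i, length=j - i))
            i = j
        else:
            i += 1
    return runs


def scan_polyT(
    seq: str,
    template_id: str = "seq",
    amplicon_span: tuple[int, int] | None = None,
    min_len: int = DEFAULT_MIN_RUN,
    both_strands: bool = False,
) -> PolyTReport:
    """Poly-T report for one sequence.

    ``amplicon_span`` is a 0-based half-open interval; ``within_amplicon``
    is true iff any qualifying run intersects it.  ``both_strands`` also
    scans for poly-A runs (the non-coding-strand appearance of an
    insert), mapped back to coding-strand coordinates.
    """
    seq = normalize(seq)
    if amplicon_span is not None:
        lo, hi = amplicon_span
        if not (0 <= lo <= hi <= len(seq)):
            raise ValueError(f"amplicon span {amplicon_span} out of bounds for length {len(seq)}")
    runs = find_runs(seq, "T", min_len)
    if both_strands:
        n = len(seq)
        for r in find_runs(reverse_complement(seq), "T", min_len):
            runs.append(HomopolymerRun(base="A", start=n - r.end, length=r.length))
        runs.sort(key=lambda r: r.start)
    within = None
    if amplicon_span is not None:
        lo, hi = amplicon_span
        within = any(r.start < hi and r.end > lo for r in runs)
    return PolyTReport(template_id=template_id, runs=tuple(runs), within_amplicon=within)
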