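"""Study × taxon outcome records and review tallies.

Thirty metabarcoding studies that compared miniCOI against microscopy
and/or another universal marker were scored per locally abundant taxon:
``fail`` (no detection, a false negative), ``bias`` (detected but more
than an order of magnitude below the comparison method), ``NA`` (taxon
absent or not reported) or ``OK``.  The packaged table carries one row
per study × taxon × basin with the study's primer combination; tallies
count distinct studies (a study observed in two basins is one study).
"""

from __future__ import annotations

import csv
import io
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "StudyOutcomeRecord",
    "TaxonTally",
    "TallySummary",
    "load_outcomes",
    "packaged_outcomes",
    "tally_taxon",
    "summarize_misperformance",
    "OUTCOMES",
    "BASINS",
    "COMBINATIONS",
    "MISPERFORMANCE",
]

OUTCOMES = ("fail", "bias", "NA", "OK")
MISPERFORMANCE = ("fail", "bias")
BASINS = ("AO", "PO", "IO", "ArO", "SO", "Undet.")
GROUPS = ("copepod", "tunicate", "other")
COMBINATIONS = ("Leray–Folmer", "Leray–Meyer", "Leray–Geller", "Leray XT", "Other")


@dataclass(frozen=True)
class StudyOutcomeRecord:
    study_code: int
    taxon: str
    taxon_group: str
    ocean_basin: str
    primer_combination: str
    outcome: str

    def __post_init__(self):
        if not 1 <= self.study_code <= 30:
            raise ValueError(f"study code {self.study_code} outside 1-30")
        for fieldname, value, vocab in (
            ("taxon_group", self.taxon_group, GROUPS),
            ("ocean_basin", self.ocean_basin, BASINS),
            ("primer_combination", self.primer_combination, COMBINATIONS),
            ("outcome", self.outcome, OUTCOMES),
        ):
            if value not in vocab:
                raise ValueError(
                    f"{fieldname} {value!r} not in {vocab} "
                    f"(study {self.study_code}, taxon {self.taxon})"
                )


@dataclass(frozen=True)
class TaxonTally:
    taxon: str
    by_basin: dict[str, int]
    total: int


@dataclass(frozen=True)
class TallySummary:
    n_taxa_misperforming: int
    by_group: dict[str, int]
    outcome_matrix: dict[str, dict[str, dict[str, int]]]  # taxon -> combo -> outcome -> n
    reviewed_per_combination: dict[str, int]
    studies_with_copepod_bias: int
    studies_with_other_bias: int


class SchemaError(ValueError):
    pass


def load_outcomes(path=None) -> list[StudyOutcomeRecord]:
    """Parse and validate an outcome table (default: the packaged one).

    Rejects vocabulary violations and fully duplicated
    (study, taxon, basin, combination) rows, naming the offending row.
    """
    if path is None:
        text = resources.files("minicoi.data").joinpath("study_outcomes.tsv").read_text(
            encoding="utf-8"
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("# ")]
    reader = csv.DictReader(io.StringIO("\n".join(lines)), delimiter="\t")
    required = {"study_code", "taxon", "taxon_group", "ocean_basin",
                "primer_combination", "outcome"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise SchemaError(
            f"header must contain {sorted(required)}, got {reader.fieldnames}"
        )
    records: list[StudyOutcomeRecord] = []
    seen: set[tuple] = set()
    for lineno, row in enumerate(reader, start=2):
        try:
            rec = StudyOutcomeRecord(
                study_code=int(row["study_code"]),
                taxon=row["taxon"].strip(),
                taxon_group=row["taxon_group"].strip(),
                ocean_basin=row["ocean_basin"].strip(),
                primer_combination=row["primer_combination"].strip(),
                outcome=row["outcome"].strip(),
            )
        except (ValueError, AttributeError) as exc:
            raise SchemaError(f"row {lineno}: {exc}") from exc
        key = (rec.study_code, rec.taxon, rec.ocean_basin, rec.primer_combination)
        if key in seen:
            raise SchemaError(f"row {lineno}: duplicate record {key}")
        seen.add(key)
        records.append(rec)
    return records


def packaged_outcomes() -> list[StudyOutcomeRecord]:
    return load_outcomes(None)


def write_outcomes(records: Sequence[StudyOutcomeRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["study_code", "taxon", "taxon_group", "ocean_basin",
                    "primer_combination", "outcome"])
        for r in records:
            w.writerow([r.study_code, r.taxon, r.taxon_group, r.ocean_basin,
                        r.primer_combination, r.outcome])


def tally_taxon(records: Iterable[StudyOutcomeRecord], taxon: str) -> TaxonTally:
    """Distinct studies reporting fail or bias for one taxon, by basin."""
    records = list(records)
    rows = [r for r in records if r.taxon == taxon]
    if not rows:
        known = sorted({r.taxon for r in records})
        raise KeyError(f"taxon {taxon!r} not present; known taxa: {known}")
    by_basin: dict[str, set[int]] = defaultdict(set)
    all_codes: set[int] = set()
    for r in rows:
        if r.outcome in MISPERFORMANCE:
            by_basin[r.ocean_basin].add(r.study_code)
            all_codes.add(r.study_code)
    return TaxonTally(
        taxon=taxon,
        by_basin={b: len(by_basin[b]) for b in BASINS if by_basin[b]},
        total=len(all_codes),
    )


def summarize_misperformance(records: Sequence[StudyOutcomeRecord]) -> TallySummary:
    """Headline counts and per-combination outcome matrices.

    The outcome matrix is built for the two focal taxa (Appendicularians
    and *Oithona similis*), counting distinct studies per combination
    and outcome; NA/OK rows exist in the data for those taxa only.
    """
    if not records:
        raise ValueError("no records")
    mis_taxa = {r.taxon for r in records if r.outcome in MISPERFORMANCE}
    group_of = {r.taxon: r.taxon_group for r in records}
    by_group = {g: sum(1 for t in mis_taxa if group_of[t] == g) for g in GROUPS}

    matrix: dict[str, dict[str, dict[str, int]]] = {}
    for taxon in ("Appendicularians", "Oithona similis"):
        per_combo: dict[str, dict[str, int]] = {}
        for combo in COMBINATIONS:
            codes: dict[str, set[int]] = {o: set() for o in OUTCOMES}
            for r in records:
                if r.taxon == taxon and r.primer_combination == combo:
                    codes[r.outcome].add(r.study_code)
            per_combo[combo] = {o: len(codes[o]) for o in OUTCOMES}
        matrix[taxon] = per_combo

    reviewed: dict[str, set[int]] = defaultdict(set)
    for r in records:
        reviewed[r.primer_combination].add(r.study_code)

    copepod_codes = {
        r.study_code for r in records
        if r.taxon_group == "copepod" and r.outcome in MISPERFORMANCE
    }
    other_codes = {
        r.study_code for r in records
        if r.taxon_group != "copepod" and r.outcome in MISPERFORMANCE
    }
    return TallySummary(
        n_taxa_misperforming=len(mis_taxa),
        by_group=by_group,
        outcome_matrix=matrix,
        reviewed_per_combination={c: len(reviewed[c]) for c in COMBINATIONS},
        studies_with_copepod_bias=len(copepod_codes),
        studies_with_other_bias=len(other_codes),
    )
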