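"""FASTA input and tab-separated report output."""

from __future__ import annotations

import gzip
import sys
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> Iterator[SeqRecord]:
    """Iterate records from a plain or gzip-compressed FASTA file."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            yield from SeqIO.parse(fh, "fasta")
    else:
        with open(path) as fh:
            yield from SeqIO.parse(fh, "fasta")


def write_fasta(records: Iterable[SeqRecord], path) -> int:
    return SeqIO.write(list(records), str(path), "fasta")


def write_tsv(rows: Sequence[dict], path=None, columns: Sequence[str] | None = None) -> None:
    """Write dict rows as UTF-8 TSV with a mandatory header row.

    ``path=None`` writes to stdout.  Column order follows ``columns`` or
    the first row's key order.
    """
    if columns is None:
        columns = list(rows[0]) if rows else []
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(str(row.get(c, "")) for c in columns))
    text = "\n".join(lines) + "\n"
    if path is None:
        sys.stdout.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")
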