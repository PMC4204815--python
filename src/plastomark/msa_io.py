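"""Reading, validating, slicing and writing multiple sequence alignments
and marker annotation tables.

Coordinates are 0-based half-open alignment columns throughout; 1-based
inclusive values appear only in TSV columns suffixed ``_1based``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Characters permitted in a stored alignment row.
ALPHABET = frozenset("ACGTN-")

# Non-N IUPAC ambiguity codes are demoted to N (real plastome assemblies
# contain them); "." is an alternate gap spelling.
_IUPAC_AMBIG = "RYSWKMBDHV"
_NORMALIZE = str.maketrans(
    {"U": "T", ".": "-", **{c: "N" for c in _IUPAC_AMBIG}}
)


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open column interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, column: int) -> bool:
        return self.start <= column < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Alignment:
    """An equal-length multiple sequence alignment over {A,C,G,T,N,-}."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("alignment has no sequences")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {', '.join(dupes)}")
        if any(not i for i in self.ids):
            raise ValueError("empty sequence id")
        length = len(self.rows[0])
        if length < 1:
            raise ValueError(f"zero-length alignment row: {self.ids[0]!r}")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise ValueError(
                    f"ragged alignment: row {sid!r} has length {len(row)}, "
                    f"expected {length}"
                )
            bad = set(row) - ALPHABET
            if bad:
                raise ValueError(
                    f"row {sid!r} contains characters outside "
                    f"{{A,C,G,T,N,-}}: {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, sid: str) -> str:
        return self.rows[self.ids.index(sid)]


def normalize_row(raw: str, sid: str = "?") -> str:
    """Uppercase a raw sequence and apply the alphabet policy.

    U becomes T, "." becomes "-", and any non-N IUPAC ambiguity code is
    demoted to N with a logged warning.
    """
    upper = raw.upper()
    n_demoted = sum(upper.count(c) for c in _IUPAC_AMBIG)
    if n_demoted:
        logger.warning(
            "record %r: %d IUPAC ambiguity character(s) demoted to N",
            sid, n_demoted,
        )
    return upper.translate(_NORMALIZE)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into a validated :class:`Alignment`."""
    path = Path(path)
    ids: list[str] = []
    rows: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        rows.append(normalize_row(str(record.seq), record.id))
    if not ids:
        raise ValueError(f"{path}: no FASTA records found")
    if len(ids) < 2:
        raise ValueError(f"{path}: an alignment needs at least 2 records")
    return Alignment(ids=ids, rows=rows)


def write_alignment(a: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(a.ids, a.rows):
            fh.write(f">{sid}\n{row}\n")


def slice_alignment(a: Alignment, iv: Interval) -> Alignment:
    """Extract columns ``[iv.start, iv.end)``, preserving row order."""
    if iv.end > a.length:
        raise ValueError(
            f"interval [{iv.start}, {iv.end}) exceeds alignment "
            f"length {a.length}"
        )
    return Alignment(
        ids=list(a.ids),
        rows=[row[iv.start:iv.end] for row in a.rows],
    )


# Markers written by write_marker_table duck-type this surface: an ``iv``
# interval, a ``marker_id`` string, a polymorphism count for the BED score,
# and a flat record of all fields for the TSV.
def _marker_record(marker) -> dict:
    rec = marker.to_record()
    rec["start_1based"] = marker.iv.start + 1
    rec["end_1based"] = marker.iv.end
    return rec


def write_marker_table(markers: Sequence, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write markers as ``<prefix>.tsv`` (all fields) and ``<prefix>.bed``.

    The BED score is the marker's polymorphism count scaled by 100 and
    capped at 1000. An empty marker list yields a header-only TSV (when a
    header can be inferred, it is the generic one) and an empty BED.
    """
    prefix = Path(path_prefix)
    tsv_path = prefix.with_suffix(".tsv")
    bed_path = prefix.with_suffix(".bed")
    prefix.parent.mkdir(parents=True, exist_ok=True)

    records = [_marker_record(m) for m in markers]
    if records:
        header = list(records[0].keys())
    else:
        header = ["id", "start", "end", "start_1based", "end_1based"]
    try:
        with open(tsv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=header, delimiter="\t")
            writer.writeheader()
            writer.writerows(records)
        with open(bed_path, "w") as fh:
            for m in markers:
                score = min(1000, int(m.polymorphism_count) * 100)
                fh.write(
                    f"chrom\t{m.iv.start}\t{m.iv.end}\t{m.marker_id}"
                    f"\t{score}\t+\n"
                )
    except OSError as exc:
        raise OSError(f"cannot write marker table at {prefix}: {exc}") from exc
    return tsv_path, bed_path


def read_marker_tsv(path: str | Path) -> list[dict]:
    """Parse a marker TSV back into a list of string-valued records."""
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
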