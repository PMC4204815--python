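"""Perfect di-/tri-nucleotide tandem repeat discovery on the best-base
track, with cross-taxon polymorphism screening via the ambiguous track.

A repeat locus covers complete units only and never spans a gap column.
Polymorphism is established by an ambiguous (N) column inside the repeat
span or within ``proximity`` bases of either boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .msa_io import Interval

_VALID = frozenset("ACGT")


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation of a repeat unit."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_homopolymer(motif: str) -> bool:
    return len(set(motif)) == 1


@dataclass(frozen=True)
class RepeatLocus:
    """A maximal perfect tandem repeat of a 2- or 3-base unit."""

    motif: str        # canonical rotation
    unit_len: int
    units: int
    iv: Interval      # complete units only

    def __post_init__(self) -> None:
        if len(self.iv) != self.unit_len * self.units:
            raise ValueError("span does not equal unit_len * units")
        if _is_homopolymer(self.motif):
            raise ValueError(f"homopolymer motif {self.motif!r}")
        if set(self.motif) - _VALID:
            raise ValueError(f"motif {self.motif!r} contains invalid characters")


@dataclass
class SSRCandidate:
    """A repeat locus plus its polymorphism evidence and optional primers."""

    locus: RepeatLocus
    polymorphic: bool
    #: distance from the repeat boundary to the closest N column
    #: (0 = inside, 1 = adjacent); None when the track has no N at all
    nearest_ambiguous_offset: Optional[int]
    primers: object | None = None

    @property
    def iv(self) -> Interval:
        return self.locus.iv

    @property
    def marker_id(self) -> str:
        return f"ssr_{self.locus.motif}_{self.iv.start}"

    @property
    def polymorphism_count(self) -> int:
        return 1 if self.polymorphic else 0

    def to_record(self) -> dict:
        return {
            "id": self.marker_id,
            "start": self.iv.start,
            "end": self.iv.end,
            "motif": self.locus.motif,
            "unit_len": self.locus.unit_len,
            "units": self.locus.units,
            "polymorphic": int(self.polymorphic),
            "nearest_ambiguous_offset": (
                "" if self.nearest_ambiguous_offset is None
                else self.nearest_ambiguous_offset
            ),
        }


def find_perfect_repeats(
    track: str,
    unit_lens: Sequence[int] = (2, 3),
    min_units: int = 4,
) -> list[RepeatLocus]:
    """All maximal perfect tandem runs with >= ``min_units`` complete units.

    Runs never span a '-' (or any non-ACGT) column, homopolymer-equivalent
    motifs are excluded, and a run whose span exactly coincides with one
    already reported at a shorter unit length is suppressed. Results are
    sorted by start, then unit length.
    """
    if min_units < 2:
        raise ValueError("min_units must be >= 2")
    loci: dict[tuple[int, int], RepeatLocus] = {}
    n = len(track)
    for k in sorted(unit_lens):
        if k not in (2, 3):
            raise ValueError("unit lengths are restricted to 2 and 3")
        # Positions j where track[j] == track[j+k], both valid bases:
        # maximal stretches of such j define maximal tandem regions.
        j = 0
        while j + k < n:
            if track[j] not in _VALID or track[j] != track[j + k]:
                j += 1
                continue
            a = j
            while j + k < n and track[j + k] in _VALID and track[j] == track[j + k]:
                j += 1
            b = j  # track[a..b-1] all satisfy s[i] == s[i+k]
            region_len = (b - a) + k
            units = region_len // k
            if units >= min_units:
                motif = track[a:a + k]
                if not _is_homopolymer(motif):
                    span = Interval(a, a + units * k)
                    key = (span.start, span.end)
                    if key not in loci:
                        loci[key] = RepeatLocus(
                            motif=canonical_motif(motif),
                            unit_len=k,
                            units=units,
                            iv=span,
                        )
            j = max(j, a + 1)
    return sorted(loci.values(), key=lambda r: (r.iv.start, r.unit_len))


def nearest_ambiguous_offset(
    iv: Interval, n_columns: np.ndarray
) -> Optional[int]:
    """Distance from a span to the closest N column.

    0 if an N column lies inside the span; otherwise 1 for an adjacent
    column, 2 for one base away, etc. None if there is no N column.
    """
    if n_columns.size == 0:
        return None
    inside = (n_columns >= iv.start) & (n_columns < iv.end)
    if inside.any():
        return 0
    left = n_columns[n_columns < iv.start]
    right = n_columns[n_columns >= iv.end]
    best = None
    if left.size:
        best = int(iv.start - left.max())
    if right.size:
        d = int(right.min() - iv.end + 1)
        best = d if best is None else min(best, d)
    return best


def screen_polymorphic(
    loci: Iterable[RepeatLocus],
    ambiguous: str,
    proximity: int = 4,
) -> list[SSRCandidate]:
    """Flag each locus polymorphic iff an N column lies within the span or
    within ``proximity`` bases of either boundary (clipped at the ends)."""
    arr = np.frombuffer(ambiguous.encode("ascii"), dtype=np.uint8)
    n_columns = np.flatnonzero(arr == ord("N"))
    out = []
    for locus in loci:
        offset = nearest_ambiguous_offset(locus.iv, n_columns)
        out.append(
            SSRCandidate(
                locus=locus,
                polymorphic=offset is not None and offset <= proximity,
                nearest_ambiguous_offset=offset,
            )
        )
    return out
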