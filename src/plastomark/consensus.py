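"""Dual consensus tracks and identity/divergence profiling.

Two per-column tracks are derived from an alignment:

* the *best-base* track: the majority base of each column, gaps and N
  excluded from the vote (ties broken A<C<G<T); '-' where no base exists;
* the *ambiguous* track: an explicit base only where every row carries
  that same base (no gap, no N anywhere in the column), N otherwise.

Both tracks keep the full alignment length so that every downstream
coordinate (repeats, blocks, primers) lives in one frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .msa_io import Alignment, Interval

logger = logging.getLogger(__name__)

_BASES = b"ACGT"


def _to_matrix(a: Alignment) -> np.ndarray:
    """Alignment rows as an (n_rows, length) uint8 matrix of ASCII codes."""
    return np.frombuffer(
        "".join(a.rows).encode("ascii"), dtype=np.uint8
    ).reshape(a.n_rows, a.length)


@dataclass
class CoordMap:
    """Bidirectional map between one row's gapless positions and columns."""

    pos_to_col: np.ndarray  # gapless position -> alignment column
    col_to_pos: np.ndarray  # alignment column -> gapless position, -1 at gaps

    def column_of(self, pos: int) -> int:
        return int(self.pos_to_col[pos])

    def position_of(self, col: int) -> int:
        pos = int(self.col_to_pos[col])
        if pos < 0:
            raise ValueError(f"column {col} is a gap in this row")
        return pos


@dataclass
class ConsensusPair:
    """The best-base and ambiguous consensus tracks of one alignment."""

    best_base: str
    ambiguous: str
    source_ids: list[str]
    maps: list[CoordMap]
    #: columns whose ambiguous-track N arises from a substitution
    #: (no gap, no N in the column, >= 2 distinct bases)
    substitution_mask: np.ndarray = field(repr=False)

    _is_n: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.best_base) != len(self.ambiguous):
            raise ValueError("track length mismatch")

    @property
    def length(self) -> int:
        return len(self.best_base)

    @property
    def is_ambiguous(self) -> np.ndarray:
        """Boolean column mask: True where the ambiguous track carries N."""
        if self._is_n is None:
            arr = np.frombuffer(self.ambiguous.encode("ascii"), dtype=np.uint8)
            self._is_n = arr == ord("N")
        return self._is_n


def build_consensus_pair(a: Alignment) -> ConsensusPair:
    """Derive both consensus tracks and per-row coordinate maps."""
    if a.n_rows < 2:
        raise ValueError("consensus requires at least 2 rows")
    mat = _to_matrix(a)
    n_rows, length = mat.shape

    counts = np.stack([(mat == b).sum(axis=0) for b in _BASES])  # (4, L)
    total_bases = counts.sum(axis=0)

    # Best-base: argmax over A,C,G,T — numpy argmax takes the first maximum,
    # which is exactly the A<C<G<T tie-break.
    best_idx = counts.argmax(axis=0)
    best = np.frombuffer(_BASES, dtype=np.uint8)[best_idx]
    no_vote = total_bases == 0
    best[no_vote] = ord("-")
    n_blank_with_n = int((no_vote & (mat == ord("N")).any(axis=0)).sum())
    if n_blank_with_n:
        logger.warning(
            "%d column(s) contain only N/gap characters; best-base "
            "records '-' there", n_blank_with_n,
        )

    # Ambiguous: explicit base iff every row carries the same A/C/G/T.
    unanimous = (counts == n_rows).any(axis=0)
    ambig = np.where(unanimous, best, ord("N")).astype(np.uint8)

    gap_any = (mat == ord("-")).any(axis=0)
    n_any = (mat == ord("N")).any(axis=0)
    distinct = (counts > 0).sum(axis=0)
    substitution_mask = (~unanimous) & (~gap_any) & (~n_any) & (distinct >= 2)

    maps = []
    for r in range(n_rows):
        not_gap = mat[r] != ord("-")
        pos_to_col = np.flatnonzero(not_gap)
        col_to_pos = np.full(length, -1, dtype=np.int64)
        col_to_pos[pos_to_col] = np.arange(pos_to_col.size)
        maps.append(CoordMap(pos_to_col=pos_to_col, col_to_pos=col_to_pos))

    return ConsensusPair(
        best_base=best.tobytes().decode("ascii"),
        ambiguous=ambig.tobytes().decode("ascii"),
        source_ids=list(a.ids),
        maps=maps,
        substitution_mask=substitution_mask,
    )


def divergence(cp: ConsensusPair, iv: Interval) -> float:
    """Fraction of columns in ``iv`` that are ambiguous (N) in the pair."""
    if iv.end > cp.length:
        raise ValueError(f"interval end {iv.end} exceeds track length {cp.length}")
    return cp.ambiguous.count("N", iv.start, iv.end) / len(iv)


@dataclass(frozen=True)
class ProfileWindow:
    iv: Interval
    identity: float
    partial: bool


def sliding_identity_profile(
    a: Alignment, window: int, step: int
) -> list[ProfileWindow]:
    """Per-window identity (1 - divergence) along the alignment.

    The final partial window, if any, is included and flagged.
    """
    if not (1 <= window <= a.length):
        raise ValueError(f"window {window} out of range for length {a.length}")
    if step < 1:
        raise ValueError("step must be >= 1")
    cp = build_consensus_pair(a)
    out: list[ProfileWindow] = []
    start = 0
    while start < a.length:
        end = min(start + window, a.length)
        iv = Interval(start, end)
        out.append(
            ProfileWindow(
                iv=iv,
                identity=1.0 - divergence(cp, iv),
                partial=(end - start) < window,
            )
        )
        if end == a.length:
            break
        start += step
    return out


def consensus_fasta(cp: ConsensusPair) -> str:
    """The two tracks as a 2-record FASTA string."""
    return (
        f">best_base\n{cp.best_base}\n>ambiguous\n{cp.ambiguous}\n"
    )


def profile_tsv(profile: list[ProfileWindow]) -> str:
    lines = ["start\tend\tidentity\tpartial"]
    for w in profile:
        lines.append(f"{w.iv.start}\t{w.iv.end}\t{w.identity:.6g}\t{int(w.partial)}")
    return "\n".join(lines) + "\n"
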