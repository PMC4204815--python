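"""Fixed-width hypervariable barcode-block discovery.

A candidate window of ``block_len`` columns is accepted when all four
criteria hold on the consensus pair:

1. divergence (ambiguous-column fraction) >= ``min_divergence``;
2. divergence <= ``max_divergence`` (level-dependent cap);
3. no run of consecutive ambiguous columns longer than
   ``max_ambiguous_run``;
4. at least ``min_flanked_snps`` substitution columns, each bordered on
   both sides by ``flank_width`` perfectly conserved columns.

Overlapping accepted windows are merged; merged-block statistics are
recomputed on the union but not re-filtered (the guarantee is that every
constituent window passed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .consensus import ConsensusPair, divergence
from .msa_io import Interval

GENUS = "genus"
FAMILY = "family"

_LEVEL_MAX_DIVERGENCE = {GENUS: 0.10, FAMILY: 0.15}
_LEVEL_MIN_FLANKED_SNPS = {GENUS: 5, FAMILY: 8}


@dataclass(frozen=True)
class ScanParams:
    """Thresholds of the block filter. All bounds are inclusive."""

    level: str = FAMILY
    block_len: int = 300
    min_divergence: float = 0.02
    max_divergence: float = 0.15
    min_flanked_snps: int = 8
    flank_width: int = 5
    max_ambiguous_run: int = 7
    step: int = 1

    def __post_init__(self) -> None:
        if self.level not in (GENUS, FAMILY):
            raise ValueError(f"unknown comparison level {self.level!r}")
        if not (0 <= self.min_divergence < self.max_divergence <= 1):
            raise ValueError("require 0 <= min_divergence < max_divergence <= 1")
        if self.flank_width < 0:
            raise ValueError("flank_width must be >= 0")
        if self.block_len <= 2 * self.flank_width:
            raise ValueError("block_len must exceed 2 * flank_width")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    @classmethod
    def for_level(cls, level: str, **overrides) -> "ScanParams":
        """Level presets: genus caps divergence at 10% and needs >= 5
        flanked SNPs; family caps at 15% and needs >= 8."""
        if level not in (GENUS, FAMILY):
            raise ValueError(f"unknown comparison level {level!r}")
        params = dict(
            level=level,
            max_divergence=_LEVEL_MAX_DIVERGENCE[level],
            min_flanked_snps=_LEVEL_MIN_FLANKED_SNPS[level],
        )
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True)
class BarcodeBlock:
    """An accepted (possibly merged) candidate barcode region."""

    iv: Interval
    divergence: float
    flanked_snp_count: int
    max_ambig_run: int
    level: str
    merged_from: int = 1

    @property
    def marker_id(self) -> str:
        return f"block_{self.level}_{self.iv.start}"

    @property
    def polymorphism_count(self) -> int:
        return self.flanked_snp_count

    def to_record(self) -> dict:
        return {
            "id": self.marker_id,
            "start": self.iv.start,
            "end": self.iv.end,
            "level": self.level,
            "divergence": round(self.divergence, 6),
            "flanked_snp_count": self.flanked_snp_count,
            "max_ambig_run": self.max_ambig_run,
            "merged_from": self.merged_from,
        }


def flanked_snp_columns(cp: ConsensusPair, flank_width: int = 5) -> np.ndarray:
    """Boolean mask over all columns: substitution columns whose
    ``flank_width`` neighbours on both sides are perfectly conserved.

    Flanks may extend outside any particular window but not outside the
    alignment; a column too close to either end never qualifies.
    """
    explicit = ~cp.is_ambiguous
    sub = cp.substitution_mask
    length = cp.length
    if flank_width == 0:
        return sub.copy()
    # run of explicit columns ending at i (inclusive)
    left_run = np.zeros(length, dtype=np.int64)
    run = 0
    expl = explicit
    for i in range(length):
        run = run + 1 if expl[i] else 0
        left_run[i] = run
    right_run = np.zeros(length, dtype=np.int64)
    run = 0
    for i in range(length - 1, -1, -1):
        run = run + 1 if expl[i] else 0
        right_run[i] = run
    ok = sub.copy()
    idx = np.flatnonzero(sub)
    for i in idx:
        left_ok = i - flank_width >= 0 and left_run[i - 1] >= flank_width
        right_ok = i + flank_width < length and right_run[i + 1] >= flank_width
        ok[i] = left_ok and right_ok
    return ok


def count_flanked_snps(
    cp: ConsensusPair, iv: Interval, flank_width: int = 5
) -> int:
    """Number of qualifying flanked-SNP columns within ``iv``."""
    if iv.end > cp.length:
        raise ValueError("interval out of bounds")
    mask = flanked_snp_columns(cp, flank_width)
    return int(mask[iv.start:iv.end].sum())


def max_ambiguous_run(cp: ConsensusPair, iv: Interval) -> int:
    """Length of the longest run of consecutive N columns within ``iv``."""
    if iv.end > cp.length:
        raise ValueError("interval out of bounds")
    best = run = 0
    for is_n in cp.is_ambiguous[iv.start:iv.end]:
        run = run + 1 if is_n else 0
        best = max(best, run)
    return best


def _block_stats(cp: ConsensusPair, iv: Interval, p: ScanParams) -> BarcodeBlock:
    return BarcodeBlock(
        iv=iv,
        divergence=divergence(cp, iv),
        flanked_snp_count=count_flanked_snps(cp, iv, p.flank_width),
        max_ambig_run=max_ambiguous_run(cp, iv),
        level=p.level,
    )


def scan_blocks(cp: ConsensusPair, p: ScanParams) -> list[BarcodeBlock]:
    """Slide a ``block_len`` window along the consensus and return the
    merged accepted blocks, sorted by start."""
    length = cp.length
    if length < p.block_len:
        raise ValueError(
            f"alignment length {length} is shorter than block_len {p.block_len}"
        )
    is_n = cp.is_ambiguous
    n_cum = np.concatenate(([0], np.cumsum(is_n)))
    snp_mask = flanked_snp_columns(cp, p.flank_width)
    snp_cum = np.concatenate(([0], np.cumsum(snp_mask)))

    # A window fails the run criterion iff it fully contains a run of
    # max_ambiguous_run + 1 consecutive N columns.
    r1 = p.max_ambiguous_run + 1
    if length >= r1:
        window_n = n_cum[r1:] - n_cum[:-r1]
        bad_start = window_n == r1  # position j starts an over-long N run
    else:
        bad_start = np.zeros(0, dtype=bool)
    bad_cum = np.concatenate(([0], np.cumsum(bad_start)))

    accepted: list[Interval] = []
    b = p.block_len
    for s in range(0, length - b + 1, p.step):
        e = s + b
        n_ambig = int(n_cum[e] - n_cum[s])
        div = n_ambig / b
        if div < p.min_divergence or div > p.max_divergence:
            continue
        # any over-long run starting in [s, e - r1]?
        lo, hi = s, e - r1 + 1
        if hi > lo and int(bad_cum[hi] - bad_cum[lo]) > 0:
            continue
        if int(snp_cum[e] - snp_cum[s]) < p.min_flanked_snps:
            continue
        accepted.append(Interval(s, e))

    # merge overlapping accepted windows
    blocks: list[BarcodeBlock] = []
    i = 0
    while i < len(accepted):
        start, end = accepted[i].start, accepted[i].end
        merged = 1
        j = i + 1
        while j < len(accepted) and accepted[j].start < end:
            end = max(end, accepted[j].end)
            merged += 1
            j += 1
        stats = _block_stats(cp, Interval(start, end), p)
        blocks.append(replace(stats, merged_from=merged))
        i = j
    return blocks
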