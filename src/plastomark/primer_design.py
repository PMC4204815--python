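"""Primer enumeration and pairing confined to perfectly conserved
consensus sequence flanking a target marker.

Candidate oligos are substrings of the ambiguous consensus whose columns
are all explicit bases (perfectly conserved across the alignment), found
within a bounded search flank on each side of the target. Pairs are
filtered on product size, pair Tm difference, a simple cross/self-dimer
screen, and the requirement that the amplicon interior cover at least one
polymorphic column of the target; survivors are ranked by a deterministic
penalty.
"""

from __future__ import annotations

import bisect
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .consensus import ConsensusPair
from .msa_io import Interval

logger = logging.getLogger(__name__)

R_GAS = 1.987  # cal / (mol K)

# SantaLucia (1998) unified nearest-neighbor parameters:
# dH in kcal/mol, dS in cal/(mol K), 5'->3' top-strand dinucleotides.
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)   # terminal G*C initiation
_INIT_AT = (2.3, 4.1)    # terminal A*T initiation

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(
    oligo: str,
    monovalent_mM: float = 50.0,
    oligo_conc_uM: float = 0.25,
) -> float:
    """Nearest-neighbor Tm (SantaLucia 1998 unified parameters), degrees C.

    Salt correction: dS + 0.368 * (N-1) * ln[Na+]. Non-self-complementary
    duplex assumed (CT/4); self-complementary oligos use CT/1 with the
    symmetry entropy penalty.
    """
    if len(oligo) < 8:
        raise ValueError("oligo must be at least 8 bases")
    bad = set(oligo) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguous base(s) in oligo: {sorted(bad)}")
    dh, ds = 0.0, 0.0
    for end in (oligo[0], oligo[-1]):
        inc = _INIT_GC if end in "GC" else _INIT_AT
        dh += inc[0]
        ds += inc[1]
    for i in range(len(oligo) - 1):
        h, s = NN_PARAMS[oligo[i:i + 2]]
        dh += h
        ds += s
    self_comp = oligo == reverse_complement(oligo)
    if self_comp:
        ds += -1.4
    ds += 0.368 * (len(oligo) - 1) * math.log(monovalent_mM / 1000.0)
    conc = oligo_conc_uM * 1e-6
    divisor = 1.0 if self_comp else 4.0
    tm_kelvin = (dh * 1000.0) / (ds + R_GAS * math.log(conc / divisor))
    return round(tm_kelvin - 273.15, 2)


def wallace_tm(oligo: str) -> float:
    """Wallace-rule Tm: 2(A+T) + 4(G+C); rough, for very short oligos."""
    at = oligo.count("A") + oligo.count("T")
    gc = oligo.count("G") + oligo.count("C")
    return 2.0 * at + 4.0 * gc


@dataclass(frozen=True)
class PrimerConstraints:
    primer_len: tuple[int, int] = (18, 24)
    product_size: tuple[int, int] = (100, 280)
    tm: tuple[float, float] = (52.0, 62.0)
    max_pair_dtm: float = 4.0
    gc: tuple[float, float] = (0.30, 0.70)
    max_search_flank: int = 300
    max_complementarity_run: int = 8
    target_tm: Optional[float] = None  # defaults to midpoint of tm range

    def __post_init__(self) -> None:
        if self.primer_len[0] > self.primer_len[1] or self.primer_len[0] < 8:
            raise ValueError("invalid primer length range")
        if self.product_size[0] > self.product_size[1]:
            raise ValueError("invalid product size range")
        if self.product_size[0] < 2 * self.primer_len[0]:
            raise ValueError(
                "product_size.min must be >= 2 * primer_len.min"
            )

    @property
    def optimal_tm(self) -> float:
        if self.target_tm is not None:
            return self.target_tm
        return (self.tm[0] + self.tm[1]) / 2.0


@dataclass(frozen=True)
class PrimerSite:
    """One candidate oligo placement on the plus strand of the consensus."""

    orientation: str  # "fwd" | "rev"
    iv: Interval
    seq: str          # oligo 5'->3' (reverse primers are revcomp'd)
    tm: float
    gc: float


@dataclass(frozen=True)
class PrimerPair:
    fwd: PrimerSite
    rev: PrimerSite
    product_size: int
    penalty: float

    @property
    def fwd_seq(self) -> str:
        return self.fwd.seq

    @property
    def rev_seq(self) -> str:
        return self.rev.seq

    def to_record(self) -> dict:
        return {
            "fwd_seq": self.fwd.seq,
            "rev_seq": self.rev.seq,
            "fwd_start_1based": self.fwd.iv.start + 1,
            "fwd_end_1based": self.fwd.iv.end,
            "rev_start_1based": self.rev.iv.start + 1,
            "rev_end_1based": self.rev.iv.end,
            "tm_fwd": self.fwd.tm,
            "tm_rev": self.rev.tm,
            "gc_fwd": round(self.fwd.gc, 4),
            "gc_rev": round(self.rev.gc, 4),
            "product_size": self.product_size,
            "penalty": round(self.penalty, 4),
        }


def _conserved_runs(cp: ConsensusPair, lo: int, hi: int):
    """Maximal runs of explicit (non-N) columns intersecting [lo, hi)."""
    explicit = ~cp.is_ambiguous
    runs = []
    i = max(lo, 0)
    hi = min(hi, cp.length)
    while i < hi:
        if explicit[i]:
            j = i
            while j < hi and explicit[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def enumerate_conserved_sites(
    cp: ConsensusPair,
    around: Interval,
    c: PrimerConstraints,
    diagnostics: Counter | None = None,
) -> list[PrimerSite]:
    """All oligo placements drawn entirely from conserved columns.

    Forward placements start within ``max_search_flank`` columns upstream
    of ``around.start`` (and before it); reverse placements end within the
    flank downstream of ``around.end`` (and after it). Tm and GC are
    filtered against the constraint ranges.
    """
    if around.end > cp.length:
        raise ValueError("target interval out of bounds")
    diag = diagnostics if diagnostics is not None else Counter()
    sites: list[PrimerSite] = []
    min_len, max_len = c.primer_len

    def consider(orientation: str, start: int, end: int) -> None:
        template = cp.ambiguous[start:end]
        seq = template if orientation == "fwd" else reverse_complement(template)
        gc = gc_fraction(seq)
        if not (c.gc[0] <= gc <= c.gc[1]):
            diag["gc_out_of_range"] += 1
            return
        tm = melting_temperature(seq)
        if not (c.tm[0] <= tm <= c.tm[1]):
            diag["tm_out_of_range"] += 1
            return
        sites.append(
            PrimerSite(orientation=orientation, iv=Interval(start, end),
                       seq=seq, tm=tm, gc=gc)
        )

    # Forward: start in [around.start - flank, around.start)
    f_lo = max(0, around.start - c.max_search_flank)
    for run_start, run_end in _conserved_runs(cp, f_lo, around.start + max_len):
        for start in range(max(run_start, f_lo), min(run_end, around.start)):
            for length in range(min_len, max_len + 1):
                end = start + length
                if end > run_end:
                    break
                consider("fwd", start, end)

    # Reverse: end in (around.end, around.end + flank]
    r_hi = min(cp.length, around.end + c.max_search_flank)
    for run_start, run_end in _conserved_runs(cp, around.end - max_len, r_hi):
        for end in range(max(run_start + min_len, around.end + 1),
                         min(run_end, r_hi) + 1):
            for length in range(min_len, max_len + 1):
                start = end - length
                if start < run_start:
                    break
                consider("rev", start, end)

    return sites


def _longest_complementarity_run(a: str, b: str) -> int:
    """Longest contiguous stretch of ``a`` complementary (antiparallel)
    to a stretch of ``b``; both oligos given 5'->3'."""
    target = reverse_complement(b)
    n, m = len(a), len(target)
    best = 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == target[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def _kmers(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def _pair_penalty(fwd: PrimerSite, rev: PrimerSite, c: PrimerConstraints) -> float:
    opt = c.optimal_tm
    penalty = abs(fwd.tm - opt) + abs(rev.tm - opt)
    penalty += 2.0 * (abs(fwd.gc - 0.5) + abs(rev.gc - 0.5))
    for site in (fwd, rev):
        if site.seq[-1] in "GC":  # 3' GC clamp bonus
            penalty -= 0.25
    return penalty


def design_pairs(
    cp: ConsensusPair,
    target: Interval,
    c: PrimerConstraints = PrimerConstraints(),
    k: int = 5,
    return_diagnostics: bool = False,
):
    """Top-``k`` primer pairs flanking ``target``, ranked by penalty.

    A pair qualifies when its product size is in range, the pair Tm
    difference is within ``max_pair_dtm``, neither the cross- nor the
    self-dimer screen fires, and the amplicon interior covers at least one
    polymorphic (N) column of the target. Order is deterministic:
    (penalty, forward start, product size, reverse end).
    """
    diag: Counter = Counter()
    sites = enumerate_conserved_sites(cp, target, c, diagnostics=diag)
    fwd_sites = [s for s in sites if s.orientation == "fwd"]
    rev_sites = [s for s in sites if s.orientation == "rev"]
    if not fwd_sites:
        diag["no_forward_site"] += 1
    if not rev_sites:
        diag["no_reverse_site"] += 1

    n_cols = np.flatnonzero(cp.is_ambiguous[target.start:target.end]) + target.start

    # A complementarity run of length >= r exists iff the oligo shares an
    # r-mer with the reverse complement of its partner.
    r = c.max_complementarity_run
    fwd_kmers = {s: _kmers(s.seq, r) for s in fwd_sites}
    rev_rc_kmers = {s: _kmers(reverse_complement(s.seq), r) for s in rev_sites}
    self_dimer_bad = {
        s: not _kmers(s.seq, r).isdisjoint(_kmers(reverse_complement(s.seq), r))
        for s in sites
    }

    rev_sites = sorted(rev_sites, key=lambda s: s.iv.end)
    rev_ends = [s.iv.end for s in rev_sites]

    pairs: list[PrimerPair] = []
    for fwd in fwd_sites:
        lo = bisect.bisect_left(rev_ends, fwd.iv.start + c.product_size[0])
        hi = bisect.bisect_right(rev_ends, fwd.iv.start + c.product_size[1])
        diag["product_size_out_of_range"] += len(rev_sites) - (hi - lo)
        for rev in rev_sites[lo:hi]:
            if rev.iv.start < fwd.iv.end:
                diag["overlapping_placement"] += 1
                continue
            product = rev.iv.end - fwd.iv.start
            if abs(fwd.tm - rev.tm) > c.max_pair_dtm:
                diag["pair_tm_difference"] += 1
                continue
            covered = n_cols[(n_cols >= fwd.iv.end) & (n_cols < rev.iv.start)]
            if covered.size == 0:
                diag["no_polymorphic_column_amplified"] += 1
                continue
            if self_dimer_bad[fwd] or self_dimer_bad[rev]:
                diag["self_dimer"] += 1
                continue
            if not fwd_kmers[fwd].isdisjoint(rev_rc_kmers[rev]):
                diag["cross_dimer"] += 1
                continue
            pairs.append(
                PrimerPair(
                    fwd=fwd, rev=rev, product_size=product,
                    penalty=_pair_penalty(fwd, rev, c),
                )
            )

    pairs.sort(key=lambda p: (p.penalty, p.fwd.iv.start, p.product_size,
                              p.rev.iv.end))
    result = pairs[:k]
    if not result:
        logger.info(
            "no primer pair for target [%d, %d); elimination histogram: %s",
            target.start, target.end, dict(diag),
        )
    if return_diagnostics:
        return result, diag
    return result
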