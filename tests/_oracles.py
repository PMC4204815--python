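"""Independent brute-force oracles used by the test suite.

These deliberately re-derive every quantity from first principles (raw
rows, naive loops, separately transcribed constants) and never call into
the package's own scanning logic.
"""

from __future__ import annotations

import math

_ACGT = set("ACGT")


# --- tandem repeats --------------------------------------------------------

def brute_repeats(track: str, unit_lens=(2, 3), min_units: int = 4):
    """Every maximal perfect tandem repeat, by testing all (start, k)
    pairs directly. Returns a sorted list of (start, end, units, k)."""
    found = {}
    n = len(track)
    for k in sorted(unit_lens):
        for start in range(n - k * min_units + 1):
            motif = track[start:start + k]
            if set(motif) - _ACGT or len(set(motif)) == 1:
                continue
            # left-maximality: cannot shift the run one base left
            if start > 0 and track[start - 1] in _ACGT \
                    and track[start - 1] == track[start + k - 1]:
                continue
            units = 1
            while True:
                nxt = track[start + units * k: start + (units + 1) * k]
                if len(nxt) == k and nxt == motif:
                    units += 1
                else:
                    break
            if units >= min_units:
                span = (start, start + units * k)
                if span not in found:
                    found[span] = (start, span[1], units, k)
    return sorted(found.values(), key=lambda t: (t[0], t[3]))


# --- barcode blocks --------------------------------------------------------

def column_states(rows: list[str]):
    """Per-column classification straight from the rows: returns three
    parallel 0/1 lists (conserved, ambiguous, substitution)."""
    length = len(rows[0])
    conserved, ambiguous, snp = [], [], []
    for i in range(length):
        chars = [r[i] for r in rows]
        uniq = set(chars)
        is_cons = len(uniq) == 1 and uniq <= _ACGT
        conserved.append(1 if is_cons else 0)
        ambiguous.append(0 if is_cons else 1)
        explicit = {c for c in chars if c in _ACGT}
        is_snp = (
            "-" not in uniq and "N" not in uniq and len(explicit) >= 2
        )
        snp.append(1 if is_snp else 0)
    return conserved, ambiguous, snp


def qualifying_snp_columns(rows: list[str], flank_width: int = 5):
    """0/1 list: substitution columns with ``flank_width`` conserved
    columns strictly inside the alignment on both sides."""
    conserved, _, snp = column_states(rows)
    length = len(conserved)
    out = [0] * length
    for i in range(length):
        if not snp[i]:
            continue
        lo, hi = i - flank_width, i + flank_width
        if lo < 0 or hi >= length:
            continue
        if all(conserved[j] for j in range(lo, i)) and \
                all(conserved[j] for j in range(i + 1, hi + 1)):
            out[i] = 1
    return out


def brute_accepted_windows(rows: list[str], block_len: int,
                           min_divergence: float, max_divergence: float,
                           min_flanked_snps: int, flank_width: int,
                           max_ambiguous_run: int):
    """All accepted (start, end) windows at stride 1, evaluated naively."""
    _, ambiguous, _ = column_states(rows)
    qual = qualifying_snp_columns(rows, flank_width)
    length = len(ambiguous)
    accepted = []
    for s in range(length - block_len + 1):
        e = s + block_len
        window = ambiguous[s:e]
        div = sum(window) / block_len
        if div < min_divergence or div > max_divergence:
            continue
        run = best = 0
        for x in window:
            run = run + 1 if x else 0
            best = max(best, run)
        if best > max_ambiguous_run:
            continue
        if sum(qual[s:e]) < min_flanked_snps:
            continue
        accepted.append((s, e))
    return accepted


def merge_windows(windows):
    """Union of overlapping (start, end) windows -> (start, end, count)."""
    merged = []
    for s, e in windows:
        if merged and s < merged[-1][1]:
            ps, pe, n = merged[-1]
            merged[-1] = (ps, max(pe, e), n + 1)
        else:
            merged.append((s, e, 1))
    return merged


# --- melting temperature ---------------------------------------------------

# Unified NN parameters, transcribed independently of the implementation.
_ORACLE_NN = {
    "AA": (-7.9, -22.2), "AC": (-8.4, -22.4), "AG": (-7.8, -21.0),
    "AT": (-7.2, -20.4), "CA": (-8.5, -22.7), "CC": (-8.0, -19.9),
    "CG": (-10.6, -27.2), "CT": (-7.8, -21.0), "GA": (-8.2, -22.2),
    "GC": (-9.8, -24.4), "GG": (-8.0, -19.9), "GT": (-8.4, -22.4),
    "TA": (-7.2, -21.3), "TC": (-8.2, -22.2), "TG": (-8.5, -22.7),
    "TT": (-7.9, -22.2),
}


def _oracle_revcomp(s: str) -> str:
    return "".join({"A": "T", "T": "A", "C": "G", "G": "C"}[c]
                   for c in reversed(s))


def brute_nn_tm(seq: str, na_molar: float = 0.05,
                conc_molar: float = 0.25e-6) -> float:
    """Hand-summed SantaLucia-1998 Tm with salt-corrected entropy."""
    dh = ds = 0.0
    for terminal in (seq[0], seq[-1]):
        if terminal in "GC":
            dh += 0.1
            ds += -2.8
        else:
            dh += 2.3
            ds += 4.1
    for i in range(len(seq) - 1):
        h, s = _ORACLE_NN[seq[i:i + 2]]
        dh += h
        ds += s
    sym = seq == _oracle_revcomp(seq)
    if sym:
        ds += -1.4
    ds += 0.368 * (len(seq) - 1) * math.log(na_molar)
    ct = conc_molar if sym else conc_molar / 4.0
    return dh * 1000.0 / (ds + 1.987 * math.log(ct)) - 273.15


# --- K80 -------------------------------------------------------------------

def brute_k80(a: str, b: str):
    """(P, Q, d) by direct per-column counting; d is None if saturated."""
    ti = tv = n = 0
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    for x, y in zip(a, b):
        if x in _ACGT and y in _ACGT:
            n += 1
            if x != y:
                if (x, y) in transitions:
                    ti += 1
                else:
                    tv += 1
    p, q = ti / n, tv / n
    arg1 = 1 - 2 * p - q
    arg2 = 1 - 2 * q
    if arg1 <= 0 or arg2 <= 0:
        return p, q, None
    return p, q, -0.5 * math.log(arg1 * math.sqrt(arg2))
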