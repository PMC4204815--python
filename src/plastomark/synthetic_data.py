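"""Simulation of small plastome families with planted, ground-truthed
marker structure.

An ancestral sequence is drawn uniformly and evolved along a user-supplied
tree under a K80 substitution process with per-site rate multipliers
(conserved islands x0, variable blocks x10 by default). SSR loci are
realized post-hoc with explicit per-taxon unit counts (length variants
padded with gap columns, emulating aligner output), and indels are planted
as gap columns. Realized — not merely requested — feature statistics are
recorded in the truth table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import dendropy
import numpy as np

from .msa_io import Alignment, Interval
from .consensus import build_consensus_pair, divergence
from .barcode_scan import (
    ScanParams, count_flanked_snps, max_ambiguous_run, FAMILY, GENUS,
)
from .ssr_scan import find_perfect_repeats, screen_polymorphic

_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: 5-taxon default topology: ((Zof,Hco) with Clo) vs (Aze,Aca)
DEFAULT_TREE = (
    "(((Zof:0.02,Hco:0.02):0.01,Clo:0.03):0.01,(Aze:0.02,Aca:0.02):0.01);"
)


@dataclass(frozen=True)
class PlantedFeature:
    kind: str  # conserved_island | variable_block | ssr_locus | indel
    start: int
    length: int = 0
    rate_multiplier: float = 10.0        # variable_block only
    motif: str = "AT"                    # ssr_locus only
    unit_counts: tuple[int, ...] = ()    # ssr_locus: per-taxon, leaf order
    taxa: tuple[str, ...] = ()           # indel: rows receiving the gap

    @property
    def footprint(self) -> int:
        if self.kind == "ssr_locus":
            if not self.unit_counts:
                raise ValueError("ssr_locus needs unit_counts")
            return len(self.motif) * max(self.unit_counts)
        return self.length

    @property
    def iv(self) -> Interval:
        return Interval(self.start, self.start + self.footprint)


@dataclass(frozen=True)
class SimulationSpec:
    tree: str = DEFAULT_TREE
    seq_len: int = 20_000
    kappa: float = 2.0
    base_mutation_rate: float = 1.0
    planted_features: tuple[PlantedFeature, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        feats = sorted(self.planted_features, key=lambda f: f.start)
        prev_end = 0
        for f in feats:
            if f.kind not in (
                "conserved_island", "variable_block", "ssr_locus", "indel"
            ):
                raise ValueError(f"unknown feature kind {f.kind!r}")
            if f.start < prev_end:
                raise ValueError(
                    f"feature at {f.start} overlaps the previous feature"
                )
            prev_end = f.start + f.footprint
            if prev_end > self.seq_len:
                raise ValueError(
                    f"feature at {f.start} exceeds seq_len {self.seq_len}"
                )


@dataclass
class TruthRecord:
    kind: str
    iv: Interval
    stats: dict

    def to_row(self) -> dict:
        return {
            "kind": self.kind,
            "start": self.iv.start,
            "end": self.iv.end,
            **{k: v for k, v in self.stats.items()},
        }


@dataclass
class TruthTable:
    records: list[TruthRecord]

    def of_kind(self, kind: str) -> list[TruthRecord]:
        return [r for r in self.records if r.kind == kind]

    def to_tsv(self) -> str:
        if not self.records:
            return "kind\tstart\tend\n"
        keys: list[str] = []
        for r in self.records:
            for k in r.to_row():
                if k not in keys:
                    keys.append(k)
        lines = ["\t".join(keys)]
        for r in self.records:
            row = r.to_row()
            lines.append("\t".join(str(row.get(k, "")) for k in keys))
        return "\n".join(lines) + "\n"


def k80_event_probs(t: np.ndarray, kappa: float):
    """Per-site K80 probabilities (transition, each transversion) after
    expected ``t`` substitutions per site, rate matrix normalized to one
    substitution per unit time."""
    t = np.asarray(t, dtype=float)
    e1 = np.exp(-4.0 * t / (kappa + 2.0))
    e2 = np.exp(-2.0 * t * (kappa + 1.0) / (kappa + 2.0))
    p_ti = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    return p_ti, p_tv


def _evolve(parent: np.ndarray, t_sites: np.ndarray, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """One branch of K80 evolution; ``t_sites`` is the per-site expected
    number of substitutions (branch length x rate multiplier)."""
    p_ti, p_tv = k80_event_probs(t_sites, kappa)
    u = rng.random(parent.size)
    child = parent.copy()
    ti = u < p_ti
    tv1 = (~ti) & (u < p_ti + p_tv)
    tv2 = (~ti) & (~tv1) & (u < p_ti + 2.0 * p_tv)
    child[ti] = (parent[ti] + 2) % 4
    child[tv1] = (parent[tv1] + 1) % 4
    child[tv2] = (parent[tv2] + 3) % 4
    return child


def simulate_family(spec: SimulationSpec) -> tuple[Alignment, TruthTable]:
    """Evolve a family alignment and report realized feature statistics."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tree = dendropy.Tree.get(data=spec.tree, schema="newick")

    rate = np.ones(spec.seq_len)
    for f in spec.planted_features:
        if f.kind == "conserved_island":
            rate[f.start:f.start + f.footprint] = 0.0
        elif f.kind == "variable_block":
            rate[f.start:f.start + f.footprint] = f.rate_multiplier
        elif f.kind == "ssr_locus":
            rate[f.start:f.start + f.footprint] = 0.0  # overwritten below

    ancestor = rng.integers(0, 4, size=spec.seq_len, dtype=np.int64)
    leaf_codes: dict[str, np.ndarray] = {}
    leaf_order: list[str] = []

    def descend(node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            t = (child.edge.length or 0.0) * spec.base_mutation_rate
            child_seq = _evolve(seq, t * rate, spec.kappa, rng)
            if child.is_leaf():
                name = child.taxon.label.replace(" ", "_")
                leaf_codes[name] = child_seq
                leaf_order.append(name)
            else:
                descend(child, child_seq)

    descend(tree.seed_node, ancestor)

    # materialize rows as character arrays so features can plant gaps
    rows = {
        name: _CODES[codes].copy() for name, codes in leaf_codes.items()
    }
    for f in spec.planted_features:
        if f.kind == "ssr_locus":
            if len(f.unit_counts) != len(leaf_order):
                raise ValueError(
                    "ssr_locus unit_counts must match taxon count"
                )
            footprint = f.footprint
            for name, n_units in zip(leaf_order, f.unit_counts):
                rep = (f.motif * n_units).encode("ascii")
                region = rep + b"-" * (footprint - len(rep))
                rows[name][f.start:f.start + footprint] = np.frombuffer(
                    region, dtype=np.uint8
                )
        elif f.kind == "indel":
            for name in f.taxa:
                if name not in rows:
                    raise ValueError(f"indel names unknown taxon {name!r}")
                rows[name][f.start:f.start + f.length] = ord("-")

    alignment = Alignment(
        ids=list(leaf_order),
        rows=[rows[name].tobytes().decode("ascii") for name in leaf_order],
    )
    truth = _build_truth(alignment, spec, leaf_order)
    return alignment, truth


def _build_truth(alignment: Alignment, spec: SimulationSpec,
                 leaf_order: list[str]) -> TruthTable:
    cp = build_consensus_pair(alignment)
    family = ScanParams.for_level(FAMILY)
    genus = ScanParams.for_level(GENUS)
    repeat_loci = find_perfect_repeats(cp.best_base)
    candidates = screen_polymorphic(repeat_loci, cp.ambiguous)

    records: list[TruthRecord] = []
    for f in spec.planted_features:
        iv = f.iv
        if f.kind == "variable_block":
            div = divergence(cp, iv)
            snps = count_flanked_snps(cp, iv, family.flank_width)
            run = max_ambiguous_run(cp, iv)
            stats = {
                "divergence": round(div, 6),
                "flanked_snp_count": snps,
                "max_ambig_run": run,
                "passes_family": int(
                    family.min_divergence <= div <= family.max_divergence
                    and run <= family.max_ambiguous_run
                    and snps >= family.min_flanked_snps
                ),
                "passes_genus": int(
                    genus.min_divergence <= div <= genus.max_divergence
                    and run <= genus.max_ambiguous_run
                    and snps >= genus.min_flanked_snps
                ),
            }
        elif f.kind == "ssr_locus":
            overlapping = [
                c for c in candidates if c.iv.overlaps(iv)
                and c.locus.motif == min(
                    f.motif[i:] + f.motif[:i] for i in range(len(f.motif))
                )
            ]
            stats = {
                "motif": f.motif,
                "unit_counts": ",".join(map(str, f.unit_counts)),
                "detected": int(bool(overlapping)),
                "polymorphic": int(any(c.polymorphic for c in overlapping)),
            }
        elif f.kind == "conserved_island":
            stats = {
                "n_ambiguous_columns": int(
                    cp.is_ambiguous[iv.start:iv.end].sum()
                ),
            }
        else:  # indel
            stats = {"taxa": ",".join(f.taxa)}
        records.append(TruthRecord(kind=f.kind, iv=iv, stats=stats))
    return TruthTable(records=records)


def default_simulation_spec(seed: int = 0) -> SimulationSpec:
    """A standard 20 kb / 5-taxon spec with a representative feature mix."""
    features = (
        PlantedFeature(kind="conserved_island", start=1_000, length=800),
        PlantedFeature(kind="variable_block", start=4_000, length=300),
        PlantedFeature(kind="ssr_locus", start=6_000, motif="AT",
                       unit_counts=(5, 5, 6, 5, 5)),
        PlantedFeature(kind="conserved_island", start=8_000, length=600),
        PlantedFeature(kind="variable_block", start=11_000, length=300),
        PlantedFeature(kind="ssr_locus", start=13_000, motif="CAG",
                       unit_counts=(4, 4, 4, 5, 4)),
        PlantedFeature(kind="indel", start=16_000, length=12,
                       taxa=("Clo",)),
    )
    return SimulationSpec(
        seq_len=20_000,
        base_mutation_rate=0.04,
        planted_features=features,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Constructed (non-stochastic beyond the background draw) fixtures for exact
# boundary probing: a perfectly conserved family plus hand-planted columns.

def conserved_alignment(n_rows: int = 5, length: int = 600,
                        seed: int = 0) -> Alignment:
    """All rows identical: a random background with zero divergence."""
    rng = np.random.default_rng(seed)
    row = _CODES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
    return Alignment(
        ids=[f"taxon{i}" for i in range(n_rows)],
        rows=[row] * n_rows,
    )


def _substitute(base: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[base]


def plant_substitutions(a: Alignment, columns, row: int = 1) -> Alignment:
    """Return a copy with one row's base changed at each given column,
    turning those columns into substitution (SNP) columns."""
    rows = [list(r) for r in a.rows]
    for col in columns:
        rows[row][col] = _substitute(rows[row][col])
    return Alignment(ids=list(a.ids), rows=["".join(r) for r in rows])


def plant_gaps(a: Alignment, columns, row: int = 1) -> Alignment:
    """Return a copy with one row gapped at each given column (an
    indel-style ambiguous column: divergent but not a SNP)."""
    rows = [list(r) for r in a.rows]
    for col in columns:
        rows[row][col] = "-"
    return Alignment(ids=list(a.ids), rows=["".join(r) for r in rows])


def plant_text(a: Alignment, start: int, text: str,
               rows: Optional[list[int]] = None) -> Alignment:
    """Return a copy with ``text`` written into the given rows (all rows
    by default) starting at column ``start``."""
    target_rows = range(a.n_rows) if rows is None else rows
    out = [list(r) for r in a.rows]
    for r in target_rows:
        out[r][start:start + len(text)] = list(text)
    return Alignment(ids=list(a.ids), rows=["".join(r) for r in out])


def spec_to_json(spec: SimulationSpec) -> str:
    return json.dumps(asdict(spec), indent=2)


def spec_from_json(text: str) -> SimulationSpec:
    raw = json.loads(text)
    feats = tuple(
        PlantedFeature(**{
            **f,
            "unit_counts": tuple(f.get("unit_counts", ())),
            "taxa": tuple(f.get("taxa", ())),
        })
        for f in raw.pop("planted_features", [])
    )
    return SimulationSpec(planted_features=feats, **raw)
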