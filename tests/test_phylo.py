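import math

import numpy as np
import pytest

from plastomark import (
    Alignment, k80_distance, distance_matrix, nj_tree, bootstrap_support,
)
from plastomark.phylo import DistanceMatrix, bipartitions
from plastomark.synthetic_data import (
    SimulationSpec, simulate_family, DEFAULT_TREE,
)

from _oracles import brute_k80


def leaf_path_distances(tree):
    """Leaf-to-leaf path lengths summed over branch lengths."""
    dists = {}

    def collect(node, acc):
        if node.is_leaf:
            return {node.name: acc}
        out = {}
        for child in node.children:
            out.update(collect(child, acc + child.length))
        return out

    # treat the root's children as meeting at a point
    depths = {}
    for child in tree.children:
        depths.update({k: (v, child) for k, v in
                       collect(child, child.length).items()})
    names = sorted(depths)
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            dx, cx = depths[x]
            dy, cy = depths[y]
            if cx is not cy:
                dists[(x, y)] = dx + dy
            else:
                sub = cx
                dists[(x, y)] = _path_within(sub, x, y)
    return dists


def _path_within(node, x, y):
    # lowest common ancestor walk within one subtree
    def depth_to(node, name, acc):
        if node.is_leaf:
            return acc if node.name == name else None
        for child in node.children:
            d = depth_to(child, name, acc + child.length)
            if d is not None:
                return d
        return None

    for child in node.children:
        names = child.leaf_names()
        if x in names and y in names:
            return _path_within(child, x, y)
    return depth_to(node, x, 0.0) + depth_to(node, y, 0.0)


class TestK80Distance:
    def test_identical_rows(self):
        r = k80_distance("ACGTACGT", "ACGTACGT")
        assert (r.p, r.q, r.d) == (0.0, 0.0, 0.0)
        assert not r.saturated

    def test_closed_form(self):
        # 100 usable columns: 10 transitions, 5 transversions
        base = "ACGT" * 25
        row_b = list(base)
        for i in range(10):       # A->G transitions at A positions
            row_b[4 * i] = "G"
        for i in range(10, 15):   # A->C transversions
            row_b[4 * i] = "C"
        r = k80_distance(base, "".join(row_b))
        assert r.p == pytest.approx(0.10)
        assert r.q == pytest.approx(0.05)
        assert r.d == pytest.approx(-0.5 * math.log(0.75 * math.sqrt(0.90)))

    def test_matches_brute_oracle(self):
        rng = np.random.default_rng(0)
        bases = "ACGTN-"
        for _ in range(20):
            a = "".join(rng.choice(list(bases), size=200))
            b = "".join(rng.choice(list(bases), size=200))
            try:
                r = k80_distance(a, b)
            except ValueError:
                continue
            p, q, d = brute_k80(a, b)
            assert r.p == pytest.approx(p)
            assert r.q == pytest.approx(q)
            if d is None:
                assert r.saturated
            else:
                assert r.d == pytest.approx(d)

    def test_gap_columns_excluded(self):
        r = k80_distance("ACGT--AA", "ACGTGCAA")
        assert r.d == 0.0
        assert r.n_sites == 6

    def test_saturation_flagged(self):
        r = k80_distance("AAAA" * 10, "GGGG" * 10)  # all transitions
        assert r.saturated
        assert math.isnan(r.d)

    def test_no_usable_columns(self):
        with pytest.raises(ValueError):
            k80_distance("----", "ACGT")

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            k80_distance("ACG", "ACGT")


class TestNJTree:
    def additive_matrix(self):
        # tree: A,B joined (1,2); C,D joined (3,4); internal edge 1
        ids = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        return DistanceMatrix(ids=ids, d=d,
                              saturated=np.zeros((4, 4), dtype=bool))

    def test_recovers_additive_topology(self):
        tree = nj_tree(self.additive_matrix())
        assert frozenset({"A", "B"}) in bipartitions(tree) or \
            frozenset({"C", "D"}) in bipartitions(tree)

    def test_reproduces_additive_path_distances(self):
        dm = self.additive_matrix()
        tree = nj_tree(dm)
        dists = leaf_path_distances(tree)
        for (x, y), expected in {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }.items():
            assert dists[(x, y)] == pytest.approx(expected)

    def test_three_taxa_closed_formulas(self):
        ids = ["x", "y", "z"]
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(
            ids=ids, d=d, saturated=np.zeros((3, 3), dtype=bool)))
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths["x"] == pytest.approx(0.0)   # (2+3-5)/2
        assert lengths["y"] == pytest.approx(2.0)   # (2+5-3)/2
        assert lengths["z"] == pytest.approx(3.0)   # (3+5-2)/2

    def test_tie_break_deterministic(self):
        # equidistant matrix: cherries must come out in id order
        ids = ["d", "c", "b", "a", "e"]
        d = np.full((5, 5), 2.0)
        np.fill_diagonal(d, 0.0)
        t1 = nj_tree(DistanceMatrix(
            ids=ids, d=d, saturated=np.zeros((5, 5), dtype=bool)))
        t2 = nj_tree(DistanceMatrix(
            ids=ids, d=d.copy(), saturated=np.zeros((5, 5), dtype=bool)))
        assert t1.newick() == t2.newick()

    def test_saturated_entry_rejected(self):
        dm = self.additive_matrix()
        dm.saturated[0, 2] = dm.saturated[2, 0] = True
        with pytest.raises(ValueError, match="A~C"):
            nj_tree(dm)

    def test_fewer_than_three_taxa(self):
        dm = DistanceMatrix(ids=["a", "b"], d=np.zeros((2, 2)),
                            saturated=np.zeros((2, 2), dtype=bool))
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_outgroup_rooting(self):
        tree = nj_tree(self.additive_matrix(), outgroup="D")
        assert len(tree.children) == 2
        leaf_children = [c for c in tree.children if c.is_leaf]
        assert leaf_children and leaf_children[0].name == "D"

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            m = rng.random((5, 5))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = nj_tree(DistanceMatrix(
                ids=list("abcde"), d=d,
                saturated=np.zeros((5, 5), dtype=bool)))

            def check(node):
                assert node.length >= 0.0
                for ch in node.children:
                    check(ch)
            check(tree)


class TestBootstrap:
    def simulated(self, seed=0, rate=1.0):
        spec = SimulationSpec(tree=DEFAULT_TREE, seq_len=5000,
                              base_mutation_rate=rate, seed=seed)
        alignment, _ = simulate_family(spec)
        return alignment

    def test_single_rep_supports_binary(self):
        tree = bootstrap_support(self.simulated(), n_reps=1, seed=4)
        collected = []

        def walk(node):
            for ch in node.children:
                if not ch.is_leaf and ch.support is not None:
                    collected.append(ch.support)
                walk(ch)
        walk(tree)
        assert collected
        assert set(collected) <= {0.0, 100.0}

    def test_same_seed_identical(self):
        a = self.simulated(seed=2)
        t1 = bootstrap_support(a, n_reps=10, seed=9)
        t2 = bootstrap_support(a, n_reps=10, seed=9)
        assert t1.newick() == t2.newick()

    def test_deep_split_full_support(self):
        # two 20%-divergent clades: the focal bipartition is certain
        a = self.simulated(seed=3, rate=5.0)
        tree = bootstrap_support(a, n_reps=25, seed=1)
        supports = []

        def walk(node):
            for ch in node.children:
                if not ch.is_leaf and ch.support is not None:
                    supports.append(ch.support)
                walk(ch)
        walk(tree)
        assert supports
        assert all(s == 100.0 for s in supports)

    def test_invalid_reps(self):
        with pytest.raises(ValueError):
            bootstrap_support(self.simulated(), n_reps=0, seed=1)


class TestK80Unbiased:
    def test_mean_estimate_within_5_percent_at_d005(self):
        # 200 two-taxon replicates of 10 kb at true distance 0.05
        estimates = []
        for seed in range(200):
            spec = SimulationSpec(tree="(x:0.0,y:0.05);", seq_len=10_000,
                                  base_mutation_rate=1.0, seed=seed)
            a, _ = simulate_family(spec)
            estimates.append(k80_distance(a.row("x"), a.row("y")).d)
        mean = sum(estimates) / len(estimates)
        assert mean == pytest.approx(0.05, rel=0.05)
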