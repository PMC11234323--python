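import itertools

import numpy as np
import pytest

from covarna.msa_io import Alignment, GAP_CODE
from covarna.phylo import (AncestralSample, PhyloTree, SubstitutionMap, TreeNode,
                           build_tree, count_substitutions, fitch_sample,
                           jukes_cantor_distances, pair_substitution_counts,
                           read_newick)
from covarna.synth import SimConfig, random_tree, simulate_structural_alignment


def balanced_four_leaf(names=("a", "b", "c", "d")):
    root = TreeNode()
    left, right = TreeNode(length=1.0), TreeNode(length=1.0)
    for node, (x, y) in zip((left, right), ((0, 1), (2, 3))):
        node.add(TreeNode(name=names[x], length=1.0))
        node.add(TreeNode(name=names[y], length=1.0))
        root.add(node)
    return PhyloTree(root=root)


def exhaustive_fitch_cost(tree: PhyloTree, leaf_states: dict[str, int]) -> int:
    """Oracle: minimize substitutions over all internal assignments (5^k)."""
    internal = [n for n in tree.nodes if not n.is_leaf]
    best = None
    for combo in itertools.product(range(5), repeat=len(internal)):
        assign = {n.index: s for n, s in zip(internal, combo)}
        for n in tree.leaves:
            assign[n.index] = leaf_states[n.name]
        cost = sum(1 for n in tree.nodes if n.parent is not None
                   and assign[n.index] != assign[n.parent.index])
        best = cost if best is None else min(best, cost)
    return best


class TestBuildTree:
    def test_two_sequences_cherry(self):
        aln = Alignment(names=["a", "b"], rows=["ACGU", "ACGG"])
        tree = build_tree(aln)
        assert sorted(tree.leaf_names) == ["a", "b"]
        assert len(tree.root.children) == 2

    def test_outgroup_placed_apart(self):
        # c is the clear outgroup; a and b must form a cherry. Oracle:
        # enumerating the 3 unrooted topologies on 3 taxa, the NJ criterion
        # (here: the only resolved split) keeps the two closest together.
        aln = Alignment(names=["a", "b", "c"],
                        rows=["AAAAAAAAGG", "AAAAAAAAGC", "CCCCCCCCGG"])
        tree = build_tree(aln)
        parents = {}
        for n in tree.nodes:
            if n.is_leaf:
                parents[n.name] = n.parent
        assert parents["a"] is parents["b"]
        assert parents["c"] is not parents["a"]

    def test_identical_sequences_zero_lengths(self):
        aln = Alignment(names=["a", "b", "c", "d"], rows=["ACGU"] * 4)
        tree = build_tree(aln)
        assert sorted(tree.leaf_names) == ["a", "b", "c", "d"]
        assert sum(n.length for n in tree.nodes if n.parent is not None) == 0.0

    def test_deterministic(self, random_alignment):
        t1 = build_tree(random_alignment).to_newick()
        t2 = build_tree(random_alignment).to_newick()
        assert t1 == t2

    def test_user_tree_name_mismatch_rejected(self, tmp_path, random_alignment):
        p = tmp_path / "t.nwk"
        p.write_text("(x:1,y:1);\n")
        with pytest.raises(ValueError, match="do not match"):
            build_tree(random_alignment, tree_path=p)

    def test_newick_round_trip(self, tmp_path, random_alignment):
        tree = build_tree(random_alignment)
        p = tmp_path / "t.nwk"
        tree.write_newick(p)
        back = read_newick(p)
        assert sorted(back.leaf_names) == sorted(tree.leaf_names)

    def test_jc_distance_zero_and_saturated(self):
        aln = Alignment(names=["a", "b", "c"],
                        rows=["ACGUACGU", "ACGUACGU", "CAUCCAUC"])
        dist, names = jukes_cantor_distances(aln)
        k = {n: i for i, n in enumerate(names)}
        assert dist[k["a"], k["b"]] == 0.0
        assert dist[k["a"], k["c"]] == pytest.approx(5.0)  # p = 1 saturates


class TestFitchSample:
    def test_identical_leaves_no_substitutions(self):
        aln = Alignment(names=["a", "b", "c", "d"], rows=["ACGU"] * 4)
        tree = balanced_four_leaf()
        sample = fitch_sample(aln, tree, seed=0)
        assert sample.total_cost == 0
        smap = count_substitutions(sample)
        assert smap.total == 0 and all(not v for v in smap.events.values())

    def test_two_leaves_one_substitution(self):
        aln = Alignment(names=["a", "b"], rows=["A", "C"])
        tree = build_tree(Alignment(names=["a", "b"], rows=["AAAA", "CAAA"]))
        # single column alignment on the same cherry topology
        root = TreeNode()
        root.add(TreeNode(name="a", length=1.0))
        root.add(TreeNode(name="b", length=1.0))
        tree = PhyloTree(root=root)
        seen_roots = set()
        for seed in range(20):
            sample = fitch_sample(aln, tree, seed=seed)
            assert sample.total_cost == 1
            seen_roots.add(int(sample.node_codes[tree.root.index][0]))
        assert seen_roots <= {0, 1}  # root drawn from {A, C}
        assert len(seen_roots) == 2  # randomized tie-breaking reaches both

    def test_four_leaf_parsimony_enumeration(self):
        aln = Alignment(names=["a", "b", "c", "d"], rows=["A", "A", "C", "C"])
        tree = balanced_four_leaf()
        leaf_states = {"a": 0, "b": 0, "c": 1, "d": 1}
        oracle = exhaustive_fitch_cost(tree, leaf_states)
        assert oracle == 1
        sample = fitch_sample(aln, tree, seed=3)
        assert sample.total_cost == oracle

    @pytest.mark.parametrize("seed", range(5))
    def test_parsimony_optimal_on_random_columns(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(6, 1.0, seed=seed)
        names = tree.leaf_names
        rows = ["".join("ACGU-"[rng.integers(5)] for _ in range(4))
                for _ in names]
        aln = Alignment(names=names, rows=rows)
        sample = fitch_sample(aln, tree, seed=seed + 1)
        codes = aln.codes()
        row_of = {n: r for r, n in enumerate(names)}
        for col in range(aln.L):
            leaf_states = {n: int(codes[row_of[n], col]) for n in names}
            assert sample.column_cost[col] == exhaustive_fitch_cost(tree, leaf_states)

    def test_reproducible_under_seed(self, random_alignment):
        tree = build_tree(random_alignment)
        s1 = fitch_sample(random_alignment, tree, seed=5)
        s2 = fitch_sample(random_alignment, tree, seed=5)
        for k in s1.node_codes:
            assert np.array_equal(s1.node_codes[k], s2.node_codes[k])


class TestSubstitutionMap:
    def _sample(self, aln):
        tree = build_tree(aln)
        return count_substitutions(fitch_sample(aln, tree, seed=1))

    def test_totals_consistent(self, gappy_alignment):
        smap = self._sample(gappy_alignment)
        assert sum(smap.per_branch.values()) == int(smap.per_column.sum())

    def test_events_match_brute_force_diffs(self, random_alignment):
        tree = build_tree(random_alignment)
        sample = fitch_sample(random_alignment, tree, seed=2)
        smap = count_substitutions(sample)
        for node in tree.nodes:
            if node.parent is None:
                continue
            p = sample.node_codes[node.parent.index]
            c = sample.node_codes[node.index]
            diffs = {(int(k), int(p[k]), int(c[k]))
                     for k in np.nonzero(p != c)[0]}
            assert set(smap.events[node.index]) == diffs

    def test_five_events_on_four_branches_representable(self):
        # a base pair with five pairing-preserving substitutions spread over
        # four branches: singles = 5, doubles = 1
        tree = balanced_four_leaf()
        branches = [n.index for n in tree.nodes if n.parent is not None][:4]
        events = {b: [] for b in branches}
        events[branches[0]] = [(4, 0, 2), (9, 3, 1)]  # both columns, one branch
        events[branches[1]] = [(4, 2, 0)]
        events[branches[2]] = [(9, 1, 3)]
        events[branches[3]] = [(9, 3, 1)]
        smap = SubstitutionMap(tree=tree, L=15, events=events)
        single, double = pair_substitution_counts(smap, 4, 9)
        assert (single, double) == (5, 1)

    def test_pair_counts_trivial_cases(self):
        tree = balanced_four_leaf()
        smap = SubstitutionMap(tree=tree, L=10, events={})
        assert pair_substitution_counts(smap, 0, 5) == (0, 0)
        b = [n.index for n in tree.nodes if n.parent is not None][0]
        smap2 = SubstitutionMap(tree=tree, L=10,
                                events={b: [(0, 0, 1), (5, 2, 3)]})
        assert pair_substitution_counts(smap2, 0, 5) == (2, 1)

    def test_indels_excluded_from_power_counts(self):
        tree = balanced_four_leaf()
        b = [n.index for n in tree.nodes if n.parent is not None][0]
        smap = SubstitutionMap(tree=tree, L=10,
                               events={b: [(0, GAP_CODE, 1), (5, 2, GAP_CODE)]})
        assert pair_substitution_counts(smap, 0, 5) == (0, 0)

    def test_pair_counts_match_brute_force(self, random_alignment):
        smap = self._sample(random_alignment)
        rng = np.random.default_rng(0)
        for _ in range(20):
            i, j = sorted(rng.choice(random_alignment.L, 2, replace=False))
            single, double = pair_substitution_counts(smap, int(i), int(j))
            s = d = 0
            for evs in smap.events.values():
                hi = sum(1 for c, x, y in evs
                         if c == i and x != GAP_CODE and y != GAP_CODE)
                hj = sum(1 for c, x, y in evs
                         if c == j and x != GAP_CODE and y != GAP_CODE)
                s += hi + hj
                d += 1 if (hi and hj) else 0
            assert (single, double) == (s, d)
            # double-subs power implies single-subs power
            assert double <= min(single, len(smap.events))
            if double > 0:
                assert single >= 2
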