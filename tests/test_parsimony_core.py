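"""Tree structure, Newick I/O, parsimony scoring, indices, MPR, consensus."""

import numpy as np
import pytest

import dendropy
import dendropy.calculate.treecompare as treecompare

from sphaerexo import (
    CharacterMatrix,
    consistency_index,
    exhaustive_search,
    fitch_steps,
    optimize_states,
    parse_newick,
    retention_index,
    robinson_foulds,
    same_topology,
    simulate_tree,
    steps_on_polytomous_tree,
    strict_consensus,
    tree_length,
    tree_splits,
    wagner_steps,
    write_newick,
)
from tests.conftest import brute_force_steps, random_column


class TestNewick:
    def test_four_leaf_binary(self, quartet):
        assert quartet.n_leaves == 4
        assert quartet.is_binary()

    def test_round_trip_random_trees(self):
        for seed in range(5):
            t = simulate_tree(20, seed)
            assert same_topology(t, parse_newick(write_newick(t)))

    def test_root_trichotomy_accepted(self):
        t = parse_newick("(A,B,C);")
        assert sorted(t.leaf_names()) == ["A", "B", "C"]
        assert len(t.root.children) == 3

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(ValueError, match="paren"):
            parse_newick("((A,B),(C,D);")

    def test_canonical_write_is_order_invariant(self):
        assert write_newick(parse_newick("((B,A),(D,C));")) == write_newick(
            parse_newick("((C,D),(A,B));")
        )


class TestScoring:
    def test_constant_character_is_free(self, quartet):
        assert fitch_steps(quartet, {t: 0 for t in "ABCD"}) == 0

    def test_one_forced_change(self, quartet):
        assert fitch_steps(quartet, {"A": 0, "B": 0, "C": 1, "D": 1}) == 1

    def test_incongruent_character_costs_two(self, quartet):
        assert fitch_steps(quartet, {"A": 0, "B": 1, "C": 0, "D": 1}) == 2

    def test_wagner_linear_scale(self):
        t = parse_newick("(A,B,C);")
        assert wagner_steps(t, {"A": 0, "B": 2, "C": 0}) == 2
        assert wagner_steps(t, {"A": 0, "B": 1, "C": 2}) == 2

    def test_polytomy_refused_by_binary_scorers(self):
        star = parse_newick("(A,B,C,D,E);")
        with pytest.raises(ValueError, match="polytom"):
            fitch_steps(star, {t: 0 for t in "ABCDE"})

    def test_star_tree_generalized_scoring(self):
        # star-tree cost = n_scored - frequency of the commonest state,
        # here 5 - 2 (verified by enumerating the center state)
        star = parse_newick("(A,B,C,D,E);")
        col = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 2}
        assert steps_on_polytomous_tree(star, col) == min(
            sum(1 for v in col.values() if v != c) for c in range(3)
        )
        assert steps_on_polytomous_tree(star, col) == 3
        assert steps_on_polytomous_tree(star, {t: 1 for t in "ABCDE"}) == 0

    def test_polytomous_equals_binary_on_binary_trees(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            t = simulate_tree(int(rng.integers(4, 8)), seed)
            col = random_column(t, rng)
            for ordered in (False, True):
                assert steps_on_polytomous_tree(t, col, ordered) == (
                    wagner_steps(t, col) if ordered else fitch_steps(t, col)
                )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for case in range(60):
            t = simulate_tree(int(rng.integers(4, 8)), int(rng.integers(10**6)))
            col = random_column(t, rng)
            ordered = bool(case % 2)
            assert steps_on_polytomous_tree(t, col, ordered) == brute_force_steps(
                t, col, ordered
            )

    def test_fitch_invariant_under_rerooting(self):
        from sphaerexo import reroot_on_leaf

        rng = np.random.default_rng(3)
        for seed in range(5):
            t = simulate_tree(8, seed)
            col = random_column(t, rng)
            base = steps_on_polytomous_tree(t, col)
            for leaf in t.leaf_names()[:4]:
                assert steps_on_polytomous_tree(reroot_on_leaf(t, leaf), col) == base


class TestTreeLength:
    def test_bounds_hold_everywhere(self):
        rng = np.random.default_rng(11)
        for seed in range(10):
            t = simulate_tree(7, seed)
            cells = rng.integers(3, size=(7, 6)).tolist()
            m = CharacterMatrix(sorted(t.leaf_names()), cells)
            s = tree_length(t, m)
            assert np.all(s.per_char_min <= s.per_char_steps + 1e-9)
            assert np.all(s.per_char_steps <= s.per_char_max + 1e-9)
            assert s.length == pytest.approx(s.per_char_steps.sum())

    def test_homoplasy_free_hits_minimum(self, clean_matrix_and_tree):
        matrix, tree = clean_matrix_and_tree
        s = tree_length(tree, matrix)
        assert np.array_equal(s.per_char_steps, s.per_char_min)

    def test_leaf_taxon_mismatch_lists_difference(self, quartet):
        m = CharacterMatrix(["A", "B", "C", "E"], [[0]] * 4)
        with pytest.raises(ValueError, match="E"):
            tree_length(quartet, m)


class TestIndices:
    def test_homoplasy_free_is_one(self, clean_matrix_and_tree):
        matrix, tree = clean_matrix_and_tree
        s = tree_length(tree, matrix)
        assert consistency_index(s) == 1.0
        assert retention_index(s) == 1.0

    def test_hand_computed_ci(self):
        # char 0: states 0,1,0,1 on ((A,B),(C,D)): m=1, s=2; char 1: m=1, s=1
        t = parse_newick("((A,B),(C,D));")
        m = CharacterMatrix(["A", "B", "C", "D"], [[0, 0], [1, 0], [0, 1], [1, 1]])
        s = tree_length(t, m)
        assert consistency_index(s) == pytest.approx(2 / 3)

    def test_worst_case_character_has_zero_retention(self):
        # on this tree the character scores its star-tree maximum
        t = parse_newick("((A,C),(B,D));")
        m = CharacterMatrix(["A", "B", "C", "D"], [[0], [0], [1], [1]])
        s = tree_length(t, m)
        assert retention_index(s) == 0.0

    def test_indices_bounded(self):
        rng = np.random.default_rng(23)
        for seed in range(10):
            t = simulate_tree(6, seed)
            m = CharacterMatrix(
                sorted(t.leaf_names()), rng.integers(3, size=(6, 5)).tolist()
            )
            s = tree_length(t, m)
            assert 0.0 <= consistency_index(s) <= 1.0
            assert 0.0 <= retention_index(s) <= 1.0


class TestOptimizeStates:
    def test_constant_character_everywhere_unambiguous(self, quartet):
        m = CharacterMatrix(["A", "B", "C", "D"], [[1]] * 4)
        rep = optimize_states(quartet, m)
        for node in rep.node_names:
            assert rep.state_of(node, 0) == frozenset({1})
            assert not rep.is_ambiguous(node, 0)

    def test_incongruent_character_root_ambiguous(self, quartet):
        m = CharacterMatrix(["A", "B", "C", "D"], [[0], [1], [0], [1]])
        rep = optimize_states(quartet, m)
        root = quartet.root.label
        assert rep.state_of(root, 0) == frozenset({0, 1})
        assert rep.is_ambiguous(root, 0)

    def test_mpr_sets_match_assignment_enumeration(self):
        # oracle: a state is in the MPR set iff forcing it keeps the optimum
        import itertools

        rng = np.random.default_rng(31)
        for case in range(10):
            t = simulate_tree(5, case)
            col = {name: int(rng.integers(3)) for name in t.leaf_names()}
            m = CharacterMatrix(
                list(col), [[col[name]] for name in col]
            )
            rep = optimize_states(t, m)
            internals = [n for n in t.postorder() if not n.is_leaf]
            best = brute_force_steps(t, col, ordered=False)
            mpr = {n.label: set() for n in internals}
            for assign in itertools.product(range(3), repeat=len(internals)):
                amap = dict(zip(internals, assign))
                total = 0
                for n in t.postorder():
                    if n.parent is None:
                        continue
                    a = col[n.label] if n.is_leaf else amap[n]
                    total += int(a != amap[n.parent])
                if total == best:
                    for n in internals:
                        mpr[n.label].add(amap[n])
            for n in internals:
                assert rep.state_of(n.label, 0) == frozenset(mpr[n.label])


class TestStrictConsensus:
    def test_idempotent(self):
        t = simulate_tree(9, 4)
        assert same_topology(strict_consensus([t, t]), t)

    def test_single_conflict_collapses_to_polytomy(self):
        a = parse_newick("((A,B),(C,(D,E)));")
        b = parse_newick("((A,B),((C,D),E));")
        cons = strict_consensus([a, b])
        assert tree_splits(cons) == frozenset(
            {frozenset({"C", "D", "E"})}
        )

    def test_with_star_tree_gives_star_tree(self):
        star = parse_newick("(T1,T2,T3,T4,T5);")
        t = simulate_tree(5, 1)
        assert tree_splits(strict_consensus([star, t])) == frozenset()

    def test_mismatched_leaf_sets_rejected(self):
        with pytest.raises(ValueError):
            strict_consensus([parse_newick("(A,B,C);"), parse_newick("(A,B,D);")])

    def test_agrees_with_dendropy(self):
        trees = [simulate_tree(10, s) for s in (1, 2, 3)]
        mine = strict_consensus(trees)
        tns = dendropy.TaxonNamespace()
        dlist = dendropy.TreeList(taxon_namespace=tns)
        for t in trees:
            dlist.append(
                dendropy.Tree.get(
                    data=write_newick(t), schema="newick", taxon_namespace=tns
                )
            )
        dcons = dlist.consensus(min_freq=1.0)
        dmine = dendropy.Tree.get(
            data=write_newick(mine), schema="newick", taxon_namespace=tns
        )
        for x in (dmine, dcons):
            x.encode_bipartitions()
        assert treecompare.symmetric_difference(dmine, dcons) == 0
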