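"""Brooks Parsimony Analysis: area cladograms, event coding, g1."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from sphaerexo import (
    AreaAssignment,
    AreaCladogram,
    BiogeoEvent,
    BiogeoMatrix,
    BiogeoScenario,
    analyze_biogeo,
    code_biogeo_matrix,
    g1_statistic,
    make_area_cladogram,
    modified_fitch_optimize,
    parse_newick,
    run_lbpa,
    simulate_biogeography,
    tree_splits,
)
from sphaerexo.lbpa import OUTGROUP_NAME
from sphaerexo.parsimony_core import _ensure_node_names
from tests.conftest import balanced_newick


def _assign(mapping, areas):
    return AreaAssignment(tuple(areas), {k: frozenset(v) for k, v in mapping.items()})


class TestAreaCladogram:
    def test_leaves_carry_their_areas(self):
        t = parse_newick("(A,B);")
        ac = make_area_cladogram(t, _assign({"A": {"x"}, "B": {"y"}}, "xy"))
        assert ac.leaf_dist == {"A": frozenset({"x"}), "B": frozenset({"y"})}
        assert not ac.optimized

    def test_unassigned_taxon_is_an_error(self):
        t = parse_newick("(A,B);")
        with pytest.raises(KeyError, match="B"):
            make_area_cladogram(t, _assign({"A": {"x"}}, "x"))


class TestModifiedFitch:
    def test_disjoint_children_give_union(self):
        t = parse_newick("(A,B);")
        ac = modified_fitch_optimize(
            make_area_cladogram(t, _assign({"A": {"1"}, "B": {"2"}}, "12"))
        )
        assert ac.dist(ac.tree.root.label) == frozenset({"1", "2"})

    def test_overlapping_children_give_intersection(self):
        t = parse_newick("(A,B);")
        ac = modified_fitch_optimize(
            make_area_cladogram(
                t, _assign({"A": {"1", "2"}, "B": {"2", "3"}}, "123")
            )
        )
        assert ac.dist(ac.tree.root.label) == frozenset({"2"})

    def test_majority_rule_in_polytomy(self):
        t = parse_newick("(A,B,C);")
        ac = modified_fitch_optimize(
            make_area_cladogram(
                t, _assign({"A": {"1"}, "B": {"1", "2"}, "C": {"3"}}, "123")
            )
        )
        # no common intersection, but area 1 occurs in two children
        assert ac.dist(ac.tree.root.label) == frozenset({"1"})

    def test_all_internal_sets_nonempty(self):
        sc = BiogeoScenario(10, frozenset("AB"), (), ("A", "B"), seed=3)
        sim = simulate_biogeography(sc)
        ac = modified_fitch_optimize(
            make_area_cladogram(sim.tree, sim.assignment)
        )
        assert all(ac.node_dist.values())


class TestCoding:
    def _manual_cladogram(self, parent_areas, child_areas):
        """Two-node path: root with one leaf child plus a sibling leaf."""
        t = parse_newick("(X,Y);")
        t.rooted = True
        _ensure_node_names(t)
        ac = AreaCladogram(
            t,
            ("1", "2", "3"),
            {"X": frozenset(child_areas), "Y": frozenset(parent_areas)},
            {t.root.label: frozenset(parent_areas)},
        )
        return t, ac

    def test_contraction_marks_every_retained_area(self):
        # parent {1,2,3}, child {1,2}: vicariance column 2,2,0
        t, ac = self._manual_cladogram({"1", "2", "3"}, {"1", "2"})
        vic = code_biogeo_matrix(ac, "vicariance").data["X"]
        assert list(vic[["1", "2", "3"]]) == [2, 2, 0]
        geo = code_biogeo_matrix(ac, "geodispersal").data["X"]
        assert list(geo[["1", "2", "3"]]) == [1, 1, 0]

    def test_expansion_marks_only_new_areas(self):
        t, ac = self._manual_cladogram({"1"}, {"1", "3"})
        geo = code_biogeo_matrix(ac, "geodispersal").data["X"]
        assert list(geo[["1", "2", "3"]]) == [1, 0, 2]
        vic = code_biogeo_matrix(ac, "vicariance").data["X"]
        assert list(vic[["1", "2", "3"]]) == [1, 0, 1]

    def test_root_column_never_two(self):
        sc = BiogeoScenario(8, frozenset("ABC"), (), ("A", "B", "C"), seed=1)
        sim = simulate_biogeography(sc)
        ac = modified_fitch_optimize(make_area_cladogram(sim.tree, sim.assignment))
        for kind in ("vicariance", "geodispersal"):
            col = code_biogeo_matrix(ac, kind).data[ac.tree.root.label]
            assert set(col) <= {0, 1}

    def test_presence_pattern_is_kind_independent(self):
        matrix, assignment, sim, _ = __import__(
            "sphaerexo"
        ).demo_scenario(3)
        ac = modified_fitch_optimize(make_area_cladogram(sim.tree, assignment))
        vic = code_biogeo_matrix(ac, "vicariance").data
        geo = code_biogeo_matrix(ac, "geodispersal").data
        assert ((vic == 0) == (geo == 0)).all().all()

    def test_outgroup_row_zero_and_column_count(self):
        sc = BiogeoScenario(8, frozenset("AB"), (), ("A", "B"), seed=2)
        sim = simulate_biogeography(sc)
        ac = modified_fitch_optimize(make_area_cladogram(sim.tree, sim.assignment))
        bm = code_biogeo_matrix(ac, "vicariance")
        assert (bm.data.loc[OUTGROUP_NAME] == 0).all()
        n_nodes = len(list(ac.tree.postorder()))
        assert bm.data.shape[1] == n_nodes

    def test_unoptimized_input_rejected(self):
        t = parse_newick("(A,B);")
        ac = make_area_cladogram(t, _assign({"A": {"x"}, "B": {"x"}}, "x"))
        with pytest.raises(ValueError, match="optimize"):
            code_biogeo_matrix(ac, "vicariance")


class TestAnalyze:
    def test_congruent_matrix_recovers_its_tree(self):
        # characters = clades of one area tree, coded as presence-1
        names = ["W", "X", "Y", "Z"]
        tree_cols = {
            "W": [1, 1, 1], "X": [1, 1, 0], "Y": [1, 0, 0], "Z": [0, 0, 0],
        }
        df = pd.DataFrame.from_dict(tree_cols, orient="index",
                                    columns=["c1", "c2", "c3"])
        df.loc[OUTGROUP_NAME] = 0
        bm = BiogeoMatrix(df, "vicariance")
        res, cons = analyze_biogeo(bm)
        assert res.best_length == 3  # one step per column
        assert frozenset({"W", "X"}) in tree_splits(cons) or frozenset(
            {"Y", "Z", OUTGROUP_NAME}
        ) in tree_splits(cons)

    def test_rooted_on_outgroup(self):
        sc = BiogeoScenario(8, frozenset("ABC"), (), ("A", "B", "C"), seed=5)
        sim = simulate_biogeography(sc)
        res = run_lbpa(sim.tree, sim.assignment)
        for branch in (res.geodispersal, res.vicariance):
            assert branch.consensus.root.children[0].label == OUTGROUP_NAME


class TestG1:
    def test_symmetric_distribution_is_zero(self):
        assert g1_statistic([1, 2, 3]).g1 == pytest.approx(0.0)

    def test_matches_direct_formula(self):
        lengths = np.array([4, 9, 9, 10, 10, 10, 11, 11, 11, 11], dtype=float)
        n = lengths.size
        s = lengths.std(ddof=1)
        expected = n / ((n - 1) * (n - 2)) * np.sum(
            ((lengths - lengths.mean()) / s) ** 3
        )
        assert g1_statistic(lengths).g1 == pytest.approx(expected)
        assert g1_statistic(lengths, "moment").g1 == pytest.approx(
            scipy.stats.skew(lengths)
        )

    def test_invariant_under_affine_rescaling(self):
        lengths = np.array([3, 5, 5, 6, 6, 6, 7.0])
        a = g1_statistic(lengths).g1
        b = g1_statistic(2.5 * lengths + 11).g1
        assert a == pytest.approx(b)

    def test_left_skew_is_negative(self):
        lengths = np.array([1, 8, 9, 9, 10, 10, 10, 10.0])
        assert g1_statistic(lengths).g1 < 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            g1_statistic([5, 5])
        with pytest.raises(ValueError):
            g1_statistic([5, 5, 5])


class TestRunLbpa:
    def test_single_area_history_is_eventless(self):
        sc = BiogeoScenario(8, frozenset({"A"}), (), ("A",), seed=4)
        sim = simulate_biogeography(sc)
        ac = modified_fitch_optimize(make_area_cladogram(sim.tree, sim.assignment))
        for kind in ("vicariance", "geodispersal"):
            assert not (code_biogeo_matrix(ac, kind).data == 2).any().any()

    def test_scripted_split_recovered_by_vicariance_consensus(self):
        names = [f"T{i + 1}" for i in range(16)]
        t = parse_newick(balanced_newick(names) + ";")
        t.rooted = True
        _ensure_node_names(t)
        kids = t.root.children
        events = tuple(
            BiogeoEvent(k.label, "vicariance", frozenset(keep))
            for k, keep in zip(kids, ({"A", "B"}, {"C", "D"}))
        )
        sc = BiogeoScenario(16, frozenset("ABCD"), events,
                            tuple("ABCD"), seed=0, tree=t)
        sim = simulate_biogeography(sc)
        res = run_lbpa(sim.tree, sim.assignment)
        geo = res.geodispersal.matrix.data
        assert not (geo == 2).any().any()  # vicariance-only history
        splits = tree_splits(res.vicariance.consensus)
        assert frozenset({"C", "D"}) in splits
        assert frozenset({"C", "D", OUTGROUP_NAME}) in splits  # = clade {A,B}

    def test_log_carries_headline_numbers(self):
        sc = BiogeoScenario(8, frozenset("AB"), (), ("A", "B"), seed=6)
        sim = simulate_biogeography(sc)
        res = run_lbpa(sim.tree, sim.assignment)
        assert res.log["geodispersal_length"] == res.geodispersal.search.best_length
        assert res.log["vicariance_n_mpts"] == res.vicariance.search.n_mpts
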