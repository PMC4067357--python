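"""Step counting, homoplasy indices, ancestral states and change tracing,
checked against exhaustive-enumeration oracles on small trees."""

import dendropy
import numpy as np
import pytest

from seedparsimony import (
    ancestral_states,
    detect_apomorphies,
    fit_indices,
    fitch_steps,
    max_steps,
    min_steps,
    per_character_steps,
    read_matrix,
    read_trees,
    trace_changes,
    tree_length,
)
from seedparsimony.matrix import Cell, CharacterDefinition, CharacterMatrix

from conftest import (
    brute_force_mpr,
    brute_force_steps,
    make_matrix,
    oracle_unambiguous_changes,
    random_messy_matrix,
    random_trifurcating_newick,
)


def quartet():
    return dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")


class TestFitchSteps:
    def test_single_origin(self):
        m = make_matrix({"A": [0], "B": [0], "C": [1], "D": [1]})
        assert fitch_steps(quartet(), m, 0).steps == 1

    def test_convergent_pattern_two_steps(self):
        m = make_matrix({"A": [0], "B": [1], "C": [0], "D": [1]})
        t = quartet()
        assert fitch_steps(t, m, 0).steps == brute_force_steps(t, m, 0) == 2

    def test_constant_with_missing_is_zero(self):
        m = make_matrix({"A": [0], "B": ["?"], "C": [0], "D": ["?"]})
        assert fitch_steps(quartet(), m, 0).steps == 0

    def test_polymorphism_mode_adds_terminal_steps(self):
        m = make_matrix(
            {"A": [Cell.polymorphic({0, 1})], "B": [0], "C": [1], "D": [1]}
        )
        t = quartet()
        unc = fitch_steps(t, m, 0, "uncertainty").steps
        pol = fitch_steps(t, m, 0, "polymorphism").steps
        assert unc == brute_force_steps(t, m, 0)
        assert pol == unc + 1

    def test_errors(self):
        m = make_matrix({"A": [0], "B": [1], "C": [0]})
        t = quartet()
        with pytest.raises(ValueError, match="'D'"):
            fitch_steps(t, m, 0)
        m4 = make_matrix({"A": [0], "B": [1], "C": [0], "D": [1]})
        with pytest.raises(IndexError):
            fitch_steps(t, m4, 5)

    def test_matches_enumeration_oracle(self, rng):
        """>= 500 random (tree, character) cases on <= 8 leaves, <= 4
        states, with missing and multistate cells."""
        cases = 0
        while cases < 500:
            n_taxa = int(rng.integers(4, 9))
            k = int(rng.integers(2, 5))
            taxa = [f"t{i}" for i in range(n_taxa)]
            tree = dendropy.Tree.get(
                data=random_trifurcating_newick(taxa, rng), schema="newick"
            )
            n_chars = 4
            m = random_messy_matrix(n_taxa, n_chars, k, rng)
            got = per_character_steps(tree, m)
            for j in range(n_chars):
                assert got[j] == brute_force_steps(tree, m, j)
                cases += 1


class TestTreeLength:
    def test_single_character_equals_fitch(self):
        m = make_matrix({"A": [0], "B": [1], "C": [0], "D": [1]})
        t = quartet()
        assert tree_length(t, m) == fitch_steps(t, m, 0).steps

    def test_reroot_invariance(self, rng):
        n_taxa = 10
        taxa = [f"t{i}" for i in range(n_taxa)]
        tree = dendropy.Tree.get(
            data=random_trifurcating_newick(taxa, rng), schema="newick"
        )
        m = random_messy_matrix(n_taxa, 6, 3, rng)
        base = tree_length(tree, m)
        for edge in list(tree.preorder_edge_iter()):
            if edge.head_node.parent_node is None:
                continue
            t2 = tree.clone(depth=1)
            e2 = [
                e for e in t2.preorder_edge_iter()
                if e.head_node.parent_node is not None
            ][0]
            t2.reroot_at_edge(e2)
            assert tree_length(t2, m) == base

    def test_all_missing_row_changes_nothing(self, rng):
        m = random_messy_matrix(6, 5, 3, rng, p_missing=0.0)
        t = dendropy.Tree.get(
            data=random_trifurcating_newick(list(m.taxa), rng), schema="newick"
        )
        fi = fit_indices(t, m)
        taxa2 = m.taxa + ["ghost"]
        cells2 = [list(r) for r in m.cells] + [[Cell.missing()] * 5]
        m2 = CharacterMatrix(taxa2, m.characters, cells2)
        # attach the all-missing taxon anywhere
        leaf = next(t.leaf_node_iter())
        parent = leaf.parent_node
        new = parent.new_child()
        new.taxon = dendropy.Taxon("ghost")
        fi2 = fit_indices(t, m2)
        assert np.array_equal(fi.s, fi2.s)
        assert np.array_equal(fi.m, fi2.m)
        assert np.array_equal(fi.g, fi2.g)
        assert fi.ci == fi2.ci and fi.ri == fi2.ri and fi.rc == fi2.rc


class TestBounds:
    @pytest.mark.parametrize(
        "column, expected_m",
        [
            ([0, 0, 1, 1, 2], 2),
            ([0, (0, 1), 1], 1),
            ([1, 1, 1], 0),
        ],
    )
    def test_min_steps(self, column, expected_m):
        rows = {f"t{i}": [c] for i, c in enumerate(column)}
        m = make_matrix(rows, n_states=[3])
        assert min_steps(m, 0) == expected_m

    @pytest.mark.parametrize(
        "column, expected_g",
        [
            ([0, 0, 1, 1], 2),
            ([0, 0, 0], 0),
            ([0, 1], 1),
        ],
    )
    def test_max_steps(self, column, expected_g):
        rows = {f"t{i}": [c] for i, c in enumerate(column)}
        m = make_matrix(rows, n_states=[2])
        assert max_steps(m, 0) == expected_g

    def test_star_value_is_maximum_over_quartet_trees(self):
        m = make_matrix({"A": [0], "B": [0], "C": [1], "D": [1]})
        g = max_steps(m, 0)
        quartets = ["((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"]
        assert g == max(
            brute_force_steps(
                dendropy.Tree.get(data=nw, schema="newick"), m, 0
            )
            for nw in quartets
        )

    def test_all_missing_column_flagged(self):
        m = make_matrix({"A": ["?"], "B": ["?"], "C": ["?"]})
        with pytest.raises(ValueError, match="undefined"):
            min_steps(m, 0)

    def test_m_le_s_le_g_random(self, rng):
        for _ in range(30):
            n_taxa = int(rng.integers(4, 9))
            m = random_messy_matrix(n_taxa, 5, 4, rng)
            tree = dendropy.Tree.get(
                data=random_trifurcating_newick(list(m.taxa), rng),
                schema="newick",
            )
            for mode in ("uncertainty", "polymorphism"):
                s = per_character_steps(tree, m, mode)
                for j in range(m.n_characters):
                    try:
                        lo, hi = min_steps(m, j, mode), max_steps(m, j, mode)
                    except ValueError:
                        continue
                    assert lo <= s[j] <= hi


class TestFitIndices:
    def test_direct_ratios(self):
        # 6 taxa, 3 states arranged so m=2, s=3, g=4 for the single character
        m = make_matrix(
            {"A": [0], "B": [1], "C": [0], "D": [1], "E": [2], "F": [2]}
        )
        t = dendropy.Tree.get(
            data="(((A,B),(C,D)),(E,F));", schema="newick"
        )
        fi = fit_indices(t, m)
        assert (fi.m[0], fi.s[0], fi.g[0]) == (2, 3, 4)
        assert fi.ci[0] == pytest.approx(2 / 3)
        assert fi.ri[0] == pytest.approx(1 / 2)
        assert fi.rc[0] == pytest.approx(fi.ci[0] * fi.ri[0])

    def test_no_homoplasy_gives_ci_ri_one(self):
        m = make_matrix({"A": [0], "B": [0], "C": [1], "D": [1]})
        fi = fit_indices(quartet(), m)
        assert fi.ci[0] == 1.0 and fi.ri[0] == 1.0

    def test_constant_character_excluded(self):
        m = make_matrix({"A": [0, 0], "B": [0, 1], "C": [0, 0], "D": [0, 1]})
        fi = fit_indices(quartet(), m)
        assert fi.ci[0] is None
        assert "s=0" in fi.excluded[0]
        assert fi.ci[1] is not None

    def test_rc_equals_ci_times_ri_everywhere(self, rng):
        for _ in range(10):
            m = random_messy_matrix(7, 6, 3, rng)
            tree = dendropy.Tree.get(
                data=random_trifurcating_newick(list(m.taxa), rng),
                schema="newick",
            )
            fi = fit_indices(tree, m)
            for j in range(m.n_characters):
                if fi.rc[j] is not None:
                    assert fi.rc[j] == fi.ci[j] * fi.ri[j]
            if fi.ensemble_rc is not None:
                assert fi.ensemble_rc == fi.ensemble_ci * fi.ensemble_ri


class TestAncestralStates:
    def test_two_state_split(self):
        m = make_matrix({"A": [0], "B": [0], "C": [1], "D": [1]})
        t = quartet()
        rec = ancestral_states(t, m, 0)
        by_leafset = {
            frozenset(l.taxon.label for l in nd.leaf_iter()): states
            for nd, states in rec.node_states.items()
        }
        assert by_leafset[frozenset("AB")] == frozenset({0})
        assert by_leafset[frozenset("CD")] == frozenset({1})
        assert by_leafset[frozenset("ABCD")] == frozenset({0, 1})

    def test_constant_character(self):
        m = make_matrix({"A": [1], "B": [1], "C": [1], "D": [1]}, n_states=[2])
        rec = ancestral_states(quartet(), m, 0)
        for nd, states in rec.node_states.items():
            assert states == frozenset({1})

    def test_two_taxon_root_ambiguous(self):
        m = make_matrix({"A": [0], "B": [1]})
        t = dendropy.Tree.get(data="(A,B);", schema="newick")
        rec = ancestral_states(t, m, 0)
        root_states = rec.node_states[t.seed_node]
        assert root_states == frozenset({0, 1})

    def test_matches_mpr_enumeration(self, rng):
        for _ in range(25):
            n_taxa = int(rng.integers(4, 8))
            m = random_messy_matrix(n_taxa, 2, 3, rng)
            tree = dendropy.Tree.get(
                data=random_trifurcating_newick(list(m.taxa), rng),
                schema="newick",
            )
            for j in range(2):
                best, node_sets, _ = brute_force_mpr(tree, m, j)
                rec = ancestral_states(tree, m, j)
                assert rec.steps == best
                for nd, expected in node_sets.items():
                    assert rec.node_states[nd] == frozenset(expected)


class TestTraceChanges:
    def test_split_character_single_unambiguous_change(self):
        m = make_matrix({"A": [0], "B": [0], "C": [1], "D": [1]})
        changes = trace_changes(quartet(), m, 0)
        assert len(changes) == 1
        ch = changes[0]
        assert {ch.from_state, ch.to_state} == {0, 1}
        assert ch.child_clade in (frozenset("AB"), frozenset("CD"))

    def test_convergent_character_all_ambiguous(self):
        m = make_matrix({"A": [0], "B": [1], "C": [0], "D": [1]})
        assert trace_changes(quartet(), m, 0) == []

    def test_constant_character_empty(self):
        m = make_matrix({"A": [0], "B": [0], "C": [0], "D": [0]}, n_states=[2])
        assert trace_changes(quartet(), m, 0) == []

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            n_taxa = int(rng.integers(4, 8))
            m = random_messy_matrix(n_taxa, 2, 3, rng, p_missing=0.05)
            tree = dendropy.Tree.get(
                data=random_trifurcating_newick(list(m.taxa), rng),
                schema="newick",
            )
            for j in range(2):
                expected = {
                    (frozenset(ls), t, s)
                    for ls, t, s in oracle_unambiguous_changes(tree, m, j)
                }
                got = {
                    (frozenset(ch.child_clade), ch.from_state, ch.to_state)
                    for ch in trace_changes(tree, m, j)
                }
                assert got == expected

    def test_full_resolution_has_cost_steps(self, rng):
        """The deterministic all-changes resolution implies exactly s
        changes."""
        for _ in range(10):
            n_taxa = int(rng.integers(4, 8))
            m = random_messy_matrix(n_taxa, 1, 3, rng, p_missing=0.0, p_multi=0.0)
            tree = dendropy.Tree.get(
                data=random_trifurcating_newick(list(m.taxa), rng),
                schema="newick",
            )
            changes = trace_changes(tree, m, 0, unambiguous_only=False)
            assert len(changes) == fitch_steps(tree, m, 0).steps


class TestApomorphies:
    def test_terminal_deviant_is_autapomorphy(self):
        m = make_matrix({"A": [0], "B": [0], "C": [0], "D": [1]})
        rep = detect_apomorphies(quartet(), m)
        assert len(rep.autapomorphies) == 1
        assert rep.autapomorphies[0].child_clade == frozenset({"D"})
        assert rep.synapomorphies == []

    def test_cherry_split_is_synapomorphy(self):
        m = make_matrix({"A": [0], "B": [0], "C": [1], "D": [1]})
        rep = detect_apomorphies(quartet(), m)
        assert len(rep.synapomorphies) == 1
        assert rep.autapomorphies == []

    def test_constant_matrix_empty_report(self):
        m = make_matrix(
            {"A": [0, 1], "B": [0, 1], "C": [0, 1], "D": [0, 1]},
            n_states=[2, 2],
        )
        rep = detect_apomorphies(quartet(), m)
        assert rep.autapomorphies == [] and rep.synapomorphies == []
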