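"""Templeton test, constraint hypothesis testing, phylogenetic signal and
the ILD partition-homogeneity test."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy import stats

from seedparsimony import (
    Constraint,
    PermutationResult,
    SearchConfig,
    SimConfig,
    ild_test,
    permutation_pvalue,
    phylo_signal,
    phylo_signal_all,
    simulate_mk,
    simulate_tree,
    templeton_test,
)
from seedparsimony.inference import (
    test_constraint_hypothesis as constraint_hypothesis,
)
from seedparsimony.inference import _signed_rank
from seedparsimony.matrix import CharacterDefinition, CharacterMatrix, Cell
from seedparsimony.simulate import _split_matrix_from_tree

from conftest import make_matrix, random_single_state_matrix


def exact_minrank_p(d: np.ndarray) -> float:
    """Brute-force two-tailed signed-rank P: enumerate every sign assignment
    of the midranks and count those with min(W+, W-) <= observed."""
    d = d[d != 0].astype(float)
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    total = ranks.sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, total - w) <= w_obs + 1e-9:
            count += 1
    return count / 2**n


class TestSignedRankMachinery:
    def test_all_zero_differences(self):
        n, T, z, p, p_exact = _signed_rank(np.zeros(5))
        assert (z, p) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        d = rng.integers(-4, 5, size=n).astype(float)
        if np.all(d == 0):
            d[0] = 1
        _, _, _, _, p_exact = _signed_rank(d)
        assert p_exact == pytest.approx(exact_minrank_p(d), abs=1e-12)

    def test_constant_unit_differences(self):
        """d = (1,1,1,1,1,1): normal-approximation z and the exact 2^6
        permutation distribution."""
        d = np.ones(6)
        n, T, z, p, p_exact = _signed_rank(d)
        assert n == 6 and T == 0.0
        assert p_exact == pytest.approx(exact_minrank_p(d))
        assert p_exact == pytest.approx(2 / 64)
        # mu = 10.5; var = 22.75 minus the tie correction (6^3-6)/48
        assert z == pytest.approx(-10.5 / np.sqrt(22.75 - 4.375))
        assert p == pytest.approx(2 * stats.norm.cdf(z))


class TestTempletonTest:
    def trees(self):
        a = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        b = dendropy.Tree.get(data="((A,C),(B,D));", schema="newick")
        return a, b

    def matrix(self, n_copies=6):
        rows = {"A": [0] * n_copies, "B": [0] * n_copies,
                "C": [1] * n_copies, "D": [1] * n_copies}
        return make_matrix(rows)

    def test_same_tree_p_one(self):
        a, _ = self.trees()
        m = self.matrix()
        w = templeton_test(a, a, m)
        assert w.p == 1.0 and w.z == 0.0 and w.n_nonzero == 0

    def test_swap_symmetry(self):
        a, b = self.trees()
        m = self.matrix()
        w_ab = templeton_test(a, b, m)
        w_ba = templeton_test(b, a, m)
        assert np.array_equal(w_ab.differences, -w_ba.differences)
        assert abs(w_ab.z) == abs(w_ba.z)
        assert w_ab.p == w_ba.p

    def test_sign_convention(self):
        a, b = self.trees()
        m = self.matrix()
        w = templeton_test(a, b, m)  # b is worse: positive delta
        assert w.delta == 6 and w.z < 0

    def test_unit_differences_match_exact_oracle(self):
        a, b = self.trees()
        m = self.matrix(n_copies=6)
        w = templeton_test(a, b, m)
        assert np.array_equal(w.differences, np.ones(6, dtype=int))
        assert w.p_exact == pytest.approx(exact_minrank_p(w.differences.astype(float)))

    def test_leafset_mismatch_raises(self):
        a, _ = self.trees()
        m = make_matrix({"A": [0], "B": [1], "C": [0], "E": [1]})
        with pytest.raises(ValueError):
            templeton_test(a, a, m)


class TestConstraintHypothesis:
    def test_satisfied_constraint_cannot_reject(self):
        cfg_sim = SimConfig(n_taxa=7, tree_model="uniform-topology",
                            n_chars=4, states_per_char=[2] * 4, seed=21)
        tree = simulate_tree(cfg_sim)
        m = _split_matrix_from_tree(tree)
        clade = {t for t, row in zip(m.taxa, m.cells) if 1 in row[0].states}
        dec = constraint_hypothesis(
            m, Constraint("present", frozenset(clade)),
            SearchConfig(n_random_additions=2, seed=2),
        )
        assert dec.delta == 0
        assert dec.wilcoxon.p == 1.0
        assert not dec.reject

    def test_contradicted_constraint_rejected(self):
        """20 homoplasy-free characters against the constrained grouping
        force a decisive signed-rank rejection."""
        cfg_sim = SimConfig(n_taxa=8, tree_model="uniform-topology",
                            n_chars=5, states_per_char=[2] * 5, seed=33)
        tree = simulate_tree(cfg_sim)
        base = _split_matrix_from_tree(tree)
        idx = [j for j in range(base.n_characters) for _ in range(4)]
        m = base.take_characters(idx)  # ~20 clean characters
        # force together two taxa separated on the generating tree: pick a
        # split character and take one taxon from each side
        col = base.cells
        side1 = [t for t, row in zip(base.taxa, col) if 1 in row[0].states]
        side0 = [t for t in base.taxa if t not in side1]
        ingroup = frozenset({side1[0], side0[0]})
        dec = constraint_hypothesis(
            m, Constraint("forced", ingroup),
            SearchConfig(n_random_additions=2, seed=3),
        )
        assert dec.delta > 0
        assert dec.reject

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        m = random_single_state_matrix(7, 8, 2, rng)
        con = Constraint("grp", frozenset(list(m.taxa)[:3]))
        cfg = SearchConfig(n_random_additions=2, seed=11)
        d1 = constraint_hypothesis(m, con, cfg)
        d2 = constraint_hypothesis(m, con, cfg)
        assert d1.wilcoxon.p == d2.wilcoxon.p
        assert d1.delta == d2.delta and d1.reject == d2.reject


class TestPhyloSignal:
    def test_p_is_exact_ratio(self):
        assert permutation_pvalue(56, 10000) == 0.0056
        assert permutation_pvalue(495, 10000) == 0.0495
        r = PermutationResult(observed_steps=5, n_perm=2000, count_le=13)
        assert r.p == 13 / 2000

    def test_full_count_gives_p_one(self):
        assert permutation_pvalue(10000, 10000) == 1.0

    def test_constant_character_p_one(self):
        m = make_matrix({t: [0] for t in "ABCDEF"}, n_states=[2])
        tree = dendropy.Tree.get(data="((A,B),(C,D),(E,F));", schema="newick")
        r = phylo_signal(tree, m, 0, n_perm=100, seed=1)
        assert r.p == 1.0

    def test_strong_signal_small_p(self):
        cfg = SimConfig(n_taxa=12, tree_model="uniform-topology",
                        n_chars=4, states_per_char=[2] * 4, seed=2)
        tree = simulate_tree(cfg)
        m = _split_matrix_from_tree(tree)
        r = phylo_signal(tree, m, 0, n_perm=500, seed=5)
        assert r.p < 0.05

    def test_invalid_n_perm(self):
        m = make_matrix({"A": [0], "B": [1], "C": [0], "D": [1]})
        tree = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        with pytest.raises(ValueError):
            phylo_signal(tree, m, 0, n_perm=0, seed=1)

    def test_all_characters_table(self):
        cfg = SimConfig(n_taxa=10, n_chars=6, states_per_char=[3] * 6,
                        rate=0.3, seed=8)
        tree = simulate_tree(cfg)
        m = simulate_mk(tree, cfg)
        results = phylo_signal_all(tree, m, n_perm=200, seed=3)
        assert len(results) == m.n_characters
        for r in results:
            assert r.p == r.count_le / r.n_perm
            assert 0 <= r.p <= 1

    def test_single_character_matrix_matches_phylo_signal(self):
        cfg = SimConfig(n_taxa=9, n_chars=1, states_per_char=[3], rate=0.4,
                        seed=13)
        tree = simulate_tree(cfg)
        m = simulate_mk(tree, cfg)
        single = phylo_signal(tree, m, 0, n_perm=300, seed=7)
        table = phylo_signal_all(tree, m, n_perm=300, seed=7)
        assert single.observed_steps == table[0].observed_steps
        # different permutation streams are allowed; P must agree closely
        assert abs(single.p - table[0].p) < 0.12

    def test_tree_generated_characters_beat_shuffled(self):
        """Median signal P for characters evolved on the reference tree is
        below the median for label-shuffled rows."""
        cfg = SimConfig(n_taxa=14, n_chars=12, states_per_char=[2] * 12,
                        rate=0.15, seed=17)
        tree = simulate_tree(cfg)
        m = simulate_mk(tree, cfg)
        from seedparsimony import shuffle_tip_labels

        shuffled = shuffle_tip_labels(m, seed=23)
        p_real = np.median([r.p for r in phylo_signal_all(tree, m, 300, seed=1)])
        p_null = np.median(
            [r.p for r in phylo_signal_all(tree, shuffled, 300, seed=2)]
        )
        assert p_real < p_null


class TestILD:
    def test_duplicated_block_statistic_zero(self):
        cfg_sim = SimConfig(n_taxa=6, tree_model="uniform-topology",
                            n_chars=3, states_per_char=[2] * 3, seed=31)
        tree = simulate_tree(cfg_sim)
        block = _split_matrix_from_tree(tree)
        doubled = CharacterMatrix(
            block.taxa,
            block.characters
            + [CharacterDefinition.generic(f"dup{j}", c.n_states)
               for j, c in enumerate(block.characters)],
            [row + row for row in block.cells],
        )
        res = ild_test(
            doubled,
            [list(range(block.n_characters)),
             list(range(block.n_characters, 2 * block.n_characters))],
            n_reps=10,
            config=SearchConfig(n_random_additions=1, swap="SPR", seed=0),
            seed=0,
        )
        assert res.observed_statistic == 0

    def test_conflicting_blocks_positive_statistic_small_p(self):
        t_a = dendropy.Tree.get(data="((a,b),(c,d),(e,f));", schema="newick")
        t_b = dendropy.Tree.get(data="((a,f),(c,b),(e,d));", schema="newick")
        block_a = _split_matrix_from_tree(t_a)
        block_b = _split_matrix_from_tree(t_b)
        # duplicate columns for stronger conflict
        a3 = block_a.take_characters([j for j in range(3) for _ in range(3)])
        b3 = block_b.take_characters([j for j in range(3) for _ in range(3)])
        combined = CharacterMatrix(
            a3.taxa,
            a3.characters + [CharacterDefinition.generic(f"b{j}", 2)
                             for j in range(9)],
            [ra + rb for ra, rb in zip(a3.cells, b3.cells)],
        )
        res = ild_test(
            combined,
            [list(range(9)), list(range(9, 18))],
            n_reps=30,
            config=SearchConfig(n_random_additions=1, swap="SPR", seed=1),
            seed=1,
        )
        assert res.observed_statistic > 0
        assert res.p < 0.05

    def test_homogeneous_blocks_usually_nonsignificant(self):
        """Both blocks evolved on the same tree: P > 0.05 in >= 90% of
        seeded runs."""
        ok = 0
        n_runs = 20
        for s in range(n_runs):
            cfg_sim = SimConfig(n_taxa=6, tree_model="uniform-topology",
                                n_chars=3, states_per_char=[2] * 3,
                                seed=600 + s)
            tree = simulate_tree(cfg_sim)
            block = _split_matrix_from_tree(tree)
            doubled = CharacterMatrix(
                block.taxa,
                block.characters
                + [CharacterDefinition.generic(f"d{j}", c.n_states)
                   for j, c in enumerate(block.characters)],
                [row + row for row in block.cells],
            )
            res = ild_test(
                doubled,
                [list(range(3)), list(range(3, 6))],
                n_reps=20,
                config=SearchConfig(n_random_additions=1, swap="NNI", seed=s),
                seed=s,
            )
            if res.p > 0.05:
                ok += 1
        assert ok >= 18

    def test_partition_validation(self):
        m = make_matrix({"A": [0, 1], "B": [1, 0], "C": [0, 0], "D": [1, 1]})
        with pytest.raises(ValueError, match="disjoint"):
            ild_test(m, [[0, 1], [1]], n_reps=2)
        with pytest.raises(ValueError, match="cover"):
            ild_test(m, [[0]], n_reps=2)

    def test_statistic_nonnegative_with_exact_search(self, rng):
        """Combined optimum >= sum of block optima (exact enumeration)."""
        from seedparsimony import exhaustive_search

        for _ in range(5):
            m = random_single_state_matrix(6, 6, 2, rng)
            blocks = [list(range(3)), list(range(3, 6))]
            combined = exhaustive_search(m).best_length
            parts = sum(
                exhaustive_search(m.take_characters(b)).best_length
                for b in blocks
            )
            assert combined >= parts
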