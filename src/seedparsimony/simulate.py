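"""Synthetic trees and discrete character matrices.

The generator emulates the statistical structure morphological parsimony
analyses assume: unordered multistate characters (2–8 states) evolved on a
tree under the symmetric k-state Markov (Mk) process, with configurable
per-cell missing-data and polymorphism probabilities, plus label-shuffled
null datasets.  Default arities and special-cell rates mirror a typical
seed-morphology matrix: 17 characters with state counts
(4,2,2,8,4,2,2,2,2,2,3,2,3,2,2,2,8), 3.8% missing cells and 2.5%
polymorphic cells.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import dendropy
import numpy as np
import yaml

from .matrix import Cell, CharacterDefinition, CharacterMatrix, normalize_taxon

#: state counts of the 17 seed characters (A–Q) the default config mimics
SEED_CHARACTER_ARITIES = (4, 2, 2, 8, 4, 2, 2, 2, 2, 2, 3, 2, 3, 2, 2, 2, 8)
SEED_CHARACTER_LABELS = tuple("ABCDEFGHIJKLMNOPQ")


@dataclass
class SimConfig:
    """Settings for one simulated (tree, matrix) pair."""

    n_taxa: int = 16
    tree_model: str = "yule"  # yule | uniform-topology
    n_chars: int = 17
    states_per_char: Sequence[int] = SEED_CHARACTER_ARITIES
    rate: float = 0.5  # expected substitutions per unit path length
    p_missing: float = 0.038
    p_polymorphic: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        for p in (self.p_missing, self.p_polymorphic):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_missing + self.p_polymorphic > 1:
            raise ValueError("p_missing + p_polymorphic must not exceed 1")
        states = list(self.states_per_char)
        if len(states) != self.n_chars:
            # recycle the arity list to the requested number of characters
            states = [states[j % len(states)] for j in range(self.n_chars)]
        if any(k < 2 or k > 8 for k in states):
            raise ValueError("states_per_char entries must lie in 2..8")
        self.states_per_char = tuple(states)


def _rng(seed, *tags) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, *tags])))


def _taxon_names(n: int) -> List[str]:
    width = len(str(n - 1))
    return [f"t{str(i).zfill(width)}" for i in range(n)]


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def simulate_tree(config: SimConfig) -> dendropy.Tree:
    """Simulate a tree under the configured model (seeded).

    ``yule`` trees come from a pure-birth process (dendropy's birth–death
    simulator with zero death rate) and carry branch lengths in units of
    expected time.  ``uniform-topology`` draws uniformly over unrooted
    labelled binary topologies by sequential insertion on a uniformly chosen
    edge, with unit branch lengths.
    """
    names = _taxon_names(config.n_taxa)
    if config.tree_model == "yule":
        from dendropy.model import birthdeath

        taxa = dendropy.TaxonNamespace(names)
        tree = birthdeath.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=config.n_taxa,
            taxon_namespace=taxa,
            rng=_random.Random(int(_rng(config.seed, 1).integers(1 << 30))),
        )
        tree.is_rooted = True
        return tree
    if config.tree_model == "uniform-topology":
        rng = _rng(config.seed, 2)
        order = list(rng.permutation(config.n_taxa))
        # sequential insertion on a uniformly drawn edge is exactly uniform
        # over unrooted labelled binary topologies
        newick = _uniform_topology_newick(names, order, rng)
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        tree.is_rooted = False
        for edge in tree.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                edge.length = 1.0
        return tree
    raise ValueError(f"unknown tree model {config.tree_model!r}")


def _uniform_topology_newick(names, order, rng) -> str:
    from .search import _connect, _copy, _disconnect, _edges, _to_newick

    adj = {}
    hub = len(names)
    for i in order[:3]:
        _connect(adj, hub, int(i))
    nxt = hub + 1
    for i in order[3:]:
        a, b = _edges(adj)[int(rng.integers(len(_edges(adj))))]
        _disconnect(adj, a, b)
        _connect(adj, a, nxt)
        _connect(adj, nxt, b)
        _connect(adj, nxt, int(i))
        nxt += 1
    return _to_newick(adj, names)


# ---------------------------------------------------------------------------
# Mk character simulation
# ---------------------------------------------------------------------------


def simulate_mk(tree: dendropy.Tree, config: SimConfig) -> CharacterMatrix:
    """Evolve unordered characters on ``tree`` under the symmetric Mk model.

    Each character draws a uniform root state and evolves independently; for
    a k-state character on a branch of length b the chance of ending in a
    given *other* state is ``(1 - exp(-k/(k-1) * rate * b)) / k``.  Branches
    without lengths count as unit length.
    """
    rng = _rng(config.seed, 3)
    ks = np.asarray(config.states_per_char)
    n_chars = config.n_chars
    states = {}  # node -> per-char state vector
    leaves = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = np.array([rng.integers(k) for k in ks], dtype=np.int64)
            continue
        parent_states = states[node.parent_node]
        b = node.edge.length if node.edge.length is not None else 1.0
        # symmetric model: P(change to one particular other state)
        p_other = (1.0 - np.exp(-ks / (ks - 1.0) * config.rate * b)) / ks
        p_change_total = (ks - 1) * p_other
        out = parent_states.copy()
        u = rng.random(n_chars)
        changed = u < p_change_total
        for j in np.flatnonzero(changed):
            k = int(ks[j])
            offset = int(rng.integers(1, k))
            out[j] = (parent_states[j] + offset) % k
        states[node] = out
        if node.is_leaf():
            leaves.append(node)
    taxa = [normalize_taxon(lf.taxon.label) for lf in leaves]
    chars = [
        CharacterDefinition.generic(
            SEED_CHARACTER_LABELS[j] if j < len(SEED_CHARACTER_LABELS) else f"c{j + 1}",
            int(ks[j]),
        )
        for j in range(n_chars)
    ]
    cells = [[Cell.single(int(s)) for s in states[lf]] for lf in leaves]
    return CharacterMatrix(taxa, chars, cells)


def inject_special_cells(
    matrix: CharacterMatrix,
    p_missing: float,
    p_polymorphic: float,
    seed: int = 0,
) -> CharacterMatrix:
    """Independently turn cells missing (probability ``p_missing``) or
    polymorphic (``p_polymorphic``: the observed state plus one uniformly
    drawn other state)."""
    if p_missing + p_polymorphic > 1:
        raise ValueError("p_missing + p_polymorphic must not exceed 1")
    rng = _rng(seed, 4)
    rows = []
    for row in matrix.cells:
        new_row = []
        for j, cell in enumerate(row):
            k = matrix.characters[j].n_states
            u = rng.random()
            if u < p_missing:
                new_row.append(Cell.missing())
            elif u < p_missing + p_polymorphic and not cell.is_missing and k >= 2:
                base = min(cell.states)
                other = (base + int(rng.integers(1, k))) % k
                new_row.append(Cell.polymorphic({base, other}))
            else:
                new_row.append(cell)
        rows.append(new_row)
    return CharacterMatrix(matrix.taxa, matrix.characters, rows)


def shuffle_tip_labels(
    obj: Union[dendropy.Tree, CharacterMatrix], seed: int = 0
) -> Union[dendropy.Tree, CharacterMatrix]:
    """Uniformly permute taxon labels (trees) or row assignments (matrices).

    The topology / row multiset is unchanged; only the taxon-to-tip (or
    taxon-to-row) association is randomized, which is the null model of the
    phylogenetic-signal test.
    """
    rng = _rng(seed, 5)
    if isinstance(obj, CharacterMatrix):
        perm = [int(i) for i in rng.permutation(obj.n_taxa)]
        return obj.with_shuffled_rows(perm)
    tree = obj.clone(depth=1)
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    perm = rng.permutation(len(labels))
    # reassign existing taxa among leaves
    taxa = [leaves[int(i)].taxon for i in perm]
    for lf, tx in zip(leaves, taxa):
        lf.taxon = tx
    return tree


def filter_variable_only(matrix: CharacterMatrix) -> CharacterMatrix:
    """Drop invariant characters (ascertainment filter mimicking
    variable-characters-only coding)."""
    keep = [
        j
        for j in range(matrix.n_characters)
        if CharacterMatrix._column_is_variable(matrix.column(j))
    ]
    return matrix.take_characters(keep)


# ---------------------------------------------------------------------------
# Canonical fixtures
# ---------------------------------------------------------------------------


@dataclass
class Fixture:
    name: str
    tree: Optional[dendropy.Tree]
    matrix: CharacterMatrix
    expected: dict


def _split_matrix_from_tree(tree: dendropy.Tree) -> CharacterMatrix:
    """One binary character per internal split: a perfectly compatible,
    homoplasy-free matrix whose generating tree attains length = number of
    characters."""
    taxa = sorted(normalize_taxon(l.taxon.label) for l in tree.leaf_node_iter())
    idx = {t: i for i, t in enumerate(taxa)}
    columns = []
    for nd in tree.preorder_internal_node_iter():
        side = {normalize_taxon(l.taxon.label) for l in nd.leaf_iter()}
        if 1 < len(side) < len(taxa) - 1:
            columns.append(side)
    chars = [CharacterDefinition.generic(f"split{j + 1}", 2) for j in range(len(columns))]
    cells = [
        [Cell.single(1 if t in side else 0) for side in columns] for t in taxa
    ]
    return CharacterMatrix(taxa, chars, cells)


def make_fixture_suite(seed: int = 0, out_dir: Optional[Path] = None) -> dict:
    """Build the canonical simulated datasets used across the test suite.

    Returns a dict of :class:`Fixture`; with ``out_dir`` set, also writes
    each as NEXUS + newick + a YAML manifest of generation parameters and
    expected values.
    """
    from .io import write_matrix, write_trees
    from .parsimony import fit_indices, min_steps, tree_length
    from .search import exhaustive_search

    fixtures = {}

    # 1. homoplasy-free 8-taxon case: matrix built from a known tree's splits
    cfg = SimConfig(n_taxa=8, tree_model="uniform-topology", n_chars=5,
                    states_per_char=[2] * 5, seed=seed)
    tree = simulate_tree(cfg)
    hf = _split_matrix_from_tree(tree)
    min_total = sum(min_steps(hf, j) for j in range(hf.n_characters))
    fixtures["homoplasy_free"] = Fixture(
        name="homoplasy_free",
        tree=tree,
        matrix=hf,
        expected={
            "length_on_generating_tree": tree_length(tree, hf),
            "sum_min_steps": int(min_total),
            "ensemble_ci": fit_indices(tree, hf).ensemble_ci,
        },
    )

    # 2. conflicting-partition case: blocks from two maximally different
    # 6-taxon trees
    t_a = dendropy.Tree.get(data="((a,b),(c,d),(e,f));", schema="newick")
    t_b = dendropy.Tree.get(data="((a,f),(c,b),(e,d));", schema="newick")
    block_a = _split_matrix_from_tree(t_a)
    block_b = _split_matrix_from_tree(t_b)
    combined = CharacterMatrix(
        block_a.taxa,
        block_a.characters + [
            CharacterDefinition.generic(f"b{c.label}", c.n_states)
            for c in block_b.characters
        ],
        [ra + rb for ra, rb in zip(block_a.cells, block_b.cells)],
    )
    ex_a = exhaustive_search(block_a).best_length
    ex_b = exhaustive_search(block_b).best_length
    ex_comb = exhaustive_search(combined).best_length
    fixtures["conflicting_partition"] = Fixture(
        name="conflicting_partition",
        tree=None,
        matrix=combined,
        expected={
            "block_sizes": [block_a.n_characters, block_b.n_characters],
            "block_optima": [ex_a, ex_b],
            "combined_optimum": ex_comb,
            "ild_statistic": ex_comb - ex_a - ex_b,
        },
    )

    # 3. null-signal case: characters independent of the reference tree
    cfg_null = SimConfig(n_taxa=12, tree_model="yule", n_chars=20,
                         states_per_char=[3] * 20, seed=seed + 1)
    null_tree = simulate_tree(cfg_null)
    rng = _rng(seed, 6)
    taxa = sorted(normalize_taxon(l.taxon.label) for l in null_tree.leaf_node_iter())
    chars = [CharacterDefinition.generic(f"n{j + 1}", 3) for j in range(20)]
    cells = [[Cell.single(int(rng.integers(3))) for _ in chars] for _ in taxa]
    fixtures["null_signal"] = Fixture(
        name="null_signal",
        tree=null_tree,
        matrix=CharacterMatrix(taxa, chars, cells),
        expected={"note": "states iid uniform; signal P approximately uniform"},
    )

    # 4. seed-matrix-shaped case: 390 taxa x 17 characters with the seed
    # arities and special-cell rates
    cfg_paper = SimConfig(n_taxa=390, tree_model="yule", n_chars=17,
                          rate=0.4, seed=seed + 2)
    paper_tree = simulate_tree(cfg_paper)
    base = simulate_mk(paper_tree, cfg_paper)
    shaped = inject_special_cells(base, cfg_paper.p_missing, cfg_paper.p_polymorphic,
                                  seed=seed + 3)
    fixtures["seed_shaped"] = Fixture(
        name="seed_shaped",
        tree=paper_tree,
        matrix=shaped,
        expected={
            "arities": list(SEED_CHARACTER_ARITIES),
            "p_missing": cfg_paper.p_missing,
            "p_polymorphic": cfg_paper.p_polymorphic,
        },
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, fx in fixtures.items():
            (out_dir / f"{name}.nex").write_text(write_matrix(fx.matrix))
            if fx.tree is not None:
                write_trees([fx.tree], out_dir / f"{name}.nwk")
            manifest = {"name": name, "seed": seed, "expected": fx.expected,
                        "summary": fx.matrix.summary().as_dict()}
            (out_dir / f"{name}.yaml").write_text(yaml.safe_dump(manifest))
    return fixtures
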