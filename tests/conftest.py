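"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's dynamic programs: step
counts come from exhaustive enumeration of internal-node state assignments,
and reconstruction sets/changes from collecting every optimal assignment.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest

from seedparsimony.matrix import Cell, CharacterDefinition, CharacterMatrix


# ---------------------------------------------------------------------------
# Random data helpers
# ---------------------------------------------------------------------------


def make_matrix(rows: dict, n_states=None, kinds=None) -> CharacterMatrix:
    """Build a matrix from {taxon: sequence-of-cell-specs}.

    A cell spec is an int (single state), a set/tuple of ints (uncertain by
    default), the string "?" (missing), or a ready Cell.
    """
    taxa = list(rows)
    n_chars = len(next(iter(rows.values())))
    cells = []
    for t in taxa:
        row = []
        for spec in rows[t]:
            if isinstance(spec, Cell):
                row.append(spec)
            elif spec == "?":
                row.append(Cell.missing())
            elif isinstance(spec, (set, frozenset, tuple, list)):
                row.append(Cell.uncertain(spec))
            else:
                row.append(Cell.single(int(spec)))
        cells.append(row)
    if n_states is None:
        n_states = []
        for j in range(n_chars):
            mx = 1
            for t in taxa:
                c = cells[taxa.index(t)][j]
                if c.states:
                    mx = max(mx, max(c.states))
            n_states.append(mx + 1)
    chars = [
        CharacterDefinition.generic(f"c{j + 1}", max(2, n_states[j]))
        for j in range(n_chars)
    ]
    return CharacterMatrix(taxa, chars, cells)


def random_single_state_matrix(n_taxa, n_chars, k, rng) -> CharacterMatrix:
    taxa = [f"t{i}" for i in range(n_taxa)]
    chars = [CharacterDefinition.generic(f"c{j}", k) for j in range(n_chars)]
    cells = [
        [Cell.single(int(rng.integers(k))) for _ in range(n_chars)]
        for _ in range(n_taxa)
    ]
    return CharacterMatrix(taxa, chars, cells)


def random_messy_matrix(n_taxa, n_chars, k, rng, p_missing=0.1, p_multi=0.15):
    """Matrix with missing and multistate (uncertain/polymorphic) cells."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    chars = [CharacterDefinition.generic(f"c{j}", k) for j in range(n_chars)]
    cells = []
    for _ in range(n_taxa):
        row = []
        for _ in range(n_chars):
            u = rng.random()
            if u < p_missing:
                row.append(Cell.missing())
            elif u < p_missing + p_multi:
                size = int(rng.integers(2, k + 1))
                states = rng.choice(k, size=size, replace=False)
                if rng.random() < 0.5:
                    row.append(Cell.polymorphic(int(s) for s in states))
                else:
                    row.append(Cell.uncertain(int(s) for s in states))
            else:
                row.append(Cell.single(int(rng.integers(k))))
        cells.append(row)
    return CharacterMatrix(taxa, chars, cells)


def random_trifurcating_newick(taxa, rng) -> str:
    """Random unrooted-style topology (root of degree 3) over given labels."""
    taxa = list(taxa)
    rng.shuffle(taxa)
    groups = [[t] for t in taxa]
    while len(groups) > 3:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        merged = [groups[i], groups[j]]
        groups = [g for idx, g in enumerate(groups) if idx not in (i, j)]
        groups.append(merged)

    def render(g):
        if isinstance(g, str):
            return g
        if len(g) == 1:
            return render(g[0])
        return "(" + ",".join(render(x) for x in g) + ")"

    return "(" + ",".join(render(g) for g in groups) + ");"


# ---------------------------------------------------------------------------
# Brute-force parsimony oracles (enumeration over internal assignments)
# ---------------------------------------------------------------------------


def _tree_structure(tree: dendropy.Tree):
    nodes = list(tree.postorder_node_iter())
    internal = [nd for nd in nodes if not nd.is_leaf()]
    edges = []
    for nd in nodes:
        if nd.parent_node is not None:
            edges.append((nd.parent_node, nd))
    return nodes, internal, edges


def brute_force_steps(tree: dendropy.Tree, matrix: CharacterMatrix, char: int) -> int:
    """Minimum steps by enumerating every internal-node state assignment.

    A leaf's cost against its parent state is 0 if the parent state is in
    the leaf's observed set (full set when missing) else 1 — each leaf picks
    its cheapest member state independently, matching the uncertainty
    interpretation.
    """
    nodes, internal, edges = _tree_structure(tree)
    k = matrix.characters[char].n_states
    leaf_sets = {}
    for nd in nodes:
        if nd.is_leaf():
            cell = matrix.row(nd.taxon.label)[char]
            leaf_sets[nd] = (
                set(range(k)) if cell.is_missing else set(cell.states)
            )
    best = None
    for assign in itertools.product(range(k), repeat=len(internal)):
        states = dict(zip(internal, assign))
        cost = 0
        for parent, child in edges:
            ps = states[parent]
            if child.is_leaf():
                cost += 0 if ps in leaf_sets[child] else 1
            else:
                cost += ps != states[child]
        if best is None or cost < best:
            best = cost
    return best


def brute_force_mpr(tree: dendropy.Tree, matrix: CharacterMatrix, char: int):
    """All optimal assignments: per-internal-node MPR state sets and, for
    every branch, the set of (parent_state, child_state) pairs over optimal
    assignments (leaf states resolved optimally per assignment)."""
    nodes, internal, edges = _tree_structure(tree)
    k = matrix.characters[char].n_states
    leaf_sets = {}
    for nd in nodes:
        if nd.is_leaf():
            cell = matrix.row(nd.taxon.label)[char]
            leaf_sets[nd] = set(range(k)) if cell.is_missing else set(cell.states)
    best = brute_force_steps(tree, matrix, char)
    node_sets = {nd: set() for nd in internal}
    branch_pairs = {child: set() for _, child in edges}
    for assign in itertools.product(range(k), repeat=len(internal)):
        states = dict(zip(internal, assign))
        cost = 0
        for parent, child in edges:
            ps = states[parent]
            if child.is_leaf():
                cost += 0 if ps in leaf_sets[child] else 1
            else:
                cost += ps != states[child]
        if cost != best:
            continue
        for nd in internal:
            node_sets[nd].add(states[nd])
        for parent, child in edges:
            ps = states[parent]
            if child.is_leaf():
                # leaf resolves to cheapest member states; all optimal
                # resolutions count
                if ps in leaf_sets[child]:
                    branch_pairs[child].add((ps, ps))
                else:
                    for s in leaf_sets[child]:
                        branch_pairs[child].add((ps, s))
            else:
                branch_pairs[child].add((ps, states[child]))
    return best, node_sets, branch_pairs


def oracle_unambiguous_changes(tree, matrix, char):
    """Branches changing state, in the same direction, in every optimal
    assignment (oracle for trace_changes with unambiguous_only)."""
    best, node_sets, branch_pairs = brute_force_mpr(tree, matrix, char)
    out = []
    for child, pairs in branch_pairs.items():
        changing = {(t, s) for t, s in pairs if t != s}
        if len(pairs) == 1 and len(changing) == 1:
            (t, s) = next(iter(pairs))
            leafset = frozenset(l.taxon.label for l in child.leaf_iter())
            out.append((leafset, t, s))
    return sorted(out, key=lambda x: (sorted(x[0]), x[1], x[2]))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240623)


@pytest.fixture(scope="session")
def quartet_tree():
    return dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
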