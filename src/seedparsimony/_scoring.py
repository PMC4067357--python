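"""Vectorized unit-cost Sankoff machinery shared by scoring and search.

Characters are unordered with at most 8 states, so a cell's state set fits a
bitmask.  Step counting uses the unit-cost Sankoff dynamic program, which for
unordered characters equals the Fitch count on binary trees and extends it
exactly to polytomies.  All per-node work is vectorized across characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrix import CellKind, CharacterMatrix

MAX_STATES = 8
BIG = np.int32(1 << 20)  # effectively infinite cost; never overflows int32 sums

MULTISTATE_MODES = ("uncertainty", "polymorphism")


def _check_mode(mode: str) -> None:
    if mode not in MULTISTATE_MODES:
        raise ValueError(
            f"multistate_mode must be one of {MULTISTATE_MODES}, got {mode!r}"
        )


@dataclass
class EncodedMatrix:
    """Bitmask view of a :class:`CharacterMatrix` for fast scoring."""

    taxa: list
    masks: np.ndarray  # (n_taxa, n_chars) uint16; missing = full valid mask
    n_states: np.ndarray  # (n_chars,) int
    poly_extra: np.ndarray  # (n_chars,) extra terminal steps in polymorphism mode
    missing: np.ndarray  # (n_taxa, n_chars) bool
    index: dict = field(default_factory=dict)

    def __post_init__(self):
        self.index = {t: i for i, t in enumerate(self.taxa)}
        self._leaf_costs = None

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return self.masks.shape[1]

    @property
    def leaf_costs(self) -> np.ndarray:
        """(n_taxa, n_chars, MAX_STATES) int32: 0 if state in cell set else BIG."""
        if self._leaf_costs is None:
            bits = (self.masks[:, :, None] >> np.arange(MAX_STATES)) & 1
            self._leaf_costs = np.where(bits == 1, np.int32(0), BIG).astype(np.int32)
        return self._leaf_costs

    def extra_steps(self, mode: str) -> np.ndarray:
        _check_mode(mode)
        if mode == "polymorphism":
            return self.poly_extra
        return np.zeros_like(self.poly_extra)

    def take_characters(self, indices) -> "EncodedMatrix":
        indices = list(indices)
        return EncodedMatrix(
            taxa=self.taxa,
            masks=self.masks[:, indices],
            n_states=self.n_states[indices],
            poly_extra=self.poly_extra[indices],
            missing=self.missing[:, indices],
        )


def encode_matrix(matrix: CharacterMatrix) -> EncodedMatrix:
    n_states = np.array([c.n_states for c in matrix.characters], dtype=np.int64)
    if n_states.max(initial=2) > MAX_STATES:
        raise ValueError(f"characters with more than {MAX_STATES} states unsupported")
    masks = np.zeros((matrix.n_taxa, matrix.n_characters), dtype=np.uint16)
    missing = np.zeros_like(masks, dtype=bool)
    poly_extra = np.zeros(matrix.n_characters, dtype=np.int64)
    full = (1 << n_states) - 1
    for i, row in enumerate(matrix.cells):
        for j, cell in enumerate(row):
            if cell.is_missing:
                masks[i, j] = full[j]
                missing[i, j] = True
            else:
                m = 0
                for s in cell.states:
                    m |= 1 << s
                masks[i, j] = m
                if cell.kind is CellKind.POLYMORPHIC:
                    poly_extra[j] += len(cell.states) - 1
    return EncodedMatrix(
        taxa=list(matrix.taxa),
        masks=masks,
        n_states=n_states,
        poly_extra=poly_extra,
        missing=missing,
    )


# ---------------------------------------------------------------------------
# Postorder representation of a tree topology
# ---------------------------------------------------------------------------


@dataclass
class Postorder:
    """A tree flattened into postorder for the Sankoff sweep.

    ``order`` lists node ids in postorder (root last); ``children[v]`` the
    child ids of node ``v``; ``leaf_row[v]`` the matrix row index of leaf
    ``v`` (-1 for internal nodes); ``parent[v]`` the parent id (-1 at root).
    """

    order: list
    children: list
    leaf_row: np.ndarray
    parent: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.order)

    @property
    def root(self) -> int:
        return self.order[-1]


def postorder_from_dendropy(tree, enc: EncodedMatrix) -> Postorder:
    nodes = list(tree.postorder_node_iter())
    ids = {id(nd): k for k, nd in enumerate(nodes)}
    n = len(nodes)
    children = [[] for _ in range(n)]
    leaf_row = np.full(n, -1, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    for nd in nodes:
        k = ids[id(nd)]
        for ch in nd.child_nodes():
            children[k].append(ids[id(ch)])
            parent[ids[id(ch)]] = k
        if nd.is_leaf():
            if nd.taxon is None:
                raise ValueError("tree contains an unlabelled leaf")
            from .matrix import normalize_taxon

            label = normalize_taxon(nd.taxon.label)
            if label not in enc.index:
                raise ValueError(f"leaf {label!r} is not a taxon of the matrix")
            leaf_row[k] = enc.index[label]
    return Postorder(order=list(range(n)), children=children, leaf_row=leaf_row,
                     parent=parent)


# ---------------------------------------------------------------------------
# Sankoff sweeps
# ---------------------------------------------------------------------------


def down_costs(post: Postorder, leaf_costs: np.ndarray) -> np.ndarray:
    """Postorder (leaves-to-root) cost table, (n_nodes, n_chars, MAX_STATES)."""
    n_chars = leaf_costs.shape[1]
    cost = np.empty((post.n_nodes, n_chars, MAX_STATES), dtype=np.int32)
    for v in post.order:
        kids = post.children[v]
        if not kids:
            cost[v] = leaf_costs[post.leaf_row[v]]
            continue
        acc = np.zeros((n_chars, MAX_STATES), dtype=np.int32)
        for c in kids:
            cc = cost[c]
            cmin = cc.min(axis=1, keepdims=True)
            acc += np.minimum(cc, cmin + 1)
        cost[v] = acc
    return cost


def tree_lengths(post: Postorder, leaf_costs: np.ndarray) -> np.ndarray:
    """Per-character minimum step counts (uncertainty interpretation)."""
    cost = down_costs(post, leaf_costs)
    return cost[post.root].min(axis=1).astype(np.int64)


def up_costs(post: Postorder, down: np.ndarray) -> np.ndarray:
    """Preorder "rest of tree" costs.

    ``up[v][s]`` is the minimum number of steps outside the subtree of ``v``
    given that ``v`` (viewed from above) is in state ``s``.  ``up[root] = 0``.
    """
    n_chars = down.shape[1]
    up = np.zeros_like(down)
    contrib = np.empty_like(down)
    for v in post.order:
        cc = down[v]
        cmin = cc.min(axis=1, keepdims=True)
        contrib[v] = np.minimum(cc, cmin + 1)
    for v in reversed(post.order):
        kids = post.children[v]
        if not kids:
            continue
        total = up[v] + sum(contrib[c] for c in kids)
        for c in kids:
            a = total - contrib[c]
            amin = a.min(axis=1, keepdims=True)
            up[c] = np.minimum(a, amin + 1)
    return up


def mpr_sets(post: Postorder, down: np.ndarray, up: np.ndarray) -> np.ndarray:
    """(n_nodes, n_chars, MAX_STATES) bool: state in some most-parsimonious
    assignment at that node."""
    total = down + up
    L = (down[post.root].min(axis=1))[None, :, None]
    return total == L
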