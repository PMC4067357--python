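"""Step counting, homoplasy indices and ancestral-state reconstruction.

All characters are unordered (any state can change to any other at unit
cost).  Two conventions are offered for cells holding several states:

``uncertainty`` (default)
    the terminal has exactly one of the listed states — the classic Fitch
    treatment, where the cell contributes whichever member state is cheapest;
``polymorphism``
    the terminal genuinely possesses all listed states, approximated as the
    uncertainty count plus ``len(states) - 1`` extra terminal steps per
    polymorphic cell.  The same additive term enters the per-character
    minimum ``m`` and maximum ``g`` so that ``m <= s <= g`` holds in both
    modes.

Missing cells are scored as compatible with every state and never add steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Sequence

import dendropy
import numpy as np

from ._scoring import (
    MAX_STATES,
    EncodedMatrix,
    Postorder,
    _check_mode,
    down_costs,
    encode_matrix,
    mpr_sets,
    postorder_from_dendropy,
    tree_lengths,
    up_costs,
)
from .matrix import CharacterMatrix


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepCount:
    character: int
    steps: int
    tree_id: Optional[str] = None


@dataclass
class FitIndices:
    """Per-character and ensemble homoplasy statistics.

    Per-character: minimum conceivable steps ``m``, realized steps ``s``,
    maximum conceivable steps ``g`` (steps on the star tree), consistency
    index ``CI = m/s``, retention index ``RI = (g-s)/(g-m)`` and rescaled
    consistency ``RC = CI*RI``; ``None`` where the ratio is undefined
    (``s = 0`` for CI, ``g = m`` for RI).  Ensemble values use the summed
    numerators and denominators.
    """

    m: np.ndarray
    s: np.ndarray
    g: np.ndarray
    ci: list
    ri: list
    rc: list
    excluded: list  # per character: None or reason string
    multistate_mode: str

    @property
    def tree_length(self) -> int:
        return int(self.s.sum())

    @property
    def ensemble_ci(self) -> Optional[float]:
        tot_s = self.s.sum()
        return float(self.m.sum() / tot_s) if tot_s > 0 else None

    @property
    def ensemble_ri(self) -> Optional[float]:
        span = self.g.sum() - self.m.sum()
        return float((self.g.sum() - self.s.sum()) / span) if span > 0 else None

    @property
    def ensemble_rc(self) -> Optional[float]:
        ci, ri = self.ensemble_ci, self.ensemble_ri
        return None if ci is None or ri is None else ci * ri


def rescaled_consistency(ci: float, ri: float) -> float:
    """Rescaled consistency index, the product of CI and RI."""
    return ci * ri


def proportion(count: int, total: int) -> float:
    """A count expressed as a fraction of a total (e.g. informative sites)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return count / total


@dataclass(frozen=True)
class ChangeRecord:
    """A state change on one branch, identified by the branch's child node."""

    character: int
    parent_clade: frozenset  # leaf labels above the branch's parent side
    child_clade: frozenset  # leaf labels subtended by the child
    from_state: int
    to_state: int
    unambiguous: bool

    @property
    def on_terminal_branch(self) -> bool:
        return len(self.child_clade) == 1


@dataclass
class Reconstruction:
    """Most-parsimonious-reconstruction state sets for one character."""

    character: int
    steps: int
    node_states: dict  # dendropy.Node -> frozenset of states
    tree: dendropy.Tree

    def annotated_newick(self) -> str:
        """Newick string with MPR state sets as node comments."""
        for node, states in self.node_states.items():
            node.comments.clear()
            node.comments.append("mpr=" + "/".join(str(s) for s in sorted(states)))
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_item_comments=False,
        )


@dataclass
class ApomorphyReport:
    autapomorphies: list  # ChangeRecord on terminal branches
    synapomorphies: list  # ChangeRecord on internal branches


# ---------------------------------------------------------------------------
# Step counting
# ---------------------------------------------------------------------------


def _check_char(matrix: CharacterMatrix, char: int) -> None:
    if not 0 <= char < matrix.n_characters:
        raise IndexError(
            f"character index {char} out of range for {matrix.n_characters} characters"
        )


def per_character_steps(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    multistate_mode: str = "uncertainty",
    enc: EncodedMatrix | None = None,
) -> np.ndarray:
    """Minimum steps for every character on ``tree``."""
    _check_mode(multistate_mode)
    enc = enc if enc is not None else encode_matrix(matrix)
    post = postorder_from_dendropy(tree, enc)
    return tree_lengths(post, enc.leaf_costs[:, :, :]) + enc.extra_steps(
        multistate_mode
    )


def fitch_steps(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    char: int,
    multistate_mode: str = "uncertainty",
) -> StepCount:
    """Parsimony step count of one character on one tree."""
    _check_char(matrix, char)
    steps = per_character_steps(tree, matrix, multistate_mode)
    return StepCount(character=char, steps=int(steps[char]))


def tree_length(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    multistate_mode: str = "uncertainty",
) -> int:
    """Total parsimony length (sum of per-character steps)."""
    return int(per_character_steps(tree, matrix, multistate_mode).sum())


# ---------------------------------------------------------------------------
# Per-character bounds m and g
# ---------------------------------------------------------------------------


def _column_state_sets(matrix: CharacterMatrix, char: int):
    return [c.states for c in matrix.column(char) if not c.is_missing]


def min_steps(
    matrix: CharacterMatrix, char: int, multistate_mode: str = "uncertainty"
) -> int:
    """Minimum conceivable steps ``m`` for a character on any tree.

    With uncertainty cells this is the size of the smallest state set that
    intersects every cell's set, minus one (exact hitting-set enumeration;
    alphabets have at most 8 states).
    """
    _check_char(matrix, char)
    _check_mode(multistate_mode)
    sets = _column_state_sets(matrix, char)
    if not sets:
        raise ValueError(f"character {char} has no scored cells; m is undefined")
    alphabet = sorted(frozenset.union(*sets))
    m = None
    for size in range(1, len(alphabet) + 1):
        for combo in combinations(alphabet, size):
            chosen = set(combo)
            if all(chosen & s for s in sets):
                m = size - 1
                break
        if m is not None:
            break
    assert m is not None
    if multistate_mode == "polymorphism":
        m += int(encode_matrix(matrix).poly_extra[char])
    return m


def max_steps(
    matrix: CharacterMatrix, char: int, multistate_mode: str = "uncertainty"
) -> int:
    """Maximum conceivable steps ``g``: the character's length on the star
    tree, with multistate cells resolved to minimize the count."""
    _check_char(matrix, char)
    _check_mode(multistate_mode)
    sets = _column_state_sets(matrix, char)
    if not sets:
        raise ValueError(f"character {char} has no scored cells; g is undefined")
    alphabet = frozenset.union(*sets)
    best_hub = max(sum(1 for s in sets if a in s) for a in alphabet)
    g = len(sets) - best_hub
    if multistate_mode == "polymorphism":
        g += int(encode_matrix(matrix).poly_extra[char])
    return g


def fit_indices(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    multistate_mode: str = "uncertainty",
) -> FitIndices:
    """Per-character and ensemble CI, RI and RC of ``matrix`` on ``tree``."""
    _check_mode(multistate_mode)
    steps = per_character_steps(tree, matrix, multistate_mode)
    n = matrix.n_characters
    m = np.zeros(n, dtype=np.int64)
    g = np.zeros(n, dtype=np.int64)
    ci: list = [None] * n
    ri: list = [None] * n
    rc: list = [None] * n
    excluded: list = [None] * n
    keep = np.ones(n, dtype=bool)
    for j in range(n):
        try:
            m[j] = min_steps(matrix, j, multistate_mode)
            g[j] = max_steps(matrix, j, multistate_mode)
        except ValueError:
            excluded[j] = "no scored cells"
            keep[j] = False
            steps[j] = 0
            continue
        if steps[j] > 0:
            ci[j] = m[j] / steps[j]
        else:
            excluded[j] = "s=0: CI undefined"
        if g[j] > m[j]:
            ri[j] = (g[j] - steps[j]) / (g[j] - m[j])
        else:
            note = "g=m: RI undefined (parsimony-uninformative)"
            excluded[j] = note if excluded[j] is None else excluded[j] + "; " + note
        if ci[j] is not None and ri[j] is not None:
            rc[j] = ci[j] * ri[j]
    return FitIndices(
        m=np.where(keep, m, 0),
        s=np.asarray(steps, dtype=np.int64),
        g=np.where(keep, g, 0),
        ci=ci,
        ri=ri,
        rc=rc,
        excluded=excluded,
        multistate_mode=multistate_mode,
    )


# ---------------------------------------------------------------------------
# Ancestral states and change tracing
# ---------------------------------------------------------------------------


def _single_char_tables(tree, matrix, char):
    enc = encode_matrix(matrix)
    sub = enc.take_characters([char])
    post = postorder_from_dendropy(tree, sub)
    down = down_costs(post, sub.leaf_costs)
    up = up_costs(post, down)
    L = int(down[post.root].min(axis=1)[0])
    return enc, sub, post, down, up, L


def ancestral_states(
    tree: dendropy.Tree, matrix: CharacterMatrix, char: int
) -> Reconstruction:
    """MPR state sets at every node for one character.

    A state belongs to a node's set iff some most-parsimonious assignment
    places it there (computed exactly by a two-pass unit-cost dynamic
    program).  Leaf sets are reported as observed (full set when missing).
    """
    _check_char(matrix, char)
    enc, sub, post, down, up, L = _single_char_tables(tree, matrix, char)
    sets = mpr_sets(post, down, up)[:, 0, :]  # (n_nodes, MAX_STATES) bool
    nodes = list(tree.postorder_node_iter())
    node_states = {}
    k = int(sub.n_states[0])
    for idx, nd in enumerate(nodes):
        if nd.is_leaf():
            row = post.leaf_row[idx]
            mask = int(sub.masks[row, 0])
            node_states[nd] = frozenset(s for s in range(k) if mask >> s & 1)
        else:
            node_states[nd] = frozenset(s for s in range(k) if sets[idx, s])
    return Reconstruction(character=char, steps=L, node_states=node_states, tree=tree)


def _leafset(node) -> frozenset:
    from .matrix import normalize_taxon

    return frozenset(
        normalize_taxon(lf.taxon.label) for lf in node.leaf_iter()
    )


def _feasible_pairs(post, down, up, contrib_sum, v, L, k):
    """State pairs (parent_state, child_state) realized by some MPR on the
    branch above node ``v``."""
    p = post.parent[v]
    # cost outside the subtree of v, as a function of the parent's state:
    # up[p] plus contributions of v's siblings through p
    a = up[p][0] + (contrib_sum[p][0] - np.minimum(down[v][0], down[v][0].min() + 1))
    pairs = []
    for t in range(k):
        if a[t] >= 1 << 19:
            continue
        for s in range(k):
            if down[v][0][s] >= 1 << 19:
                continue
            if int(a[t]) + (t != s) + int(down[v][0][s]) == L:
                pairs.append((t, s))
    return pairs


def trace_changes(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    char: int,
    unambiguous_only: bool = True,
) -> List[ChangeRecord]:
    """Branch-by-branch state changes for one character.

    With ``unambiguous_only`` (the default), a change is reported for a
    branch only when *every* most-parsimonious assignment changes state on
    that branch, in the same direction; this is established exactly from the
    set of (parent-state, child-state) pairs attainable on the branch.

    Without the flag, one most-parsimonious assignment is resolved
    deterministically (root takes its smallest MPR state; each child then
    takes the cheapest state, ties broken toward the smallest code) and its
    changes are reported, each flagged for whether it is unambiguous.
    """
    _check_char(matrix, char)
    enc, sub, post, down, up, L = _single_char_tables(tree, matrix, char)
    k = int(sub.n_states[0])
    nodes = list(tree.postorder_node_iter())

    contrib_sum = np.zeros_like(down)
    for idx in post.order:
        kids = post.children[idx]
        if kids:
            acc = np.zeros_like(down[idx])
            for c in kids:
                acc += np.minimum(down[c], down[c].min(axis=1, keepdims=True) + 1)
            contrib_sum[idx] = acc

    # A root with exactly two children merely subdivides one unrooted branch;
    # its two half-branches are merged into a single branch so that a change
    # forced onto the central branch is not split (and thereby lost) between
    # them.  Parsimony length is unaffected by the subdivision.
    root = post.root
    root_kids = post.children[root]
    merged = tuple(root_kids) if len(root_kids) == 2 else None

    branch_pairs = {}
    for idx, nd in enumerate(nodes):
        if post.parent[idx] < 0:
            continue
        if merged and idx in merged:
            continue
        branch_pairs[idx] = _feasible_pairs(post, down, up, contrib_sum, idx, L, k)
    if merged:
        c1, c2 = merged
        pairs = []
        for t in range(k):
            if down[c1][0][t] >= 1 << 19:
                continue
            for s in range(k):
                if down[c2][0][s] >= 1 << 19:
                    continue
                if int(down[c1][0][t]) + (t != s) + int(down[c2][0][s]) == L:
                    pairs.append((t, s))
        branch_pairs[("central", c2)] = pairs

    def record(idx, t, s, unamb):
        if isinstance(idx, tuple):  # merged central branch
            c2 = idx[1]
            child = nodes[c2]
            parent_clade = _leafset(nodes[merged[0]])
        else:
            child = nodes[idx]
            parent_clade = _leafset(nodes[post.parent[idx]])
        return ChangeRecord(
            character=char,
            parent_clade=parent_clade,
            child_clade=_leafset(child),
            from_state=t,
            to_state=s,
            unambiguous=unamb,
        )

    def is_unambiguous(pairs):
        changing = [(t, s) for t, s in pairs if t != s]
        return len(pairs) == 1 and len(changing) == 1

    if unambiguous_only:
        out = []
        for idx, pairs in branch_pairs.items():
            if is_unambiguous(pairs):
                t, s = pairs[0]
                out.append(record(idx, t, s, True))
        return out

    # deterministic single resolution, preorder
    chosen = {}
    root = post.root
    root_cost = down[root][0]
    chosen[root] = int(np.flatnonzero(root_cost == root_cost.min())[0])
    out = []
    for idx in reversed(post.order):
        p = post.parent[idx]
        if p < 0:
            continue
        t = chosen[p]
        cost_s = np.array(
            [int(t != s) + int(down[idx][0][s]) for s in range(k)], dtype=np.int64
        )
        s = int(np.flatnonzero(cost_s == cost_s.min())[0])
        chosen[idx] = s
        if s != t:
            key = ("central", merged[1]) if (merged and idx in merged) else idx
            out.append(record(idx, t, s, is_unambiguous(branch_pairs[key])))
    return out


def detect_apomorphies(tree: dendropy.Tree, matrix: CharacterMatrix) -> ApomorphyReport:
    """Unambiguous autapomorphies and synapomorphies across all characters.

    An autapomorphy is an unambiguous change on a terminal branch.  A
    synapomorphy is an unambiguous change on an internal branch with no
    subsequent unambiguous change in the same character inside the subtended
    clade.
    """
    aut, syn = [], []
    for char in range(matrix.n_characters):
        changes = trace_changes(tree, matrix, char, unambiguous_only=True)
        for ch in changes:
            if ch.on_terminal_branch:
                aut.append(ch)
            else:
                nested = any(
                    other is not ch and other.child_clade < ch.child_clade
                    for other in changes
                )
                if not nested:
                    syn.append(ch)
    return ApomorphyReport(autapomorphies=aut, synapomorphies=syn)
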