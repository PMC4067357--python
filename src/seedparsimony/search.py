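"""Heuristic maximum-parsimony tree search.

The search follows the classic two-phase strategy: build a starting tree by
stepwise addition (taxa inserted one at a time at the attachment point that
minimizes total length), then refine it by branch swapping (NNI, SPR or TBR
hill climbing), optionally under a positive monophyly constraint.  Multiple
random-addition-sequence replicates are pooled; equally parsimonious distinct
topologies are accumulated up to ``max_trees``.

Internally trees are unrooted and binary, held as adjacency maps over integer
node ids (leaves are matrix row indices).  Scoring uses the vectorized
unit-cost Sankoff sweep from :mod:`seedparsimony._scoring`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from ._scoring import EncodedMatrix, Postorder, _check_mode, encode_matrix, tree_lengths
from .matrix import CharacterMatrix, Constraint, normalize_taxon

Adj = Dict[int, List[int]]


# ---------------------------------------------------------------------------
# Configuration and results
# ---------------------------------------------------------------------------


@dataclass
class SearchConfig:
    """Settings for a heuristic parsimony search.

    ``rearrangement_limit`` caps the number of swap neighbors evaluated per
    search; ``max_trees`` caps how many equally parsimonious distinct
    topologies are kept.
    """

    n_random_additions: int = 10
    swap: str = "TBR"  # none | NNI | SPR | TBR
    max_trees: int = 100
    rearrangement_limit: Optional[int] = None
    seed: int = 0
    constraint: Optional[Constraint] = None
    multistate_mode: str = "uncertainty"
    addition_order: str = "random"  # random | as-is

    def __post_init__(self):
        if self.n_random_additions < 1:
            raise ValueError("n_random_additions must be >= 1")
        if self.max_trees < 1:
            raise ValueError("max_trees must be >= 1")
        if self.swap not in ("none", "NNI", "SPR", "TBR"):
            raise ValueError(f"unknown swap mode {self.swap!r}")
        _check_mode(self.multistate_mode)


@dataclass
class SearchResult:
    best_length: int
    trees: List[dendropy.Tree]
    n_evaluated: int
    replicate_lengths: List[int]
    signatures: Set[FrozenSet] = field(default_factory=set, repr=False)


@dataclass
class SupportTable:
    """Bipartition frequencies over bootstrap replicates (or a tree set).

    Keys are frozensets of taxon labels — the side of the split not
    containing the reference (first) taxon.  Trivial splits are excluded.
    """

    frequencies: Dict[FrozenSet, float]
    n_replicates: int

    def support_for(self, taxa) -> Optional[float]:
        return self.frequencies.get(frozenset(normalize_taxon(t) for t in taxa))


# ---------------------------------------------------------------------------
# Adjacency-map utilities
# ---------------------------------------------------------------------------


def _copy(adj: Adj) -> Adj:
    return {v: list(nb) for v, nb in adj.items()}


def _leaves(adj: Adj) -> List[int]:
    return sorted(v for v, nb in adj.items() if len(nb) == 1)


def _edges(adj: Adj) -> List[Tuple[int, int]]:
    out = []
    for v in sorted(adj):
        for w in adj[v]:
            if v < w:
                out.append((v, w))
    return out


def _connect(adj: Adj, a: int, b: int) -> None:
    adj.setdefault(a, []).append(b)
    adj.setdefault(b, []).append(a)


def _disconnect(adj: Adj, a: int, b: int) -> None:
    adj[a].remove(b)
    adj[b].remove(a)


def _splice_degree2(adj: Adj, v: int) -> None:
    """Remove a degree-2 node, joining its two neighbors directly."""
    a, b = adj[v]
    _disconnect(adj, v, a)
    _disconnect(adj, v, b)
    del adj[v]
    _connect(adj, a, b)


def _postorder(adj: Adj) -> Postorder:
    leaves = _leaves(adj)
    start = leaves[0]
    root = adj[start][0] if len(adj) > 1 else start
    order: List[int] = []
    parent = {root: -1}
    stack = [root]
    seen = {root}
    while stack:
        v = stack.pop()
        order.append(v)
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                parent[w] = v
                stack.append(w)
    order.reverse()  # children before parents
    ids = {v: i for i, v in enumerate(order)}
    children: List[List[int]] = [[] for _ in order]
    par = np.full(len(order), -1, dtype=np.int64)
    leaf_row = np.full(len(order), -1, dtype=np.int64)
    for v in order:
        if parent[v] != -1:
            children[ids[parent[v]]].append(ids[v])
            par[ids[v]] = ids[parent[v]]
        if len(adj[v]) == 1:
            leaf_row[ids[v]] = v  # leaf ids ARE matrix row indices
    return Postorder(order=list(range(len(order))), children=children,
                     leaf_row=leaf_row, parent=par)


class _Scorer:
    """Scores adjacency trees against one encoded matrix."""

    def __init__(self, enc: EncodedMatrix, mode: str):
        self.enc = enc
        self.extra = int(enc.extra_steps(mode).sum())
        self.n_evaluated = 0

    def length(self, adj: Adj) -> int:
        self.n_evaluated += 1
        post = _postorder(adj)
        return int(tree_lengths(post, self.enc.leaf_costs).sum()) + self.extra


def _side_leafset(adj: Adj, a: int, b: int) -> FrozenSet:
    """Leaves on the ``b`` side of edge (a, b)."""
    out = []
    stack, seen = [b], {a, b}
    while stack:
        v = stack.pop()
        if len(adj[v]) == 1:
            out.append(v)
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return frozenset(out)


def _signature(adj: Adj) -> FrozenSet:
    """Canonical topology id: the set of nontrivial splits (each split given
    as the side not containing the smallest leaf)."""
    leaves = set(_leaves(adj))
    ref = min(leaves)
    splits = set()
    for a, b in _edges(adj):
        if len(adj[a]) == 1 or len(adj[b]) == 1:
            continue
        side = _side_leafset(adj, a, b)
        if ref in side:
            side = frozenset(leaves - side)
        if 1 < len(side) < len(leaves) - 1:
            splits.add(side)
    return frozenset(splits)


def _is_monophyletic(adj: Adj, group: Set[int]) -> bool:
    leaves = set(_leaves(adj))
    group = set(group) & leaves
    if len(group) < 2 or len(leaves - group) < 1:
        return True
    for a, b in _edges(adj):
        side = _side_leafset(adj, a, b)
        if side == group or (leaves - side) == group:
            return True
    return False


def _satisfies(adj: Adj, ingroup_rows: Optional[Set[int]]) -> bool:
    return ingroup_rows is None or _is_monophyletic(adj, ingroup_rows)


# ---------------------------------------------------------------------------
# dendropy conversion
# ---------------------------------------------------------------------------


def _to_newick(adj: Adj, taxa: Sequence[str]) -> str:
    leaves = _leaves(adj)
    if len(leaves) == 1:
        return f"{taxa[leaves[0]]};"
    if len(leaves) == 2:
        return f"({taxa[leaves[0]]},{taxa[leaves[1]]});"
    root = adj[leaves[0]][0]

    def sub(v: int, parent: int) -> str:
        if len(adj[v]) == 1:
            return taxa[v]
        parts = [sub(w, v) for w in adj[v] if w != parent]
        return "(" + ",".join(parts) + ")"

    return sub(root, -1) + ";"


def _to_dendropy(adj: Adj, taxa: Sequence[str]) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=_to_newick(adj, taxa), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = False
    return tree


def _from_dendropy(tree: dendropy.Tree, enc: EncodedMatrix) -> Adj:
    adj: Adj = {}
    next_internal = [enc.n_taxa]
    ids: Dict[int, int] = {}

    def node_id(nd) -> int:
        key = id(nd)
        if key not in ids:
            if nd.is_leaf():
                label = normalize_taxon(nd.taxon.label)
                if label not in enc.index:
                    raise ValueError(f"leaf {label!r} is not a taxon of the matrix")
                ids[key] = enc.index[label]
            else:
                ids[key] = next_internal[0]
                next_internal[0] += 1
        return ids[key]

    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            _connect(adj, node_id(nd.parent_node), node_id(nd))
    # a rooted binary presentation adds a degree-2 root: splice it away
    for v in [v for v, nb in adj.items() if len(nb) == 2]:
        _splice_degree2(adj, v)
    return adj


# ---------------------------------------------------------------------------
# Stepwise addition
# ---------------------------------------------------------------------------


def _stepwise_addition_adj(
    enc: EncodedMatrix,
    order: Sequence[int],
    rng: np.random.Generator,
    mode: str,
    ingroup_rows: Optional[Set[int]],
    scorer: Optional[_Scorer] = None,
) -> Adj:
    if len(order) < 3:
        raise ValueError("stepwise addition needs at least 3 taxa")
    scorer = scorer or _Scorer(enc, mode)
    hub = enc.n_taxa  # internal ids start after the leaf rows
    next_internal = hub + 1
    adj: Adj = {}
    for leaf in order[:3]:
        _connect(adj, hub, leaf)
    if not _satisfies(adj, ingroup_rows):
        # any 3-leaf star satisfies any constraint; defensive only
        raise ValueError("constraint unsatisfiable at initialization")
    for leaf in order[3:]:
        best_len = None
        best_edges = []
        for a, b in _edges(adj):
            cand = _copy(adj)
            _disconnect(cand, a, b)
            w = next_internal
            _connect(cand, a, w)
            _connect(cand, w, b)
            _connect(cand, w, leaf)
            if not _satisfies(cand, ingroup_rows):
                continue
            ln = scorer.length(cand)
            if best_len is None or ln < best_len:
                best_len, best_edges = ln, [(a, b)]
            elif ln == best_len:
                best_edges.append((a, b))
        if not best_edges:
            raise ValueError(
                f"no attachment point for taxon row {leaf} satisfies the constraint"
            )
        a, b = best_edges[int(rng.integers(len(best_edges)))]
        _disconnect(adj, a, b)
        w = next_internal
        next_internal += 1
        _connect(adj, a, w)
        _connect(adj, w, b)
        _connect(adj, w, leaf)
    return adj


def stepwise_addition(
    matrix: CharacterMatrix,
    order: str = "as-is",
    seed: int = 0,
    constraint: Optional[Constraint] = None,
    multistate_mode: str = "uncertainty",
) -> dendropy.Tree:
    """Build a starting tree by greedy stepwise taxon addition.

    ``order`` is ``"as-is"`` (matrix order; PAUP*'s "simple addition") or
    ``"random"`` (a seeded permutation).  Ties among equally good attachment
    points are broken by a seeded uniform draw.
    """
    enc = encode_matrix(matrix)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    rows = list(range(enc.n_taxa))
    if order == "random":
        rows = [int(i) for i in rng.permutation(enc.n_taxa)]
    elif order != "as-is":
        raise ValueError(f"unknown addition order {order!r}")
    ingroup_rows = _ingroup_rows(constraint, enc, matrix)
    adj = _stepwise_addition_adj(enc, rows, rng, multistate_mode, ingroup_rows)
    return _to_dendropy(adj, enc.taxa)


def _ingroup_rows(constraint, enc, matrix) -> Optional[Set[int]]:
    if constraint is None:
        return None
    constraint.validate_against(matrix.taxa)
    return {enc.index[t] for t in constraint.ingroup}


# ---------------------------------------------------------------------------
# Branch swapping
# ---------------------------------------------------------------------------


def _nni_neighbors(adj: Adj):
    """Two neighbors per internal edge (swap one subtree across the edge)."""
    for u, v in _edges(adj):
        if len(adj[u]) == 1 or len(adj[v]) == 1:
            continue
        u_sub = [w for w in adj[u] if w != v]
        v_sub = [w for w in adj[v] if w != u]
        # swap u_sub[0] with each subtree on the v side
        for x in v_sub:
            cand = _copy(adj)
            a = u_sub[0]
            _disconnect(cand, u, a)
            _disconnect(cand, v, x)
            _connect(cand, u, x)
            _connect(cand, v, a)
            yield cand


def _spr_neighbors(adj: Adj):
    """Prune each subtree and regraft on every other edge."""
    for u, v in _edges(adj):
        # prune the component on the v side by cutting (u, v); v side keeps v
        for prune_root, anchor in ((v, u), (u, v)):
            cand0 = _copy(adj)
            _disconnect(cand0, anchor, prune_root)
            if len(cand0[anchor]) == 0:
                # kept side is a lone leaf: regrafting the rest reproduces
                # the original tree, so nothing to yield
                continue
            if len(cand0[anchor]) == 2:
                _splice_degree2(cand0, anchor)
            pruned_side = _component(cand0, prune_root)
            for a, b in _edges(cand0):
                if a in pruned_side or b in pruned_side:
                    continue
                cand = _copy(cand0)
                w = max(cand) + 1
                _disconnect(cand, a, b)
                _connect(cand, a, w)
                _connect(cand, w, b)
                _connect(cand, w, prune_root)
                yield cand


def _component(adj: Adj, start: int) -> Set[int]:
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return seen


def _tbr_neighbors(adj: Adj):
    """Bisect every edge and reconnect every pair of edges across the gap."""
    for u, v in _edges(adj):
        cand0 = _copy(adj)
        _disconnect(cand0, u, v)
        rep = {}
        for x in (u, v):
            nbs = cand0[x]
            if len(nbs) == 2:
                rep[x] = nbs[0]
                _splice_degree2(cand0, x)
            else:
                rep[x] = x  # still present (leaf now isolated, or degree >2)
        comp_u = _component(cand0, rep[u])
        all_edges = _edges(cand0)
        edges_u = [e for e in all_edges if e[0] in comp_u]
        edges_v = [e for e in all_edges if e[0] not in comp_u]
        # single-node components reattach at the node itself
        sides_u = edges_u or [None]
        sides_v = edges_v or [None]
        for e1 in sides_u:
            for e2 in sides_v:
                cand = _copy(cand0)
                w = max(cand) + 1
                if e1 is None:
                    p1 = next(n for n in comp_u)  # the lone leaf
                else:
                    a, b = e1
                    _disconnect(cand, a, b)
                    _connect(cand, a, w)
                    _connect(cand, w, b)
                    p1 = w
                    w += 1
                if e2 is None:
                    p2 = next(n for n in cand if n not in comp_u)
                else:
                    a, b = e2
                    _disconnect(cand, a, b)
                    _connect(cand, a, w)
                    _connect(cand, w, b)
                    p2 = w
                _connect(cand, p1, p2)
                yield cand


_NEIGHBOR_FNS = {"NNI": _nni_neighbors, "SPR": _spr_neighbors, "TBR": _tbr_neighbors}


def _swap_search(
    starts: List[Adj],
    scorer: _Scorer,
    config: SearchConfig,
    ingroup_rows: Optional[Set[int]],
) -> Tuple[int, Dict[FrozenSet, Adj], bool]:
    """Hill-climb from ``starts``; returns (best_length, {signature: tree},
    hit_limit)."""
    best_len = None
    best: Dict[FrozenSet, Adj] = {}
    for adj in starts:
        ln = scorer.length(adj)
        if best_len is None or ln < best_len:
            best_len, best = ln, {}
        if ln == best_len:
            best.setdefault(_signature(adj), _copy(adj))
    if config.swap == "none":
        return best_len, best, False

    neighbor_fn = _NEIGHBOR_FNS[config.swap]
    limit = config.rearrangement_limit
    queue = list(best.keys())
    examined: Set[FrozenSet] = set()
    while queue:
        sig = queue.pop(0)
        if sig in examined or sig not in best:
            continue
        examined.add(sig)
        adj = best[sig]
        for cand in neighbor_fn(adj):
            if limit is not None and scorer.n_evaluated >= limit:
                return best_len, best, True
            if not _satisfies(cand, ingroup_rows):
                continue
            ln = scorer.length(cand)
            if ln < best_len:
                best_len = ln
                best = {_signature(cand): _copy(cand)}
                queue = list(best.keys())
                examined = set()
                break  # greedy restart from the improved tree
            if ln == best_len and len(best) < config.max_trees:
                csig = _signature(cand)
                if csig not in best:
                    best[csig] = _copy(cand)
                    queue.append(csig)
    return best_len, best, False


def tbr_search(
    start: dendropy.Tree | Sequence[dendropy.Tree],
    matrix: CharacterMatrix,
    config: SearchConfig,
) -> SearchResult:
    """Branch swapping (per ``config.swap``) from one or more start trees."""
    enc = encode_matrix(matrix)
    trees = [start] if isinstance(start, dendropy.Tree) else list(start)
    starts = [_from_dendropy(t, enc) for t in trees]
    ingroup_rows = _ingroup_rows(config.constraint, enc, matrix)
    for adj in starts:
        if not _satisfies(adj, ingroup_rows):
            raise ValueError("a start tree violates the constraint")
    scorer = _Scorer(enc, config.multistate_mode)
    best_len, best, _ = _swap_search(starts, scorer, config, ingroup_rows)
    return SearchResult(
        best_length=best_len,
        trees=[_to_dendropy(a, enc.taxa) for a in best.values()],
        n_evaluated=scorer.n_evaluated,
        replicate_lengths=[best_len],
        signatures=set(best.keys()),
    )


def heuristic_search(matrix: CharacterMatrix, config: SearchConfig) -> SearchResult:
    """Full heuristic search: stepwise-addition replicates + branch swapping.

    Each replicate derives its own random stream from ``config.seed``, so
    results are reproducible and independent of replicate scheduling.
    """
    enc = encode_matrix(matrix)
    ingroup_rows = _ingroup_rows(config.constraint, enc, matrix)
    scorer = _Scorer(enc, config.multistate_mode)
    overall_len = None
    pooled: Dict[FrozenSet, Adj] = {}
    replicate_lengths: List[int] = []
    for rep in range(config.n_random_additions):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([config.seed, rep]))
        )
        rows = list(range(enc.n_taxa))
        if config.addition_order == "random":
            rows = [int(i) for i in rng.permutation(enc.n_taxa)]
        adj = _stepwise_addition_adj(
            enc, rows, rng, config.multistate_mode, ingroup_rows, scorer
        )
        rep_len, rep_best, _ = _swap_search([adj], scorer, config, ingroup_rows)
        replicate_lengths.append(rep_len)
        if overall_len is None or rep_len < overall_len:
            overall_len = rep_len
            pooled = {}
        if rep_len == overall_len:
            for sig, a in rep_best.items():
                if len(pooled) >= config.max_trees:
                    break
                pooled.setdefault(sig, a)
    return SearchResult(
        best_length=overall_len,
        trees=[_to_dendropy(a, enc.taxa) for a in pooled.values()],
        n_evaluated=scorer.n_evaluated,
        replicate_lengths=replicate_lengths,
        signatures=set(pooled.keys()),
    )


def constrained_search(matrix: CharacterMatrix, config: SearchConfig) -> SearchResult:
    """Heuristic search restricted to trees where the constraint ingroup is
    monophyletic."""
    if config.constraint is None:
        raise ValueError("constrained_search requires config.constraint")
    return heuristic_search(matrix, config)


# ---------------------------------------------------------------------------
# Exhaustive enumeration (small n): the oracle-grade search
# ---------------------------------------------------------------------------


def enumerate_topologies(n_leaves: int):
    """Yield every unrooted binary topology over leaves 0..n-1 (adjacency)."""
    if n_leaves < 3:
        raise ValueError("need >= 3 leaves")

    def build(adj: Adj, next_leaf: int, next_internal: int):
        if next_leaf == n_leaves:
            yield adj
            return
        for a, b in _edges(adj):
            cand = _copy(adj)
            w = next_internal
            _disconnect(cand, a, b)
            _connect(cand, a, w)
            _connect(cand, w, b)
            _connect(cand, w, next_leaf)
            yield from build(cand, next_leaf + 1, next_internal + 1)

    base: Adj = {}
    hub = n_leaves
    for leaf in range(3):
        _connect(base, hub, leaf)
    yield from build(base, 3, hub + 1)


def exhaustive_search(
    matrix: CharacterMatrix,
    multistate_mode: str = "uncertainty",
    constraint: Optional[Constraint] = None,
) -> SearchResult:
    """Score every topology (feasible only for small taxon counts)."""
    enc = encode_matrix(matrix)
    ingroup_rows = _ingroup_rows(constraint, enc, matrix)
    scorer = _Scorer(enc, multistate_mode)
    best_len = None
    best: Dict[FrozenSet, Adj] = {}
    for adj in enumerate_topologies(enc.n_taxa):
        if not _satisfies(adj, ingroup_rows):
            continue
        ln = scorer.length(adj)
        if best_len is None or ln < best_len:
            best_len, best = ln, {}
        if ln == best_len:
            best[_signature(adj)] = _copy(adj)
    return SearchResult(
        best_length=best_len,
        trees=[_to_dendropy(a, enc.taxa) for a in best.values()],
        n_evaluated=scorer.n_evaluated,
        replicate_lengths=[best_len],
        signatures=set(best.keys()),
    )


# ---------------------------------------------------------------------------
# Consensus and bootstrap
# ---------------------------------------------------------------------------


def _common_namespace_trees(trees: Sequence[dendropy.Tree]) -> dendropy.TreeList:
    newicks = []
    leafsets = []
    for t in trees:
        leafsets.append(frozenset(normalize_taxon(l.taxon.label) for l in t.leaf_node_iter()))
        newicks.append(
            t.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True).strip()
        )
    if len(set(leafsets)) > 1:
        raise ValueError("consensus requires identical leaf sets across trees")
    return dendropy.TreeList.get(
        data="\n".join(newicks), schema="newick", preserve_underscores=True
    )


def strict_consensus(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Tree containing exactly the bipartitions present in every input tree."""
    if not trees:
        raise ValueError("need at least one tree")
    tl = _common_namespace_trees(trees)
    cons = tl.consensus(min_freq=1.0)
    cons.is_rooted = False
    return cons


def majority_rule_consensus(
    trees: Sequence[dendropy.Tree], threshold: float = 0.5
) -> dendropy.Tree:
    """Consensus containing splits with frequency strictly above ``threshold``
    (splits at exactly the threshold are excluded); split frequencies are
    attached as node support values."""
    if not trees:
        raise ValueError("need at least one tree")
    tl = _common_namespace_trees(trees)
    # smallest split count strictly above the threshold; the midpoint cutoff
    # is robust to dendropy's inclusive/exclusive min_freq convention
    n = len(tl)
    j = int(np.floor(threshold * n + 1e-9)) + 1
    cons = tl.consensus(min_freq=min((j - 0.5) / n, 1.0))
    cons.is_rooted = False
    freqs = split_frequencies(trees)
    leafset = frozenset(
        normalize_taxon(l.taxon.label) for l in cons.leaf_node_iter()
    )
    ref = min(leafset)
    for nd in cons.preorder_internal_node_iter():
        side = frozenset(normalize_taxon(l.taxon.label) for l in nd.leaf_iter())
        if ref in side:
            side = leafset - side
        if 1 < len(side) < len(leafset) - 1:
            nd.support = freqs.get(side, 0.0)
    return cons


def split_frequencies(trees: Sequence[dendropy.Tree]) -> Dict[FrozenSet, float]:
    """Frequency of every nontrivial split over a tree set.

    Splits are keyed by the side not containing the lexicographically first
    taxon.
    """
    counts: Dict[FrozenSet, int] = {}
    leafsets = set()
    for t in trees:
        leafset = frozenset(normalize_taxon(l.taxon.label) for l in t.leaf_node_iter())
        leafsets.add(leafset)
        ref = min(leafset)
        seen = set()
        for nd in t.preorder_internal_node_iter():
            side = frozenset(normalize_taxon(l.taxon.label) for l in nd.leaf_iter())
            if ref in side:
                side = leafset - side
            if 1 < len(side) < len(leafset) - 1:
                seen.add(side)
        for side in seen:
            counts[side] = counts.get(side, 0) + 1
    if len(leafsets) > 1:
        raise ValueError("split frequencies require identical leaf sets")
    return {k: v / len(trees) for k, v in counts.items()}


def bootstrap_support(
    matrix: CharacterMatrix,
    config: SearchConfig,
    n_replicates: int = 100,
    seed: int = 0,
) -> SupportTable:
    """Nonparametric bootstrap clade support.

    Characters are resampled with replacement per replicate; each replicate
    runs one simple-addition search with the configured swapping and holds
    one best tree; split frequencies are tallied over replicates.
    """
    enc = encode_matrix(matrix)
    ref = matrix.taxa[0]
    counts: Dict[FrozenSet, int] = {}
    for rep in range(n_replicates):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([seed, rep]))
        )
        idx = [int(i) for i in rng.integers(matrix.n_characters, size=matrix.n_characters)]
        sub_enc = enc.take_characters(idx)
        scorer = _Scorer(sub_enc, config.multistate_mode)
        rows = list(range(enc.n_taxa))
        adj = _stepwise_addition_adj(
            sub_enc, rows, rng, config.multistate_mode, None, scorer
        )
        rep_config = replace(config, constraint=None, max_trees=1)
        _, best, _ = _swap_search([adj], scorer, rep_config, None)
        first_sig = sorted(best.keys(), key=lambda s: sorted(map(sorted, s)))[0]
        one = best[first_sig]
        leaves = set(_leaves(one))
        for a, b in _edges(one):
            if len(one[a]) == 1 or len(one[b]) == 1:
                continue
            side = _side_leafset(one, a, b)
            if enc.index[ref] in side:
                side = frozenset(leaves - side)
            if 1 < len(side) < len(leaves) - 1:
                key = frozenset(enc.taxa[i] for i in side)
                counts[key] = counts.get(key, 0) + 1
    freqs = {k: v / n_replicates for k, v in counts.items()}
    return SupportTable(frequencies=freqs, n_replicates=n_replicates)
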