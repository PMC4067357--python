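"""Tree-comparison and phylogenetic-signal tests.

Three procedures:

* the Templeton test — a Wilcoxon signed-rank test on per-character step
  differences between two trees, the standard nonparametric check of whether
  one topology explains the data significantly worse than another;
* a tip-randomization permutation test of phylogenetic signal — the observed
  step count of a character on a reference tree is compared with its counts
  after shuffling the taxon-to-data assignment;
* the incongruence length difference (ILD, partition-homogeneity) test —
  the excess of the combined-matrix tree length over the sum of
  per-partition optima, referred to a null built by randomly reassigning
  characters to partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import dendropy
import numpy as np
from scipy import stats

from ._scoring import _check_mode, encode_matrix, postorder_from_dendropy, tree_lengths
from .matrix import CharacterMatrix, Constraint
from .parsimony import per_character_steps
from .search import SearchConfig, constrained_search, heuristic_search

ALPHA_DEFAULT = 0.05


# ---------------------------------------------------------------------------
# Templeton (Wilcoxon signed-rank) test
# ---------------------------------------------------------------------------


@dataclass
class WilcoxonResult:
    """Templeton test outcome.

    ``z`` follows the reporting convention that a positive length difference
    (``tree_b`` longer than ``tree_a``) carries a negative z.  ``p_exact`` is
    the full signed-rank permutation probability, reported when the number
    of nonzero differences is at most 20.
    """

    differences: np.ndarray  # per character, tree_b - tree_a
    n_nonzero: int
    t_statistic: float  # min of the positive/negative rank sums
    z: float
    p: float
    p_exact: Optional[float]

    @property
    def delta(self) -> int:
        return int(self.differences.sum())


def _signed_rank(d: np.ndarray):
    """Rank sums, tie-corrected normal z and exact permutation P for the
    Wilcoxon signed-rank statistic T = min(W+, W-)."""
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0, 0.0, 0.0, 1.0, 1.0
    ranks = stats.rankdata(np.abs(d))  # midranks for ties
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    T = min(w_pos, w_neg)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction over groups of equal |d|
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        return n, T, 0.0, 1.0, 1.0
    z = (T - mu) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.cdf(z))
    p_exact = None
    if n <= 20:
        p_exact = _exact_signed_rank_p(ranks, T)
    return n, T, float(z), float(p), p_exact


def _exact_signed_rank_p(ranks: np.ndarray, T_obs: float) -> float:
    """P(T <= T_obs) over all 2^n sign assignments of the ranks, where
    T = min(W+, W-).

    Midranks are half-integers, so doubling makes every rank integral and a
    generating-function sweep counts the assignments at each positive-rank
    sum.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    sums = np.arange(total + 1)
    keep = np.minimum(sums, total - sums) <= 2 * T_obs + 1e-9
    return float(counts[keep].sum() / counts.sum())


def templeton_test(
    tree_a: dendropy.Tree,
    tree_b: dendropy.Tree,
    matrix: CharacterMatrix,
    multistate_mode: str = "uncertainty",
) -> WilcoxonResult:
    """Compare two trees on per-character parsimony steps.

    Differences are ``steps(tree_b) - steps(tree_a)``; zero differences are
    dropped, absolute differences are midranked, and the two-tailed P comes
    from the tie-corrected normal approximation (plus the exact permutation
    distribution when at most 20 characters differ).
    """
    enc = encode_matrix(matrix)
    steps_a = per_character_steps(tree_a, matrix, multistate_mode, enc=enc)
    steps_b = per_character_steps(tree_b, matrix, multistate_mode, enc=enc)
    d = (steps_b - steps_a).astype(np.int64)
    n, T, z, p, p_exact = _signed_rank(d.astype(float))
    if d.sum() > 0:
        z = -abs(z)
    elif d.sum() < 0:
        z = abs(z)
    return WilcoxonResult(
        differences=d, n_nonzero=n, t_statistic=T, z=z, p=p, p_exact=p_exact
    )


# ---------------------------------------------------------------------------
# Constraint hypothesis testing
# ---------------------------------------------------------------------------


@dataclass
class ConstraintDecision:
    constraint: Constraint
    unconstrained_length: int
    constrained_length: int
    wilcoxon: WilcoxonResult
    alpha: float
    reject: bool

    @property
    def delta(self) -> int:
        return self.constrained_length - self.unconstrained_length


def test_constraint_hypothesis(
    matrix: CharacterMatrix,
    constraint: Constraint,
    config: SearchConfig,
    alpha: float = ALPHA_DEFAULT,
) -> ConstraintDecision:
    """Can the monophyly of ``constraint.ingroup`` be rejected?

    Runs an unconstrained and a constrained heuristic search, draws one tree
    uniformly (seeded) from each best set, and applies the Templeton test.
    """
    free = heuristic_search(matrix, config)
    from dataclasses import replace

    constrained = constrained_search(matrix, replace(config, constraint=constraint))
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([config.seed, 0xC0]))
    )
    tree_a = free.trees[int(rng.integers(len(free.trees)))]
    tree_b = constrained.trees[int(rng.integers(len(constrained.trees)))]
    wil = templeton_test(tree_a, tree_b, matrix, config.multistate_mode)
    return ConstraintDecision(
        constraint=constraint,
        unconstrained_length=free.best_length,
        constrained_length=constrained.best_length,
        wilcoxon=wil,
        alpha=alpha,
        reject=wil.p < alpha,
    )


# ---------------------------------------------------------------------------
# Tip-randomization phylogenetic signal
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    observed_steps: int
    n_perm: int
    count_le: int
    character: Optional[int] = None

    def __post_init__(self):
        if self.n_perm <= 0:
            raise ValueError("n_perm must be positive")
        if not 0 <= self.count_le <= self.n_perm:
            raise ValueError("count_le must lie in [0, n_perm]")

    @property
    def p(self) -> float:
        return self.count_le / self.n_perm

    @property
    def significant(self) -> bool:
        return self.p < ALPHA_DEFAULT


def permutation_pvalue(count_le: int, n_perm: int) -> float:
    """P-value estimator for the tip-randomization test: the number of
    randomized datasets with equal-or-lower steps over the number of
    permutations."""
    return PermutationResult(observed_steps=0, n_perm=n_perm, count_le=count_le).p


def _signal_counts(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    chars: Sequence[int],
    n_perm: int,
    seed: int,
    joint: bool,
):
    """Observed per-character steps and counts of permutations with
    equal-or-lower steps.  ``joint`` reuses one row shuffle across
    characters per replicate; otherwise each character gets its own
    permutations (identical marginal null either way)."""
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    enc = encode_matrix(matrix)
    post = postorder_from_dendropy(tree, enc)
    leaf_costs = enc.leaf_costs
    observed = tree_lengths(post, leaf_costs)
    chars = list(chars)
    counts = np.zeros(len(chars), dtype=np.int64)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed])))
    if joint:
        for _ in range(n_perm):
            perm = rng.permutation(enc.n_taxa)
            lens = tree_lengths(post, leaf_costs[perm])
            counts += lens[chars] <= observed[chars]
    else:
        for i, c in enumerate(chars):
            # stack all permutations of this character as pseudo-characters
            perms = np.stack([rng.permutation(enc.n_taxa) for _ in range(n_perm)])
            stacked = leaf_costs[perms.T, c, :]  # (n_taxa, n_perm, 8)
            lens = tree_lengths(post, stacked)
            counts[i] = int((lens <= observed[c]).sum())
    return observed, counts


def phylo_signal(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    char: int,
    n_perm: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """Tip-randomization test of phylogenetic signal for one character.

    ``P = count_le / n_perm`` where ``count_le`` is the number of shuffled
    datasets whose step count is less than or equal to the observed count;
    small P means the observed distribution of states is better structured
    on the tree than random relabelings.
    """
    observed, counts = _signal_counts(tree, matrix, [char], n_perm, seed, joint=False)
    return PermutationResult(
        observed_steps=int(observed[char]),
        n_perm=n_perm,
        count_le=int(counts[0]),
        character=char,
    )


def phylo_signal_all(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    n_perm: int = 10000,
    seed: int = 0,
) -> List[PermutationResult]:
    """Signal test for every character, one joint row shuffle per replicate.

    The joint shuffle leaves each character's marginal null unchanged while
    evaluating all characters against the same randomized trees.
    """
    chars = list(range(matrix.n_characters))
    observed, counts = _signal_counts(tree, matrix, chars, n_perm, seed, joint=True)
    return [
        PermutationResult(
            observed_steps=int(observed[c]),
            n_perm=n_perm,
            count_le=int(counts[i]),
            character=c,
        )
        for i, c in enumerate(chars)
    ]


# ---------------------------------------------------------------------------
# ILD / partition homogeneity test
# ---------------------------------------------------------------------------


@dataclass
class ILDResult:
    observed_statistic: int
    n_reps: int
    count_ge: int
    partition_sizes: List[int]
    null_statistics: List[int] = field(default_factory=list, repr=False)

    @property
    def p(self) -> float:
        return self.count_ge / self.n_reps


def _partition_lengths(matrix, blocks, config, seed_tag):
    from dataclasses import replace

    lengths = []
    for b, block in enumerate(blocks):
        sub = matrix.take_characters(block)
        res = heuristic_search(sub, replace(config, seed=(config.seed + seed_tag * 1009 + b) % (1 << 31)))
        lengths.append(res.best_length)
    return lengths


def ild_test(
    matrix: CharacterMatrix,
    partition: Sequence[Sequence[int]],
    n_reps: int = 250,
    config: Optional[SearchConfig] = None,
    seed: int = 0,
) -> ILDResult:
    """Incongruence length difference test between character blocks.

    The statistic is the combined-matrix best length minus the sum of
    per-block best lengths (all via heuristic searches).  The null
    reassigns characters to blocks of the original sizes at random; P is
    the proportion of null statistics greater than or equal to the observed
    one (larger excess = more incongruent).
    """
    blocks = [list(b) for b in partition]
    if any(len(b) < 1 for b in blocks):
        raise ValueError("every partition block needs at least one character")
    flat = sorted(c for b in blocks for c in b)
    if flat != sorted(set(flat)):
        raise ValueError("partition blocks must be disjoint")
    if flat != list(range(matrix.n_characters)):
        raise ValueError("partition blocks must cover all characters")
    if config is None:
        config = SearchConfig(n_random_additions=2, swap="TBR", seed=seed)

    combined = heuristic_search(matrix, config).best_length
    observed = combined - sum(_partition_lengths(matrix, blocks, config, 0))

    sizes = [len(b) for b in blocks]
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 0x11D])))
    count_ge = 0
    nulls = []
    for rep in range(n_reps):
        perm = [int(i) for i in rng.permutation(matrix.n_characters)]
        shuffled_blocks = []
        start = 0
        for size in sizes:
            shuffled_blocks.append(perm[start : start + size])
            start += size
        null_stat = combined - sum(
            _partition_lengths(matrix, shuffled_blocks, config, rep + 1)
        )
        nulls.append(null_stat)
        if null_stat >= observed:
            count_ge += 1
    return ILDResult(
        observed_statistic=observed,
        n_reps=n_reps,
        count_ge=count_ge,
        partition_sizes=sizes,
        null_statistics=nulls,
    )
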