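# Methods

This note records the models, conventions and numerical choices behind
`seedparsimony`, in the spirit of the methods documentation that simulation
and statistics packages ship alongside their APIs.

## Characters, cells and scoring conventions

A character is unordered and multistate (2–8 states, coded 0..k−1): any
state may change to any other at unit cost.  A matrix cell is one of four
kinds — a single state; *polymorphic* (the taxon genuinely shows several
states, NEXUS `(01)`); *uncertain* (one true state, unknown which, NEXUS
`{01}`); or *missing* (`?`).  Missing cells are scored as compatible with
every state and never add steps, but are tallied separately in matrix
summaries, since the fraction of missing cells and the fraction of
polymorphic cells are distinct descriptive statistics of such datasets.
In delimited (TSV/CSV) input a bare multi-digit token like `01` is read as
polymorphic, since morphological datasets conventionally mean "both states
present" there.

Two scoring modes govern multi-state cells:

* **uncertainty** (default): the cell contributes whichever member state is
  cheapest — the classic Fitch treatment.  This mode is exact.
* **polymorphism**: the terminal must ultimately possess all its observed
  states.  This is approximated as the uncertainty count plus
  `len(states) − 1` additional terminal steps per polymorphic cell — a
  documented, bounded approximation of the convention in classic parsimony
  software, exact whenever no polymorphism is present.  The same additive
  term is applied to the per-character minimum `m` and maximum `g`, so the
  invariant `m ≤ s ≤ g` and the behaviour of CI/RI are preserved in both
  modes (a homoplasy-free character keeps CI = 1 either way).

## Step counting

Step counts use the unit-cost Sankoff dynamic program (per-state minimal
costs, one postorder sweep), vectorized across characters with 8-state cost
rows.  On binary trees this equals the Fitch count; on polytomies it is the
exact minimum for the hard-polytomy interpretation, so trees with
unresolved nodes (e.g. consensus trees) are scored correctly.  The count is
invariant to the arbitrary rooting of an unrooted tree; a dedicated
property test reroots on every branch and checks equality, and a 500-case
randomized suite checks the count against exhaustive enumeration of all
internal-node state assignments on trees of up to 8 leaves.

Per-character bounds:

* `m` (minimum conceivable steps) is the size of the smallest state set
  hitting every cell's state set, minus one, found by exact subset
  enumeration (alphabets have at most 8 states).  With no multistate cells
  this reduces to the number of distinct observed states minus one.
* `g` (maximum conceivable steps) is the character's length on the star
  tree: the number of scored cells minus the best single-state coverage,
  with multistate cells resolved to minimize the count.  Refining a star
  into any binary tree can only lower the parsimony length, so this is the
  maximum over trees.

Homoplasy indices follow the standard definitions (CI = m/s,
RI = (g−s)/(g−m), RC = CI·RI; ensemble versions from summed numerators and
denominators).  Characters with s = 0 (CI undefined) or g = m
(parsimony-uninformative; RI undefined) are excluded from the affected
per-character ratio and flagged in the output table; ensemble sums include
every scored character.  All ratios are kept at full precision and rounded
only at report time.

## Ancestral states and change tracing

MPR (most-parsimonious-reconstruction) state sets come from a two-pass
dynamic program: the postorder pass gives the cost of each subtree per
state, a preorder pass gives the cost of the rest of the tree per state,
and a state belongs to a node's MPR set iff the two sum to the global
minimum.  Leaf sets are reported as observed (the full set for missing
cells).

Change tracing classifies each branch by the set of (parent-state,
child-state) pairs attainable in some most-parsimonious assignment.  A
change is *unambiguous* when exactly one pair is attainable and it changes
state — i.e. every optimal assignment changes state on that branch in the
same direction.  A root with exactly two children merely subdivides one
unrooted branch; its two half-branches are merged before classification so
that a change forced onto the central branch is not split between them and
lost.  Without the unambiguous-only flag, one full assignment is resolved
deterministically (root takes the smallest state in its MPR set; each child
then the cheapest state, ties toward the smaller code) and its changes are
listed with per-branch ambiguity flags.  An autapomorphy is an unambiguous
change on a terminal branch; a synapomorphy an unambiguous change on an
internal branch with no later unambiguous change of the same character
inside the subtended clade.  The tracer is verified against explicit
enumeration of all optimal assignments on trees of up to 8 leaves.

## Tree search

Starting trees come from stepwise addition: each taxon is inserted on the
edge minimizing total length at that stage, ties broken by a seeded uniform
draw (avoiding input-order bias while staying reproducible).  "Simple
addition" means matrix-order insertion and is the default for bootstrap
replicates.  Refinement is hill climbing over NNI, SPR or TBR
neighborhoods; swapping never accepts a longer tree, equally parsimonious
distinct topologies are accumulated up to `max_trees` (topology identity =
the set of nontrivial unrooted bipartitions) and each is itself swapped.
`rearrangement_limit` caps the number of neighbors evaluated per search.
A full heuristic search runs several random-addition replicates, each with
its own substream derived from the master seed, and pools best trees, so
results are independent of scheduling and bit-reproducible.

Positive constraints require a named ingroup to be monophyletic: stepwise
insertions and swap neighbors violating the (partial) constraint are
skipped.  Only single-clade positive constraints are supported; backbone
constraints are out of scope.  On seven or fewer taxa an exhaustive
enumeration over all unrooted topologies (945 at n = 7) provides the
oracle: randomized suites require the heuristic to hit the global optimum
in at least 99 of 100 matrices, and constrained searches are checked
against enumeration restricted to constraint-compatible topologies.

Majority-rule consensus retains splits with frequency strictly above the
threshold (a split at exactly 0.5 is excluded), implemented with a midpoint
cutoff that is robust to inclusive/exclusive library conventions; split
frequencies are annotated as node support.  Bootstrap support resamples
characters with replacement, runs one simple-addition search per replicate
holding one best tree, and tallies split frequencies.

## Resampling tests

**Templeton test.** Per-character step differences between two trees;
zero differences dropped (classic signed-rank practice — the source
analyses do not state their zero handling); absolute differences midranked;
T = min(W⁺, W⁻); z from the tie-corrected normal approximation with
two-tailed P.  The reported z is negative when the second (constrained)
tree is longer, matching the reporting convention of such tables.  When at
most 20 differences are nonzero the exact permutation P — the mass of sign
assignments with T at or below the observed value, computed by a
generating-function sweep over doubled (integral) midranks — is reported
alongside, and the machinery is tested against full 2ⁿ enumeration for all
n ≤ 12.

**Constraint hypothesis testing** runs the unconstrained and constrained
searches, draws one tree uniformly (seeded) from each best set — mirroring
the practice of comparing one random most-parsimonious tree against one
random constrained tree — and applies the Templeton test at α = 0.05
(two-tailed).

**Phylogenetic signal.** For each character, the observed step count on the
reference tree is compared with counts after uniformly shuffling the
taxon-to-row assignment; P = (number of shuffles with equal-or-lower
steps) / n_perm, exactly.  The whole-matrix variant reuses one joint row
shuffle per replicate across characters: each character's marginal null is
identical to per-character shuffling, and one relabelling per replicate is
what "randomizing terminal taxa" describes.  Because the null is a
permutation distribution of an integer statistic, the test is conservative
on small trees where that distribution is coarse; the type-I calibration
check therefore uses a 128-taxon tree, where the null is fine-grained
enough for the rejection rate at α = 0.05 over 1000 independent characters
to sit inside the 95% binomial envelope.

**ILD / partition homogeneity.** The statistic is the combined-matrix best
length minus the sum of per-block best lengths (all heuristic, seeded); the
null reassigns characters to blocks of the original sizes at random, and P
is the proportion of null statistics ≥ the observed excess (one-sided:
larger excess = more incongruence).  With exact search the statistic is
provably non-negative; with heuristic search this holds in practice and is
asserted under enumeration on small cases.

## Synthetic data

The simulator emulates the structure of seed-morphology matrices: 17
characters with arities (4,2,2,8,4,2,2,2,2,2,3,2,3,2,2,2,8), 3.8% missing
cells, 2.5% polymorphic cells — the default `SimConfig`.  Trees are Yule
(pure birth, unit birth rate, branch lengths in expected time; delegated to
dendropy's birth–death simulator) or uniform over unrooted labelled binary
topologies.  For the uniform model, sequential insertion of each new leaf
on a uniformly chosen edge is *exactly* uniform at every size, so it is
used throughout rather than enumerating small cases separately.

Characters evolve under the symmetric k-state Mk process from a uniform
root state; on a branch of length b the probability of ending in a specific
other state is (1 − exp(−k/(k−1)·rate·b))/k, with `rate` the expected
number of substitutions per unit branch length (default 0.5 — enough
change for variable characters on a unit-height tree without saturating).
Variable-only ascertainment is available as a post-filter.  Missing and
polymorphic cells are injected independently per cell; a polymorphic cell
gains one uniformly drawn extra state.  Label shuffling permutes only the
taxon-to-data association.

What the generator does **not** emulate: correlated character evolution,
rate variation across lineages or characters, and non-random patterns of
missing data (in real matrices missingness concentrates in poorly sampled
taxa).  Passing tests therefore demonstrate correctness of the algorithms
and calibration under the stated model, not robustness of the biological
conclusions to model violations.

## Problem sizes and reproducibility

Randomized suites use sizes at which exact oracles are feasible: trees of
4–10 leaves for enumeration oracles, 100 seeded replicates for search and
recovery rates, 499–999 permutations per signal test, and the 128-taxon
calibration run above.  Every stochastic component takes an explicit seed
and derives independent substreams (numpy `SeedSequence`) per replicate, so
identical seeds give bit-identical results and adding a pipeline stage
never perturbs earlier draws.  The published 390 × 17 study matrix exists
only as a PDF supplement; `seedparsimony.datasets.load_study_matrix`
defines the transcription pathway, and the checks that depend on the real
matrix (its 3.8%/2.5% summaries; the length-526 search target) run only
against such a transcription, whose fidelity rests with the transcriber.

## Known limitations

* The polymorphism scoring mode is an additive approximation, not the exact
  polymorphic-terminal optimization of classic parsimony software; counts
  of most-parsimonious trees may also differ across implementations because
  tree-identity conventions differ.
* Hill climbing with TBR is a local search; optimality guarantees exist
  only where the exhaustive oracle runs (≤ 7 taxa in the test suite).
* Ordered/Dollo/weighted characters, backbone constraints and
  likelihood-based ancestral states are out of scope.
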