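# Methods

This note documents the models and procedures implemented in `ptmix`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make runs exactly
reproducible.

## Trees, splits, and distances

Trees are unrooted leaf-labeled trees: connected acyclic graphs with no
degree-2 vertices, leaves labeled bijectively with taxon names. *Resolved*
means every vertex has degree 1 or 3; a resolved tree on n ≥ 3 leaves has
2n − 3 edges and n − 3 nontrivial bipartitions. One- and two-leaf trees
are permitted as degenerate partial trees (they arise transiently during
mixing) and count as resolved by convention.

Rooted Newick input is silently unrooted by suppressing the degree-2 root,
since all machinery here operates on unrooted trees. Internal node labels
are ignored on input and omitted on output. Bipartitions are canonicalized
with the side containing the lexicographically smallest taxon first, which
gives deterministic hashing and orientation-independent equality.

Robinson–Foulds (RF) distance is the size of the symmetric difference of
the two trees' nontrivial bipartition sets. In the exact 0/1 partition
space (one dimension per possible split), Euclidean distance equals
√RF, every resolved n-taxon tree has norm √(n−3), and the star tree sits
at the origin; `exact_distance` computes this through RF without ever
materializing the exponential-dimensional vectors.

## Fitch parsimony

Characters are A, C, G, T encoded as 4-bit masks; gap `-` and missing `?`
both encode the full state set (the standard Fitch "any state"
convention). Constant and uninformative sites are scored, not stripped;
site patterns are deduplicated with multiplicities as a pure optimization
that cannot change any score.

On resolved trees the classic two-state-set Fitch pass gives the exact
minimum number of changes. Multifurcating vertices are scored by the
sequential running-intersection generalization (each child set that fails
to intersect the running set costs one change and is unioned in). This
rule is deterministic and standard, but it is *not* guaranteed to equal
the exhaustive minimum on multifurcations (e.g. child sets
{A},{A},{C},{C},{C} give 1 sequentially, minimum 2); the search never
scores unresolved trees, so the rule exists only as defensive support, and
exact-minimum oracle tests are run on resolved trees.

Per-branch mutation counts come from one canonical most-parsimonious
reconstruction: a downpass collects state sets, then states are assigned
top-down keeping the parent's state when it is available and otherwise the
lowest-index state (A<C<G<T). Which MP reconstruction defines "the longest
branch" is genuinely underdetermined; determinism and reproducibility were
prioritized over any particular choice, and on resolved trees the counts
provably sum to the Fitch score.

### Incremental scoring

For every edge of a resolved tree the package keeps the two directional
Fitch state sets (each side of the edge viewed from the other) and their
accumulated costs. The score of inserting a taxon on an edge, or of
reconnecting two bisection halves at an edge pair, is then exact in
O(sites): for halves with midpoint sets M1, M2 and internal scores S1, S2,
the joined tree scores S1 + S2 + Σ_sites w·[M1 ∩ M2 = ∅]. This identity is
what makes full TBR neighborhood scans affordable — a scan is one
broadcast AND over the (edges × edges × sites) array — and it is tested
against from-scratch rescoring.

## Search primitives

Stepwise addition shuffles the taxa (seeded), builds the unique three-taxon
tree, and inserts each remaining taxon at the edge minimizing the resulting
score, ties broken by the first edge in canonical enumeration order
(edges sorted by vertex ids, which are themselves deterministic given the
construction history and seed).

TBR removes one branch, smooths the cut endpoints, and reconnects the two
halves by subdividing one edge in each and joining the new vertices; when a
half is a single leaf the reconnection attaches at that leaf (the standard
degenerate convention). The neighborhood excludes the one reconnection
that recreates the input. The hill-climb accepts strict improvements only
— so trajectories strictly decrease and terminate — and scans the full
neighborhood per iteration taking the best improvement (a first-improvement
policy is available; both reach TBR local minima when rounds are
unlimited). An optional evaluation budget counts every scored reconnection
candidate and stops the search when exhausted, returning the best tree
found; it exists to compare search strategies under matched amounts of
scoring work.

## Cartographic projection

The projection into R^d never materializes reference vectors: the
component of a bipartition in dimension k is obtained from a keyed 64-bit
BLAKE2b hash of the bipartition's canonical byte encoding and k, taking 53
high bits to [0,1) and mapping affinely to [−1,1). Components are
deterministic given (bipartition, dimension, seed), empirically uniform
(KS-tested), and platform-independent. A tree projects to the sum of its
bipartitions' vectors, so projection is additive and O(n·d).

d defaults to 10: small enough that projection is negligible next to
scoring, large enough that projected distance rank-correlates with RF
(Spearman ρ ≈ 0.6–0.7 over tree pairs spanning the RF range). Partial
trees are projected from their own bipartitions of their taxon subset,
encoded by taxon names so a given split hashes identically wherever it
appears.

A note on testing the fidelity claim: two *independent* uniform random
20-taxon trees almost always realize the maximal RF distance (about 85%
of pairs), so rank correlation over independent pairs is degenerate. The
fidelity test therefore generates pairs by random TBR walks (0–11 moves),
which span RF from 0 to its maximum.

### Image bounds

Resolving an unresolved tree only adds branches, each contributing a
vector of norm at most √d. An unresolved tree over the full taxon set
missing m branches therefore contains all its resolutions within m·√d of
its own projection. For a partial tree on n−m of n taxa the center is
taken at the canonical unresolved resolution (all missing taxa attached to
the internal vertex adjacent to the smallest leaf); any unresolved
resolution has the same n−m−3 extended internal splits in count, so two of
them differ by at most 2(n−m−3)·√d, and every full resolution lies within
m·√d + 2(n−m−3)·√d of the canonical center. These bounds are upper bounds
only (tightness is not claimed) and are verified by Monte-Carlo sampling
of resolutions with zero tolerance for violations.

## Partial Tree Mixing

**Phase 1 — partitioning.** Hamming distance (over sites where both taxa
are unambiguous) to one randomly chosen reference taxon orders the taxa;
the order is sliced into ⌈n/group_size⌉ consecutive groups whose sizes
differ by at most one, so similar taxa are co-grouped at O(n log n) cost.
group_size defaults to max_size so round-one joins respect the size cap.
Each group gets a stepwise tree refined to a TBR local minimum.

**Phase 2 — mixing** (default 3 iterations). Each round: pair → join →
refine → divide.

- *Pairing* is greedy in random order. The predicted location of a
  prospective combined tree is the vector sum of the two partials'
  projections — the projection is additive over splits and all of both
  partials' splits are candidates to survive the join; the true combined
  location cannot be known before joining. Each partial prefers the
  admissible partner maximizing the distance between that prediction and
  the location of the combined tree it was last divided from (first-round
  partials, which have no such memory, maximize distance from the current
  population centroid). Siblings of the immediately preceding division are
  inadmissible, as are pairs whose combined size exceeds max_size; an odd
  partial sits the round out. Only the preceding round's sibling/location
  memory is kept.
- *Joining* evaluates every edge pair, exactly the reconnection half of
  TBR, keeps the most parsimonious combination (ties: first in canonical
  order), then refines with strict-improvement TBR — the result is never
  worse than the best raw reconnection.
- *Division* removes the branch with the greatest mutation count (the
  bisection half of TBR), letting taxa that sit at the end of a long
  branch migrate to partials where they fit better. Trees at or below
  min_size do not divide; children below three taxa are legal degenerate
  partials that only join. Both children remember the parent's location
  and each other's identity.

After every round the population's taxon subsets are verified to be
pairwise disjoint and to cover the full taxon set.

**Phase 3 — final build.** Pairing continues with the same preference but
the size cap lifted and no division, until a single resolved tree over all
taxa remains (exactly k−1 joins for k partials). One deadlock exists that
the mixing rules alone cannot resolve: the last two partials can be
siblings of one another, which the sibling rule would block forever; the
rule is relaxed only when no non-sibling pairing is possible. The
assembled tree is then handed to an ordinary TBR hill-climb, exactly as a
stepwise tree would be.

Defaults: min_size 40, max_size 60 (deliberately conservative sizes),
3 mixing iterations. With one initial group and zero mixing iterations the
pipeline reduces exactly to stepwise addition + TBR, a tested regression
equivalence. Runs are fully determined by (rng_seed, projection_seed).

## Synthetic data

Topologies are uniform over resolved unrooted trees (sequential random
edge attachment); branch lengths are exponential with configurable mean
(default 0.05 expected substitutions per site); sequences evolve under
Jukes–Cantor from a uniform root, with the per-site probability of
differing across a branch of length b equal to (3/4)(1 − e^(−4b/3)) — the
closed form used to calibrate the simulator to within 3 standard errors at
10,000 sites. Defaults (60 taxa, 1000 sites) give strong but not noiseless
signal. Jukes–Cantor suffices because parsimony scoring is model-free and
the simulator's only job is tunable signal; there are no indels, no rate
heterogeneity, and no model misspecification, so passing tests say nothing
about robustness to those features of real data.

What the generator does *not* emulate matters for one result: with
exponential branch lengths a tree routinely contains internal branches of
a few thousandths of a substitution per site, i.e. a couple of expected
changes over 1000 sites. On such datasets the maximum-parsimony optimum is
frequently *not* the generating topology (a search run to its local
minimum typically scores 1–10 changes below the true tree). Exact
topology recovery at n = 60 under these conditions is therefore an
identifiability limit of the data, not a property any parsimony search can
deliver; the test suite keeps the recovery check at the stated conditions
and it fails honestly there.

## Desk-scale comparison

The comparison of PTM against stepwise+TBR mirrors the design of running
both starters to a TBR local minimum with identical (unlimited) evaluation
budgets, on ten simulated datasets of 100 taxa × 1000 sites. At this scale
the parsimony landscape is easy: in nearly every dataset both methods
converge to exactly the same score, and residual differences are single
mutation events in either direction. The exploratory advantage PTM is
designed for — escaping the local minima that trap searches started from
greedy trees — is a large-n phenomenon that 100-taxon high-signal data do
not exhibit; desk-scale results should be read as "no worse", not as a
reproduction of large-scale speedups.

## Numerical and degenerate-case conventions

- All tie-breaks (insertion edge, reconnection pair, division branch) take
  the first candidate in canonical edge order; all randomness flows from
  named seeds kept below 2^31.
- Pattern weights are int64; scores are exact integers throughout — no
  floating-point comparisons enter any accept/reject decision.
- Degenerate partials (1–2 taxa) score by direct comparison of their one
  or two rows and project to the zero vector.
- Joining two single-leaf partials produces the two-leaf tree; joining
  anything to a single leaf attaches at that leaf's vertex.
- `image_radius` of a fully resolved tree over all taxa is 0; of a partial
  tree with fewer than four leaves it reduces to m·√d (no internal splits).

## Known limitations

- Parsimony only; no likelihood criterion, weighted steps, or character
  weights. DNA alphabet only.
- The multifurcating scoring rule is a deterministic heuristic, not the
  exact minimum (see above).
- The TBR neighborhood is enumerated afresh per iteration; no
  neighborhood caching or incremental rescoring across accepted moves.
- Image-radius bounds are loose for partial trees missing many taxa.
- No Parsimony Ratchet or sectorial-search refinement; PTM hands its tree
  to plain TBR.
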