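"""Partial Tree Mixing: globally guided construction of starting trees.

PTM is a divide-and-conquer initializer for maximum-parsimony search.
The taxa are split into nearly even groups of similar sequences; a
stepwise-addition tree refined by TBR is built for each group; then the
population of partial trees *mixes*: pairs join (exactly the reconnection
half of TBR, over every edge pair), the joined tree is refined by
strict-improvement TBR, and trees above the minimum size divide on their
longest branch (the branch with the greatest parsimony mutation count —
the bisection half of TBR).  Join partners are chosen to push the
predicted combined tree as far as possible from the tree it was last
divided from, measured in the hashed cartographic projection of
partition-based tree space, so the population's images spread over the
hypersphere of trees instead of re-searching one region.  After a fixed
number of mixing rounds no further division occurs and the partials join
up into one resolved tree over all taxa, which is handed to an ordinary
TBR search.

Throughout, the taxon subsets of the population are pairwise disjoint and
cover the full taxon set; no joined tree ever exceeds the maximum size
during mixing; trees at or below the minimum size never divide; and
siblings from the immediately preceding division never rejoin.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .treeio import CharacterMatrix, Tree, TreeError
from .parsimony import branch_mutation_counts, edge_tables, encode_matrix, fitch_score
from .classic_search import (
    SearchConfig,
    bisect_tree,
    reconnect,
    stepwise_addition,
    tbr_hillclimb,
)
from .tree_space import CartographicProjection, project

__all__ = [
    "PartialTree",
    "PTMParams",
    "partition_taxa",
    "build_initial_partials",
    "join_partials",
    "divide_partial",
    "pair_partials",
    "mix",
    "finalize",
    "ptm_search",
]


@dataclass
class PartialTree:
    """A resolved tree over a taxon subset plus mixing bookkeeping.

    ``previous_location`` is the projected point of the combined tree this
    partial was divided from; ``sibling_id`` identifies the co-product of
    that division.  Both are absent for initial partials.  Partials with
    fewer than three taxa are degenerate: they only join, never divide.
    """

    tree: Tree
    score: int
    location: np.ndarray
    id: int
    previous_location: Optional[np.ndarray] = None
    sibling_id: Optional[int] = None

    @property
    def size(self) -> int:
        return self.tree.n_leaves

    def taxa(self) -> frozenset[str]:
        return self.tree.taxa()


@dataclass
class PTMParams:
    """Tunable sizes and seeds of a PTM run.

    min_size is a soft lower limit (trees at or below it do not divide);
    max_size a hard upper limit on joins during mixing.  Defaults 40/60
    are deliberately conservative.  Three mixing iterations work well
    across datasets.  initial_group_size defaults to max_size so that
    round-one products respect the join cap.
    """

    min_size: int = 40
    max_size: int = 60
    mix_iterations: int = 3
    initial_group_size: Optional[int] = None
    d: int = 10
    projection_seed: int = 0
    rng_seed: int = 0
    final_tbr: bool = True

    def __post_init__(self) -> None:
        if not (3 < self.min_size <= self.max_size):
            raise ValueError("need 3 < min_size <= max_size")
        if self.mix_iterations < 0:
            raise ValueError("mix_iterations must be >= 0")

    @property
    def group_size(self) -> int:
        return self.initial_group_size or self.max_size

    def projection(self) -> CartographicProjection:
        return CartographicProjection(d=self.d, seed=self.projection_seed)


# ---------------------------------------------------------------------------
# Phase 1: partitioning and initial partial trees
# ---------------------------------------------------------------------------


def partition_taxa(matrix: CharacterMatrix, group_size: int,
                   rng: np.random.Generator) -> list[list[str]]:
    """Split taxa into nearly even groups of similar sequences.

    One reference taxon is drawn at random; every taxon's Hamming distance
    to it (over sites where both states are unambiguous) orders a priority
    queue, which is sliced consecutively into ceil(n / group_size) groups
    whose sizes differ by at most one.  Similar taxa therefore land in the
    same group at O(n log n) cost.
    """
    if group_size < 4:
        raise ValueError("group_size must be >= 4")
    names = list(matrix.taxon_names)
    n = len(names)
    n_groups = max(1, math.ceil(n / group_size))
    while n_groups > 1 and n // n_groups < 4:
        n_groups -= 1
    if n_groups == 1:
        return [sorted(names)]

    enc = encode_matrix(matrix)
    ref = names[int(rng.integers(n))]
    ref_row = enc.rows[ref]
    ref_known = ref_row != 15
    dists = []
    for name in names:
        row = enc.rows[name]
        both = ref_known & (row != 15)
        diff = both & (row != ref_row)
        dists.append(int(enc.weights[diff].sum()))
    ranked = [name for _, name in sorted(zip(dists, names))]

    base, extra = divmod(n, n_groups)
    groups, start = [], 0
    for i in range(n_groups):
        size = base + (1 if i < extra else 0)
        groups.append(ranked[start:start + size])
        start += size
    return groups


def _make_partial(tree: Tree, matrix: CharacterMatrix,
                  proj: CartographicProjection, pid: int,
                  previous_location: Optional[np.ndarray] = None,
                  sibling_id: Optional[int] = None) -> PartialTree:
    return PartialTree(
        tree=tree,
        score=fitch_score(tree, matrix),
        location=project(tree, proj),
        id=pid,
        previous_location=previous_location,
        sibling_id=sibling_id,
    )


def build_initial_partials(matrix: CharacterMatrix, groups: list[list[str]],
                           config: SearchConfig,
                           proj: Optional[CartographicProjection] = None,
                           rng: Optional[np.random.Generator] = None) -> list[PartialTree]:
    """One TBR-refined stepwise tree per taxon group."""
    if proj is None:
        proj = CartographicProjection()
    if rng is None:
        rng = config.rng()
    seen: set[str] = set()
    for g in groups:
        overlap = seen & set(g)
        if overlap:
            raise TreeError(f"taxon in multiple groups: {sorted(overlap)}")
        seen |= set(g)
    partials = []
    for pid, group in enumerate(groups):
        if len(group) < 3:
            tree = Tree()
            nodes = [tree.add_leaf(t) for t in sorted(group)]
            if len(nodes) == 2:
                tree.add_edge(nodes[0], nodes[1])
        else:
            tree = stepwise_addition(matrix, config, taxa_subset=set(group), rng=rng)
            tree = tbr_hillclimb(tree, matrix, config)
        partials.append(_make_partial(tree, matrix, proj, pid))
    return partials


# ---------------------------------------------------------------------------
# Join and divide
# ---------------------------------------------------------------------------


def _best_reconnection(a: Tree, b: Tree, matrix: CharacterMatrix,
                       config: SearchConfig) -> Tree:
    """Most parsimonious reconnection of two leaf-disjoint trees.

    Every edge pair is evaluated, exactly as in the reconnection half of
    TBR; ties break to the first pair in canonical enumeration order.
    """
    if a.taxa() & b.taxa():
        raise TreeError(f"overlapping taxa: {sorted(a.taxa() & b.taxa())}")
    enc = encode_matrix(matrix)
    ta = edge_tables(a, matrix)
    tb = edge_tables(b, matrix)
    if config.eval_budget is not None:
        config.eval_budget.charge(len(ta.attach_points) * len(tb.attach_points))
    empty = (ta.mid[:, None, :] & tb.mid[None, :, :]) == 0
    scores = empty @ enc.weights
    flat = int(np.argmin(scores))
    i, j = divmod(flat, scores.shape[1])
    return reconnect(a, ta.attach_points[i], b, tb.attach_points[j])


def join_partials(a: PartialTree, b: PartialTree, matrix: CharacterMatrix,
                  config: SearchConfig,
                  proj: Optional[CartographicProjection] = None,
                  new_id: Optional[int] = None) -> PartialTree:
    """Join two disjoint partials at the best edge pair, then refine by TBR.

    The returned score never exceeds the best raw reconnection score
    (refinement accepts strict improvements only).
    """
    if proj is None:
        proj = CartographicProjection()
    joined = _best_reconnection(a.tree, b.tree, matrix, config)
    if joined.n_leaves >= 4:
        joined = tbr_hillclimb(joined, matrix, config)
    pid = new_id if new_id is not None else max(a.id, b.id) + 1
    return _make_partial(joined, matrix, proj, pid)


def divide_partial(t: PartialTree, matrix: CharacterMatrix,
                   proj: CartographicProjection,
                   id_start: int) -> tuple[PartialTree, PartialTree]:
    """Divide a partial tree on its longest branch.

    Longest = greatest mutation count under the canonical parsimony
    reconstruction (ties: first edge in canonical order), mirroring the
    bisection half of TBR.  Both children remember the parent's projected
    location and each other's identity; children with fewer than three
    taxa are legal, degenerate (join-only) partials.
    """
    counts = branch_mutation_counts(t.tree, matrix)
    edges = t.tree.edges()
    best_edge = max(edges, key=lambda e: (counts[e], ))  # ties: first in order
    best_count = counts[best_edge]
    for e in edges:  # deterministic first-max
        if counts[e] == best_count:
            best_edge = e
            break
    t1, _, t2, _ = bisect_tree(t.tree, best_edge)
    id_a, id_b = id_start, id_start + 1
    pa = _make_partial(t1, matrix, proj, id_a,
                       previous_location=t.location, sibling_id=id_b)
    pb = _make_partial(t2, matrix, proj, id_b,
                       previous_location=t.location, sibling_id=id_a)
    return pa, pb


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------


def pair_partials(partials: list[PartialTree], params: PTMParams,
                  rng: np.random.Generator,
                  enforce_max: bool = True,
                  allow_sibling_fallback: bool = False,
                  ) -> tuple[list[tuple[int, int]], list[int]]:
    """Greedy distance-maximizing matching of join partners.

    Partials are processed in random order.  Each unmatched partial picks
    the unmatched, non-sibling partner that maximizes the distance between
    the predicted combined location (the vector sum of the two projected
    points — the projection is additive over bipartitions) and its
    previous combined-tree location; partials with no previous location
    maximize distance to the population centroid instead.  Pairs whose
    combined size would exceed max_size are skipped while ``enforce_max``
    holds.  With ``allow_sibling_fallback`` (the final build phase),
    sibling pairs become admissible when nothing else is.

    Returns index pairs into ``partials`` plus the unpaired indices.
    """
    k = len(partials)
    if k < 2:
        return [], list(range(k))
    centroid = np.mean([p.location for p in partials], axis=0)
    order = list(rng.permutation(k))
    unmatched = set(range(k))
    pairs: list[tuple[int, int]] = []

    def admissible(i: int, j: int, allow_sib: bool) -> bool:
        pi, pj = partials[i], partials[j]
        if not allow_sib and pi.sibling_id is not None and pi.sibling_id == pj.id:
            return False
        if enforce_max and pi.size + pj.size > params.max_size:
            return False
        return True

    def choose(i: int, allow_sib: bool) -> Optional[int]:
        pi = partials[i]
        ref = pi.previous_location if pi.previous_location is not None else centroid
        best_j, best_dist = None, -1.0
        for j in sorted(unmatched):
            if j == i or not admissible(i, j, allow_sib):
                continue
            predicted = pi.location + partials[j].location
            dist = float(np.linalg.norm(predicted - ref))
            if dist > best_dist:
                best_j, best_dist = j, dist
        return best_j

    for i in order:
        if i not in unmatched:
            continue
        j = choose(i, allow_sib=False)
        if j is None and allow_sibling_fallback:
            j = choose(i, allow_sib=True)
        if j is not None:
            unmatched.discard(i)
            unmatched.discard(j)
            pairs.append((i, j))
    return pairs, sorted(unmatched)


# ---------------------------------------------------------------------------
# Mixing and final build
# ---------------------------------------------------------------------------


def _check_cover(partials: list[PartialTree], full_taxa: frozenset[str]) -> None:
    seen: set[str] = set()
    for p in partials:
        overlap = seen & p.taxa()
        if overlap:
            raise TreeError(f"taxon represented twice: {sorted(overlap)}")
        seen |= p.taxa()
    if seen != full_taxa:
        raise TreeError(f"taxa lost from population: {sorted(full_taxa - seen)}")


def mix(partials: list[PartialTree], matrix: CharacterMatrix,
        params: PTMParams, config: SearchConfig,
        proj: Optional[CartographicProjection] = None,
        rng: Optional[np.random.Generator] = None,
        trace: Optional[list] = None) -> list[PartialTree]:
    """Run ``params.mix_iterations`` rounds of pair → join+refine → divide.

    Only trees strictly above min_size divide; only the immediately
    preceding round's sibling/location memory is kept.  The disjoint-cover
    invariant is asserted after every round.
    """
    if proj is None:
        proj = params.projection()
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    full_taxa = frozenset().union(*(p.taxa() for p in partials)) if partials else frozenset()
    population = list(partials)
    next_id = max((p.id for p in population), default=0) + 1

    for round_no in range(params.mix_iterations):
        pairs, leftover = pair_partials(population, params, rng, enforce_max=True)
        new_pop: list[PartialTree] = []
        for i, j in pairs:
            joined = join_partials(population[i], population[j], matrix,
                                   config, proj, new_id=next_id)
            next_id += 1
            new_pop.append(joined)
        new_pop.extend(population[i] for i in leftover)

        divided: list[PartialTree] = []
        for p in new_pop:
            if p.size > params.min_size:
                pa, pb = divide_partial(p, matrix, proj, next_id)
                next_id += 2
                divided.extend((pa, pb))
            else:
                divided.append(p)
        population = divided
        _check_cover(population, full_taxa)
        if trace is not None:
            trace.append({
                "phase": "mix", "round": round_no + 1,
                "n_partials": len(population),
                "sizes": sorted(p.size for p in population),
                "total_score": sum(p.score for p in population),
            })
    return population


def finalize(partials: list[PartialTree], matrix: CharacterMatrix,
             params: PTMParams, config: SearchConfig,
             proj: Optional[CartographicProjection] = None,
             rng: Optional[np.random.Generator] = None,
             trace: Optional[list] = None) -> Tree:
    """Join partials (no more division) until one resolved tree remains.

    Partner preference works as during mixing but the size cap is lifted;
    the sibling rule is relaxed only when it would block all remaining
    joins.  Exactly len(partials) - 1 joins are performed.
    """
    if proj is None:
        proj = params.projection()
    if rng is None:
        rng = np.random.default_rng(params.rng_seed + 1)
    population = list(partials)
    next_id = max((p.id for p in population), default=0) + 1
    round_no = 0
    while len(population) > 1:
        pairs, leftover = pair_partials(population, params, rng,
                                        enforce_max=False,
                                        allow_sibling_fallback=True)
        if not pairs:
            raise TreeError("final build could not pair any partials")
        new_pop = []
        for i, j in pairs:
            joined = join_partials(population[i], population[j], matrix,
                                   config, proj, new_id=next_id)
            next_id += 1
            new_pop.append(joined)
        new_pop.extend(population[i] for i in leftover)
        population = new_pop
        round_no += 1
        if trace is not None:
            trace.append({
                "phase": "final", "round": round_no,
                "n_partials": len(population),
                "sizes": sorted(p.size for p in population),
                "total_score": sum(p.score for p in population),
            })
    return population[0].tree


def ptm_search(matrix: CharacterMatrix, params: PTMParams,
               config: SearchConfig,
               trace: Optional[list] = None) -> Tree:
    """Full PTM pipeline: partition → initial partials → mix → build → TBR.

    Fully reproducible under fixed (rng_seed, projection_seed).  With
    ``params.final_tbr`` the assembled tree is handed to an ordinary TBR
    hill-climb, as a stepwise tree would be.
    """
    if matrix.n_taxa < 4:
        raise TreeError("PTM needs at least 4 taxa")
    proj = params.projection()
    rng = np.random.default_rng(params.rng_seed)
    groups = partition_taxa(matrix, params.group_size, rng)
    partials = build_initial_partials(matrix, groups, config, proj, rng)
    if trace is not None:
        trace.append({
            "phase": "init", "round": 0,
            "n_partials": len(partials),
            "sizes": sorted(p.size for p in partials),
            "total_score": sum(p.score for p in partials),
        })
    partials = mix(partials, matrix, params, config, proj, rng, trace)
    tree = finalize(partials, matrix, params, config, proj, rng, trace)
    if params.final_tbr:
        tree = tbr_hillclimb(tree, matrix, config)
    if trace is not None:
        trace.append({
            "phase": "done", "round": 0, "n_partials": 1,
            "sizes": [tree.n_leaves],
            "total_score": fitch_score(tree, matrix),
        })
    return tree
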