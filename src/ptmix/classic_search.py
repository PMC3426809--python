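"""Stepwise-addition starting trees and TBR hill-climbing.

TBR (tree bisection and reconnection) removes one branch, splitting the
tree into two subtrees, then reconnects the halves by joining a branch of
one to a branch of the other; one full iteration considers every bisection
and every reconnection.  The hill-climb accepts strict improvements only,
so scores along a trajectory are strictly decreasing and the search
terminates at a TBR local minimum (or when the round/evaluation budget is
exhausted).

Reconnections are scored in bulk: for a bisection into halves with edge
midpoint state-set tables ``M1`` and ``M2`` (see
:mod:`ptmix.parsimony`), the joined tree's Fitch score at edge pair
``(i, j)`` is ``S1 + S2 + sum_sites w * [M1[i] & M2[j] == 0]``, an exact
identity that turns a neighborhood scan into one broadcast operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .treeio import CharacterMatrix, Tree, TreeError
from .parsimony import edge_tables, encode_matrix, fitch_score, insertion_score_deltas

__all__ = [
    "Budget",
    "SearchConfig",
    "stepwise_addition",
    "tbr_neighbors",
    "tbr_hillclimb",
    "bisect_tree",
    "reconnect",
]


class Budget:
    """Shared counter of candidate-tree evaluations across search calls.

    Used to compare search strategies under a matched amount of scoring
    work: every scored reconnection or insertion candidate charges one
    unit.  ``limit=None`` means unlimited.
    """

    def __init__(self, limit: Optional[int] = None):
        self.limit = limit
        self.used = 0

    def charge(self, n: int) -> None:
        self.used += n

    @property
    def exhausted(self) -> bool:
        return self.limit is not None and self.used >= self.limit

    def __repr__(self) -> str:
        return f"Budget(used={self.used}, limit={self.limit})"


@dataclass
class SearchConfig:
    """Reproducible search settings.

    policy: "best" scans the full neighborhood and takes the best strict
    improvement (first encountered on ties, in canonical edge order);
    "first" accepts the first strict improvement found.
    """

    rng_seed: int = 0
    policy: str = "best"
    max_tbr_rounds: Optional[int] = None
    eval_budget: Optional[Budget] = None

    def __post_init__(self) -> None:
        if self.policy not in ("best", "first"):
            raise ValueError(f"unknown policy {self.policy!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


# ---------------------------------------------------------------------------
# Stepwise addition
# ---------------------------------------------------------------------------


def _three_taxon_tree(names: list[str]) -> Tree:
    tree = Tree()
    hub = tree.add_node()
    for n in names:
        tree.add_edge(hub, tree.add_leaf(n))
    return tree


def insert_leaf(tree: Tree, edge: tuple[int, int], name: str) -> int:
    """Attach a new leaf on ``edge`` by subdividing it; returns the leaf id."""
    w = tree.split_edge(*edge)
    leaf = tree.add_leaf(name)
    tree.add_edge(w, leaf)
    return leaf


def stepwise_addition(matrix: CharacterMatrix, config: SearchConfig,
                      taxa_subset: Optional[set[str]] = None,
                      rng: Optional[np.random.Generator] = None) -> Tree:
    """Greedy stepwise maximum parsimony over ``taxa_subset`` (default: all).

    Taxa are shuffled into a random order; the first three form the unique
    three-taxon tree; each remaining taxon is inserted on the edge that
    minimizes the resulting Fitch score (ties: first edge in canonical
    enumeration order).
    """
    names = sorted(taxa_subset) if taxa_subset is not None else list(matrix.taxon_names)
    missing = set(names) - set(matrix.taxon_names)
    if missing:
        raise TreeError(f"taxa not in matrix: {sorted(missing)}")
    if len(names) < 3:
        raise TreeError("stepwise addition needs at least 3 taxa")
    if rng is None:
        rng = config.rng()
    order = [names[i] for i in rng.permutation(len(names))]

    tree = _three_taxon_tree(order[:3])
    enc = encode_matrix(matrix)
    budget = config.eval_budget
    for name in order[3:]:
        tables = edge_tables(tree, matrix)
        deltas = insertion_score_deltas(tables, enc.rows[name], enc.weights)
        if budget is not None:
            budget.charge(len(tables.edges))
        best = int(np.argmin(deltas))  # first index on ties; edges are canonical
        insert_leaf(tree, tables.edges[best], name)
    return tree


# ---------------------------------------------------------------------------
# Bisection / reconnection
# ---------------------------------------------------------------------------


def bisect_tree(tree: Tree, cut: tuple[int, int]) -> tuple[Tree, Optional[tuple[int, int]], Tree, Optional[tuple[int, int]]]:
    """Remove edge ``cut``; return the two smoothed halves.

    Returns ``(T1, origin1, T2, origin2)`` where ``origin_i`` is the edge of
    half ``i`` produced by merging the cut endpoint's remaining edges (the
    reconnection at ``(origin1, origin2)`` recreates the input tree), or
    None when the half is a single node.
    """
    u, v = cut
    work = tree.copy()
    work.remove_edge(u, v)

    def extract(start: int) -> tuple[Tree, Optional[tuple[int, int]]]:
        seen = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in work.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        half = Tree.__new__(Tree)
        half.adj = {x: set(work.adj[x]) for x in seen}
        half.leaf_name = {x: work.leaf_name[x] for x in seen if x in work.leaf_name}
        half._name2node = {n: x for x, n in half.leaf_name.items()}
        half.lengths = {k: L for k, L in work.lengths.items() if k[0] in seen}
        half._next_id = tree._next_id
        origin = None
        if start in half.adj and len(half.adj[start]) == 2 and start not in half.leaf_name:
            a, b = sorted(half.adj[start])
            half.smooth_node(start)
            origin = Tree._ekey(a, b)
        return half, origin

    t1, o1 = extract(u)
    t2, o2 = extract(v)
    return t1, o1, t2, o2


def _offset_copy(tree: Tree, offset: int) -> Tree:
    t = Tree.__new__(Tree)
    t.adj = {u + offset: {v + offset for v in s} for u, s in tree.adj.items()}
    t.leaf_name = {u + offset: n for u, n in tree.leaf_name.items()}
    t._name2node = {n: u for u, n in t.leaf_name.items()}
    t.lengths = {(k[0] + offset, k[1] + offset): L for k, L in tree.lengths.items()}
    t._next_id = tree._next_id + offset
    return t


def reconnect(t1: Tree, attach1, t2: Tree, attach2) -> Tree:
    """Join two leaf-disjoint trees at the given attachment points.

    An attachment point is an edge (subdivided to create the junction) or,
    for a single-node tree, that node itself.
    """
    if t1.taxa() & t2.taxa():
        raise TreeError(f"overlapping taxa: {sorted(t1.taxa() & t2.taxa())}")
    offset = t1._next_id
    joined = t1.copy()
    other = _offset_copy(t2, offset)
    joined.adj.update(other.adj)
    joined.leaf_name.update(other.leaf_name)
    joined._name2node.update(other._name2node)
    joined.lengths.update(other.lengths)
    joined._next_id = other._next_id

    def junction(attach, off: int) -> int:
        if isinstance(attach, tuple):
            return joined.split_edge(attach[0] + off, attach[1] + off)
        return attach + off  # single node

    a = junction(attach1, 0)
    b = junction(attach2, offset)
    joined.add_edge(a, b)
    return joined


def _attachments(half: Tree) -> list:
    """Reconnection attachment points of a bisection half (canonical order)."""
    if half.n_leaves == 1 and half.n_edges() == 0:
        return [next(iter(half.adj))]
    return half.edges()


def tbr_neighbors(tree: Tree) -> Iterator[Tree]:
    """Yield every TBR neighbor (one bisection + one reconnection).

    The reconnection recreating the input is excluded; other duplicate
    topologies may be emitted (deduplication is the caller's choice).
    """
    if not tree.is_resolved():
        raise TreeError("TBR requires a resolved tree")
    if tree.n_leaves < 4:
        raise TreeError("TBR requires at least 4 leaves")
    for cut in tree.edges():
        t1, o1, t2, o2 = bisect_tree(tree, cut)
        a1s = _attachments(t1)
        a2s = _attachments(t2)
        identity1 = o1 if o1 is not None else a1s[0]
        identity2 = o2 if o2 is not None else a2s[0]
        for a1 in a1s:
            for a2 in a2s:
                if a1 == identity1 and a2 == identity2:
                    continue
                yield reconnect(t1, a1, t2, a2)


def random_tbr_move(tree: Tree, rng: np.random.Generator) -> Tree:
    """One uniformly drawn bisection + reconnection (may recreate the input).

    Useful for random walks through tree space, e.g. to generate tree pairs
    spanning the whole range of RF distances.
    """
    edges = tree.edges()
    cut = edges[int(rng.integers(len(edges)))]
    t1, _, t2, _ = bisect_tree(tree, cut)
    a1s, a2s = _attachments(t1), _attachments(t2)
    a1 = a1s[int(rng.integers(len(a1s)))]
    a2 = a2s[int(rng.integers(len(a2s)))]
    return reconnect(t1, a1, t2, a2)


def _scan_bisections(tree: Tree, matrix: CharacterMatrix, current_score: int,
                     config: SearchConfig):
    """Best strict improvement over the full TBR neighborhood.

    Returns (score, cut, a1, a2) or None.  With policy "first", returns as
    soon as any strict improvement is seen (still the best within that
    bisection's bulk scan).
    """
    enc = encode_matrix(matrix)
    W = enc.weights
    budget = config.eval_budget
    best: Optional[tuple[int, tuple[int, int], object, object]] = None
    for cut in tree.edges():
        if budget is not None and budget.exhausted:
            break
        t1, o1, t2, o2 = bisect_tree(tree, cut)
        tab1 = edge_tables(t1, matrix)
        tab2 = edge_tables(t2, matrix)
        if budget is not None:
            budget.charge(len(tab1.attach_points) * len(tab2.attach_points))
        # (E1, E2) matrix of join extras
        empty = (tab1.mid[:, None, :] & tab2.mid[None, :, :]) == 0
        extra = empty @ W
        scores = tab1.score + tab2.score + extra
        i1 = tab1.attach_points.index(o1) if o1 is not None else 0
        i2 = tab2.attach_points.index(o2) if o2 is not None else 0
        scores[i1, i2] = np.iinfo(np.int64).max  # exclude identity reconnection
        flat = int(np.argmin(scores))
        smin = int(scores.flat[flat])
        if smin < current_score and (best is None or smin < best[0]):
            i, j = divmod(flat, scores.shape[1])
            best = (smin, cut, tab1.attach_points[i], tab2.attach_points[j])
            if config.policy == "first":
                return best
    return best


def tbr_hillclimb(tree: Tree, matrix: CharacterMatrix, config: SearchConfig) -> Tree:
    """Strict-improvement TBR hill-climb.

    Returns a tree whose full TBR neighborhood contains no strictly better
    tree, or the best tree found when ``max_tbr_rounds`` or the evaluation
    budget is hit.  The returned score never exceeds the input score.
    """
    if not tree.is_resolved():
        raise TreeError("TBR requires a resolved tree")
    if tree.n_leaves < 4:
        return tree.copy()
    current = tree.copy()
    score = fitch_score(current, matrix)
    rounds = 0
    while config.max_tbr_rounds is None or rounds < config.max_tbr_rounds:
        if config.eval_budget is not None and config.eval_budget.exhausted:
            break
        found = _scan_bisections(current, matrix, score, config)
        if found is None:
            break
        score, cut, a1, a2 = found
        t1, _, t2, _ = bisect_tree(current, cut)
        current = reconnect(t1, a1, t2, a2)
        rounds += 1
    return current
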