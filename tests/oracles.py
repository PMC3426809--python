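"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against first principles (explicit
enumeration over assignments and topologies) and never calls the fast code
paths it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np

from ptmix.treeio import CharacterMatrix, Tree, bipartitions

_CODE = {"A": 1, "C": 2, "G": 4, "T": 8, "-": 15, "?": 15}
_STATES = (1, 2, 4, 8)


def exhaustive_fitch(tree: Tree, matrix: CharacterMatrix) -> int:
    """Minimum changes over all internal-state assignments, per site.

    Leaves with ambiguous states contribute 0 to an incident edge whenever
    the neighbor's assigned state lies in the leaf's state set (the leaf is
    then free to match), else 1 — exact minimization over leaf choices.
    """
    internal = [v for v in tree.nodes() if v not in tree.leaf_name]
    leaf_edges = []
    internal_edges = []
    for u, v in tree.edges():
        if u in tree.leaf_name or v in tree.leaf_name:
            leaf, other = (u, v) if u in tree.leaf_name else (v, u)
            leaf_edges.append((leaf, other))
        else:
            internal_edges.append((u, v))

    if not internal:  # 1- or 2-leaf tree
        total = 0
        leaves = tree.leaves()
        if len(leaves) == 2:
            s1 = matrix.sequence(tree.leaf_name[leaves[0]])
            s2 = matrix.sequence(tree.leaf_name[leaves[1]])
            for a, b in zip(s1, s2):
                total += int(_CODE[a] & _CODE[b] == 0)
        return total

    idx = {v: i for i, v in enumerate(internal)}
    # all assignments: (4^k, k) state masks
    assigns = np.array(list(itertools.product(_STATES, repeat=len(internal))),
                       dtype=np.uint8)
    total = 0
    for site in range(matrix.n_sites):
        cost = np.zeros(len(assigns), dtype=np.int64)
        for u, v in internal_edges:
            cost += assigns[:, idx[u]] != assigns[:, idx[v]]
        for leaf, other in leaf_edges:
            mask = _CODE[matrix.sequence(tree.leaf_name[leaf])[site]]
            cost += (assigns[:, idx[other]] & mask) == 0
        total += int(cost.min())
    return total


def mp_reconstruction_count_vectors(tree: Tree, matrix: CharacterMatrix):
    """All per-edge change-count vectors achievable by an MP reconstruction.

    Exponential; intended for single-site matrices on tiny trees.  Leaf
    states are enumerated within their ambiguity sets.
    """
    nodes = tree.nodes()
    leaves = [v for v in nodes if v in tree.leaf_name]
    internal = [v for v in nodes if v not in tree.leaf_name]
    edges = tree.edges()
    assert matrix.n_sites == 1
    leaf_opts = {
        v: [s for s in _STATES if s & _CODE[matrix.sequence(tree.leaf_name[v])[0]]]
        for v in leaves
    }
    best = None
    vectors = set()
    for leaf_assign in itertools.product(*(leaf_opts[v] for v in leaves)):
        state = dict(zip(leaves, leaf_assign))
        for int_assign in itertools.product(_STATES, repeat=len(internal)):
            state.update(zip(internal, int_assign))
            vec = tuple(int(state[u] != state[v]) for u, v in edges)
            cost = sum(vec)
            if best is None or cost < best:
                best = cost
                vectors = {vec}
            elif cost == best:
                vectors.add(vec)
    return best, edges, vectors


def all_topologies(names: list[str]) -> list[Tree]:
    """Every resolved unrooted topology on the given taxa (by edge insertion)."""
    names = sorted(names)
    if len(names) < 3:
        raise ValueError("need >= 3 taxa")
    base = Tree()
    hub = base.add_node()
    for n in names[:3]:
        base.add_edge(hub, base.add_leaf(n))
    trees = [base]
    for name in names[3:]:
        nxt = []
        for t in trees:
            for e in t.edges():
                c = t.copy()
                w = c.split_edge(*e)
                c.add_edge(w, c.add_leaf(name))
                nxt.append(c)
        trees = nxt
    return trees


def restricted_split_set(tree: Tree, subset: frozenset[str]) -> frozenset:
    """Nontrivial splits of the topology induced on a taxon subset."""
    out = set()
    for b in bipartitions(tree):
        a = b.side1 & subset
        c = b.side2 & subset
        if len(a) >= 2 and len(c) >= 2:
            out.add(frozenset([a, c]))
    return frozenset(out)


def tbr_neighbor_oracle(tree: Tree, topologies: list[Tree]) -> set:
    """Distinct TBR-neighbor topologies by the two-halves characterization.

    T' is one TBR move from T iff, for some edge split A|B of T (trivial
    edges included), T' contains the split A|B (automatic when one side is
    a singleton) and induces the same topology as T on both A and B.
    """
    taxa = tree.taxa()
    below, parent = tree.leafset_below()
    halves = []
    for v, side in below.items():
        if parent[v] == -1:
            continue
        side = frozenset(side)
        halves.append((side, taxa - side))
    base_key = bipartitions(tree)
    base_restr = {A: restricted_split_set(tree, A) for half in halves for A in half}
    out = set()
    for t2 in topologies:
        k2 = bipartitions(t2)
        if k2 == base_key:
            continue
        splits2 = {frozenset([b.side1, b.side2]) for b in k2}
        for A, B in halves:
            if len(A) >= 2 and len(B) >= 2 and frozenset([A, B]) not in splits2:
                continue
            if (restricted_split_set(t2, A) == base_restr[A]
                    and restricted_split_set(t2, B) == base_restr[B]):
                out.add(k2)
                break
    return out


def random_matrix(n_taxa: int, n_sites: int, rng: np.random.Generator,
                  names=None, ambiguous: bool = False) -> CharacterMatrix:
    """Uniform random matrix; optionally sprinkle '-'/'?' characters."""
    alphabet = "ACGT-?" if ambiguous else "ACGT"
    if names is None:
        names = [f"t{i + 1}" for i in range(n_taxa)]
    seqs = [
        "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n_sites))
        for _ in range(n_taxa)
    ]
    return CharacterMatrix(list(names), seqs)
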