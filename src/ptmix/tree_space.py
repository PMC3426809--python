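"""Partition-based tree space and hash-based cartographic projections.

A tree is identified with the 0/1 indicator vector of its nontrivial
bipartitions, one dimension per possible split.  In that (exponentially
large) space the Euclidean distance between two trees is exactly the
square root of their Robinson-Foulds distance, every resolved n-taxon
tree lies on the hypersphere of radius sqrt(n - 3), and the fully
unresolved tree sits at the origin.

Because the full space has O(n!!) dimensions it is never materialized.
Instead a *cartographic projection* maps each bipartition to a
d-dimensional component vector whose entries are uniform on [-1, 1],
obtained from a stable keyed hash of the bipartition's canonical byte
encoding — the hash function IS the reference-vector store.  A tree
projects to the sum of its bipartitions' component vectors, so the
projection is additive, O(n·d) per tree, and identical for the same split
wherever it appears.

Image bounds: a resolution of an unresolved tree keeps all its
bipartitions and adds the missing ones, each contributing a vector of
norm at most sqrt(d); an unresolved tree missing m branches therefore has
all its resolutions within m*sqrt(d) of its own projection.  For a partial
tree on n - m of n taxa, any two unresolved resolutions share no more
than their n - m - 3 extended internal splits, giving a center separation
of at most 2*(n - m - 3)*sqrt(d); combining the two bounds circumscribes
every full resolution within m*sqrt(d) + 2*(n - m - 3)*sqrt(d) of one
canonical center.
"""

from __future__ import annotations

import hashlib
import struct
from typing import Iterable, Optional

import numpy as np

from .treeio import Bipartition, Tree, TreeError, bipartitions

__all__ = [
    "CartographicProjection",
    "project",
    "exact_distance",
    "image_radius",
    "image_center",
    "sample_resolution",
]


class CartographicProjection:
    """Deterministic hash-defined projection of bipartition space into R^d.

    component(b, k) is uniform on [-1, 1), fully determined by the
    bipartition's canonical encoding, the dimension index k and the seed;
    reference vectors are never stored.
    """

    def __init__(self, d: int = 10, seed: int = 0):
        if d < 1:
            raise ValueError("d must be >= 1")
        self.d = d
        self.seed = int(seed)
        self._key = struct.pack("<q", self.seed)
        self._cache: dict[Bipartition, np.ndarray] = {}

    def component(self, bipartition: Bipartition, dim: int) -> float:
        """Uniform-[-1,1) component of one bipartition in one dimension."""
        h = hashlib.blake2b(
            bipartition.encode() + b"#" + struct.pack("<q", dim),
            key=self._key, digest_size=8,
        ).digest()
        (bits,) = struct.unpack("<Q", h)
        u = (bits >> 11) / float(1 << 53)  # 53 high bits -> [0, 1)
        return 2.0 * u - 1.0

    def vector(self, bipartition: Bipartition) -> np.ndarray:
        """The d-dimensional component vector of one bipartition (cached)."""
        v = self._cache.get(bipartition)
        if v is None:
            v = np.array([self.component(bipartition, k) for k in range(self.d)])
            v.flags.writeable = False
            self._cache[bipartition] = v
        return v


def project(tree: Tree, proj: CartographicProjection) -> np.ndarray:
    """Project a tree to the sum of its bipartitions' component vectors.

    Trees with no nontrivial bipartition (fully unresolved, or fewer than
    four leaves) map to the zero vector.  Partial trees are projected from
    their own bipartitions of their taxon subset; the name-based canonical
    encoding makes the same split hash identically wherever it occurs.
    """
    point = np.zeros(proj.d)
    for b in bipartitions(tree):
        point = point + proj.vector(b)
    return point


def exact_distance(t1: Tree, t2: Tree) -> float:
    """Euclidean distance in the exact 0/1 partition space: sqrt(RF).

    Computed through the Robinson-Foulds distance, never materializing the
    exponential-dimensional indicator vectors.
    """
    from .treeio import rf_distance

    return float(np.sqrt(rf_distance(t1, t2)))


# ---------------------------------------------------------------------------
# Images of unresolved and partial trees
# ---------------------------------------------------------------------------


def _missing_branches(tree: Tree, full_taxon_count: int) -> tuple[int, int]:
    """(m_taxa missing, m_branches missing once all taxa are attached)."""
    n = full_taxon_count
    if tree.n_leaves > n:
        raise TreeError("tree has more leaves than full_taxon_count")
    m_taxa = n - tree.n_leaves
    return m_taxa, max(n - 3, 0) - len(bipartitions(tree))


def image_radius(tree: Tree, full_taxon_count: int,
                 proj: CartographicProjection) -> float:
    """Radius of a hypersphere containing the projections of all resolutions.

    For a tree over all taxa missing m branches the radius is m*sqrt(d)
    (each branch added during resolution contributes a vector of norm at
    most sqrt(d)).  For a partial tree on n - m taxa the bound additionally
    absorbs the worst-case separation between the centers of its
    unresolved resolutions, 2*(n - m - 3)*sqrt(d), and is taken around the
    canonical center of :func:`image_center`.
    """
    sqd = float(np.sqrt(proj.d))
    n = full_taxon_count
    if tree.n_leaves == n:
        _, m_branches = _missing_branches(tree, n)
        return m_branches * sqd
    k = len(bipartitions(tree))  # branches of any unresolved resolution
    m_branches = max(n - 3, 0) - k  # branches added by full resolution
    return m_branches * sqd + 2 * k * sqd


def image_center(tree: Tree, full_taxa: Iterable[str],
                 proj: CartographicProjection) -> np.ndarray:
    """Canonical center of the image hypersphere.

    For a tree over the full taxon set: its own projection.  For a partial
    tree: the projection of the canonical unresolved resolution in which
    every missing taxon is attached to one fixed internal vertex, whose
    nontrivial splits are the partial tree's internal splits extended by
    the missing taxa.
    """
    full = frozenset(full_taxa)
    if not tree.taxa() <= full:
        raise TreeError("tree taxa not contained in full taxon set")
    if tree.taxa() == full:
        return project(tree, proj)
    missing = full - tree.taxa()
    if tree.n_leaves < 4:
        return np.zeros(proj.d)
    # anchor: the internal vertex adjacent to the lexicographically least leaf
    anchor = next(iter(tree.adj[tree.leaf_node(min(tree.taxa()))]))
    below, parent = tree.leafset_below(root=anchor)
    point = np.zeros(proj.d)
    all_sub = tree.taxa()
    for v, side in below.items():
        if parent[v] == -1:
            continue
        # side away from the anchor keeps its taxa; the anchor side gains `missing`
        other = (all_sub - side) | missing
        if len(side) >= 2 and len(other) >= 2:
            point = point + proj.vector(Bipartition(side, other))
    return point


# ---------------------------------------------------------------------------
# Sampling resolutions (for Monte-Carlo containment checks)
# ---------------------------------------------------------------------------


def _resolve_multifurcations(tree: Tree, rng: np.random.Generator) -> Tree:
    """Randomly refine every vertex of degree > 3 into degree-3 vertices."""
    t = tree.copy()
    again = True
    while again:
        again = False
        for v in sorted(t.adj):
            if t.degree(v) > 3:
                nbrs = sorted(t.adj[v])
                k = len(nbrs)
                idx = rng.permutation(k)
                group = [nbrs[i] for i in idx[:2]]  # at least 2 move to the new vertex
                for i in idx[2:-2]:
                    if rng.random() < 0.5:
                        group.append(nbrs[i])
                # leave at least 2 neighbors on v
                w = t.add_node()
                for g in group:
                    length = t.edge_length(v, g)
                    t.remove_edge(v, g)
                    t.add_edge(w, g, length)
                t.add_edge(v, w)
                again = True
                break
    return t


def sample_resolution(tree: Tree, full_taxa: Iterable[str],
                      rng: np.random.Generator) -> Tree:
    """Sample one resolved tree over ``full_taxa`` that resolves ``tree``.

    Missing taxa are first attached to random internal (non-leaf) vertices,
    then every multifurcation is randomly refined.  Requires the input to
    have at least one internal vertex (>= 3 leaves).
    """
    full = sorted(frozenset(full_taxa))
    t = tree.copy()
    missing = sorted(frozenset(full) - t.taxa())
    internal = [v for v in t.nodes() if v not in t.leaf_name]
    if missing and not internal:
        raise TreeError("cannot attach missing taxa: no internal vertex")
    for name in missing:
        v = internal[int(rng.integers(len(internal)))]
        leaf = t.add_leaf(name)
        t.add_edge(v, leaf)
    resolved = _resolve_multifurcations(t, rng)
    resolved.validate()
    if not resolved.is_resolved():
        raise TreeError("resolution failed to produce a resolved tree")
    return resolved
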