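"""Tree and alignment containers with Newick/alignment I/O and bipartition primitives.

Trees here are *unrooted* leaf-labeled trees in the strict sense used by
parsimony search: connected acyclic graphs with no degree-2 vertices, whose
degree-1 vertices (leaves) are labeled bijectively with taxon names.  A tree
is *resolved* when every vertex has degree one or three; a resolved tree on
``n >= 3`` leaves has exactly ``2n - 3`` edges and ``n - 3`` nontrivial
bipartitions.  Degenerate trees on one or two leaves are permitted (they
arise transiently as tiny partial trees) and are treated as resolved by
convention.

Robinson-Foulds distance is the size of the symmetric difference of the two
trees' nontrivial bipartition sets.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import dendropy
from Bio import AlignIO

__all__ = [
    "CharacterMatrix",
    "Tree",
    "Bipartition",
    "TreeError",
    "NewickError",
    "AlignmentError",
    "parse_newick",
    "write_newick",
    "read_alignment",
    "bipartitions",
    "rf_distance",
]

ALLOWED_CHARS = frozenset("ACGT-?")


class TreeError(ValueError):
    """Structural violation of the unrooted-tree invariants."""


class NewickError(ValueError):
    """Malformed Newick input."""


class AlignmentError(ValueError):
    """Malformed or inconsistent alignment input."""


# ---------------------------------------------------------------------------
# Character matrix
# ---------------------------------------------------------------------------


@dataclass
class CharacterMatrix:
    """Aligned taxa-by-sites DNA matrix over {A, C, G, T, -, ?}.

    ``-`` (gap) and ``?`` (missing) are both scored as "any state" by the
    parsimony machinery.  Input is case-insensitive; sequences are stored
    uppercase.
    """

    taxon_names: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.taxon_names) != len(self.sequences):
            raise AlignmentError("taxon_names and sequences differ in length")
        if len(set(self.taxon_names)) != len(self.taxon_names):
            dupes = sorted({n for n in self.taxon_names if self.taxon_names.count(n) > 1})
            raise AlignmentError(f"duplicate taxon names: {dupes}")
        if any(not n for n in self.taxon_names):
            raise AlignmentError("empty taxon name")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            bad = [n for n, s in zip(self.taxon_names, self.sequences)
                   if len(s) != len(self.sequences[0])]
            raise AlignmentError(f"ragged alignment; offending taxa: {bad}")
        for name, seq in zip(self.taxon_names, self.sequences):
            illegal = set(seq) - ALLOWED_CHARS
            if illegal:
                raise AlignmentError(
                    f"taxon {name!r} has characters outside ACGT-?: {sorted(illegal)}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def sequence(self, name: str) -> str:
        try:
            return self.sequences[self.taxon_names.index(name)]
        except ValueError:
            raise KeyError(f"no sequence for taxon {name!r}") from None

    def subset(self, names: Iterable[str]) -> "CharacterMatrix":
        names = list(names)
        return CharacterMatrix(names, [self.sequence(n) for n in names])

    def to_fasta(self) -> str:
        return "".join(f">{n}\n{s}\n" for n, s in zip(self.taxon_names, self.sequences))


# ---------------------------------------------------------------------------
# Bipartition
# ---------------------------------------------------------------------------


class Bipartition:
    """A nontrivial split of a taxon set into two disjoint sides.

    Canonical orientation: the side containing the lexicographically
    smallest taxon is stored first.  Equality and hashing are
    orientation-independent as a consequence.
    """

    __slots__ = ("side1", "side2")

    def __init__(self, a: Iterable[str], b: Iterable[str]):
        a, b = frozenset(a), frozenset(b)
        if a & b:
            raise TreeError(f"bipartition sides overlap: {sorted(a & b)}")
        if len(a) < 2 or len(b) < 2:
            raise TreeError("trivial bipartition: both sides need >= 2 taxa")
        if min(a) <= min(b):
            self.side1, self.side2 = a, b
        else:
            self.side1, self.side2 = b, a

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, Bipartition)
                and self.side1 == other.side1 and self.side2 == other.side2)

    def __hash__(self) -> int:
        return hash((self.side1, self.side2))

    def __repr__(self) -> str:
        s1 = ",".join(sorted(self.side1))
        s2 = ",".join(sorted(self.side2))
        return f"{{{s1}}}|{{{s2}}}"

    @property
    def taxa(self) -> frozenset[str]:
        return self.side1 | self.side2

    def encode(self) -> bytes:
        """Stable byte encoding used for hashing into tree-space dimensions.

        Depends only on the two taxon-name sets, so the same split hashes
        identically regardless of the tree it came from.
        """
        s1 = ",".join(sorted(self.side1))
        s2 = ",".join(sorted(self.side2))
        return f"{s1}|{s2}".encode()


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


class Tree:
    """Mutable unrooted leaf-labeled tree.

    Vertices are integer ids; adjacency is symmetric.  Edge lengths are
    optional and, in this package, usually integer mutation counts from a
    parsimony reconstruction.
    """

    __slots__ = ("adj", "leaf_name", "_name2node", "lengths", "_next_id")

    def __init__(self) -> None:
        self.adj: dict[int, set[int]] = {}
        self.leaf_name: dict[int, str] = {}
        self._name2node: dict[str, int] = {}
        self.lengths: dict[tuple[int, int], float] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------------

    def add_node(self) -> int:
        v = self._next_id
        self._next_id += 1
        self.adj[v] = set()
        return v

    def add_leaf(self, name: str) -> int:
        if not name:
            raise TreeError("empty leaf label")
        if name in self._name2node:
            raise TreeError(f"duplicate leaf label {name!r}")
        v = self.add_node()
        self.leaf_name[v] = name
        self._name2node[name] = v
        return v

    def add_edge(self, u: int, v: int, length: Optional[float] = None) -> None:
        if v in self.adj[u]:
            raise TreeError(f"edge ({u},{v}) already present")
        self.adj[u].add(v)
        self.adj[v].add(u)
        if length is not None:
            self.lengths[self._ekey(u, v)] = length

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.lengths.pop(self._ekey(u, v), None)

    def remove_node(self, v: int) -> None:
        for u in list(self.adj[v]):
            self.remove_edge(u, v)
        del self.adj[v]
        name = self.leaf_name.pop(v, None)
        if name is not None:
            del self._name2node[name]

    @staticmethod
    def _ekey(u: int, v: int) -> tuple[int, int]:
        return (u, v) if u < v else (v, u)

    # -- queries ------------------------------------------------------------

    def nodes(self) -> list[int]:
        return sorted(self.adj)

    def neighbors(self, v: int) -> set[int]:
        return self.adj[v]

    def degree(self, v: int) -> int:
        return len(self.adj[v])

    def edges(self) -> list[tuple[int, int]]:
        """Canonical deterministic edge enumeration: sorted (min, max) pairs."""
        out = []
        for u in self.adj:
            for v in self.adj[u]:
                if u < v:
                    out.append((u, v))
        out.sort()
        return out

    def n_edges(self) -> int:
        return sum(len(s) for s in self.adj.values()) // 2

    def leaves(self) -> list[int]:
        return sorted(self.leaf_name)

    def taxa(self) -> frozenset[str]:
        return frozenset(self._name2node)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_name)

    def leaf_node(self, name: str) -> int:
        return self._name2node[name]

    def edge_length(self, u: int, v: int) -> Optional[float]:
        return self.lengths.get(self._ekey(u, v))

    def set_edge_length(self, u: int, v: int, length: float) -> None:
        if v not in self.adj[u]:
            raise TreeError(f"no edge ({u},{v})")
        self.lengths[self._ekey(u, v)] = length

    def is_resolved(self) -> bool:
        if len(self.adj) <= 2:
            return True  # degenerate 1- or 2-leaf tree
        return all(len(s) in (1, 3) for s in self.adj.values())

    def validate(self) -> None:
        """Check connectivity, acyclicity and the no-degree-2 rule."""
        if not self.adj:
            raise TreeError("empty tree")
        n_nodes = len(self.adj)
        if self.n_edges() != n_nodes - 1:
            raise TreeError("edge count inconsistent with a tree (cycle or forest)")
        # connectivity
        start = next(iter(self.adj))
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) != n_nodes:
            raise TreeError("tree is not connected")
        if n_nodes > 2 and any(len(s) == 2 for s in self.adj.values()):
            raise TreeError("degree-2 vertex present")
        for v in self.adj:
            if len(self.adj[v]) <= 1 and n_nodes > 1 and v not in self.leaf_name:
                raise TreeError(f"unlabeled leaf vertex {v}")

    # -- mutation helpers ---------------------------------------------------

    def split_edge(self, u: int, v: int) -> int:
        """Subdivide edge (u, v); return the new midpoint vertex.

        Any stored length is dropped (parsimony lengths are recomputed, never
        split).
        """
        if v not in self.adj[u]:
            raise TreeError(f"no edge ({u},{v})")
        self.remove_edge(u, v)
        w = self.add_node()
        self.add_edge(u, w)
        self.add_edge(w, v)
        return w

    def smooth_node(self, v: int) -> None:
        """Remove a degree-2 vertex, merging its two incident edges."""
        if self.degree(v) != 2:
            raise TreeError(f"vertex {v} has degree {self.degree(v)}, not 2")
        a, b = sorted(self.adj[v])
        la = self.edge_length(a, v)
        lb = self.edge_length(v, b)
        self.remove_node(v)
        length = (la + lb) if (la is not None and lb is not None) else None
        self.add_edge(a, b, length)

    def copy(self) -> "Tree":
        t = Tree.__new__(Tree)
        t.adj = {u: set(s) for u, s in self.adj.items()}
        t.leaf_name = dict(self.leaf_name)
        t._name2node = dict(self._name2node)
        t.lengths = dict(self.lengths)
        t._next_id = self._next_id
        return t

    # -- traversal ----------------------------------------------------------

    def rooted_orientation(self, root: Optional[int] = None) -> tuple[list[int], dict[int, int]]:
        """Return (postorder node list, parent map) for an arbitrary rooting.

        Default root: the leaf with the lexicographically smallest taxon
        name, making every derived traversal deterministic.
        """
        if root is None:
            root = self._name2node[min(self._name2node)]
        parent = {root: -1}
        order = [root]
        stack = [root]
        while stack:
            u = stack.pop()
            for v in sorted(self.adj[u]):
                if v not in parent:
                    parent[v] = u
                    order.append(v)
                    stack.append(v)
        order.reverse()  # children before parents
        return order, parent

    def leafset_below(self, root: Optional[int] = None) -> tuple[dict[int, frozenset[str]], dict[int, int]]:
        """Taxon set of the subtree below each node under the default rooting."""
        order, parent = self.rooted_orientation(root)
        below: dict[int, frozenset[str]] = {}
        for v in order:
            if v in self.leaf_name and self.degree(v) <= 1:
                below[v] = frozenset([self.leaf_name[v]])
            else:
                acc: set[str] = set()
                if v in self.leaf_name:
                    acc.add(self.leaf_name[v])
                for c in self.adj[v]:
                    if c != parent[v]:
                        acc |= below[c]
                below[v] = frozenset(acc)
        return below, parent

    def __repr__(self) -> str:
        return f"<Tree n_leaves={self.n_leaves} n_edges={self.n_edges()}>"


# ---------------------------------------------------------------------------
# Bipartitions and RF
# ---------------------------------------------------------------------------


def bipartitions(tree: Tree) -> frozenset[Bipartition]:
    """Nontrivial bipartitions of the tree's taxon set, one per internal edge.

    Trivial splits (a single taxon against the rest) are ignored; a resolved
    n-taxon tree yields exactly n - 3 bipartitions; trees with fewer than
    four leaves yield the empty set.
    """
    if tree.n_leaves < 4:
        return frozenset()
    all_taxa = tree.taxa()
    below, parent = tree.leafset_below()
    out = set()
    for v, side in below.items():
        if parent[v] == -1:
            continue
        other = all_taxa - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(Bipartition(side, other))
    return frozenset(out)


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance: |B1 Δ B2| over nontrivial bipartition sets."""
    if t1.taxa() != t2.taxa():
        only1 = sorted(t1.taxa() - t2.taxa())
        only2 = sorted(t2.taxa() - t1.taxa())
        raise TreeError(f"leaf sets differ; only in first: {only1}, only in second: {only2}")
    return len(bipartitions(t1) ^ bipartitions(t2))


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy)
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into an unrooted :class:`Tree`.

    A degree-2 root produced by rooted Newick is suppressed (its two edges
    merged), so the result always satisfies the unrooted-tree invariants.
    """
    if not text.strip():
        raise NewickError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc

    tree = Tree()
    seen: dict[str, int] = {}
    node_map: dict[int, int] = {}
    for dnode in dtree.preorder_node_iter():
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else None
            if not label:
                raise NewickError("leaf with empty label")
            if label in seen:
                raise NewickError(f"duplicate leaf label {label!r}")
            v = tree.add_leaf(label)
            seen[label] = v
        else:
            v = tree.add_node()
        node_map[id(dnode)] = v
        if dnode.parent_node is not None:
            u = node_map[id(dnode.parent_node)]
            tree.add_edge(u, v, dnode.edge.length)

    # suppress any degree-2 vertices (rooted input, or singleton nestings)
    for v in list(tree.adj):
        if v in tree.adj and tree.degree(v) == 2 and v not in tree.leaf_name:
            tree.smooth_node(v)
    tree.validate()
    return tree


def _format_length(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def write_newick(tree: Tree, include_lengths: bool = True) -> str:
    """Serialize an unrooted tree to Newick.

    The serialization roots at an internal vertex adjacent to the
    lexicographically smallest leaf; parsing it back yields the same
    bipartition set (round trip up to rotation).
    """
    if tree.n_leaves == 0:
        raise TreeError("cannot serialize empty tree")
    if tree.n_leaves == 1:
        (v,) = tree.leaves()
        return f"{tree.leaf_name[v]};"
    if tree.n_leaves == 2:
        a, b = tree.leaves()
        la = tree.edge_length(a, b)
        if include_lengths and la is not None:
            return f"({tree.leaf_name[a]}:{_format_length(la)},{tree.leaf_name[b]}:{_format_length(la)});"
        return f"({tree.leaf_name[a]},{tree.leaf_name[b]});"

    start_leaf = tree.leaf_node(min(tree.taxa()))
    root = next(iter(tree.adj[start_leaf]))

    def render(v: int, parent: int) -> str:
        children = sorted(tree.adj[v] - {parent})
        if not children:  # leaf
            label = tree.leaf_name[v]
        else:
            label = "(" + ",".join(render(c, v) for c in children) + ")"
        if include_lengths and parent != -1:
            length = tree.edge_length(parent, v)
            if length is not None:
                return f"{label}:{_format_length(length)}"
        return label

    return render(root, -1) + ";"


# ---------------------------------------------------------------------------
# Alignment reading (delegated to Bio.AlignIO)
# ---------------------------------------------------------------------------

_FORMAT_MAP = {
    "fasta": "fasta",
    "phylip": "phylip-relaxed",
    "nexus": "nexus",
}


def read_alignment(path: str, fmt: str = "fasta",
                   map_ambiguous_to_missing: bool = False) -> CharacterMatrix:
    """Read an aligned DNA matrix from FASTA, relaxed PHYLIP or NEXUS.

    IUPAC ambiguity codes other than ``?``/``-`` are rejected unless
    ``map_ambiguous_to_missing`` is set, in which case they become ``?``.
    """
    if fmt not in _FORMAT_MAP:
        raise AlignmentError(f"unsupported format {fmt!r}; choose from {sorted(_FORMAT_MAP)}")
    try:
        aln = AlignIO.read(path, _FORMAT_MAP[fmt])
    except ValueError as exc:
        # Biopython's AlignIO raises ValueError for ragged FASTA etc.
        raise AlignmentError(f"could not read {fmt} alignment from {path}: {exc}") from exc
    names = [rec.id for rec in aln]
    seqs = [str(rec.seq).upper() for rec in aln]
    if map_ambiguous_to_missing:
        cleaned = []
        for s in seqs:
            cleaned.append("".join(c if c in ALLOWED_CHARS else "?" for c in s))
        seqs = cleaned
    return CharacterMatrix(names, seqs)


def parse_alignment_string(text: str, fmt: str = "fasta", **kw) -> CharacterMatrix:
    """Convenience wrapper reading an alignment from an in-memory string."""
    handle = io.StringIO(text)
    if fmt not in _FORMAT_MAP:
        raise AlignmentError(f"unsupported format {fmt!r}")
    try:
        aln = AlignIO.read(handle, _FORMAT_MAP[fmt])
    except ValueError as exc:
        raise AlignmentError(f"could not parse {fmt} alignment: {exc}") from exc
    names = [rec.id for rec in aln]
    seqs = [str(rec.seq).upper() for rec in aln]
    if kw.get("map_ambiguous_to_missing"):
        seqs = ["".join(c if c in ALLOWED_CHARS else "?" for c in s) for s in seqs]
    return CharacterMatrix(names, seqs)
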