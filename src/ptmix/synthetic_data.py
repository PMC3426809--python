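"""Random trees and Jukes-Cantor sequence simulation for offline testing.

Topologies are drawn uniformly by sequential random edge attachment
(attaching leaf k+1 to a uniformly chosen edge of the current tree makes
every resolved unrooted topology equally likely).  Branch lengths are
exponential with a configurable mean, in expected substitutions per site.
Sequences evolve under Jukes-Cantor: along a branch of length b each site
differs from its ancestor with probability (3/4)(1 - exp(-4b/3)), the
closed form used to calibrate the whole simulator.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .treeio import CharacterMatrix, Tree, TreeError, write_newick

__all__ = [
    "SimulationSpec",
    "random_resolved_tree",
    "evolve_sequences",
    "make_dataset",
    "jc_expected_difference",
]

_BASES = np.array([ord(c) for c in "ACGT"], dtype=np.uint8)


@dataclass
class SimulationSpec:
    """Conditions of one simulated dataset.

    Defaults (60 taxa, 1000 sites, mean branch length 0.05 expected
    substitutions per site) give a high-signal alignment on which the
    generating topology is recoverable by parsimony.
    """

    n_taxa: int = 60
    n_sites: int = 1000
    mean_branch_length: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.mean_branch_length <= 0:
            raise ValueError("mean branch length must be > 0")


def jc_expected_difference(b: float) -> float:
    """JC69 probability that two sites separated by path length b differ."""
    return 0.75 * (1.0 - np.exp(-4.0 * b / 3.0))


def random_resolved_tree(n: int, rng: np.random.Generator,
                         mean_branch_length: float | None = None) -> Tree:
    """Uniformly random resolved unrooted topology on taxa t1..tn.

    Optional exponential branch lengths with the given mean.
    """
    if n < 3:
        raise TreeError("need at least 3 taxa")
    names = [f"t{i + 1}" for i in range(n)]
    tree = Tree()
    hub = tree.add_node()
    for name in names[:3]:
        tree.add_edge(hub, tree.add_leaf(name))
    for name in names[3:]:
        edges = tree.edges()
        u, v = edges[int(rng.integers(len(edges)))]
        w = tree.split_edge(u, v)
        tree.add_edge(w, tree.add_leaf(name))
    if mean_branch_length is not None:
        for u, v in tree.edges():
            tree.set_edge_length(u, v, float(rng.exponential(mean_branch_length)))
    return tree


def evolve_sequences(tree: Tree, spec: SimulationSpec,
                     rng: np.random.Generator) -> CharacterMatrix:
    """Evolve sequences along a branch-length-annotated tree under JC69.

    The root sequence (at an arbitrary internal vertex) is uniform over
    {A,C,G,T}; each branch substitutes per site with the JC probability of
    differing, replacement uniform over the three other bases.
    """
    for u, v in tree.edges():
        if tree.edge_length(u, v) is None:
            raise TreeError(f"edge ({u},{v}) has no branch length")
    order, parent = tree.rooted_orientation()
    root = order[-1]
    seq: dict[int, np.ndarray] = {
        root: rng.integers(0, 4, size=spec.n_sites).astype(np.uint8)
    }
    for v in reversed(order):  # preorder: parents before children
        if v == root:
            continue
        p = parent[v]
        b = tree.edge_length(p, v)
        p_diff = jc_expected_difference(b)
        child = seq[p].copy()
        hit = rng.random(spec.n_sites) < p_diff
        if hit.any():
            # uniform over the three other bases: add 1..3 mod 4
            child[hit] = (child[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        seq[v] = child
    names = sorted(tree.taxa())
    seqs = [
        _BASES[seq[tree.leaf_node(name)]].tobytes().decode()
        for name in names
    ]
    return CharacterMatrix(names, seqs)


def make_dataset(spec: SimulationSpec, out_dir: str,
                 prefix: str = "sim") -> tuple[str, str]:
    """Write a (true tree Newick, alignment FASTA) pair; byte-deterministic.

    Returns (tree_path, fasta_path).
    """
    rng = np.random.default_rng(spec.seed)
    tree = random_resolved_tree(spec.n_taxa, rng, spec.mean_branch_length)
    matrix = evolve_sequences(tree, spec, rng)
    os.makedirs(out_dir, exist_ok=True)
    tree_path = os.path.join(out_dir, f"{prefix}.nwk")
    fasta_path = os.path.join(out_dir, f"{prefix}.fasta")
    with open(tree_path, "w") as fh:
        fh.write(write_newick(tree) + "\n")
    with open(fasta_path, "w") as fh:
        fh.write(matrix.to_fasta())
    return tree_path, fasta_path


def simulate(spec: SimulationSpec) -> tuple[Tree, CharacterMatrix]:
    """In-memory convenience: (true tree, alignment) for a spec."""
    rng = np.random.default_rng(spec.seed)
    tree = random_resolved_tree(spec.n_taxa, rng, spec.mean_branch_length)
    matrix = evolve_sequences(tree, spec, rng)
    return tree, matrix
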