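# ptmix

Partial Tree Mixing (PTM): a divide-and-conquer, globally guided algorithm
for building high-quality **starting trees** for maximum-parsimony
phylogenetic search, together with the machinery it stands on — Fitch
parsimony scoring, stepwise addition, TBR hill-climbing, and a hashed
low-dimensional embedding of partition-based tree space.

## Who this is for

Anyone doing parsimony tree search on aligned DNA matrices who cares about
where the search *starts*. Hill-climbing searches (TBR) are only as good as
their starting tree; greedy starters (stepwise addition, distance methods)
use purely local information, so practitioners traditionally run many
searches from many starts. PTM instead builds one deliberately exploratory
starting tree guided by a global representation of tree space.

## The method in brief

A tree on taxon set $X$ is identified with the set of nontrivial
bipartitions (splits) induced by its internal branches. In the 0/1
partition space with one dimension per possible split:

- the Euclidean distance between two trees is $\sqrt{RF}$, the square root
  of their Robinson–Foulds distance;
- every resolved $n$-taxon tree lies on the hypersphere of radius
  $\sqrt{n-3}$; the fully unresolved star sits at the origin.

Because this space has $O(n!!)$ dimensions, trees are *projected* into
$\mathbb{R}^d$ by hashing: each split maps to a $d$-vector with entries
uniform on $[-1,1]$ determined by a keyed hash of its canonical encoding,
and a tree projects to the sum of its splits' vectors. The projection is
additive, $O(nd)$ per tree, and the hash function itself is the
reference-vector store.

PTM then works in three phases:

1. **Initial partials.** Taxa are ordered by Hamming distance to a random
   reference taxon and sliced into nearly even groups (default size 60);
   each group gets a stepwise-addition tree refined by TBR.
2. **Mixing** (default 3 rounds). Pairs of partial trees *join* — exactly
   the reconnection half of TBR, best edge pair over all pairs — are
   refined by strict-improvement TBR, and trees above the minimum size
   (default 40) *divide* on the branch carrying the most parsimony
   mutations (the bisection half of TBR). Join partners are chosen to push
   the predicted combined tree as far as possible from the tree it was
   divided from, measured in the projection; siblings of the last division
   never rejoin, and no join may exceed the maximum size (default 60).
3. **Final build.** No more division; partials keep joining until one
   resolved tree over all taxa remains, which is handed to an ordinary TBR
   search.

A Jukes–Cantor simulator (random uniform topologies, exponential branch
lengths) generates alignments over known trees so every stage is testable
offline.

## Worked example

```sh
# simulate a 60-taxon, 1000-site alignment along a random tree
ptmix simulate --taxa 60 --sites 1000 --mean-branch 0.05 --seed 3 --out-dir demo

# PTM starting tree (min 40 / max 60, 3 mixing rounds), then score it
ptmix ptm demo/sim.fasta --seed 3 --out demo/ptm.nwk --trace demo/trace.tsv
ptmix score demo/ptm.nwk demo/sim.fasta
ptmix rf demo/ptm.nwk demo/sim.nwk
```

On this dataset the run prints

```
# ptmix 0.1.0 seed=3 projection-seed=0 --min-size 40 --max-size 60 iterations=3 dims=10 score=6372
6372
4
```

i.e. the PTM tree explains the alignment with 6372 mutations and differs
from the generating tree by an RF distance of 4 (two splits). For
comparison, the generating tree itself requires 6375 mutations here — with
exponentially distributed branch lengths some true branches are so short
that the parsimony optimum is *not* the generating tree, a data limit, not
a search failure.

The same operations are available as a library:

```python
from ptmix import SearchConfig, PTMParams, ptm_search, fitch_score, read_alignment

matrix = read_alignment("demo/sim.fasta", "fasta")
tree = ptm_search(matrix, PTMParams(rng_seed=3), SearchConfig(rng_seed=3))
print(fitch_score(tree, matrix))
```

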