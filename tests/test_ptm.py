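"""PTM population mechanics: partitioning, join/divide, pairing, mixing."""

import itertools

import numpy as np
import pytest

from ptmix.treeio import CharacterMatrix, Tree, TreeError, rf_distance
from ptmix.parsimony import branch_mutation_counts, fitch_score
from ptmix.classic_search import SearchConfig, reconnect, stepwise_addition, tbr_hillclimb
from ptmix.tree_space import CartographicProjection, project
from ptmix.ptm import (
    PTMParams,
    PartialTree,
    build_initial_partials,
    divide_partial,
    finalize,
    join_partials,
    mix,
    pair_partials,
    partition_taxa,
    ptm_search,
)
from ptmix.synthetic_data import SimulationSpec, random_resolved_tree, simulate

from oracles import random_matrix


def _partial(tree, matrix, proj, pid, prev=None, sib=None):
    return PartialTree(tree=tree, score=fitch_score(tree, matrix),
                       location=project(tree, proj), id=pid,
                       previous_location=prev, sibling_id=sib)


@pytest.fixture(scope="module")
def proj():
    return CartographicProjection(d=10, seed=0)


class TestPartitionTaxa:
    def test_even_split_exact(self):
        rng = np.random.default_rng(0)
        m = random_matrix(120, 20, rng)
        groups = partition_taxa(m, 60, rng)
        assert sorted(len(g) for g in groups) == [60, 60]

    def test_nearly_even_slicing(self):
        rng = np.random.default_rng(1)
        m = random_matrix(100, 20, rng)
        groups = partition_taxa(m, 30, rng)
        assert sorted(len(g) for g in groups) == [25, 25, 25, 25]

    def test_disjoint_cover(self):
        rng = np.random.default_rng(2)
        m = random_matrix(50, 10, rng)
        groups = partition_taxa(m, 12, rng)
        flat = list(itertools.chain.from_iterable(groups))
        assert sorted(flat) == sorted(m.taxon_names)

    def test_similar_taxa_grouped_contiguously(self):
        # two clusters of mutually similar sequences: each group must be
        # drawn from contiguous distance ranks, so no group mixes clusters
        # unless it straddles the single boundary slice
        rng = np.random.default_rng(3)
        a = "A" * 40
        b = "T" * 40
        names, seqs = [], []
        for i in range(12):
            names.append(f"a{i}")
            seqs.append(a[: 39] + "ACGT"[i % 2])  # tiny within-cluster noise
        for i in range(12):
            names.append(f"b{i}")
            seqs.append(b[: 39] + "TGCA"[i % 2])
        m = CharacterMatrix(names, seqs)
        groups = partition_taxa(m, 12, rng)
        assert len(groups) == 2
        clusters = ["".join(sorted({g[0] for g in grp})) for grp in groups]
        assert sorted(clusters) == ["a", "b"]


class TestBuildInitialPartials:
    def test_partials_cover_groups_and_are_local_minima(self, proj):
        _, m = simulate(SimulationSpec(n_taxa=12, n_sites=150, seed=1))
        rng = np.random.default_rng(1)
        groups = partition_taxa(m, 6, rng)
        cfg = SearchConfig(rng_seed=1)
        partials = build_initial_partials(m, groups, cfg, proj, rng)
        union = frozenset().union(*(p.taxa() for p in partials))
        assert union == frozenset(m.taxon_names)
        for p in partials:
            assert p.tree.is_resolved()
            assert p.score == fitch_score(p.tree, m)
            assert p.previous_location is None and p.sibling_id is None
            refined = tbr_hillclimb(p.tree, m, cfg)
            assert fitch_score(refined, m) == p.score  # already a local minimum

    def test_overlapping_groups_rejected(self, proj):
        _, m = simulate(SimulationSpec(n_taxa=8, n_sites=50, seed=2))
        with pytest.raises(TreeError):
            build_initial_partials(m, [m.taxon_names[:5], m.taxon_names[4:]],
                                   SearchConfig(), proj)


class TestJoinPartials:
    def test_join_is_globally_best_reconnection(self, proj):
        # brute force over every edge pair at small sizes
        rng = np.random.default_rng(4)
        m = random_matrix(12, 30, rng)
        cfg = SearchConfig(rng_seed=4)
        a_names, b_names = set(m.taxon_names[:6]), set(m.taxon_names[6:])
        ta = stepwise_addition(m, cfg, taxa_subset=a_names)
        tb = stepwise_addition(m, cfg, taxa_subset=b_names)
        pa, pb = _partial(ta, m, proj, 0), _partial(tb, m, proj, 1)
        cfg_noref = SearchConfig(rng_seed=4, max_tbr_rounds=0)  # raw join only
        joined = join_partials(pa, pb, m, cfg_noref, proj)
        brute = min(
            fitch_score(reconnect(ta, e1, tb, e2), m)
            for e1 in ta.edges() for e2 in tb.edges()
        )
        assert joined.score == brute

    def test_refined_join_not_worse_than_raw(self, proj):
        _, m = simulate(SimulationSpec(n_taxa=16, n_sites=100, seed=5))
        cfg = SearchConfig(rng_seed=5)
        names = sorted(m.taxon_names)
        ta = stepwise_addition(m, cfg, taxa_subset=set(names[:8]))
        tb = stepwise_addition(m, cfg, taxa_subset=set(names[8:]))
        pa, pb = _partial(ta, m, proj, 0), _partial(tb, m, proj, 1)
        raw = join_partials(pa, pb, m, SearchConfig(rng_seed=5, max_tbr_rounds=0), proj)
        refined = join_partials(pa, pb, m, cfg, proj)
        assert refined.score <= raw.score
        assert refined.taxa() == pa.taxa() | pb.taxa()

    def test_overlap_rejected(self, proj):
        rng = np.random.default_rng(6)
        m = random_matrix(6, 20, rng)
        cfg = SearchConfig()
        t1 = stepwise_addition(m, cfg, taxa_subset=set(m.taxon_names[:4]))
        t2 = stepwise_addition(m, cfg, taxa_subset=set(m.taxon_names[2:]))
        with pytest.raises(TreeError):
            join_partials(_partial(t1, m, proj, 0), _partial(t2, m, proj, 1), m, cfg, proj)

    def test_degenerate_singleton_join(self, proj):
        rng = np.random.default_rng(7)
        m = random_matrix(5, 20, rng)
        cfg = SearchConfig()
        big = stepwise_addition(m, cfg, taxa_subset=set(m.taxon_names[:4]))
        single = Tree()
        single.add_leaf(m.taxon_names[4])
        joined = join_partials(_partial(big, m, proj, 0), _partial(single, m, proj, 1),
                               m, cfg, proj)
        assert joined.size == 5 and joined.tree.is_resolved()


class TestDividePartial:
    def test_children_partition_parent(self, proj):
        _, m = simulate(SimulationSpec(n_taxa=14, n_sites=100, seed=8))
        cfg = SearchConfig(rng_seed=8)
        t = tbr_hillclimb(stepwise_addition(m, cfg), m, cfg)
        p = _partial(t, m, proj, 0)
        a, b = divide_partial(p, m, proj, id_start=1)
        assert a.taxa() | b.taxa() == p.taxa()
        assert not (a.taxa() & b.taxa())
        assert a.sibling_id == b.id and b.sibling_id == a.id
        assert np.array_equal(a.previous_location, p.location)

    def test_splits_on_max_mutation_edge(self, proj):
        _, m = simulate(SimulationSpec(n_taxa=10, n_sites=80, seed=9))
        cfg = SearchConfig(rng_seed=9)
        t = stepwise_addition(m, cfg)
        p = _partial(t, m, proj, 0)
        counts = branch_mutation_counts(t, m)
        a, b = divide_partial(p, m, proj, id_start=1)
        # the two children's taxon sets correspond to one edge of max count
        max_count = max(counts.values())
        sides = []
        below, parent = t.leafset_below()
        taxa = t.taxa()
        for (u, v), c in counts.items():
            if c == max_count:
                child = v if parent.get(v) == u else u
                sides.append(frozenset(below[child]))
        assert a.taxa() in sides or b.taxa() in sides

    def test_outlier_clade_separates(self, proj):
        # three distant outliers migrate as one division product
        core = ["A" * 60] * 7
        outl = ["T" * 60] * 3
        names = [f"c{i}" for i in range(7)] + [f"o{i}" for i in range(3)]
        m = CharacterMatrix(names, core + outl)
        cfg = SearchConfig(rng_seed=0)
        t = tbr_hillclimb(stepwise_addition(m, cfg), m, cfg)
        p = _partial(t, m, proj, 0)
        a, b = divide_partial(p, m, proj, id_start=1)
        parts = {frozenset(a.taxa()), frozenset(b.taxa())}
        assert frozenset(f"o{i}" for i in range(3)) in parts


class TestPairPartials:
    def _pop(self, proj, specs):
        """specs: list of (size, prev_loc_or_None, sibling_or_None)."""
        rng = np.random.default_rng(0)
        pop = []
        for i, (size, prev, sib) in enumerate(specs):
            t = random_resolved_tree(size, rng)
            # relabel to keep taxa disjoint
            mapping = {name: f"p{i}_{name}" for name in t.taxa()}
            t2 = Tree()
            ids = {}
            for v in t.nodes():
                ids[v] = (t2.add_leaf(mapping[t.leaf_name[v]])
                          if v in t.leaf_name else t2.add_node())
            for u, v in t.edges():
                t2.add_edge(ids[u], ids[v])
            pop.append(PartialTree(tree=t2, score=0, location=project(t2, proj),
                                   id=i, previous_location=prev, sibling_id=sib))
        return pop

    def test_siblings_never_pair(self, proj):
        pop = self._pop(proj, [(5, np.zeros(10), 1), (5, np.zeros(10), 0)])
        pairs, unpaired = pair_partials(pop, PTMParams(min_size=4, max_size=60),
                                        np.random.default_rng(0))
        assert pairs == [] and unpaired == [0, 1]

    def test_size_cap_blocks_pair(self, proj):
        pop = self._pop(proj, [(40, None, None), (30, None, None)])
        pairs, _ = pair_partials(pop, PTMParams(min_size=4, max_size=60),
                                 np.random.default_rng(0))
        assert pairs == []

    def test_sibling_fallback_allows_last_join(self, proj):
        pop = self._pop(proj, [(5, np.zeros(10), 1), (5, np.zeros(10), 0)])
        pairs, _ = pair_partials(pop, PTMParams(min_size=4, max_size=60),
                                 np.random.default_rng(0),
                                 allow_sibling_fallback=True)
        assert len(pairs) == 1

    def test_matches_greedy_bruteforce(self, proj):
        pop = self._pop(proj, [(5, None, None), (6, None, None),
                               (7, None, None), (8, None, None)])
        params = PTMParams(min_size=4, max_size=60)
        rng = np.random.default_rng(42)
        pairs, unpaired = pair_partials(pop, params, rng)
        # replay the same greedy process independently
        order = list(np.random.default_rng(42).permutation(4))
        centroid = np.mean([p.location for p in pop], axis=0)
        unmatched = set(range(4))
        expected = []
        for i in order:
            if i not in unmatched:
                continue
            cands = [j for j in sorted(unmatched) if j != i]
            if not cands:
                continue
            best = max(cands, key=lambda j: (np.linalg.norm(
                pop[i].location + pop[j].location - centroid)))
            unmatched -= {i, best}
            expected.append((i, best))
        assert pairs == expected
        assert unpaired == sorted(unmatched)


class TestMixAndFinalize:
    def test_mix_zero_iterations_identity(self, proj):
        _, m = simulate(SimulationSpec(n_taxa=12, n_sites=80, seed=10))
        rng = np.random.default_rng(10)
        cfg = SearchConfig(rng_seed=10)
        groups = partition_taxa(m, 6, rng)
        partials = build_initial_partials(m, groups, cfg, proj, rng)
        params = PTMParams(min_size=4, max_size=6, mix_iterations=0)
        out = mix(partials, m, params, cfg, proj, rng)
        assert [p.id for p in out] == [p.id for p in partials]
        assert all(rf_distance(a.tree, b.tree) == 0 for a, b in zip(out, partials))

    def test_disjoint_cover_after_every_round(self, proj):
        _, m = simulate(SimulationSpec(n_taxa=20, n_sites=100, seed=11))
        rng = np.random.default_rng(11)
        cfg = SearchConfig(rng_seed=11)
        groups = partition_taxa(m, 7, rng)
        partials = build_initial_partials(m, groups, cfg, proj, rng)
        params = PTMParams(min_size=5, max_size=10, mix_iterations=3)
        # mix() asserts the disjoint-cover invariant internally every round
        out = mix(partials, m, params, cfg, proj, rng)
        union = frozenset().union(*(p.taxa() for p in out))
        assert union == frozenset(m.taxon_names)
        assert sum(p.size for p in out) == m.n_taxa

    def test_no_oversize_trees_during_mixing(self, proj):
        _, m = simulate(SimulationSpec(n_taxa=24, n_sites=100, seed=12))
        rng = np.random.default_rng(12)
        cfg = SearchConfig(rng_seed=12)
        params = PTMParams(min_size=5, max_size=9, mix_iterations=4)
        groups = partition_taxa(m, params.group_size, rng)
        partials = build_initial_partials(m, groups, cfg, proj, rng)
        trace = []
        out = mix(partials, m, params, cfg, proj, rng, trace=trace)
        for row in trace:
            # after division no tree exceeds max_size; joins were capped too
            assert max(row["sizes"]) <= max(params.max_size, params.group_size)

    def test_finalize_produces_full_resolved_tree(self, proj):
        _, m = simulate(SimulationSpec(n_taxa=15, n_sites=100, seed=13))
        rng = np.random.default_rng(13)
        cfg = SearchConfig(rng_seed=13)
        groups = partition_taxa(m, 5, rng)
        partials = build_initial_partials(m, groups, cfg, proj, rng)
        tree = finalize(partials, m, PTMParams(min_size=4, max_size=8), cfg, proj, rng)
        assert tree.taxa() == frozenset(m.taxon_names)
        assert tree.n_edges() == 2 * 15 - 3
        assert tree.is_resolved()

    def test_finalize_single_partial_returned_as_is(self, proj):
        _, m = simulate(SimulationSpec(n_taxa=8, n_sites=60, seed=14))
        cfg = SearchConfig(rng_seed=14)
        t = stepwise_addition(m, cfg)
        p = _partial(t, m, proj, 0)
        out = finalize([p], m, PTMParams(min_size=4, max_size=60), cfg, proj)
        assert rf_distance(out, t) == 0


class TestPtmSearch:
    def test_deterministic_under_seeds(self):
        _, m = simulate(SimulationSpec(n_taxa=20, n_sites=150, seed=15))
        params = PTMParams(min_size=5, max_size=10, rng_seed=3, projection_seed=7)
        t1 = ptm_search(m, params, SearchConfig(rng_seed=3))
        t2 = ptm_search(m, params, SearchConfig(rng_seed=3))
        assert rf_distance(t1, t2) == 0

    def test_degenerates_to_stepwise_tbr_with_one_group(self):
        _, m = simulate(SimulationSpec(n_taxa=10, n_sites=100, seed=16))
        params = PTMParams(min_size=20, max_size=30, mix_iterations=0, rng_seed=5)
        cfg = SearchConfig(rng_seed=5)
        via_ptm = ptm_search(m, params, cfg)
        rng = np.random.default_rng(5)
        sw = stepwise_addition(m, SearchConfig(rng_seed=5),
                               taxa_subset=set(m.taxon_names), rng=rng)
        direct = tbr_hillclimb(sw, m, SearchConfig(rng_seed=5))
        assert rf_distance(via_ptm, direct) == 0

    def test_result_is_tbr_local_minimum(self):
        _, m = simulate(SimulationSpec(n_taxa=12, n_sites=120, seed=17))
        params = PTMParams(min_size=4, max_size=8, rng_seed=1)
        out = ptm_search(m, params, SearchConfig(rng_seed=1))
        s = fitch_score(out, m)
        from ptmix.classic_search import tbr_neighbors

        assert all(fitch_score(nb, m) >= s for nb in tbr_neighbors(out))

    def test_too_few_taxa_raises(self):
        m = random_matrix(3, 10, np.random.default_rng(0))
        with pytest.raises(TreeError):
            ptm_search(m, PTMParams(min_size=4, max_size=6), SearchConfig())
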