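import itertools

import numpy as np
import pytest

from camelscan import (
    DistanceMatrix,
    PhyloTree,
    bootstrap_support,
    fst_distance_matrix,
    majority_consensus,
    neighbor_joining,
    read_newick,
    write_newick,
)

from helpers import make_matrix, make_popmap


def leaf_edge_lengths(tree: PhyloTree) -> dict[str, float]:
    return {lf.taxon.label: lf.edge.length for lf in tree.tree.leaf_node_iter()}


def random_additive_tree(rng, n_leaves):
    """Random binary topology + branch lengths; returns (splits, distances)."""
    labels = [f"t{i}" for i in range(n_leaves)]
    nodes = {lbl: frozenset([lbl]) for lbl in labels}
    dist = {(a, b): 0.0 for a, b in itertools.combinations(labels, 2)}

    def add_len(members, length):
        members = set(members)
        rest = set(labels) - members
        for a in members:
            for b in rest:
                key = (a, b) if (a, b) in dist else (b, a)
                dist[key] += length

    splits = set()
    active = list(labels)
    for lbl in labels:
        add_len([lbl], rng.uniform(0.5, 2.0))
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        merged = nodes[a] | nodes[b]
        length = rng.uniform(0.5, 2.0)
        if 2 <= len(merged) <= n_leaves - 2:
            splits.add(merged)
            add_len(merged, length)
        name = f"{a}+{b}"
        nodes[name] = merged
        active = [x for x in active if x not in (a, b)] + [name]
    values = np.zeros((n_leaves, n_leaves))
    for (a, b), v in dist.items():
        ia, ib = labels.index(a), labels.index(b)
        values[ia, ib] = values[ib, ia] = v
    return labels, splits, values


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(list("ABC"), np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float))
        tree = neighbor_joining(d)
        assert leaf_edge_lengths(tree) == {"A": 2.0, "B": 3.0, "C": 7.0}

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4))
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        assert tree.contains_split({"A", "B"})
        lengths = leaf_edge_lengths(tree)
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_ultrametric_ties_resolved_deterministically(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(list("ABCD"), d)
        assert neighbor_joining(dm).newick() == neighbor_joining(dm).newick()

    def test_non_symmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(list("AB"), np.array([[0.0, 1.0], [2.0, 0.0]]))

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_recovers_random_additive_trees(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for _ in range(5):
            labels, splits, values = random_additive_tree(rng, n_leaves)
            tree = neighbor_joining(DistanceMatrix(labels, values))
            got = set(tree.bipartitions())
            expected = {tree._canonical(frozenset(s)) for s in splits}
            assert got == expected

    def test_agrees_with_scikit_bio(self):
        import io

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(77)
        labels, _, values = random_additive_tree(rng, 6)
        noise = rng.uniform(0, 0.05, values.shape)
        values = values + noise + noise.T
        np.fill_diagonal(values, 0.0)
        ours = neighbor_joining(DistanceMatrix(labels, values))
        theirs = skbio_nj(SkbioDM(values, ids=labels))
        theirs_tree = PhyloTree.from_newick(str(theirs))
        assert set(ours.bipartitions()) == set(theirs_tree.bipartitions())

    def test_invariant_to_label_permutation(self):
        rng = np.random.default_rng(21)
        labels, _, values = random_additive_tree(rng, 6)
        perm = rng.permutation(6)
        permuted = DistanceMatrix([labels[i] for i in perm], values[np.ix_(perm, perm)])
        a = neighbor_joining(DistanceMatrix(labels, values))
        b = neighbor_joining(permuted)
        assert set(a.bipartitions()) == set(b.bipartitions())


class TestNewickIO:
    def test_three_taxon_round_trip(self, tmp_path):
        tree = PhyloTree.from_newick("(A:1.5,B:2.25,C:0.5);")
        write_newick(tree, tmp_path / "t.nwk")
        back = read_newick(tmp_path / "t.nwk")
        assert leaf_edge_lengths(back) == leaf_edge_lengths(tree)

    def test_support_labels_survive_round_trip(self, tmp_path):
        tree = PhyloTree.from_newick("((A:1,B:1)87:0.5,(C:1,D:1)52:0.5,E:1);")
        write_newick(tree, tmp_path / "t.nwk")
        back = read_newick(tmp_path / "t.nwk")
        sups = {tuple(sorted(k)): v for k, v in back.bipartitions().items()}
        assert set(sups.values()) == {87.0, 52.0}

    def test_eight_leaf_bipartitions_preserved(self, tmp_path):
        rng = np.random.default_rng(30)
        labels, _, values = random_additive_tree(rng, 8)
        tree = neighbor_joining(DistanceMatrix(labels, values))
        write_newick(tree, tmp_path / "t.nwk")
        back = read_newick(tmp_path / "t.nwk")
        assert set(back.bipartitions()) == set(tree.bipartitions())
        a = leaf_edge_lengths(tree)
        b = leaf_edge_lengths(back)
        assert all(abs(a[k] - b[k]) < 1e-9 for k in a)


class TestConsensus:
    def test_identical_trees_full_support(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        cons = majority_consensus([t, t, t])
        assert set(cons.bipartitions()) == set(t.bipartitions())
        assert all(v == 100.0 for v in cons.bipartitions().values())

    def test_two_thirds_split_retained(self):
        t1 = PhyloTree.from_newick("((A,B),(C,D));")
        t2 = PhyloTree.from_newick("((A,B),(C,D));")
        t3 = PhyloTree.from_newick("((A,C),(B,D));")
        cons = majority_consensus([t1, t2, t3])
        bps = cons.bipartitions()
        key = cons._canonical(frozenset({"A", "B"}))
        assert bps[key] == pytest.approx(200 / 3, abs=0.05)

    def test_even_conflict_drops_both(self):
        t1 = PhyloTree.from_newick("((A,B),(C,D));")
        t2 = PhyloTree.from_newick("((A,C),(B,D));")
        cons = majority_consensus([t1, t2])
        assert cons.bipartitions() == {}

    def test_majority_keeps_all_splits_of_dominant_tree(self):
        rng = np.random.default_rng(31)
        labels, _, values = random_additive_tree(rng, 6)
        t = neighbor_joining(DistanceMatrix(labels, values))
        labels2, _, values2 = random_additive_tree(np.random.default_rng(99), 6)
        t2 = neighbor_joining(DistanceMatrix(labels, values2))
        cons = majority_consensus([t, t, t2])
        assert set(t.bipartitions()) <= set(cons.bipartitions())

    def test_leaf_set_mismatch_rejected(self):
        t1 = PhyloTree.from_newick("((A,B),(C,D));")
        t2 = PhyloTree.from_newick("((A,B),(C,E));")
        with pytest.raises(ValueError, match="leaf sets"):
            majority_consensus([t1, t2])


def hierarchical_matrix(n_windows=30, sites_per_window=10):
    """Deterministic genotypes with window-identical content: four populations
    with a clear ((A,B),(C,D)) structure in every window."""
    block = []
    for _ in range(n_windows):
        for s in range(sites_per_window):
            if s % 2 == 0:
                row = [0, 0, 0, 0, 2, 2, 2, 2]   # AB vs CD fixed difference
            else:
                row = [0, 0, 2, 2, 0, 0, 2, 2]   # A vs B and C vs D difference
            block.append(row)
    pos = np.arange(len(block)) * (1000 // sites_per_window) + 1
    # spread windows 1 kb apart
    pos = np.concatenate([
        np.arange(sites_per_window) * 90 + w * 1000 + 1 for w in range(n_windows)
    ])
    return make_matrix(np.array(block, dtype=np.int8), pos=pos), make_popmap(
        {"A": 2, "B": 2, "C": 2, "D": 2}
    )


class TestFstDistanceAndBootstrap:
    def test_identical_populations_have_near_zero_distance(self):
        rng = np.random.default_rng(40)
        p = rng.uniform(0.2, 0.8, 200)
        geno = rng.binomial(2, p[:, None], (200, 20)).astype(np.int8)
        matrix = make_matrix(geno, pos=np.arange(1, 201) * 10)
        d = fst_distance_matrix(matrix, make_popmap({"A": 10, "B": 10}), window_size=1000)
        assert d[("A", "B")] < 0.02

    def test_matches_direct_weir_fst_calls(self):
        from camelscan import popstats

        rng = np.random.default_rng(41)
        geno = rng.integers(0, 3, (100, 12)).astype(np.int8)
        matrix = make_matrix(geno, pos=np.arange(1, 101) * 10)
        popmap = make_popmap({"A": 4, "B": 4, "C": 4})
        windows = popstats.windows_from_matrix(matrix, 500)
        d = fst_distance_matrix(matrix, popmap, windows)
        for a, b in (("A", "B"), ("A", "C"), ("B", "C")):
            df, _ = popstats.weir_fst(matrix, popmap, a, b, windows)
            expected = max(np.nanmean(df.value), 0.0)
            assert d[(a, b)] == pytest.approx(expected, abs=1e-12)

    def test_population_with_single_sample_rejected(self):
        matrix = make_matrix(np.zeros((10, 3), dtype=np.int8))
        with pytest.raises(ValueError, match="fewer than 2"):
            fst_distance_matrix(matrix, make_popmap({"A": 2, "B": 1}))

    def test_zero_variance_data_gives_full_support(self):
        matrix, popmap = hierarchical_matrix()
        tree, reps = bootstrap_support(
            matrix, popmap, n_windows=8, window=1000, min_spacing=0,
            replicates=20, seed=5,
        )
        bps = tree.bipartitions()
        assert bps and all(v == 100.0 for v in bps.values())

    def test_two_populations_have_no_internal_bipartitions(self):
        matrix, _ = hierarchical_matrix()
        popmap = make_popmap({"A": 4, "B": 4})
        tree, _ = bootstrap_support(
            matrix, popmap, n_windows=8, window=1000, min_spacing=0,
            replicates=5, seed=5,
        )
        assert tree.bipartitions() == {}

    def test_infeasible_spacing_reports_maximum(self):
        matrix, popmap = hierarchical_matrix()
        with pytest.raises(ValueError, match="maximum feasible"):
            bootstrap_support(
                matrix, popmap, n_windows=1000, window=1000,
                min_spacing=10_000, replicates=2, seed=0,
            )

    def test_default_scenario_orders_populations_by_drift(self, default_sim):
        _, matrix, popmap, _, _ = default_sim
        sub = matrix.take(np.arange(0, matrix.n_sites, 5))
        d = fst_distance_matrix(sub, popmap, window_size=50_000)
        assert d[("drom", "MG")] > d[("wild", "MG")] > d[("IRAN", "MG")] > d[("MG", "IMG")]
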