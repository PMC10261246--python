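"""Neighbour joining, rooting, bipartitions, bootstrap and local trees."""

import numpy as np
import pytest

from utaka.containers import DistanceMatrix
from utaka.distances import WindowDistanceSet
from utaka.trees import (
    block_bootstrap_support,
    contains_bipartition,
    local_tree_support_fraction,
    neighbor_joining,
    parse_newick,
    root_by_outgroup,
)

from conftest import random_additive_tree


def dm(labels, values):
    return DistanceMatrix(list(labels), np.asarray(values, dtype=float))


THREE_TAXON = dm("ABC", [[0, 5, 9], [5, 0, 10], [9, 10, 0]])


def test_three_taxon_closed_form():
    tree = neighbor_joining(THREE_TAXON)
    center = max(tree.adj, key=lambda u: len(tree.adj[u]))
    lengths = {tree.leaf_labels[v]: w for v, w in tree.adj[center].items()}
    assert lengths == pytest.approx({"A": 2.0, "B": 3.0, "C": 7.0})


def test_four_taxon_additive_recovery():
    """AB|CD topology and exact branch lengths from an additive matrix."""
    values = [[0, 3, 3.5, 4.5], [3, 0, 4.5, 5.5],
              [3.5, 4.5, 0, 4], [4.5, 5.5, 4, 0]]
    tree = neighbor_joining(dm("ABCD", values))
    assert contains_bipartition(tree, {"A", "B"})
    assert not contains_bipartition(tree, {"A", "C"})
    for i, a in enumerate("ABCD"):
        for j, b in enumerate("ABCD"):
            if i < j:
                assert tree.path_length(a, b) == pytest.approx(values[i][j], abs=1e-12)


def test_identical_rows_join_first_with_zero_branches():
    values = [[0, 0, 4, 5], [0, 0, 4, 5], [4, 4, 0, 3], [5, 5, 3, 0]]
    tree = neighbor_joining(dm("ABCD", values))
    assert contains_bipartition(tree, {"A", "B"})
    assert tree.path_length("A", "B") == pytest.approx(0.0, abs=1e-12)


def test_too_few_taxa_and_asymmetry_are_errors():
    with pytest.raises(ValueError):
        neighbor_joining(dm("AB", [[0, 1], [1, 0]]))
    bad = DistanceMatrix.__new__(DistanceMatrix)
    bad.labels = ["A", "B", "C"]
    bad.values = np.array([[0, 1, 2], [1.1, 0, 1], [2, 1, 0.0]])
    with pytest.raises(ValueError):
        neighbor_joining(bad)


def test_nj_consistent_on_random_additive_matrices():
    """Topology and path lengths reproduce the generating tree (spot sample)."""
    rng = np.random.default_rng(123)
    for _ in range(20):
        n = int(rng.integers(4, 13))
        labels, D, bips = random_additive_tree(rng, n)
        tree = neighbor_joining(dm(labels, D))
        assert tree.bipartitions() == bips
        for i in range(n):
            for j in range(i + 1, n):
                assert tree.path_length(labels[i], labels[j]) == pytest.approx(
                    D[i, j], abs=1e-9
                )


def test_nj_topology_matches_biopython_oracle():
    """Unrooted topology agrees with Bio.Phylo's NJ on a noisy matrix."""
    from Bio.Phylo.TreeConstruction import DistanceMatrix as BioDM
    from Bio.Phylo.TreeConstruction import DistanceTreeConstructor

    rng = np.random.default_rng(5)
    labels, D, _ = random_additive_tree(rng, 8)
    noisy = D + rng.normal(0, 0.01, D.shape)
    noisy = (noisy + noisy.T) / 2
    np.fill_diagonal(noisy, 0.0)

    tree = neighbor_joining(dm(labels, noisy))

    bio_dm = BioDM(
        names=labels,
        matrix=[[float(noisy[i, j]) for j in range(i + 1)] for i in range(len(labels))],
    )
    bio_tree = DistanceTreeConstructor().nj(bio_dm)
    bio_bips = set()
    leaves = frozenset(labels)
    for clade in bio_tree.find_clades():
        names = frozenset(t.name for t in clade.get_terminals())
        if 0 < len(names) < len(labels):
            bio_bips.add(names)
            bio_bips.add(leaves - names)
    assert tree.bipartitions() == bio_bips


def test_rooting_splits_outgroup_branch_at_midpoint():
    tree = root_by_outgroup(neighbor_joining(THREE_TAXON), "C")
    root_edges = tree.adj[tree.root]
    assert sorted(root_edges.values()) == pytest.approx([3.5, 3.5])
    assert contains_bipartition(tree, {"A", "B"})


def test_rooting_preserves_path_lengths_and_is_idempotent():
    rng = np.random.default_rng(9)
    labels, D, _ = random_additive_tree(rng, 7)
    tree = neighbor_joining(dm(labels, D))
    rooted = root_by_outgroup(tree, labels[0])
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            assert rooted.path_length(labels[i], labels[j]) == pytest.approx(
                tree.path_length(labels[i], labels[j]), abs=1e-12
            )
    again = root_by_outgroup(rooted, labels[0])
    assert again.path_length(labels[0], labels[1]) == pytest.approx(
        rooted.path_length(labels[0], labels[1]), abs=1e-12
    )
    assert len(again.adj) == len(rooted.adj)


def test_rooting_unknown_label_is_error():
    with pytest.raises(KeyError):
        root_by_outgroup(neighbor_joining(THREE_TAXON), "Z")


def test_contains_bipartition_examples():
    tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
    assert contains_bipartition(tree, {"A", "B"})
    assert contains_bipartition(tree, {"C", "D"})
    assert not contains_bipartition(tree, {"A", "C"})
    with pytest.raises(ValueError):
        contains_bipartition(tree, {"A", "B", "C", "D"})
    with pytest.raises(ValueError):
        contains_bipartition(tree, {"A", "X"})


def test_bipartitions_match_dendropy_oracle():
    """Edge-induced splits agree with dendropy's bipartition encoding."""
    import dendropy

    rng = np.random.default_rng(31)
    for _ in range(10):
        labels, D, _ = random_additive_tree(rng, 8)
        tree = neighbor_joining(dm(labels, D))
        newick = tree.to_newick()
        dt = dendropy.Tree.get(data=newick, schema="newick")
        dt.encode_bipartitions()
        taxa = frozenset(labels)
        oracle = set()
        for edge in dt.preorder_edge_iter():
            if edge.bipartition is None:
                continue
            side = frozenset(
                t.label for t in dt.taxon_namespace
                if edge.bipartition.leafset_bitmask
                & dt.taxon_namespace.taxon_bitmask(t)
            )
            if 0 < len(side) < len(labels):
                oracle.add(side)
                oracle.add(taxa - side)
        assert tree.bipartitions() == oracle


def make_wds(matrices, denom=1_000.0, labels=None):
    """WindowDistanceSet whose per-window ratios equal the given matrices."""
    matrices = [np.asarray(m, dtype=float) for m in matrices]
    n = matrices[0].shape[0]
    labels = labels or [f"s{i}" for i in range(n)]
    W = len(matrices)
    diff = np.stack([m * denom for m in matrices])
    den = np.full((W, n, n), denom)
    for w in range(W):
        np.fill_diagonal(den[w], 0.0)
        np.fill_diagonal(diff[w], 0.0)
    het = np.zeros((W, n))
    hden = np.full((W, n), denom)
    return WindowDistanceSet(
        samples=labels, windows=[("1", w * 1000) for w in range(W)],
        diff_counts=diff, pair_denominators=den,
        het_counts=het, het_denominators=hden,
    )


CLEAN_SPLIT = np.array(
    [[0.0, 0.1, 1.0, 1.0], [0.1, 0.0, 1.0, 1.0],
     [1.0, 1.0, 0.0, 0.1], [1.0, 1.0, 0.1, 0.0]]
) * 0.01


def test_bootstrap_identical_windows_give_full_support():
    wds = make_wds([CLEAN_SPLIT] * 10)
    for reps in (10, 57):
        (res,) = block_bootstrap_support(wds, [{"s0", "s1"}], replicates=reps, seed=3)
        assert res.support == 100.0
        assert res.replicates == reps


def test_bootstrap_is_deterministic_given_seed(small_wds, pop_labels):
    a, _ = pop_labels
    r1 = block_bootstrap_support(small_wds, [a], replicates=25, seed=42, net=True)
    r2 = block_bootstrap_support(small_wds, [a], replicates=25, seed=42, net=True)
    assert [x.support for x in r1] == [x.support for x in r2]
    r3 = block_bootstrap_support(small_wds, [a], replicates=25, seed=43, net=True)
    assert r3[0].replicates == 25  # different seed still valid, support in range
    assert 0.0 <= r3[0].support <= 100.0


def test_bootstrap_support_monotone_in_internal_branch():
    """Longer internal branches cannot lose support under resampling noise."""
    rng = np.random.default_rng(7)
    supports = []
    for internal in (0.0005, 0.002, 0.02):
        base = np.array(
            [[0.0, 0.01, 0.02 + internal, 0.02 + internal],
             [0.01, 0.0, 0.02 + internal, 0.02 + internal],
             [0.02 + internal, 0.02 + internal, 0.0, 0.01],
             [0.02 + internal, 0.02 + internal, 0.01, 0.0]]
        )
        noise_sd = 0.004
        mats = []
        for _ in range(30):
            e = rng.normal(0, noise_sd, base.shape)
            e = (e + e.T) / 2
            np.fill_diagonal(e, 0)
            mats.append(np.clip(base + e, 0, None))
        wds = make_wds(mats)
        (res,) = block_bootstrap_support(wds, [{"s0", "s1"}], replicates=100, seed=1)
        supports.append(res.support)
    assert supports == sorted(supports)
    assert supports[-1] == 100.0


def test_local_tree_support_planted_fixture():
    """7 windows separating the groups, 3 scrambled: fraction = 0.7."""
    scrambled = np.array(
        [[0.0, 1.0, 0.1, 1.0], [1.0, 0.0, 1.0, 0.1],
         [0.1, 1.0, 0.0, 1.0], [1.0, 0.1, 1.0, 0.0]]
    ) * 0.01
    wds = make_wds([CLEAN_SPLIT] * 7 + [scrambled] * 3)
    a, b = {"s0", "s1"}, {"s2", "s3"}
    assert local_tree_support_fraction(wds, a, b) == pytest.approx(0.7)
    assert local_tree_support_fraction(wds, b, a) == pytest.approx(0.7)


def test_local_tree_support_single_clean_window():
    wds = make_wds([CLEAN_SPLIT])
    assert local_tree_support_fraction(wds, {"s0", "s1"}, {"s2", "s3"}) == 1.0


def test_local_tree_support_excludes_outgroup_by_default(small_wds, pop_labels):
    a, b = pop_labels
    frac = local_tree_support_fraction(small_wds, a, b)
    assert 0.0 <= frac <= 1.0


def test_local_tree_support_overlapping_groups_error(small_wds, pop_labels):
    a, _ = pop_labels
    with pytest.raises(ValueError):
        local_tree_support_fraction(small_wds, a, a)


def test_ils_increases_at_shallower_splits():
    """Local gene-tree support falls toward zero as the split becomes younger."""
    from utaka.filtering import build_accessibility
    from utaka.distances import window_distances
    from utaka.simulate import GenSimConfig, simulate_split_genotypes

    means = []
    for t_split in (1_000, 10_000, 50_000):
        fracs = []
        for rep in range(8):
            cfg = GenSimConfig(
                n_per_pop=4, n_outgroup=1, ne=10_000, t_split=t_split,
                t_outgroup=500_000, n_windows=20, seed=100 * rep + t_split,
            )
            m, _ = simulate_split_genotypes(cfg)
            wds = window_distances(
                m, build_accessibility(None, m.chrom_lengths, cfg.window_size)
            )
            a = {s for s in m.samples if s.startswith("A")}
            b = {s for s in m.samples if s.startswith("B")}
            fracs.append(local_tree_support_fraction(wds, a, b))
        means.append(np.mean(fracs))
    assert means[0] < means[1] < means[2]


def test_newick_round_trip():
    tree = neighbor_joining(THREE_TAXON)
    again = parse_newick(tree.to_newick())
    assert again.leaves == tree.leaves
    assert again.path_length("A", "C") == pytest.approx(9.0)
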