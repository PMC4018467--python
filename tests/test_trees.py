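"""Clustering, neighbour joining, bootstrap, concordance, Newick IO."""

import numpy as np
import pytest
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from conftest import random_additive_tree
from drbstr.distances import DistanceMatrix
from drbstr.trees import (
    Dendrogram,
    bootstrap_support,
    compare_groupings,
    from_newick,
    hclust,
    nj_tree,
    p_distance_matrix,
    to_newick,
    tree_bipartitions,
    tree_cut,
)


def dm_from(labels, values, metric="manhattan", mode="size"):
    return DistanceMatrix(tuple(labels), np.asarray(values, dtype=float), metric, mode)


def alignment_from(rows):
    return MultipleSeqAlignment(
        SeqRecord(Seq(s), id=f"s{i}", description="") for i, s in enumerate(rows)
    )


# -- hierarchical clustering -------------------------------------------------

def test_two_labels_merge_at_their_distance():
    dm = dm_from("AB", [[0, 5], [5, 0]])
    for linkage in ("single", "complete"):
        dend = hclust(dm, linkage)
        assert dend.heights.tolist() == [5.0]
        assert dend.to_newick() == "(A:2.5,B:2.5);"


def test_three_label_merge_heights_by_hand():
    # d(A,B)=1, d(A,C)=2, d(B,C)=3: single merges at (1, 2); complete at (1, 3)
    dm = dm_from("ABC", [[0, 1, 2], [1, 0, 3], [2, 3, 0]])
    assert hclust(dm, "single").heights.tolist() == [1.0, 2.0]
    assert hclust(dm, "complete").heights.tolist() == [1.0, 3.0]


def test_merge_heights_are_monotone_on_random_matrices():
    rng = np.random.default_rng(2)
    for _ in range(10):
        n = int(rng.integers(4, 15))
        x = rng.random((n, 3))
        v = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        dm = dm_from([f"l{i}" for i in range(n)], v)
        for linkage in ("single", "complete"):
            h = hclust(dm, linkage).heights
            assert (np.diff(h) >= -1e-12).all()


def test_hclust_rejects_bad_linkage_and_asymmetry():
    dm = dm_from("AB", [[0, 5], [5, 0]])
    with pytest.raises(ValueError):
        hclust(dm, "average")
    with pytest.raises(ValueError):
        dm_from("AB", [[0, 5], [4, 0]])


# -- neighbour joining -------------------------------------------------------

def test_nj_recovers_four_taxon_additive_tree_exactly():
    # tree ((A:1,B:2):1,(C:3,D:1)); path-sum distances:
    labels = ["A", "B", "C", "D"]
    v = [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]]
    tree = nj_tree(dm_from(labels, v))
    tips = {t.name: t for t in tree.tree.tips()}
    td = tree.tree.tip_tip_distances()
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            assert td[a, b] == pytest.approx(v[i][j], abs=1e-9)
    splits = tree_bipartitions(tree.tree)
    assert frozenset([frozenset("AB"), frozenset("CD")]) in splits
    assert tips["A"].length == pytest.approx(1.0)
    assert tips["B"].length == pytest.approx(2.0)


def test_nj_star_tree_has_zero_internal_branches():
    v = np.full((4, 4), 2.0)
    np.fill_diagonal(v, 0.0)
    tree = nj_tree(dm_from("ABCD", v))
    assert tree_bipartitions(tree.tree) == set()  # zero-length edges collapse


def test_nj_is_invariant_to_label_order():
    rng = np.random.default_rng(8)
    _, dm, splits = random_additive_tree(rng, 7)
    labels = [f"t{i}" for i in range(7)]
    t1 = nj_tree(dm_from(labels, dm))
    perm = rng.permutation(7)
    t2 = nj_tree(dm_from([labels[i] for i in perm], dm[np.ix_(perm, perm)]))
    assert tree_bipartitions(t1.tree) == tree_bipartitions(t2.tree)


@pytest.mark.parametrize("seed", range(6))
def test_nj_exact_on_random_additive_matrices(seed):
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(7, 13))
    taxa, dm, true_splits = random_additive_tree(rng, n)
    tree = nj_tree(dm_from(taxa, dm))
    td = tree.tree.tip_tip_distances()
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            assert td[a, b] == pytest.approx(dm[i, j], abs=1e-8)
    assert tree_bipartitions(tree.tree) == true_splits


def test_nj_requires_three_labels():
    with pytest.raises(ValueError):
        nj_tree(dm_from("AB", [[0, 1], [1, 0]]))


# -- bootstrap ---------------------------------------------------------------

def test_bootstrap_on_identical_sequences_has_no_supported_groups():
    aln = alignment_from(["ACGTACGTAC"] * 5)
    tree = bootstrap_support(aln, n=20, seed=1)
    assert all(v < tree.support_threshold for v in tree.supports.values())


def test_bootstrap_strong_signal_and_determinism():
    # two 4-taxon clans separated by 30 fixed differences
    left, right = "A" * 30, "G" * 30
    noise = "ACGT" * 5
    aln = alignment_from([left + noise] * 4 + [right + noise] * 4)
    t1 = bootstrap_support(aln, n=100, seed=42)
    clan = frozenset(f"s{i}" for i in range(4))
    others = frozenset(f"s{i}" for i in range(4, 8))
    split = frozenset([clan, others])
    assert t1.supports[split] >= 95.0
    t2 = bootstrap_support(aln, n=100, seed=42)
    assert t1.supports == t2.supports


def test_bootstrap_preconditions():
    aln = alignment_from(["ACGT", "ACGA", "ACGG"])
    with pytest.raises(ValueError):
        bootstrap_support(aln, n=10, seed=0)


# -- concordance -------------------------------------------------------------

def test_tree_compared_with_itself():
    rng = np.random.default_rng(3)
    taxa, dm, _ = random_additive_tree(rng, 8)
    tree = nj_tree(dm_from(taxa, dm))
    res = compare_groupings(tree, tree, k=3)
    assert res.ari == pytest.approx(1.0)
    assert res.shared_bipartitions == res.n_bipartitions_a == res.n_bipartitions_b


def test_conflicting_caterpillars_share_no_bipartitions():
    # caterpillar on A..F vs the reversed-ladder pairing
    a = from_newick("((((A:1,B:1):1,C:1):1,D:1):1,(E:1,F:1):1);")
    b = from_newick("((((A:1,F:1):1,E:1):1,D:1):1,(C:1,B:1):1);")
    res = compare_groupings(a, b, k=3)
    assert res.shared_bipartitions == 0
    assert res.n_bipartitions_a > 0 and res.n_bipartitions_b > 0


def test_ari_of_random_permutations_is_near_zero():
    rng = np.random.default_rng(4)
    labels = [f"x{i}" for i in range(24)]
    truth = {lab: f"g{i % 6}" for i, lab in enumerate(labels)}
    from sklearn.metrics import adjusted_rand_score

    base = [truth[lab] for lab in labels]
    aris = []
    for _ in range(100):
        perm = rng.permutation(len(labels))
        aris.append(adjusted_rand_score(base, [base[i] for i in perm]))
    assert abs(float(np.mean(aris))) <= 0.05


def test_leaf_set_mismatch_raises():
    a = from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    b = from_newick("((A:1,B:1):1,(C:1,E:1):1);")
    with pytest.raises(ValueError):
        compare_groupings(a, b, k=2)


def test_tree_cut_splits_longest_edges_first():
    tree = from_newick("((A:1,B:1):10,(C:1,D:1):10,(E:1,F:1):0.1);")
    cut = tree_cut(tree.tree, 3)
    groups = {}
    for leaf, g in cut.items():
        groups.setdefault(g, set()).add(leaf)
    assert {frozenset(g) for g in groups.values()} == {
        frozenset("AB"),
        frozenset("CD"),
        frozenset("EF"),
    }


# -- Newick IO ---------------------------------------------------------------

def test_newick_round_trip_on_random_trees():
    rng = np.random.default_rng(9)
    for _ in range(20):
        n = int(rng.integers(4, 10))
        taxa, dm, _ = random_additive_tree(rng, n)
        tree = nj_tree(dm_from(taxa, dm))
        again = from_newick(to_newick(tree))
        assert tree_bipartitions(again.tree) == tree_bipartitions(tree.tree)


def test_support_labels_survive_round_trip():
    aln = alignment_from(
        ["A" * 20 + "ACGTACGT"] * 4 + ["G" * 20 + "ACGTACGT"] * 4
    )
    tree = bootstrap_support(aln, n=50, seed=5)
    again = from_newick(to_newick(tree))
    for split, val in tree.supports.items():
        if split in again.supports:
            assert again.supports[split] == pytest.approx(val, abs=0.5)
    assert again.supports  # at least the strong split label survived


def test_malformed_newick_raises():
    with pytest.raises(ValueError, match="Newick"):
        from_newick("((A:1,B:1;")


def test_dendrogram_newick_is_ultrametric_under_midpoint_convention():
    dm = dm_from("AB", [[0, 5], [5, 0]])
    assert hclust(dm, "single").to_newick() == "(A:2.5,B:2.5);"
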