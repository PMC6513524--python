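import numpy as np
import pytest

import dendropy

from levikit.cluster import (
    cophenetic_matrix,
    cut_tree,
    leaf_order_and_heatmap,
    threshold_sweep,
    to_newick,
    upgma,
)
from levikit.similarity import BsrMatrix, DistanceMatrix, build_bsr

from oracles import scipy_cophenetic


def three_leaf():
    d = np.array([[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]])
    return DistanceMatrix(["A", "B", "C"], d)


def test_three_leaf_agglomeration_and_newick():
    tree = upgma(three_leaf())
    heights = [h for h, _, _ in tree.merge_order]
    assert heights == pytest.approx([0.1, 0.4])
    assert to_newick(tree) == "((A:0.1,B:0.1):0.3,C:0.4);"


def test_two_leaf_tree():
    d = DistanceMatrix(["A", "B"], np.array([[0.0, 0.1], [0.1, 0.0]]))
    assert to_newick(upgma(d)) == "(A:0.05,B:0.05);"


def test_rejects_invalid_input():
    bad = np.array([[0.0, 0.5], [0.4, 0.0]])
    with pytest.raises(ValueError):
        DistanceMatrix(["A", "B"], bad)


def test_upgma_matches_scipy_reference():
    rng = np.random.default_rng(1)
    for _ in range(60):
        n = int(rng.integers(2, 13))
        m = rng.uniform(0.05, 1.0, size=(n, n))
        d = np.triu(m, 1)
        d = d + d.T
        ids = [f"t{i}" for i in range(n)]
        tree = upgma(DistanceMatrix(ids, d))
        coph = cophenetic_matrix(tree)
        reindex = [coph.ids.index(i) for i in ids]
        mine = coph.dist[np.ix_(reindex, reindex)]
        assert np.allclose(mine, scipy_cophenetic(d), atol=1e-9)


def test_ultrametricity():
    rng = np.random.default_rng(2)
    n = 9
    m = rng.uniform(0.05, 1.0, size=(n, n))
    d = np.triu(m, 1)
    d = d + d.T
    tree = upgma(DistanceMatrix([f"t{i}" for i in range(n)], d))

    def depths(node, acc):
        if node.is_leaf:
            yield acc + node.height  # leaf height is 0
        else:
            for child in node.children:
                yield from depths(child, acc + (node.height - child.height))

    root = tree.root
    leaf_depths = list(depths(root, 0.0)) if not root.is_leaf else [0.0]
    # path length from root to each leaf equals the root height
    assert np.allclose(leaf_depths, root.height, atol=1e-9)


def test_cophenetic_fixed_point_on_ultrametric_input():
    rng = np.random.default_rng(3)
    n = 8
    m = rng.uniform(0.05, 1.0, size=(n, n))
    d = np.triu(m, 1)
    d = d + d.T
    coph = cophenetic_matrix(upgma(DistanceMatrix([f"t{i}" for i in range(n)], d)))
    again = cophenetic_matrix(upgma(coph))
    reindex = [again.ids.index(i) for i in coph.ids]
    assert np.allclose(again.dist[np.ix_(reindex, reindex)], coph.dist, atol=1e-9)


def test_newick_round_trip():
    rng = np.random.default_rng(4)
    n = 7
    m = rng.uniform(0.05, 1.0, size=(n, n))
    d = np.triu(m, 1)
    d = d + d.T
    ids = [f"t{i}" for i in range(n)]
    tree = upgma(DistanceMatrix(ids, d))
    parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
    pdm = parsed.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in parsed.taxon_namespace}
    coph = cophenetic_matrix(tree)
    for i, a in enumerate(coph.ids):
        for j, b in enumerate(coph.ids):
            if i < j:
                got = pdm.patristic_distance(taxa[a], taxa[b])
                assert got == pytest.approx(coph.dist[i, j], abs=1e-9)


def test_cut_tree_thresholds():
    tree = upgma(three_leaf())
    groups = cut_tree(tree, 0.5)
    assert groups.n_groups == 2
    assert groups.groups["A"] == groups.groups["B"] != groups.groups["C"]
    assert cut_tree(tree, 1.0).n_groups == 1
    assert cut_tree(tree, 0.0).n_groups == 3
    with pytest.raises(ValueError):
        cut_tree(tree, 1.5)


def test_tie_breaking_is_deterministic():
    # four leaves all at equal distance: merges follow original index order
    d = np.full((4, 4), 0.6)
    np.fill_diagonal(d, 0.0)
    tree = upgma(DistanceMatrix(list("ABCD"), d))
    assert to_newick(tree, branch_lengths=False) == "(((A,B),C),D);"


def test_leaf_order_and_heatmap_permutes_consistently(family_data):
    records, truth = family_data
    subset = records[:4] + records[5:9]
    _, bsr, dist = build_bsr(subset)
    tree = upgma(dist)
    order, heatmap = leaf_order_and_heatmap(tree, bsr)
    assert sorted(order) == sorted(bsr.ids)
    assert np.allclose(np.diag(heatmap), 1.0)
    # planted two-family structure shows as contiguous blocks in leaf order
    families = [truth[name] for name in order]
    assert families == sorted(families) or families == sorted(families, reverse=True)


def test_leaf_order_id_mismatch_errors():
    tree = upgma(three_leaf())
    bsr = BsrMatrix(["X", "Y", "Z"], np.eye(3))
    with pytest.raises(ValueError, match="ids differ"):
        leaf_order_and_heatmap(tree, bsr)


def test_planted_families_recovered(family_data):
    records, truth = family_data
    _, _, dist = build_bsr(records)
    groups = cut_tree(upgma(dist), 0.7)
    # the partition must equal the planted one (labels may differ)
    by_group: dict[str, set] = {}
    for name, label in groups.groups.items():
        by_group.setdefault(label, set()).add(truth[name])
    assert groups.n_groups == 3
    assert all(len(v) == 1 for v in by_group.values())


def test_threshold_sweep_monotone(family_data):
    records, _ = family_data
    _, _, dist = build_bsr(records[:8])
    sweep = threshold_sweep(upgma(dist))
    counts = [k for _, k in sweep]
    assert counts[0] == 8 and counts[-1] == 1
    assert all(a >= b for a, b in zip(counts, counts[1:]))
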