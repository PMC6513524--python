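"""UPGMA dendrogram construction, Newick export, tree cutting, leaf order.

UPGMA (unweighted pair-group method with arithmetic mean) repeatedly merges
the two clusters with the smallest average-linkage distance; the merged
node's height is half that distance, so the tree is ultrametric: every leaf
lies at distance ``height`` below each ancestor of height ``height``.

Ties are broken deterministically: among pairs at the minimal distance the
pair whose smallest original leaf index is lowest wins, then the smallest
second index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .similarity import BsrMatrix, DistanceMatrix


@dataclass
class TreeNode:
    """A node of the rooted binary UPGMA tree (leaves carry ids)."""

    height: float
    id: str | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def leaf_ids(self) -> list[str]:
        return [leaf.id for leaf in self.leaves()]


@dataclass
class UpgmaTree:
    """Rooted ultrametric dendrogram plus its merge trace."""

    root: TreeNode
    ids: list[str]
    #: (height, member leaf-index tuples) per merge, in merge order.
    merge_order: list[tuple[float, tuple[int, ...], tuple[int, ...]]] = field(
        default_factory=list
    )

    def leaf_order(self) -> list[str]:
        return self.root.leaf_ids()


def upgma(dist: DistanceMatrix) -> UpgmaTree:
    """Build the UPGMA tree from a symmetric zero-diagonal dissimilarity."""
    d = np.asarray(dist.dist, dtype=float)
    n = len(dist.ids)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if np.any(d < 0) or not np.allclose(d, d.T):
        raise ValueError("input must be a symmetric non-negative matrix")

    # active clusters: key -> (node, size, member leaf indices)
    clusters: dict[int, tuple[TreeNode, int, tuple[int, ...]]] = {
        i: (TreeNode(0.0, id=dist.ids[i]), 1, (i,)) for i in range(n)
    }
    # distances between active clusters, averaged over leaf pairs
    dd: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merge_order: list[tuple[float, tuple[int, ...], tuple[int, ...]]] = []
    next_key = n
    while len(clusters) > 1:
        # minimal distance with deterministic tie-break on original indices
        best_pair = None
        best = (np.inf, (np.inf,), (np.inf,))
        for (i, j), value in dd.items():
            mi, mj = clusters[i][2], clusters[j][2]
            lo, hi = (mi, mj) if min(mi) < min(mj) else (mj, mi)
            cand = (value, (min(lo),), (min(hi),))
            if cand < best:
                best = cand
                best_pair = (i, j)
        i, j = best_pair
        dij = dd[(i, j)]
        node_i, size_i, mem_i = clusters[i]
        node_j, size_j, mem_j = clusters[j]
        # child order: smaller original leaf index first (determinism)
        if min(mem_i) > min(mem_j):
            node_i, node_j = node_j, node_i
            mem_i, mem_j = mem_j, mem_i
        parent = TreeNode(dij / 2.0, children=(node_i, node_j))
        merge_order.append((dij / 2.0, mem_i, mem_j))
        members = tuple(sorted(mem_i + mem_j))
        del clusters[i], clusters[j]
        # size-weighted average linkage update
        new_dd: dict[tuple[int, int], float] = {}
        for (a, b), value in dd.items():
            if i in (a, b) or j in (a, b):
                continue
            new_dd[(a, b)] = value
        for k in clusters:
            dik = dd[(min(i, k), max(i, k))]
            djk = dd[(min(j, k), max(j, k))]
            new_dd[(min(k, next_key), max(k, next_key))] = (
                size_i * dik + size_j * djk
            ) / (size_i + size_j)
        dd = new_dd
        clusters[next_key] = (parent, size_i + size_j, members)
        next_key += 1
    (root, _, _) = next(iter(clusters.values()))
    return UpgmaTree(root=root, ids=list(dist.ids), merge_order=merge_order)


def _quote_newick(name: str) -> str:
    if any(c in name for c in "()[]{}:;,= \t'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: UpgmaTree, branch_lengths: bool = True) -> str:
    """Serialize to Newick; branch length = parent height − child height."""

    def render(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            label = _quote_newick(node.id)
        else:
            inner = ",".join(render(c, node.height) for c in node.children)
            label = f"({inner})"
        if branch_lengths and parent_height is not None:
            label += f":{parent_height - node.height:.12g}"
        return label

    return render(tree.root, None) + ";"


@dataclass
class GroupAssignment:
    """A partition of leaf ids obtained by cutting the tree."""

    threshold: float
    groups: dict[str, str]

    @property
    def n_groups(self) -> int:
        return len(set(self.groups.values()))

    def partition(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for leaf, label in self.groups.items():
            out.setdefault(label, []).append(leaf)
        return out


def cut_tree(tree: UpgmaTree, threshold: float) -> GroupAssignment:
    """Cut at a cophenetic-distance threshold.

    Two leaves share a group iff the height of their lowest common ancestor
    is at most ``threshold / 2`` (cophenetic distance ≤ threshold).  Group
    labels are ``g1..gk`` assigned in dendrogram leaf order.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")

    clusters: list[list[str]] = []

    def collect(node: TreeNode) -> None:
        if node.is_leaf:
            clusters.append([node.id])
        elif node.height <= threshold / 2 + 1e-12:
            clusters.append(node.leaf_ids())
        else:
            for child in node.children:
                collect(child)

    collect(tree.root)
    groups: dict[str, str] = {}
    for k, members in enumerate(clusters, start=1):
        for leaf in members:
            groups[leaf] = f"g{k}"
    return GroupAssignment(threshold=threshold, groups=groups)


def cophenetic_matrix(tree: UpgmaTree) -> DistanceMatrix:
    """Tree-induced leaf distances (twice the LCA height)."""
    order = tree.leaf_order()
    index = {name: i for i, name in enumerate(order)}
    n = len(order)
    coph = np.zeros((n, n))

    def walk(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.id]
        left = walk(node.children[0])
        right = walk(node.children[1])
        for a in left:
            for b in right:
                coph[index[a], index[b]] = coph[index[b], index[a]] = (
                    2.0 * node.height
                )
        return left + right

    walk(tree.root)
    return DistanceMatrix(order, coph)


def leaf_order_and_heatmap(
    tree: UpgmaTree, bsr: BsrMatrix
) -> tuple[list[str], np.ndarray]:
    """Dendrogram leaf order and the BSR matrix permuted to it."""
    order = tree.leaf_order()
    if set(order) != set(bsr.ids):
        raise ValueError("tree leaves and BSR matrix ids differ")
    index = [bsr.ids.index(name) for name in order]
    permuted = np.asarray(bsr.bsr)[np.ix_(index, index)]
    return order, permuted


def threshold_sweep(
    tree: UpgmaTree, thresholds: Sequence[float] | None = None
) -> list[tuple[float, int]]:
    """Group count as a function of the cut threshold (sensitivity report)."""
    if thresholds is None:
        thresholds = [round(0.05 * i, 2) for i in range(21)]
    return [(t, cut_tree(tree, t).n_groups) for t in thresholds]
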