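"""Array-indexed view of a rooted binary tree for the numerical kernels.

dendropy trees are the user-facing container; the likelihood and signal
kernels need flat arrays (postorder node order, child indices, branch
lengths), which this module builds once per tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["IndexedTree", "index_tree", "as_indexed"]


@dataclass
class IndexedTree:
    """Flat representation of a rooted strictly binary tree.

    Nodes are numbered 0..n_nodes-1 with tips first (0..n_tips-1, in the
    order of ``tip_labels``).  ``children[i]`` holds the two child indices of
    internal node i (rows for tips are -1); ``blen[i]`` is the length of the
    edge above node i (0 for the root); ``postorder`` lists all nodes children
    before parents, so iterating it visits every internal node after both of
    its children.
    """

    tip_labels: list[str]
    parent: np.ndarray  # (n_nodes,) int, -1 at root
    children: np.ndarray  # (n_nodes, 2) int, -1 rows for tips
    blen: np.ndarray  # (n_nodes,) float
    postorder: np.ndarray  # (n_nodes,) int
    root: int

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def internal_postorder(self) -> np.ndarray:
        return self.postorder[self.postorder >= self.n_tips]

    @property
    def preorder(self) -> np.ndarray:
        return self.postorder[::-1]

    def tip_index(self, label: str) -> int:
        try:
            return self.tip_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown tip label {label!r}") from None

    def node_heights(self) -> np.ndarray:
        """Height (time above the tips) of every node, assuming ultrametricity."""
        depth = np.zeros(self.n_nodes)
        for i in self.preorder:
            p = self.parent[i]
            if p >= 0:
                depth[i] = depth[p] + self.blen[i]
        return depth.max() - depth

    def tipset_below(self) -> list[frozenset[int]]:
        """For every node, the set of tip indices in its subtree."""
        below: list[frozenset[int]] = [frozenset()] * self.n_nodes
        for i in self.postorder:
            if i < self.n_tips:
                below[i] = frozenset((i,))
            else:
                c1, c2 = self.children[i]
                below[i] = below[c1] | below[c2]
        return below

    def mrca(self, tip_indices: set[int] | frozenset[int]) -> int:
        """Most recent common ancestor (node index) of a set of tips."""
        want = frozenset(tip_indices)
        if not want:
            raise ValueError("empty tip set")
        below = self.tipset_below()
        candidates = [i for i in range(self.n_nodes) if want <= below[i]]
        return min(candidates, key=lambda i: len(below[i]))


def index_tree(tree: dendropy.Tree) -> IndexedTree:
    """Build the flat representation from a rooted binary dendropy tree."""
    leaves = [lf for lf in tree.leaf_node_iter()]
    tip_labels = [lf.taxon.label if lf.taxon else lf.label for lf in leaves]
    if len(set(tip_labels)) != len(tip_labels):
        raise ValueError("duplicate tip labels")
    n_tips = len(tip_labels)
    internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
    for nd in internals:
        if len(nd.child_nodes()) != 2:
            raise ValueError(
                f"tree is not strictly binary (node with {len(nd.child_nodes())} children)"
            )
    index: dict[int, int] = {}
    for i, lf in enumerate(leaves):
        index[id(lf)] = i
    for k, nd in enumerate(internals):
        index[id(nd)] = n_tips + k

    n_nodes = n_tips + len(internals)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children = np.full((n_nodes, 2), -1, dtype=np.int64)
    blen = np.zeros(n_nodes)
    post: list[int] = []
    for nd in tree.postorder_node_iter():
        i = index[id(nd)]
        post.append(i)
        if nd.edge.length is not None:
            blen[i] = float(nd.edge.length)
        if not nd.is_leaf():
            c1, c2 = nd.child_nodes()
            children[i, 0] = index[id(c1)]
            children[i, 1] = index[id(c2)]
            parent[index[id(c1)]] = i
            parent[index[id(c2)]] = i
    root = index[id(tree.seed_node)]
    blen[root] = 0.0
    return IndexedTree(
        tip_labels=tip_labels,
        parent=parent,
        children=children,
        blen=blen,
        postorder=np.asarray(post, dtype=np.int64),
        root=root,
    )


def as_indexed(tree: "dendropy.Tree | IndexedTree") -> IndexedTree:
    if isinstance(tree, IndexedTree):
        return tree
    return index_tree(tree)
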