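"""Array-backed view of dendropy trees for dynamic programming.

Every parsimony / pruning / contrast algorithm in this package walks the
same flattened structure: nodes in postorder, parent pointers, branch
lengths, and leaf labels.  Trees themselves are parsed and written with
dendropy (see :mod:`panne.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np


@dataclass
class TreeIndex:
    """Postorder-flattened rooted tree.

    Attributes
    ----------
    postorder : node indices in postorder (root last)
    parent : parent index per node (-1 for the root)
    blen : branch length of the edge above each node (0.0 at the root)
    children : list of child index lists
    leaf_labels : taxon label per node (None for internal nodes)
    """

    postorder: np.ndarray
    parent: np.ndarray
    blen: np.ndarray
    children: list[list[int]]
    leaf_labels: list[Optional[str]]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    @property
    def leaves(self) -> list[int]:
        return [i for i, lab in enumerate(self.leaf_labels) if lab is not None]

    @property
    def leaf_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.leaf_labels) if lab is not None}

    def total_length(self) -> float:
        return float(self.blen.sum())


def index_tree(tree: dendropy.Tree) -> TreeIndex:
    """Flatten a dendropy tree; missing branch lengths become 0."""
    nodes = list(tree.preorder_node_iter())
    idx = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n)
    children: list[list[int]] = [[] for _ in range(n)]
    labels: list[Optional[str]] = [None] * n
    for nd in nodes:
        i = idx[id(nd)]
        if nd.parent_node is not None:
            parent[i] = idx[id(nd.parent_node)]
            children[parent[i]].append(i)
        if nd.edge.length is not None:
            blen[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise ValueError("leaf without a taxon label")
            labels[i] = nd.taxon.label
    post = [idx[id(nd)] for nd in tree.postorder_node_iter()]
    return TreeIndex(np.asarray(post), parent, blen, children, labels)


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse one Newick string; duplicate leaf labels are an error."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        if "Duplicate taxon" in str(exc) or "Multiple occurrences" in str(exc):
            raise ValueError(f"duplicate leaf labels in Newick: {exc}") from exc
        raise
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def to_newick(tree: dendropy.Tree, precision: int = 12) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=f".{precision}g",
    ).strip()


def patristic_distances(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Leaf labels (sorted) and the matrix of path-length distances."""
    ti = index_tree(tree)
    labels = sorted(ti.leaf_index)
    li = ti.leaf_index
    n = len(labels)
    # distance to root for every node
    depth = np.zeros(ti.n_nodes)
    for i in ti.postorder[::-1]:
        p = ti.parent[i]
        if p >= 0:
            depth[i] = depth[p] + ti.blen[i]
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            i, j = li[labels[a]], li[labels[b]]
            # walk up to the MRCA
            ai, bj = i, j
            anc_a = set()
            while ai >= 0:
                anc_a.add(ai)
                ai = ti.parent[ai]
            mrca = bj
            while mrca not in anc_a:
                mrca = ti.parent[mrca]
            d = depth[i] + depth[j] - 2 * depth[mrca]
            dist[a, b] = dist[b, a] = d
    return labels, dist


def neighbor_joining_tree(labels: list[str], dist: np.ndarray) -> dendropy.Tree:
    """NJ fallback from a distance matrix (plumbing; skbio implementation)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(dist, ids=labels)
    sk = nj(dm)
    return parse_newick(str(sk))
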