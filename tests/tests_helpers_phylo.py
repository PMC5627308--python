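"""Shared oracle helpers for tree tests (independent of trcensus.phylo)."""

import itertools

import numpy as np

from trcensus import phylo
from trcensus.tree import TreeNode


def leaf_distances(tree):
    """Path-length distances between all leaf pairs (oracle helper)."""
    dists = {}
    leaves = tree.leaves()

    def path_to_root(node):
        path = {}
        total = 0.0
        while node is not None:
            path[id(node)] = total
            total += node.length
            node = node.parent
        return path

    paths = {leaf.name: path_to_root(leaf) for leaf in leaves}
    for a, b in itertools.combinations(leaves, 2):
        pb = paths[b.name]
        node = a
        total = 0.0
        best = None
        while node is not None:
            if id(node) in pb:
                best = total + pb[id(node)]
                break
            total += node.length
            node = node.parent
        dists[frozenset((a.name, b.name))] = best
    return dists


def random_additive_tree(rng, n_leaves):
    names = [f"L{i}" for i in range(n_leaves)]
    nodes = [TreeNode(name, float(rng.uniform(0.05, 1.0)))
             for name in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(None, float(rng.uniform(0.05, 1.0)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = TreeNode()
    for node in nodes:
        root.add_child(node)
    return root


def matrix_from_tree(tree):
    ids = sorted(tree.leaf_names())
    dists = leaf_distances(tree)
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = dists[frozenset((ids[i], ids[j]))]
    return phylo.DistanceMatrix(ids, m)
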