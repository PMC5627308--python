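"""Block selection, corrected distances, neighbor joining and tree checks.

Replaces the heavyweight phylogenetics stack at desk scale: conserved
alignment blocks are selected with the relaxed parameters (flank fraction
> 0.5, minimum block length 2, gaps allowed), distances are
Poisson-corrected p-distances, trees are built by Saitou-Nei neighbor
joining, rooted by the outgroup approach, and compared to the reference
taxonomy by Robinson-Foulds distance and per-leaf incongruence flags.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .box_motifs import MSA
from .errors import ValidationError
from .tree import TreeNode

logger = logging.getLogger(__name__)

#: distance cap: p-distances at or above this saturate the correction
SATURATION_P = 0.95


@dataclass
class BlockParameters:
    flank_min_fraction: float = 0.5
    min_block_length: int = 2
    gaps_allowed: bool = True


@dataclass
class BlockSelection:
    kept_columns: List[int]
    parameters: BlockParameters

    def runs(self) -> List[Tuple[int, int]]:
        """Maximal runs of kept columns as (start, end) inclusive."""
        runs = []
        for _k, grp in itertools.groupby(enumerate(self.kept_columns),
                                         key=lambda t: t[1] - t[0]):
            cols = [c for _i, c in grp]
            runs.append((cols[0], cols[-1]))
        return runs


@dataclass
class DistanceMatrix:
    ids: List[str]
    matrix: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(self.matrix < 0) or not np.all(np.isfinite(self.matrix)):
            raise ValidationError("distances must be finite and >= 0")


# -- block selection -------------------------------------------------------

def select_blocks(msa: MSA,
                  parameters: Optional[BlockParameters] = None
                  ) -> BlockSelection:
    """Keep maximal runs (length >= min) of flank-conserved columns.

    A column is flank-conserved iff its most frequent non-gap residue
    occurs in strictly more than ``flank_min_fraction`` of the sequences.
    With ``gaps_allowed`` false, any column containing a gap is dropped.
    """
    params = parameters or BlockParameters()
    if not msa.rows:
        raise ValidationError("empty MSA")
    n_rows = len(msa.rows)
    conserved = []
    for j in range(msa.column_count):
        column = [row[j] for row in msa.rows]
        if not params.gaps_allowed and "-" in column:
            conserved.append(False)
            continue
        counts: Dict[str, int] = {}
        for c in column:
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        top = max(counts.values()) if counts else 0
        conserved.append(top > params.flank_min_fraction * n_rows)
    kept: List[int] = []
    run: List[int] = []
    for j, good in enumerate(conserved + [False]):
        if good:
            run.append(j)
        else:
            if len(run) >= params.min_block_length:
                kept.extend(run)
            run = []
    return BlockSelection(kept, params)


# -- distances -------------------------------------------------------------

def protein_distance(row_a: str, row_b: str,
                     kept_columns: Sequence[int]) -> float:
    """Poisson-corrected distance d = -ln(1 - p) over comparable columns."""
    comparable = 0
    mismatches = 0
    for j in kept_columns:
        a, b = row_a[j], row_b[j]
        if a == "-" or b == "-":
            continue
        comparable += 1
        if a != b:
            mismatches += 1
    if comparable == 0:
        raise ValidationError("no mutually non-gap kept columns")
    p = mismatches / comparable
    if p >= SATURATION_P:
        logger.warning("p-distance %.3f saturated; capped at %.3f", p,
                       SATURATION_P)
        p = SATURATION_P
    return -math.log(1.0 - p)


def distance_matrix(msa: MSA, selection: BlockSelection) -> DistanceMatrix:
    n = len(msa.rows)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = protein_distance(msa.rows[i], msa.rows[j],
                                 selection.kept_columns)
            matrix[i, j] = matrix[j, i] = d
    return DistanceMatrix(list(msa.member_ids), matrix)


# -- neighbor joining ------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; unrooted (trifurcating root) tree.

    Ties in the Q criterion break on the lexicographically smallest pair
    of cluster representatives (the minimum leaf name per cluster), so
    the output is deterministic. Negative branch lengths are clamped to
    zero with the deficit moved to the sister branch.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValidationError("neighbor joining needs >= 3 leaves")
    nodes: List[TreeNode] = [TreeNode(name) for name in dm.ids]
    reps: List[str] = list(dm.ids)
    d = dm.matrix.astype(float).copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> Tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((reps[i], reps[j])))
                if (q < best_q - 1e-12
                        or (abs(q - best_q) <= 1e-12
                            and key < best[0])):  # type: ignore[index]
                    best_q = q
                    best = (key, i, j)
        _key, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_index = len(nodes)
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dk = (d[i, k] + d[j, k] - d[i, j]) / 2
            d[new_index, k] = d[k, new_index] = max(dk, 0.0)
        active = [k for k in active if k not in (i, j)] + [new_index]

    i, j, k = active
    root = TreeNode()
    # three-point formulas for the final star
    li = (d[i, j] + d[i, k] - d[j, k]) / 2
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(length, 0.0)
        root.add_child(nodes[idx])
    return root


# -- bipartitions, RF, rooting --------------------------------------------

def _bipartitions(tree: TreeNode) -> Set[FrozenSet[str]]:
    """Non-trivial splits, each canonicalized to the side holding the
    lexicographically smallest leaf."""
    all_leaves = frozenset(tree.leaf_names())
    if len(all_leaves) != len(tree.leaf_names()):
        raise ValidationError("tree leaves must have unique names")
    anchor = min(all_leaves)
    splits: Set[FrozenSet[str]] = set()
    for node in tree.preorder():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        splits.add(side if anchor in side else all_leaves - side)
    return splits


def robinson_foulds(tree_a: TreeNode, tree_b: TreeNode) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    if set(tree_a.leaf_names()) != set(tree_b.leaf_names()):
        raise ValidationError("trees must share an identical leaf set")
    return len(_bipartitions(tree_a) ^ _bipartitions(tree_b))


def _adjacency(tree: TreeNode) -> Dict[TreeNode, List[Tuple[TreeNode, float]]]:
    adj: Dict[TreeNode, List[Tuple[TreeNode, float]]] = {}
    for node in tree.preorder():
        for child in node.children:
            adj.setdefault(node, []).append((child, child.length))
            adj.setdefault(child, []).append((node, child.length))
    return adj


def _rehang(node: TreeNode, come_from: Optional[TreeNode],
            adj: Dict[TreeNode, List[Tuple[TreeNode, float]]],
            length: float) -> TreeNode:
    clone = TreeNode(node.name, length)
    for neighbor, edge_len in adj.get(node, []):
        if neighbor is come_from:
            continue
        clone.add_child(_rehang(neighbor, node, adj, edge_len))
    return clone


def root_with_outgroup(tree: TreeNode,
                       outgroup_leaf_ids: Sequence[str]) -> TreeNode:
    """Root on the edge separating the outgroup clade, at its midpoint."""
    outgroup = set(outgroup_leaf_ids)
    all_leaves = set(tree.leaf_names())
    if not outgroup:
        raise ValidationError("outgroup is empty")
    if not outgroup <= all_leaves:
        raise ValidationError("outgroup contains unknown leaves")
    if outgroup == all_leaves:
        raise ValidationError("outgroup cannot contain every leaf")

    target = None
    for node in tree.preorder():
        if node is tree:
            continue
        below = set(node.leaf_names())
        if below == outgroup or (all_leaves - below) == outgroup:
            target = node
            break
    if target is None:
        smallest = None
        for node in tree.preorder():
            below = set(node.leaf_names())
            for side in (below, all_leaves - below):
                if outgroup <= side and (smallest is None
                                         or len(side) < len(smallest)):
                    smallest = side
        violators = sorted(smallest - outgroup) if smallest else []
        raise ValidationError(
            f"outgroup is not monophyletic; intruding leaves: {violators}")

    adj = _adjacency(tree)
    parent = target.parent
    half = target.length / 2
    root = TreeNode()
    out_side = _rehang(target, parent, adj, half)
    in_side = _rehang(parent, target, adj, half)
    # orient: outgroup clade side first when it is the below-set
    if set(out_side.leaf_names()) == outgroup:
        root.add_child(in_side)
        root.add_child(out_side)
    else:
        root.add_child(out_side)
        root.add_child(in_side)
    return root


# -- incongruence and duplications ----------------------------------------

def flag_incongruent_leaves(tree: TreeNode, class_of: Dict[str, str],
                            min_clade_size: int = 2
                            ) -> List[Tuple[str, str, str]]:
    """Leaves whose local neighborhood has a foreign strict-majority class.

    For each leaf, the smallest enclosing clade with at least
    ``min_clade_size`` leaves is examined; the leaf is flagged iff the
    strict majority class of the *other* leaves differs from its own.
    """
    if min_clade_size < 2:
        raise ValidationError("min_clade_size must be >= 2")
    leaves = tree.leaves()
    for leaf in leaves:
        if leaf.name not in class_of:
            raise ValidationError(f"leaf {leaf.name!r} has no class label")
    if min_clade_size > len(leaves):
        logger.warning("min_clade_size %d exceeds leaf count %d; no flags",
                       min_clade_size, len(leaves))
        return []
    flags: List[Tuple[str, str, str]] = []
    for leaf in leaves:
        node = leaf
        while node.parent is not None and len(node.leaves()) < min_clade_size:
            node = node.parent
        others = [l.name for l in node.leaves() if l is not leaf]
        if not others:
            continue
        counts: Dict[str, int] = {}
        for name in others:
            cls = class_of[name]
            counts[cls] = counts.get(cls, 0) + 1
        majority, top = max(sorted(counts.items()), key=lambda kv: kv[1])
        if top * 2 > len(others) and majority != class_of[leaf.name]:
            flags.append((leaf.name, class_of[leaf.name], majority))
    flags.sort(key=lambda t: t[0])
    return flags


@dataclass
class DuplicationReport:
    organism_id: str
    leaf_ids: List[str]
    mrca_leaf_ids: List[str]


def _mrca(tree: TreeNode, names: Set[str]) -> TreeNode:
    node = next(l for l in tree.leaves() if l.name in names)
    while node.parent is not None:
        if names <= set(node.leaf_names()):
            return node
        node = node.parent
    return node


def detect_duplications(tree: TreeNode,
                        organism_of: Dict[str, str]
                        ) -> List[DuplicationReport]:
    """Organisms contributing >= 2 leaves, reported with their MRCA."""
    by_organism: Dict[str, List[str]] = {}
    for name in tree.leaf_names():
        org = organism_of.get(name)
        if org is None:
            raise ValidationError(f"leaf {name!r} has no organism mapping")
        by_organism.setdefault(org, []).append(name)
    reports = []
    for org in sorted(by_organism):
        names = sorted(by_organism[org])
        if len(names) < 2:
            continue
        mrca = _mrca(tree, set(names))
        reports.append(DuplicationReport(org, names,
                                         sorted(mrca.leaf_names())))
    return reports


# -- pruning and bootstrap -------------------------------------------------

def prune_to(tree: TreeNode, keep: Sequence[str]) -> TreeNode:
    """Restrict to a leaf subset, suppressing unary nodes (lengths add)."""
    keep_set = set(keep)
    missing = keep_set - set(tree.leaf_names())
    if missing:
        raise ValidationError(f"leaves not in tree: {sorted(missing)}")

    def rebuild(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf:
            if node.name in keep_set:
                return TreeNode(node.name, node.length)
            return None
        kids = [k for k in (rebuild(c) for c in node.children)
                if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length += node.length
            return kids[0]
        clone = TreeNode(node.name, node.length)
        for k in kids:
            clone.add_child(k)
        return clone

    pruned = rebuild(tree)
    if pruned is None:
        raise ValidationError("pruning removed every leaf")
    pruned.length = 0.0
    return pruned


def bootstrap_support(msa: MSA, selection: BlockSelection,
                      n_replicates: int = 100,
                      seed: int = 0) -> Dict[FrozenSet[str], float]:
    """Fraction of column-resampled NJ replicates containing each split."""
    if not selection.kept_columns:
        raise ValidationError("no kept columns to resample")
    rng = np.random.default_rng(seed)
    counts: Dict[FrozenSet[str], int] = {}
    for _ in range(n_replicates):
        cols = rng.choice(selection.kept_columns,
                          size=len(selection.kept_columns), replace=True)
        dm = distance_matrix(msa, BlockSelection(sorted(int(c) for c in cols),
                                                 selection.parameters))
        for split in _bipartitions(nj_tree(dm)):
            counts[split] = counts.get(split, 0) + 1
    return {split: c / n_replicates for split, c in counts.items()}
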