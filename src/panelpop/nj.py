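"""Weighted p-distances, neighbor joining, midpoint rooting, bootstrap.

Distances use pairwise deletion: each pair is compared over the loci called
in both samples (guarded by a minimum shared-locus count). Genotypes weigh
1 for either homozygote and 0.5 for heterozygotes, and the distance is the
mean absolute weight difference over shared loci.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .newick import TreeNode
from .types import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # (n, n) float, NaN where undefined
    shared: np.ndarray  # (n, n) shared-locus counts
    min_shared: int = 50

    @property
    def n(self) -> int:
        return len(self.ids)

    def defined(self) -> np.ndarray:
        off_diag = ~np.eye(self.n, dtype=bool)
        return ~np.isnan(self.values) | ~off_diag

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def weighted_p_distance(
    matrix: GenotypeMatrix, min_shared: int = 50
) -> DistanceMatrix:
    """Mean |weight difference| over loci called in both samples.

    Weight = alt-dosage / 2 in {0, 0.5, 1}. Pairs sharing fewer than
    ``min_shared`` called loci are undefined (NaN).
    """
    d = matrix.dosages
    a0 = (d == 0).astype(np.float64)
    ah = (d == 1).astype(np.float64)
    a2 = (d == 2).astype(np.float64)
    called = (d != MISSING).astype(np.float64)

    shared = called @ called.T
    half_steps = a0 @ ah.T + ah @ a0.T + ah @ a2.T + a2 @ ah.T
    full_steps = a0 @ a2.T + a2 @ a0.T
    total = 0.5 * half_steps + full_steps
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(shared > 0, total / np.maximum(shared, 1), np.nan)
    dist[shared < min_shared] = np.nan
    np.fill_diagonal(dist, 0.0)
    shared_int = shared.astype(np.int64)
    return DistanceMatrix(
        ids=matrix.sample_ids, values=dist, shared=shared_int, min_shared=min_shared
    )


def neighbor_joining(dist: DistanceMatrix | np.ndarray, ids=None) -> TreeNode:
    """Saitou-Nei agglomeration; returns an unrooted tree represented with
    a trifurcating root node.

    Q(i, j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k); ties break at the
    smallest (i, j) index pair; negative branch lengths are clamped to 0
    with the deficit moved to the sibling branch.
    """
    if isinstance(dist, DistanceMatrix):
        ids = dist.ids
        d = dist.values.copy()
    else:
        d = np.asarray(dist, dtype=float).copy()
        ids = list(ids) if ids is not None else [f"t{i}" for i in range(d.shape[0])]
    if np.isnan(d).any():
        undef = np.argwhere(np.isnan(d))
        i, j = undef[0]
        raise ValueError(
            f"distance undefined for pair ({ids[i]}, {ids[j]}); too few shared "
            "loci - remove sparse samples before tree building"
        )
    n = d.shape[0]
    nodes: list[TreeNode] = [TreeNode(name=s) for s in ids]
    if n == 1:
        return nodes[0]
    if n == 2:
        half = d[0, 1] / 2.0
        nodes[0].length = nodes[1].length = half
        return TreeNode(children=nodes)

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major: smallest (i, j) wins ties
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]

        dij = d[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)

        node_i, node_j = nodes[i], nodes[j]
        node_i.length = li
        node_j.length = lj
        parent = TreeNode(children=[node_i, node_j])

        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    li = (dij + dik - djk) / 2.0
    lj = (dij + djk - dik) / 2.0
    lk = (dik + djk - dij) / 2.0
    li, lj = _clamp_pair(li, lj)
    lk = max(lk, 0.0)
    nodes[i].length = li
    nodes[j].length = lj
    nodes[k].length = lk
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    if lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


# ---------------------------------------------------------------------------
# midpoint rooting


def _adjacency(root: TreeNode):
    """Undirected adjacency {id(node): [(neighbor, length), ...]}."""
    adj: dict[int, list[tuple[TreeNode, float]]] = {}
    by_id: dict[int, TreeNode] = {}

    def visit(node: TreeNode):
        by_id[id(node)] = node
        adj.setdefault(id(node), [])
        for child in node.children:
            by_id[id(child)] = child
            adj.setdefault(id(child), [])
            adj[id(node)].append((child, child.length))
            adj[id(child)].append((node, child.length))
            visit(child)

    visit(root)
    return adj, by_id


def _farthest_from(start: TreeNode, adj) -> tuple[TreeNode, float, dict]:
    """BFS over the tree; returns the farthest *leaf*, its distance and the
    predecessor map for path reconstruction."""
    dist = {id(start): 0.0}
    prev: dict[int, TreeNode] = {}
    stack = [start]
    best, best_d = start, 0.0
    while stack:
        node = stack.pop()
        for nb, ln in adj[id(node)]:
            if id(nb) in dist:
                continue
            dist[id(nb)] = dist[id(node)] + ln
            prev[id(nb)] = node
            stack.append(nb)
            if nb.is_leaf and dist[id(nb)] > best_d:
                best, best_d = nb, dist[id(nb)]
    return best, best_d, prev


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    If the midpoint falls exactly on a node, the tree is rooted at that
    node. Raises when every branch length is zero (no path to bisect).
    """
    adj, _ = _adjacency(tree)
    leaves = tree.leaves()
    if len(leaves) < 2:
        return tree
    a, _, _ = _farthest_from(leaves[0], adj)
    b, diameter, prev = _farthest_from(a, adj)
    if diameter <= 0:
        raise ValueError("all branch lengths are zero; midpoint undefined")

    # path b -> a via predecessor map (BFS started at a)
    path = [b]
    while id(path[-1]) != id(a):
        path.append(prev[id(path[-1])])
    path.reverse()  # a ... b

    half = diameter / 2.0
    acc = 0.0
    for u, v in zip(path[:-1], path[1:]):
        ln = next(l for nb, l in adj[id(u)] if id(nb) == id(v))
        if acc + ln >= half:
            offset = half - acc  # distance from u along edge (u, v)
            return _reroot_on_edge(adj, u, v, ln, offset)
        acc += ln
    return _rebuild(adj, path[-1], None)  # numerical fallback: root at b side


def _reroot_on_edge(adj, u: TreeNode, v: TreeNode, length: float, offset: float):
    if offset <= 0:
        return _rebuild(adj, u, None)
    if offset >= length:
        return _rebuild(adj, v, None)
    left = _rebuild(adj, u, v)
    right = _rebuild(adj, v, u)
    left.length = offset
    right.length = length - offset
    return TreeNode(children=[left, right])


def _rebuild(adj, node: TreeNode, come_from: TreeNode | None) -> TreeNode:
    out = TreeNode(name=node.name, length=0.0)
    for nb, ln in adj[id(node)]:
        if come_from is not None and id(nb) == id(come_from):
            continue
        child = _rebuild(adj, nb, node)
        child.length = ln
        out.children.append(child)
    return out


# ---------------------------------------------------------------------------
# bootstrap


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions as canonical frozensets (the side not
    containing the lexicographically smallest leaf)."""
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    out: set[frozenset] = set()

    def visit(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(visit(c) for c in node.children))
        if 2 <= len(below) <= len(all_leaves) - 2:
            side = below if ref not in below else all_leaves - below
            out.add(side)
        return below

    visit(tree)
    return out


def bootstrap_support(
    matrix: GenotypeMatrix,
    n_replicates: int = 1000,
    seed: int = 0,
    min_shared: int = 50,
    max_redraws: int | None = None,
) -> TreeNode:
    """Midpoint-rooted NJ tree with Felsenstein bootstrap supports.

    Loci are resampled with replacement per replicate; replicates with an
    undefined distance pair are redrawn (counted, capped). Supports are the
    percentage of replicates whose NJ tree contains each bipartition of the
    original tree, attached to the corresponding internal nodes.
    """
    rng = np.random.default_rng(seed)
    base_dist = weighted_p_distance(matrix, min_shared=min_shared)
    base_unrooted = neighbor_joining(base_dist)
    base_parts = _bipartitions(base_unrooted)
    counts = {p: 0 for p in base_parts}

    max_redraws = max_redraws if max_redraws is not None else 10 * n_replicates
    n_loci = matrix.n_snps
    done = attempts = 0
    while done < n_replicates:
        if attempts > max_redraws:
            raise RuntimeError(
                "too many bootstrap redraws; distance matrix too sparse"
            )
        attempts += 1
        idx = rng.integers(0, n_loci, size=n_loci)
        rep = matrix.take_snps(idx)
        dist = weighted_p_distance(rep, min_shared=min_shared)
        off = ~np.eye(dist.n, dtype=bool)
        if np.isnan(dist.values[off]).any():
            continue
        rep_parts = _bipartitions(neighbor_joining(dist))
        for p in base_parts & rep_parts:
            counts[p] += 1
        done += 1

    rooted = midpoint_root(base_unrooted)
    all_leaves = frozenset(rooted.leaf_names())
    ref = min(all_leaves)

    def annotate(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c) for c in node.children))
        if 2 <= len(below) <= len(all_leaves) - 2:
            side = below if ref not in below else all_leaves - below
            if side in counts:
                node.support = int(round(100.0 * counts[side] / n_replicates))
        return below

    annotate(rooted)
    return rooted
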