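"""Neighbor-joining trees, midpoint rooting, bootstrap support, clade cuts.

Neighbor joining is implemented directly (Q-matrix minimization with the
standard branch-length formulas) because the pipeline pins down behaviour
libraries leave open: ties in Q are broken by the lexicographically
smallest label pair, and negative branch lengths are clamped to zero with
the deficit moved to the sibling so downstream depth logic always sees
non-negative lengths. On additive matrices the result is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import DistanceMatrix, MultipleAlignment, distance_matrix
from .treemodel import PhyloTree, TreeNode


@dataclass(frozen=True)
class Clade:
    clade_id: int
    members: tuple[str, ...]
    depth: float


@dataclass(frozen=True)
class CladePartition:
    """Disjoint cover of the leaf set obtained by cutting the rooted tree."""

    clades: tuple[Clade, ...]

    def member_clade(self) -> dict[str, int]:
        return {m: c.clade_id for c in self.clades for m in c.members}

    def __len__(self) -> int:
        return len(self.clades)


def _clamp_pair(li: float, lj: float, total: float) -> tuple[float, float]:
    # negative limb clamped to 0; the deficit goes to the sibling
    if li < 0.0:
        return 0.0, total
    if lj < 0.0:
        return total, 0.0
    return li, lj


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Standard neighbor joining; returns an unrooted tree (trifurcating top)."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    D = dm.values.copy()
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in dm.labels]
    tags: list[str] = list(dm.labels)  # smallest descendant leaf label per cluster

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        # keep the upper triangle only: the two float evaluations of a
        # symmetric entry can differ in the last ulp
        Q[np.tril_indices(k)] = np.inf
        minq = Q.min()
        pairs = np.argwhere(Q == minq)
        best = None
        for i, j in pairs:
            key = tuple(sorted((tags[i], tags[j])))
            if best is None or key < best[0]:
                best = (key, int(i), int(j))
        assert best is not None
        _, i, j = best
        total = D[i, j]
        li = 0.5 * total + (r[i] - r[j]) / (2.0 * (k - 2))
        li, lj = _clamp_pair(li, total - li, total)
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length, b.length = li, lj
        parent.add_child(a)
        parent.add_child(b)

        dnew = 0.5 * (D[i, :] + D[j, :] - total)
        keep = [x for x in range(k) if x not in (i, j)]
        newD = np.empty((k - 1, k - 1))
        newD[: k - 2, : k - 2] = D[np.ix_(keep, keep)]
        newD[: k - 2, k - 2] = newD[k - 2, : k - 2] = dnew[keep]
        newD[k - 2, k - 2] = 0.0
        D = newD
        nodes = [nodes[x] for x in keep] + [parent]
        tags = [tags[x] for x in keep] + [min(tags[i], tags[j])]

    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    center = TreeNode()
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = max(0.0, length)
        center.add_child(node)
    return PhyloTree(center, rooted=False).canonicalize()


def _adjacency(tree: PhyloTree) -> dict[int, list[tuple[TreeNode, float, float | None]]]:
    """Undirected adjacency: node id -> [(neighbor, edge length, edge support)]."""
    adj: dict[int, list[tuple[TreeNode, float, float | None]]] = {}
    for node in tree.root.postorder():
        adj.setdefault(id(node), [])
        for child in node.children:
            adj[id(node)].append((child, child.length, child.support))
            adj.setdefault(id(child), []).append((node, child.length, child.support))
    return adj


def _leaf_distances(tree: PhyloTree, adj, start: TreeNode) -> tuple[dict[int, float], dict[int, TreeNode]]:
    dist = {id(start): 0.0}
    prev: dict[int, TreeNode] = {}
    stack = [start]
    while stack:
        node = stack.pop()
        for nbr, length, _ in adj[id(node)]:
            if id(nbr) not in dist:
                dist[id(nbr)] = dist[id(node)] + length
                prev[id(nbr)] = node
                stack.append(nbr)
    return dist, prev


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties are broken by the lexicographically smallest (leaf, leaf) pair;
    if every branch length is zero the root lands on the edge adjacent to
    the lexicographically smallest leaf.
    """
    work = tree.copy()
    leaves = sorted(work.leaves(), key=lambda x: x.label or "")
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    adj = _adjacency(work)

    # Leaf pairs are enumerated in lexicographic order, so keeping only a
    # strictly longer path implements the smallest-pair tie rule.
    best: tuple[TreeNode, TreeNode, dict[int, TreeNode]] | None = None
    best_len = -1.0
    for leaf in leaves:
        dist, prev = _leaf_distances(work, adj, leaf)
        for other in leaves:
            if (other.label or "") <= (leaf.label or ""):
                continue
            d = dist[id(other)]
            if d > best_len + 1e-12:
                best_len = d
                best = (leaf, other, prev)
    assert best is not None
    a, b, prev = best
    total = best_len

    # path from a to b
    path = [b]
    while path[-1] is not a:
        path.append(prev[id(path[-1])])
    path.reverse()

    edge_len = {  # length of each path edge
        (id(u), id(v)): next(l for nbr, l, _ in adj[id(u)] if nbr is v)
        for u, v in zip(path, path[1:])
    }
    half = total / 2.0
    cum = 0.0
    u = v = None
    offset = 0.0
    for x, y in zip(path, path[1:]):
        length = edge_len[(id(x), id(y))]
        if cum + length >= half:
            u, v, offset = x, y, half - cum
            break
        cum += length
    assert u is not None and v is not None
    edge_length = edge_len[(id(u), id(v))]
    edge_support = next(s for nbr, _, s in adj[id(u)] if nbr is v)

    def rebuild(node: TreeNode, came_from: TreeNode, length: float, support: float | None) -> TreeNode:
        out = TreeNode(label=node.label, length=length, support=support)
        for nbr, l, s in adj[id(node)]:
            if nbr is not came_from:
                out.add_child(rebuild(nbr, node, l, s))
        return out

    root = TreeNode()
    root.add_child(rebuild(u, v, offset, edge_support))
    root.add_child(rebuild(v, u, edge_length - offset, edge_support))
    return PhyloTree(root, rooted=True).canonicalize()


def bootstrap_support(
    msa: MultipleAlignment,
    n_reps: int = 100,
    seed: int = 0,
    model: str = "poisson",
) -> PhyloTree:
    """NJ tree with internal edges annotated by bootstrap percentages.

    Columns are resampled with replacement per replicate; each internal
    edge of the reference tree is scored by the percentage of replicate
    trees containing the same leaf bipartition. Deterministic given seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ref = nj_tree(distance_matrix(msa, model))
    all_leaves = frozenset(msa.ids)
    anchor = min(all_leaves)

    def node_split(node: TreeNode) -> frozenset[str] | None:
        side = frozenset(leaf.label or "" for leaf in node.leaves())
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            return side
        return None

    targets = {
        id(node): node_split(node)
        for node in ref.root.postorder()
        if node is not ref.root and not node.is_leaf
    }
    counts = {key: 0 for key, split in targets.items() if split is not None}

    rng = np.random.default_rng(seed)
    arr = msa.encoded()
    ncol = msa.ncol
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        rep_rows = [
            (rid, bytes(arr[k, idx]).decode("ascii")) for k, rid in enumerate(msa.ids)
        ]
        rep_tree = nj_tree(distance_matrix(MultipleAlignment(rep_rows), model))
        rep_splits = rep_tree.splits()
        for key in counts:
            if targets[key] in rep_splits:
                counts[key] += 1

    for node in ref.root.postorder():
        if id(node) in counts:
            node.support = 100.0 * counts[id(node)] / n_reps
    return ref


def cut_clades(tree: PhyloTree, height_fraction: float) -> CladePartition:
    """Partition leaves by cutting edges at ``height_fraction x max leaf depth``.

    Each leaf is assigned to its shallowest ancestor (possibly itself)
    whose depth reaches the cut; leaves whose whole path stays above the
    cut form singleton clades. Clades are numbered in order of their
    smallest member label.
    """
    if not tree.rooted:
        raise ValueError("cut_clades requires a rooted tree")
    if not 0.0 < height_fraction <= 1.0:
        raise ValueError("height_fraction must be in (0, 1]")
    depths = tree.depths()
    leaves = tree.leaves()
    maxd = max(depths[id(leaf)] for leaf in leaves)
    cut = height_fraction * maxd

    groups: dict[int, tuple[float, list[str]]] = {}
    for leaf in leaves:
        path: list[TreeNode] = []
        node: TreeNode | None = leaf
        while node is not None:
            path.append(node)
            node = node.parent
        path.reverse()  # root ... leaf
        key_node = leaf
        for anc in path:
            if depths[id(anc)] >= cut:
                key_node = anc
                break
        depth, members = groups.setdefault(id(key_node), (depths[id(key_node)], []))
        members.append(leaf.label or "")

    ordered = sorted(groups.values(), key=lambda g: min(g[1]))
    clades = tuple(
        Clade(i + 1, tuple(sorted(members)), depth)
        for i, (depth, members) in enumerate(ordered)
    )
    seen = [m for c in clades for m in c.members]
    assert len(seen) == len(set(seen)) == len(leaves)
    return CladePartition(clades)
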