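"""Minimal phylogenetic machinery: vectorised neighbor joining, newick
output, bipartition bookkeeping and bootstrap support.

The NJ implementation follows the Studier & Keppler formulation and is kept
in numpy so that thousand-replicate bootstraps stay cheap; a unit test
cross-checks its topologies against skbio.tree.nj.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def neighbor_joining(dist: np.ndarray, names: list[str]) -> Node:
    """Neighbor-joining tree from a symmetric distance matrix.

    Ties in the Q matrix break on the first (row-major) minimum, so the
    result is deterministic for a given input.
    """
    n = len(names)
    if n < 2:
        raise ValueError("need at least two taxa")
    if dist.shape != (n, n):
        raise ValueError("distance matrix does not match names")
    nodes: list[Node] = [Node(name=nm) for nm in names]
    D = np.asarray(dist, dtype=float).copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        idx = np.asarray(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        a, b = np.unravel_index(np.argmin(Q), Q.shape)
        if a > b:
            a, b = b, a
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        ci, cj = nodes[i], nodes[j]
        ci.length = max(li, 0.0)
        cj.length = max(lj, 0.0)
        parent = Node(children=[ci, cj])
        # distances from the new node to every remaining node
        new_row = 0.5 * (D[i, idx] + D[j, idx] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        D[k, idx] = new_row
        D[idx, k] = new_row
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]
    i, j = active
    dij = D[i, j]
    ci, cj = nodes[i], nodes[j]
    ci.length = max(dij / 2, 0.0)
    cj.length = max(dij / 2, 0.0)
    return Node(children=[ci, cj])


def newick(node: Node, with_support: bool = True) -> str:
    def fmt(nd: Node) -> str:
        if nd.is_leaf:
            return f"{nd.name}:{nd.length:.6f}"
        inner = ",".join(fmt(c) for c in nd.children)
        label = ""
        if with_support and nd.support is not None:
            label = f"{nd.support:.0f}"
        return f"({inner}){label}:{nd.length:.6f}"

    return fmt(node) + ";"


def _canonical_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Canonical representation of an unrooted bipartition: the side that
    does not contain the lexicographically smallest leaf."""
    anchor = min(all_leaves)
    return frozenset(all_leaves - side) if anchor in side else side


def splits(tree: Node) -> set[frozenset]:
    """Non-trivial unrooted bipartitions of the tree (canonical form)."""
    all_leaves = frozenset(tree.leaves())
    out: set[frozenset] = set()

    def walk(nd: Node) -> frozenset:
        if nd.is_leaf:
            return frozenset([nd.name])
        below = frozenset().union(*(walk(c) for c in nd.children))
        if 1 < len(below) < len(all_leaves) - 1:
            out.add(_canonical_split(below, all_leaves))
        return below

    walk(tree)
    return out


def annotate_support(tree: Node, boot_trees: list[Node]) -> Node:
    """Label internal nodes with % of bootstrap trees containing their split."""
    all_leaves = frozenset(tree.leaves())
    counts: dict[frozenset, int] = {}
    for bt in boot_trees:
        for sp in splits(bt):
            counts[sp] = counts.get(sp, 0) + 1
    nrep = max(len(boot_trees), 1)

    def walk(nd: Node) -> frozenset:
        if nd.is_leaf:
            return frozenset([nd.name])
        below = frozenset().union(*(walk(c) for c in nd.children))
        if 1 < len(below) < len(all_leaves) - 1:
            key = _canonical_split(below, all_leaves)
            nd.support = 100.0 * counts.get(key, 0) / nrep
        return below

    walk(tree)
    return tree


def split_support(
    side: frozenset, all_leaves: frozenset, boot_trees: list[Node]
) -> float:
    """Bootstrap % for one specific bipartition side."""
    if not (1 < len(side) < len(all_leaves) - 1):
        return 100.0
    key = _canonical_split(side, all_leaves)
    hits = sum(1 for bt in boot_trees if key in splits(bt))
    return 100.0 * hits / max(len(boot_trees), 1)


# ---------------------------------------------------------------------------
# rooted views
# ---------------------------------------------------------------------------


def _adjacency(tree: Node) -> tuple[dict[int, list[tuple[int, float]]], dict[int, str]]:
    adj: dict[int, list[tuple[int, float]]] = {}
    leaf_name: dict[int, str] = {}
    counter = [0]

    def walk(nd: Node) -> int:
        my = counter[0]
        counter[0] += 1
        adj.setdefault(my, [])
        if nd.is_leaf:
            leaf_name[my] = nd.name
        for c in nd.children:
            cid = walk(c)
            adj[my].append((cid, c.length))
            adj[cid].append((my, c.length))
        return my

    walk(tree)
    return adj, leaf_name


def leaf_sister_set(tree: Node, target: str, root_with: str | None = None) -> frozenset:
    """Leaves of the sister group of `target` when the tree is rooted on
    `root_with` (an outgroup leaf; defaults to the first leaf that is neither
    target nor its neighbor)."""
    adj, leaf_name = _adjacency(tree)
    name_to_id = {v: k for k, v in leaf_name.items()}
    if target not in name_to_id:
        raise KeyError(f"leaf {target!r} not in tree")
    if root_with is None:
        root_with = next(nm for nm in sorted(name_to_id) if nm != target)
    root_id = name_to_id[root_with]

    # rooted leaf-sets by DFS from the outgroup leaf's single neighbor
    def leafset(nid: int, parent: int) -> frozenset:
        if nid in leaf_name:
            return frozenset([leaf_name[nid]])
        out: frozenset = frozenset()
        for nb, _ in adj[nid]:
            if nb != parent:
                out |= leafset(nb, nid)
        return out

    # walk down from root until target's parent is found
    tid = name_to_id[target]

    def find_parent(nid: int, parent: int) -> int | None:
        for nb, _ in adj[nid]:
            if nb == parent:
                continue
            if nb == tid:
                return nid
            got = find_parent(nb, nid)
            if got is not None:
                return got
        return None

    parent = find_parent(root_id, -1)
    if parent is None:  # target adjacent to the root leaf
        parent = root_id
    sisters: frozenset = frozenset()
    # children of parent other than target, excluding the branch back toward root
    on_root_path = _path(adj, parent, root_id)
    for nb, _ in adj[parent]:
        if nb == tid:
            continue
        if nb in on_root_path:
            continue
        sisters |= leafset(nb, parent)
    return sisters


def _path(adj: dict[int, list[tuple[int, float]]], a: int, b: int) -> set[int]:
    """Nodes on the path from a to b (inclusive of b, exclusive of a)."""

    def dfs(nid: int, parent: int, acc: list[int]) -> bool:
        if nid == b:
            acc.append(nid)
            return True
        for nb, _ in adj[nid]:
            if nb != parent and dfs(nb, nid, acc):
                acc.append(nb)
                return True
        return False

    acc: list[int] = []
    dfs(a, -1, acc)
    return set(acc) - {a}


def patristic_to_leaf(tree: Node, source: str) -> dict[str, float]:
    """Path lengths from one leaf to every other leaf."""
    adj, leaf_name = _adjacency(tree)
    name_to_id = {v: k for k, v in leaf_name.items()}
    start = name_to_id[source]
    dist: dict[int, float] = {start: 0.0}
    stack = [start]
    while stack:
        nid = stack.pop()
        for nb, ln in adj[nid]:
            if nb not in dist:
                dist[nb] = dist[nid] + ln
                stack.append(nb)
    return {nm: dist[nid] for nid, nm in leaf_name.items() if nm != source}
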