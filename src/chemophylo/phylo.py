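"""Neighbor-Joining trees, randomized-order consensus, midpoint rooting.

NJ is implemented directly (Saitou–Nei, Studier–Keppler Q-criterion)
rather than delegated, because the consensus procedure randomizes the
taxon *input order* and relies on order-dependent tie-breaking exactly
as PHYLIP ``neighbor`` does: ties in Q are broken toward the smallest
(i, j) index pair of the current matrix, so permuting the input can
change which of several equally good joins is made.  On an additive
matrix the result is order-independent and exact.

Trees are scikit-bio ``TreeNode`` objects; consensus supports are stored
on ``node.support`` and serialized as internal Newick labels.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)


def nj(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei Neighbor-Joining; returns an unrooted tree.

    The root node of the returned ``TreeNode`` is the final trifurcation
    (degree 3), i.e. an unrooted tree in the usual rooted-storage
    convention.  Negative branch lengths are clamped to zero and the
    clamped deficit logged.
    """
    D = np.array(dm.data, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    n = D.shape[0]
    if n < 3:
        raise ValueError("Neighbor-Joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.ids]
    clamped = 0.0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while n > 3:
        r = D.sum(axis=1)
        # Q(i,j) = (n-2) d(i,j) - r_i - r_j ; minimal Q joined, ties -> smallest (i,j)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = np.inf
        bi = bj = -1
        for i in range(n):
            for j in range(i + 1, n):
                if Q[i, j] < best:
                    best = Q[i, j]
                    bi, bj = i, j
        li = 0.5 * D[bi, bj] + (r[bi] - r[bj]) / (2.0 * (n - 2))
        lj = D[bi, bj] - li
        a, b = nodes[bi], nodes[bj]
        a.length = _clamp(li)
        b.length = _clamp(lj)
        parent = TreeNode(children=[a, b])
        # reduce the matrix: replace i by the new node, delete j
        du = 0.5 * (D[bi, :] + D[bj, :] - D[bi, bj])
        D[bi, :] = du
        D[:, bi] = du
        D[bi, bi] = 0.0
        keep = [k for k in range(n) if k != bj]
        D = D[np.ix_(keep, keep)]
        nodes[bi] = parent
        del nodes[bj]
        n -= 1

    # final trifurcation, closed form for 3 taxa
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    nodes[0].length = _clamp(0.5 * (d01 + d02 - d12))
    nodes[1].length = _clamp(0.5 * (d01 + d12 - d02))
    nodes[2].length = _clamp(0.5 * (d02 + d12 - d01))
    root = TreeNode(children=nodes)
    if clamped > 0:
        logger.info("NJ clamped negative branch lengths totalling %.6g", clamped)
    return root


def _bipartitions(tree: TreeNode, ref_leaf: str) -> dict[frozenset, TreeNode]:
    """Internal-edge bipartitions, each keyed by the side NOT containing ``ref_leaf``."""
    all_tips = frozenset(t.name for t in tree.tips())
    out: dict[frozenset, TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref_leaf in side:
            side = all_tips - side
        if 1 < len(side) < len(all_tips) - 1:
            out[side] = node
    return out


def majority_rule_consensus(trees: list[TreeNode], extended: bool = False) -> TreeNode:
    """Majority-rule consensus of trees over a common leaf set.

    Keeps exactly the bipartitions appearing in strictly more than half
    of the input trees (``extended=True`` greedily adds the remaining
    compatible bipartitions by frequency, PHYLIP consense style).
    Supports (bipartition frequencies) go on ``node.support``; the tree
    carries no branch lengths.
    """
    if not trees:
        raise ValueError("no trees to take a consensus of")
    tip_sets = {frozenset(t.name for t in tree.tips()) for tree in trees}
    if len(tip_sets) != 1:
        raise ValueError("consensus requires identical leaf sets")
    tips = sorted(next(iter(tip_sets)))
    ref = tips[0]
    counts: dict[frozenset, int] = {}
    for tree in trees:
        for split in _bipartitions(tree, ref):
            counts[split] = counts.get(split, 0) + 1
    n = len(trees)
    kept = {s: c / n for s, c in counts.items() if c / n > 0.5}
    if extended:
        # add further splits by descending frequency if compatible with all kept
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], sorted(kv[0]))):
            if s in kept:
                continue
            if all(_compatible(s, k) for k in kept):
                kept[s] = c / n
    # build: star tree refined by splits, largest first so parents precede children
    root = TreeNode(children=[TreeNode(name=t) for t in tips])
    for split, freq in sorted(kept.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))):
        node = root
        while True:
            child = next(
                (c for c in node.children if not c.is_tip() and split <= _tipset(c)),
                None,
            )
            if child is None:
                break
            node = child
        group = [c for c in node.children if _tipset(c) <= split]
        if len(group) < 2:
            continue  # split already implied or incompatible placement
        for c in group:
            node.remove(c)
        new = TreeNode(children=group)
        new.support = freq
        node.append(new)
    return root


def _compatible(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


def _tipset(node: TreeNode) -> frozenset:
    if node.is_tip():
        return frozenset([node.name])
    return frozenset(t.name for t in node.tips())


def randomized_consensus(
    dm: DistanceMatrix, n_orders: int = 10, seed: int = 0, extended: bool = False
) -> tuple[TreeNode, list[TreeNode]]:
    """NJ under ``n_orders`` seeded input-order permutations, then consensus.

    Returns ``(consensus, trees)``; branch lengths of the first
    replicate tree are mapped onto matching consensus bipartitions so the
    consensus can be midpoint rooted (unmatched edges get length 0, tips
    keep the first tree's tip lengths).
    """
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    rng = np.random.default_rng(seed)
    ids = list(dm.ids)
    trees = []
    for _ in range(n_orders):
        perm = rng.permutation(len(ids))
        trees.append(nj(dm.filter([ids[p] for p in perm])))
    consensus = majority_rule_consensus(trees, extended=extended)
    _map_lengths(consensus, trees[0])
    return consensus, trees


def _map_lengths(consensus: TreeNode, reference: TreeNode) -> None:
    ref_leaf = sorted(t.name for t in reference.tips())[0]
    ref_splits = _bipartitions(reference, ref_leaf)
    tip_len = {t.name: t.length for t in reference.tips()}
    all_tips = frozenset(t.name for t in consensus.tips())
    for node in consensus.postorder(include_self=False):
        if node.is_tip():
            node.length = tip_len.get(node.name, 0.0)
        else:
            split = _tipset(node)
            if ref_leaf in split:
                split = all_tips - split
            match = ref_splits.get(split)
            node.length = match.length if match is not None else 0.0


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long leaf pairs are broken by lexicographic
    (name, name) order.  A tree whose branch lengths are all zero is
    rooted at its first internal node with a warning.
    """
    t = tree.copy()
    for node in t.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    dists = t.tip_tip_distances()
    names = list(dists.ids)
    best = (-1.0, ("", ""))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            pair = tuple(sorted((a, names[j])))
            d = dists[a, names[j]]
            if d > best[0] or (d == best[0] and pair < best[1]):
                best = (d, pair)
    dmax, (a_name, b_name) = best
    if dmax <= 0:
        logger.warning("all branch lengths zero; rooting at an arbitrary internal edge")
        internal = next(t.non_tips(include_self=False), None)
        return t if internal is None else t.root_at(internal)
    a = t.find(a_name)
    b = t.find(b_name)
    lca = t.lca([a, b])
    # ordered edge list a -> lca -> b as (lower_node, length, from_a_side)
    edges: list[tuple[TreeNode, float]] = []
    node = a
    while node is not lca:
        edges.append((node, node.length))
        node = node.parent
    down: list[tuple[TreeNode, float]] = []
    node = b
    while node is not lca:
        down.append((node, node.length))
        node = node.parent
    a_side = len(edges)
    edges.extend(reversed(down))
    half = dmax / 2.0
    cum = 0.0
    for k, (child, length) in enumerate(edges):
        if cum + length >= half - 1e-12:
            # distance of the root point from the child end of this edge
            if k < a_side:
                from_child = half - cum
            else:
                from_child = length - (half - cum)
            from_child = min(max(from_child, 0.0), length)
            if from_child <= 1e-12:
                return t.root_at(child) if not child.is_tip() else _split_edge(t, child, 1e-12)
            if length - from_child <= 1e-12 and child.parent is not None:
                target = child.parent
                if target.is_root():
                    return t
                return t.root_at(target)
            return _split_edge(t, child, from_child)
        cum += length
    raise AssertionError("midpoint not located on the path")  # pragma: no cover


def _split_edge(t: TreeNode, child: TreeNode, from_child: float) -> TreeNode:
    parent = child.parent
    mid = TreeNode(length=child.length - from_child)
    parent.remove(child)
    child.parent = None
    child.length = from_child
    mid.append(child)
    parent.append(mid)
    rooted = t.root_at(mid)
    # root_at leaves the old unrooted view; ensure the new root has no length
    rooted.length = None
    return rooted


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write Newick; consensus supports become internal node labels.

    (scikit-bio emits a ``node.support`` attribute as the internal label
    when the node has no name of its own.)
    """
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    """Read Newick; numeric internal labels are exposed as ``node.support``."""
    tree = TreeNode.read(str(path), format="newick")
    return _promote_supports(tree)


def read_newick_string(newick: str) -> TreeNode:
    """Parse a Newick string (same label handling as :func:`read_newick`)."""
    import io

    return _promote_supports(TreeNode.read(io.StringIO(newick), format="newick"))


def _promote_supports(tree: TreeNode) -> TreeNode:
    for node in tree.non_tips(include_self=False):
        if node.name is not None:
            try:
                node.support = float(node.name)
                node.name = None
            except ValueError:
                pass
    return tree
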