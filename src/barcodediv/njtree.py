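"""Neighbour-joining tree construction with optional site-bootstrap support.

Classical Saitou–Nei agglomeration: at each step the pair of nodes
minimising the rate-corrected criterion

    Q(i, j) = (r - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

(with r active nodes) is joined, branch lengths follow the standard
two-point formulas, the matrix is reduced by the average rule, and the last
three nodes are closed with the three-point formulas. The result is an
unrooted tree (represented with a trifurcating root) that reconstructs
additive distance matrices exactly.

Tie-breaking is deterministic: among equal Q values the pair with the
smallest (i, j) position in the current node order wins. Negative branch
lengths produced by the formulas are clamped to zero by default, the
deficit being transferred to the sibling branch so that path lengths
through the joined pair are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix, distance_matrix, matrix_from_codes
from .panel import BarcodePanel

__all__ = ["TreeNode", "NJTree", "neighbour_joining", "bootstrap_support"]


@dataclass
class TreeNode:
    """Minimal tree node: a name, a branch length to the parent, children."""

    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def traverse(self):
        yield self
        for c in self.children:
            yield from c.traverse()


@dataclass
class NJTree:
    """Unrooted NJ tree over a fixed leaf set.

    ``support``, when present, maps each internal-edge bipartition (the
    frozenset of leaf names on the side not containing the reference leaf,
    ``ids[0]``) to a proportion in [0, 1].
    """

    root: TreeNode
    ids: list[str]
    support: dict[frozenset, float] | None = None

    def leaf_names(self) -> set[str]:
        return {leaf.name for leaf in self.root.leaves()}

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, one per internal edge."""
        all_leaves = self.leaf_names()
        ref = self.ids[0]
        out = set()
        for node in self.root.traverse():
            if node is self.root or node.is_leaf():
                continue
            side = {leaf.name for leaf in node.leaves()}
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(frozenset(side))
        return out

    def path_length(self, name_a: str, name_b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        parents: dict[int, TreeNode | None] = {id(self.root): None}
        stack = [self.root]
        node_a = node_b = None
        while stack:
            node = stack.pop()
            if node.name == name_a and node.is_leaf():
                node_a = node
            if node.name == name_b and node.is_leaf():
                node_b = node
            for c in node.children:
                parents[id(c)] = node
                stack.append(c)
        if node_a is None or node_b is None:
            raise KeyError(f"leaf not found: {name_a!r} or {name_b!r}")
        ancestors = {}
        node, acc = node_a, 0.0
        while node is not None:
            ancestors[id(node)] = acc
            acc += node.length or 0.0
            node = parents[id(node)]
        node, acc = node_b, 0.0
        while id(node) not in ancestors:
            acc += node.length or 0.0
            node = parents[id(node)]
        return acc + ancestors[id(node)]

    def annotate_support(self, fmt: str = "{:.2f}") -> None:
        """Write support values into internal node labels (Newick-friendly)."""
        if self.support is None:
            return
        all_leaves = self.leaf_names()
        ref = self.ids[0]
        for node in self.root.traverse():
            if node is self.root or node.is_leaf():
                continue
            side = {leaf.name for leaf in node.leaves()}
            if ref in side:
                side = all_leaves - side
            key = frozenset(side)
            if key in self.support:
                node.name = fmt.format(self.support[key])


def _argmin_q(D: np.ndarray, r: int) -> tuple[int, int]:
    sums = D.sum(axis=1)
    Q = (r - 2) * D - sums[:, None] - sums[None, :]
    np.fill_diagonal(Q, np.inf)
    # deterministic tie-break: row-major first occurrence of the minimum
    # restricted to the upper triangle == smallest (i, j) position pair
    iu = np.triu_indices(r, 1)
    qvals = Q[iu]
    k = int(np.argmin(qvals))
    return int(iu[0][k]), int(iu[1][k])


def neighbour_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> NJTree:
    """Build an unrooted NJ tree from a complete distance matrix.

    ``clamp_negative`` replaces negative branch lengths by zero and moves
    the deficit onto the sibling branch (set ``False`` to keep raw values).
    """
    if dm.n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if not dm.is_complete():
        pairs = dm.undefined_pairs()
        raise ValueError(
            f"distance matrix has {len(pairs)} undefined pair(s), e.g. {pairs[0]}"
        )

    D = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]

    while len(nodes) > 3:
        r = len(nodes)
        i, j = _argmin_q(D, r)
        sums = D.sum(axis=1)
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        if clamp_negative:
            if li < 0:
                lj += li
                li = 0.0
            if lj < 0:
                li += lj
                lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        new = TreeNode(children=[child_i, child_j])

        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.empty((r - 1, r - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = d_new[keep]
        D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]

    # three-point closure: join the remaining nodes at one internal vertex
    (a, b, c) = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    lengths = [la, lb, lc]
    if clamp_negative:
        lengths = [max(0.0, x) for x in lengths]
    for node, length in zip(nodes, lengths):
        node.length = length
    root = TreeNode(children=[a, b, c])
    return NJTree(root=root, ids=list(dm.ids))


def bootstrap_support(
    panel: BarcodePanel,
    n_replicates: int,
    seed: int,
    deletion: str = "pairwise",
) -> NJTree:
    """NJ tree with internal-edge support from site (column) bootstrapping.

    Alignment columns are resampled with replacement; the distance matrix
    and NJ tree are recomputed per replicate; the support of an internal
    edge is the proportion of retained replicates whose tree contains the
    same bipartition. Replicates yielding an undefined distance are dropped
    (an error is raised if more than half are lost).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    base_dm = distance_matrix(panel, deletion=deletion)
    base_tree = neighbour_joining(base_dm)
    target = base_tree.bipartitions()
    counts = {bp: 0 for bp in target}

    rng = np.random.default_rng(seed)
    X = panel.encoded()
    L = X.shape[1]
    kept = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep_dm = matrix_from_codes(X[:, cols], panel.ids)
        if not rep_dm.is_complete():
            warnings.warn("bootstrap replicate dropped: undefined distance", stacklevel=2)
            continue
        kept += 1
        rep_bps = neighbour_joining(rep_dm).bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    if kept < n_replicates / 2:
        raise RuntimeError(
            f"more than half of bootstrap replicates dropped ({kept}/{n_replicates} kept)"
        )
    base_tree.support = {bp: counts[bp] / kept for bp in target}
    return base_tree
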