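"""Neighbour joining: three-point formulas, additivity, LS optimality, bootstrap."""

import itertools

import numpy as np
import pytest

from barcodediv import DistanceMatrix, bootstrap_support, neighbour_joining
from barcodediv.panel import newick_string

from conftest import make_panel


def dm_from_array(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(list(ids), d, np.full_like(d, 100, dtype=np.int64))


# ---------------------------------------------------------------- oracles


def random_additive_tree(rng, n_leaves):
    """Random unrooted binary tree as an adjacency map with edge lengths."""
    adj = {}

    def add_edge(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def del_edge(u, v):
        adj[u] = [(x, w) for x, w in adj[u] if x != v]
        adj[v] = [(x, w) for x, w in adj[v] if x != u]

    center = "i0"
    for i in range(3):
        add_edge(center, f"L{i}", rng.uniform(0.1, 1.0))
    next_internal = 1
    for i in range(3, n_leaves):
        edges = [
            (u, v, w)
            for u in adj
            for v, w in adj[u]
            if str(u) < str(v)
        ]
        u, v, w = edges[rng.integers(len(edges))]
        x = f"i{next_internal}"
        next_internal += 1
        del_edge(u, v)
        add_edge(u, x, rng.uniform(0.1, 1.0))
        add_edge(x, v, rng.uniform(0.1, 1.0))
        add_edge(x, f"L{i}", rng.uniform(0.1, 1.0))
    return adj


def tree_leaf_distances(adj, leaves):
    """All-pairs leaf path lengths by per-leaf traversal."""
    out = np.zeros((len(leaves), len(leaves)))
    index = {name: i for i, name in enumerate(leaves)}
    for src in leaves:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nbr, w in adj[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    stack.append(nbr)
        for dst in leaves:
            out[index[src], index[dst]] = dist[dst]
    return out


def tree_bipartitions(adj, leaves):
    """Leaf splits induced by internal edges of the true tree."""
    n = len(leaves)
    ref = leaves[0]
    out = set()
    for u in adj:
        for v, _ in adj[u]:
            if not (str(u) < str(v)):
                continue
            # leaves on the v side when edge (u, v) is cut
            seen = {v}
            stack = [v]
            while stack:
                node = stack.pop()
                for nbr, _ in adj[node]:
                    if nbr != u and nbr not in seen:
                        seen.add(nbr)
                        stack.append(nbr)
            side = {x for x in seen if x in leaves}
            if ref in side:
                side = set(leaves) - side
            if 2 <= len(side) <= n - 2:
                out.add(frozenset(side))
    return out


QUARTET_SPLITS = {
    ((0, 1), (2, 3)): frozenset({"t2", "t3"}),
    ((0, 2), (1, 3)): frozenset({"t1", "t3"}),
    ((0, 3), (1, 2)): frozenset({"t1", "t2"}),
}


def quartet_ls_residual(d, split):
    """OLS residual of fitting a 4-taxon tree with the given cherry split."""
    (a, b), (c, e) = split
    pairs = list(itertools.combinations(range(4), 2))
    # columns: pendant edges 0..3, internal edge 4
    A = np.zeros((6, 5))
    for row, (i, j) in enumerate(pairs):
        A[row, i] = 1
        A[row, j] = 1
        same_cherry = {i, j} in ({a, b}, {c, e})
        if not same_cherry:
            A[row, 4] = 1
    y = np.array([d[i, j] for i, j in pairs])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ coef - y) ** 2).sum())


# ------------------------------------------------------------------ tests


class TestNeighbourJoining:
    def test_three_taxon_closure(self):
        dm = dm_from_array(
            ["A", "B", "C"],
            [[0.0, 0.2, 0.4], [0.2, 0.0, 0.4], [0.4, 0.4, 0.0]],
        )
        tree = neighbour_joining(dm)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"A": 0.1, "B": 0.1, "C": 0.3})
        assert newick_string(tree) == "(A:0.1,B:0.1,C:0.3);"

    def test_too_few_taxa_rejected(self):
        dm = dm_from_array(["A", "B"], [[0.0, 0.1], [0.1, 0.0]])
        with pytest.raises(ValueError, match="at least 3"):
            neighbour_joining(dm)

    def test_undefined_entries_rejected_naming_pair(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        dm = dm_from_array(["A", "B", "C"], d)
        with pytest.raises(ValueError, match="undefined"):
            neighbour_joining(dm)

    @pytest.mark.parametrize("n_leaves", [5, 6, 7, 8])
    def test_exact_recovery_on_additive_matrices(self, n_leaves):
        """On tree-realizable distances NJ returns the generating tree:
        same bipartitions and identical leaf path lengths."""
        rng = np.random.default_rng(100 + n_leaves)
        for _ in range(5):
            adj = random_additive_tree(rng, n_leaves)
            leaves = [f"L{i}" for i in range(n_leaves)]
            D = tree_leaf_distances(adj, leaves)
            tree = neighbour_joining(dm_from_array(leaves, D))
            assert tree.bipartitions() == tree_bipartitions(adj, leaves)
            for i, j in itertools.combinations(range(n_leaves), 2):
                assert tree.path_length(leaves[i], leaves[j]) == pytest.approx(
                    D[i, j], abs=1e-9
                )

    def test_quartet_choice_matches_least_squares(self):
        """For 4 taxa the NJ split is the least-squares-best of the 3
        possible unrooted topologies."""
        rng = np.random.default_rng(42)
        ids = ["t0", "t1", "t2", "t3"]
        n_checked = 0
        for _ in range(30):
            adj = random_additive_tree(rng, 4)
            D = tree_leaf_distances(adj, [f"L{i}" for i in range(4)])
            D = D + rng.uniform(0, 0.05, size=(4, 4))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            residuals = {
                bp: quartet_ls_residual(D, split)
                for split, bp in QUARTET_SPLITS.items()
            }
            ranked = sorted(residuals.values())
            if ranked[1] - ranked[0] < 1e-6:
                continue  # no clear LS winner; skip degenerate draw
            best = min(residuals, key=residuals.get)
            tree = neighbour_joining(dm_from_array(ids, D))
            bps = tree.bipartitions()
            assert len(bps) == 1
            assert next(iter(bps)) == best
            n_checked += 1
        assert n_checked >= 20

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(5)
        adj = random_additive_tree(rng, 7)
        leaves = [f"L{i}" for i in range(7)]
        D = tree_leaf_distances(adj, leaves)
        base = neighbour_joining(dm_from_array(leaves, D))
        perm = rng.permutation(7)
        tree2 = neighbour_joining(
            dm_from_array([leaves[i] for i in perm], D[np.ix_(perm, perm)])
        )
        # normalize both bipartition sets to a common reference leaf
        def norm(bps, all_names, ref):
            return {
                bp if ref not in bp else frozenset(all_names - bp) for bp in bps
            }

        names = set(leaves)
        assert norm(base.bipartitions(), names, "L0") == norm(
            tree2.bipartitions(), names, "L0"
        )
        for i, j in itertools.combinations(range(7), 2):
            assert tree2.path_length(leaves[i], leaves[j]) == pytest.approx(
                base.path_length(leaves[i], leaves[j]), abs=1e-9
            )

    def test_agrees_with_reference_implementation(self):
        """Topology cross-check against scikit-bio's NJ on a noisy matrix."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(17)
        adj = random_additive_tree(rng, 8)
        leaves = [f"L{i}" for i in range(8)]
        D = tree_leaf_distances(adj, leaves)
        noise = rng.uniform(0, 0.02, size=D.shape)
        D = D + (noise + noise.T) / 2
        D = (D + D.T) / 2  # exact float symmetry
        np.fill_diagonal(D, 0.0)

        ours = neighbour_joining(dm_from_array(leaves, D))
        ref_tree = skbio.tree.nj(skbio.DistanceMatrix(D, leaves))
        names = set(leaves)
        ref_bps = set()
        for node in ref_tree.traverse(include_self=False):
            if node.is_tip():
                continue
            side = {t.name for t in node.tips()}
            if "L0" in side:
                side = names - side
            if 2 <= len(side) <= 6:
                ref_bps.add(frozenset(side))
        assert ours.bipartitions() == ref_bps

    def test_negative_branch_lengths_clamped_by_default(self):
        # a strongly non-additive matrix that provokes a negative NJ length
        d = np.array(
            [
                [0.0, 0.856, 0.623, 0.329],
                [0.856, 0.0, 0.571, 0.183],
                [0.623, 0.571, 0.0, 0.081],
                [0.329, 0.183, 0.081, 0.0],
            ]
        )
        dm = dm_from_array(["a", "b", "c", "d"], d)
        clamped = neighbour_joining(dm, clamp_negative=True)
        raw = neighbour_joining(dm, clamp_negative=False)
        c_lengths = [n.length for n in clamped.root.traverse() if n.length is not None]
        assert min(c_lengths) >= 0.0
        r_lengths = [n.length for n in raw.root.traverse() if n.length is not None]
        assert min(r_lengths) < 0.0
        # the deficit transfer preserves the first joined pair's path length
        assert clamped.path_length("a", "c") == pytest.approx(
            raw.path_length("a", "c"), abs=1e-12
        )


class TestBootstrapSupport:
    def _fixed_difference_panel(self):
        # three species blocks separated by many fixed differences
        base = {
            "A": "AAAAAAAAAAAAAAAAAAAA",
            "B": "TTTTTTTTTTTTTTTTTTTT",
            "C": "GGGGGGGGGGGGGGGGGGGG",
        }
        seqs, species = {}, {}
        for sp, seq in base.items():
            for i in range(3):
                sid = f"{sp}{i}"
                # one private substitution per sample keeps samples distinct
                mutated = seq[:i] + "C" + seq[i + 1 :]
                seqs[sid] = mutated
                species[sid] = sp
        return make_panel(seqs, species=species)

    def test_fixed_differences_give_full_support(self):
        panel = self._fixed_difference_panel()
        tree = bootstrap_support(panel, n_replicates=50, seed=1)
        all_names = set(panel.ids)
        ref = panel.ids[0]
        for sp in "ABC":
            side = {name for name in all_names if name.startswith(sp)}
            key = frozenset(side if ref not in side else all_names - side)
            assert key in tree.support, f"species {sp} split missing"
            assert tree.support[key] == pytest.approx(1.0)

    def test_single_replicate_support_is_binary(self):
        panel = self._fixed_difference_panel()
        tree = bootstrap_support(panel, n_replicates=1, seed=3)
        assert set(tree.support.values()) <= {0.0, 1.0}

    def test_same_seed_reproduces_supports(self):
        panel = self._fixed_difference_panel()
        t1 = bootstrap_support(panel, n_replicates=25, seed=9)
        t2 = bootstrap_support(panel, n_replicates=25, seed=9)
        assert t1.support == t2.support

    def test_support_annotation_lands_in_newick(self):
        panel = self._fixed_difference_panel()
        tree = bootstrap_support(panel, n_replicates=10, seed=2)
        tree.annotate_support()
        nwk = newick_string(tree)
        assert ")1.00:" in nwk or ")0." in nwk
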