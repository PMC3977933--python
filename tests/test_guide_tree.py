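import numpy as np
import pytest

from gridmsa.pairwise import DistanceMatrix
from gridmsa.tree import (GuideTree, TreeNode, compute_weights, midpoint_root,
                          nj_build, traversal_schedule)


def _dm(ids, d):
    return DistanceMatrix(ids=list(ids), d=np.asarray(d, dtype=float))


def random_additive_tree(rng, n):
    """A random binary topology with positive branch lengths, plus its
    path-length distance matrix and split set."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    members = [{f"t{i}"} for i in range(n)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        joined = TreeNode(children=[a, b])
        nodes[i] = joined
        members[i] = members[i] | members[j]
        del nodes[j], members[j]
    nodes[0].length = float(rng.uniform(0.05, 1.0))
    nodes[1].length = float(rng.uniform(0.05, 1.0))
    tree = GuideTree(TreeNode(children=nodes), rooted=False)

    ids = sorted(tree.leaf_names())
    d = np.zeros((n, n))
    dists = {}

    def collect(node, acc):
        if node.is_leaf:
            dists[node.name] = acc
        for c in node.children:
            collect(c, acc + c.length)

    # path lengths via per-leaf traversals over the undirected tree
    from gridmsa.tree import _adjacency, _leaf_paths
    adj, _ = _adjacency(tree)
    leaves = {l.name: l for l in tree.leaves()}
    for i, a in enumerate(ids):
        dist, _prev = _leaf_paths(tree, leaves[a], adj)
        for j, b in enumerate(ids):
            d[i, j] = dist[id(leaves[b])]
    d = (d + d.T) / 2  # exact symmetry despite float summation order
    np.fill_diagonal(d, 0.0)
    return tree, _dm(ids, d)


def splits(tree):
    """Non-trivial leaf bipartitions induced by internal edges."""
    all_leaves = frozenset(tree.leaf_names())
    out = set()

    def rec(node):
        below = (frozenset({node.name}) if node.is_leaf
                 else frozenset().union(*[rec(c) for c in node.children]))
        if 1 < len(below) < len(all_leaves) - 1:
            out.add(min(below, other := all_leaves - below,
                        key=lambda s: sorted(s)))
        return below

    rec(tree.root)
    return out


class TestNjBuild:
    def test_two_taxa_symmetric_split(self):
        t = nj_build(_dm("AB", [[0, .4], [.4, 0]]))
        kids = t.root.children
        assert {k.name for k in kids} == {"A", "B"}
        assert all(k.length == pytest.approx(0.2) for k in kids)

    def test_three_taxa_closed_form(self):
        d_ab, d_ac, d_bc = 0.4, 0.6, 0.8
        t = nj_build(_dm("ABC", [[0, d_ab, d_ac], [d_ab, 0, d_bc],
                                 [d_ac, d_bc, 0]]))
        lengths = {k.name: k.length for k in t.root.children}
        assert lengths["A"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["B"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["C"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_additive_five_taxon_topology_recovered(self):
        rng = np.random.default_rng(42)
        true, dm = random_additive_tree(rng, 5)
        assert splits(nj_build(dm)) == splits(true)

    def test_additive_recovery_matches_skbio(self):
        """On additive matrices our NJ and scikit-bio's agree on topology."""
        import skbio

        rng = np.random.default_rng(7)
        for _ in range(5):
            n = int(rng.integers(4, 9))
            true, dm = random_additive_tree(rng, n)
            ours = splits(nj_build(dm))
            sk = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=dm.ids))
            sk_splits = set()
            for node in sk.non_tips():
                below = frozenset(t.name for t in node.tips())
                rest = frozenset(dm.ids) - below
                if 1 < len(below) < len(dm.ids) - 1:
                    sk_splits.add(min(below, rest, key=lambda s: sorted(s)))
            assert ours == sk_splits == splits(true)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            nj_build(_dm("AB", [[0, -.1], [-.1, 0]]))

    def test_additive_recovery_many_random_trees(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            true, dm = random_additive_tree(rng, n)
            assert splits(nj_build(dm)) == splits(true)


class TestMidpointRoot:
    def test_two_leaf_split(self):
        t = nj_build(_dm("AB", [[0, .4], [.4, 0]]))
        rooted = midpoint_root(t)
        assert rooted.rooted
        kids = {k.name: k.length for k in rooted.root.children}
        assert kids == {"A": pytest.approx(0.2), "B": pytest.approx(0.2)}

    def test_root_lands_on_long_branch(self):
        # Chain A -0.1- x -0.5- B: midpoint (0.3) sits on the x-B branch.
        x = TreeNode(children=[TreeNode("A", 0.1), TreeNode("B", 0.5)])
        x.add(TreeNode("C", 0.05))
        rooted = midpoint_root(GuideTree(x))
        sides = rooted.root.children
        b_side = [s for s in sides if s.name == "B"]
        assert b_side and b_side[0].length == pytest.approx(0.3)

    def test_path_lengths_preserved(self):
        rng = np.random.default_rng(9)
        true, dm = random_additive_tree(rng, 7)
        rooted = midpoint_root(nj_build(dm))
        from gridmsa.tree import _adjacency, _leaf_paths
        adj, _ = _adjacency(rooted)
        leaves = {l.name: l for l in rooted.leaves()}
        first = dm.ids[0]
        dist, _ = _leaf_paths(rooted, leaves[first], adj)
        for j, other in enumerate(dm.ids):
            assert dist[id(leaves[other])] == pytest.approx(dm.d[0, j])

    def test_symmetric_tree_unchanged(self):
        t = nj_build(_dm("ABCD", [[0, .2, .6, .6], [.2, 0, .6, .6],
                                  [.6, .6, 0, .2], [.6, .6, .2, 0]]))
        rooted = midpoint_root(t)
        assert splits(rooted) == splits(t)


class TestComputeWeights:
    def test_equal_branches_equal_weights(self):
        root = TreeNode(children=[TreeNode("A", 0.3), TreeNode("B", 0.3)])
        w = compute_weights(GuideTree(root, rooted=True))
        assert w["A"] == w["B"] == 1.0

    def test_star_tree_heaviest_on_long_branch(self):
        root = TreeNode(children=[TreeNode("A", 0.1), TreeNode("B", 0.1),
                                  TreeNode("C", 0.4)])
        w = compute_weights(GuideTree(root, rooted=True))
        assert w["C"] == 1.0
        assert w["A"] == pytest.approx(0.25)

    def test_zero_length_tree_gives_unit_weights(self):
        root = TreeNode(children=[TreeNode("A", 0.0), TreeNode("B", 0.0)])
        w = compute_weights(GuideTree(root, rooted=True))
        assert w["A"] == w["B"] == 1.0

    def test_shared_branches_divided(self):
        inner = TreeNode(children=[TreeNode("A", 0.2), TreeNode("B", 0.2)])
        inner.length = 0.4
        root = TreeNode(children=[inner, TreeNode("C", 0.5)])
        w = compute_weights(GuideTree(root, rooted=True))
        # A and B share the 0.4 branch: 0.2 + 0.4/2 = 0.4 < C's 0.5.
        assert w["C"] == 1.0
        assert w["A"] == pytest.approx(0.4 / 0.5)

    def test_invariant_under_leaf_order(self):
        rng = np.random.default_rng(31)
        true, dm = random_additive_tree(rng, 6)
        w1 = compute_weights(midpoint_root(nj_build(dm)))
        perm = list(rng.permutation(len(dm.ids)))
        dm2 = DistanceMatrix(ids=[dm.ids[p] for p in perm],
                             d=dm.d[np.ix_(perm, perm)])
        w2 = compute_weights(midpoint_root(nj_build(dm2)))
        for name, val in w1.items():
            assert val == pytest.approx(w2[name])


class TestTraversalSchedule:
    def _rooted(self, newick_like):
        return GuideTree(newick_like, rooted=True)

    def test_two_leaves_single_step(self):
        root = TreeNode(children=[TreeNode("A", .1), TreeNode("B", .1)])
        steps = traversal_schedule(self._rooted(root))
        assert len(steps) == 1
        assert steps[0].members == frozenset("AB")

    def test_balanced_four_leaves_first_two_parallel(self):
        left = TreeNode(children=[TreeNode("A", .1), TreeNode("B", .1)])
        left.length = .1
        right = TreeNode(children=[TreeNode("C", .1), TreeNode("D", .1)])
        right.length = .1
        steps = traversal_schedule(
            self._rooted(TreeNode(children=[left, right])))
        assert len(steps) == 3
        assert steps[0].parallel_eligible and steps[1].parallel_eligible
        assert not steps[2].parallel_eligible

    def test_caterpillar_no_parallelism(self):
        ab = TreeNode(children=[TreeNode("A", .1), TreeNode("B", .1)])
        ab.length = .1
        abc = TreeNode(children=[ab, TreeNode("C", .1)])
        abc.length = .1
        steps = traversal_schedule(
            self._rooted(TreeNode(children=[abc, TreeNode("D", .1)])))
        assert len(steps) == 3
        assert not any(s.parallel_eligible for s in steps)

    def test_polytomy_resolved_smallest_id_first(self):
        root = TreeNode(children=[TreeNode("C", .1), TreeNode("A", .1),
                                  TreeNode("B", .1)])
        steps = traversal_schedule(self._rooted(root))
        assert len(steps) == 2
        assert steps[0].left == frozenset("A")
        assert steps[0].right == frozenset("B")

    def test_step_count_is_n_minus_one(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = int(rng.integers(2, 12))
            true, dm = random_additive_tree(rng, n)
            steps = traversal_schedule(midpoint_root(nj_build(dm)))
            assert len(steps) == n - 1
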