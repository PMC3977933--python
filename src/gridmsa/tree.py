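"""Stage 2: neighbor-joining guide tree, rooting, weights, merge schedule.

The Saitou-Nei NJ algorithm turns the distance matrix into an unrooted tree
(trifurcating final join), which is midpoint-rooted to fix the progressive
merge order.  Sequence weights follow the branch-sharing rule: each leaf
accumulates, along its root-to-leaf path, every branch length divided by the
number of leaves sharing that branch, normalized so the largest weight is 1.
Finally the rooted tree is flattened into a post-order schedule of profile
merge steps, with steps on independent subtrees flagged as parallel-eligible.

NJ is implemented directly (rather than through a library call) because the
pipeline contract pins behaviors libraries leave open: the lexicographic
(i, j) tie-break on the Q criterion, and clamping of negative branch lengths
to zero with the deficit moved to the sister branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pairwise import DistanceMatrix


class TreeNode:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 children: list["TreeNode"] | None = None):
        self.name = name
        self.length = length
        self.children: list[TreeNode] = children or []
        self.parent: TreeNode | None = None
        for c in self.children:
            c.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def walk(self):
        """Depth-first, parents before children."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]


@dataclass
class GuideTree:
    root: TreeNode
    rooted: bool = False

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())


def nj_build(dm: DistanceMatrix) -> GuideTree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing Q(i,j) = (r-2) d(i,j) - R_i - R_j
    (ties broken toward the smallest (i, j) in current order); branch lengths
    come from the standard NJ formulas, with negative lengths clamped to zero
    and the deficit added to the sister branch.  Returns an unrooted tree
    whose final join is a trifurcation (n >= 3) or a single edge split at its
    middle (n = 2).
    """
    n = dm.n
    if n < 2:
        raise ValueError("need at least two taxa")
    D = dm.d.astype(np.float64).copy()
    nodes = [TreeNode(name=rid) for rid in dm.ids]

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        Q[np.tril_indices(r)] = np.inf
        # argmin over the flattened row-major array: ties resolve to the
        # smallest (i, j) automatically.
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        li = D[i, j] / 2 + (R[i] - R[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        li, lj = clamp_pair(li, lj)
        nodes[i].length, nodes[j].length = li, lj
        joined = TreeNode(children=[nodes[i], nodes[j]])
        dk = (D[i, :] + D[j, :] - D[i, j]) / 2
        D[i, :] = dk
        D[:, i] = dk
        D[i, i] = 0.0
        keep = [t for t in range(r) if t != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = joined
        del nodes[j]

    if len(nodes) == 2:
        half = D[0, 1] / 2
        nodes[0].length = half
        nodes[1].length = half
        return GuideTree(TreeNode(children=nodes), rooted=False)

    la = (D[0, 1] + D[0, 2] - D[1, 2]) / 2
    lb = (D[0, 1] + D[1, 2] - D[0, 2]) / 2
    lc = (D[0, 2] + D[1, 2] - D[0, 1]) / 2
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = max(length, 0.0)
    return GuideTree(TreeNode(children=nodes), rooted=False)


def _adjacency(tree: GuideTree):
    adj: dict[int, list[tuple[TreeNode, float]]] = {}
    index: dict[int, TreeNode] = {}
    for node in tree.root.walk():
        index[id(node)] = node
        adj.setdefault(id(node), [])
        for child in node.children:
            adj[id(node)].append((child, child.length))
            adj.setdefault(id(child), []).append((node, child.length))
    return adj, index


def _leaf_paths(tree: GuideTree, start: TreeNode, adj):
    """Distances and predecessor links from one node over the whole tree."""
    dist = {id(start): 0.0}
    prev: dict[int, TreeNode] = {}
    stack = [start]
    while stack:
        node = stack.pop()
        for nbr, length in adj[id(node)]:
            if id(nbr) not in dist:
                dist[id(nbr)] = dist[id(node)] + length
                prev[id(nbr)] = node
                stack.append(nbr)
    return dist, prev


def midpoint_root(tree: GuideTree) -> GuideTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Path lengths are preserved; the two endpoints are chosen deterministically
    (largest distance, ties toward lexicographically smallest leaf names).
    """
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValueError("need at least two leaves to root")
    adj, _ = _adjacency(tree)

    best: tuple[float, str, str] | None = None
    best_pair: tuple[TreeNode, TreeNode] | None = None
    paths: dict[int, tuple[dict, dict]] = {}
    for a in sorted(leaves, key=lambda n: n.name):
        dist, prev = _leaf_paths(tree, a, adj)
        paths[id(a)] = (dist, prev)
        for b in sorted(leaves, key=lambda n: n.name):
            if b.name <= a.name:
                continue
            cand = (dist[id(b)], a.name, b.name)
            if best is None or cand[0] > best[0]:
                best = cand
                best_pair = (a, b)
    assert best_pair is not None
    a, b = best_pair
    dist, prev = paths[id(a)]
    total = dist[id(b)]

    # Node path a -> b.
    path = [b]
    while path[-1] is not a:
        path.append(prev[id(path[-1])])
    path.reverse()

    half = total / 2
    cum = 0.0
    u = path[0]
    for u, v in zip(path, path[1:]):
        edge = dist[id(v)] - dist[id(u)]
        if cum + edge >= half:
            offset = half - cum  # distance from u along edge (u, v)
            return _root_on_edge(adj, u, v, edge, offset)
        cum += edge
    # Degenerate all-zero-length tree: root on the first edge.
    u, v = path[0], path[1]
    return _root_on_edge(adj, u, v, dist[id(v)] - dist[id(u)], 0.0)


def _root_on_edge(adj, u: TreeNode, v: TreeNode, edge: float,
                  offset: float) -> GuideTree:
    """Re-orient the tree from a new root placed on edge (u, v)."""

    def build(node: TreeNode, come_from: TreeNode, length: float) -> TreeNode:
        children = [build(nbr, node, l) for nbr, l in adj[id(node)]
                    if nbr is not come_from]
        out = TreeNode(name=node.name, length=length)
        for c in children:
            out.add(c)
        return out

    side_u = build(u, v, offset)
    side_v = build(v, u, edge - offset)
    root = TreeNode(children=[side_u, side_v])
    _suppress_unary(root)
    return GuideTree(root, rooted=True)


def _suppress_unary(root: TreeNode) -> None:
    """Merge internal nodes left with a single child into that child."""
    for node in list(root.walk()):
        for idx, child in enumerate(list(node.children)):
            while len(child.children) == 1 and child.name is None:
                only = child.children[0]
                only.length += child.length
                only.parent = node
                node.children[idx] = only
                child = only


@dataclass
class SequenceWeights:
    """Per-sequence weights, positive, normalized so the maximum is 1."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        for name, w in self.weights.items():
            if not np.isfinite(w) or w <= 0:
                raise ValueError(f"weight for {name!r} must be positive")

    def __getitem__(self, name: str) -> float:
        return self.weights[name]

    def items(self):
        return self.weights.items()


def compute_weights(tree: GuideTree) -> SequenceWeights:
    """Branch-sharing weights from a rooted tree.

    weight(leaf) = sum over root-to-leaf branches of length / (leaves below
    the branch), normalized to max 1.  An all-zero-length tree yields equal
    weights of 1; individual zero-path leaves are floored at a tiny positive
    value to keep every weight usable as a multiplier.
    """
    if not tree.rooted:
        raise ValueError("weights require a rooted tree")
    below: dict[int, int] = {}

    def count(node: TreeNode) -> int:
        below[id(node)] = (1 if node.is_leaf
                           else sum(count(c) for c in node.children))
        return below[id(node)]

    count(tree.root)

    raw: dict[str, float] = {}

    def descend(node: TreeNode, acc: float) -> None:
        if node is not tree.root:
            acc += node.length / below[id(node)]
        if node.is_leaf:
            raw[node.name] = acc
        for c in node.children:
            descend(c, acc)

    descend(tree.root, 0.0)
    top = max(raw.values())
    if top <= 0:
        return SequenceWeights({name: 1.0 for name in raw})
    return SequenceWeights(
        {name: max(w / top, 1e-8) for name, w in raw.items()})


@dataclass(frozen=True)
class MergeStep:
    """One profile-profile merge of the progressive schedule."""

    left: frozenset
    right: frozenset
    round: int
    parallel_eligible: bool

    @property
    def members(self) -> frozenset:
        return self.left | self.right


def traversal_schedule(tree: GuideTree) -> list[MergeStep]:
    """Post-order merge schedule of a rooted tree.

    Polytomies are resolved deterministically (children folded smallest
    leaf-id first).  A step is parallel-eligible when another step of the same
    dependency round exists — such steps cover disjoint subtrees and can run
    simultaneously.  A tree of n leaves always yields n - 1 steps.
    """
    if not tree.rooted:
        raise ValueError("schedule requires a rooted tree")

    steps: list[tuple[frozenset, frozenset, int]] = []

    def rec(node: TreeNode) -> tuple[frozenset, int]:
        if node.is_leaf:
            return frozenset({node.name}), 0
        parts = sorted((rec(c) for c in node.children),
                       key=lambda p: min(p[0]))
        ids, rnd = parts[0]
        for other_ids, other_rnd in parts[1:]:
            rnd = 1 + max(rnd, other_rnd)
            steps.append((ids, other_ids, rnd))
            ids = ids | other_ids
        return ids, rnd

    rec(tree.root)
    per_round: dict[int, int] = {}
    for _, _, rnd in steps:
        per_round[rnd] = per_round.get(rnd, 0) + 1
    return [MergeStep(left=l, right=r, round=rnd,
                      parallel_eligible=per_round[rnd] > 1)
            for l, r, rnd in steps]
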