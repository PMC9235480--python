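"""Rooted binary trees over single cells and their subtree-indicator algebra.

Cells are leaves with *fixed* indices 0..N-1 that never change across
topologies; internal nodes occupy indices N..2N-2 and are re-assigned
canonically (post-order) whenever the topology changes. Under the
infinite-sites assumption a mutation placed at node k produces exactly the
genotype column equal to row k of the subtree-indicator matrix S, where
S[k, i] = 1 iff leaf i lies in the subtree rooted at node k. S carries one
extra all-zero row (index 2N-1) encoding "no mutation at this site", so the
2N rows of S enumerate every genotype column reachable at a single site.
"""

from __future__ import annotations

import io as _io
from typing import Iterator, Sequence

import numpy as np
import skbio

__all__ = [
    "CellTree",
    "hamming_distances",
    "neighbor_joining",
    "build_subtree_matrix",
    "nni_move",
    "spr_move",
    "leaf_swap",
    "random_move",
]


class CellTree:
    """Rooted binary tree on N >= 2 cells.

    Parameters are the flat link arrays; most callers construct trees via
    :meth:`from_nested`, :meth:`from_newick`, :meth:`random_topology` or
    :func:`neighbor_joining`. Internal node indices are canonical: they follow
    post-order traversal from the root, so two structurally identical trees
    have identical arrays.
    """

    __slots__ = ("parent", "children", "root", "n_leaves", "names")

    def __init__(
        self,
        parent: np.ndarray,
        children: np.ndarray,
        root: int,
        names: Sequence[str] | None = None,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = np.asarray(children, dtype=np.int64)
        n_nodes = self.parent.shape[0]
        if n_nodes % 2 != 1:
            raise ValueError("a binary tree on N leaves has 2N-1 nodes")
        self.n_leaves = (n_nodes + 1) // 2
        self.root = int(root)
        self.names = (
            list(names) if names is not None else [f"cell{i}" for i in range(self.n_leaves)]
        )
        self.validate()

    # ------------------------------------------------------------------ #
    # construction

    @classmethod
    def from_nested(cls, nested, names: Sequence[str] | None = None) -> "CellTree":
        """Build from nested 2-tuples of leaf indices, e.g. ``((0, 1), 2)``."""
        leaves: list[int] = []

        def collect(x):
            if isinstance(x, tuple):
                if len(x) != 2:
                    raise ValueError("internal nodes must have exactly 2 children")
                collect(x[0])
                collect(x[1])
            else:
                leaves.append(int(x))

        collect(nested)
        n = len(leaves)
        if sorted(leaves) != list(range(n)):
            raise ValueError("leaf indices must be a permutation of 0..N-1")
        parent = np.full(2 * n - 1, -1, dtype=np.int64)
        children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
        counter = [n]

        def build(x) -> int:
            if not isinstance(x, tuple):
                return int(x)
            a = build(x[0])
            b = build(x[1])
            k = counter[0]
            counter[0] += 1
            children[k] = (a, b)
            parent[a] = k
            parent[b] = k
            return k

        root = build(nested)
        return cls(parent, children, root, names)

    @classmethod
    def random_topology(
        cls, n_leaves: int, rng: np.random.Generator, names: Sequence[str] | None = None
    ) -> "CellTree":
        """Uniform random rooted binary topology via sequential edge attachment.

        Leaf k is attached to one of the 2k-1 insertion points (every edge
        plus the slot above the root) uniformly, which makes all (2N-3)!!
        rooted labeled topologies equally likely.
        """
        if n_leaves < 2:
            raise ValueError("need at least 2 leaves")
        order = rng.permutation(n_leaves)
        # temp structure: dict node -> [left, right]; temp internal ids >= n
        par: dict[int, int] = {}
        kids: dict[int, list[int]] = {}
        nxt = n_leaves
        root = nxt
        kids[root] = [int(order[0]), int(order[1])]
        par[int(order[0])] = root
        par[int(order[1])] = root
        nxt += 1
        for leaf in order[2:]:
            leaf = int(leaf)
            nodes = [x for x in par]  # every non-root node: its parent edge
            choice = rng.integers(0, len(nodes) + 1)
            new = nxt
            nxt += 1
            if choice == len(nodes):  # above the root
                kids[new] = [root, leaf]
                par[root] = new
                par[leaf] = new
                root = new
            else:
                b = nodes[choice]
                a = par[b]
                kids[a][kids[a].index(b)] = new
                par[new] = a
                kids[new] = [b, leaf]
                par[b] = new
                par[leaf] = new
        return cls._from_link_dicts(kids, root, n_leaves, names)

    @classmethod
    def _from_link_dicts(
        cls,
        kids: dict[int, list[int]],
        root: int,
        n_leaves: int,
        names: Sequence[str] | None = None,
    ) -> "CellTree":
        """Canonicalize arbitrary internal ids into post-order indices."""
        post: list[int] = []
        stack: list[tuple[int, bool]] = [(root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                post.append(node)
                continue
            stack.append((node, True))
            if node in kids:
                for ch in reversed(kids[node]):
                    stack.append((ch, False))
        mapping: dict[int, int] = {}
        nxt = n_leaves
        for nd in post:
            if nd in kids:
                mapping[nd] = nxt
                nxt += 1
            else:
                mapping[nd] = nd
        parent = np.full(2 * n_leaves - 1, -1, dtype=np.int64)
        children = np.full((2 * n_leaves - 1, 2), -1, dtype=np.int64)
        for nd, (a, b) in kids.items():
            k = mapping[nd]
            children[k] = (mapping[a], mapping[b])
            parent[mapping[a]] = k
            parent[mapping[b]] = k
        return cls(parent, children, mapping[root], names)

    @classmethod
    def from_newick(cls, newick: str, names: Sequence[str]) -> "CellTree":
        """Parse a rooted binary newick string; leaf labels must match ``names``."""
        tn = skbio.TreeNode.read(_io.StringIO(newick))
        index = {str(nm): i for i, nm in enumerate(names)}
        return cls._from_skbio(tn, names, index)

    @classmethod
    def _from_skbio(cls, tn, names: Sequence[str], index: dict[str, int]) -> "CellTree":
        kids: dict[int, list[int]] = {}
        nxt = [len(names)]

        def conv(node) -> int:
            if node.is_tip():
                try:
                    return index[str(node.name)]
                except KeyError:
                    raise ValueError(f"unknown leaf label {node.name!r}")
            ch = list(node.children)
            if len(ch) != 2:
                raise ValueError("tree must be rooted and binary")
            k = nxt[0]
            nxt[0] += 1
            kids[k] = [conv(ch[0]), conv(ch[1])]
            return k

        root = conv(tn)
        return cls._from_link_dicts(kids, root, len(names), names)

    # ------------------------------------------------------------------ #
    # structure

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    def is_leaf(self, k: int) -> bool:
        return k < self.n_leaves

    def postorder(self) -> Iterator[int]:
        stack: list[tuple[int, bool]] = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
                continue
            stack.append((node, True))
            if not self.is_leaf(node):
                stack.append((int(self.children[node, 1]), False))
                stack.append((int(self.children[node, 0]), False))

    def validate(self) -> None:
        n = self.n_leaves
        if np.sum(self.parent == -1) != 1 or self.parent[self.root] != -1:
            raise ValueError("tree must have exactly one root")
        seen = list(self.postorder())
        if len(seen) != self.n_nodes or len(set(seen)) != self.n_nodes:
            raise ValueError("tree is not connected over all 2N-1 nodes")
        for k in range(self.n_nodes):
            if self.is_leaf(k):
                if self.children[k, 0] != -1 or self.children[k, 1] != -1:
                    raise ValueError(f"leaf {k} has children")
            else:
                a, b = self.children[k]
                if a == -1 or b == -1 or a == b:
                    raise ValueError(f"internal node {k} is not strictly binary")
                if self.parent[a] != k or self.parent[b] != k:
                    raise ValueError("parent/child links disagree")
        if len(self.names) != n:
            raise ValueError("names length must equal leaf count")

    def copy(self) -> "CellTree":
        return CellTree(self.parent.copy(), self.children.copy(), self.root, list(self.names))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CellTree)
            and self.root == other.root
            and np.array_equal(self.parent, other.parent)
            and np.array_equal(self.children, other.children)
        )

    def __hash__(self):  # canonical arrays make this a topology hash
        return hash((self.root, self.parent.tobytes(), self.children.tobytes()))

    def leaves_under(self, k: int) -> np.ndarray:
        """Sorted leaf indices in the subtree rooted at node k."""
        out = []
        stack = [k]
        while stack:
            nd = stack.pop()
            if self.is_leaf(nd):
                out.append(nd)
            else:
                stack.extend(self.children[nd])
        return np.array(sorted(out), dtype=np.int64)

    def subtree_matrix(self) -> np.ndarray:
        """2N x N subtree-indicator matrix S (float64 0/1), last row all zeros."""
        return build_subtree_matrix(self)

    def clades(self) -> set[frozenset]:
        """Leaf sets of all internal nodes (the tree's clades)."""
        S = self.subtree_matrix()
        return {
            frozenset(np.flatnonzero(S[k]).tolist())
            for k in range(self.n_leaves, self.n_nodes)
        }

    # ------------------------------------------------------------------ #
    # newick io (via scikit-bio)

    def to_skbio(self) -> skbio.TreeNode:
        nodes = [skbio.TreeNode(name=None) for _ in range(self.n_nodes)]
        for i in range(self.n_leaves):
            nodes[i].name = self.names[i]
        for k in self.postorder():
            if not self.is_leaf(k):
                nodes[k].extend([nodes[int(c)] for c in self.children[k]])
        return nodes[self.root]

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self.to_skbio().write(buf, format="newick")
        return buf.getvalue().strip()

    def __repr__(self) -> str:
        return f"<CellTree n_leaves={self.n_leaves} root={self.root}>"


def build_subtree_matrix(tree: CellTree) -> np.ndarray:
    """Subtree-indicator matrix in one post-order pass.

    Row k marks the leaves of the subtree rooted at node k; the appended row
    2N-1 is all zeros (the no-mutation placement). The root row is all ones.
    """
    n, m = tree.n_leaves, tree.n_nodes
    S = np.zeros((m + 1, n), dtype=np.float64)
    S[np.arange(n), np.arange(n)] = 1.0
    for k in tree.postorder():
        if not tree.is_leaf(k):
            a, b = tree.children[k]
            np.add(S[a], S[b], out=S[k])  # disjoint leaf sets: OR == sum
    return S


def hamming_distances(G: np.ndarray, missing_mask: np.ndarray | None = None) -> np.ndarray:
    """Pairwise-complete normalized Hamming distance between genotype rows.

    d(a,b) = #{loci observed in both cells where g_a != g_b} / #{loci observed
    in both}; 0 when the cells share no observed loci.
    """
    G = np.asarray(G)
    if missing_mask is None:
        missing_mask = np.zeros_like(G, dtype=bool)
    valid = (~np.asarray(missing_mask, dtype=bool)).astype(np.float64)
    A = (G == 1) * valid
    B = (G == 0) * valid
    mismatch = A @ B.T + B @ A.T
    shared = valid @ valid.T
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(shared > 0, mismatch / np.maximum(shared, 1.0), 0.0)
    np.fill_diagonal(D, 0.0)
    return D


def neighbor_joining(D: np.ndarray, names: Sequence[str]) -> CellTree:
    """Saitou–Nei neighbor joining (scikit-bio), rooted deterministically.

    The unrooted NJ tree is represented by scikit-bio with a trifurcating
    root; we root on the edge to its first child, which fixes a reproducible
    rooted topology. Root placement only shifts which node carries the clonal
    (all-cells) mutation placement; the all-ones indicator row exists for any
    rooting.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if D.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distance matrix must be non-negative")
    ids = [str(nm) for nm in names]
    dm = skbio.DistanceMatrix(D, ids=ids)
    tn = skbio.tree.nj(dm)
    ch = list(tn.children)
    if len(ch) == 3:
        first = ch[0]
        tn.remove(first)
        new_root = skbio.TreeNode()
        new_root.extend([first, tn])
    elif len(ch) == 2:
        new_root = tn
    else:
        raise RuntimeError("unexpected NJ tree degree")
    index = {nm: i for i, nm in enumerate(ids)}
    return CellTree._from_skbio(new_root, list(names), index)


# ---------------------------------------------------------------------- #
# rearrangement moves. Each returns (new_tree, changed); the input tree is
# never mutated and the output has canonical internal indices.


def _links(tree: CellTree) -> tuple[dict[int, list[int]], int]:
    kids = {
        int(k): [int(tree.children[k, 0]), int(tree.children[k, 1])]
        for k in range(tree.n_leaves, tree.n_nodes)
    }
    return kids, tree.root


def leaf_swap(tree: CellTree, rng: np.random.Generator) -> tuple[CellTree, bool]:
    """Exchange the tree positions of two random distinct cells."""
    n = tree.n_leaves
    if n < 2:
        return tree.copy(), False
    i, j = rng.choice(n, size=2, replace=False)
    i, j = int(i), int(j)
    kids, root = _links(tree)
    pi, pj = int(tree.parent[i]), int(tree.parent[j])
    kids[pi][kids[pi].index(i)] = j
    kids[pj][kids[pj].index(j)] = i
    return CellTree._from_link_dicts(kids, root, n, tree.names), True


def nni_move(tree: CellTree, rng: np.random.Generator) -> tuple[CellTree, bool]:
    """Nearest-neighbor interchange around a random internal edge.

    For an internal edge (u, w), swaps the sibling of w with a random child
    of w — one of the two alternative resolutions of that edge.
    """
    n = tree.n_leaves
    internal_edges = [
        k for k in range(n, tree.n_nodes) if tree.parent[k] != -1
    ]
    if not internal_edges:
        return tree.copy(), False
    w = int(internal_edges[rng.integers(0, len(internal_edges))])
    u = int(tree.parent[w])
    kids, root = _links(tree)
    sib = kids[u][0] if kids[u][1] == w else kids[u][1]
    x = kids[w][int(rng.integers(0, 2))]
    kids[u][kids[u].index(sib)] = x
    kids[w][kids[w].index(x)] = sib
    return CellTree._from_link_dicts(kids, root, n, tree.names), True


def spr_move(tree: CellTree, rng: np.random.Generator) -> tuple[CellTree, bool]:
    """Subtree prune and regraft: detach a random non-root subtree and
    reattach it on a random edge of the remaining tree."""
    n = tree.n_leaves
    non_root = [k for k in range(tree.n_nodes) if k != tree.root]
    if not non_root:
        return tree.copy(), False
    p = int(non_root[rng.integers(0, len(non_root))])
    kids, root = _links(tree)
    u = int(tree.parent[p])
    sib = kids[u][0] if kids[u][1] == p else kids[u][1]
    pruned = set(tree.leaves_under(p).tolist())
    stack = [p]
    pruned_nodes = set()
    while stack:
        nd = stack.pop()
        pruned_nodes.add(nd)
        if nd in kids and nd != u:
            stack.extend(kids[nd])
    # splice out u
    del kids[u]
    if u == root:
        new_root = sib
    else:
        g = int(tree.parent[u])
        kids[g][kids[g].index(u)] = sib
        new_root = root
    # eligible regraft edges: above any remaining non-root node
    remaining = [
        k
        for k in range(tree.n_nodes)
        if k not in pruned_nodes and k != u and k != new_root
    ]
    # exclude the edge above sib when it recreates the original attachment?
    # keep it: regrafting there reproduces the input topology, a harmless
    # proposal that the acceptance rule treats as a neutral move.
    if not remaining:
        return tree.copy(), False
    b = int(remaining[rng.integers(0, len(remaining))])
    # find b's current parent in the edited links
    a = next(k for k, ch in kids.items() if b in ch)
    kids[a][kids[a].index(b)] = u
    kids[u] = [b, p]
    return CellTree._from_link_dicts(kids, new_root, n, tree.names), True


_MOVES = (nni_move, spr_move, leaf_swap)


def random_move(
    tree: CellTree,
    rng: np.random.Generator,
    probs: Sequence[float] = (0.5, 0.4, 0.1),
) -> tuple[CellTree, str, bool]:
    """Draw one of NNI / SPR / leaf-swap with the given mixture probabilities."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (3,) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("move probabilities must be 3 values summing to 1")
    idx = int(rng.choice(3, p=probs))
    new, changed = _MOVES[idx](tree, rng)
    return new, ("nni", "spr", "leaf_swap")[idx], changed
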