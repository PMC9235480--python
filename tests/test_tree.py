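"""Cell-tree structure, subtree indicators, NJ and rearrangement moves."""

import itertools

import numpy as np
import pytest

from phylosnv.tree import (
    CellTree,
    build_subtree_matrix,
    hamming_distances,
    leaf_swap,
    neighbor_joining,
    nni_move,
    random_move,
    spr_move,
)


def unrooted_splits(tree: CellTree) -> set:
    """Non-trivial bipartitions of the leaf set (rooting-independent)."""
    n = tree.n_leaves
    full = frozenset(range(n))
    out = set()
    for clade in tree.clades():
        if 1 < len(clade) < n - 1 or (len(clade) == n - 1):
            comp = frozenset(full - clade)
            if len(clade) > 1 and len(comp) > 1:
                out.add(frozenset({clade, comp}))
    return out


def all_rooted_topologies(n):
    """Exhaustive enumeration of rooted binary trees on leaves 0..n-1."""

    def build(leaves):
        if len(leaves) == 1:
            yield leaves[0]
            return
        first, rest = leaves[0], leaves[1:]
        for k in range(1, len(leaves)):
            for left_rest in itertools.combinations(rest, k - 1):
                right = [x for x in rest if x not in left_rest]
                for lt in build([first, *left_rest]):
                    for rt in build(right):
                        yield (lt, rt)

    for nested in build(list(range(n))):
        yield CellTree.from_nested(nested)


# --------------------------------------------------------------------- #
# structure / subtree matrix


def test_three_leaf_subtree_matrix_by_hand():
    tree = CellTree.from_nested(((0, 1), 2))
    S = build_subtree_matrix(tree)
    expected = np.array(
        [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [1, 1, 1], [0, 0, 0]], float
    )
    np.testing.assert_array_equal(S, expected)


def test_subtree_matrix_invariants_random(rng):
    for _ in range(50):
        n = int(rng.integers(3, 33))
        tree = CellTree.random_topology(n, rng)
        S = build_subtree_matrix(tree)
        assert S.shape == (2 * n, n)
        np.testing.assert_array_equal(S[tree.root], np.ones(n))
        np.testing.assert_array_equal(S[:n], np.eye(n))
        np.testing.assert_array_equal(S[2 * n - 1], np.zeros(n))
        for k in range(n, 2 * n - 1):
            a, b = tree.children[k]
            np.testing.assert_array_equal(S[k], np.maximum(S[a], S[b]))
        # each leaf belongs to exactly its ancestors' subtrees
        depth_plus_one = S[: 2 * n - 1].sum(axis=0)
        for i in range(n):
            d, node = 0, i
            while node != -1:
                d += 1
                node = int(tree.parent[node])
            assert depth_plus_one[i] == d


@pytest.mark.parametrize("n", [3, 4, 5])
def test_placement_to_genotype_map_is_injective(n):
    # all 2N rows of S distinct on every rooted topology
    for tree in all_rooted_topologies(n):
        S = build_subtree_matrix(tree)
        assert len({row.tobytes() for row in S}) == 2 * n


def test_newick_round_trip(rng):
    tree = CellTree.random_topology(8, rng)
    back = CellTree.from_newick(tree.to_newick(), tree.names)
    assert back == tree


# --------------------------------------------------------------------- #
# hamming distances


def test_hamming_hand_counts():
    G = np.array([[0, 0, 1, 1], [0, 1, 1, 0]])
    D = hamming_distances(G)
    assert D[0, 1] == pytest.approx(0.5)
    assert D[0, 0] == 0.0

    G2 = np.array([[0, 1], [1, 1]])
    miss = np.array([[True, False], [False, False]])
    D2 = hamming_distances(G2, miss)
    assert D2[0, 1] == 0.0  # only the shared locus 2 counts, and it agrees

    identical = np.array([[1, 0, 1], [1, 0, 1]])
    assert hamming_distances(identical)[0, 1] == 0.0


def test_hamming_no_shared_loci_is_zero():
    G = np.array([[1, 0], [0, 1]])
    miss = np.array([[False, True], [True, False]])
    assert hamming_distances(G, miss)[0, 1] == 0.0


# --------------------------------------------------------------------- #
# neighbor joining


def _additive_distance(tree_nested, bl):
    """Path distances on a 4-taxon tree ((0,1),(2,3)) with branch lengths."""
    # leaves 0,1 join at u; 2,3 at w; u-w internal edge
    d = np.zeros((4, 4))
    paths = {
        (0, 1): bl[0] + bl[1],
        (0, 2): bl[0] + bl[4] + bl[2],
        (0, 3): bl[0] + bl[4] + bl[3],
        (1, 2): bl[1] + bl[4] + bl[2],
        (1, 3): bl[1] + bl[4] + bl[3],
        (2, 3): bl[2] + bl[3],
    }
    for (a, b), v in paths.items():
        d[a, b] = d[b, a] = v
    return d


def test_nj_three_taxa_single_topology():
    D = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float)
    tree = neighbor_joining(D, ["a", "b", "c"])
    assert tree.n_leaves == 3  # only one unrooted topology exists
    tree.validate()


def test_nj_recovers_additive_four_taxon_topology(rng):
    for _ in range(10):
        bl = rng.uniform(0.5, 3.0, size=5)
        D = _additive_distance(((0, 1), (2, 3)), bl)
        tree = neighbor_joining(D, [f"c{i}" for i in range(4)])
        assert unrooted_splits(tree) == {
            frozenset({frozenset({0, 1}), frozenset({2, 3})})
        }


def test_nj_least_squares_oracle_four_taxa(rng):
    """NJ's chosen topology minimizes least-squares fit over all 3 topologies."""
    from scipy.optimize import nnls

    def ls_error(D, split):
        # design matrix over the 5 branch lengths of the split topology
        pairs = list(itertools.combinations(range(4), 2))
        (a, b), (c, d) = split
        A = np.zeros((6, 5))
        for row, (x, y) in enumerate(pairs):
            for leaf, col in ((a, 0), (b, 1), (c, 2), (d, 3)):
                if leaf in (x, y):
                    A[row, col] = 1
            same = {x, y} in ({a, b}, {c, d})
            if not same:
                A[row, 4] = 1
        y = np.array([D[x, yy] for x, yy in pairs])
        _, err = nnls(A, y)
        return err

    splits = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
    for _ in range(10):
        bl = rng.uniform(0.5, 3.0, size=5)
        D = _additive_distance(None, bl)
        best = min(splits, key=lambda s: ls_error(D, s))
        tree = neighbor_joining(D, [f"c{i}" for i in range(4)])
        want = frozenset({frozenset(best[0]), frozenset(best[1])})
        assert unrooted_splits(tree) == {want}


def test_nj_invariant_to_taxon_permutation(rng):
    bl = rng.uniform(0.5, 3.0, size=5)
    D = _additive_distance(None, bl)
    names = [f"c{i}" for i in range(4)]
    base = unrooted_splits(neighbor_joining(D, names))
    perm = rng.permutation(4)
    Dp = D[np.ix_(perm, perm)]
    tree_p = neighbor_joining(Dp, [names[i] for i in perm])
    # translate leaf indices of the permuted tree back to original labels
    back = {
        frozenset(
            frozenset(int(perm[i]) for i in side) for side in split
        )
        for split in unrooted_splits(tree_p)
    }
    assert back == base


def test_nj_rejects_bad_matrices():
    with pytest.raises(ValueError):
        neighbor_joining(np.array([[0, 1], [1, 0]]), ["a", "b"])
    bad = np.array([[0, 1, 2], [9, 0, 3], [2, 3, 0]], float)
    with pytest.raises(ValueError):
        neighbor_joining(bad, ["a", "b", "c"])
    neg = np.array([[0, -1, 2], [-1, 0, 3], [2, 3, 0]], float)
    with pytest.raises(ValueError):
        neighbor_joining(neg, ["a", "b", "c"])


def test_nj_recovers_generating_topology_from_clean_genotypes(rng):
    from phylosnv.simulate import SimConfig, simulate

    for seed in (11, 12, 13):
        counts, truth = simulate(
            SimConfig(n_cells=16, n_sites=500, coverage_mean=40, seed=seed)
        )
        D = hamming_distances(truth.genotypes)
        tree = neighbor_joining(D, counts.cell_names)
        assert unrooted_splits(tree) == unrooted_splits(truth.tree)  # RF = 0


# --------------------------------------------------------------------- #
# moves


def test_leaf_swap_hand_example(rng):
    tree = CellTree.from_nested(((0, 1), 2))
    # force the swap of leaves 0 and 2 by trying seeds until that pair is drawn
    for seed in range(50):
        r = np.random.default_rng(seed)
        i, j = r.choice(3, size=2, replace=False)
        if {int(i), int(j)} == {0, 2}:
            new, changed = leaf_swap(tree, np.random.default_rng(seed))
            assert changed
            assert new == CellTree.from_nested(((2, 1), 0))
            return
    pytest.fail("no seed drew the (0, 2) leaf pair")


@pytest.mark.parametrize("move", [nni_move, spr_move, leaf_swap])
def test_moves_preserve_invariants(move, rng):
    for _ in range(200):
        n = int(rng.integers(4, 20))
        tree = CellTree.random_topology(n, rng)
        new, _ = move(tree, rng)
        new.validate()
        assert new.n_leaves == n
        assert sorted(new.leaves_under(new.root)) == list(range(n))


def test_nni_reaches_exact_neighborhood(rng):
    """Random NNI draws cover exactly the brute-force NNI neighborhood."""
    tree = CellTree.from_nested((((0, 1), (2, 3)), 4))

    # brute force: for every internal edge, both swaps
    expected = set()
    for w in range(tree.n_leaves, tree.n_nodes):
        if tree.parent[w] == -1:
            continue
        u = int(tree.parent[w])
        for child_slot in (0, 1):
            kids = {
                int(k): [int(tree.children[k, 0]), int(tree.children[k, 1])]
                for k in range(tree.n_leaves, tree.n_nodes)
            }
            sib = kids[u][0] if kids[u][1] == w else kids[u][1]
            x = kids[w][child_slot]
            kids[u][kids[u].index(sib)] = x
            kids[w][kids[w].index(x)] = sib
            expected.add(CellTree._from_link_dicts(kids, tree.root, 5, tree.names))

    seen = set()
    for _ in range(400):
        new, changed = nni_move(tree, rng)
        assert changed
        seen.add(new)
    assert seen == expected


def test_spr_can_change_root_side_and_stays_valid(rng):
    tree = CellTree.random_topology(6, rng)
    results = {spr_move(tree, rng)[0] for _ in range(100)}
    assert all(t.n_leaves == 6 for t in results)
    assert len(results) > 5  # SPR explores many distinct topologies


def test_random_move_respects_mixture(rng):
    tree = CellTree.random_topology(6, rng)
    kinds = {random_move(tree, rng)[1] for _ in range(300)}
    assert kinds == {"nni", "spr", "leaf_swap"}
    with pytest.raises(ValueError):
        random_move(tree, rng, probs=(0.5, 0.5, 0.5))
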