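"""Neighbor joining, bootstrap supports, Fitch parsimony scoring."""

import random

import numpy as np
import pytest

from _oracles import fitch_exhaustive, quartet_best_topology, random_additive_tree
from ugtevol.phylogeny import (
    bootstrap,
    DistanceMatrix,
    fitch_score,
    nj_tree,
    p_distance,
    Tree,
    TreeNode,
)


def test_p_distance_examples():
    dm = p_distance({"x": "AAAA", "y": "AAAT", "z": "AAAA"})
    i, j = dm.ids.index("x"), dm.ids.index("y")
    assert dm.d[i, j] == pytest.approx(0.25)
    assert dm.d[i, dm.ids.index("z")] == 0.0
    assert np.allclose(dm.d, dm.d.T)


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float)
    tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
    lengths = {child.name: bl for child, bl in tree.root.children}
    assert lengths["a"] == pytest.approx((5 + 9 - 8) / 2)
    assert lengths["b"] == pytest.approx((5 + 8 - 9) / 2)
    assert lengths["c"] == pytest.approx((9 + 8 - 5) / 2)


def test_nj_needs_three_taxa():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


def test_nj_quartet_matches_least_squares_oracle(rng):
    for _ in range(25):
        splits, d, ids = random_additive_tree(4, rng)
        mat = np.array([[d[(x, y)] for y in ids] for x in ids])
        tree = nj_tree(DistanceMatrix(ids, mat))
        got = tree.splits()
        assert got == splits
        # independent four-point-condition oracle agrees on the grouping
        pair = quartet_best_topology(ids, d)
        assert pair in got or (frozenset(ids) - pair) in got


def test_nj_recovers_additive_topologies(rng):
    for _ in range(40):
        n = rng.randint(5, 8)
        splits, d, ids = random_additive_tree(n, rng)
        mat = np.array([[d[(x, y)] for y in ids] for x in ids])
        tree = nj_tree(DistanceMatrix(ids, mat))
        assert tree.splits() == splits


def test_nj_ultrametric_matches_single_linkage(rng):
    # clear two-cluster ultrametric: {a,b} vs {c,d,e}
    ids = ["a", "b", "c", "d", "e"]
    d = np.full((5, 5), 1.0)
    for i in range(5):
        d[i, i] = 0
    d[0, 1] = d[1, 0] = 0.2
    d[2, 3] = d[3, 2] = 0.3
    d[2, 4] = d[4, 2] = 0.5
    d[3, 4] = d[4, 3] = 0.5
    tree = nj_tree(DistanceMatrix(ids, d))
    assert frozenset(["c", "d", "e"]) in tree.splits() or frozenset(["a", "b"]) in tree.splits()


def test_nj_crosscheck_dendropy(rng):
    """Independent NJ implementation produces the same unrooted topology."""
    import dendropy

    for _ in range(5):
        n = rng.randint(5, 7)
        splits, d, ids = random_additive_tree(n, rng)
        mat = np.array([[d[(x, y)] for y in ids] for x in ids])
        mine = nj_tree(DistanceMatrix(ids, mat)).splits()

        csv = "," + ",".join(ids) + "\n"
        for x in ids:
            csv += x + "," + ",".join(str(d[(x, y)]) for y in ids) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv)
        )
        dtree = pdm.nj_tree()
        theirs = Tree.from_newick(dtree.as_string(schema="newick")).splits()
        assert mine == theirs


def test_negative_branch_clamped():
    ids = ["a", "b", "c", "d"]
    d = np.array(
        [[0, 1, 10, 10], [1, 0, 1, 10], [10, 1, 0, 1], [10, 10, 1, 0]], dtype=float
    )
    tree = nj_tree(DistanceMatrix(ids, d))

    def all_lengths(node):
        for child, bl in node.children:
            yield bl
            yield from all_lengths(child)

    assert all(bl >= 0 for bl in all_lengths(tree.root))


def _constant_alignment():
    return {t: "AAAACCCC" for t in "abcde"}


def test_bootstrap_constant_columns_full_support(rng):
    # two clean groups; every resampled replicate yields the same split
    aln = {"a": "AAAAAAAA", "b": "AAAAAAAA", "c": "TTTTTTTT",
           "d": "TTTTTTCC", "e": "TTTTTTCC"}
    support = bootstrap(aln, n_reps=50, seed=4)
    assert support
    assert all(0 <= v <= 100 for v in support.values())
    assert max(support.values()) == 100.0


def test_bootstrap_deterministic_under_seed():
    aln = {"a": "AAAATTAA", "b": "AAAATAAA", "c": "TTTTAATT",
           "d": "TTCTTTTT", "e": "TCTTTTCT"}
    s1 = bootstrap(aln, n_reps=30, seed=123)
    s2 = bootstrap(aln, n_reps=30, seed=123)
    assert s1 == s2


def test_bootstrap_strong_split_high_support():
    rng = random.Random(6)
    # 40 columns supporting {a,b} vs {c,d,e}
    cols_ab = ["A"] * 40
    aln = {
        "a": "".join(cols_ab),
        "b": "".join("A" if rng.random() > 0.05 else "C" for _ in range(40)),
        "c": "".join("T" if rng.random() > 0.05 else "G" for _ in range(40)),
        "d": "".join("T" if rng.random() > 0.05 else "C" for _ in range(40)),
        "e": "".join("T" if rng.random() > 0.05 else "A" for _ in range(40)),
    }
    support = bootstrap(aln, n_reps=500, seed=9)
    key = frozenset(["c", "d", "e"])
    alt = frozenset(["a", "b"])
    val = support.get(key, support.get(alt))
    assert val is not None and val > 95


def test_bootstrap_invariant_to_leaf_order():
    aln = {"a": "AAAATTAA", "b": "AAAATAAA", "c": "TTTTAATT",
           "d": "TTCTTTTT", "e": "TCTTTTCT"}
    s1 = bootstrap(aln, n_reps=25, seed=5)
    s2 = bootstrap(dict(reversed(list(aln.items()))), n_reps=25, seed=5)
    assert s1 == s2


def _quartet_tree():
    # ((1,2),(3,4)) unrooted
    n1, n2, n3, n4 = (TreeNode(name=str(i)) for i in range(1, 5))
    inner = TreeNode(children=[(n3, 1.0), (n4, 1.0)])
    root = TreeNode(children=[(n1, 1.0), (n2, 1.0), (inner, 1.0)])
    return Tree(root=root)


@pytest.mark.parametrize(
    "states,expected",
    [({"1": "A", "2": "A", "3": "C", "4": "C"}, 1),
     ({"1": "A", "2": "C", "3": "A", "4": "C"}, 2),
     ({"1": "A", "2": "A", "3": "A", "4": "A"}, 0)],
)
def test_fitch_quartet_examples(states, expected):
    aln = {k: v for k, v in states.items()}
    assert fitch_score(_quartet_tree(), aln) == expected


def test_fitch_matches_exhaustive_enumeration(rng):
    for _ in range(10):
        n = rng.randint(4, 6)
        splits, d, ids = random_additive_tree(n, rng)
        mat = np.array([[d[(x, y)] for y in ids] for x in ids])
        tree = nj_tree(DistanceMatrix(ids, mat))

        # flatten my tree to parent pointers for the oracle
        parent_of = {}

        def walk(node, parent):
            parent_of[id(node)] = id(parent) if parent is not None else None
            for child, _ in node.children:
                walk(child, node)

        walk(tree.root, None)

        for _ in range(10):
            states = {i: rng.choice("ACGT") for i in ids}
            leaf_states = {}

            def attach(node):
                if node.is_leaf:
                    leaf_states[id(node)] = states[node.name]
                for child, _ in node.children:
                    attach(child)

            attach(tree.root)
            expected = fitch_exhaustive(parent_of, leaf_states, "ACGT")
            got = fitch_score(tree, {i: states[i] for i in ids})
            assert got == expected


def test_fitch_label_mismatch():
    with pytest.raises(ValueError):
        fitch_score(_quartet_tree(), {"1": "A", "2": "A", "3": "C"})


def test_newick_round_trip():
    tree = _quartet_tree()
    tree.supports = {frozenset(["3", "4"]): 87.0}
    text = tree.newick()
    assert text.endswith(";")
    back = Tree.from_newick(text)
    assert set(back.leaf_names()) == {"1", "2", "3", "4"}
    assert back.splits() == tree.splits()
    assert back.supports.get(frozenset(["3", "4"])) == 87.0


def test_phylip_output():
    dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]]))
    text = dm.to_phylip()
    assert text.splitlines()[0].strip() == "3"
    assert len(text.splitlines()) == 4
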