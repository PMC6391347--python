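import numpy as np
import pytest

from campop.core import GenotypeMatrix
from campop.distances import DistanceMatrix
from campop.njtree import bootstrap_support, neighbor_joining


def _random_additive_tree(n_leaves, rng):
    """Random binary tree with positive branch lengths; returns the leaf
    distance matrix and the set of non-trivial bipartitions."""
    labels = [f"t{i}" for i in range(n_leaves)]
    # start from a 3-star, then attach leaves to random edges
    adj = {}

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def del_edge(a, b):
        del adj[a][b]
        del adj[b][a]

    lengths = rng.uniform(0.5, 3.0, size=4 * n_leaves)
    li = iter(lengths)
    add_edge(labels[0], "x0", next(li))
    add_edge(labels[1], "x0", next(li))
    add_edge(labels[2], "x0", next(li))
    next_internal = 1
    for leaf in labels[3:]:
        edges = [(a, b) for a in adj for b in adj[a] if str(a) < str(b)]
        a, b = edges[rng.integers(len(edges))]
        w = adj[a][b]
        node = f"x{next_internal}"
        next_internal += 1
        del_edge(a, b)
        u = rng.uniform(0.2, 0.8)
        add_edge(a, node, w * u)
        add_edge(node, b, w * (1 - u))
        add_edge(node, leaf, next(li))

    # path lengths by BFS
    def dist(a, b):
        stack = [(a, 0.0)]
        seen = {a}
        while stack:
            node, acc = stack.pop()
            if node == b:
                return acc
            for nbr, w in adj[node].items():
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append((nbr, acc + w))
        raise AssertionError("disconnected")

    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dist(labels[i], labels[j])

    def leaves_behind(frm, to):
        stack = [to]
        seen = {frm, to}
        out = set()
        while stack:
            node = stack.pop()
            if node in labels:
                out.add(node)
            for nbr in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return out

    splits = set()
    allset = set(labels)
    for a in adj:
        for b in adj[a]:
            side = leaves_behind(a, b)
            if 2 <= len(side) <= n - 2:
                other = allset - side
                splits.add(frozenset(min(sorted(side), sorted(other))))
    return labels, d, splits


class TestNeighborJoining:
    def test_two_leaves_single_edge(self):
        tree = neighbor_joining(
            DistanceMatrix(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        )
        edges = tree.edges()
        assert len(edges) == 1
        assert edges[0][2] == pytest.approx(3.0)

    def test_four_taxon_additive_recovered_exactly(self):
        # tree: (A:1,B:2) -- 5 -- (C:3,D:4)
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 9, 10],
                [3, 0, 10, 11],
                [9, 10, 0, 7],
                [10, 11, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(labels, d))
        lengths = {
            frozenset((str(a), str(b))): l for a, b, l in tree.edges()
        }
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        pendant = {
            leaf: next(l for k, l in lengths.items() if leaf in k)
            for leaf in labels
        }
        assert pendant == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        internal = [l for k, l in lengths.items()
                    if not (k & set(labels))]
        assert internal == pytest.approx([5.0])

    def test_equidistant_triplet_splits_evenly(self):
        d = np.full((3, 3), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(DistanceMatrix(list("ABC"), d))
        assert [l for _, _, l in tree.edges()] == pytest.approx([1.0] * 3)

    def test_edge_count_invariant(self):
        rng = np.random.default_rng(0)
        labels, d, _ = _random_additive_tree(7, rng)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert len(tree.edges()) == 2 * 7 - 3

    @pytest.mark.parametrize("trial", range(10))
    def test_additive_matrices_recover_generating_bipartitions(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 11))
        labels, d, splits = _random_additive_tree(n, rng)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert tree.bipartitions() == splits

    def test_leaf_permutation_yields_isomorphic_tree(self):
        rng = np.random.default_rng(5)
        labels, d, _ = _random_additive_tree(8, rng)
        tree1 = neighbor_joining(DistanceMatrix(labels, d))
        perm = rng.permutation(len(labels))
        tree2 = neighbor_joining(
            DistanceMatrix([labels[i] for i in perm], d[np.ix_(perm, perm)])
        )
        assert tree1.bipartitions() == tree2.bipartitions()

    def test_agrees_with_skbio_on_additive_matrix(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj

        rng = np.random.default_rng(9)
        labels, d, _ = _random_additive_tree(8, rng)
        ours = neighbor_joining(DistanceMatrix(labels, d)).bipartitions()
        sk_tree = nj(SkDM(d, ids=labels))
        theirs = set()
        allset = set(labels)
        for node in sk_tree.non_tips(include_self=False):
            side = {t.name for t in node.tips()}
            other = allset - side
            if 2 <= len(side) <= len(labels) - 2:
                theirs.add(frozenset(min(sorted(side), sorted(other))))
        assert ours == theirs

    def test_newick_roundtrips_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(2)
        labels, d, splits = _random_additive_tree(6, rng)
        newick = neighbor_joining(DistanceMatrix(labels, d)).to_newick()
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {t.taxon.label for t in tree.leaf_node_iter()} == set(labels)


class TestBootstrap:
    def test_separated_populations_get_high_support(self, two_pop_panel):
        gm = two_pop_panel["gm"].take_individuals(
            np.concatenate([np.arange(8), np.arange(30, 38)])
        )
        tree = bootstrap_support(gm, n_replicates=50, seed=3)
        splits = tree.bipartitions()
        pop1 = frozenset(gm.sample_ids[:8])
        target = pop1 if pop1 in splits else frozenset(gm.sample_ids[8:])
        assert target in splits
        edge = tree.edge_for_bipartition(target)
        assert tree.support[frozenset(edge)] >= 95.0

    def test_single_replicate_supports_are_binary(self, two_pop_panel):
        gm = two_pop_panel["gm"].take_individuals(np.arange(8))
        tree = bootstrap_support(gm, n_replicates=1, seed=0)
        assert set(tree.support.values()) <= {0.0, 100.0}

    def test_duplicated_individuals_form_certain_cherry(self):
        rng = np.random.default_rng(8)
        base = rng.integers(0, 3, size=(6, 80)).astype(np.int8)
        base[5] = base[4]  # exact duplicates
        # separate the duplicate pair from the rest so the cherry is an
        # internal bipartition
        base[4:, :40] = 2
        gm = GenotypeMatrix(base, [f"i{k}" for k in range(6)],
                            [f"L{j}" for j in range(80)])
        tree = bootstrap_support(gm, n_replicates=30, seed=1)
        # canonical split representative is the lexicographically smaller side
        cherry = frozenset(min(sorted({"i4", "i5"}),
                               sorted({"i0", "i1", "i2", "i3"})))
        assert cherry in tree.bipartitions()
        edge = tree.edge_for_bipartition(cherry)
        assert tree.support[frozenset(edge)] == 100.0

    def test_deterministic_under_seed(self, two_pop_panel):
        gm = two_pop_panel["gm"].take_individuals(np.arange(10))
        t1 = bootstrap_support(gm, n_replicates=20, seed=9)
        t2 = bootstrap_support(gm, n_replicates=20, seed=9)
        assert t1.support == t2.support
        assert t1.to_newick() == t2.to_newick()
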