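"""NJ/UPGMA reconstruction, midpoint rooting and Robinson-Foulds."""

import io

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

import phylogap as pg
from phylogap.io import newick_string


def random_binary_tree(rng, n, min_len=0.1, max_len=1.0):
    """Random rooted binary tree over t1..tn with lengths in [min_len, max_len]."""
    tns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n):
        node = dendropy.Node(taxon=tns.require_taxon(label=f"t{i+1}"))
        node.edge.length = rng.uniform(min_len, max_len)
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = rng.uniform(min_len, max_len)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i] = parent
        del nodes[j]
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = True
    return tree


def path_length_matrix(tree):
    """Leaf-to-leaf path lengths via dendropy's distance matrix (the oracle)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return pg.DistanceMatrix(tuple(labels), D)


class TestNJ:
    def test_four_taxon_additive_exact(self):
        # pairwise path lengths of ((a:1,b:2):1,(c:3,d:4):1)
        labels = ("a", "b", "c", "d")
        D = np.array(
            [[0, 3, 6, 7], [3, 0, 7, 8], [6, 7, 0, 7], [7, 8, 7, 0]], float
        )
        tree = pg.nj(pg.DistanceMatrix(labels, D))
        assert pg.bipartitions(tree) == frozenset({frozenset({"c", "d"})})
        leaf_lengths = {
            n.taxon.label: n.edge.length for n in tree.leaf_node_iter()
        }
        assert leaf_lengths == pytest.approx({"a": 1, "b": 2, "c": 3, "d": 4})
        internal = [
            n.edge.length
            for n in tree.preorder_node_iter()
            if n.parent_node is not None and not n.is_leaf()
        ]
        assert internal == pytest.approx([2.0])

    def test_three_taxon_three_point_formula(self):
        D = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        tree = pg.nj(pg.DistanceMatrix(("a", "b", "c"), D))
        lengths = {n.taxon.label: n.edge.length for n in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 0.1, "b": 0.2, "c": 0.3})
        assert len(tree.seed_node.child_nodes()) == 3  # unrooted trifurcation

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_random_additive_eight_leaf_trees(self, seed):
        rng = np.random.default_rng(seed)
        truth = random_binary_tree(rng, 8)
        m = path_length_matrix(truth)
        rebuilt = pg.nj(m)
        assert pg.bipartitions(rebuilt) == pg.bipartitions(truth)
        # additive input: reconstructed path lengths match the input matrix
        back = path_length_matrix(rebuilt)
        assert np.allclose(back.values, m.values, atol=1e-9)

    def test_permutation_invariance(self, rng):
        truth = random_binary_tree(rng, 7)
        m = path_length_matrix(truth)
        perm = rng.permutation(m.n)
        shuffled = pg.DistanceMatrix(
            tuple(m.labels[i] for i in perm), m.values[np.ix_(perm, perm)]
        )
        assert pg.bipartitions(pg.nj(shuffled)) == pg.bipartitions(pg.nj(m))

    def test_matches_dendropy_on_noisy_matrix(self, rng):
        n = 10
        noise = rng.uniform(0.05, 1.0, size=(n, n))
        D = (noise + noise.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = tuple(f"t{i+1}" for i in range(n))
        mine = pg.nj(pg.DistanceMatrix(labels, D))
        csv = "," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(str(x) for x in D[i]) for i in range(n)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=","
        )
        theirs = pdm.nj_tree()
        assert pg.bipartitions(mine) == pg.bipartitions(theirs)

    def test_requires_three_taxa_and_defined_entries(self):
        with pytest.raises(ValueError, match=">= 3"):
            pg.nj(pg.DistanceMatrix(("a", "b"), np.zeros((2, 2))))


class TestUPGMA:
    def test_two_taxa_split_evenly(self):
        m = pg.DistanceMatrix(("a", "b"), np.array([[0, 0.4], [0.4, 0]]))
        tree = pg.upgma(m)
        lengths = [n.edge.length for n in tree.leaf_node_iter()]
        assert lengths == pytest.approx([0.2, 0.2])

    @pytest.mark.parametrize("seed", range(4))
    def test_ultrametric_matrix_round_trip(self, seed):
        """UPGMA recovers an ultrametric tree exactly (matrix round-trip)."""
        rng = np.random.default_rng(seed)
        labels = [f"t{i+1}" for i in range(6)]
        clusters = [({lab}, 0.0) for lab in labels]
        n = len(labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        D = np.zeros((n, n))
        height = 0.0
        while len(clusters) > 1:
            height += rng.uniform(0.1, 0.5)
            i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
            (set_i, _), (set_j, _) = clusters[i], clusters[j]
            for a in set_i:
                for b in set_j:
                    D[idx[a], idx[b]] = D[idx[b], idx[a]] = 2 * height
            clusters[i] = (set_i | set_j, height)
            del clusters[j]
        m = pg.DistanceMatrix(tuple(labels), D)
        tree = pg.upgma(m)
        back = path_length_matrix(tree)
        order = [back.labels.index(lab) for lab in labels]
        assert np.allclose(back.values[np.ix_(order, order)], D, atol=1e-9)

    def test_output_is_ultrametric_even_on_noisy_input(self, rng):
        n = 9
        noise = rng.uniform(0.1, 1.0, size=(n, n))
        D = (noise + noise.T) / 2
        np.fill_diagonal(D, 0.0)
        tree = pg.upgma(
            pg.DistanceMatrix(tuple(f"t{i}" for i in range(n)), D)
        )
        depths = []
        for leaf in tree.leaf_node_iter():
            depth, node = 0.0, leaf
            while node.parent_node is not None:
                depth += node.edge.length
                node = node.parent_node
            depths.append(depth)
        assert max(depths) - min(depths) < 1e-9

    def test_tie_break_is_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        m = pg.DistanceMatrix(("a", "b", "c", "d"), D)
        assert newick_string(pg.upgma(m)) == newick_string(pg.upgma(m))


class TestMidpointRoot:
    def test_two_leaf_tree(self):
        t = pg.parse_newick("(a:0.3,b:0.1);")
        rooted = pg.midpoint_root(t)
        lengths = sorted(n.edge.length for n in rooted.leaf_node_iter())
        assert lengths == pytest.approx([0.2, 0.2])

    def test_idempotent(self, rng):
        t = random_binary_tree(rng, 6)
        once = pg.midpoint_root(t)
        twice = pg.midpoint_root(once)
        d1 = path_length_matrix(once)
        d2 = path_length_matrix(twice)
        assert np.allclose(d1.values, d2.values, atol=1e-9)
        assert pg.bipartitions(once) == pg.bipartitions(twice)

    @pytest.mark.parametrize("seed", range(3))
    def test_deepest_leaf_is_half_the_longest_path(self, seed):
        """Brute-force oracle: all-pairs path enumeration on the input tree."""
        rng = np.random.default_rng(seed)
        t = random_binary_tree(rng, 7)
        longest = path_length_matrix(t).values.max()
        rooted = pg.midpoint_root(t)
        depths = []
        for leaf in rooted.leaf_node_iter():
            depth, node = 0.0, leaf
            while node.parent_node is not None:
                depth += node.edge.length or 0.0
                node = node.parent_node
            depths.append(depth)
        assert max(depths) == pytest.approx(longest / 2, abs=1e-9)
        assert pg.bipartitions(rooted) == pg.bipartitions(t)


class TestRobinsonFoulds:
    def test_identical_trees(self, rng):
        t = random_binary_tree(rng, 8)
        t2 = pg.parse_newick(newick_string(t))
        assert pg.rf_distance(t, t2) == 0
        assert pg.same_topology(t, t2)

    def test_four_leaf_alternative_splits(self):
        t1 = pg.parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = pg.parse_newick("((a:1,c:1):1,(b:1,d:1):1);")
        assert pg.rf_distance(t1, t2) == 2
        assert not pg.same_topology(t1, t2)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_bound_and_dendropy_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 10))
        t1 = random_binary_tree(rng, n)
        t2 = random_binary_tree(rng, n)
        d12 = pg.rf_distance(t1, t2)
        assert d12 == pg.rf_distance(t2, t1)
        assert 0 <= d12 <= 2 * (n - 3)
        tns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=newick_string(t1), schema="newick",
                              taxon_namespace=tns)
        b = dendropy.Tree.get(data=newick_string(t2), schema="newick",
                              taxon_namespace=tns)
        a.encode_bipartitions()
        b.encode_bipartitions()
        assert d12 == treecompare.symmetric_difference(a, b)

    def test_label_mismatch_rejected(self, rng):
        t1 = random_binary_tree(rng, 5)
        t2 = pg.parse_newick("((x:1,y:1):1,(z:1,w:1):1,(q:1,r:1):1);")
        with pytest.raises(ValueError, match="leaf sets"):
            pg.rf_distance(t1, t2)
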