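"""Neighbor joining (exact recovery on additive matrices), midpoint
rooting, monophyly, Newick round-trips (cross-checked with dendropy),
and supermatrix construction/export."""

import io
import itertools

import dendropy
import numpy as np
import pytest

from mitocomp.divergence import DistanceMatrix
from mitocomp.genome import PCG_ORDER, Mitogenome
from mitocomp.phylo import (Supermatrix, TreeNode, concatenate_pcgs,
                            is_monophyletic, midpoint_root,
                            neighbor_joining, pairwise_leaf_distances,
                            parse_newick, tree_depths, write_nexus,
                            write_partitions, write_phylip)


def random_additive_tree(rng, n_taxa):
    """Random binary tree with positive lengths; returns (tree, labels)."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.05, 1.0)))
             for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = TreeNode(length=float(rng.uniform(0.05, 1.0)),
                          children=[b, a])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = TreeNode(children=nodes)
    return root, [f"t{i}" for i in range(n_taxa)]


def matrix_from_tree(tree, labels):
    dists = pairwise_leaf_distances(tree)
    n = len(labels)
    m = np.zeros((n, n))
    for (a, b), v in dists.items():
        i, j = labels.index(a), labels.index(b)
        m[i, j] = m[j, i] = v
    return DistanceMatrix(labels, m)


def topology(tree):
    """Set of non-trivial leaf bipartition halves (unrooted topology)."""
    all_leaves = tree.leaf_names()
    out = set()
    for clade in tree.clades():
        if 1 < len(clade) < len(all_leaves) - 1:
            out.add(min(clade, all_leaves - clade, key=sorted))
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], m))
        lengths = {lf.name: lf.length for lf in tree.leaves()}
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_recovers_additive_four_taxon_matrix(self):
        rng = np.random.default_rng(2)
        tree, labels = random_additive_tree(rng, 4)
        recovered = neighbor_joining(matrix_from_tree(tree, labels))
        assert topology(recovered) == topology(tree)
        orig = pairwise_leaf_distances(tree)
        back = pairwise_leaf_distances(recovered)
        for key, v in orig.items():
            assert back[key] == pytest.approx(v, abs=1e-9)

    def test_recovery_on_random_trees(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            tree, labels = random_additive_tree(rng, n)
            recovered = neighbor_joining(matrix_from_tree(tree, labels))
            assert topology(recovered) == topology(tree)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(6)
        tree, labels = random_additive_tree(rng, 6)
        dm = matrix_from_tree(tree, labels)
        perm = list(rng.permutation(len(labels)))
        dm2 = DistanceMatrix([labels[i] for i in perm],
                             dm.matrix[np.ix_(perm, perm)])
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(dm2)
        assert topology(t1) == topology(t2)
        d1, d2 = pairwise_leaf_distances(t1), pairwise_leaf_distances(t2)
        for key, v in d1.items():
            assert d2[key] == pytest.approx(v, abs=1e-9)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestMidpointRoot:
    def test_balances_cherry(self):
        tree = TreeNode(children=[TreeNode(name="a", length=1.0),
                                  TreeNode(name="b", length=3.0)])
        rooted = midpoint_root(tree)
        depths = tree_depths(rooted)
        assert depths["a"] == pytest.approx(2.0)
        assert depths["b"] == pytest.approx(2.0)

    def test_symmetric_tree_rooted_at_center(self):
        kids = [TreeNode(children=[TreeNode(name=n, length=1.0)
                                   for n in pair], length=0.5)
                for pair in (("a", "b"), ("c", "d"))]
        tree = TreeNode(children=kids)
        depths = tree_depths(midpoint_root(tree))
        assert all(v == pytest.approx(1.5) for v in depths.values())

    def test_deepest_leaves_at_half_diameter(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            tree, labels = random_additive_tree(rng, int(rng.integers(4, 9)))
            diameter = max(pairwise_leaf_distances(tree).values())
            depths = tree_depths(midpoint_root(tree))
            assert max(depths.values()) == pytest.approx(diameter / 2,
                                                         abs=1e-9)

    def test_input_not_mutated(self):
        tree = TreeNode(children=[TreeNode(name="a", length=1.0),
                                  TreeNode(name="b", length=3.0)])
        midpoint_root(tree)
        assert [c.length for c in tree.children] == [1.0, 3.0]


class TestMonophyly:
    @pytest.fixture()
    def rooted(self):
        return parse_newick("(((a:1,b:1):1,c:2):1,(d:1,e:1):2):0;")

    def test_single_taxon(self, rooted):
        assert is_monophyletic(rooted, ["a"])

    def test_all_leaves(self, rooted):
        assert is_monophyletic(rooted, list("abcde"))

    def test_cherry_true_nonadjacent_false(self, rooted):
        assert is_monophyletic(rooted, ["a", "b"])
        assert is_monophyletic(rooted, ["a", "b", "c"])
        assert not is_monophyletic(rooted, ["a", "c"])
        assert not is_monophyletic(rooted, ["b", "d"])

    def test_unknown_taxon_rejected(self, rooted):
        with pytest.raises(ValueError):
            is_monophyletic(rooted, ["a", "zz"])


class TestNewick:
    def test_write_read_write_idempotent(self):
        rng = np.random.default_rng(12)
        tree, _ = random_additive_tree(rng, 7)
        s1 = tree.newick()
        s2 = parse_newick(s1).newick()
        assert s1 == s2

    def test_lengths_preserved_to_1e9(self):
        rng = np.random.default_rng(13)
        tree, _ = random_additive_tree(rng, 6)
        back = parse_newick(tree.newick())
        d1, d2 = pairwise_leaf_distances(tree), pairwise_leaf_distances(back)
        for key, v in d1.items():
            assert d2[key] == pytest.approx(v, abs=1e-9)

    def test_dendropy_agrees_on_distances(self):
        # independent parser: dendropy's phylogenetic distance matrix
        rng = np.random.default_rng(14)
        tree, labels = random_additive_tree(rng, 6)
        dt = dendropy.Tree.get(data=tree.newick(), schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dt.taxon_namespace}
        ours = pairwise_leaf_distances(tree)
        for (a, b), v in ours.items():
            assert pdm.patristic_distance(taxa[a], taxa[b]) == \
                pytest.approx(v, abs=1e-9)

    def test_malformed_rejected(self):
        from mitocomp.phylo import NewickError
        with pytest.raises(NewickError):
            parse_newick("(a,b")
        with pytest.raises(NewickError):
            parse_newick("(a,(b,c):1;")


class TestSupermatrix:
    def test_width_and_partitions(self, genome_family):
        genomes, _ = genome_family
        sm = concatenate_pcgs(genomes)
        assert sm.aligned
        gene_lengths = {}
        for gene, start, end in sm.partitions:
            gene_lengths[gene] = end - start + 1
        assert sm.width == sum(gene_lengths.values())
        assert sm.partitions[-1][2] == sm.width
        assert [p[0] for p in sm.partitions] == list(PCG_ORDER)
        # partitions tile without gaps
        for (g1, s1, e1), (g2, s2, e2) in zip(sm.partitions,
                                              sm.partitions[1:]):
            assert s2 == e1 + 1

    def test_missing_gene_drops_taxon(self, genome_family):
        genomes, _ = genome_family
        stripped = Mitogenome(
            id="partial", sequence=genomes[0].sequence,
            features=[f for f in genomes[0].features if f.name != "ND3"])
        sm = concatenate_pcgs([stripped] + list(genomes))
        assert "partial" not in sm.labels
        assert sm.labels == [g.id for g in genomes]

    def test_dropping_gene_shifts_partitions(self, genome_family):
        genomes, _ = genome_family
        full = concatenate_pcgs(genomes)
        reduced_order = tuple(g for g in PCG_ORDER if g != "COI")
        reduced = concatenate_pcgs(genomes, gene_order_=reduced_order)
        coi_len = dict((g, e - s + 1) for g, s, e in full.partitions)["COI"]
        assert reduced.width == full.width - coi_len
        full_after = {g: (s, e) for g, s, e in full.partitions}
        red_after = {g: (s, e) for g, s, e in reduced.partitions}
        for gene in PCG_ORDER[2:]:  # genes after COI in the fixed order
            assert red_after[gene][0] == full_after[gene][0] - coi_len

    def test_exports_are_consistent(self, genome_family):
        genomes, _ = genome_family
        sm = concatenate_pcgs(genomes)
        phy = io.StringIO()
        write_phylip(sm, phy)
        header = phy.getvalue().splitlines()[0].split()
        assert header == [str(len(sm.labels)), str(sm.width)]
        nex = io.StringIO()
        write_nexus(sm, nex)
        text = nex.getvalue()
        assert f"nchar={sm.width}" in text
        assert "begin mrbayes;" in text
        assert "ngen=5000000" in text
        parts = io.StringIO()
        write_partitions(sm, parts)
        lines = parts.getvalue().splitlines()
        assert lines[0] == f"DNA, ND2 = 1-{sm.partitions[0][2]}"
        assert len(lines) == 13

    def test_nexus_parses_with_dendropy(self, genome_family):
        genomes, _ = genome_family
        sm = concatenate_pcgs(genomes)
        nex = io.StringIO()
        write_nexus(sm, nex, mrbayes_block=False)
        dna = dendropy.DnaCharacterMatrix.get(data=nex.getvalue(),
                                              schema="nexus")
        assert len(dna) == len(sm.labels)

    def test_unaligned_refuses_matrix_formats(self):
        sm = Supermatrix(labels=["a", "b"], sequences=["ACGTAA", "ACG"],
                         partitions=[("COI", 1, 6)])
        with pytest.raises(ValueError):
            write_phylip(sm, io.StringIO())
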