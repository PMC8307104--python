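"""Supermatrix assembly, export round-trips, NJ correctness, monophyly."""

import itertools

import numpy as np
import pytest

from mitocompare import supermatrix as sm_mod
from mitocompare.errors import (
    AlignmentRequiredError,
    InputError,
    MissingDataError,
    NameError_,
    UndefinedDistanceError,
)


def toy_blocks(n_taxa=4, seed=0):
    rng = np.random.default_rng(seed)
    genes = ["ND2", "COI", "lrRNA"]
    lengths = {"ND2": 30, "COI": 24, "lrRNA": 18}
    return {
        f"t{i}": {
            g: "".join(rng.choice(list("ACGT"), size=lengths[g]))
            for g in genes
        }
        for i in range(n_taxa)
    }, genes


class TestAssembly:
    def test_partitions_tile_exactly(self, small_clade):
        sm = sm_mod.supermatrix_from_genomes(small_clade.genomes)
        assert len(sm.partitions) == 15
        assert sm.partitions[0][1] == 1
        total = sum(end - start + 1 for _, start, end in sm.partitions)
        assert total == sm.length
        for (_, _, e1), (_, s2, _) in zip(sm.partitions, sm.partitions[1:]):
            assert s2 == e1 + 1

    def test_canonical_gene_order(self, small_clade):
        sm = sm_mod.supermatrix_from_genomes(small_clade.genomes)
        assert tuple(p[0] for p in sm.partitions) == sm_mod.CANONICAL_GENE_ORDER

    def test_single_taxon(self):
        blocks, genes = toy_blocks(n_taxa=1)
        sm = sm_mod.build_supermatrix(blocks, gene_order=genes)
        assert len(sm.taxa) == 1
        assert len(sm.partitions) == 3

    def test_missing_gene_is_error(self):
        blocks, genes = toy_blocks()
        del blocks["t1"]["COI"]
        with pytest.raises(MissingDataError):
            sm_mod.build_supermatrix(blocks, gene_order=genes)

    def test_unequal_blocks_require_alignment(self):
        blocks, genes = toy_blocks()
        blocks["t2"]["ND2"] = blocks["t2"]["ND2"][:-3]
        with pytest.raises(AlignmentRequiredError):
            sm_mod.build_supermatrix(blocks, gene_order=genes)


class TestRoundTrips:
    @pytest.fixture()
    def sm(self, small_clade):
        return sm_mod.supermatrix_from_genomes(small_clade.genomes)

    def test_phylip_plus_partition_file(self, sm, tmp_path):
        sm_mod.write_phylip(sm, tmp_path / "m.phy")
        sm_mod.write_raxml_partitions(sm, tmp_path / "m.part")
        again = sm_mod.read_phylip(tmp_path / "m.phy")
        assert again.sequences == sm.sequences
        assert again.taxa == sm.taxa
        assert sm_mod.read_raxml_partitions(tmp_path / "m.part") == sm.partitions

    def test_fasta(self, sm, tmp_path):
        sm_mod.write_fasta(sm, tmp_path / "m.fasta")
        again = sm_mod.read_fasta(tmp_path / "m.fasta")
        assert again.sequences == sm.sequences

    def test_nexus_with_charsets(self, sm, tmp_path):
        sm_mod.write_nexus(sm, tmp_path / "m.nex")
        again = sm_mod.read_nexus(tmp_path / "m.nex")
        assert again.sequences == sm.sequences
        assert again.partitions == sm.partitions

    def test_write_is_deterministic(self, sm, tmp_path):
        sm_mod.write_nexus(sm, tmp_path / "a.nex")
        sm_mod.write_nexus(sm, tmp_path / "b.nex")
        assert (tmp_path / "a.nex").read_bytes() == (tmp_path / "b.nex").read_bytes()


class TestPDistance:
    def test_identical_rows(self):
        sm = sm_mod.Supermatrix(
            taxa=["a", "b"], sequences={"a": "ACGT", "b": "ACGT"}, partitions=[]
        )
        dm = sm_mod.p_distance_matrix(sm)
        assert dm.matrix[0, 1] == 0.0

    def test_half_different(self):
        sm = sm_mod.Supermatrix(
            taxa=["a", "b"], sequences={"a": "AAAA", "b": "AATT"}, partitions=[]
        )
        assert sm_mod.p_distance_matrix(sm).matrix[0, 1] == pytest.approx(0.5)

    def test_ambiguity_columns_excluded(self):
        sm = sm_mod.Supermatrix(
            taxa=["a", "b"], sequences={"a": "AANA", "b": "ATTA"}, partitions=[]
        )
        assert sm_mod.p_distance_matrix(sm).matrix[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_columns(self):
        sm = sm_mod.Supermatrix(
            taxa=["a", "b"], sequences={"a": "NN", "b": "AA"}, partitions=[]
        )
        with pytest.raises(UndefinedDistanceError):
            sm_mod.p_distance_matrix(sm)

    def test_clade_structure_in_distances(self, small_clade):
        sm = sm_mod.supermatrix_from_genomes(small_clade.genomes)
        dm = sm_mod.p_distance_matrix(sm)
        idx = {t: i for i, t in enumerate(dm.taxa)}
        ingroup = [t for t in dm.taxa if t.startswith("I")]
        outgroup = [t for t in dm.taxa if t.startswith("O")]
        within = max(
            dm.matrix[idx[a], idx[b]]
            for a, b in itertools.combinations(ingroup, 2)
        )
        across = min(
            dm.matrix[idx[a], idx[b]] for a in ingroup for b in outgroup
        )
        assert within < across


class TestNeighborJoining:
    def test_three_taxa_exact_branch_lengths(self):
        dm = sm_mod.DistanceMatrix(
            taxa=["a", "b", "c"],
            matrix=np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float),
        )
        tree = sm_mod.nj_tree(dm)
        # three-point formulas: la=(d12+d13-d23)/2 etc.
        lengths = {}

        def walk(node, acc):
            for child, length in node.children:
                if child.is_leaf:
                    lengths[child.name] = acc + length
                else:
                    walk(child, acc + length)

        walk(tree.root, 0.0)
        # pairwise path lengths reproduce the additive input
        newick = tree.to_newick()
        assert set(lengths) == {"a", "b", "c"}
        d = _pairwise_path_lengths(tree)
        assert d[("a", "b")] == pytest.approx(2.0)
        assert d[("a", "c")] == pytest.approx(3.0)
        assert d[("b", "c")] == pytest.approx(4.0)
        assert newick.endswith(";")

    def test_zero_matrix_gives_zero_branches(self):
        dm = sm_mod.DistanceMatrix(
            taxa=list("abcd"), matrix=np.zeros((4, 4))
        )
        tree = sm_mod.nj_tree(dm)
        d = _pairwise_path_lengths(tree)
        assert all(v == pytest.approx(0.0) for v in d.values())

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(InputError):
            sm_mod.DistanceMatrix(
                taxa=["a", "b"], matrix=np.array([[0, 1], [2, 0.0]])
            )

    @pytest.mark.parametrize("n_leaves", [6, 8, 10])
    def test_additive_matrix_recovers_topology(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        tree_d, taxa = _random_additive_matrix(rng, n_leaves)
        dm = sm_mod.DistanceMatrix(
            taxa=taxa,
            matrix=np.array(
                [[tree_d[(a, b)] if a != b else 0.0 for b in taxa] for a in taxa]
            ),
        )
        tree = sm_mod.nj_tree(dm)
        recovered = _pairwise_path_lengths(tree)
        for (a, b), expected in tree_d.items():
            if a != b:
                assert recovered[tuple(sorted((a, b)))] == pytest.approx(
                    expected, abs=1e-9
                )

    def test_matches_scikit_bio_on_noisy_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(17)
        tree_d, taxa = _random_additive_matrix(rng, 7)
        matrix = np.array(
            [[tree_d[(a, b)] if a != b else 0.0 for b in taxa] for a in taxa]
        )
        ours = sm_mod.nj_tree(
            sm_mod.DistanceMatrix(taxa=taxa, matrix=matrix)
        )
        theirs = skbio.tree.nj(skbio.DistanceMatrix(matrix, ids=taxa))
        ours_d = _pairwise_path_lengths(ours)
        for a, b in itertools.combinations(taxa, 2):
            assert ours_d[(a, b)] == pytest.approx(
                theirs.find(a).distance(theirs.find(b)), abs=1e-6
            )


def _random_additive_matrix(rng, n_leaves):
    """Leaf-pair path lengths on a random binary tree with positive branches."""
    clusters = [
        {"leaves": {f"L{i}": 0.0}} for i in range(n_leaves)
    ]
    pair_d = {}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        a, b = clusters[i], clusters[j]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        for leaf_a, da in a["leaves"].items():
            for leaf_b, db in b["leaves"].items():
                key = tuple(sorted((leaf_a, leaf_b)))
                pair_d[key] = da + la + db + lb
        merged = {
            "leaves": {
                **{x: d + la for x, d in a["leaves"].items()},
                **{x: d + lb for x, d in b["leaves"].items()},
            }
        }
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    taxa = sorted({t for pair in pair_d for t in pair})
    full = {}
    for (a, b), d in pair_d.items():
        full[(a, b)] = d
        full[(b, a)] = d
    return full, taxa


def _pairwise_path_lengths(tree):
    """Leaf-to-leaf path lengths from the rooted representation."""
    lineages = {}  # leaf -> [(ancestor id, depth of ancestor), ...]
    leaf_depth = {}

    def walk(node, depth, lineage):
        if node.is_leaf:
            lineages[node.name] = lineage
            leaf_depth[node.name] = depth
            return
        for child, length in node.children:
            walk(child, depth + length, lineage + [(id(node), depth)])

    walk(tree.root, 0.0, [])
    out = {}
    for a, b in itertools.combinations(sorted(tree.leaves()), 2):
        ancestors_a = dict(lineages[a])
        shared = max(
            (d for node_id, d in lineages[b] if node_id in ancestors_a),
            default=0.0,
        )
        out[(a, b)] = leaf_depth[a] + leaf_depth[b] - 2 * shared
    return out


class TestMonophyly:
    def _tree(self, newick_like):
        # build tiny trees by hand
        from mitocompare.supermatrix import Tree, TreeNode

        def leaf(name):
            return TreeNode(name=name)

        if newick_like == "((A,B),(C,D))":
            root = TreeNode(children=[
                (TreeNode(children=[(leaf("A"), 1), (leaf("B"), 1)]), 1),
                (TreeNode(children=[(leaf("C"), 1), (leaf("D"), 1)]), 1),
            ])
        else:  # ((A,C),(B,D))
            root = TreeNode(children=[
                (TreeNode(children=[(leaf("A"), 1), (leaf("C"), 1)]), 1),
                (TreeNode(children=[(leaf("B"), 1), (leaf("D"), 1)]), 1),
            ])
        return Tree(root=root)

    def test_true_clade(self):
        assert sm_mod.check_monophyly(self._tree("((A,B),(C,D))"), {"A", "B"})

    def test_broken_clade(self):
        assert not sm_mod.check_monophyly(self._tree("((A,C),(B,D))"), {"A", "B"})

    def test_unknown_taxon(self):
        with pytest.raises(NameError_):
            sm_mod.check_monophyly(self._tree("((A,B),(C,D))"), {"A", "Z"})

    def test_simulated_ingroup_is_monophyletic(self, small_clade):
        sm = sm_mod.supermatrix_from_genomes(small_clade.genomes)
        tree = sm_mod.nj_tree(sm_mod.p_distance_matrix(sm))
        ingroup = [t for t in small_clade.taxa if t.startswith("I")]
        assert sm_mod.check_monophyly(tree, ingroup)
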