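import numpy as np
import pytest

from karyofix import (
    MISSING,
    ConcatAlignment,
    DistanceMatrix,
    KaryotypeLabel,
    TreeNode,
    concat_sequences,
    export_alignment,
    midpoint_root,
    nj,
    p_distance,
)
from karyofix.concat_phylo import parse_newick, read_nexus_alignment
from karyofix.genotype_io import Locus
from karyofix.locus_mapping import LocusAssignment

from conftest import build_matrix


def two_locus_matrix():
    loci = [
        Locus("L0", ref_allele="A", alt_allele="G"),
        Locus("L1", ref_allele="C", alt_allele="T"),
    ]
    m = build_matrix([[0, 1, 2], [0, 2, MISSING]], ["AA", "MA", "MM"], loci=loci)
    assign = [
        LocusAssignment("L1", "scafX", 500, 569, "+"),
        LocusAssignment("L0", "scafX", 100, 169, "+"),
    ]
    return m, assign


class TestConcatSequences:
    def test_het_becomes_ambiguity_code(self):
        m, assign = two_locus_matrix()
        aln = concat_sequences(m, assign, "scafX")
        # loci ordered by position: L0 (100) then L1 (500)
        assert aln.locus_order == ("L0", "L1")
        assert aln.sequences == ("AC", "RT", "GN")

    def test_all_ref_calls_give_ref_string(self):
        loci = [Locus(f"L{i}", ref_allele="A", alt_allele="C") for i in range(3)]
        m = build_matrix([[0], [0], [0]], ["AA"], loci=loci)
        assign = [LocusAssignment(f"L{i}", "s", i * 100, i * 100 + 69, "+") for i in range(3)]
        aln = concat_sequences(m, assign, "s")
        assert aln.sequences == ("AAA",)

    def test_identical_calls_identical_sequences(self, noiseless_sim):
        matrix, assignments, _, truth = noiseless_sim
        scaf = truth.config.planted_region[0]
        aln = concat_sequences(matrix, assignments, scaf)
        by_kar = {}
        for ind, seq in zip(matrix.individuals, aln.sequences):
            by_kar.setdefault(ind.karyotype, set()).add(
                "".join(
                    c for c, lid in zip(seq, aln.locus_order)
                    if lid in truth.linked_locus_ids
                )
            )
        # zero noise: every individual of a karyotype shares one linked haplotype
        assert all(len(seqs) == 1 for seqs in by_kar.values())

    def test_unknown_scaffold_raises(self):
        m, assign = two_locus_matrix()
        with pytest.raises(KeyError):
            concat_sequences(m, assign, "missing_scaffold")


class TestPDistance:
    def make(self, *seqs):
        return ConcatAlignment(
            tuple(f"x{i}" for i in range(len(seqs))),
            tuple(seqs),
            tuple(f"L{i}" for i in range(len(seqs[0]))),
        )

    def test_identical_sequences_zero(self):
        d = p_distance(self.make("ACGT", "ACGT"))
        assert d.values[0, 1] == 0.0

    def test_homozygote_vs_heterozygote_half(self):
        d = p_distance(self.make("A", "R"))
        assert d.values[0, 1] == 0.5

    def test_opposite_homozygotes_one(self):
        d = p_distance(self.make("A", "G"))
        assert d.values[0, 1] == 1.0

    def test_same_het_scores_zero(self):
        d = p_distance(self.make("R", "R"))
        assert d.values[0, 1] == 0.0

    def test_n_sites_excluded(self):
        d = p_distance(self.make("AN", "GG"))
        assert d.values[0, 1] == 1.0  # only first site counted

    def test_invariant_to_locus_order_permutation(self):
        rng = np.random.default_rng(6)
        chars = np.array(list("ACGTRYSWKMN"))
        seqs = ["".join(rng.choice(chars, 30)) for _ in range(4)]
        base = p_distance(self.make(*seqs)).values
        perm = rng.permutation(30)
        shuffled = ["".join(np.array(list(s))[perm]) for s in seqs]
        assert np.allclose(p_distance(self.make(*shuffled)).values, base)

    def test_disjoint_pair_raises(self):
        with pytest.raises(ValueError):
            p_distance(self.make("AN", "NG"))


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        tree = nj(d)
        paths = tree.path_lengths()
        assert paths[("a", "b")] == pytest.approx(3.0)

    def test_three_taxa_closed_form(self):
        d12, d13, d23 = 5.0, 9.0, 10.0
        d = DistanceMatrix(
            ["t1", "t2", "t3"],
            np.array([[0, d12, d13], [d12, 0, d23], [d13, d23, 0]]),
        )
        tree = nj(d)
        depths = {}
        for child, bl in tree.children:
            depths[child.label] = bl
        assert depths["t1"] == pytest.approx((d12 + d13 - d23) / 2)
        assert depths["t2"] == pytest.approx((d12 + d23 - d13) / 2)
        assert depths["t3"] == pytest.approx((d13 + d23 - d12) / 2)

    @staticmethod
    def random_additive(k, rng):
        items = [TreeNode(f"t{i}") for i in range(k)]
        while len(items) > 2:
            i, j = sorted(rng.choice(len(items), 2, replace=False))
            b = items.pop(j)
            a = items.pop(i)
            parent = TreeNode()
            parent.children = [
                (a, float(rng.uniform(0.1, 2.0))),
                (b, float(rng.uniform(0.1, 2.0))),
            ]
            items.append(parent)
        root = TreeNode()
        root.children = [
            (items[0], float(rng.uniform(0.1, 2.0))),
            (items[1], float(rng.uniform(0.1, 2.0))),
        ]
        labels = sorted(root.path_lengths().keys())
        taxa = sorted({t for pair in labels for t in pair})
        D = np.zeros((k, k))
        for (a, b), dist in root.path_lengths().items():
            i, j = taxa.index(a), taxa.index(b)
            D[i, j] = D[j, i] = dist
        return taxa, D

    @pytest.mark.parametrize("k", [4, 5, 6, 7, 8])
    def test_recovers_additive_matrices_exactly(self, k):
        rng = np.random.default_rng(100 + k)
        for _ in range(5):
            taxa, D = self.random_additive(k, rng)
            tree = nj(DistanceMatrix(taxa, D))
            paths = tree.path_lengths()
            for i, a in enumerate(taxa):
                for j, b in enumerate(taxa):
                    if i < j:
                        assert paths[(a, b)] == pytest.approx(D[i, j], abs=1e-9)

    def test_non_symmetric_input_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestMidpointRoot:
    def test_two_leaves_split_evenly(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 10.0], [10.0, 0.0]]))
        rooted = midpoint_root(nj(d))
        (c1, bl1), (c2, bl2) = rooted.children
        assert bl1 == pytest.approx(5.0) and bl2 == pytest.approx(5.0)

    def test_root_equidistant_from_longest_path_ends(self):
        rng = np.random.default_rng(55)
        taxa, D = TestNeighborJoining.random_additive(7, rng)
        unrooted = nj(DistanceMatrix(taxa, D))
        paths = unrooted.path_lengths()
        (la, lb), longest = min(paths.items(), key=lambda kv: (-kv[1], kv[0]))
        rooted = midpoint_root(unrooted)

        def depths(node, acc=0.0, out=None):
            out = {} if out is None else out
            if node.is_leaf:
                out[node.label] = acc
            for child, bl in node.children:
                depths(child, acc + bl, out)
            return out

        dd = depths(rooted)
        assert dd[la] == pytest.approx(longest / 2)
        assert dd[lb] == pytest.approx(longest / 2)
        # rooting preserves the path metric
        rp = rooted.path_lengths()
        for pair, dist in paths.items():
            assert rp[pair] == pytest.approx(dist, abs=1e-9)

    def test_all_zero_edges_degenerate(self):
        star = TreeNode()
        star.children = [(TreeNode(x), 0.0) for x in "abc"]
        rooted = midpoint_root(star)
        assert sorted(rooted.leaves()) == ["a", "b", "c"]
        assert all(d == 0.0 for d in rooted.path_lengths().values())

    def test_karyotypes_form_disjoint_clades(self, noiseless_sim):
        # zero noise: the midpoint-rooted NJ tree over the planted scaffold
        # separates the two homozygous arrangements with MA between
        matrix, assignments, _, truth = noiseless_sim
        scaf = truth.config.planted_region[0]
        aln = concat_sequences(matrix, assignments, scaf)
        rooted = midpoint_root(nj(p_distance(aln)))
        label = {i.id: i.karyotype for i in matrix.individuals}

        def smallest_pure_clades(node, out):
            kinds = {label[leaf] for leaf in node.leaves()}
            if kinds == {KaryotypeLabel.AA} or kinds == {KaryotypeLabel.MM}:
                out.append((kinds.pop(), set(node.leaves())))
                return
            for child, _ in node.children:
                smallest_pure_clades(child, out)

        clades = []
        smallest_pure_clades(rooted, clades)
        found = {}
        for kind, leaves in clades:
            found.setdefault(kind, set()).update(leaves)
        all_aa = {i.id for i in matrix.individuals if label[i.id] == KaryotypeLabel.AA}
        all_mm = {i.id for i in matrix.individuals if label[i.id] == KaryotypeLabel.MM}
        # each homozygous karyotype is covered by pure clades only
        assert found[KaryotypeLabel.AA] == all_aa
        assert found[KaryotypeLabel.MM] == all_mm


class TestExports:
    def test_fasta_order_and_round_trip(self, tmp_path):
        aln = ConcatAlignment(("b", "a"), ("ACR", "GTN"), ("L0", "L1", "L2"))
        text = export_alignment(aln, "fasta")
        assert text.startswith(">b\nACR\n>a\n")
        from io import StringIO

        from Bio import SeqIO

        records = list(SeqIO.parse(StringIO(text), "fasta"))
        assert [r.id for r in records] == ["b", "a"]

    def test_nexus_round_trip(self):
        aln = ConcatAlignment(("x", "y"), ("ACGRY", "NNSWK"), tuple("ABCDE"))
        text = export_alignment(aln, "nexus")
        assert text.startswith("#NEXUS")
        back = read_nexus_alignment(text)
        assert back == {"x": "ACGRY", "y": "NNSWK"}

    def test_empty_alignment_raises(self):
        with pytest.raises(ValueError):
            export_alignment(ConcatAlignment((), (), ()), "fasta")

    def test_newick_round_trip_preserves_metric(self):
        rng = np.random.default_rng(77)
        taxa, D = TestNeighborJoining.random_additive(6, rng)
        tree = midpoint_root(nj(DistanceMatrix(taxa, D)))
        back = parse_newick(tree.to_newick())
        orig = tree.path_lengths()
        rt = back.path_lengths()
        for pair, dist in orig.items():
            assert rt[pair] == pytest.approx(dist, abs=1e-6)

    def test_newick_matches_dendropy_distances(self):
        # independent reader cross-check on the serialized tree
        import dendropy

        rng = np.random.default_rng(13)
        taxa, D = TestNeighborJoining.random_additive(5, rng)
        tree = midpoint_root(nj(DistanceMatrix(taxa, D)))
        dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        tx = {t.label: t for t in dt.taxon_namespace}
        for (a, b), dist in tree.path_lengths().items():
            assert pdm.distance(tx[a], tx[b]) == pytest.approx(dist, abs=1e-6)
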