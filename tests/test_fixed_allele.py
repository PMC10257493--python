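import itertools

import numpy as np
import pytest

from karyofix import (
    MISSING,
    FixedDiffPolicy,
    FixedStatus,
    KaryotypeLabel,
    Orientation,
    ScaffoldCountRow,
    aggregate_counts,
    classify_locus,
    group_diversity,
    hierarchical_cluster,
    pairwise_call_distance,
    scan_fixed_differences,
)
from karyofix.fixed_allele_core import write_count_table_tsv
from karyofix.locus_mapping import LocusAssignment

from conftest import build_matrix

STRICT = FixedDiffPolicy()


class TestClassifyLocus:
    def test_textbook_fixed_locus(self):
        v = classify_locus([0, 0], [2, 2], [1], STRICT)
        assert v.status is FixedStatus.FIXED
        assert v.orientation is Orientation.AA_IS_0
        assert v.ma_consistency == 1.0

    def test_non_uniform_group_is_not_fixed(self):
        assert classify_locus([0, 2], [2, 2], [], STRICT).status is FixedStatus.NOT_FIXED

    def test_exhaustive_enumeration_groups_2_2_1(self):
        # over all 3^5 call matrices, exactly the two orientations are FIXED
        fixed = []
        for calls in itertools.product((0, 1, 2), repeat=5):
            v = classify_locus(calls[:2], calls[2:4], calls[4:], STRICT)
            if v.status is FixedStatus.FIXED:
                fixed.append(calls)
        assert sorted(fixed) == [(0, 0, 2, 2, 1), (2, 2, 0, 0, 1)]

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(5)
        flip = {Orientation.AA_IS_0: Orientation.AA_IS_2,
                Orientation.AA_IS_2: Orientation.AA_IS_0,
                Orientation.NA: Orientation.NA}
        for _ in range(200):
            aa = rng.integers(0, 3, size=3).tolist()
            mm = rng.integers(0, 3, size=3).tolist()
            ma = rng.integers(0, 3, size=2).tolist()
            v1 = classify_locus(aa, mm, ma, STRICT)
            v2 = classify_locus(mm, aa, ma, STRICT)
            assert v1.status == v2.status
            assert v2.orientation == flip[v1.orientation]

    def test_missing_renders_ineligible_by_default(self):
        v = classify_locus([0, MISSING], [2, 2], [1], STRICT)
        assert v.status is FixedStatus.INELIGIBLE

    def test_allow_missing_evaluates_remaining_calls(self):
        policy = FixedDiffPolicy(allow_missing=True)
        v = classify_locus([0, 0, MISSING], [2, 2], [1], policy)
        assert v.status is FixedStatus.FIXED

    def test_small_group_is_ineligible_not_error(self):
        v = classify_locus([0], [2, 2], [], STRICT)
        assert v.status is FixedStatus.INELIGIBLE and "group" in v.reason

    def test_ma_consistency_reported_for_not_fixed(self):
        v = classify_locus([0, 0], [2, 2], [1, 0], STRICT)
        assert v.status is FixedStatus.NOT_FIXED
        assert v.ma_consistency == 0.5

    def test_lenient_ma_ignores_heterokaryotype_veto(self):
        policy = FixedDiffPolicy(require_het_in_MA=False)
        v = classify_locus([0, 0], [2, 2], [0, 0], policy)
        assert v.status is FixedStatus.FIXED and v.ma_consistency == 0.0

    def test_policy_tightening_never_increases_fixed_count(self):
        rng = np.random.default_rng(17)
        lenient = FixedDiffPolicy(require_het_in_MA=False, min_group_size=1,
                                  allow_missing=True)

        def n_fixed(policy, mats):
            return sum(
                classify_locus(aa, mm, ma, policy).status is FixedStatus.FIXED
                for aa, mm, ma in mats
            )

        mats = []
        for _ in range(300):
            draw = lambda n: rng.choice([0, 1, 2, MISSING], size=n).tolist()
            mats.append((draw(3), draw(3), draw(2)))
        base = n_fixed(lenient, mats)
        for tighter in (
            FixedDiffPolicy(require_het_in_MA=True, min_group_size=1, allow_missing=True),
            FixedDiffPolicy(require_het_in_MA=False, min_group_size=2, allow_missing=True),
            FixedDiffPolicy(require_het_in_MA=False, min_group_size=1, allow_missing=False),
            STRICT,
        ):
            assert n_fixed(tighter, mats) <= base


class TestScanAndCounts:
    def test_no_assignments_yields_empty_outputs(self):
        m = build_matrix([[0, 2]], ["AA", "MM"])
        verdicts, rows = scan_fixed_differences(m, [], STRICT)
        assert verdicts == [] and rows == []

    def test_planted_loci_all_fixed_zero_noise(self, noiseless_sim):
        matrix, assignments, _, truth = noiseless_sim
        verdicts, rows = scan_fixed_differences(matrix, assignments, STRICT)
        fixed = {v.locus_id for v in verdicts if v.status is FixedStatus.FIXED}
        assert fixed == truth.linked_locus_ids  # precision = recall = 1
        planted_scaf = truth.config.planted_region[0]
        by_scaf = {r.scaffold: r.n_fixed for r in rows if r.scaffold != "TOTAL"}
        assert by_scaf[planted_scaf] == len(truth.linked_locus_ids)
        assert all(v == 0 for s, v in by_scaf.items() if s != planted_scaf)

    def test_reference_set_restricts_groups(self):
        # outside-reference individuals cannot veto a fixed difference
        m = build_matrix(
            [[0, 0, 2, 2, 2]],
            ["AA", "AA", "MM", "MM", "AA"],
            ["bh", "bh", "bh", "bh", "other"],
        )
        assign = [LocusAssignment("L0", "s", 0, 69, "+")]
        ref = [i.id for i in m.individuals if i.population == "bh"]
        v_all, _ = scan_fixed_differences(m, assign, STRICT)
        v_ref, _ = scan_fixed_differences(m, assign, STRICT, ref)
        assert v_all[0].status is FixedStatus.NOT_FIXED
        assert v_ref[0].status is FixedStatus.FIXED

    def test_empty_reference_raises(self):
        m = build_matrix([[0, 2]], ["AA", "MM"])
        with pytest.raises(ValueError):
            scan_fixed_differences(m, [], STRICT, [])

    def test_totals_row_and_aggregate(self):
        rows = [ScaffoldCountRow("a", 10, 3), ScaffoldCountRow("b", 5, 1)]
        assert aggregate_counts(rows) == (15, 4)
        assert aggregate_counts([]) == (0, 0)
        assert aggregate_counts([ScaffoldCountRow("x", 10, 3)]) == (10, 3)

    def test_count_table_export(self, tmp_path):
        rows = [ScaffoldCountRow("a", 10, 3), ScaffoldCountRow("TOTAL", 10, 3)]
        path = tmp_path / "counts.tsv"
        write_count_table_tsv(rows, str(path))
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == ["scaffold", "n_loci_mapped", "n_fixed"]
        assert lines[1].split("\t") == ["a", "10", "3"]


class TestPairwiseDistance:
    def test_identical_vectors_give_zero(self):
        m = build_matrix([[1, 1], [2, 2]], ["AA", "MM"])
        pw = pairwise_call_distance(m, m.locus_ids())
        assert pw.values[0, 1] == 0.0

    def test_opposite_homozygotes_two_loci(self):
        m = build_matrix([[0, 2], [0, 2]], ["AA", "MM"])
        pw = pairwise_call_distance(m, m.locus_ids())
        assert pw.values[0, 1] == pytest.approx(np.sqrt(8.0))

    def test_pairwise_complete_rescaling(self):
        # one of two loci missing for one individual; the other differs by 2
        m = build_matrix([[0, 2], [1, MISSING]], ["AA", "MM"])
        pw = pairwise_call_distance(m, m.locus_ids())
        assert pw.values[0, 1] == pytest.approx(2.0 * np.sqrt(2.0 / 1.0))
        raw = pairwise_call_distance(m, m.locus_ids(), pairwise_complete_scaling=False)
        assert raw.values[0, 1] == pytest.approx(2.0)

    def test_no_shared_loci_raises(self):
        m = build_matrix([[0, MISSING], [MISSING, 2]], ["AA", "MM"])
        with pytest.raises(ValueError, match="share no non-missing"):
            pairwise_call_distance(m, m.locus_ids())


class TestClustering:
    def test_two_individuals_single_merge(self):
        m = build_matrix([[0, 2]], ["AA", "MM"])
        pw = pairwise_call_distance(m, m.locus_ids())
        tree = hierarchical_cluster(pw)
        assert tree.height == pytest.approx(2.0)
        assert sorted(tree.leaves()) == ["i0", "i1"]

    @pytest.mark.parametrize("linkage", ["single", "complete", "average"])
    def test_close_pair_merges_first(self, linkage):
        from karyofix import PairwiseMatrix

        vals = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], dtype=float)
        pw = PairwiseMatrix(["a", "b", "c"], vals, "test")
        tree = hierarchical_cluster(pw, linkage)
        subtrees = [set(child.leaves()) for child in tree.children]
        assert {"a", "b"} in subtrees and {"c"} in subtrees

    def test_merge_heights_non_decreasing(self, noiseless_sim):
        matrix, _, _, truth = noiseless_sim
        pw = pairwise_call_distance(matrix, sorted(truth.linked_locus_ids))
        tree = hierarchical_cluster(pw, "average")

        def heights(node, acc):
            for child in node.children:
                if not child.is_leaf:
                    acc.append((node.height, child.height))
                    heights(child, acc)
            return acc

        for parent_h, child_h in heights(tree, []):
            assert parent_h >= child_h - 1e-9

    def test_karyotype_groups_separate_cleanly(self, noiseless_sim):
        # within-karyotype distances < between-karyotype distances (AA vs MM),
        # and the dendrogram puts AA and MM in clean blocks with MA between
        matrix, _, _, truth = noiseless_sim
        pw = pairwise_call_distance(matrix, sorted(truth.linked_locus_ids))
        label = {i.id: i.karyotype for i in matrix.individuals}
        ids = pw.individuals
        within, between = [], []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                ki, kj = label[ids[i]], label[ids[j]]
                if KaryotypeLabel.MA in (ki, kj):
                    continue
                (within if ki == kj else between).append(pw.values[i, j])
        assert np.mean(within) < np.mean(between)
        assert max(within) < min(between)

        order = hierarchical_cluster(pw).leaves()
        kinds = [label[i] for i in order]
        # AA block and MM block must be contiguous, zero-noise
        for lab in (KaryotypeLabel.AA, KaryotypeLabel.MM):
            idx = [k for k, x in enumerate(kinds) if x == lab]
            assert idx == list(range(min(idx), max(idx) + 1))

    def test_matches_scipy_linkage_heights(self):
        # independent cross-check of the agglomerative heights on a
        # tie-free random distance matrix
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        from karyofix import PairwiseMatrix

        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        pw = PairwiseMatrix([f"x{i}" for i in range(8)], d, "euclid")
        for link in ("single", "complete", "average"):
            tree = hierarchical_cluster(pw, link)

            def merge_heights(node, out):
                if not node.is_leaf:
                    out.append(node.height)
                    for c in node.children:
                        merge_heights(c, out)
                return out

            mine = sorted(merge_heights(tree, []))
            ref = sorted(linkage(squareform(d), method=link)[:, 2])
            assert np.allclose(mine, ref, atol=1e-9)

    def test_single_individual_raises(self):
        from karyofix import PairwiseMatrix

        pw = PairwiseMatrix(["a"], np.zeros((1, 1)), "t")
        with pytest.raises(ValueError):
            hierarchical_cluster(pw)


class TestGroupDiversity:
    def test_monomorphic_group(self):
        m = build_matrix([[0, 0], [0, 0]], ["AA", "AA"])
        (summ,) = group_diversity(m, {KaryotypeLabel.AA: ["i0", "i1"]})
        assert summ.het_obs == (0.0, 0.0)
        assert summ.minor_call_freq == (0.0, 0.0)
        assert summ.mean_het == 0.0

    def test_het_fraction(self):
        m = build_matrix([[0, 1, 1, 2]], ["MM"] * 4)
        (summ,) = group_diversity(m, {KaryotypeLabel.MM: [f"i{j}" for j in range(4)]})
        assert summ.het_obs[0] == 0.5
        assert summ.minor_call_freq[0] == 0.5  # one 0 vs one 2

    def test_all_missing_locus_excluded_from_mean(self):
        calls = [[1, 1], [MISSING, MISSING]]
        m = build_matrix(calls, ["AA", "AA"])
        (summ,) = group_diversity(m, {KaryotypeLabel.AA: ["i0", "i1"]})
        assert np.isnan(summ.het_obs[1])
        assert summ.mean_het == 1.0

    def test_rearranged_region_loses_diversity_in_homokaryotypes(self, noiseless_sim):
        # both homozygous-arrangement groups are monomorphic over linked loci,
        # while heterokaryotypes are uniformly heterozygous
        matrix, _, _, truth = noiseless_sim
        from karyofix import subset

        sub = subset(matrix, keep_loci=truth.linked_locus_ids)
        out = {s.group: s for s in group_diversity(sub)}
        assert out[KaryotypeLabel.AA].mean_het == 0.0
        assert out[KaryotypeLabel.MM].mean_het == 0.0
        assert out[KaryotypeLabel.MA].mean_het == 1.0

    def test_empty_group_raises(self):
        m = build_matrix([[0, 2]], ["AA", "MM"])
        with pytest.raises(ValueError):
            group_diversity(m, {KaryotypeLabel.AA: []})
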