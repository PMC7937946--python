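import numpy as np
import pandas as pd
import pytest

from endoseq import endotype as et
from endoseq.io import load_clinical_fixture

from conftest import make_assignment, make_vst, two_group_assignment


def brute_force_average_linkage(points: np.ndarray):
    """O(n^3) reference implementation: repeatedly merge the closest pair of
    clusters under the average of all pairwise point distances."""
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        merges.append(dist)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(merges)


class TestClusterSamples:
    def test_hand_computed_four_point_tree(self):
        vm = make_vst([[0.0, 1.0, 10.0, 11.0]], sample_ids=["a", "b", "c", "d"])
        dend = et.cluster_samples(vm)
        np.testing.assert_allclose(sorted(dend.heights[:2]), [1.0, 1.0])
        # final merge: average of cross distances {10, 11, 9, 10}
        assert dend.heights[2] == pytest.approx(10.0)

    def test_duplicated_sample_merges_at_zero(self):
        vm = make_vst([[1.0, 1.0, 5.0], [2.0, 2.0, 9.0]])
        dend = et.cluster_samples(vm)
        assert dend.heights[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((5, 8))  # 8 samples, 5 genes
        vm = make_vst(x)
        dend = et.cluster_samples(vm)
        expected = brute_force_average_linkage(x.T)
        np.testing.assert_allclose(np.sort(dend.heights), np.sort(expected),
                                   rtol=1e-10)

    def test_heights_monotone_and_order_invariant(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal((20, 12))
        vm = make_vst(x)
        dend = et.cluster_samples(vm)
        assert np.all(np.diff(dend.heights) >= -1e-12)
        perm = rng.permutation(12)
        vm2 = make_vst(x[:, perm], sample_ids=[vm.sample_ids[i] for i in perm])
        dend2 = et.cluster_samples(vm2)
        np.testing.assert_allclose(dend.heights, dend2.heights)
        assert dend.leaf_ids == dend2.leaf_ids

    def test_nan_rejected(self):
        vm = make_vst([[0.0, np.nan, 1.0]])
        with pytest.raises(ValueError, match="finite"):
            et.cluster_samples(vm)

    def test_newick_serialization_parses(self):
        vm = make_vst([[0.0, 1.0, 10.0, 11.0]], sample_ids=["a", "b", "c", "d"])
        nwk = et.cluster_samples(vm).to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 3
        for leaf in "abcd":
            assert leaf in nwk


class TestAssignEndotypes:
    @staticmethod
    def _clouds(sizes, centers, seed=0, n_genes=30):
        rng = np.random.default_rng(seed)
        cols, ids = [], []
        for k, (n, c) in enumerate(zip(sizes, centers)):
            cols.append(rng.normal(c, 0.3, size=(n_genes, n)))
            ids += [f"grp{k}_{i}" for i in range(n)]
        return make_vst(np.hstack(cols), sample_ids=ids)

    def test_two_separated_clouds_split_perfectly(self):
        vm = self._clouds([10, 10], [0.0, 5.0])
        assignment = et.assign_endotypes(et.cluster_samples(vm), n_clusters=2)
        sizes = assignment.sizes()
        assert sizes == {"A": 10, "B": 10, "other": 0}
        groups = {s.split("_")[0] for s in assignment.samples("A")}
        assert len(groups) == 1

    def test_cohort_structure_13_14_3(self):
        vm = self._clouds([13, 14, 3], [0.0, 4.0, 8.0], seed=3)
        assignment = et.assign_endotypes(et.cluster_samples(vm), n_clusters=3)
        assert sorted([len(assignment.samples("A")), len(assignment.samples("B"))]) \
            == [13, 14]
        assert len(assignment.samples("other")) == 3

    def test_every_sample_its_own_cluster_boundary(self):
        vm = self._clouds([4], [0.0], seed=1)
        dend = et.cluster_samples(vm)
        a1 = et.assign_endotypes(dend, n_clusters=4)
        a2 = et.assign_endotypes(dend, n_clusters=4)
        assert a1.sizes() == {"A": 1, "B": 1, "other": 2}
        assert a1.labels.equals(a2.labels)  # deterministic despite ties

    def test_too_few_clusters_rejected(self):
        vm = self._clouds([5], [0.0])
        with pytest.raises(ValueError, match="at least 2"):
            et.assign_endotypes(et.cluster_samples(vm), n_clusters=1)


class TestLabelEndotypes:
    def test_anchor_high_cluster_becomes_a(self):
        rng = np.random.default_rng(0)
        base = rng.normal(5.0, 0.2, size=(10, 20))
        base[:2, 10:] += 2.0  # anchors doubled in the second group
        vm = make_vst(base, gene_ids=["anch1", "anch2"] + [f"g{i}" for i in range(8)])
        assignment = et.assign_endotypes(et.cluster_samples(vm), 2)
        labeled = et.label_endotypes(assignment, vm, {"anch1", "anch2"})
        a_samples = set(labeled.samples("A"))
        assert a_samples == set(vm.sample_ids[10:])

    def test_opposite_anchor_set_flips_labels(self):
        rng = np.random.default_rng(1)
        base = rng.normal(5.0, 0.2, size=(10, 20))
        base[0, 10:] += 2.0
        base[1, :10] += 2.0
        vm = make_vst(base, gene_ids=["up_right", "up_left"] + [f"g{i}" for i in range(8)])
        assignment = et.assign_endotypes(et.cluster_samples(vm), 2)
        one = et.label_endotypes(assignment, vm, {"up_right"})
        other = et.label_endotypes(assignment, vm, {"up_left"})
        assert set(one.samples("A")) == set(other.samples("B"))

    def test_missing_anchors_is_error(self):
        vm = make_vst(np.zeros((3, 4)))
        assignment = two_group_assignment(vm.sample_ids, 2)
        with pytest.raises(et.LabelingError, match="anchor"):
            et.label_endotypes(assignment, vm, {"absent"})


class TestConcordance:
    def test_identical_assignments(self):
        a = two_group_assignment([f"s{i}" for i in range(10)], 5)
        rep = et.concordance(a, a)
        assert rep.agreement_fraction == 1.0
        assert rep.adjusted_rand_index == 1.0
        assert rep.discordant_samples == []

    def test_swapped_labels_equivalent(self):
        ids = [f"s{i}" for i in range(10)]
        a = two_group_assignment(ids, 5)
        swapped = make_assignment(a.labels.map({"A": "B", "B": "A"}))
        rep = et.concordance(a, swapped)
        assert rep.agreement_fraction == 1.0
        assert rep.adjusted_rand_index == 1.0

    def test_independent_assignments_have_null_ari(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(1000)]
        a = make_assignment(pd.Series(rng.choice(["A", "B"], 1000), index=ids))
        b = make_assignment(pd.Series(rng.choice(["A", "B"], 1000), index=ids))
        rep = et.concordance(a, b)
        assert abs(rep.adjusted_rand_index) < 0.05

    def test_disjoint_sample_sets_rejected(self):
        a = two_group_assignment(["s1", "s2", "s3", "s4"], 2)
        b = two_group_assignment(["t1", "t2", "t3", "t4"], 2)
        with pytest.raises(ValueError, match="no samples"):
            et.concordance(a, b)


class TestClinicalSummary:
    def test_discovery_cohort_headline_numbers(self):
        summary = et.clinical_summary(load_clinical_fixture("pediatric_cohort1"))
        a, b, other = summary.loc["A"], summary.loc["B"], summary.loc["other"]
        assert a["n"] == 13 and a["mean_activity_score"] == 21 and a["anca_PR3"] == 9
        assert b["n"] == 14 and b["mean_activity_score"] == 14
        assert other["n"] == 3

    def test_counts_conserve_row_total(self):
        clin = load_clinical_fixture("pediatric_cohort1")
        summary = et.clinical_summary(clin)
        assert summary["n"].sum() == len(clin)
        assert (summary.filter(like="sex_").sum(axis=1) == summary["n"]).all()
        assert (summary.filter(like="anca_").sum(axis=1) == summary["n"]).all()

    def test_active_disease_rule(self):
        clin = pd.DataFrame({
            "patient_id": ["p1", "p2", "p3"], "endotype": ["A", "A", "A"],
            "ema_class": ["GPA"] * 3, "anca": ["PR3"] * 3,
            "timepoint": ["Diagnosis"] * 3, "sex": ["F"] * 3,
            "organ_systems": ["Renal"] * 3, "activity_score": [0, 2, 3],
        }).set_index("patient_id")
        summary = et.clinical_summary(clin)
        assert summary.loc["A", "n_active"] == 1  # only the score of 3 exceeds 2

    def test_empty_table_gives_empty_summary(self):
        assert et.clinical_summary(pd.DataFrame()).empty

    def test_unknown_label_rejected(self):
        clin = pd.DataFrame({
            "endotype": ["Z"], "sex": ["F"], "ema_class": ["GPA"],
            "anca": ["PR3"], "activity_score": [3],
        })
        with pytest.raises(ValueError, match="unknown endotype"):
            et.clinical_summary(clin)

    def test_adult_cohort_summary(self):
        summary = et.clinical_summary(load_clinical_fixture("adult"))
        assert summary.loc["A", "n"] == 5
        assert summary.loc["B", "n"] == 5
        assert summary.loc["other", "n"] == 1
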