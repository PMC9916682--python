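"""Hierarchical phenotype discovery and PLS-DA variable importance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import shine_ecgem as se


def well_separated_pairs(rng=None):
    """8 points forming 4 tight, well-separated pairs in the plane."""
    centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
    pts = np.repeat(centers, 2, axis=0)
    pts[1::2] += 0.3
    return pd.DataFrame(pts, columns=["x", "y"],
                        index=[f"s{i}" for i in range(8)])


def brute_force_best_partition(matrix, k):
    """Minimal max-intra-cluster-diameter partition over all assignments."""
    pts = matrix.to_numpy()
    n = len(pts)
    best, best_score = None, np.inf
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        score = 0.0
        for c in range(k):
            idx = [i for i, l in enumerate(labels) if l == c]
            for a, b in itertools.combinations(idx, 2):
                score = max(score, np.linalg.norm(pts[a] - pts[b]))
        if score < best_score:
            best, best_score = labels, score
    return pd.Series(best, index=matrix.index)


class TestHierCluster:
    def test_recovers_four_pairs_vs_brute_force(self):
        m = well_separated_pairs()
        assignment = se.hier_cluster(m, k=4)
        expected = brute_force_best_partition(m, 4)
        assert adjusted_rand_score(expected, assignment.labels) == 1.0

    def test_k_equals_one_collects_everything(self):
        m = well_separated_pairs()
        assignment = se.hier_cluster(m, k=1)
        assert assignment.labels.nunique() == 1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            se.hier_cluster(well_separated_pairs(), k=9)

    def test_default_cohort_recovery(self, default_cohort, patient_normalized):
        assignment = se.hier_cluster(patient_normalized, k=4)
        truth = default_cohort.true_phenotypes.loc[patient_normalized.index]
        assert adjusted_rand_score(truth, assignment.labels) >= 0.9

    def test_labels_invariant_to_sample_order(self, patient_normalized):
        a = se.hier_cluster(patient_normalized, k=4)
        shuffled = patient_normalized.sample(frac=1, random_state=3)
        b = se.hier_cluster(shuffled, k=4)
        joint = pd.crosstab(a.labels, b.labels.loc[a.labels.index])
        # one-to-one correspondence between labelings
        assert (joint.gt(0).sum(axis=1) == 1).all()

    def test_letters_follow_marker_gradient(self, default_cohort,
                                            patient_normalized):
        assignment = se.hier_cluster(patient_normalized, k=4)
        letters = se.assign_phenotype_letters(assignment, patient_normalized)
        means = patient_normalized["succinate"].groupby(letters).mean()
        assert list(means.sort_values().index) == ["A", "B", "C", "D"]


class TestVip:
    def test_single_informative_metabolite_tops_ranking(self):
        rng = np.random.default_rng(4)
        n = 60
        labels = pd.Series(["a"] * 30 + ["b"] * 30,
                           index=[f"s{i}" for i in range(n)])
        X = rng.normal(0, 1, (n, 8))
        X[:30, 3] += 4.0  # the only class-separating column
        m = pd.DataFrame(X, index=labels.index,
                         columns=[f"met{i}" for i in range(8)])
        vip = se.plsda_vip(m, labels)
        assert vip.scores.index[0] == "met3"

    def test_permuted_labels_destroy_ranking(self):
        """Under label permutation the planted column's VIP rank is ~uniform.

        Every column carries the same bimodal marginal (a ±3 split), but only
        met0's split aligns with the class labels — so the columns are
        exchangeable once labels are permuted.
        """
        rng = np.random.default_rng(9)
        n, p = 40, 6
        labels = pd.Series(["a"] * 20 + ["b"] * 20,
                           index=[f"s{i}" for i in range(n)])
        X = rng.normal(0, 1, (n, p))
        X[:20, 0] += 3.0
        for j in range(1, p):
            rows = rng.choice(n, size=n // 2, replace=False)
            X[rows, j] += 3.0
        m = pd.DataFrame(X, index=labels.index,
                         columns=[f"met{i}" for i in range(p)])
        observed = list(se.plsda_vip(m, labels).scores.index).index("met0") + 1
        assert observed == 1
        ranks = []
        for _ in range(200):
            perm = pd.Series(rng.permutation(labels.to_numpy()),
                             index=labels.index)
            vip = se.plsda_vip(m, perm)
            ranks.append(list(vip.scores.index).index("met0") + 1)
        # mean rank of a non-informative column under the null is (p+1)/2
        assert abs(np.mean(ranks) - (p + 1) / 2) < 0.8

    def test_mean_squared_vip_is_one(self, patient_normalized, default_cohort):
        truth = default_cohort.true_phenotypes.loc[patient_normalized.index]
        vip = se.plsda_vip(patient_normalized, truth)
        assert (vip.scores ** 2).mean() == pytest.approx(1.0, abs=1e-9)
        assert (vip.scores >= 0).all()

    def test_succinate_among_top_discriminators(self, default_cohort,
                                                patient_normalized):
        truth = default_cohort.true_phenotypes.loc[patient_normalized.index]
        vip = se.plsda_vip(patient_normalized, truth)
        assert "succinate" in vip.top(3).index

    def test_ranking_invariant_to_column_permutation(self, patient_normalized,
                                                     default_cohort):
        truth = default_cohort.true_phenotypes.loc[patient_normalized.index]
        a = se.plsda_vip(patient_normalized, truth)
        permuted = patient_normalized[list(reversed(patient_normalized.columns))]
        b = se.plsda_vip(permuted, truth)
        assert list(a.scores.index) == list(b.scores.index)

    def test_singleton_class_rejected(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)),
                         index=[f"s{i}" for i in range(5)])
        labels = pd.Series(["a", "a", "a", "a", "b"], index=m.index)
        with pytest.raises(ValueError, match="single"):
            se.plsda_vip(m, labels)


class TestHeatmap:
    def test_ordered_csv_is_row_permutation(self, patient_normalized, tmp_path):
        assignment = se.hier_cluster(patient_normalized, k=4)
        paths = se.render_phenotype_heatmap(patient_normalized, assignment,
                                            tmp_path / "heat")
        ordered = pd.read_csv(paths["csv"], index_col=0)
        assert sorted(ordered.index) == sorted(patient_normalized.index)
        pd.testing.assert_frame_equal(
            ordered.loc[patient_normalized.index], patient_normalized,
            check_exact=False)

    def test_leaf_order_consistent_with_tree(self, patient_normalized, tmp_path):
        from scipy.cluster.hierarchy import leaves_list

        assignment = se.hier_cluster(patient_normalized, k=4)
        paths = se.render_phenotype_heatmap(patient_normalized, assignment,
                                            tmp_path / "heat")
        ordered = pd.read_csv(paths["csv"], index_col=0)
        expected = patient_normalized.index[
            leaves_list(assignment.linkage_matrix)]
        assert list(ordered.index) == list(expected)

    def test_re_render_identical(self, patient_normalized, tmp_path):
        assignment = se.hier_cluster(patient_normalized, k=4)
        p1 = se.render_phenotype_heatmap(patient_normalized, assignment,
                                         tmp_path / "a")
        p2 = se.render_phenotype_heatmap(patient_normalized, assignment,
                                         tmp_path / "b")
        assert (open(p1["csv"]).read() == open(p2["csv"]).read())
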