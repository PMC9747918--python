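"""PCO, Calinski-Harabasz, cascade K-means, agreement and the two-step loop."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import (adjusted_rand_score, calinski_harabasz_score,
                             cohen_kappa_score)

from trajclust import (DistanceMatrix, agreement, calinski_harabasz,
                       cascade_kmeans, pco, reference_profiles,
                       two_step_cluster)


def _dm(points):
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    ids = [f"i{k}" for k in range(len(points))]
    return DistanceMatrix(ids, squareform(pdist(points)))


class TestPco:

    def test_zero_distances_give_zero_coordinates(self):
        dm = DistanceMatrix(list("abcd"), np.zeros((4, 4)))
        emb = pco(dm, 3)
        np.testing.assert_allclose(emb.coords, 0.0)

    def test_unit_square_eigenstructure_and_roundtrip(self):
        pts = [(0, 0), (1, 0), (0, 1), (1, 1)]
        emb = pco(_dm(pts), 3)
        lam = emb.eigenvalues
        assert lam[0] > 0 and lam[1] > 0
        assert lam[0] == pytest.approx(lam[1], rel=1e-9)
        assert abs(lam[2]) < 1e-9
        rec = squareform(pdist(emb.coords))
        np.testing.assert_allclose(rec, _dm(pts).values, atol=1e-9)

    def test_collinear_points_single_axis_with_gap_ratio(self):
        emb = pco(_dm([0.0, 1.0, 3.0]), 2)
        lam = emb.eigenvalues
        assert lam[0] > 1e-9
        assert np.all(np.abs(lam[1:]) < 1e-9)
        c = emb.coords[:, 0]
        gaps = np.abs(np.diff(c))
        assert gaps[1] / gaps[0] == pytest.approx(2.0, rel=1e-9)
        np.testing.assert_allclose(emb.coords[:, 1], 0.0, atol=1e-9)

    def test_euclidean_roundtrip_high_dim(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(25, 3))
        dm = _dm(pts)
        emb = pco(dm, 24)
        rec = squareform(pdist(emb.coords))
        assert np.max(np.abs(rec - dm.values)) <= 1e-8

    def test_matches_skbio_reference(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 4))
        dm = _dm(pts)
        ours = pco(dm, 3)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.values, ids=dm.ids), number_of_dimensions=3)
        np.testing.assert_allclose(np.abs(ours.coords),
                                   np.abs(ref.samples.to_numpy()), atol=1e-8)

    def test_component_count_validated(self):
        with pytest.raises(ValueError):
            pco(_dm([0.0, 1.0, 3.0]), 0)
        with pytest.raises(ValueError):
            pco(_dm([0.0, 1.0, 3.0]), 3)


class TestCalinskiHarabasz:

    def test_hand_evaluated_two_cluster_case(self):
        # {0,1,10,11} split at the obvious gap: B=100, W=1 -> 200
        score = calinski_harabasz([0.0, 1.0, 10.0, 11.0], [1, 1, 2, 2])
        assert score == pytest.approx(200.0)

    def test_perfect_separation_returns_infinity(self):
        pts = [0.0, 0.0, 5.0, 5.0]
        assert calinski_harabasz(pts, [0, 0, 1, 1]) == np.inf

    def test_label_names_are_irrelevant(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(30, 2))
        labels = rng.integers(0, 3, size=30)
        relabeled = np.array(["xyz"[v] for v in labels])
        assert calinski_harabasz(pts, labels) == pytest.approx(
            calinski_harabasz(pts, relabeled))

    def test_matches_sklearn(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(50, 3))
        labels = rng.integers(0, 4, size=50)
        assert calinski_harabasz(pts, labels) == pytest.approx(
            calinski_harabasz_score(pts, labels))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            calinski_harabasz([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError):
            calinski_harabasz([1.0, 2.0], [0, 1])


class TestCascadeKmeans:

    def _blobs(self, rng, centers, n_per=20, sd=0.1):
        pts = np.vstack([rng.normal(c, sd, size=(n_per, len(c)))
                         for c in centers])
        return pco(_dm(pts), 3)

    def test_three_well_separated_blobs_choose_three(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            emb = self._blobs(rng, [(0, 0), (10, 0), (0, 10)])
            res = cascade_kmeans(emb, seed=seed)
            assert res.chosen_k == 3

    def test_two_duplicated_locations_choose_two_via_sentinel(self):
        pts = np.array([[0.0, 0.0]] * 50 + [[4.0, 4.0]] * 50)
        emb = pco(_dm(pts), 2)
        res = cascade_kmeans(emb, seed=0)
        assert res.chosen_k == 2
        assert res.scores[2] == np.inf

    def test_chosen_labels_have_no_empty_cluster(self):
        rng = np.random.default_rng(3)
        emb = self._blobs(rng, [(0, 0), (6, 0), (0, 6), (6, 6)], sd=0.5)
        res = cascade_kmeans(emb, seed=3)
        lab = res.labels[res.chosen_k]
        assert lab.nunique() == res.chosen_k

    def test_item_order_invariance(self, template_set):
        from trajclust import pairwise_frechet
        ts, _ = template_set
        dm = pairwise_frechet(ts)
        emb = pco(dm, 3)
        res1 = cascade_kmeans(emb, seed=5)

        rng = np.random.default_rng(0)
        perm = rng.permutation(len(dm.ids))
        dm2 = DistanceMatrix([dm.ids[i] for i in perm],
                             dm.values[np.ix_(perm, perm)])
        res2 = cascade_kmeans(pco(dm2, 3), seed=5)
        assert res1.chosen_k == res2.chosen_k
        a = res1.labels[res1.chosen_k]
        b = res2.labels[res2.chosen_k].loc[a.index]
        assert adjusted_rand_score(a, b) == pytest.approx(1.0)


class TestReferenceProfiles:

    def test_single_member_cluster_is_the_member(self, template_set):
        ts, _ = template_set
        sub = ts.subset(ts.gene_ids[:3])
        labels = pd.Series([0, 1, 1], index=sub.gene_ids)
        refs = reference_profiles(sub, labels)
        np.testing.assert_allclose(refs.profiles.loc[0],
                                   sub.values.iloc[0])

    def test_two_member_mean(self):
        from trajclust import TrajectorySet
        times = np.array([4.0, 12.0])
        vals = pd.DataFrame([[0.0, 2.0], [2.0, 0.0]], index=["a", "b"])
        ts = TrajectorySet(times, vals, "logfc")
        refs = reference_profiles(ts, pd.Series({"a": 0, "b": 0}))
        np.testing.assert_allclose(refs.profiles.loc[0], [1.0, 1.0])

    def test_random_clusters_match_naive_means(self, template_set):
        ts, _ = template_set
        rng = np.random.default_rng(6)
        labels = pd.Series(rng.integers(0, 4, size=len(ts)),
                           index=ts.gene_ids)
        refs = reference_profiles(ts, labels)
        for c in range(4):
            members = labels.index[labels == c]
            np.testing.assert_allclose(
                refs.profiles.loc[c],
                ts.values.loc[members].to_numpy().mean(axis=0))


class TestAgreement:

    def test_identical_labelings(self):
        lab = pd.Series([1, 2, 1, 3], index=list("abcd"))
        st = agreement(lab, lab)
        assert st.percent == 100.0
        assert st.kappa == pytest.approx(1.0)

    def test_symmetric_confusion_hand_kappa(self):
        # confusion [[45,5],[5,45]]: po=0.9, pe=0.5, kappa=0.8
        a = pd.Series([0] * 50 + [1] * 50)
        b = a.copy()
        b.iloc[:5] = 1
        b.iloc[50:55] = 0
        st = agreement(a, b)
        assert st.percent == pytest.approx(90.0)
        assert st.kappa == pytest.approx(0.8)

    def test_constant_labeling_has_zero_kappa(self):
        a = pd.Series([0] * 50 + [1] * 50)
        b = pd.Series([0] * 100)
        st = agreement(a, b)
        assert st.percent == pytest.approx(50.0)
        assert st.kappa == pytest.approx(0.0)

    def test_matches_sklearn_cohen_kappa(self):
        rng = np.random.default_rng(8)
        a = pd.Series(rng.integers(0, 4, size=200))
        b = pd.Series(rng.integers(0, 4, size=200))
        st = agreement(a, b)
        assert st.kappa == pytest.approx(cohen_kappa_score(a, b))

    def test_foreign_alphabet_greedily_matched(self):
        a = pd.Series([0] * 10 + [1] * 10)
        b = pd.Series(["up"] * 10 + ["down"] * 10)
        st = agreement(a, b)
        assert st.percent == 100.0
        assert st.kappa == pytest.approx(1.0)
        assert st.mapping == {"up": 0, "down": 1}

    def test_item_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different items"):
            agreement(pd.Series({"a": 1}), pd.Series({"b": 1}))


class TestTwoStep:

    def test_noiseless_templates_fully_self_consistent(self, template_set):
        ts, truth = template_set
        res = two_step_cluster(ts, n_train=500, seed=0)
        assert res.cascade.chosen_k == 6
        assert res.agreement.percent == 100.0
        assert res.agreement.kappa == pytest.approx(1.0)
        assert adjusted_rand_score(truth, res.assignment.labels) == 1.0

    def test_default_noise_recovery(self):
        from trajclust import SimConfig, build_trajectories, log2_cpm, \
            simulate_timecourse
        cfg = SimConfig(n_genes=400, null_frac=0.0, seed=23)
        matrix, truth = simulate_timecourse(cfg)
        ts = build_trajectories(log2_cpm(matrix))
        res = two_step_cluster(ts, seed=23)
        ari = adjusted_rand_score(
            truth.table.loc[res.assignment.table.index, "pattern"],
            res.assignment.labels)
        assert ari >= 0.8
        assert res.agreement.percent >= 90.0

    def test_small_set_trains_on_everything(self, template_set):
        ts, _ = template_set
        res = two_step_cluster(ts, n_train=10_000, seed=1)
        assert len(res.training_labels) == len(ts)
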