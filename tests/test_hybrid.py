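import numpy as np
import pytest

from stresscluster import (
    HybridConfig,
    Partition,
    cluster_radius,
    estimate_k,
    generate_labeled,
    hybrid_fit,
    lloyd,
    mean_silhouette,
    split_cluster,
)
from stresscluster.hierarchy import agglomerate

from conftest import make_scores


class TestMeanSilhouette:
    def test_two_coincident_far_clusters(self):
        sm = make_scores([0.0, 0.0, 9.0, 9.0])
        part = Partition.from_labels([0, 0, 1, 1])
        assert mean_silhouette(sm, part) == pytest.approx(1.0)

    def test_single_cluster_rejected(self):
        sm = make_scores([0.0, 1.0])
        with pytest.raises(ValueError):
            mean_silhouette(sm, Partition.from_labels([0, 0]))

    def test_hand_computed_four_points(self):
        # 1-D {0,1,10,11} split {0,1}|{10,11}:
        # outer points: a=1, b=10.5 -> 9.5/10.5; inner points: a=1, b=9.5 -> 8.5/9.5
        sm = make_scores([0.0, 1.0, 10.0, 11.0])
        part = Partition.from_labels([0, 0, 1, 1])
        expected = (2 * (9.5 / 10.5) + 2 * (8.5 / 9.5)) / 4
        assert mean_silhouette(sm, part) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import silhouette_score

        x = rng.uniform(0, 10, size=(30, 4))
        labels = rng.integers(0, 3, size=30)
        if len(np.unique(labels)) < 2:
            labels[0] = (labels[0] + 1) % 3
        part = Partition.from_labels(labels)
        sm = make_scores(x)
        got = mean_silhouette(sm, part)
        want = silhouette_score(x, part.labels)
        assert got == pytest.approx(want, abs=1e-9)

    def test_singletons_contribute_zero(self):
        sm = make_scores([0.0, 5.0, 5.0])
        part = Partition.from_labels([0, 1, 1])
        # singleton scores 0; the coincident pair scores 1 each
        assert mean_silhouette(sm, part) == pytest.approx(2 / 3)


class TestEstimateK:
    def test_singleton_range(self, rng):
        sm = make_scores(rng.uniform(0, 10, size=(10, 2)))
        assert estimate_k(sm, (3, 3)) == 3

    def test_two_well_separated_blobs(self):
        ds = generate_labeled(n=100, k=2, m=4, separation=20, seed=11)
        assert estimate_k(ds.scores, (2, 6)) == 2

    def test_three_tight_blobs(self):
        ds = generate_labeled(n=90, k=3, m=4, separation=12, seed=7)
        assert estimate_k(ds.scores, (2, 5)) == 3

    def test_empty_range_rejected(self, rng):
        sm = make_scores(rng.uniform(0, 10, size=(10, 2)))
        with pytest.raises(ValueError):
            estimate_k(sm, (5, 4))


class TestRadiusAndSplit:
    def test_singleton_radius_zero(self):
        sm = make_scores([3.0])
        assert cluster_radius(sm, [0], np.array([3.0])) == 0.0

    def test_hand_computed_radius(self):
        sm = make_scores([0.0, 1.0, 10.0])
        r = cluster_radius(sm, [0, 1, 2], np.array([11 / 3]))
        assert r == pytest.approx(19 / 3, abs=1e-12)

    def test_coincident_members_radius_zero(self):
        sm = make_scores([4.0, 4.0])
        assert cluster_radius(sm, [0, 1], np.array([4.0])) == 0.0

    def test_empty_cluster_rejected(self):
        sm = make_scores([0.0])
        with pytest.raises(ValueError):
            cluster_radius(sm, [], np.array([0.0]))

    def test_split_farthest_then_farthest(self):
        sm = make_scores([0.0, 1.0, 10.0])
        x1, x2 = split_cluster(sm, [0, 1, 2], np.array([11 / 3]))
        assert (x1, x2) == (2, 0)

    def test_split_two_member_cluster(self):
        sm = make_scores([2.0, 8.0])
        assert set(split_cluster(sm, [0, 1], np.array([5.0]))) == {0, 1}

    def test_split_tie_goes_to_lowest_index(self):
        sm = make_scores([0.0, 10.0])
        x1, _ = split_cluster(sm, [0, 1], np.array([5.0]))
        assert x1 == 0

    def test_split_singleton_rejected(self):
        sm = make_scores([0.0])
        with pytest.raises(ValueError):
            split_cluster(sm, [0], np.array([0.0]))


class TestLloyd:
    def test_fixed_point_input(self):
        sm = make_scores([0.0, 2.0, 10.0, 12.0])
        res = lloyd(sm, np.array([[1.0], [11.0]]))
        assert res.partition.labels.tolist() == [0, 0, 1, 1]
        np.testing.assert_allclose(res.centroids.ravel(), [1.0, 11.0])
        assert res.iterations == 1

    def test_converges_from_extreme_init(self):
        sm = make_scores([0.0, 2.0, 10.0, 12.0])
        res = lloyd(sm, np.array([[0.0], [12.0]]))
        assert res.partition.labels.tolist() == [0, 0, 1, 1]
        np.testing.assert_allclose(res.centroids.ravel(), [1.0, 11.0])

    def test_k_one_gives_grand_mean(self, rng):
        x = rng.uniform(0, 10, size=(12, 3))
        sm = make_scores(x)
        res = lloyd(sm, x[:1].copy())
        np.testing.assert_allclose(res.centroids[0], x.mean(axis=0), atol=1e-9)

    def test_bad_max_iter_rejected(self):
        sm = make_scores([0.0, 1.0])
        with pytest.raises(ValueError):
            lloyd(sm, np.array([[0.0]]), max_iter=0)

    def test_empty_cluster_reseeded(self):
        # second center far outside the data captures nothing at first
        sm = make_scores([0.0, 1.0, 2.0], scale=None)
        res = lloyd(sm, np.array([[1.0], [9.0]]))
        assert res.partition.k == 2  # reseeding kept both clusters alive

    def test_sse_non_increasing_random_runs(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 40))
            m = int(rng.integers(1, 5))
            k = int(rng.integers(1, 5))
            x = rng.uniform(0, 10, size=(n, m))
            sm = make_scores(x)
            init = x[rng.choice(n, size=min(k, n), replace=False)]
            res = lloyd(sm, init)
            hist = res.sse_history
            assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))
            assert res.iterations <= 300


class TestHybridConfig:
    def test_default_split_budget_rules(self):
        cfg = HybridConfig()
        assert cfg.resolve_split_budget(2) == 0
        assert cfg.resolve_split_budget(3) == 0
        assert cfg.resolve_split_budget(4) == 1
        assert cfg.resolve_split_budget(8) == 1

    def test_configured_budget_clamped(self):
        cfg = HybridConfig(split_budget=3)
        assert cfg.resolve_split_budget(4) == 1  # 0 <= budget < k - 2
        assert cfg.resolve_split_budget(2) == 0
        assert cfg.resolve_split_budget(10) == 3

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            HybridConfig(k_range=(1, 4))
        with pytest.raises(ValueError):
            HybridConfig(split_budget=-1)
        with pytest.raises(ValueError):
            HybridConfig(max_iter=0)


class TestHybridFit:
    def test_no_split_matches_warm_started_lloyd(self):
        ds = generate_labeled(n=60, k=3, m=4, separation=10, seed=3)
        cfg = HybridConfig(k_range=(3, 3), split_budget=0)
        result = hybrid_fit(ds.scores, cfg)
        _, tree = agglomerate(ds.scores, 3)
        direct = lloyd(ds.scores, tree.final_centers)
        assert result.partition == direct.partition
        assert result.diagnostics["splits"] == 0

    def test_three_blob_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        ds = generate_labeled(n=150, k=3, m=6, separation=8, seed=1)
        result = hybrid_fit(ds.scores, HybridConfig(k_range=(2, 6), split_budget=1))
        assert adjusted_rand_score(result.partition.labels, ds.truth.labels) == 1.0

    def test_split_branch_executes(self):
        ds = generate_labeled(n=120, k=4, m=4, separation=10, seed=5)
        cfg = HybridConfig(k_range=(4, 4), split_budget=1)
        result = hybrid_fit(ds.scores, cfg)
        assert result.diagnostics["splits"] == 1
        assert result.partition.k == 4

    def test_deterministic_repeat(self):
        ds = generate_labeled(n=80, k=3, m=4, separation=4, seed=9)
        cfg = HybridConfig(k_range=(2, 5), seed=42)
        r1 = hybrid_fit(ds.scores, cfg)
        r2 = hybrid_fit(ds.scores, cfg)
        assert r1.partition == r2.partition
        assert r1.diagnostics == r2.diagnostics

    def test_diagnostics_contract(self):
        ds = generate_labeled(n=60, k=3, m=4, separation=8, seed=2)
        result = hybrid_fit(ds.scores, HybridConfig(k_range=(2, 4), seed=7))
        d = result.diagnostics
        for key in ("k", "split_budget", "splits", "lloyd_iterations", "sse", "seed"):
            assert key in d
        assert d["sse"] >= 0
        hist = d["sse_history"]
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))
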