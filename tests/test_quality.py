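"""Validity indices vs from-scratch oracles and the benchmark harness contract."""

import numpy as np
import pytest
from sklearn import metrics as skmetrics

from dermatone import (
    ClusterModelConfig,
    UndefinedMetricError,
    benchmark_models,
    calinski_harabasz,
    davies_bouldin,
    silhouette_score,
)

# ---------------------------------------------------------------------------
# naive O(N^2) / from-scratch oracle implementations


def silhouette_oracle(pix, labels):
    n = len(pix)
    svals = []
    for i in range(n):
        own = labels[i]
        same = [j for j in range(n) if labels[j] == own and j != i]
        if not same:
            svals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(pix[i] - pix[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(pix[i] - pix[j]) for j in range(n) if labels[j] == other])
            for other in set(labels)
            if other != own
        )
        svals.append((b - a) / max(a, b))
    return float(np.mean(svals))


def ch_oracle(pix, labels):
    n = len(pix)
    uniq = sorted(set(labels))
    k = len(uniq)
    g = pix.mean(axis=0)
    tr_b = sum(
        (labels == u).sum() * np.sum((pix[labels == u].mean(axis=0) - g) ** 2)
        for u in uniq
    )
    tr_w = sum(np.sum((pix[labels == u] - pix[labels == u].mean(axis=0)) ** 2) for u in uniq)
    return (tr_b / (k - 1)) / (tr_w / (n - k))


def db_oracle(pix, labels):
    uniq = sorted(set(labels))
    cents = [pix[labels == u].mean(axis=0) for u in uniq]
    spread = [
        np.mean([np.linalg.norm(p - c) for p in pix[labels == u]])
        for u, c in zip(uniq, cents)
    ]
    vals = []
    for i in range(len(uniq)):
        vals.append(
            max(
                (spread[i] + spread[j]) / np.linalg.norm(cents[i] - cents[j])
                for j in range(len(uniq))
                if j != i
            )
        )
    return float(np.mean(vals))


def random_instance(seed, n=60, k=3):
    rng = np.random.default_rng(seed)
    pix = rng.uniform(0, 100, size=(n, 3))
    labels = rng.integers(0, k, size=n)
    while len(set(labels)) < k:  # ensure every cluster occupied
        labels = rng.integers(0, k, size=n)
    return pix, labels


class TestSilhouette:
    def test_perfectly_tight_far_clusters_score_one(self):
        pix = np.vstack([np.tile([0.0, 0, 0], (5, 1)), np.tile([100.0, 0, 0], (5, 1))])
        labels = np.array([0] * 5 + [1] * 5)
        assert silhouette_score(pix, labels) == pytest.approx(1.0)

    def test_four_point_hand_computation(self):
        pix = np.array([[0.0, 0, 0], [0.0, 1, 0], [10.0, 10, 0], [10.0, 11, 0]])
        labels = np.array([0, 0, 1, 1])
        assert silhouette_score(pix, labels) == pytest.approx(
            silhouette_oracle(pix, labels), abs=1e-12
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_labels(self, seed):
        pix, labels = random_instance(seed)
        assert silhouette_score(pix, labels, sample_size=None) == pytest.approx(
            silhouette_oracle(pix, labels), abs=1e-9
        )

    def test_matches_sklearn(self):
        pix, labels = random_instance(17, n=100)
        assert silhouette_score(pix, labels, sample_size=None) == pytest.approx(
            skmetrics.silhouette_score(pix, labels), abs=1e-9
        )

    def test_full_sample_size_equals_full_score(self):
        pix, labels = random_instance(4, n=80)
        assert silhouette_score(pix, labels, sample_size=80) == pytest.approx(
            silhouette_score(pix, labels, sample_size=None), abs=1e-12
        )

    def test_single_cluster_undefined(self):
        with pytest.raises(UndefinedMetricError):
            silhouette_score(np.zeros((5, 3)), np.zeros(5, dtype=int))


class TestCalinskiHarabasz:
    def test_zero_within_scatter_is_inf(self):
        pix = np.vstack([np.tile([0.0, 0, 0], (4, 1)), np.tile([9.0, 0, 0], (4, 1))])
        labels = np.array([0] * 4 + [1] * 4)
        assert calinski_harabasz(pix, labels) == np.inf

    def test_noise_monotonicity(self):
        rng = np.random.default_rng(2)
        base = np.vstack(
            [
                rng.normal([20, 0, 0], 1.0, size=(40, 3)),
                rng.normal([80, 0, 0], 1.0, size=(40, 3)),
            ]
        )
        labels = np.array([0] * 40 + [1] * 40)
        noise = rng.normal(size=base.shape)
        tight = calinski_harabasz(base + noise, labels)
        loose = calinski_harabasz(base + 3 * noise, labels)
        assert tight > loose

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_scratch_formula(self, seed):
        pix, labels = random_instance(seed)
        ours = calinski_harabasz(pix, labels)
        assert ours == pytest.approx(ch_oracle(pix, labels), abs=1e-9)
        assert ours == pytest.approx(skmetrics.calinski_harabasz_score(pix, labels), rel=1e-9)

    def test_k_equals_n_undefined(self):
        with pytest.raises(UndefinedMetricError):
            calinski_harabasz(np.random.default_rng(0).normal(size=(3, 3)), np.arange(3))


class TestDaviesBouldin:
    def test_zero_variance_clusters_score_zero(self):
        pix = np.vstack([np.tile([0.0, 0, 0], (4, 1)), np.tile([9.0, 0, 0], (4, 1))])
        labels = np.array([0] * 4 + [1] * 4)
        assert davies_bouldin(pix, labels) == 0.0

    def test_linear_in_spread_at_fixed_centroids(self):
        rng = np.random.default_rng(6)
        offsets = rng.normal(size=(30, 3))
        offsets -= offsets.mean(axis=0)  # keep centroids fixed when scaling
        c1, c2 = np.array([10.0, 0, 0]), np.array([60.0, 0, 0])
        pix1 = np.vstack([c1 + offsets, c2 + offsets])
        pix2 = np.vstack([c1 + 2 * offsets, c2 + 2 * offsets])
        labels = np.array([0] * 30 + [1] * 30)
        assert davies_bouldin(pix2, labels) == pytest.approx(
            2 * davies_bouldin(pix1, labels), rel=1e-9
        )

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_matches_scratch_formula(self, seed):
        pix, labels = random_instance(seed)
        ours = davies_bouldin(pix, labels)
        assert ours == pytest.approx(db_oracle(pix, labels), abs=1e-9)
        assert ours == pytest.approx(skmetrics.davies_bouldin_score(pix, labels), rel=1e-9)

    def test_coincident_centroids_undefined(self):
        pix = np.vstack([np.tile([5.0, 0, 0], (3, 1)), np.tile([5.0, 0, 0], (3, 1))])
        labels = np.array([0] * 3 + [1] * 3)
        with pytest.raises(UndefinedMetricError):
            davies_bouldin(pix, labels)


def test_indices_degrade_monotonically_with_noise(two_blobs):
    """Silhouette and C-H fall, D-B rises, as isotropic noise grows."""
    pixels, labels = two_blobs
    rng = np.random.default_rng(10)
    noise = rng.normal(size=pixels.shape)
    sil, ch, db = [], [], []
    for level in (0.0, 4.0, 8.0):
        noisy = pixels + level * noise
        sil.append(silhouette_score(noisy, labels))
        ch.append(calinski_harabasz(noisy, labels))
        db.append(davies_bouldin(noisy, labels))
    assert sil[0] > sil[1] > sil[2]
    assert ch[0] > ch[1] > ch[2]
    assert db[0] < db[1] < db[2]


class TestBenchmarkHarness:
    def test_single_kmeans_config_on_blobs(self, two_blobs):
        pixels, _ = two_blobs
        reports = benchmark_models(pixels, [ClusterModelConfig(n_clusters=2, seed=0)])
        assert len(reports) == 1
        assert reports[0].status == "ok"
        assert reports[0].silhouette > 0.9

    def test_failing_model_isolated(self, two_blobs):
        pixels, _ = two_blobs
        good = ClusterModelConfig(n_clusters=2, seed=0)
        bad = ClusterModelConfig(n_clusters=2, seed=0)
        bad.model_name = "kmedoids"  # bypass constructor validation
        reports = benchmark_models(pixels, [good, bad])
        assert reports[0].status == "ok"
        assert reports[1].status.startswith("error:")
        assert reports[1].silhouette is None

    def test_reports_deterministic_except_timing(self, two_blobs):
        pixels, _ = two_blobs
        cfgs = [ClusterModelConfig(n_clusters=2, seed=0, model_name=m) for m in ("kmeans", "gmm")]
        r1 = benchmark_models(pixels, cfgs)
        r2 = benchmark_models(pixels, cfgs)
        for a, b in zip(r1, r2):
            d1, d2 = a.to_dict(), b.to_dict()
            d1.pop("fit_seconds"), d2.pop("fit_seconds")
            assert d1 == d2

    def test_empty_config_list_rejected(self, two_blobs):
        with pytest.raises(ValueError):
            benchmark_models(two_blobs[0], [])
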