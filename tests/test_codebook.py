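"""Chi-squared distance, chi-squared K-means, and BoW encoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bowfood.codebook import (
    BowHistogram,
    Codebook,
    UnencodableImageError,
    assign_codeword,
    chi2_cdist,
    chi2_distance,
    encode_image,
    kmeans_chi2,
)
from bowfood.features import FeatureSet, InterestPoint


def chi2_reference(u, v):
    """Direct elementwise evaluation of the chi-squared dissimilarity."""
    total = 0.0
    for a, b in zip(u, v):
        if a + b > 0:
            total += (a - b) ** 2 / (a + b)
    return 0.5 * total


class TestChi2Distance:
    def test_identity(self, rng):
        x = rng.random(32)
        assert chi2_distance(x, x) == 0.0

    @pytest.mark.parametrize("u,v,expected", [
        ((1, 0), (0, 1), 1.0),
        ((2, 0, 0), (0, 0, 2), 2.0),
        ((0, 0), (0, 0), 0.0),
    ])
    def test_hand_evaluated(self, u, v, expected):
        assert chi2_distance(u, v) == pytest.approx(expected, abs=1e-12)

    def test_matches_reference_on_random_pairs(self, rng):
        for _ in range(200):
            u = rng.random(16) * rng.integers(1, 5)
            v = rng.random(16)
            d = chi2_distance(u, v)
            assert d == pytest.approx(chi2_reference(u, v), abs=1e-12)
            assert d == pytest.approx(chi2_distance(v, u), abs=1e-12)

    def test_rejects_negative_entries(self):
        with pytest.raises(ValueError, match="non-negative"):
            chi2_distance([1.0, -0.1], [0.5, 0.5])

    def test_rejects_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            chi2_distance([1.0, 2.0], [1.0, 2.0, 3.0])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 100), min_size=1, max_size=12),
           st.lists(st.floats(0, 100), min_size=1, max_size=12))
    def test_symmetric_nonnegative(self, u, v):
        n = min(len(u), len(v))
        u, v = u[:n], v[:n]
        d = chi2_distance(u, v)
        assert d >= 0
        assert d == pytest.approx(chi2_distance(v, u), abs=1e-12)

    def test_cdist_matches_scalar(self, rng):
        X = rng.random((20, 8))
        C = rng.random((5, 8))
        D = chi2_cdist(X, C)
        for i in (0, 7, 19):
            for j in range(5):
                assert D[i, j] == pytest.approx(chi2_distance(X[i], C[j]),
                                                abs=1e-12)


def brute_force_lloyd(X, K, seed, n_restarts=50):
    """Independent plain-python Lloyd oracle, best of many random inits."""
    rng = np.random.default_rng(seed)
    best = np.inf
    n = len(X)
    for _ in range(n_restarts):
        centroids = X[rng.choice(n, size=K, replace=False)].astype(float)
        for _ in range(200):
            d = np.array([[chi2_reference(x, c) for c in centroids]
                          for x in X])
            labels = d.argmin(axis=1)
            new = centroids.copy()
            for k in range(K):
                if (labels == k).any():
                    new[k] = X[labels == k].mean(axis=0)
            if np.allclose(new, centroids):
                break
            centroids = new
        d = np.array([[chi2_reference(x, c) for c in centroids] for x in X])
        best = min(best, d.min(axis=1).sum())
    return best


class TestKmeansChi2:
    def test_degenerate_k_equals_n(self, rng):
        X = rng.random((5, 4)) + 0.1
        cb = kmeans_chi2(X, K=5, seed=0)
        assert cb.objective_history[-1] == pytest.approx(0.0, abs=1e-12)
        # centroids are a permutation of the inputs
        matched = {tuple(np.round(c, 12)) for c in cb.centroids}
        assert matched == {tuple(np.round(x, 12)) for x in X}

    def test_two_blob_recovery(self, rng):
        a = np.abs(rng.normal([1, 0, 0], 0.01, (50, 3)))
        b = np.abs(rng.normal([0, 0, 1], 0.01, (50, 3)))
        X = np.vstack([a, b])
        cb = kmeans_chi2(X, K=2, seed=1)
        d = chi2_cdist(X, cb.centroids)
        labels = d.argmin(axis=1)
        assert len(set(labels[:50])) == 1
        assert len(set(labels[50:])) == 1
        assert labels[0] != labels[50]
        means = [a.mean(axis=0), b.mean(axis=0)]
        for c in cb.centroids:
            assert min(chi2_distance(c, m) for m in means) < 0.05

    def test_objective_monotone_and_reproducible(self, rng):
        X = rng.random((60, 6))
        cb1 = kmeans_chi2(X, K=4, seed=3)
        cb2 = kmeans_chi2(X, K=4, seed=3)
        hist = cb1.objective_history
        assert all(hist[i + 1] <= hist[i] + 1e-12
                   for i in range(len(hist) - 1))
        assert np.array_equal(cb1.centroids, cb2.centroids)

    def test_small_instances_reach_brute_force_optimum(self, rng):
        for trial in range(5):
            n = int(rng.integers(6, 13))
            K = int(rng.integers(2, 4))
            X = rng.random((n, 3)) + 0.05
            cb = kmeans_chi2(X, K=K, seed=trial)
            oracle = brute_force_lloyd(X, K, seed=100 + trial)
            assert cb.objective_history[-1] <= oracle + 1e-9

    def test_too_few_distinct_features(self):
        X = np.tile([0.5, 0.5], (10, 1))
        with pytest.raises(ValueError, match="distinct"):
            kmeans_chi2(X, K=2, seed=0)


class TestAssignCodeword:
    def test_exact_centroid_match(self, rng):
        cb = Codebook("colour", rng.random((8, 5)) + 0.01)
        assert assign_codeword(cb.centroids[3], cb) == 3

    def test_tie_broken_to_lowest_index(self):
        # centroids 0 and 2 equidistant from the query by symmetry
        centroids = np.array([[1.0, 0.0], [5.0, 5.0], [0.0, 1.0]])
        cb = Codebook("colour", centroids)
        assert assign_codeword(np.array([0.5, 0.5]), cb) == 0

    def test_matches_exhaustive_search(self, rng):
        cb = Codebook("shape", rng.random((40, 16)))
        for _ in range(50):
            v = rng.random(16)
            dists = [chi2_reference(v, c) for c in cb.centroids]
            assert assign_codeword(v, cb) == int(np.argmin(dists))

    def test_dimension_mismatch(self, rng):
        cb = Codebook("shape", rng.random((4, 16)))
        with pytest.raises(ValueError):
            assign_codeword(rng.random(8), cb)


def _featureset(rng, n_points, dims=(128, 59, 64)):
    points = [InterestPoint(x=float(i), y=float(i), scale=1.0,
                            orientation=0.0) for i in range(n_points)]
    by_channel = {ch: rng.random((n_points, d)) for ch, d in
                  zip(("shape", "texture", "colour"), dims)}
    return FeatureSet(points=points, by_channel=by_channel)


class TestEncodeImage:
    def _codebooks(self, rng, sizes=(100, 40, 50)):
        return {ch: Codebook(ch, rng.random((k, d)) + 0.01)
                for ch, k, d in zip(("shape", "texture", "colour"),
                                    sizes, (128, 59, 64))}

    def test_default_sizes_concatenate_to_190(self, rng):
        fs = _featureset(rng, 7)
        h = encode_image(fs, self._codebooks(rng))
        assert h.values.shape == (190,)
        assert h.layout == (("shape", 100), ("texture", 40), ("colour", 50))

    def test_single_point_matching_centroid_zero(self, rng):
        cbs = self._codebooks(rng, sizes=(4, 3, 3))
        fs = _featureset(rng, 1)
        fs.by_channel["shape"][0] = cbs["shape"].centroids[0]
        h = encode_image(fs, cbs)
        assert h.values[0] == pytest.approx(1.0)
        assert h.values[1:4].sum() == pytest.approx(0.0)

    def test_channel_blocks_sum_to_one(self, rng):
        fs = _featureset(rng, 23)
        h = encode_image(fs, self._codebooks(rng))
        start = 0
        for _, k in h.layout:
            assert h.values[start:start + k].sum() == pytest.approx(
                1.0, abs=1e-9)
            start += k

    def test_invariant_to_point_permutation(self, rng):
        fs = _featureset(rng, 15)
        cbs = self._codebooks(rng)
        h1 = encode_image(fs, cbs)
        perm = rng.permutation(15)
        fs2 = FeatureSet(points=[fs.points[i] for i in perm],
                         by_channel={ch: m[perm]
                                     for ch, m in fs.by_channel.items()})
        h2 = encode_image(fs2, cbs)
        assert np.allclose(h1.values, h2.values)

    def test_zero_points_unencodable(self, rng):
        fs = _featureset(rng, 0)
        with pytest.raises(UnencodableImageError):
            encode_image(fs, self._codebooks(rng))

    def test_channel_subset(self, rng):
        fs = _featureset(rng, 9)
        h = encode_image(fs, self._codebooks(rng), channels=("colour",))
        assert h.layout == (("colour", 50),)
        assert h.values.shape == (50,)
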