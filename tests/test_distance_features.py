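import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cdboost import (
    DistanceFeatureSelector,
    chebyshev,
    city_block,
    cosine_distance,
    decode_predictions,
    distance_correlation,
    encode_targets,
    select_features,
)
from cdboost.correlation_dimension import CDFeatureMatrix, EmbeddingConfig

finite_vec = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=2, max_size=8
)


def brute_force_dcor(x, y):
    """Independent double-centering oracle written as explicit loops."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    a = np.array([[abs(x[i] - x[j]) for j in range(n)] for i in range(n)])
    b = np.array([[abs(y[i] - y[j]) for j in range(n)] for i in range(n)])

    def center(d):
        out = np.empty_like(d)
        for i in range(n):
            for j in range(n):
                out[i, j] = d[i, j] - d[i].mean() - d[:, j].mean() + d.mean()
        return out

    A, B = center(a), center(b)
    dcov2 = (A * B).mean()
    return np.sqrt(max(dcov2, 0.0) / np.sqrt((A * A).mean() * (B * B).mean()))


class TestDistanceCorrelation:
    def test_identical_samples_give_one(self, rng):
        x = rng.normal(size=50)
        assert distance_correlation(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip_still_one(self, rng):
        """Unlike Pearson, dCor detects sign-flipped dependence as full."""
        x = rng.normal(size=40)
        assert distance_correlation(x, -x) == pytest.approx(1.0, abs=1e-12)
        assert distance_correlation(x, -x) == pytest.approx(
            brute_force_dcor(x, -x), abs=1e-12
        )

    def test_independent_samples_near_zero(self):
        r = np.random.default_rng(42)
        x = r.normal(size=2000)
        y = r.normal(size=2000)
        assert distance_correlation(x, y) < 0.08

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25) + 0.5 * x**2
        assert distance_correlation(x, y) == pytest.approx(
            brute_force_dcor(x, y), abs=1e-12
        )

    def test_degenerate_constant_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            distance_correlation(np.ones(10), np.arange(10.0))

    def test_invariance_under_similarity_transforms(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30) + x
        base = distance_correlation(x, y)
        assert distance_correlation(3.0 * x + 7.0, y) == pytest.approx(base, abs=1e-9)
        assert distance_correlation(x, -2.0 * y + 1.0) == pytest.approx(base, abs=1e-9)


class TestSimpleMetrics:
    def test_textbook_values(self):
        assert city_block([0, 0], [3, 4]) == 7.0
        assert chebyshev([0, 0], [3, 4]) == 4.0
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)
        assert cosine_distance([1, 2], [1, 2]) == pytest.approx(0.0, abs=1e-12)
        assert cosine_distance([1, 2], [-1, -2]) == pytest.approx(2.0)

    def test_zero_vector_rejected_for_cosine(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_distance([0, 0], [1, 2])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            city_block([1, 2], [1, 2, 3])

    @given(finite_vec, finite_vec, finite_vec)
    @settings(max_examples=50, deadline=None)
    def test_metric_axioms_on_random_triples(self, a, b, c):
        n = min(len(a), len(b), len(c))
        a, b, c = a[:n], b[:n], c[:n]
        for d in (city_block, chebyshev):
            assert d(a, b) == pytest.approx(d(b, a))
            assert d(a, a) == 0.0
            assert d(a, c) <= d(a, b) + d(b, c) + 1e-9

    @given(finite_vec)
    @settings(max_examples=50, deadline=None)
    def test_chebyshev_euclidean_cityblock_chain(self, a):
        b = [v + 1.5 for v in a]
        eu = float(np.linalg.norm(np.array(a) - np.array(b)))
        assert chebyshev(a, b) <= eu + 1e-12
        assert eu <= city_block(a, b) + 1e-12

    def test_cosine_scale_invariance(self, rng):
        a = rng.normal(size=6)
        for c in (0.1, 2.0, 1e3):
            assert cosine_distance(a, c * a) == pytest.approx(0.0, abs=1e-9)


def _planted_cd_matrix(n_records=30, n_channels=16, n_windows=20, signal_channels=10, seed=0):
    """CD-like matrix where only the first `signal_channels` carry class signal.

    Class 0 channels follow a channel-specific sinusoidal window profile;
    in the signal channels class 1 swaps it for a phase-shifted profile and
    a level shift, so both shape-sensitive (dCor, cosine) and magnitude
    metrics can see the difference.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n_records // 2)
    w = np.arange(n_windows)
    prof0 = np.stack(
        [1.5 + 0.4 * np.sin(2 * np.pi * (c + 1) * w / n_windows) for c in range(n_channels)]
    )
    prof1 = np.stack(
        [1.0 + 0.4 * np.cos(2 * np.pi * (c + 1) * w / n_windows) for c in range(n_channels)]
    )
    values = prof0[None, :, :] + rng.normal(0, 0.2, size=(n_records, n_channels, n_windows))
    alt = prof1[None, :signal_channels, :] + rng.normal(
        0, 0.2, size=(n_records, signal_channels, n_windows)
    )
    values[labels == 1, :signal_channels, :] = alt[labels == 1]
    return (
        CDFeatureMatrix(
            values=values.reshape(n_records, -1),
            n_channels=n_channels,
            n_windows=n_windows,
            config=EmbeddingConfig(),
        ),
        labels,
    )


class TestSelector:
    def test_feature_width_contract(self, medium_cd_matrix):
        fs = select_features(
            medium_cd_matrix, medium_cd_matrix.labels, metric="city_block", k=8
        )
        assert fs.features.shape == (24, 8)
        assert len(fs.selector_meta) == 8
        assert fs.target_encoding["threshold"] == 0.45

    def test_k_exceeding_channels_rejected(self, medium_cd_matrix):
        with pytest.raises(ValueError, match="exceeds"):
            select_features(medium_cd_matrix, medium_cd_matrix.labels, k=99)

    def test_single_class_rejected(self, medium_cd_matrix):
        with pytest.raises(ValueError, match="single class"):
            select_features(medium_cd_matrix, np.zeros(24, dtype=int), k=4)

    @pytest.mark.parametrize("metric", ["distance_correlation", "city_block", "chebyshev", "cosine"])
    def test_planted_signal_channels_recovered(self, metric):
        cd, labels = _planted_cd_matrix(seed=3)
        sel = DistanceFeatureSelector(metric=metric, k=10).fit(cd, labels)
        hits = np.intersect1d(sel.selected_channels_, np.arange(10)).size
        assert hits >= 8

    def test_identical_classes_give_near_zero_scores(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(40, 8, 12))
        cd = CDFeatureMatrix(
            values=values.reshape(40, -1), n_channels=8, n_windows=12,
            config=EmbeddingConfig(),
        )
        labels = np.repeat([0, 1], 20)
        sel = DistanceFeatureSelector(metric="city_block", k=4).fit(cd, labels)
        # scores exist and are small relative to the distance scale
        assert np.all(sel.scores_ >= 0)
        assert sel.scores_.max() < 2.0  # city-block over 12 windows of N(0,1)

    def test_deterministic_and_no_test_label_leakage(self):
        cd, labels = _planted_cd_matrix(seed=5)
        train = np.arange(20)
        test = np.arange(20, 30)
        from cdboost.evaluation import _take

        sel1 = DistanceFeatureSelector(metric="chebyshev", k=5).fit(
            _take(cd, train), labels[train]
        )
        sel2 = DistanceFeatureSelector(metric="chebyshev", k=5).fit(
            _take(cd, train), labels[train]
        )
        np.testing.assert_array_equal(sel1.selected_channels_, sel2.selected_channels_)
        # transforming test data never consults labels at all (signature), and
        # the transform is frozen: same output for any hypothetical test labels
        np.testing.assert_array_equal(
            sel1.transform(_take(cd, test)), sel2.transform(_take(cd, test))
        )


class TestTargetCoding:
    def test_encode_values(self):
        np.testing.assert_array_equal(encode_targets([0, 1, 1]), [0.0, 1.0, 1.0])

    def test_decode_boundary_ge_rule(self):
        np.testing.assert_array_equal(
            decode_predictions(np.array([0.45, 0.449, 0.9, 0.0])), [1, 0, 1, 0]
        )

    def test_encode_decode_identity_on_clean_targets(self):
        labels = np.array([0, 1, 0, 1, 1])
        np.testing.assert_array_equal(
            decode_predictions(encode_targets(labels)), labels
        )

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            encode_targets([0, 2])
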