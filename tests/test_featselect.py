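import numpy as np
import pytest
from scipy import stats

import ggapdc
from ggapdc.exceptions import DataError, DegenerateScoreError
from ggapdc.features import FeatureMatrix, PAIR_NAMES
from ggapdc.featselect import (
    fscore,
    rank_features,
    score_features,
    signed_normalized_fscore,
)


def matrix_from(X, y, g=0):
    """Embed an arbitrary (n, d) block into the first d of 400 features."""
    X = np.asarray(X, dtype=float)
    full = np.zeros((X.shape[0], 400))
    full[:, : X.shape[1]] = X
    return FeatureMatrix(X=full, y=np.asarray(y), g=g)


class TestFScore:
    def test_frozen_two_group_example(self):
        # positives (0.1, 0.2, 0.3), negatives (0.4, 0.5, 0.6):
        # means 0.2 / 0.5, grand 0.35
        # MS_between = 3*(0.15)^2 + 3*(0.15)^2 = 0.135
        # MS_within  = (0.01 + 0 + 0.01 + 0.01 + 0 + 0.01) / 4 = 0.01
        m = matrix_from([[0.1], [0.2], [0.3], [0.4], [0.5], [0.6]],
                        [1, 1, 1, 0, 0, 0])
        table = fscore(m)
        assert table.F[0] == pytest.approx(13.5, rel=1e-12)

    def test_matches_scipy_anova_oracle(self, rng):
        X = rng.random((30, 400))
        y = np.array([1] * 12 + [0] * 18)
        table = fscore(FeatureMatrix(X=X, y=y, g=0))
        for j in range(0, 400, 17):
            expected = stats.f_oneway(X[y == 1, j], X[y == 0, j]).statistic
            assert table.F[j] == pytest.approx(expected, rel=1e-9)

    def test_equals_squared_pooled_t(self, rng):
        """Two-group ANOVA F is the square of the pooled-variance t statistic."""
        X = rng.normal(size=(25, 400))
        y = np.array([1] * 10 + [0] * 15)
        table = fscore(FeatureMatrix(X=X, y=y, g=0))
        t = stats.ttest_ind(X[y == 1], X[y == 0], equal_var=True).statistic
        np.testing.assert_allclose(table.F, t**2, rtol=1e-9)

    def test_equal_class_means_give_zero(self):
        m = matrix_from([[0.1], [0.3], [0.1], [0.3]], [1, 1, 0, 0])
        assert fscore(m).F[0] == 0.0

    def test_constant_feature_is_zero_by_convention(self):
        m = matrix_from([[0.2], [0.2], [0.2], [0.2]], [1, 1, 0, 0])
        assert fscore(m).F[0] == 0.0

    def test_perfect_separation_is_infinite_sentinel(self):
        m = matrix_from([[0.9], [0.9], [0.1], [0.1]], [1, 1, 0, 0])
        assert np.isinf(fscore(m).F[0])

    def test_shift_and_scale_invariance(self, rng):
        """Adding a constant or scaling a feature leaves its F unchanged."""
        X = rng.random((20, 400))
        y = np.array([1] * 8 + [0] * 12)
        base = fscore(FeatureMatrix(X=X, y=y, g=0)).F
        shifted = fscore(FeatureMatrix(X=X + 0.37, y=y, g=0)).F
        scaled = fscore(FeatureMatrix(X=X * -2.5, y=y, g=0)).F
        np.testing.assert_allclose(shifted, base, rtol=1e-7, atol=1e-10)
        np.testing.assert_allclose(scaled, base, rtol=1e-7, atol=1e-10)

    def test_single_class_rejected(self):
        m = matrix_from([[0.1], [0.2], [0.3]], [1, 1, 1])
        with pytest.raises(DataError):
            fscore(m)

    def test_tiny_class_rejected(self):
        m = matrix_from([[0.1], [0.2], [0.3]], [1, 0, 0])
        with pytest.raises(DataError, match="2 samples per class"):
            fscore(m)

    def test_null_matrix_mean_f_near_expectation(self, null_matrix):
        """Under no signal, E[F] = (n-2)/(n-4) for the F(1, n-2) distribution."""
        table = fscore(null_matrix)
        n = null_matrix.n_samples
        expected = (n - 2) / (n - 4)
        assert abs(np.mean(table.F) - expected) < 0.25


class TestSignedNorm:
    def test_bounds_and_extremes(self, planted_matrix):
        table = score_features(planted_matrix)
        s = table.signed_norm
        assert ((-1 <= s) & (s <= 1)).all()
        finite = np.isfinite(table.F)
        top = np.argmax(np.where(finite, table.F, -np.inf))
        assert abs(s[top]) == 1.0
        assert s[np.argmin(table.F)] == 0.0

    def test_positive_enriched_top_feature_is_plus_one(self):
        X = np.zeros((8, 400))
        rng = np.random.default_rng(3)
        X[:, :5] = rng.random((8, 5))
        y = np.array([1] * 4 + [0] * 4)
        X[y == 1, 0] += 5.0  # dominant, positively enriched
        table = fscore(FeatureMatrix(X=X, y=y, g=0))
        signed_normalized_fscore(table)
        assert table.signed_norm[0] == 1.0

    def test_equal_means_give_zero_sign(self):
        m = matrix_from(
            [[0.1, 0.6], [0.3, 0.7], [0.1, 0.1], [0.3, 0.2]], [1, 1, 0, 0]
        )
        table = fscore(m)
        signed_normalized_fscore(table)
        assert table.signed_norm[0] == 0.0  # mean_pos == mean_neg

    def test_sentinels_map_to_unit_magnitude(self):
        m = matrix_from(
            [[0.9, 0.5], [0.9, 0.6], [0.1, 0.1], [0.1, 0.2]], [1, 1, 0, 0]
        )
        table = fscore(m)
        signed_normalized_fscore(table)
        assert np.isinf(table.F[0])
        assert table.signed_norm[0] == 1.0

    def test_degenerate_identical_scores_rejected(self):
        m = matrix_from(np.zeros((4, 3)), [1, 1, 0, 0])
        table = fscore(m)
        with pytest.raises(DegenerateScoreError):
            signed_normalized_fscore(table)


class TestRanking:
    def test_descending_order_and_permutation(self, planted_matrix):
        table = score_features(planted_matrix)
        order = table.order
        assert sorted(order.tolist()) == list(range(400))
        F = np.where(np.isinf(table.F), np.finfo(float).max, table.F)
        assert (np.diff(F[order]) <= 1e-30).all() or (
            F[order][:-1] >= F[order][1:]
        ).all()
        assert sorted(table.rank.tolist()) == list(range(1, 401))

    def test_simple_order(self):
        m = matrix_from(
            [[0.0, 0.0, 0.5], [0.1, 0.05, 0.6], [0.5, 0.2, 0.0], [0.6, 0.21, 0.1]],
            [1, 1, 0, 0],
        )
        table = fscore(m)
        order = rank_features(table)
        by_f = np.argsort(-table.F[:3])
        assert list(order[:3]) == list(by_f)

    def test_ties_broken_by_dipeptide_name(self):
        # two features with identical values -> identical F; name order decides
        X = np.zeros((4, 400))
        j1, j2 = PAIR_NAMES.index("CA"), PAIR_NAMES.index("AC")
        X[:, j1] = [0.1, 0.2, 0.4, 0.5]
        X[:, j2] = [0.1, 0.2, 0.4, 0.5]
        table = fscore(FeatureMatrix(X=X, y=np.array([1, 1, 0, 0]), g=0))
        order = rank_features(table)
        assert list(order[:2]) == [j2, j1]  # "AC" before "CA"
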