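import numpy as np
import pytest

import ggapdc
from ggapdc.exceptions import (
    ContractError,
    DataError,
    ModelFormatError,
    StratificationError,
)
from ggapdc.features import FeatureMatrix
from ggapdc.svm_eval import (
    MetricsReport,
    SVMConfig,
    cross_validate,
    grid_search_svm,
    jackknife,
    load_model,
    save_model,
    stratified_folds,
    train_svm,
)


@pytest.fixture(scope="module")
def planted_config():
    return SVMConfig(folds=5, seed=3)


class TestMetricsReport:
    def test_identities(self):
        r = MetricsReport(51, 135, 53, 136)
        assert r.sn == pytest.approx(51 / 53)
        assert r.sp == pytest.approx(135 / 136)
        assert r.oa == pytest.approx((51 + 135) / 189)

    def test_sn_example_three_decimals(self):
        assert round(MetricsReport(51, 0, 53, 10).sn, 3) == 0.962

    def test_perfect_prediction(self):
        r = MetricsReport(10, 20, 10, 20)
        assert r.sn == r.sp == r.oa == 1.0

    def test_bounds_enforced(self):
        with pytest.raises(ContractError):
            MetricsReport(11, 0, 10, 5)

    def test_oa_is_weighted_mean_of_sn_sp(self, rng):
        for _ in range(20):
            N_pos, N_neg = rng.integers(2, 50, size=2)
            n_pos = rng.integers(0, N_pos + 1)
            n_neg = rng.integers(0, N_neg + 1)
            r = MetricsReport(int(n_pos), int(n_neg), int(N_pos), int(N_neg))
            w_pos = N_pos / (N_pos + N_neg)
            assert r.oa == pytest.approx(w_pos * r.sn + (1 - w_pos) * r.sp)


class TestFolds:
    def test_stratification_within_one_sample(self):
        y = np.array([1] * 20 + [0] * 45)
        folds = stratified_folds(y, 5, seed=0)
        global_frac = 20 / 65
        for _, test_idx in folds:
            n_pos = int(np.sum(y[test_idx] == 1))
            assert abs(n_pos - global_frac * len(test_idx)) <= 1.0

    def test_each_sample_tested_once(self):
        y = np.array([1] * 10 + [0] * 15)
        folds = stratified_folds(y, 5, seed=1)
        tested = np.concatenate([t for _, t in folds])
        assert sorted(tested.tolist()) == list(range(25))

    def test_seed_determinism(self):
        y = np.array([1] * 12 + [0] * 18)
        a = stratified_folds(y, 4, seed=9)
        b = stratified_folds(y, 4, seed=9)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)

    def test_infeasible_k_rejected(self):
        y = np.array([1, 1, 0, 0, 0, 0])
        with pytest.raises(StratificationError):
            stratified_folds(y, 3, seed=0)


class TestTrainPredict:
    def test_separable_training_set_memorized(self, planted_matrix):
        model = train_svm(planted_matrix, C=8.0, gamma=8.0)
        pred = model.predict(planted_matrix.X)
        assert np.mean(pred == planted_matrix.y) > 0.95

    def test_dimension_contract(self, planted_matrix):
        model = train_svm(planted_matrix, C=1.0, gamma=1.0,
                          feature_indices=list(range(20)))
        assert model.n_features == 20
        with pytest.raises(ContractError, match="expects 20"):
            model.predict(planted_matrix.X)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((5, 400))
        with pytest.raises(DataError):
            train_svm(X, np.ones(5, dtype=int), C=1.0, gamma=1.0)

    def test_persistence_round_trip(self, planted_matrix, tmp_path):
        model = train_svm(planted_matrix, C=2.0, gamma=0.5)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.C == 2.0 and loaded.gamma == 0.5 and loaded.g == 6
        assert np.array_equal(
            loaded.predict(planted_matrix.X), model.predict(planted_matrix.X)
        )

    def test_incompatible_version_refused(self, planted_matrix, tmp_path):
        import joblib

        model = train_svm(planted_matrix, C=1.0, gamma=1.0)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        payload = joblib.load(path)
        payload["format_version"] = 999
        joblib.dump(payload, path)
        with pytest.raises(ModelFormatError):
            load_model(path)


class TestCrossValidate:
    def test_separable_data_reaches_perfect_oa(self, planted_matrix, planted_config):
        C, gamma = grid_search_svm(planted_matrix, planted_config)
        report = cross_validate(planted_matrix, planted_config.with_params(C, gamma))
        assert report.oa >= 0.98

    def test_count_conservation(self, planted_matrix, planted_config):
        report = cross_validate(planted_matrix, planted_config.with_params(8.0, 2.0))
        assert report.n_pos_total == planted_matrix.m_pos
        assert report.n_neg_total == planted_matrix.m_neg

    def test_seed_determinism(self, planted_matrix):
        cfg = SVMConfig(C=8.0, gamma=2.0, folds=5, seed=21)
        assert cross_validate(planted_matrix, cfg) == cross_validate(
            planted_matrix, cfg
        )

    def test_requires_chosen_params(self, planted_matrix, planted_config):
        with pytest.raises(ContractError):
            cross_validate(planted_matrix, planted_config)


class TestGridSearch:
    def test_singleton_grid_returned(self, planted_matrix):
        cfg = SVMConfig(c_grid=(4.0,), gamma_grid=(0.25,), folds=5, seed=0)
        assert grid_search_svm(planted_matrix, cfg) == (4.0, 0.25)

    def test_tie_broken_toward_smaller_c_then_gamma(self, planted_matrix):
        # strong signal: many grid points reach identical (perfect) OA
        cfg = SVMConfig(c_grid=(2.0, 8.0, 32.0), gamma_grid=(1.0, 4.0),
                        folds=5, seed=0)
        C, gamma = grid_search_svm(planted_matrix, cfg)
        best_oa = cross_validate(
            planted_matrix, cfg.with_params(C, gamma)
        ).oa
        for C2 in cfg.c_grid:
            for g2 in cfg.gamma_grid:
                oa = cross_validate(planted_matrix, cfg.with_params(C2, g2)).oa
                if oa > best_oa:
                    pytest.fail("grid search missed a better point")
                if oa == best_oa:
                    assert (C, gamma) <= (C2, g2)


@pytest.fixture(scope="module")
def small_matrix():
    from ggapdc.synth import SynthSpec, generate_dataset

    spec = SynthSpec(n_pos=8, n_neg=12, length_range=(80, 150),
                     g_star=6, effect=0.05, seed=5)
    records, labels, _ = generate_dataset(spec)
    return ggapdc.build_feature_matrix(records, labels, 6)


class TestJackknife:
    def test_runs_are_identical_and_seed_independent(self, small_matrix):
        a = jackknife(small_matrix, SVMConfig(C=8.0, gamma=2.0, seed=1))
        b = jackknife(small_matrix, SVMConfig(C=8.0, gamma=2.0, seed=999))
        assert a == b

    def test_every_sample_predicted_once(self, small_matrix):
        report = jackknife(small_matrix, SVMConfig(C=8.0, gamma=2.0))
        assert report.n_pos_total + report.n_neg_total == small_matrix.n_samples

    def test_separable_data_perfect(self, small_matrix):
        cfg = SVMConfig(folds=4, seed=0)
        C, gamma = grid_search_svm(small_matrix, cfg)
        report = jackknife(small_matrix, cfg.with_params(C, gamma))
        assert report.oa == 1.0
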