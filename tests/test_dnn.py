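"""Resistance regressor: splitting, normalization, training, k-fold CV,
prediction and persistence."""

import numpy as np
import pandas as pd
import pytest

from glottiflow.dnn import (
    DNNConfig,
    Normalizer,
    TargetScale,
    TrainedModel,
    evaluate_mae,
    kfold_cross_validate,
    load_model,
    predict_fr,
    save_model,
    split_data,
    train_final,
)
from glottiflow.geometry import FEATURE_COLUMNS


def records_from_arrays(X, y, shape_id=None):
    df = pd.DataFrame(X, columns=list(FEATURE_COLUMNS))
    df["fr_target"] = y
    if shape_id is not None:
        df["shape_id"] = shape_id
    return df


@pytest.fixture
def linear_records():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(400, 8))
    beta = rng.normal(size=8)
    y = X @ beta + 0.7
    return records_from_arrays(X, y)


class TestSplit:
    def test_row_level_sizes(self):
        rng = np.random.default_rng(0)
        rec = records_from_arrays(rng.normal(size=(8192, 8)), rng.normal(size=8192))
        train, test = split_data(rec, 0.2, seed=1)
        assert len(test) == pytest.approx(1638, abs=1)
        assert len(train) + len(test) == 8192

    def test_zero_fraction_keeps_all_for_training(self, linear_records):
        train, test = split_data(linear_records, 0.0, seed=1)
        assert len(train) == len(linear_records) and len(test) == 0

    def test_reproducible_under_seed(self, linear_records):
        a = split_data(linear_records, 0.25, seed=9)
        b = split_data(linear_records, 0.25, seed=9)
        assert a[0].index.equals(b[0].index)

    def test_shapes_do_not_straddle_the_split(self):
        rng = np.random.default_rng(0)
        shape_id = np.repeat(np.arange(20), 16)
        rec = records_from_arrays(
            rng.normal(size=(320, 8)), rng.normal(size=320), shape_id
        )
        train, test = split_data(rec, 0.2, seed=3)
        assert set(train["shape_id"]).isdisjoint(set(test["shape_id"]))
        assert len(test) % 16 == 0


class TestNormalizer:
    def test_round_trip(self):
        rng = np.random.default_rng(1)
        X = rng.normal(3.0, 2.0, size=(50, 8))
        norm = Normalizer.fit(X)
        assert np.allclose(norm.inverse(norm.transform(X)), X)
        Z = norm.transform(X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_constant_feature_rejected(self):
        X = np.ones((20, 3))
        X[:, 0] = np.arange(20)
        with pytest.raises(ValueError, match="constant"):
            Normalizer.fit(X)


class TestTraining:
    def test_constant_target_is_fit(self):
        rng = np.random.default_rng(2)
        rec = records_from_arrays(rng.normal(size=(50, 8)), np.full(50, 3.7))
        cfg = DNNConfig(hidden_layers=(16,), epochs=800, seed=0, dropout_rate=0.0)
        model = train_final(rec, cfg)
        pred = model.predict(rec[list(FEATURE_COLUMNS)].to_numpy())
        assert np.max(np.abs(pred - 3.7)) < 1e-2

    def test_same_seed_reproduces_weights(self, linear_records):
        cfg = DNNConfig(hidden_layers=(8,), epochs=50, seed=5)
        m1 = train_final(linear_records, cfg)
        m2 = train_final(linear_records, cfg)
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)

    def test_default_architecture_memorizes_smooth_targets(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 8))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2
        rec = records_from_arrays(X, y)
        cfg = DNNConfig(epochs=1500, seed=0, dropout_rate=0.0, batch_size=100)
        model = train_final(rec, cfg)
        mae, _ = evaluate_mae(model, rec)
        assert mae < 1e-2


class TestCrossValidation:
    def test_fold_rotation_shapes_and_history_length(self, linear_records):
        cfg = DNNConfig(hidden_layers=(8,), epochs=30, seed=0, k_folds=5)
        report = kfold_cross_validate(linear_records, cfg)
        assert report.fold_train_mae.shape == (5, 30)
        assert report.fold_val_mae.shape == (5, 30)
        assert report.mean_final_val_mae >= 0

    def test_linear_network_matches_least_squares_oracle(self, linear_records):
        # a no-hidden-layer network on linear data must reach the OLS fit
        X = linear_records[list(FEATURE_COLUMNS)].to_numpy()
        y = linear_records["fr_target"].to_numpy()
        coef, *_ = np.linalg.lstsq(np.column_stack([X, np.ones(len(X))]), y, rcond=None)
        ols_mae = np.mean(np.abs(np.column_stack([X, np.ones(len(X))]) @ coef - y))
        cfg = DNNConfig(
            hidden_layers=(),
            epochs=3000,
            seed=0,
            dropout_rate=0.0,
            batch_size=400,
            l2_lambda=0.0,
            learning_rate=1e-2,
            final_learning_rate=1e-4,
        )
        report = kfold_cross_validate(linear_records, cfg)
        assert report.mean_final_val_mae < max(1e-3, 10 * ols_mae)


class TestPrediction:
    def _zero_model(self, bias=1.5):
        weights = [np.zeros((8, 4)), np.zeros((4, 1))]
        biases = [np.zeros(4), np.full(1, bias)]
        norm = Normalizer(mean=np.zeros(8), std=np.ones(8))
        return TrainedModel(
            weights=weights,
            biases=biases,
            normalizer=norm,
            config=DNNConfig(hidden_layers=(4,)),
        )

    def test_zero_weights_output_output_bias(self):
        model = self._zero_model(bias=1.5)
        X = np.random.default_rng(0).normal(size=(6, 8))
        assert np.allclose(predict_fr(model, X), 1.5)

    def test_duplicated_rows_give_duplicated_outputs(self, linear_records):
        cfg = DNNConfig(hidden_layers=(8,), epochs=30, seed=0)
        model = train_final(linear_records, cfg)
        X = linear_records[list(FEATURE_COLUMNS)].to_numpy()[:4]
        out = predict_fr(model, np.vstack([X, X]))
        assert np.array_equal(out[:4], out[4:])

    def test_wrong_column_count_rejected(self):
        model = self._zero_model()
        with pytest.raises(ValueError):
            predict_fr(model, np.zeros((3, 5)))

    def test_inference_is_deterministic_despite_dropout_config(self, linear_records):
        cfg = DNNConfig(hidden_layers=(16,), epochs=30, seed=0, dropout_rate=0.5)
        model = train_final(linear_records, cfg)
        X = linear_records[list(FEATURE_COLUMNS)].to_numpy()
        assert np.array_equal(model.predict(X), model.predict(X))


class TestEvaluation:
    def test_perfect_and_offset_predictions(self):
        model = TestPrediction()._zero_model(bias=2.0)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 8))
        rec = records_from_arrays(X, np.full(30, 2.0))
        mae, rel = evaluate_mae(model, rec)
        assert mae == pytest.approx(0.0)
        rec_off = records_from_arrays(X, np.full(30, 1.9))
        mae, rel = evaluate_mae(model, rec_off)
        assert mae == pytest.approx(0.1)
        assert rel == pytest.approx(0.1 / 1.9)

    def test_zero_mean_target_flags_relative(self):
        model = TestPrediction()._zero_model(bias=0.0)
        X = np.random.default_rng(0).normal(size=(10, 8))
        rec = records_from_arrays(X, np.concatenate([np.ones(5), -np.ones(5)]))
        mae, rel = evaluate_mae(model, rec)
        assert np.isnan(rel)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, linear_records):
        cfg = DNNConfig(hidden_layers=(8, 4), epochs=40, seed=0)
        model = train_final(linear_records, cfg)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        X = linear_records[list(FEATURE_COLUMNS)].to_numpy()
        assert np.array_equal(model.predict(X), back.predict(X))
        assert back.config == model.config
        assert back.target_scale.std == model.target_scale.std
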