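import numpy as np
import pytest

import seatherm as st
from seatherm.ann import (
    ANNModel,
    LMConfig,
    MinMaxScaler,
    ScalingError,
    build_features,
    split_data,
    train_lm,
)
from seatherm.traces import ParameterError


def _identity_model(n_features=1, n_hidden=1):
    """Network whose scalers are the identity on [-1, 1]."""
    scaler = MinMaxScaler(lo=np.full(n_features, -1.0), hi=np.full(n_features, 1.0))
    target = MinMaxScaler(lo=np.array([-1.0]), hi=np.array([1.0]))
    return ANNModel(w_in=np.zeros((n_hidden, n_features)),
                    b_hidden=np.zeros(n_hidden), w_out=np.zeros(n_hidden),
                    b_out=0.0, input_scaling=scaler, target_scaling=target)


class TestFeatures:
    def test_feature_matrix_shape_and_covariates(self, condition):
        trial = st.generate_trial(condition, master_seed=0)
        filtered, _ = st.denoise(trial.nctm_raw)
        x = build_features(filtered, condition)
        assert x.shape == (3600, 3)
        assert np.all(x[:, 1] == condition.thickness)
        assert np.all(x[:, 2] == condition.density)

    def test_minmax_scaling_endpoints(self):
        scaler = MinMaxScaler.fit(np.array([[26.0], [33.0]]))
        out = scaler.transform(np.array([[26.0], [33.0]]))
        np.testing.assert_allclose(out.ravel(), [-1.0, 1.0])

    def test_constant_feature_maps_to_zero(self):
        scaler = MinMaxScaler.fit(np.array([[5.0], [5.0]]))
        assert scaler.transform(np.array([[5.0]]))[0, 0] == 0.0

    def test_wrong_channel_rejected(self, condition):
        dctm = st.generate_dctm(condition, seed=0)
        with pytest.raises(ParameterError):
            build_features(dctm, condition)


class TestSplitData:
    def test_exact_fractions_at_3600(self):
        split = split_data(3600, seed=0)
        assert (len(split.train_idx), len(split.val_idx), len(split.test_idx)) \
            == (2520, 540, 540)

    def test_partition_is_disjoint_and_complete(self):
        split = split_data(101, seed=3)
        all_idx = np.concatenate([split.train_idx, split.val_idx, split.test_idx])
        assert len(np.unique(all_idx)) == 101

    def test_seeded_reproducibility(self):
        a, b = split_data(100, seed=5), split_data(100, seed=5)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.array_equal(a.test_idx, b.test_idx)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            split_data(10)

    def test_block_split_is_contiguous_and_complete(self):
        split = split_data(200, seed=1, method="blocks")
        for idx in (split.train_idx, split.val_idx, split.test_idx):
            assert np.array_equal(idx, np.arange(idx[0], idx[-1] + 1))
        all_idx = np.concatenate([split.train_idx, split.val_idx,
                                  split.test_idx])
        assert len(np.unique(all_idx)) == 200
        assert len(split.train_idx) == 140


class TestForward:
    def test_zero_network_outputs_target_midpoint(self):
        model = _identity_model()
        model.target_scaling = MinMaxScaler(lo=np.array([20.0]), hi=np.array([40.0]))
        assert st.forward(model, np.array([0.3])) == pytest.approx(30.0)

    def test_hand_tanh_evaluation(self):
        model = _identity_model(n_features=3)
        model.w_in = np.array([[1.0, 0.0, 0.0]])
        model.w_out = np.array([1.0])
        y = st.forward(model, np.array([0.5, 0.0, 0.0]))
        assert y == pytest.approx(np.tanh(0.5), abs=1e-12)
        assert y == pytest.approx(0.4621, abs=1e-4)

    def test_zero_output_weights_give_constant(self):
        model = _identity_model(n_features=2, n_hidden=4)
        model.w_in = np.ones((4, 2))
        model.b_out = 0.25
        xs = np.random.default_rng(0).uniform(-1, 1, size=(10, 2))
        out = st.forward(model, xs)
        np.testing.assert_allclose(out, 0.25)

    def test_pure_function_bit_exact(self):
        rng = np.random.default_rng(4)
        model = _identity_model(n_features=2, n_hidden=3)
        model.w_in = rng.standard_normal((3, 2))
        model.w_out = rng.standard_normal(3)
        x = rng.standard_normal((50, 2))
        assert np.array_equal(st.forward(model, x), st.forward(model, x))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            st.forward(_identity_model(n_features=3), np.array([1.0]))


class TestTrainLM:
    def test_recovers_linear_map(self, rng):
        x = rng.uniform(25, 35, size=(400, 1))
        y = 1.8 * x[:, 0] - 12.0
        split = split_data(400, seed=1)
        cfg = LMConfig(max_epochs=200)
        model, history = train_lm(x, y, split, n_hidden=3, lm_config=cfg, seed=2)
        pred = st.forward(model, x)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 0.01

    def test_seeded_training_is_bit_reproducible(self, rng):
        x = rng.uniform(0, 1, size=(200, 2))
        y = x[:, 0] + 0.2 * rng.standard_normal(200)
        split = split_data(200, seed=0)
        cfg = LMConfig(max_epochs=30)
        m1, _ = train_lm(x, y, split, n_hidden=4, lm_config=cfg, seed=7)
        m2, _ = train_lm(x, y, split, n_hidden=4, lm_config=cfg, seed=7)
        assert np.array_equal(m1.w_in, m2.w_in)
        assert np.array_equal(m1.w_out, m2.w_out)

    def test_pure_noise_triggers_validation_stop(self, rng):
        x = rng.standard_normal((600, 1))
        y = rng.standard_normal(600)
        split = split_data(600, seed=2)
        cfg = LMConfig(max_epochs=500)
        _, history = train_lm(x, y, split, n_hidden=8, lm_config=cfg, seed=3)
        assert history.stop_reason in ("validation patience", "lambda overflow",
                                       "gradient tolerance")
        assert history.epochs < 500

    def test_accepted_training_loss_non_increasing(self, rng):
        x = rng.uniform(0, 1, size=(300, 2))
        y = np.sin(3 * x[:, 0]) + x[:, 1]
        split = split_data(300, seed=4)
        _, history = train_lm(x, y, split, n_hidden=5,
                              lm_config=LMConfig(max_epochs=100), seed=5)
        mses = history.train_mse
        assert all(b <= a + 1e-15 for a, b in zip(mses, mses[1:]))

    def test_constant_target_rejected(self, rng):
        x = rng.uniform(0, 1, size=(100, 1))
        with pytest.raises(ScalingError):
            train_lm(x, np.full(100, 5.0), split_data(100, seed=0))


class TestModelResults:
    def test_fit_and_estimate_trial(self, condition):
        trial = st.generate_trial(condition, master_seed=2, n_samples=600)
        filtered, _ = st.denoise(trial.nctm_raw)
        model = st.TemperatureANN.from_trials([filtered], [trial.dctm],
                                              n_hidden=4)
        res = model.fit(split_seed=0, init_seed=0,
                        lm_config=LMConfig(max_epochs=60))
        est = res.estimate_trial(filtered, condition)
        assert est.channel == "estimate"
        assert len(est) == len(filtered)
        # a fitted model should track the warming curve far better than
        # the raw attenuated reading does
        assert st.rmse(trial.dctm.values, est.values) \
            < 0.2 * st.rmse(trial.dctm.values, filtered.values)

    def test_summary_reports_three_splits(self, condition):
        trial = st.generate_trial(condition, master_seed=2, n_samples=400)
        filtered, _ = st.denoise(trial.nctm_raw)
        res = st.TemperatureANN.from_trials([filtered], [trial.dctm],
                                            n_hidden=3).fit(
            lm_config=LMConfig(max_epochs=40))
        df = res.summary()
        assert list(df["set"]) == ["train", "val", "test"]
        assert (df["rmse_C"] >= df["mae_C"]).all()
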