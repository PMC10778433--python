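import math

import numpy as np
import pytest

import sweetdry as sd
from sweetdry.mlp import forward, r_squared, sos_error

from conftest import toy_results


class TestForward:
    def test_zero_weights_give_half(self):
        y = forward(np.zeros(7), np.zeros((9, 7)), np.zeros(9),
                    np.zeros((22, 9)), np.zeros(22))
        assert np.allclose(y, 0.5)

    def test_toy_scalar_network(self):
        # 1-1-1 net, unit weights, zero biases: y = logistic(tanh(x))
        W1 = [[1.0]]; B1 = [0.0]; W2 = [[1.0]]; B2 = [0.0]
        assert forward(np.array([0.0]), *map(np.array, (W1, B1, W2, B2)))[0] \
            == pytest.approx(0.5)
        expected = 1.0 / (1.0 + math.exp(-math.tanh(1.0)))
        assert forward(np.array([1.0]), *map(np.array, (W1, B1, W2, B2)))[0] \
            == pytest.approx(expected, abs=1e-15)

    def test_outputs_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(3)
        W1 = rng.normal(0, 2, (9, 7))
        y = forward(rng.random((20, 7)), W1, rng.normal(0, 2, 9),
                    rng.normal(0, 2, (22, 9)), rng.normal(0, 2, 22))
        assert np.all(y > 0) and np.all(y < 1)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension"):
            forward(np.zeros(5), np.zeros((9, 7)), np.zeros(9),
                    np.zeros((22, 9)), np.zeros(22))


class TestSosError:
    def test_exact_fit_is_zero(self):
        y = np.random.default_rng(0).random((4, 3))
        assert sos_error(y, y) == 0.0

    def test_single_deviation(self):
        assert sos_error(np.array([[0.5]]), np.array([[0.0]])) == 0.25

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(5)
        p, t = rng.random((6, 4)), rng.random((6, 4))
        acc = 0.0
        for i in range(6):
            for j in range(4):
                acc += (p[i, j] - t[i, j]) ** 2
        assert sos_error(p, t) == pytest.approx(acc, rel=1e-14)


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_is_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)

    def test_hand_example(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) \
            == pytest.approx(0.5)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            r_squared([2.0, 2.0], [1.0, 2.0])


class TestTraining:
    def test_same_seed_is_bit_identical(self, study):
        cfg = sd.TrainConfig(restarts=2, explore_maxiter=100, polish_top=1,
                             polish_maxiter=100, seed=42)
        a = sd.DryingMLP(study).fit(cfg)
        b = sd.DryingMLP(study).fit(cfg)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)
        assert a.report.sos == b.report.sos
        assert a.report.r2_train == b.report.r2_train

    def test_sos_non_increasing_along_polish(self, study):
        cfg = sd.TrainConfig(restarts=1, explore_maxiter=50, polish_top=1,
                             polish_maxiter=200, seed=3)
        res = sd.DryingMLP(study).fit(cfg, track_history=True)
        hist = np.array(res.report.sos_history)
        assert len(hist) > 5
        assert np.all(np.diff(hist) <= 1e-9)

    def test_more_restarts_never_worse(self, study):
        kw = dict(explore_maxiter=150, polish_top=8, polish_maxiter=150,
                  seed=5)
        few = sd.DryingMLP(study).fit(sd.TrainConfig(restarts=2, **kw))
        many = sd.DryingMLP(study).fit(sd.TrainConfig(restarts=6, **kw))
        assert many.report.sos <= few.report.sos + 1e-12

    def test_report_r2_bounded(self, quick_fit):
        rep = quick_fit.report
        assert rep.r2_train <= 1.0
        assert (rep.r2_per_output <= 1.0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sd.TrainConfig(restarts=0)
        with pytest.raises(ValueError):
            sd.TrainConfig(split=(0.5, 0.2, 0.2))


class TestPrediction:
    def test_identity_scaler_toy_model_equals_forward(self):
        rng = np.random.default_rng(8)
        W1 = rng.normal(0, 0.5, (9, 7))
        B1, W2, B2 = rng.normal(0, 0.5, 9), rng.normal(0, 0.5, (22, 9)), \
            rng.normal(0, 0.5, 22)
        scaler = sd.Scaler(list(sd.RESPONSES), np.zeros(22), np.ones(22),
                           lo=0.0, hi=1.0)
        res = toy_results(W1, B1, W2, B2, scaler)
        dp = sd.DesignPoint("orange", "osmotic")
        np.testing.assert_allclose(
            res.predict_responses(dp).to_numpy(),
            res.forward(sd.encode_design(dp)))

    def test_missing_scaler_raises(self):
        res = toy_results(np.zeros((9, 7)), np.zeros(9), np.zeros((22, 9)),
                          np.zeros(22))
        with pytest.raises(ValueError, match="scaler"):
            res.predict_responses(sd.DesignPoint("white", "convective"))

    def test_fittedvalues_align_with_dataset(self, quick_fit, study):
        fv = quick_fit.fittedvalues
        assert fv.shape == (12, 22)
        assert list(fv.index) == list(study.ids)
        # even a cheap fit tracks the data broadly
        assert quick_fit.report.r2_train > 0.9


class TestSerialization:
    def test_json_round_trip_exact(self, quick_fit, tmp_path):
        path = tmp_path / "model.json"
        quick_fit.to_json(path)
        back = sd.MLPResults.from_json(path)
        assert np.array_equal(back.W1, quick_fit.W1)
        assert np.array_equal(back.B2, quick_fit.B2)
        dp = sd.DesignPoint("purple", "lyophilization")
        np.testing.assert_array_equal(
            back.predict_responses(dp).to_numpy(),
            quick_fit.predict_responses(dp).to_numpy())

    def test_inconsistent_shapes_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            sd.MLPResults(None, np.zeros((9, 7)), np.zeros(8),
                          np.zeros((22, 9)), np.zeros(22), None)
        with pytest.raises(ValueError, match="finite"):
            sd.MLPResults(None, np.full((9, 7), np.nan), np.zeros(9),
                          np.zeros((22, 9)), np.zeros(22), None)
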