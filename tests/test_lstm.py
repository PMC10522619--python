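"""LSTM cell algebra, normalization, windowing and component training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from habforecast.lstm_forecaster import (
    ForecastConfig,
    LayerParams,
    _forward,
    denormalize,
    fit_normalization,
    forecast_component,
    init_parameters,
    lstm_cell_step,
    make_supervised,
    minmax_normalize,
    train_component_forecaster,
)
from reference_impls import ref_lstm_cell


def _sigma(v):
    return 1.0 / (1.0 + np.exp(-v))


class TestCellStep:
    def test_zero_weights_zero_state_gives_zero_output(self):
        H, I = 4, 2
        p = LayerParams(W=np.zeros((4 * H, H + I)), b=np.zeros(4 * H))
        h, c = lstm_cell_step(np.ones(I), np.zeros(H), np.zeros(H), p)
        np.testing.assert_array_equal(h, 0.0)
        np.testing.assert_array_equal(c, 0.0)

    def test_scalar_hand_evaluation_with_saturated_gates(self):
        # W = 0, b_f = +10, b_i = -10, b_o = +10, c_prev = 0.7:
        # the forget gate holds the cell, the input gate blocks the candidate
        H, I = 1, 1
        b = np.array([10.0, -10.0, 0.0, 10.0])
        p = LayerParams(W=np.zeros((4, 2)), b=b)
        h, c = lstm_cell_step(np.array([0.3]), np.array([0.0]), np.array([0.7]), p)
        c_expected = _sigma(10) * 0.7 + _sigma(-10) * np.tanh(0.0)
        h_expected = _sigma(10) * np.tanh(c_expected)
        assert c[0] == pytest.approx(c_expected, abs=1e-12)
        assert h[0] == pytest.approx(h_expected, abs=1e-12)

    @pytest.mark.parametrize("tied", [False, True])
    def test_matches_literal_transcription(self, tied):
        rng = np.random.default_rng(7)
        p = init_parameters(3, (5,), rng, tied_candidate=tied).layers[0]
        x = rng.standard_normal(3)
        h0 = 0.2 * rng.standard_normal(5)
        c0 = 0.2 * rng.standard_normal(5)
        h, c = lstm_cell_step(x, h0, c0, p)
        hr, cr = ref_lstm_cell(
            x, h0, c0, p.W_f, p.W_i, p.W_c, p.W_o, p.b_f, p.b_i, p.b_c, p.b_o, tied
        )
        np.testing.assert_allclose(h, hr, atol=1e-10)
        np.testing.assert_allclose(c, cr, atol=1e-10)

    def test_shape_mismatch_is_error(self):
        p = init_parameters(2, (3,), np.random.default_rng(0)).layers[0]
        with pytest.raises(ValueError, match="shape mismatch"):
            lstm_cell_step(np.ones(5), np.zeros(3), np.zeros(3), p)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_gate_and_state_bounds(self, seed):
        rng = np.random.default_rng(seed)
        p = init_parameters(2, (4,), rng).layers[0]
        h, c = np.zeros(4), rng.standard_normal(4)
        for _ in range(5):
            x = 3 * rng.standard_normal(2)
            h_new, c_new = lstm_cell_step(x, h, c, p)
            assert np.all(np.abs(h_new) < 1.0)
            # cell state can grow by at most the candidate magnitude (<1)
            assert np.all(np.abs(c_new) <= np.abs(c) + 1.0 + 1e-12)
            h, c = h_new, c_new

    def test_whole_network_forward_matches_chained_cell_steps(self):
        rng = np.random.default_rng(3)
        params = init_parameters(1, (4, 3), rng)
        X = rng.standard_normal((2, 6))
        out = _forward(params, X)
        # chain lstm_cell_step manually through time and layers
        states = [(np.zeros((2, 4)), np.zeros((2, 4))), (np.zeros((2, 3)), np.zeros((2, 3)))]
        for t in range(6):
            inp = X[:, t : t + 1]
            for li, layer in enumerate(params.layers):
                h, c = lstm_cell_step(inp, states[li][0], states[li][1], layer)
                states[li] = (h, c)
                inp = h
        expected = (states[-1][0] @ params.W_out.T + params.b_out).ravel()
        np.testing.assert_allclose(out, expected, atol=1e-12)


class TestNormalization:
    def test_maps_train_range_to_unit_interval(self):
        params = fit_normalization(np.array([0.0, 5.0, 10.0]))
        np.testing.assert_allclose(
            minmax_normalize(np.array([0.0, 5.0, 10.0]), params), [0.0, 0.5, 1.0]
        )

    def test_round_trip_is_identity(self):
        v = np.random.default_rng(0).standard_normal(100) * 7 + 3
        params = fit_normalization(v)
        np.testing.assert_allclose(denormalize(minmax_normalize(v, params), params), v, atol=1e-12)

    def test_values_outside_train_range_are_not_clipped(self):
        params = fit_normalization(np.array([0.0, 10.0]))
        out = minmax_normalize(np.array([-5.0, 15.0]), params)
        assert out[0] < 0 and out[1] > 1

    def test_degenerate_component_passes_through_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            params = fit_normalization(np.full(10, 3.0))
        v = np.array([1.0, 2.0])
        np.testing.assert_array_equal(minmax_normalize(v, params), v)


class TestMakeSupervised:
    def test_window_count_formula(self):
        x = np.arange(10.0)
        windows, targets = make_supervised(x, 3, 1)
        assert windows.shape == (7, 3)
        assert targets.shape == (7,)

    def test_boundary_single_pair(self):
        x = np.arange(7.0)
        windows, targets = make_supervised(x, 4, 3)
        assert windows.shape == (1, 4)
        assert targets[0] == x[-1]

    def test_windows_tile_the_series(self):
        x = np.random.default_rng(1).standard_normal(30)
        windows, targets = make_supervised(x, 5, 2)
        for k in range(len(windows)):
            np.testing.assert_array_equal(windows[k], x[k : k + 5])
            assert targets[k] == x[k + 5 + 2 - 1]

    def test_too_short_series_is_error(self):
        with pytest.raises(ValueError, match="too short"):
            make_supervised(np.arange(5.0), 4, 2)


class TestTraining:
    CFG = ForecastConfig(lookback=8, horizon=3, hidden_sizes=(8,), epochs=12,
                         batch_size=16, seed=0)

    def test_constant_component_is_forecast_exactly(self):
        # a constant has no variation to learn: normalization is degenerate
        # and the trivial constant forecaster reproduces it with zero loss
        from habforecast.lstm_forecaster import ConstantForecaster

        x = np.full(80, 0.5)
        with pytest.warns(UserWarning, match="degenerate"):
            params = fit_normalization(x)
        assert params.degenerate
        model = ConstantForecaster()
        np.testing.assert_array_equal(forecast_component(model, x, 3), 0.5)
        assert model.loss_trace[-1] == 0.0

    def test_training_reduces_loss(self):
        rng = np.random.default_rng(2)
        x = np.sin(np.arange(300) / 5.0) + 0.05 * rng.standard_normal(300)
        params = fit_normalization(x)
        model = train_component_forecaster(minmax_normalize(x, params), self.CFG)
        assert model.loss_trace[-1] < model.loss_trace[0]

    def test_same_seed_gives_identical_loss_trace(self):
        x = np.sin(np.arange(200) / 7.0)
        m1 = train_component_forecaster(x, self.CFG)
        m2 = train_component_forecaster(x, self.CFG)
        assert m1.loss_trace == m2.loss_trace
        for a, b in zip(m1.params.arrays(), m2.params.arrays()):
            np.testing.assert_array_equal(a, b)

    def test_sine_one_step_in_sample_error_is_small(self):
        x = np.sin(2 * np.pi * np.arange(400) / 24.0)
        norm = fit_normalization(x)
        cfg = ForecastConfig(lookback=24, horizon=1, hidden_sizes=(16,), epochs=30,
                             batch_size=32, seed=1)
        model = train_component_forecaster(minmax_normalize(x, norm), cfg)
        windows, targets = make_supervised(minmax_normalize(x, norm), 24, 1)
        preds = np.array([model.predict_one(w) for w in windows[::5]])
        meas = denormalize(targets[::5], norm)
        pf = denormalize(preds, norm)
        keep = np.abs(meas) > 0.3  # percentage error blows up near zero
        mape = np.mean(np.abs((meas[keep] - pf[keep]) / meas[keep]))
        assert mape < 0.05

    def test_multi_step_forecast_is_chained_one_step(self):
        x = np.sin(np.arange(100) / 9.0)
        model = train_component_forecaster(x, self.CFG)
        fc = forecast_component(model, x, 3)
        buf = list(x[-8:])
        for step in range(3):
            y = model.predict_one(np.asarray(buf))
            assert fc[step] == pytest.approx(y, abs=1e-12)
            buf = buf[1:] + [y]

    def test_short_history_is_error(self):
        x = np.sin(np.arange(60) / 5.0)
        model = train_component_forecaster(x, self.CFG)
        with pytest.raises(ValueError, match="shorter than lookback"):
            model.forecast(x[:4], 2)

    def test_noiseless_sine_multistep_error_bound(self):
        x = np.sin(2 * np.pi * np.arange(500) / 24.0)
        norm = fit_normalization(x)
        cfg = ForecastConfig(lookback=24, horizon=6, hidden_sizes=(16,), epochs=40,
                             batch_size=32, seed=5)
        model = train_component_forecaster(minmax_normalize(x, norm), cfg)
        fc = denormalize(model.forecast(minmax_normalize(x, norm), 6), norm)
        truth = np.sin(2 * np.pi * (np.arange(500, 506)) / 24.0)
        assert np.mean(np.abs(fc - truth)) < 0.1  # < 0.1 x unit amplitude
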