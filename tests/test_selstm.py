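"""SE block and LSTM cell oracles, forward-pass contracts, training protocol."""

import math

import numpy as np
import pytest

from leafspec.selstm import (
    EvalReport,
    LSTMCellParams,
    SEBlockParams,
    SELSTMConfig,
    SELSTMModel,
    SplitSpec,
    _forward,
    _init_params,
    evaluate,
    grid_search_architecture,
    lstm_cell_step,
    se_block_forward,
    selstm_forward,
    stratified_split,
    sweep_optimizer_lr,
    train_selstm,
)


def scalar_lstm_oracle(p, x, h, c):
    """Independent scalar implementation of the six gate equations."""
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    f = sig(p["wfx"] * x + p["wfh"] * h + p["bf"])
    i = sig(p["wix"] * x + p["wih"] * h + p["bi"])
    o = sig(p["wox"] * x + p["woh"] * h + p["bo"])
    g = math.tanh(p["wgx"] * x + p["wgh"] * h + p["bg"])
    c_t = f * c + i * g
    h_t = o * math.tanh(c_t)
    return h_t, c_t


def scalar_cell(p) -> LSTMCellParams:
    a = lambda v: np.array([[v]])
    b = lambda v: np.array([v])
    return LSTMCellParams(
        W_fx=a(p["wfx"]), W_ix=a(p["wix"]), W_ox=a(p["wox"]), W_gx=a(p["wgx"]),
        W_fh=a(p["wfh"]), W_ih=a(p["wih"]), W_oh=a(p["woh"]), W_gh=a(p["wgh"]),
        b_f=b(p["bf"]), b_i=b(p["bi"]), b_o=b(p["bo"]), b_g=b(p["bg"]),
    )


class TestLSTMCell:
    def test_all_zero_parameters_closed_form(self):
        p = {k: 0.0 for k in ("wfx wix wox wgx wfh wih woh wgh bf bi bo bg".split())}
        h, c = lstm_cell_step(scalar_cell(p), np.array([3.7]), np.array([0.0]), np.array([0.0]))
        # gates at sigmoid(0)=0.5, candidate tanh(0)=0 -> state stays zero
        assert h[0] == 0.0 and c[0] == 0.0

    def test_unit_weights_worked_example_to_five_decimals(self):
        p = {k: 1.0 for k in ("wfx wix wox wgx wfh wih woh wgh".split())}
        p.update(bf=0.0, bi=0.0, bo=0.0, bg=0.0)
        h, c = lstm_cell_step(scalar_cell(p), np.array([1.0]), np.array([0.0]), np.array([0.0]))
        assert c[0] == pytest.approx(0.55677, abs=5e-6)
        assert h[0] == pytest.approx(0.36961, abs=5e-6)

    def test_saturated_forget_gate_drops_previous_state(self):
        rng = np.random.default_rng(0)
        p = {k: float(rng.normal()) for k in ("wfx wix wox wgx wfh wih woh wgh bi bo bg".split())}
        p["bf"] = -1000.0
        x, h0, c0 = 0.3, 0.2, 5.0
        h, c = lstm_cell_step(scalar_cell(p), np.array([x]), np.array([h0]), np.array([c0]))
        sig = lambda v: 1.0 / (1.0 + math.exp(-v))
        i = sig(p["wix"] * x + p["wih"] * h0 + p["bi"])
        g = math.tanh(p["wgx"] * x + p["wgh"] * h0 + p["bg"])
        assert abs(c[0] - i * g) < 1e-12

    def test_agrees_with_scalar_oracle_over_random_draws(self):
        rng = np.random.default_rng(42)
        keys = "wfx wix wox wgx wfh wih woh wgh bf bi bo bg".split()
        for _ in range(100):
            p = {k: float(rng.normal(scale=1.5)) for k in keys}
            x, h0, c0 = rng.normal(size=3)
            h, c = lstm_cell_step(scalar_cell(p), np.array([x]), np.array([h0]), np.array([c0]))
            h_ref, c_ref = scalar_lstm_oracle(p, x, h0, c0)
            assert abs(h[0] - h_ref) < 1e-9
            assert abs(c[0] - c_ref) < 1e-9

    def test_non_finite_input_rejected(self):
        p = {k: 0.0 for k in ("wfx wix wox wgx wfh wih woh wgh bf bi bo bg".split())}
        with pytest.raises(ValueError, match="non-finite"):
            lstm_cell_step(scalar_cell(p), np.array([np.nan]), np.array([0.0]), np.array([0.0]))


class TestSEBlock:
    def test_zero_weights_halve_the_input(self):
        params = SEBlockParams(
            reduce_weights=np.zeros((4, 2)), reduce_bias=np.zeros(2),
            expand_weights=np.zeros((2, 4)), expand_bias=np.zeros(4), reduction_ratio=2,
        )
        x = np.array([1.0, -2.0, 0.5, 3.0])
        assert np.allclose(se_block_forward(params, x), 0.5 * x, atol=1e-15)

    def test_zero_input_maps_to_zero(self):
        rng = np.random.default_rng(0)
        params = SEBlockParams(
            reduce_weights=rng.normal(size=(4, 2)), reduce_bias=rng.normal(size=2),
            expand_weights=rng.normal(size=(2, 4)), expand_bias=rng.normal(size=4),
            reduction_ratio=2,
        )
        assert np.array_equal(se_block_forward(params, np.zeros(4)), np.zeros(4))

    def test_two_channel_hand_composition(self):
        # C=2, r=1: hand-evaluate sigmoid(W2 relu(W1 x + b1) + b2) * x
        W1 = np.array([[0.5], [-1.0]])
        b1 = np.array([0.1])
        W2 = np.array([[2.0, -0.5]])
        b2 = np.array([0.0, 0.3])
        params = SEBlockParams(W1, b1, W2, b2, reduction_ratio=2)
        x = np.array([0.8, 0.4])
        hidden = max(0.8 * 0.5 + 0.4 * (-1.0) + 0.1, 0.0)  # = 0.1
        s0 = 1 / (1 + math.exp(-(2.0 * hidden + 0.0)))
        s1 = 1 / (1 + math.exp(-(-0.5 * hidden + 0.3)))
        out = se_block_forward(params, x)
        assert abs(out[0] - s0 * 0.8) < 1e-9
        assert abs(out[1] - s1 * 0.4) < 1e-9

    def test_channel_mismatch_rejected(self):
        params = SEBlockParams(
            np.zeros((4, 2)), np.zeros(2), np.zeros((2, 4)), np.zeros(4), 2
        )
        with pytest.raises(ValueError, match="channels"):
            se_block_forward(params, np.zeros(5))

    def test_incompatible_ratio_rejected(self):
        with pytest.raises(ValueError, match="ratio"):
            SEBlockParams(np.zeros((4, 3)), np.zeros(3), np.zeros((3, 4)), np.zeros(4), 3)


def tiny_model(**kw) -> SELSTMModel:
    cfg = SELSTMConfig(
        n_bands=kw.pop("n_bands", 6), n_layers=kw.pop("n_layers", 1),
        units=kw.pop("units", 4), reduction_ratio=kw.pop("reduction_ratio", 2),
        seed=kw.pop("seed", 0), **kw,
    )
    return SELSTMModel(cfg, _init_params(cfg, np.random.default_rng(cfg.seed)))


class TestForward:
    def test_probability_rows_sum_to_one(self):
        model = tiny_model()
        X = np.random.default_rng(1).random((7, 6))
        probs = selstm_forward(model, X)
        assert probs.shape == (7, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_fixed_weights_are_bitwise_stable(self):
        model = tiny_model()
        X = np.random.default_rng(2).random((5, 6))
        assert np.array_equal(selstm_forward(model, X), selstm_forward(model, X))

    def test_single_unit_forward_matches_chained_cell_oracle(self):
        # 3 bands, 1 layer, 1 unit, no SE: chain lstm_cell_step by hand
        cfg = SELSTMConfig(n_bands=3, n_layers=1, units=1, use_se=False,
                           reduction_ratio=1, seed=5)
        model = SELSTMModel(cfg, _init_params(cfg, np.random.default_rng(5)))
        x = np.array([0.2, 0.7, 0.4])
        cell = model.cell_params(0)
        h = np.zeros(1)
        c = np.zeros(1)
        for t in range(3):
            h, c = lstm_cell_step(cell, np.array([x[t]]), h, c)
        logits = h @ model.params["head_W"] + model.params["head_b"]
        expected = np.exp(logits - logits.max())
        expected /= expected.sum()
        got = selstm_forward(model, x[None, :])[0]
        assert np.allclose(got, expected, atol=1e-12)

    def test_band_count_mismatch_rejected(self):
        model = tiny_model()
        with pytest.raises(ValueError, match="bands"):
            selstm_forward(model, np.zeros((2, 9)))

    def test_head_relabeling_permutes_probabilities(self):
        model = tiny_model()
        X = np.random.default_rng(3).random((4, 6))
        base = selstm_forward(model, X)
        perm = np.array([2, 0, 1])
        model.params["head_W"] = model.params["head_W"][:, perm]
        model.params["head_b"] = model.params["head_b"][perm]
        assert np.allclose(selstm_forward(model, X), base[:, perm], atol=1e-12)


class _FixedProba:
    """Deterministic pseudo-model: row i correct iff flagged."""

    def __init__(self, correct_flags, n_classes=3):
        self.flags = np.asarray(correct_flags, dtype=bool)
        self.n_classes = n_classes

    def predict_proba(self, X):
        n = X.shape[0]
        out = np.full((n, self.n_classes), 1e-9)
        # true label is always 0; predict 0 where flagged else 1
        out[self.flags[:n], 0] = 1.0
        out[~self.flags[:n], 1] = 1.0
        return out / out.sum(axis=1, keepdims=True)


class TestEvaluate:
    def test_identical_sets_have_zero_overfit(self):
        rng = np.random.default_rng(0)
        X = rng.random((50, 4))
        flags = rng.random(50) < 0.8
        model = _FixedProba(flags)
        y = np.zeros(50, dtype=int)
        rep = evaluate(model, (X, y), (X, y))
        assert rep.overfit_coefficient == 0.0

    def test_overfit_is_calibration_minus_prediction_points(self):
        # 9601/10000 correct vs 9388/10000 correct -> 96.01 - 93.88 = 2.13
        Xc = np.zeros((10_000, 2))
        Xp = np.zeros((10_000, 2))
        y = np.zeros(10_000, dtype=int)
        cal_flags = np.arange(10_000) < 9601
        pred_flags = np.arange(10_000) < 9388
        rep_c = evaluate(_FixedProba(cal_flags), (Xc, y), (Xc, y))
        assert rep_c.accuracy_calibration == pytest.approx(96.01)
        rep = EvalReport(
            accuracy_calibration=evaluate(_FixedProba(cal_flags), (Xc, y), (Xc, y)).accuracy_calibration,
            accuracy_prediction=evaluate(_FixedProba(pred_flags), (Xp, y), (Xp, y)).accuracy_prediction,
            loss_calibration=0.0, loss_prediction=0.0, overfit_coefficient=0.0,
        )
        assert rep.accuracy_calibration - rep.accuracy_prediction == pytest.approx(2.13)

    def test_perfect_classifier_has_tiny_loss(self):
        X = np.zeros((20, 2))
        y = np.zeros(20, dtype=int)
        rep = evaluate(_FixedProba(np.ones(20, dtype=bool)), (X, y), (X, y))
        assert rep.accuracy_calibration == 100.0
        assert rep.loss_calibration <= 1e-6

    def test_label_outside_class_range_rejected(self):
        X = np.zeros((3, 2))
        model = _FixedProba(np.ones(3, dtype=bool))
        with pytest.raises(ValueError, match="label"):
            evaluate(model, (X, np.array([0, 1, 5])), (X, np.array([0, 0, 0])))


@pytest.fixture(scope="module")
def tiny_train_data(small_spectra):
    """32-band separable 3-class data, 120 samples."""
    return small_spectra


class TestTraining:
    def test_separable_spectra_reach_high_accuracy(self, tiny_train_data):
        cfg = SELSTMConfig(n_bands=32, units=16, n_layers=1, reduction_ratio=4,
                           epochs=10, seed=0)
        _, rep, losses = train_selstm(cfg, tiny_train_data)
        assert rep.accuracy_prediction >= 90.0
        assert len(losses) == 10

    def test_zero_learning_rate_leaves_parameters_unchanged(self, tiny_train_data):
        cfg = SELSTMConfig(n_bands=32, units=8, n_layers=1, reduction_ratio=4,
                           epochs=2, learning_rate=0.0, seed=1)
        model, rep, _ = train_selstm(cfg, tiny_train_data)
        fresh = _init_params(cfg, np.random.default_rng(cfg.seed))
        for k, v in fresh.items():
            assert np.array_equal(model.params[k], v)

    def test_same_config_and_seed_reproduce_final_loss(self, tiny_train_data):
        cfg = SELSTMConfig(n_bands=32, units=8, n_layers=1, reduction_ratio=4,
                           epochs=3, seed=2)
        _, _, la = train_selstm(cfg, tiny_train_data)
        _, _, lb = train_selstm(cfg, tiny_train_data)
        assert la == lb

    def test_single_class_calibration_rejected(self):
        X = np.random.default_rng(0).random((20, 8))
        y = np.zeros(20, dtype=int)
        cfg = SELSTMConfig(n_bands=8, units=4, reduction_ratio=2, epochs=1)
        with pytest.raises(ValueError, match="2 classes"):
            train_selstm(cfg, (X, y))

    def test_stratified_split_is_proportional_and_seeded(self):
        y = np.array([0] * 30 + [1] * 30 + [2] * 30)
        cal, pred = stratified_split(y, SplitSpec(calibration_frac=0.7, seed=0))
        assert cal.size == 63 and pred.size == 27
        for cls in (0, 1, 2):
            assert np.sum(y[cal] == cls) == 21
        cal2, _ = stratified_split(y, SplitSpec(calibration_frac=0.7, seed=0))
        assert np.array_equal(cal, cal2)


class TestGridProtocol:
    def test_single_cell_grid_has_one_row(self, tiny_train_data):
        base = SELSTMConfig(n_bands=32, reduction_ratio=4, epochs=2, seed=0)
        df = grid_search_architecture(
            tiny_train_data, layer_grid=(1,), unit_grid=(8,), base_config=base
        )
        assert len(df) == 1

    def test_default_grid_is_three_by_four(self, tiny_train_data):
        base = SELSTMConfig(n_bands=32, reduction_ratio=4, epochs=1, seed=0)
        df = grid_search_architecture(tiny_train_data, base_config=base)
        assert len(df) == 12
        assert set(zip(df.n_layers, df.units)) == {
            (l, u) for l in (1, 2, 3) for u in (16, 32, 64, 128)
        }

    def test_ties_rank_smaller_model_first(self, tiny_train_data):
        # easy data: both cells hit the same accuracy, smaller net must lead
        base = SELSTMConfig(n_bands=32, reduction_ratio=4, epochs=6, seed=0)
        df = grid_search_architecture(
            tiny_train_data, layer_grid=(1,), unit_grid=(8, 16), base_config=base
        )
        ties = df[df.accuracy_prediction == df.accuracy_prediction.max()]
        assert (ties.n_parameters.diff().dropna() >= 0).all()

    def test_optimizer_sweep_is_three_by_five(self, tiny_train_data):
        base = SELSTMConfig(n_bands=32, reduction_ratio=4, epochs=1, seed=0)
        df = sweep_optimizer_lr(tiny_train_data, base_config=base)
        assert len(df) == 15
        assert set(df.optimizer) == {"sgd", "adam", "rmsprop"}
        assert set(df.learning_rate) == {0.001, 0.005, 0.01, 0.05, 0.1}

    def test_empty_grid_rejected(self, tiny_train_data):
        with pytest.raises(ValueError, match="empty"):
            grid_search_architecture(tiny_train_data, layer_grid=(), unit_grid=(8,))
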