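"""Core recurrence: cell equations, BPTT gradients, clipping, Adam.

The gradient tests are the load-bearing ones: every analytic gradient is
checked against central finite differences on a <= 50 parameter network in
double precision, and the single cell against an independently coded
scalar calculator.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synchar.sync_lstm import (AdamState, CellState,
                               TrainingConfig, adam_step, bptt_backward,
                               clip_gradients, init_params, learning_rate_at,
                               loss, lstm_cell_forward, predict_proba,
                               sync_forward, l2_penalty)
from synchar.adversarial import AdversarialConfig, train_adversarial


def small_params(rng, D=2, h=2, M=2, K=2):
    return init_params(D, h, M, K, rng)


def zero_state(h=1, B=None):
    shape = (h,) if B is None else (B, h)
    return CellState(h=np.zeros(shape), c=np.zeros(shape))


class TestCellForward:
    def test_all_zero_params_give_half_gates_and_zero_state(self):
        p = init_params(3, 4, 1, 2, np.random.default_rng(0))
        for k in p.weights:
            p.weights[k][:] = 0.0
        state, gates = lstm_cell_forward(np.zeros(3), zero_state(4), p)
        for g in ("i", "f", "o"):
            assert np.allclose(gates[g], 0.5)
        assert np.allclose(state.c, 0.0) and np.allclose(state.h, 0.0)

    def test_scalar_cell_matches_independent_calculator(self):
        """Independent plain-math scalar peephole cell, h = 1, to 1e-12."""
        def scalar_cell(x, h_prev, c_prev, w):
            sig = lambda z: 1.0 / (1.0 + math.exp(-z))
            i = sig(w["xi"] * x + w["hi"] * h_prev + w["ci"] * c_prev + w["bi"])
            f = sig(w["xf"] * x + w["hf"] * h_prev + w["cf"] * c_prev + w["bf"])
            o = sig(w["xo"] * x + w["ho"] * h_prev + w["co"] * c_prev + w["bo"])
            g = math.tanh(w["xc"] * x + w["hc"] * h_prev + w["bc"])
            c = f * c_prev + i * g
            return o * math.tanh(c), c

        w = {"xi": 0.3, "hi": -0.2, "ci": 0.5, "bi": 0.1,
             "xf": -0.4, "hf": 0.6, "cf": -0.1, "bf": 0.2,
             "xo": 0.7, "ho": 0.1, "co": 0.4, "bo": -0.3,
             "xc": 0.2, "hc": -0.5, "bc": 0.05}
        p = init_params(1, 1, 1, 2, np.random.default_rng(0))
        p.weights.update({
            "Wxi": np.array([[w["xi"]]]), "Whi": np.array([[w["hi"]]]),
            "wci": np.array([w["ci"]]), "bi": np.array([w["bi"]]),
            "Wxf": np.array([[w["xf"]]]), "Whf": np.array([[w["hf"]]]),
            "wcf": np.array([w["cf"]]), "bf": np.array([w["bf"]]),
            "Wxo": np.array([[w["xo"]]]), "Who": np.array([[w["ho"]]]),
            "wco": np.array([w["co"]]), "bo": np.array([w["bo"]]),
            "Wxc": np.array([[w["xc"]]]), "Whc": np.array([[w["hc"]]]),
            "bc": np.array([w["bc"]])})
        h_prev, c_prev = 0.3, -0.6
        state, _ = lstm_cell_forward(
            np.array([0.8]), CellState(h=np.array([h_prev]), c=np.array([c_prev])), p)
        h_ref, c_ref = scalar_cell(0.8, h_prev, c_prev, w)
        assert state.h[0] == pytest.approx(h_ref, abs=1e-12)
        assert state.c[0] == pytest.approx(c_ref, abs=1e-12)

    def test_saturated_forget_gate_preserves_cell(self):
        """b_f = +20 drives f within 1e-6 of 1 (logistic limit), so
        c_t ~ c_prev + i*tanh(.)."""
        rng = np.random.default_rng(1)
        p = init_params(2, 3, 1, 2, rng, scale=0.01)
        p.weights["bf"][:] = 20.0
        c_prev = rng.normal(size=3)
        state, gates = lstm_cell_forward(
            rng.normal(size=2) * 0.01, CellState(h=np.zeros(3), c=c_prev), p)
        assert np.all(np.abs(gates["f"] - 1.0) < 1e-6)
        expected = gates["f"] * c_prev + gates["i"] * gates["g"]
        assert np.allclose(state.c, expected)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_gate_boundedness(self, seed):
        rng = np.random.default_rng(seed)
        p = init_params(3, 4, 1, 2, rng, scale=2.0)
        state = CellState(h=rng.normal(size=4), c=rng.normal(size=4))
        new, gates = lstm_cell_forward(rng.normal(size=3) * 5, state, p)
        for g in ("i", "f", "o"):
            assert np.all((gates[g] > 0) & (gates[g] < 1))
        assert np.all(np.abs(np.tanh(new.c)) < 1)


class TestSyncForward:
    def test_m1_reduces_to_cell_chain(self):
        """M = 1 forward equals an explicit chain of single-cell steps."""
        rng = np.random.default_rng(3)
        p = init_params(3, 4, 1, 2, rng)
        X = rng.normal(size=(1, 1, 5, 3))
        cache = sync_forward(X, p)
        state = zero_state(4, B=1)
        for t in range(5):
            state, _ = lstm_cell_forward(X[:, 0, t], state, p)
        merged = state.h
        logits = merged @ p.weights["Wy"] + p.weights["by"]
        assert np.allclose(cache.logits, logits, atol=1e-12)

    def test_identical_streams_with_shared_weights_are_symmetric(self):
        rng = np.random.default_rng(4)
        p = small_params(rng, D=3, h=4, M=2, K=2)
        x = rng.normal(size=(1, 1, 6, 3))
        X = np.concatenate([x, x], axis=1)
        cache = sync_forward(X, p)
        for step in cache.steps:
            assert np.allclose(step["h_used"][:, 0], step["h_used"][:, 1])

    def test_merged_width_is_streams_times_hidden(self):
        rng = np.random.default_rng(5)
        p = init_params(4, 128, 3, 5, rng)
        X = rng.normal(size=(2, 3, 4, 4))
        assert sync_forward(X, p).merged.shape == (2, 3 * 128)

    def test_stream_count_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        p = small_params(rng, M=2)
        with pytest.raises(ValueError, match="streams"):
            sync_forward(rng.normal(size=(1, 3, 4, 2)), p)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(7)
        p = small_params(rng, K=5)
        X = rng.normal(size=(4, 2, 3, 2))
        probs = sync_forward(X, p).probs
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= 0).all()

    def test_literal_output_lag_reads_previous_step(self):
        rng = np.random.default_rng(8)
        p = small_params(rng)
        X = rng.normal(size=(1, 2, 4, 2))
        lagged = sync_forward(X, p, literal_output_lag=True)
        assert lagged.merge_step == 2
        h_lag = lagged.steps[2]["h_used"].reshape(1, -1)
        assert np.allclose(lagged.merged, h_lag)


class TestLoss:
    def test_perfect_one_hot_prediction_zero_loss(self):
        rng = np.random.default_rng(9)
        p = small_params(rng, K=3)
        probs = np.eye(3)
        assert loss(probs, [0, 1, 2], p, gamma=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_prediction_ln_k(self):
        rng = np.random.default_rng(10)
        p = small_params(rng, K=4)
        probs = np.full((2, 4), 0.25)
        assert loss(probs, [1, 3], p, gamma=0.0) == pytest.approx(math.log(4))

    def test_l2_penalty_closed_form(self):
        """Gamma = 0.01 adds 0.01 * sum of squared weights, biases excluded."""
        rng = np.random.default_rng(11)
        p = small_params(rng)
        from synchar.sync_lstm import WEIGHT_KEYS
        expected = 0.01 * sum(np.sum(p.weights[k] ** 2) for k in WEIGHT_KEYS)
        assert l2_penalty(p, 0.01) == pytest.approx(expected, rel=1e-12)

    def test_label_out_of_range_rejected(self):
        rng = np.random.default_rng(12)
        p = small_params(rng, K=2)
        with pytest.raises(ValueError):
            loss(np.full((1, 2), 0.5), [2], p)


def _num_params(p):
    return sum(v.size for v in p.weights.values())


def _finite_difference_check(p, X, y, gamma=0.0, literal=False, sw=None,
                             tol=1e-4, atol=1e-9):
    """Central differences at step h = 1e-6; ``atol`` absorbs the oracle's
    own roundoff floor (machine epsilon x |loss| / 2h ~ 1e-10) on gradient
    components that are themselves near zero."""
    cache = sync_forward(X, p, literal_output_lag=literal)
    grads, dX = bptt_backward(cache, y, gamma, sample_weights=sw)
    eps = 1e-6

    def loss_at():
        c = sync_forward(X, p, literal_output_lag=literal)
        return loss(c, y, p, gamma, sample_weights=sw)

    worst = 0.0
    for k, w in p.weights.items():
        flat = w.reshape(-1)
        for j in range(flat.size):
            orig = flat[j]
            flat[j] = orig + eps
            up = loss_at()
            flat[j] = orig - eps
            dn = loss_at()
            flat[j] = orig
            num = (up - dn) / (2 * eps)
            ana = grads[k].reshape(-1)[j]
            err = abs(num - ana)
            rel = err / max(abs(num), abs(ana), 1e-12)
            worst = max(worst, rel if err > atol else 0.0)
            assert err < tol * max(abs(num), abs(ana)) + atol, \
                f"{k}[{j}]: analytic {ana} vs numeric {num}"
    # input gradients feed the adversarial module: check them too
    flatX = X.reshape(-1)
    for j in range(flatX.size):
        orig = flatX[j]
        flatX[j] = orig + eps
        up = loss_at()
        flatX[j] = orig - eps
        dn = loss_at()
        flatX[j] = orig
        num = (up - dn) / (2 * eps)
        ana = dX.reshape(-1)[j]
        err = abs(num - ana)
        rel = err / max(abs(num), abs(ana), 1e-12)
        worst = max(worst, rel if err > atol else 0.0)
        assert err < tol * max(abs(num), abs(ana)) + atol
    return worst


class TestBPTTGradients:
    def test_matches_central_finite_differences(self):
        """All parameter and input gradients within 1e-4 relative error on
        a <= 50 parameter network in double precision."""
        rng = np.random.default_rng(13)
        p = small_params(rng, D=1, h=2, M=2, K=2)
        assert _num_params(p) <= 50
        X = rng.normal(size=(3, 2, 3, 1))
        y = np.array([0, 1, 0])
        _finite_difference_check(p, X, y, gamma=0.01)

    def test_matches_finite_differences_with_output_lag_and_weights(self):
        rng = np.random.default_rng(14)
        p = small_params(rng, D=1, h=2, M=2, K=2)
        X = rng.normal(size=(3, 2, 3, 1))
        y = np.array([1, 0, 1])
        _finite_difference_check(p, X, y, literal=True,
                                 sw=np.array([1.0, 0.5, 2.0]))

    def test_duplicating_batch_leaves_mean_gradient_unchanged(self):
        rng = np.random.default_rng(15)
        p = small_params(rng)
        X = rng.normal(size=(2, 2, 3, 2))
        y = np.array([0, 1])
        g1, _ = bptt_backward(sync_forward(X, p), y)
        X2 = np.concatenate([X, X])
        g2, _ = bptt_backward(sync_forward(X2, p), np.concatenate([y, y]))
        for k in g1:
            assert np.allclose(g1[k], g2[k], atol=1e-12)

    def test_l2_gradient_alone_is_2_gamma_w(self):
        rng = np.random.default_rng(16)
        p = small_params(rng)
        X = rng.normal(size=(2, 2, 3, 2))
        y = np.array([0, 1])
        g0, _ = bptt_backward(sync_forward(X, p), y, gamma=0.0)
        g1, _ = bptt_backward(sync_forward(X, p), y, gamma=0.05)
        from synchar.sync_lstm import WEIGHT_KEYS, BIAS_KEYS
        for k in WEIGHT_KEYS:
            assert np.allclose(g1[k] - g0[k], 2 * 0.05 * p.weights[k], atol=1e-12)
        for k in BIAS_KEYS:
            assert np.allclose(g1[k], g0[k], atol=1e-12)


class TestClipGradients:
    def test_norm_above_threshold_scaled(self):
        g = {"a": np.array([6.0, 8.0])}  # norm 10
        clipped = clip_gradients(g, 5.0)
        assert np.allclose(clipped["a"], [3.0, 4.0])
        assert np.linalg.norm(clipped["a"]) == pytest.approx(5.0)

    def test_norm_below_threshold_unchanged_object(self):
        g = {"a": np.array([1.0, 2.0])}
        assert clip_gradients(g, 5.0) is g

    def test_zero_gradients_unchanged(self):
        g = {"a": np.zeros(3)}
        assert clip_gradients(g, 5.0) is g


class TestAdam:
    def _tc(self, **kw):
        return TrainingConfig(hidden=1, **kw)

    def test_zero_gradient_leaves_params_and_moments(self):
        rng = np.random.default_rng(17)
        p = small_params(rng)
        before = p.copy()
        state = AdamState.zeros(p)
        adam_step(p, p.zeros_like(), state, 0.01, self._tc())
        for k in p.weights:
            assert np.array_equal(p.weights[k], before.weights[k])
            assert not state.m[k].any() and not state.v[k].any()

    def test_two_steps_match_hand_trace(self):
        """Scalar parameter, constant gradient g = 2, hand-rolled Adam
        recurrences with beta1 = 0.5, beta2 = 0.999."""
        b1, b2, eps, lr, g = 0.5, 0.999, 1e-8, 0.1, 2.0
        theta, m, v = 1.0, 0.0, 0.0
        for t in (1, 2):
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            theta -= lr * (m / (1 - b1 ** t)) / (math.sqrt(v / (1 - b2 ** t)) + eps)
        p = init_params(1, 1, 1, 1, np.random.default_rng(0))
        p.weights = {"w": np.array([1.0])}
        state = AdamState(m={"w": np.zeros(1)}, v={"w": np.zeros(1)})
        cfg = self._tc(momentum=0.5)
        for _ in range(2):
            adam_step(p, {"w": np.array([g])}, state, lr, cfg)
        assert p.weights["w"][0] == pytest.approx(theta, rel=1e-12)

    def test_default_batch_size_is_100(self):
        assert TrainingConfig().batch_size == 100

    def test_learning_rate_warmup_schedule(self):
        cfg = self._tc(epochs=100, initial_lr=0.001, target_lr=0.005)
        lrs = [learning_rate_at(e, cfg) for e in range(12)]
        assert lrs[9] == pytest.approx(0.005)
        assert lrs[11] == 0.005
        assert all(a <= b + 1e-12 for a, b in zip(lrs, lrs[1:]))
        assert lrs[0] > 0.001


def _toy_separable(rng, n=40, D=3, T=4, M=2):
    """Two classes with disjoint active input dimensions."""
    X = np.zeros((n, M, T, D))
    y = rng.integers(0, 2, size=n)
    for i in range(n):
        d = 0 if y[i] == 0 else 1
        X[i, :, :, d] = 1.0 + 0.1 * rng.normal(size=(M, T))
    return X, y


def test_loss_decreases_on_separable_task():
    """Training loss drops over 50 epochs on a linearly separable toy task."""
    rng = np.random.default_rng(18)
    X, y = _toy_separable(rng)
    cfg = TrainingConfig(hidden=4, epochs=50, batch_size=20, dropout_rate=0.0,
                         seed=18, target_lr=0.01)
    res = train_adversarial((X, y), cfg, AdversarialConfig(epsilon=0.0))
    assert res.history[-1].clean_loss < res.history[0].clean_loss


def test_training_is_bitwise_deterministic():
    rng = np.random.default_rng(19)
    X, y = _toy_separable(rng, n=20)
    cfg = TrainingConfig(hidden=4, epochs=5, batch_size=10, seed=3)
    r1 = train_adversarial((X, y), cfg, AdversarialConfig(epsilon=0.05))
    r2 = train_adversarial((X, y), cfg, AdversarialConfig(epsilon=0.05))
    for k in r1.params.weights:
        assert np.array_equal(r1.params.weights[k], r2.params.weights[k])
    assert [h.clean_loss for h in r1.history] == [h.clean_loss for h in r2.history]


def test_params_stay_finite_through_training():
    rng = np.random.default_rng(20)
    X, y = _toy_separable(rng, n=20)
    cfg = TrainingConfig(hidden=4, epochs=10, batch_size=10, seed=4)
    res = train_adversarial((X, y), cfg)
    res.params.check_finite()


def test_checkpoint_round_trip(tmp_path):
    from synchar.sync_lstm import load_params, save_params
    rng = np.random.default_rng(21)
    p = small_params(rng)
    save_params(p, tmp_path / "model.npz", TrainingConfig())
    q = load_params(tmp_path / "model.npz")
    assert q.n_streams == p.n_streams and q.shared == p.shared
    for k in p.weights:
        assert np.array_equal(p.weights[k], q.weights[k])
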