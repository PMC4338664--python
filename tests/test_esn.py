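"""Echo-state predictors: initialization, dynamics, RLS training, scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from evsn.esn import (
    ESN,
    ESNBank,
    ESNParams,
    ESNState,
    ESNWeights,
    RLSState,
    batch_ridge_readout,
    esn_step,
    init_esn,
    load_bank,
    prediction_error,
    rls_update,
    save_bank,
    similarity,
)


PARAMS = ESNParams(n_reservoir=15, input_dim=10)


class TestInit:
    def test_spectral_radius_is_exact(self):
        w = init_esn(PARAMS, seed=3)
        radius = np.max(np.abs(np.linalg.eigvals(w.W_r)))
        assert radius == pytest.approx(0.7, abs=1e-9)

    def test_weight_ranges(self):
        w = init_esn(PARAMS, seed=3)
        assert np.all(np.abs(w.W_in) <= 0.4)
        assert np.all(np.abs(w.W_back) <= 0.02)
        assert np.all(np.abs(w.W_out) <= 0.01)

    def test_identical_seeds_identical_weights(self):
        a, b = init_esn(PARAMS, 11), init_esn(PARAMS, 11)
        for name in ("W_r", "W_in", "W_back", "W_out"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_zero_reservoir_rejected(self):
        with pytest.raises(ValueError):
            ESNParams(n_reservoir=0)


class TestStep:
    def test_zero_weights_give_half_state(self):
        n, m = 5, 3
        w = ESNWeights(np.zeros((n, n)), np.zeros((n, m)), np.zeros((n, m)),
                       np.zeros((m, n)))
        state = ESNState(np.zeros(n), np.zeros(m), np.zeros(n))
        new, out = esn_step(w, state, np.ones(m))
        assert np.allclose(new.s, 0.5)
        assert np.allclose(out, 0.0)

    def test_one_neuron_converges_to_logistic_fixed_point(self):
        # bisection oracle on s - logistic(0.7 s)
        lo, hi = 0.5, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if mid - expit(0.7 * mid) < 0:
                lo = mid
            else:
                hi = mid
        fixed_point = 0.5 * (lo + hi)
        assert fixed_point == pytest.approx(0.604, abs=5e-4)

        w = ESNWeights(np.array([[0.7]]), np.zeros((1, 1)), np.zeros((1, 1)),
                       np.zeros((1, 1)))
        state = ESNState(np.zeros(1), np.zeros(1), np.zeros(1))
        for _ in range(200):
            state, _ = esn_step(w, state, np.zeros(1))
        assert state.s[0] == pytest.approx(fixed_point, abs=1e-12)

    def test_linear_readout_scales_with_weights(self):
        w = init_esn(PARAMS, 5)
        state = ESNState(np.full(15, 0.5), np.zeros(10), np.full(15, 0.5))
        _, out1 = esn_step(w, state, np.ones(10))
        w.W_out = 2 * w.W_out
        _, out2 = esn_step(w, state, np.ones(10))
        assert np.allclose(out2, 2 * out1)

    def test_dimension_mismatch_rejected(self):
        w = init_esn(PARAMS, 5)
        state = ESNState(np.full(15, 0.5), np.zeros(10), np.full(15, 0.5))
        with pytest.raises(ValueError):
            esn_step(w, state, np.ones(7))

    def test_fading_memory(self, rng):
        # echo-state property at spectral radius 0.7: state distance between
        # two copies driven identically vanishes
        w = init_esn(PARAMS, 21)
        a = ESNState(rng.uniform(0, 1, 15), np.zeros(10), np.zeros(15))
        b = ESNState(rng.uniform(0, 1, 15), np.zeros(10), np.zeros(15))
        for _ in range(200):
            u = rng.uniform(0, 1, 10)
            a, _ = esn_step(w, a, u)
            b, _ = esn_step(w, b, u)
        assert np.linalg.norm(a.s - b.s) < 1e-6


class TestRLS:
    def test_noiseless_teacher_recovered(self, rng):
        # 15-dim state, 500 steps, forgetting 1: RLS matches the batch
        # least-squares oracle and the teacher to 1e-6
        n, o = 15, 4
        W_star = rng.uniform(-0.5, 0.5, (o, n))
        rls = RLSState.fresh(n, forgetting=1.0, delta=1e-8)
        W = np.zeros((o, n))
        states = rng.uniform(0, 1, (500, n))
        for s in states:
            rls, W = rls_update(rls, s, W_star @ s, W)
        batch = batch_ridge_readout(states, states @ W_star.T, delta=1e-8)
        assert np.max(np.abs(W - W_star)) < 1e-6
        assert np.max(np.abs(W - batch)) < 1e-6

    def test_forgetting_one_equals_batch_ridge(self, rng):
        # exact recursion/batch equivalence on a noisy 100-step problem
        n, o = 8, 3
        delta = 0.01
        rls = RLSState.fresh(n, forgetting=1.0, delta=delta)
        W = np.zeros((o, n))
        states = rng.normal(size=(100, n))
        targets = rng.normal(size=(100, o))
        for s, y in zip(states, targets):
            rls, W = rls_update(rls, s, y, W)
        batch = batch_ridge_readout(states, targets, delta=delta)
        assert np.max(np.abs(W - batch)) < 1e-8

    def test_zero_innovation_leaves_readout_unchanged(self, rng):
        n = 6
        rls = RLSState.fresh(n)
        W = rng.normal(size=(2, n))
        s = rng.uniform(0, 1, n)
        _, W_new = rls_update(rls, s, W @ s, W)
        assert np.allclose(W_new, W)

    def test_constant_scalar_regressor_converges_to_mean_ratio(self, rng):
        c = 0.7
        y = rng.normal(2.0, 0.3, 200)
        rls = RLSState.fresh(1, forgetting=1.0, delta=1e-9)
        W = np.zeros(1)
        for yi in y:
            rls, W = rls_update(rls, np.array([c]), np.array([yi]), W)
        assert W[0] == pytest.approx(np.mean(y) / c, abs=1e-6)


class TestScores:
    def test_prediction_error_examples(self):
        assert prediction_error([1, 2, 3], [1, 2, 3]) == 0.0
        assert prediction_error([3, 4], [0, 0]) == pytest.approx(5.0)
        assert prediction_error([1, 0], [0, 1]) == pytest.approx(np.sqrt(2))

    def test_similarity_examples(self):
        one_hot = np.zeros(8)
        one_hot[0] = 1.0
        assert similarity(one_hot, one_hot) == pytest.approx(1.0)
        assert similarity([1, 0], [0, 1]) == 0.0  # disjoint supports
        assert similarity([1, 1], [1, 1]) == pytest.approx(0.5)  # (1+1)/(2*2)
        assert similarity([0, 0], [1, 1]) == 0.0  # zero-vector guard

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_similarity_bounded_for_normalized_inputs(self, a, b):
        m = min(len(a), len(b))
        s = similarity(np.array(a[:m]), np.array(b[:m]))
        assert 0.0 <= s <= 1.0


class TestBank:
    def test_bank_step_matches_single_esn_math(self, rng):
        bank = ESNBank(PARAMS, seed=17, n_esns=3)
        # mirror network 1 with the single-ESN path
        w = ESNWeights(bank.W_r[1].copy(), bank.W_in[1].copy(),
                       bank.W_back[1].copy(), bank.W_out[1].copy())
        state = ESNState(bank.states[1].copy(), bank.outs[1].copy(),
                         bank.regressors[1].copy())
        for _ in range(5):
            u = rng.uniform(0, 1, PARAMS.input_dim)
            bank.step(u)
            state, out = esn_step(w, state, u)
        assert np.allclose(bank.states[1], state.s, atol=1e-14)
        assert np.allclose(bank.preds[1], out, atol=1e-14)

    def test_bank_train_matches_rls_update(self, rng):
        bank = ESNBank(PARAMS, seed=17, n_esns=2)
        u = rng.uniform(0, 1, PARAMS.input_dim)
        bank.step(u)
        rls = RLSState.fresh(15, PARAMS.forgetting, PARAMS.p_delta)
        W = bank.W_out[0].copy()
        target = rng.uniform(0, 1, PARAMS.input_dim)
        _, W_ref = rls_update(rls, bank.regressors[0], target, W)
        bank.train_one(0, target)
        assert np.allclose(bank.W_out[0], W_ref, atol=1e-14)

    def test_scores_match_scalar_functions(self, rng):
        bank = ESNBank(PARAMS, seed=4, n_esns=3)
        bank.step(rng.uniform(0, 1, PARAMS.input_dim))
        actual = rng.uniform(0, 1, PARAMS.input_dim)
        sims, errors = bank.scores(actual)
        for k in range(3):
            assert sims[k] == pytest.approx(similarity(actual, bank.preds[k]))
            assert errors[k] == pytest.approx(prediction_error(actual, bank.preds[k]))

    def test_hdf5_roundtrip(self, tmp_path):
        bank = ESNBank(PARAMS, seed=8, n_esns=3)
        bank.train_one(0, np.ones(PARAMS.input_dim))
        path = tmp_path / "weights.h5"
        save_bank(bank, path, seed=8)
        loaded = load_bank(path)
        assert loaded.n_esns == 3
        for name in ("W_r", "W_in", "W_back", "W_out", "P"):
            assert np.array_equal(getattr(loaded, name), getattr(bank, name))


def test_single_esn_class_trains_online(rng):
    params = ESNParams(n_reservoir=10, input_dim=4)
    net = ESN(params, seed=2)
    # predictable input: slow sinusoid sampled at the tick rate
    t = np.arange(3000)
    signal = 0.5 + 0.4 * np.sin(2 * np.pi * t / 50.0)
    errors = []
    for k in range(len(t) - 1):
        u = np.full(4, signal[k])
        net.step(u)
        target = np.full(4, signal[k + 1])
        errors.append(prediction_error(target, net.state.out))
        net.train(target)
    # online adaptation: settled error well below the adaptation transient
    # and small in absolute terms for a smooth, predictable drive
    assert np.mean(errors[-200:]) < 0.5 * np.mean(errors[:200])
    assert np.mean(errors[-200:]) < 0.05
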