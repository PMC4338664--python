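"""Sigmoid current encoding, IF winner-take-all, gating, predictability
minimization."""

import itertools
import math

import numpy as np
import pytest

from evsn.wta_pm import (
    NO_WINNER,
    IFNeuron,
    OffsetController,
    PMPool,
    SigmoidGain,
    WTACircuit,
    encode_current,
    gate,
    pm_step,
    select_winner,
    update_offset,
)


class TestSigmoidEncoding:
    def test_midpoint(self):
        g = SigmoidGain(x0=0.3)
        assert encode_current(0.3, g) == pytest.approx((5000 + 15000) / 2)

    def test_saturation(self):
        g = SigmoidGain(x0=0.5)
        assert encode_current(1.0, g) == pytest.approx(15000)
        assert encode_current(0.0, g) == pytest.approx(5000)

    def test_three_quarter_point_at_lambda_ln3(self):
        g = SigmoidGain(x0=0.2, selectivity=0.01)
        s = 0.2 + 0.01 * math.log(3)
        assert encode_current(s, g) == pytest.approx(5000 + 0.75 * 10000)

    def test_invalid_gain_rejected(self):
        with pytest.raises(ValueError):
            SigmoidGain(g_min=10, g_max=10)


class TestOffsetController:
    def test_equal_similarity_leaves_offset(self):
        c = OffsetController(kp=0.1)
        assert update_offset(0.4, 0.4, c) == 0.4

    def test_unit_gain_jumps_to_winner(self):
        c = OffsetController(kp=1.0)
        assert update_offset(0.9, 0.2, c) == pytest.approx(0.2)

    def test_contraction_factor(self):
        c = OffsetController(kp=0.25)
        x0, s = 0.8, 0.2
        for _ in range(5):
            new = update_offset(x0, s, c)
            assert abs(new - s) == pytest.approx((1 - c.kp) * abs(x0 - s))
            x0 = new

    def test_offset_clamped_to_unit_interval(self):
        c = OffsetController(kp=2.0)
        assert update_offset(0.0, 1.0, c) == 1.0

    def test_stationary_similarity_attracts_offset(self):
        # |S_winner - x0| -> 0 under a constant winning similarity
        wta = WTACircuit(3)
        sims = np.array([0.1, 0.62, 0.3])
        for k in range(100):
            wta.select(sims, t_us=k * 1000)
        assert abs(wta.gain.x0 - 0.62) < 1e-6


class TestIFNeuron:
    def test_interspike_interval_closed_form(self):
        n = IFNeuron(theta=2.0)
        times = n.spike_times(current=8.0, duration_s=1.0)
        assert np.allclose(np.diff(times), 2.0 / 8.0)
        assert len(times) == 4

    def test_rate_equals_current_at_unit_threshold(self):
        # the 5-15 kHz span: currents at the encoding extremes map to rates
        g = SigmoidGain(x0=0.5)
        for s, rate in [(0.0, 5000), (1.0, 15000)]:
            current = encode_current(s, g)
            spikes = IFNeuron(theta=1.0).spike_times(current, 1.0)
            assert len(spikes) == pytest.approx(rate, abs=1)

    def test_stepwise_integration_accumulates_without_leak(self):
        n = IFNeuron(theta=1.0)
        total = sum(n.integrate(100.0, 0.004) for _ in range(5))
        assert total == 2  # 100 Hz * 20 ms = 2 spikes
        assert n.v == pytest.approx(0.0, abs=1e-12)


class TestSelectWinner:
    def test_highest_current_wins(self):
        w, spikes = select_winner(np.array([5000.0, 9000.0, 15000.0]), None, 1000)
        assert w == 2
        assert len(spikes) == 15  # 15 kHz for 1 ms

    def test_inhibited_channel_never_wins(self):
        inhibited = np.array([False, False, True])
        w, _ = select_winner(np.array([5000.0, 9000.0, 15000.0]), inhibited, 1000)
        assert w == 1

    def test_all_inhibited_gives_no_winner(self):
        w, spikes = select_winner(np.array([5000.0, 9000.0]), np.array([True, True]), 1000)
        assert w == NO_WINNER
        assert len(spikes) == 0

    def test_spikes_all_from_one_channel_at_winner_rate(self):
        currents = np.array([3000.0, 7000.0])
        w, spikes = select_winner(currents, None, 2000)
        assert w == 1
        assert np.allclose(np.diff(spikes), 1e6 / 7000.0)

    def test_exhaustive_permutations_match_argmax_oracle(self):
        currents = [5000.0, 7000.0, 11000.0, 15000.0]
        for perm in itertools.permutations(currents):
            arr = np.array(perm)
            for inhibit_mask in itertools.product([False, True], repeat=4):
                mask = np.array(inhibit_mask)
                w, _ = select_winner(arr, mask, 1000)
                if mask.all():
                    assert w == NO_WINNER
                else:
                    oracle = int(np.argmax(np.where(mask, -np.inf, arr)))
                    assert w == oracle

    def test_fuzz_against_argmax_oracle(self, rng):
        for _ in range(10_000):
            n = int(rng.integers(2, 8))
            currents = rng.uniform(0, 20000, n)
            mask = rng.random(n) < 0.3
            w, _ = select_winner(currents, mask, 1000)
            if mask.all():
                assert w == NO_WINNER
            else:
                assert w == int(np.argmax(np.where(mask, -np.inf, currents)))

    def test_ties_break_to_lowest_index(self):
        w, _ = select_winner(np.array([9000.0, 9000.0, 1000.0]), None, 1000)
        assert w == 0

    def test_invalid_currents_rejected(self):
        with pytest.raises(ValueError):
            select_winner(np.array([np.nan, 1.0]), None, 1000)
        with pytest.raises(ValueError):
            select_winner(np.array([-1.0, 1.0]), None, 1000)


class TestGate:
    def test_zero_vector_inactive(self):
        assert gate(np.zeros(10), 0.01) is False

    def test_mean_exactly_at_threshold_inactive(self):
        # strict inequality decision
        assert gate(np.full(10, 0.01), 0.01) is False

    def test_mean_above_threshold_active(self):
        assert gate(np.full(10, 0.011), 0.01) is True


def force_estimate(pool: PMPool, estimator: int, guess: int) -> None:
    """Pin estimator's readout so its argmax output is a chosen channel."""
    pool.W_out[estimator] = 0.0
    pool.W_out[estimator, guess, :] = 1.0


class TestPMStep:
    def test_correct_self_prediction_inhibits_winner(self):
        pool = PMPool(4, seed=0)
        wta = WTACircuit(4, t_inh_us=10_000)
        force_estimate(pool, estimator=2, guess=2)
        sims = np.array([0.1, 0.2, 0.6, 0.1])
        inhibited = pm_step(pool, wta, sims, winner=2, t_us=5000, train=False)
        assert inhibited == [2]
        assert wta.inhibited(6000)[2]
        assert not wta.inhibited(16_000)[2]  # expires after t_inh

    def test_wrong_guess_does_not_inhibit(self):
        pool = PMPool(4, seed=0)
        wta = WTACircuit(4, t_inh_us=10_000)
        force_estimate(pool, estimator=2, guess=0)
        inhibited = pm_step(pool, wta, np.array([0.1, 0.2, 0.6, 0.1]),
                            winner=2, t_us=5000, train=False)
        assert inhibited == []
        assert not wta.inhibited(6000).any()

    def test_inhibition_is_temporary(self):
        pool = PMPool(3, seed=1)
        # a soft gain keeps the three currents distinct in floating point
        wta = WTACircuit(3, gain=SigmoidGain(selectivity=0.05, x0=0.5), t_inh_us=5_000)
        force_estimate(pool, 1, 1)
        pm_step(pool, wta, np.array([0.1, 0.9, 0.2]), winner=1, t_us=0, train=False)
        sims = np.array([0.1, 0.9, 0.2])
        assert wta.select(sims, t_us=1000) == 2  # best non-inhibited channel
        assert wta.select(sims, t_us=7000) == 1  # can win again after expiry

    def test_estimator_never_sees_own_similarity(self):
        pool = PMPool(3, seed=2)
        sims = np.array([0.5, 0.6, 0.7])
        pool.step(sims)
        # estimator k's input row excludes component k
        X = np.broadcast_to(sims, (3, 3))[pool._keep].reshape(3, 2)
        assert np.array_equal(X[0], [0.6, 0.7])
        assert np.array_equal(X[1], [0.5, 0.7])
        assert np.array_equal(X[2], [0.5, 0.6])

    def test_redundant_channel_gets_suppressed(self):
        """Two channels fed identical similarity streams: once the winner's
        estimator has learned to predict it from its twin, predictability
        minimization inhibits it on most winning steps, forcing the twin to
        win.  Estimators are evaluated frozen, as in a test phase."""
        pool = PMPool(3, seed=3)
        sims = np.array([0.7, 0.7, 0.1])  # channels 0 and 1 are duplicates
        # channel 0 (lowest index) wins the tie uncontested while the
        # estimators learn the winner from the other channels' similarities
        for _ in range(1000):
            pool.step(sims)
            pool.train(0)
        assert pool.estimates()[0] == 0
        wta = WTACircuit(3, t_inh_us=10_000)
        winners, inhibitions = [], []
        for k in range(400):
            t_us = k * 1000
            w = wta.select(sims, t_us)
            winners.append(w)
            inh = pm_step(pool, wta, sims, w, t_us, train=False) if w != NO_WINNER else []
            inhibitions.append(inh)
        winners = np.array(winners)
        zero_wins = np.flatnonzero(winners == 0)
        assert len(zero_wins) > 0
        frac_inhibited = np.mean([0 in inhibitions[i] for i in zero_wins])
        assert frac_inhibited >= 0.5
        # the twin carries the winning role during the inhibition windows
        assert (winners == 1).sum() > (winners == 0).sum()
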