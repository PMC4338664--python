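"""Spiking winner-take-all selection with predictability minimization.

The similarity score of each predictor is converted to an input current by
a sigmoid gain whose offset ``x0`` is servoed (proportional controller,
0.5 ms period) onto the winning score, keeping the sigmoid centred on the
operating point and hence maximally selective; the selectivity constant
``lambda`` is deliberately sharp (5e-5) so the gain acts almost as a
comparator around ``x0``.  The currents drive non-leaky integrate-and-fire
neurons coupled through a global inhibitory neuron: every spike resets all
accumulators, so only the most strongly driven (non-inhibited) channel
ever fires — over a decision window the circuit computes an argmax, with
ties broken toward the lowest channel index.  With threshold 1 the firing
rate in Hz equals the input current, so the default gain range produces
5-15 kHz spike rates.

A gating flag suppresses selection (and learning) when the mean analog
input activity is at or below a threshold, so the circuit is silent
without stimulation.

Predictability minimization gives each channel ``k`` an estimator network
``PM_k`` that tries to guess the WTA winner from the *other* channels'
similarity scores only.  When the estimator's guess matches the winner and
the winner is channel ``k`` itself, ``k``'s output is redundant — it is
inhibited for ``t_inh`` so a competing channel can win and learn,
promoting non-overlapping (orthogonal) feature detectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .esn import ESNParams, init_esn

__all__ = [
    "SigmoidGain",
    "OffsetController",
    "IFNeuron",
    "WTACircuit",
    "PMPool",
    "encode_current",
    "update_offset",
    "select_winner",
    "gate",
    "pm_step",
]

#: sentinel for "no winner" (all channels inhibited or gate closed)
NO_WINNER = -1


@dataclass
class SigmoidGain:
    """Similarity -> input-current map ``g(S) = G_min + (G_max - G_min) *
    sigmoid((S - x0)/lambda)`` (currents in Hz-equivalent units)."""

    g_min: float = 5000.0
    g_max: float = 15000.0
    selectivity: float = 5.0e-5
    x0: float = 0.0

    def __post_init__(self) -> None:
        if not self.g_min < self.g_max:
            raise ValueError("g_min must be below g_max")
        if not self.selectivity > 0:
            raise ValueError("selectivity must be positive")


def encode_current(similarity, gain: SigmoidGain):
    """Sigmoid current encoding; output confined to [g_min, g_max]."""
    s = np.asarray(similarity, dtype=np.float64)
    out = gain.g_min + (gain.g_max - gain.g_min) * expit((s - gain.x0) / gain.selectivity)
    return float(out) if np.isscalar(similarity) else out


@dataclass
class OffsetController:
    """Proportional controller servoing the sigmoid offset onto the winner's
    similarity; runs every ``period_us`` of simulated time."""

    kp: float = 0.1
    period_us: float = 500.0


def update_offset(x0: float, s_winner: float, controller: OffsetController) -> float:
    """One controller period: ``x0 + Kp (S_winner - x0)``, clamped to [0, 1]."""
    return float(np.clip(x0 + controller.kp * (s_winner - x0), 0.0, 1.0))


class IFNeuron:
    """Non-leaky integrate-and-fire neuron: accumulates current without decay,
    spikes and resets to zero at threshold.  With constant current ``I`` the
    inter-spike interval is exactly ``theta / I``."""

    def __init__(self, theta: float = 1.0):
        if not theta > 0:
            raise ValueError("threshold must be positive")
        self.theta = theta
        self.v = 0.0

    def integrate(self, current: float, dt_s: float) -> int:
        """Advance by ``dt_s`` under constant current; returns spike count."""
        self.v += current * dt_s
        n = int(self.v // self.theta) if self.v >= self.theta else 0
        self.v -= n * self.theta
        return n

    def spike_times(self, current: float, duration_s: float, t0_s: float = 0.0) -> np.ndarray:
        """Closed-form spike times under constant positive current."""
        if current <= 0:
            return np.empty(0)
        isi = self.theta / current
        n = int(duration_s / isi + 1e-9)
        return t0_s + isi * np.arange(1, n + 1)


def select_winner(
    currents: np.ndarray,
    inhibited: np.ndarray | None,
    window_us: float,
    theta: float = 1.0,
) -> tuple[int, np.ndarray]:
    """Simulate the WTA circuit over one decision window.

    Non-leaky IF neurons integrate their currents; the first to reach
    threshold spikes and the global inhibitory neuron resets every
    accumulator, so all spikes in the window come from the channel with the
    highest current among non-inhibited channels (ties toward the lowest
    index — simultaneous threshold crossings are resolved by channel
    order).  Returns ``(winner, spike_times_us)``; ``(NO_WINNER, [])`` if
    every channel is inhibited or no current is positive.
    """
    currents = np.asarray(currents, dtype=np.float64)
    if np.any(~np.isfinite(currents)) or np.any(currents < 0):
        raise ValueError("currents must be finite and non-negative")
    eligible = currents > 0
    if inhibited is not None:
        eligible &= ~np.asarray(inhibited, dtype=bool)
    if not eligible.any():
        return NO_WINNER, np.empty(0)
    masked = np.where(eligible, currents, -np.inf)
    winner = int(np.argmax(masked))  # argmax returns the first (lowest) index on ties
    isi_us = theta / currents[winner] * 1e6
    n = int(window_us / isi_us + 1e-9)
    return winner, isi_us * np.arange(1, n + 1)


def gate(analog: np.ndarray, threshold: float) -> bool:
    """Input-activity gate: active iff the mean component strictly exceeds
    the threshold."""
    analog = np.asarray(analog, dtype=np.float64)
    mean = analog.mean() if analog.size else 0.0
    return bool(mean > threshold)


class WTACircuit:
    """Stateful winner-take-all over N channels with adaptive offset and
    per-channel inhibition expiries."""

    def __init__(
        self,
        n_channels: int,
        gain: SigmoidGain | None = None,
        controller: OffsetController | None = None,
        t_inh_us: float = 10_000.0,
        theta: float = 1.0,
    ):
        self.n_channels = n_channels
        self.gain = gain if gain is not None else SigmoidGain()
        self.controller = controller if controller is not None else OffsetController()
        self.t_inh_us = t_inh_us
        self.theta = theta
        self.inhibit_until_us = np.zeros(n_channels, dtype=np.int64)

    def inhibited(self, t_us: int) -> np.ndarray:
        return self.inhibit_until_us > t_us

    def inhibit(self, k: int, t_us: int) -> None:
        """Inhibit channel ``k`` from now until ``t_us + t_inh``."""
        self.inhibit_until_us[k] = max(
            self.inhibit_until_us[k], int(t_us + self.t_inh_us)
        )

    def select(self, similarities: np.ndarray, t_us: int, dt_us: float = 1000.0) -> int:
        """Winner for the tick starting at ``t_us``; servoes the offset onto
        the winner's similarity at the controller sub-period."""
        currents = encode_current(similarities, self.gain)
        winner, _ = select_winner(currents, self.inhibited(t_us), dt_us, self.theta)
        if winner != NO_WINNER:
            n_sub = max(int(round(dt_us / self.controller.period_us)), 1)
            for _ in range(n_sub):
                self.gain.x0 = update_offset(
                    self.gain.x0, float(similarities[winner]), self.controller
                )
        return winner


class PMPool:
    """Per-channel winner estimators implementing predictability minimization.

    Estimator ``k`` is an echo-state network that receives the similarity
    scores of every channel except ``k`` and is RLS-trained, one update per
    gated tick, toward the one-hot encoding of the actual winner.  All
    estimators are advanced and trained batched.
    """

    def __init__(self, n_channels: int, seed, n_reservoir: int = 15,
                 forgetting: float = 0.999, p_delta: float = 0.01):
        self.n = n_channels
        params = ESNParams(
            n_reservoir=n_reservoir,
            input_dim=n_channels - 1,
            output_dim=n_channels,
            forgetting=forgetting,
            p_delta=p_delta,
        )
        self.params = params
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        seeds = ss.spawn(n_channels)
        nets = [init_esn(params, np.random.default_rng(s)) for s in seeds]
        self.W_r = np.stack([w.W_r for w in nets])
        self.W_in = np.stack([w.W_in for w in nets])
        self.W_back = np.stack([w.W_back for w in nets])
        self.W_out = np.stack([w.W_out for w in nets])
        self.states = np.full((n_channels, n_reservoir), 0.5)
        self.outs = np.zeros((n_channels, n_channels))
        # mask that drops S_k from estimator k's input, fixed column order
        self._keep = ~np.eye(n_channels, dtype=bool)

    def step(self, similarities: np.ndarray) -> np.ndarray:
        """Advance all estimators; returns their winner estimates (N, N)."""
        sims = np.asarray(similarities, dtype=np.float64)
        X = np.broadcast_to(sims, (self.n, self.n))[self._keep].reshape(
            self.n, self.n - 1
        )
        pre = (
            np.einsum("kij,kj->ki", self.W_r, self.states)
            + np.einsum("kij,kj->ki", self.W_in, X)
            + np.einsum("kij,kj->ki", self.W_back, self.outs)
        )
        self.states = expit(pre)
        self.outs = np.einsum("koi,ki->ko", self.W_out, self.states)
        return self.outs

    def train(self, winner: int) -> None:
        """Batched RLS step of every estimator toward one-hot(winner)."""
        lam = self.params.forgetting
        S = self.states
        Ps = np.einsum("kij,kj->ki", self.P, S)
        denom = lam + np.einsum("ki,ki->k", S, Ps)
        bad = ~np.isfinite(denom) | (denom <= 0)
        if bad.any():
            warnings.warn("PM estimator RLS P reinitialized")
            self.P[bad] = np.eye(S.shape[1]) / self.params.p_delta
            Ps = np.einsum("kij,kj->ki", self.P, S)
            denom = lam + np.einsum("ki,ki->k", S, Ps)
        gain = Ps / denom[:, None]
        target = np.zeros(self.n)
        target[winner] = 1.0
        err = target[None, :] - np.einsum("koi,ki->ko", self.W_out, S)
        self.W_out += np.einsum("ko,ki->koi", err, gain)
        P = (self.P - np.einsum("ki,kj->kij", gain, Ps)) / lam
        self.P = 0.5 * (P + np.swapaxes(P, 1, 2))

    @property
    def P(self) -> np.ndarray:
        if not hasattr(self, "_P"):
            n = self.params.n_reservoir
            self._P = np.broadcast_to(
                np.eye(n) / self.params.p_delta, (self.n, n, n)
            ).copy()
        return self._P

    @P.setter
    def P(self, value: np.ndarray) -> None:
        self._P = value

    def estimates(self) -> np.ndarray:
        """Current winner guesses (argmax of each estimator's output)."""
        return np.argmax(self.outs, axis=1)


def pm_step(
    pool: PMPool,
    wta: WTACircuit,
    similarities: np.ndarray,
    winner: int,
    t_us: int,
    train: bool = True,
) -> list[int]:
    """One predictability-minimization step for a gated tick.

    Advances every estimator on the other channels' similarities, inhibits
    the winner's channel when its own estimator correctly guessed the
    winner (redundant output), then RLS-trains the estimators toward the
    one-hot winner.  Returns the list of channels inhibited this tick.
    """
    pool.step(similarities)
    guesses = pool.estimates()
    inhibited: list[int] = []
    # agreement rule: estimator k guessed the winner AND the winner is k
    if guesses[winner] == winner:
        wta.inhibit(winner, t_us)
        inhibited.append(winner)
    if train:
        pool.train(winner)
    return inhibited
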