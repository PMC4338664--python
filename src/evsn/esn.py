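"""Echo-state network predictors with online recursive-least-squares readouts.

Each predictor is a small reservoir (default 15 logistic neurons) with
fixed random recurrent, input and feedback weights, and a linear readout
trained online.  The reservoir matrix is rescaled to a spectral radius
below one (default 0.7) so the network has the echo-state property: its
state asymptotically forgets initial conditions and depends only on the
input history.  Driven by the analog vector ``A(t_n)``, the readout of the
state at ``t_n`` is interpreted as the one-step-ahead prediction
``Â(t_n + dt)``.

The readout is adapted by the standard recursive-least-squares (RLS)
recursion with exponential forgetting, one update per arriving sample; the
recursion shares a single inverse-correlation matrix ``P`` across output
dimensions because all outputs regress on the same reservoir state.

Two scalar scores compare a prediction with the observed input: the
prediction error (Euclidean norm of the difference) and a similarity

    S = sum_i |A_i . Â_i| / (sum_i |A_i| . sum_i |Â_i|),

which lies in [0, 1] for non-negative inputs and feeds the winner-take-all
selection stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np
from scipy.special import expit

__all__ = [
    "ESNParams",
    "ESNWeights",
    "ESNState",
    "RLSState",
    "ESN",
    "ESNBank",
    "init_esn",
    "esn_step",
    "rls_update",
    "prediction_error",
    "similarity",
    "batch_ridge_readout",
    "save_bank",
    "load_bank",
]


@dataclass(frozen=True)
class ESNParams:
    """Reservoir geometry, weight ranges and readout-training constants.

    Weight matrices are drawn uniformly from symmetric ranges:
    ``[-w_in_range, w_in_range]`` for the input weights, and likewise for
    feedback and initial readout weights.  ``forgetting`` is the RLS
    exponential-forgetting factor (1 = ordinary least squares);
    ``p_delta`` regularizes the RLS inverse-correlation matrix, which is
    initialized to ``(1/p_delta) I``.
    """

    n_reservoir: int = 15
    input_dim: int = 289
    output_dim: int | None = None  # defaults to input_dim (input prediction)
    spectral_radius: float = 0.7
    w_in_range: float = 0.4
    w_back_range: float = 0.02
    w_out_range: float = 0.01
    forgetting: float = 0.999
    p_delta: float = 0.01

    def __post_init__(self) -> None:
        if self.n_reservoir < 1:
            raise ValueError("reservoir must have at least one neuron")
        if not 0 < self.spectral_radius < 1:
            raise ValueError("spectral radius must lie in (0, 1) for the echo-state property")
        if not 0 < self.forgetting <= 1:
            raise ValueError("forgetting factor must lie in (0, 1]")
        if not self.p_delta > 0:
            raise ValueError("p_delta must be positive")

    @property
    def out_dim(self) -> int:
        return self.input_dim if self.output_dim is None else self.output_dim


@dataclass
class ESNWeights:
    """The four weight matrices of one echo-state network."""

    W_r: np.ndarray    # (n, n) reservoir
    W_in: np.ndarray   # (n, input_dim)
    W_back: np.ndarray # (n, out_dim) output feedback
    W_out: np.ndarray  # (out_dim, n) linear readout (the only trained matrix)


@dataclass
class ESNState:
    """Reservoir state, last output, and the regressor behind the pending
    prediction (the state that produced it)."""

    s: np.ndarray
    out: np.ndarray
    regressor: np.ndarray


def init_esn(params: ESNParams, seed) -> ESNWeights:
    """Draw random weights; ``W_r`` is rescaled to the exact spectral radius.

    All matrices are uniform draws from the ranges in ``params``; the
    reservoir matrix is drawn uniform in [-1, 1] and scaled so its largest
    eigenvalue magnitude equals ``spectral_radius``.  Reproducible per seed
    (an int or a ``numpy.random.Generator``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, m, o = params.n_reservoir, params.input_dim, params.out_dim
    W_r = rng.uniform(-1.0, 1.0, (n, n))
    radius = np.max(np.abs(np.linalg.eigvals(W_r)))
    if radius == 0:
        raise ValueError("degenerate reservoir draw (zero spectral radius)")
    W_r *= params.spectral_radius / radius
    W_in = rng.uniform(-params.w_in_range, params.w_in_range, (n, m))
    W_back = rng.uniform(-params.w_back_range, params.w_back_range, (n, o))
    W_out = rng.uniform(-params.w_out_range, params.w_out_range, (o, n))
    return ESNWeights(W_r, W_in, W_back, W_out)


def esn_step(
    weights: ESNWeights, state: ESNState, u: np.ndarray
) -> tuple[ESNState, np.ndarray]:
    """One reservoir update: ``s' = logistic(W_r s + W_in u + W_back out)``,
    output ``W_out s'`` (the prediction for the next tick)."""
    u = np.asarray(u, dtype=np.float64)
    if u.shape != (weights.W_in.shape[1],):
        raise ValueError(f"input has dimension {u.shape}, expected ({weights.W_in.shape[1]},)")
    s_new = expit(weights.W_r @ state.s + weights.W_in @ u + weights.W_back @ state.out)
    out = weights.W_out @ s_new
    return ESNState(s_new, out, s_new.copy()), out


@dataclass
class RLSState:
    """Recursive-least-squares accumulators for one readout.

    ``P`` is the (symmetric positive-definite) inverse correlation matrix of
    the regressor stream, initialized to ``(1/delta) I``; ``forgetting`` is
    the exponential weight on past samples.
    """

    P: np.ndarray
    forgetting: float = 0.999
    delta: float = 0.01

    @classmethod
    def fresh(cls, n: int, forgetting: float = 0.999, delta: float = 0.01) -> "RLSState":
        return cls(np.eye(n) / delta, forgetting, delta)


def rls_update(
    rls: RLSState, regressor: np.ndarray, target: np.ndarray, W_out: np.ndarray
) -> tuple[RLSState, np.ndarray]:
    """One RLS step for a (possibly multi-output) linear readout.

    All output dimensions share the gain vector computed from the single
    ``P`` because they regress on the same state.  With zero innovation
    (target equals the current prediction) the readout is unchanged.  If
    ``P`` loses positive-definiteness (numerically), it is reinitialized
    and a warning is issued.
    """
    s = np.asarray(regressor, dtype=np.float64)
    y = np.atleast_1d(np.asarray(target, dtype=np.float64))
    W = np.atleast_2d(W_out)
    lam = rls.forgetting
    Ps = rls.P @ s
    denom = lam + s @ Ps
    if not np.isfinite(denom) or denom <= 0:
        warnings.warn("RLS inverse-correlation matrix lost positive-definiteness; reinitializing")
        rls = RLSState.fresh(len(s), lam, rls.delta)
        Ps = rls.P @ s
        denom = lam + s @ Ps
    gain = Ps / denom
    err = y - W @ s
    W_new = W + np.outer(err, gain)
    P_new = (rls.P - np.outer(gain, Ps)) / lam
    P_new = 0.5 * (P_new + P_new.T)
    if np.asarray(W_out).ndim == 1:
        W_new = W_new[0]
    return RLSState(P_new, lam, rls.delta), W_new


def batch_ridge_readout(
    states: np.ndarray, targets: np.ndarray, delta: float
) -> np.ndarray:
    """Closed-form readout minimizing ``sum ||y - W s||^2 + delta ||W||^2``.

    Reference solution that the RLS recursion (forgetting 1, ``P``
    initialized to ``I/delta``, zero initial readout) reproduces exactly.
    """
    S = np.asarray(states, dtype=np.float64)          # (T, n)
    Y = np.atleast_2d(np.asarray(targets, dtype=np.float64))  # (T, o) or (T,)
    if Y.shape[0] != S.shape[0]:
        Y = Y.T
    A = S.T @ S + delta * np.eye(S.shape[1])
    return np.linalg.solve(A, S.T @ Y).T


def prediction_error(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Euclidean norm of the prediction residual."""
    actual = np.asarray(actual, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    if actual.shape != predicted.shape:
        raise ValueError("vectors must have equal dimension")
    return float(np.linalg.norm(predicted - actual))


def similarity(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Overlap score ``sum|a_i b_i| / (sum|a_i| sum|b_i|)`` in [0, 1].

    Returns 0 when either vector is all-zero (guarded division).
    """
    a = np.abs(np.asarray(actual, dtype=np.float64))
    b = np.abs(np.asarray(predicted, dtype=np.float64))
    if a.shape != b.shape:
        raise ValueError("vectors must have equal dimension")
    sa, sb = a.sum(), b.sum()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    # scale-invariant form of sum(a*b) / (sum(a) sum(b)); robust to underflow
    return float((a / sa) @ (b / sb))


class ESN:
    """One echo-state predictor bundling weights, state and RLS training."""

    def __init__(self, params: ESNParams, seed):
        self.params = params
        self.weights = init_esn(params, seed)
        n = params.n_reservoir
        self.state = ESNState(
            np.full(n, 0.5), np.zeros(params.out_dim), np.full(n, 0.5)
        )
        self.rls = RLSState.fresh(n, params.forgetting, params.p_delta)

    def step(self, u: np.ndarray) -> np.ndarray:
        self.state, out = esn_step(self.weights, self.state, u)
        return out

    def train(self, target: np.ndarray) -> None:
        """RLS-update the readout pairing the stored regressor (the state
        that produced the pending prediction) with the observed target."""
        self.rls, self.weights.W_out = rls_update(
            self.rls, self.state.regressor, target, self.weights.W_out
        )


class ESNBank:
    """A bank of N echo-state predictors advanced in lock-step.

    The per-network math is identical to :func:`esn_step`/:func:`rls_update`
    but batched over the bank with stacked weight tensors, which keeps the
    per-tick cost of the training loop dominated by arithmetic rather than
    dispatch.  ``preds`` holds each network's pending one-step-ahead
    prediction; ``regressors`` the states that produced them.
    """

    def __init__(self, params: ESNParams, seed, n_esns: int):
        self.params = params
        self.n_esns = n_esns
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        seeds = ss.spawn(n_esns)
        nets = [init_esn(params, np.random.default_rng(s)) for s in seeds]
        self.W_r = np.stack([w.W_r for w in nets])        # (N, n, n)
        self.W_in = np.stack([w.W_in for w in nets])      # (N, n, m)
        self.W_back = np.stack([w.W_back for w in nets])  # (N, n, o)
        self.W_out = np.stack([w.W_out for w in nets])    # (N, o, n)
        n = params.n_reservoir
        self.states = np.full((n_esns, n), 0.5)
        self.outs = np.zeros((n_esns, params.out_dim))
        self.preds = np.zeros((n_esns, params.out_dim))
        self.regressors = np.full((n_esns, n), 0.5)
        self.P = np.broadcast_to(np.eye(n) / params.p_delta, (n_esns, n, n)).copy()

    def step(self, u: np.ndarray) -> np.ndarray:
        """Advance every network on the shared input; returns predictions."""
        pre = (
            np.einsum("kij,kj->ki", self.W_r, self.states)
            + self.W_in @ u
            + np.einsum("kij,kj->ki", self.W_back, self.outs)
        )
        self.states = expit(pre)
        self.outs = np.einsum("koi,ki->ko", self.W_out, self.states)
        self.regressors = self.states.copy()
        self.preds = self.outs
        return self.preds

    def train_one(self, k: int, target: np.ndarray) -> None:
        """RLS update of network ``k``'s readout toward ``target``."""
        lam = self.params.forgetting
        s = self.regressors[k]
        Ps = self.P[k] @ s
        denom = lam + s @ Ps
        if not np.isfinite(denom) or denom <= 0:
            warnings.warn("RLS P reinitialized for bank member %d" % k)
            self.P[k] = np.eye(len(s)) / self.params.p_delta
            Ps = self.P[k] @ s
            denom = lam + s @ Ps
        gain = Ps / denom
        err = target - self.W_out[k] @ s
        self.W_out[k] += np.outer(err, gain)
        P = (self.P[k] - np.outer(gain, Ps)) / lam
        self.P[k] = 0.5 * (P + P.T)

    def scores(self, actual: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Similarities and prediction errors of all pending predictions."""
        diff = self.preds - actual
        errors = np.sqrt(np.einsum("ko,ko->k", diff, diff))
        a = np.abs(actual)
        b = np.abs(self.preds)
        sa = a.sum()
        sb = b.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            sims = np.where((sa > 0) & (sb > 0), (b / np.where(sb > 0, sb, 1.0)[:, None]) @ (a / max(sa, 1e-300)), 0.0)
        return sims, errors

    def copy(self) -> "ESNBank":
        """Independent clone (weights and accumulators deep-copied)."""
        clone = object.__new__(ESNBank)
        clone.params = self.params
        clone.n_esns = self.n_esns
        for name in ("W_r", "W_in", "W_back", "W_out", "states", "outs",
                     "preds", "regressors", "P"):
            setattr(clone, name, getattr(self, name).copy())
        return clone

    def reset_states(self) -> None:
        self.states[:] = 0.5
        self.outs[:] = 0.0
        self.preds[:] = 0.0
        self.regressors[:] = 0.5


def save_bank(bank: ESNBank, path, seed: int | None = None) -> None:
    """Archive a bank to HDF5: one group per network with its matrices."""
    with h5py.File(path, "w") as fh:
        fh.attrs["n_esns"] = bank.n_esns
        if seed is not None:
            fh.attrs["seed"] = seed
        for key, val in vars(bank.params).items():
            fh.attrs[f"param_{key}"] = -1 if val is None else val
        for k in range(bank.n_esns):
            g = fh.create_group(f"esn_{k}")
            g.create_dataset("W_r", data=bank.W_r[k])
            g.create_dataset("W_in", data=bank.W_in[k])
            g.create_dataset("W_back", data=bank.W_back[k])
            g.create_dataset("W_out", data=bank.W_out[k])
            g.create_dataset("P", data=bank.P[k])


def load_bank(path) -> ESNBank:
    """Restore a bank archived with :func:`save_bank`."""
    with h5py.File(path, "r") as fh:
        n_esns = int(fh.attrs["n_esns"])
        kwargs = {}
        for key in ESNParams.__dataclass_fields__:
            val = fh.attrs[f"param_{key}"]
            if key == "output_dim":
                val = None if val == -1 else int(val)
            elif key in ("n_reservoir", "input_dim"):
                val = int(val)
            else:
                val = float(val)
            kwargs[key] = val
        params = ESNParams(**kwargs)
        bank = ESNBank(params, 0, n_esns)
        for k in range(n_esns):
            g = fh[f"esn_{k}"]
            bank.W_r[k] = g["W_r"][()]
            bank.W_in[k] = g["W_in"][()]
            bank.W_back[k] = g["W_back"][()]
            bank.W_out[k] = g["W_out"][()]
            bank.P[k] = g["P"][()]
        bank.reset_states()
    return bank
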