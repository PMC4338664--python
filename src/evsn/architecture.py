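"""Orchestration of the full feature-learning architecture.

Per 1 ms tick the system (one receptive field) runs:

1. analog update — fold the tick's events into the exponentially filtered
   per-cell activity and sample the normalized vector ``A(t_n)``;
2. scoring — compare ``A(t_n)`` with every predictor's pending one-step
   prediction (issued at the previous tick), yielding similarities and
   prediction errors;
3. gated winner-take-all — if the mean input activity exceeds the gate
   threshold, select the winner among non-inhibited channels;
4. predictability minimization — estimators guess the winner from the
   other channels' similarities; a correctly predicted winner is inhibited
   for ``t_inh`` so competitors can take over;
5. selective training — only the winner's readout receives an RLS update,
   pairing its stored regressor with the observed ``A(t_n)``; then all
   reservoirs advance on ``A(t_n)``, issuing predictions for the next tick.

Experiments present synthetic stimuli (oriented bars, jittered digits)
with noise-only pauses, in a learning phase (RLS enabled) optionally
followed by frozen test phases.  A bank trained on a central receptive
field can be tiled: copies with identical weights but independent states
and analog pipelines detect the learned features across a grid of
receptive fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .esn import ESNBank, ESNParams
from .events import EventStream, SensorModel
from .preprocessing import AnalogPipeline, CellGrid, ExponentialKernel, ReceptiveField
from .simulate import StimulusSpec, bar_projection, simulate_jittered_pattern, simulate_moving_bar, simulate_noise
from .wta_pm import NO_WINNER, OffsetController, PMPool, SigmoidGain, WTACircuit, gate, pm_step

__all__ = [
    "ArchitectureConfig",
    "Presentation",
    "ExperimentReport",
    "FeatureLearner",
    "MultiRFDetector",
    "train_step",
    "tile_receptive_fields",
    "run_experiment",
    "recruitment_report",
    "make_bar_spec",
    "orientation_schedule",
    "run_orientation_experiment",
    "digit_schedule",
]

DEFAULT_ORIENTATIONS = tuple(range(0, 180, 20))  # nine orientations, 20 deg apart


@dataclass(frozen=True)
class ArchitectureConfig:
    """Every tunable of the architecture, with the experiment-1 defaults."""

    # pool
    n_esns: int = 8
    n_reservoir: int = 15
    spectral_radius: float = 0.7
    w_in_range: float = 0.4
    w_back_range: float = 0.02
    w_out_range: float = 0.01
    forgetting: float = 0.999
    p_delta: float = 0.01
    # preprocessing
    cell_size: int = 5
    rf_half_extent: int = 8  # 17 x 17 cells
    tau_ms: float = 10.0
    dt_ms: float = 1.0
    # WTA / PM
    g_min: float = 5000.0
    g_max: float = 15000.0
    lambda_selectivity: float = 5.0e-5
    kp: float = 0.1
    controller_period_ms: float = 0.5
    t_inh_ms: float = 10.0
    gate_threshold: float = 0.01
    # sensor
    width: int = 128
    height: int = 128
    contrast_threshold: float = 0.14
    noise_rate: float = 0.5

    @property
    def sensor(self) -> SensorModel:
        return SensorModel(self.width, self.height, self.contrast_threshold, self.noise_rate)

    @property
    def dt_us(self) -> int:
        return int(round(self.dt_ms * 1000))

    def esn_params(self, input_dim: int) -> ESNParams:
        return ESNParams(
            n_reservoir=self.n_reservoir,
            input_dim=input_dim,
            spectral_radius=self.spectral_radius,
            w_in_range=self.w_in_range,
            w_back_range=self.w_back_range,
            w_out_range=self.w_out_range,
            forgetting=self.forgetting,
            p_delta=self.p_delta,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ArchitectureConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class Presentation:
    """One schedule entry: a stimulus (or a noise-only pause) and whether
    readout learning is enabled while it plays."""

    label: str
    spec: StimulusSpec | None
    duration_s: float
    learn: bool = True


@dataclass
class ExperimentReport:
    """Winner timeline, score traces and training statistics of one run."""

    dt_us: int
    t_us: np.ndarray          # (T,) tick sample times
    winners: np.ndarray       # (T,) winner index or NO_WINNER
    gated: np.ndarray         # (T,) bool
    errors: np.ndarray        # (T, N) prediction errors
    sims: np.ndarray          # (T, N) similarity scores
    inhibited: np.ndarray     # (T, N) bool, channel inhibited at tick
    counts: np.ndarray        # (N,) training samples per ESN
    intervals: pd.DataFrame   # label, t0_us, t1_us, learn

    @property
    def n_esns(self) -> int:
        return self.errors.shape[1]

    def winners_frame(self, rf_id: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_us": self.t_us, "rf_id": rf_id, "winner_index": self.winners,
             "gated": self.gated.astype(int)}
        )

    def modal_winner(self, t0_us: int, t1_us: int) -> int:
        """Most frequent winning channel among gated winning ticks in a window."""
        m = (self.t_us >= t0_us) & (self.t_us < t1_us) & (self.winners != NO_WINNER)
        if not m.any():
            return NO_WINNER
        return int(np.bincount(self.winners[m]).argmax())

    def interval_modal_winners(self) -> pd.DataFrame:
        """Modal winner per schedule interval (stimulus intervals only)."""
        rows = []
        for row in self.intervals.itertuples():
            if row.label.startswith("pause"):
                continue
            rows.append(
                {"label": row.label, "learn": row.learn,
                 "t0_us": row.t0_us, "t1_us": row.t1_us,
                 "winner": self.modal_winner(row.t0_us, row.t1_us)}
            )
        return pd.DataFrame(rows)

    def save(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.winners_frame().to_csv(out / "winners.csv", index=False)
        err = pd.DataFrame(self.errors, columns=[f"esn_{k}" for k in range(self.n_esns)])
        err.insert(0, "t_us", self.t_us)
        err.to_csv(out / "errors.csv", index=False)
        rec = pd.DataFrame({"esn": np.arange(self.n_esns), "training_samples": self.counts})
        rec["recruited"] = (self.counts > 0.01 * self.counts.sum()).astype(int)
        rec.to_csv(out / "recruitment.csv", index=False)
        self.intervals.to_csv(out / "intervals.csv", index=False)


class FeatureLearner:
    """The full single-receptive-field system, advanced tick by tick."""

    def __init__(self, config: ArchitectureConfig, seed,
                 rf: ReceptiveField | None = None):
        self.config = config
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        bank_ss, pm_ss = ss.spawn(2)
        self.grid = CellGrid(config.width, config.height, config.cell_size)
        self.rf = rf if rf is not None else ReceptiveField.centered(self.grid, config.rf_half_extent)
        kernel = ExponentialKernel(config.tau_ms * 1e-3)
        self.pipeline = AnalogPipeline(self.grid, self.rf, kernel)
        self.bank = ESNBank(config.esn_params(self.pipeline.dim), bank_ss, config.n_esns)
        self.wta = WTACircuit(
            config.n_esns,
            SigmoidGain(config.g_min, config.g_max, config.lambda_selectivity),
            OffsetController(config.kp, config.controller_period_ms * 1000),
            t_inh_us=config.t_inh_ms * 1000,
        )
        self.pm = PMPool(config.n_esns, pm_ss, n_reservoir=config.n_reservoir,
                         forgetting=config.forgetting, p_delta=config.p_delta)
        self.counts = np.zeros(config.n_esns, dtype=np.int64)
        self.learning = True
        self.t_us = 0
        self._records: list[dict] = []

    # -- one tick ------------------------------------------------------------

    def train_step(self, events: EventStream, t_us: int) -> dict:
        """Advance the system by one tick ending at ``t_us``; ``events`` must
        fall in ``(previous tick, t_us]``.  Returns the tick record."""
        idx = self.pipeline.local_indices(events.x, events.y)
        keep = idx >= 0
        return self._tick(events.t[keep], idx[keep], t_us)

    def _tick(self, ev_t: np.ndarray, ev_idx: np.ndarray, t_us: int) -> dict:
        cfg = self.config
        self.pipeline.state.update(t_us, ev_t, ev_idx)
        A = self.pipeline.sample()
        sims, errors = self.bank.scores(A)
        active = gate(A, cfg.gate_threshold)
        inhibited = self.wta.inhibited(t_us)
        winner = NO_WINNER
        if active:
            winner = self.wta.select(sims, t_us, cfg.dt_us)
            if winner != NO_WINNER:
                pm_step(self.pm, self.wta, sims, winner, t_us, train=self.learning)
                if self.learning:
                    self.bank.train_one(winner, A)
                    self.counts[winner] += 1
        self.bank.step(A)
        self.t_us = t_us
        return {"t_us": t_us, "winner": winner, "gated": active,
                "sims": sims, "errors": errors, "inhibited": inhibited}

    # -- stream segments -----------------------------------------------------

    def run_segment(self, stream: EventStream, duration_us: int,
                    record: list | None = None) -> None:
        """Run ticks over a stream segment whose local time starts at 0."""
        dt = self.config.dt_us
        t0 = self.t_us
        n_ticks = int(duration_us // dt)
        ev_t = stream.t + t0
        idx = self.pipeline.local_indices(stream.x, stream.y)
        keep = idx >= 0
        ev_t, idx = ev_t[keep], idx[keep]
        edges = t0 + dt * np.arange(n_ticks + 1, dtype=np.int64)
        bounds = np.searchsorted(ev_t, edges, side="right")
        for k in range(n_ticks):
            i0, i1 = bounds[k], bounds[k + 1]
            rec = self._tick(ev_t[i0:i1], idx[i0:i1], int(edges[k + 1]))
            if record is not None:
                record.append(rec)


def train_step(learner: FeatureLearner, events: EventStream, t_us: int) -> dict:
    """Functional wrapper around :meth:`FeatureLearner.train_step`."""
    return learner.train_step(events, t_us)


# -- stimulus schedules ------------------------------------------------------


def make_bar_spec(orientation_deg: float, duration_s: float,
                  sensor: SensorModel, speed_px_s: float | None = None,
                  start_offset_px: float = 0.0) -> StimulusSpec:
    """Bar stimulus whose traversal spans the field of view once per
    presentation unless an explicit speed is given."""
    spec = StimulusSpec("bar", duration_s=duration_s, orientation_deg=orientation_deg,
                        speed_px_s=1.0, start_offset_px=start_offset_px)
    if speed_px_s is None:
        proj = bar_projection(spec, sensor)
        travel = float(proj.max() - proj.min()) + spec.bar_width_px + 2.0
        speed_px_s = travel / duration_s
    return dataclasses.replace(spec, speed_px_s=speed_px_s)


def orientation_schedule(
    sensor: SensorModel,
    repetitions: int = 3,
    presentation_s: float = 1.0,
    pause_s: float = 0.5,
    orientations=DEFAULT_ORIENTATIONS,
    learn: bool = True,
    speed_scale: float = 1.0,
) -> list[Presentation]:
    """Oriented bars presented in fixed order, each followed by a pause."""
    out: list[Presentation] = []
    for rep in range(repetitions):
        for deg in orientations:
            spec = make_bar_spec(deg, presentation_s, sensor)
            if speed_scale != 1.0:
                spec = dataclasses.replace(
                    spec, speed_px_s=spec.speed_px_s * speed_scale,
                    duration_s=spec.duration_s / speed_scale,
                )
            out.append(Presentation(f"ori{deg}", spec, spec.duration_s, learn))
            if pause_s > 0:
                out.append(Presentation("pause", None, pause_s, learn))
    return out


def digit_schedule(
    digits: list[int],
    bitmaps: dict[int, np.ndarray],
    presentation_s: float = 5.0,
    pause_s: float = 3.0,
    jitter_amplitude_px: int = 2,
    jitter_rate_hz: float = 100.0,
    learn: bool = True,
) -> list[Presentation]:
    """Jittered digits presented in the given order with optional pauses."""
    out: list[Presentation] = []
    for d in digits:
        spec = StimulusSpec(
            "bitmap", duration_s=presentation_s, bitmap=bitmaps[d],
            jitter_amplitude_px=jitter_amplitude_px, jitter_rate_hz=jitter_rate_hz,
        )
        out.append(Presentation(f"digit{d}", spec, presentation_s, learn))
        if pause_s > 0:
            out.append(Presentation("pause", None, pause_s, learn))
    return out


# -- experiment runner -------------------------------------------------------


def _simulate_presentation(p: Presentation, sensor: SensorModel, rng) -> EventStream:
    if p.spec is None:
        return simulate_noise(sensor, p.duration_s, rng)
    if p.spec.kind == "bar":
        return simulate_moving_bar(p.spec, sensor, rng)
    return simulate_jittered_pattern(p.spec, sensor, rng)


def run_experiment(
    config: ArchitectureConfig,
    schedule: list[Presentation],
    seed: int,
    learner: FeatureLearner | None = None,
) -> tuple[ExperimentReport, FeatureLearner]:
    """Simulate the schedule's stimuli and run the training loop over them.

    Deterministic per seed: one child seed drives the learner's random
    weights, one drives each presentation's stimulus/noise draw.  An
    existing learner can be passed to continue a run (e.g. frozen test
    phases after learning).
    """
    ss = np.random.SeedSequence(seed)
    learner_ss, stim_ss = ss.spawn(2)
    if learner is None:
        learner = FeatureLearner(config, learner_ss)
    sensor = config.sensor
    stim_children = stim_ss.spawn(len(schedule))
    records: list[dict] = []
    intervals = []
    for p, child in zip(schedule, stim_children):
        rng = np.random.default_rng(child)
        stream = _simulate_presentation(p, sensor, rng)
        t0 = learner.t_us
        learner.learning = p.learn
        learner.run_segment(stream, int(p.duration_s * 1e6), records)
        intervals.append({"label": p.label, "t0_us": t0, "t1_us": learner.t_us,
                          "learn": p.learn})
    report = ExperimentReport(
        dt_us=config.dt_us,
        t_us=np.array([r["t_us"] for r in records], dtype=np.int64),
        winners=np.array([r["winner"] for r in records], dtype=np.int32),
        gated=np.array([r["gated"] for r in records], dtype=bool),
        errors=np.stack([r["errors"] for r in records]) if records else np.empty((0, config.n_esns)),
        sims=np.stack([r["sims"] for r in records]) if records else np.empty((0, config.n_esns)),
        inhibited=np.stack([r["inhibited"] for r in records]) if records else np.empty((0, config.n_esns), bool),
        counts=learner.counts.copy(),
        intervals=pd.DataFrame(intervals),
    )
    return report, learner


def run_orientation_experiment(
    config: ArchitectureConfig,
    seed: int,
    repetitions: int = 3,
    presentation_s: float = 1.0,
    pause_s: float = 0.5,
    test_repetitions: int = 0,
    orientations=DEFAULT_ORIENTATIONS,
) -> tuple[ExperimentReport, FeatureLearner]:
    """Learning phase on repeated oriented-bar presentations, optionally
    followed by frozen (no-RLS) test presentations of the same stimuli."""
    sensor = config.sensor
    schedule = orientation_schedule(sensor, repetitions, presentation_s, pause_s,
                                    orientations, learn=True)
    if test_repetitions:
        schedule += orientation_schedule(sensor, test_repetitions, presentation_s,
                                         pause_s, orientations, learn=False)
    return run_experiment(config, schedule, seed)


def recruitment_report(report: ExperimentReport) -> tuple[int, np.ndarray]:
    """Recruited-ESN count: networks whose training-sample count exceeds 1%
    of all gated training ticks."""
    total = report.counts.sum()
    mask = report.counts > 0.01 * total
    return int(mask.sum()), mask


# -- multi-receptive-field tiling --------------------------------------------


class MultiRFDetector:
    """Grid of detector banks sharing one set of trained weights.

    Each receptive field gets an independent copy of the trained bank
    (identical weights, fresh states), its own analog pipeline and its own
    WTA circuit; readouts are frozen (inference only, no predictability
    minimization).  Per tick, each RF emits a winner only when its gate is
    active.
    """

    def __init__(self, config: ArchitectureConfig, trained_bank: ESNBank,
                 rfs: list[ReceptiveField]):
        self.config = config
        self.grid = CellGrid(config.width, config.height, config.cell_size)
        half = (config.rf_half_extent, config.rf_half_extent)
        for rf in rfs:
            if (rf.half_extent_cols, rf.half_extent_rows) != half:
                raise ValueError("receptive-field grid not congruent with the trained RF")
        kernel = ExponentialKernel(config.tau_ms * 1e-3)
        self.rfs = rfs
        self.pipelines = [AnalogPipeline(self.grid, rf, kernel) for rf in rfs]
        self.banks = [trained_bank.copy() for _ in rfs]
        for b in self.banks:
            b.reset_states()
        self.wtas = [
            WTACircuit(config.n_esns,
                       SigmoidGain(config.g_min, config.g_max, config.lambda_selectivity),
                       OffsetController(config.kp, config.controller_period_ms * 1000),
                       t_inh_us=config.t_inh_ms * 1000)
            for _ in rfs
        ]
        self.t_us = 0

    def run(self, stream: EventStream, duration_us: int) -> pd.DataFrame:
        """Inference over a stream; returns per-tick winners for every RF."""
        dt = self.config.dt_us
        n_ticks = int(duration_us // dt)
        cfg = self.config
        per_rf = []
        for pipe in self.pipelines:
            idx = pipe.local_indices(stream.x, stream.y)
            keep = idx >= 0
            ev_t = stream.t[keep] + self.t_us
            edges = self.t_us + dt * np.arange(n_ticks + 1, dtype=np.int64)
            bounds = np.searchsorted(ev_t, edges, side="right")
            per_rf.append((ev_t, idx[keep], bounds, edges))
        rows = []
        for k in range(n_ticks):
            for rf_id, (pipe, bank, wta) in enumerate(zip(self.pipelines, self.banks, self.wtas)):
                ev_t, idx, bounds, edges = per_rf[rf_id]
                t_us = int(edges[k + 1])
                pipe.state.update(t_us, ev_t[bounds[k]:bounds[k + 1]], idx[bounds[k]:bounds[k + 1]])
                A = pipe.sample()
                sims, _ = bank.scores(A)
                winner = NO_WINNER
                if gate(A, cfg.gate_threshold):
                    winner = wta.select(sims, t_us, cfg.dt_us)
                bank.step(A)
                rows.append((t_us, rf_id, winner))
        self.t_us += n_ticks * dt
        return pd.DataFrame(rows, columns=["t_us", "rf_id", "winner_index"])


def tile_receptive_fields(
    config: ArchitectureConfig,
    trained_bank: ESNBank,
    n_rows: int = 3,
    n_cols: int = 3,
) -> MultiRFDetector:
    """Tile an ``n_rows x n_cols`` grid of receptive fields, congruent with
    the trained geometry, across the centre of the cell grid."""
    grid = CellGrid(config.width, config.height, config.cell_size)
    pitch = 2 * config.rf_half_extent + 1
    used_c, used_r = n_cols * pitch, n_rows * pitch
    if used_c > grid.n_cols or used_r > grid.n_rows:
        raise ValueError("receptive-field grid does not fit the sensor")
    c0 = (grid.n_cols - used_c) // 2
    r0 = (grid.n_rows - used_r) // 2
    rfs = [
        ReceptiveField(c0 + j * pitch + config.rf_half_extent,
                       r0 + i * pitch + config.rf_half_extent,
                       config.rf_half_extent, config.rf_half_extent)
        for i in range(n_rows) for j in range(n_cols)
    ]
    return MultiRFDetector(config, trained_bank, rfs)
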