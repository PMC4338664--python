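# Methods

## Sensor model and synthetic stimuli

Each pixel of the emulated event camera holds the log-luminance level at
its last emitted event and fires one ON (+1) or OFF (−1) event per
crossing of ±ΔI relative to that level.  Stimulus movies are rendered on a
0.1 ms frame grid — ten times finer than the 1 ms processing tick — and
crossing times are linearly interpolated between frames, then rounded to
integer microseconds.  ΔI defaults to 0.14 ≈ ln(1.15), i.e. ~15% relative
contrast.  Background activity is modelled as a stationary Poisson process
per pixel with balanced polarity; the default 0.5 events/pixel/s is a
typical quiet-scene rate for a 128×128 DVS.  Coordinates are 0-based and
half-open; timestamps are non-negative, non-decreasing integer µs.

Two stimulus classes emulate the training scenes:

* **Moving bar** — a stripe 3 px wide at orientation θ, contrast 10·ΔI,
  translating along its normal at constant speed.  The high contrast makes
  each edge emit a burst of 10 events per swept pixel, as a real
  high-contrast edge does.  Experiment helpers choose the speed so one
  traversal of the field of view fits the presentation window (≈264 px/s
  for a 1 s presentation on 128×128).
* **Jittered bitmap** — a binary pattern (seven-segment digits 1–9 are
  provided) that jumps to a uniformly drawn integer offset within a
  Chebyshev radius (default 2 px) of the centre at a fixed rate (default
  100/s), emulating microsaccade-like motion that makes static shapes
  visible to a change-driven sensor.

What the generator does *not* model: pixel latency, refractory periods,
hot pixels, per-pixel threshold mismatch, and photometric detail.  Passing
tests therefore demonstrate the architecture's behaviour under idealized
event statistics with realistic rates and timing, not robustness to every
real-sensor artifact.

## Preprocessing

Pixels are tiled into non-overlapping s×s cells (s = 5 for the single-RF
experiments, s = 3 for the multi-RF tiling), anchored at the top-left;
remainder pixels are unassigned and dropped.  A receptive field is a
(2Δ+1)×(2Δ+1) block of cells (17×17 = 289 components by default).  Events
are pooled per cell — polarity is not used — and filtered with the causal
exponential kernel, one trace per cell, updated incrementally: decay by
e^−(t−t′)/τ plus one kernel term per new event, which is algebraically
identical to re-summing the kernel over the whole event history (verified
to 1e−12 relative error against a direct summation).  The sampled vector
is divided by the running maximum component observed in the RF, floored
at 1 so silence is never amplified; components then lie in [0, 1].  The
running maximum stabilizes within the first presentation, after which the
normalization is effectively fixed.

## Predictors

Each ESN has reservoir matrix W_r (uniform draw rescaled to spectral
radius exactly 0.7, satisfying the echo-state property), input weights
uniform in [−0.4, 0.4], feedback weights in [−0.02, 0.02] and initial
readout in [−0.01, 0.01], all 64-bit floats.  State update:
s(tₙ) = logistic(W_r s(tₙ₋₁) + W_in **A**(tₙ) + W_back out(tₙ₋₁)); the
linear readout of the new state is the one-step-ahead prediction.  The
readout is the only trained matrix.  Feedback carries the network's own
output (free-running), not a teacher-forced target.

RLS uses exponential forgetting λ = 0.999 and inverse-correlation matrix
initialized to (1/δ)·I with δ = 0.01; all output dimensions share one
gain vector since they regress on the same state.  With λ = 1 the
recursion reproduces batch ridge regression with penalty δ exactly
(verified to 1e−8).  If the P matrix loses positive-definiteness
numerically it is reinitialized with a warning.  The prediction error is
the Euclidean norm of the residual; the similarity score is computed in
the scale-invariant form Σ(aᵢ/Σa)(bᵢ/Σb) to avoid underflow.

## Selection circuit

The sigmoid gain maps similarities to currents in [5, 15] kHz; with IF
threshold 1 the firing rate equals the current, so the circuit's output
spans 5–15 kHz.  Selectivity is 5·10⁻⁵, which makes the gain nearly a
comparator around the adaptive offset x₀.  The offset is a proportional
controller (gain 0.1 per 0.5 ms period, two periods per tick, clamped to
[0, 1]) that tracks the winning similarity, so discrimination is sharpest
at the current operating point.  Because the gain saturates in floating
point, channels far from x₀ can carry bit-identical currents; such ties
resolve deterministically toward the lowest channel index.  This gives
transition windows (after a stimulus switch, while x₀ re-converges) a
low-index bias that concentrates transient training on channel 0 — a
deliberate determinism choice; resolving ties by the underlying similarity
instead spreads transient training across the pool and roughly doubles the
number of weakly recruited networks.

The winner is evaluated once per 1 ms tick by exact continuous-time
simulation of the non-leaky IF race with global reset (equivalent to an
argmax over non-inhibited channels, fuzz-verified).  A gate keeps the
circuit silent when the mean analog component is ≤ 0.01; gated-off ticks
produce no winner, no learning and no estimator updates.

Predictability minimization gives each channel an estimator ESN (same
reservoir size) whose input is the N−1 other similarities and whose
N-dimensional readout is RLS-trained toward the one-hot winner on every
gated tick.  If the winner's own estimator currently guesses the winner,
the winner is inhibited for T_inh = 10 ms (it cannot win while inhibited;
selection passes to the next-best channel).  Inhibition durations of
5–20 ms behave qualitatively alike; 5 ms measurably under-recruits a
surplus pool, so 10 ms is the default.

## Orchestration and experiments

Per tick: analog update and sampling; scoring of the predictions issued at
the previous tick; gated winner selection; predictability-minimization
step; RLS update of the winner's readout only, pairing its stored
regressor with the observed **A**(tₙ); then all reservoirs advance.
Training-sample counts increment only on gated winning ticks with learning
enabled; test phases run with frozen readouts and estimators.  A network
is *recruited* when its training-sample count exceeds 1% of all gated
training ticks.

Experiment runners present oriented bars (9 orientations, 0°–160° in 20°
steps) or jittered digits with noise-only pauses.  Runs are deterministic
per seed: one seed stream drives the network initialisations, one child
seed per presentation drives the stimulus and noise draws.  Presentations
are scaled to 1 s with 0.5 s pauses (the tick count shrinks, not the
dynamics); full-length presentations are a parameter away.

Multi-RF tiling copies the weights of a bank trained on the central RF to
a 3×3 grid of congruent RFs; each copy keeps independent state, analog
pipeline and WTA circuit and runs inference-only (no RLS, no
predictability minimization).  Winners are reported only where the local
gate is open.

## Measured behaviour and known limitations

* A pool of 20 ESNs trained on 9 orientations recruits 9 networks in the
  modal case, matching the intended "only as many as there are features"
  behaviour; across seeds the count varies between 8 and 11 (distribution
  over 15 seeds: one 8, eight 9s, five 10s, one 11) because two networks
  occasionally share one orientation at the scaled presentation length.
* With 8 ESNs and 9 orientations, the orientation→winner map in frozen
  test phases is stable for at least 8 of 9 orientations, and at least one
  network covers two orientations.
* The winner has the minimal prediction error among non-inhibited networks
  on ≈88–90% of gated ticks; the shortfall from 100% consists almost
  entirely of near-ties (winner error within ~5% of the minimum) plus the
  low-index saturation bias described above.
* During noise-only gaps the prediction errors do **not** fall to ~10% of
  their stimulated-period medians: with the logistic state nonlinearity
  the undriven reservoir settles near 0.5 per component, and because
  learning is gated off without input, readouts are never fitted at that
  baseline; gap errors are ~40–70% of stimulated medians.  Quenching them
  requires training during ungated ticks, which rotates gap training over
  the whole pool and destroys the surplus-pool recruitment behaviour —
  the two behaviours are mutually exclusive in this design, and the
  recruitment behaviour was kept.
* A single repeated feature is shared across a small pool rather than
  committed to one network: a lone specialist is perfectly predictable by
  its estimator and is therefore inhibited regularly.  This is the same
  mechanism that suppresses duplicated channels, operating as designed.
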