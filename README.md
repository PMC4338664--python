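# evsn — unsupervised spatiotemporal features for event-based vision

`evsn` learns and detects dynamic visual features from the output of an
event camera (DVS-style silicon retina).  Instead of frames, such sensors
emit an asynchronous stream of address events `(t, x, y, p)` whenever a
pixel's log-luminance changes by more than a contrast threshold ΔI (~15%),
with microsecond timing.  The package implements a competitive
predictive architecture for this input, plus a full sensor emulator so the
system can be exercised without hardware:

1. **Preprocessing** — pixels are pooled into cells, a receptive field (RF)
   of cells is filtered with a causal exponential kernel
   G(t, tᵢ) = e^−(t−tᵢ)/τ (τ = 10 ms), producing an analog vector **A**(t)
   normalized to [0, 1], sampled every 1 ms.
2. **Prediction** — a pool of N echo-state networks (ESNs; 15 logistic
   neurons, spectral radius 0.7, fixed random weights, linear readout)
   each predicts **Â**(t+dt).  Readouts are trained online by recursive
   least squares (RLS).  Prediction quality is scored by
   S_k = Σᵢ|Aᵢ·Âᵢ| / (Σᵢ|Aᵢ|·Σᵢ|Âᵢ|) ∈ [0, 1].
3. **Selection** — similarities drive a spiking winner-take-all: a sigmoid
   gain (5–15 kHz range, selectivity 5·10⁻⁵, offset servoed onto the
   winner by a 0.5 ms proportional controller) feeds non-leaky
   integrate-and-fire neurons with global inhibition; only the best
   predictor fires, and only it receives an RLS update ("winner trains").
   An input-activity gate silences the circuit without stimulation.
4. **Predictability minimization** — per channel, an estimator network
   guesses the winner from the *other* channels' similarities; a winner
   its own estimator can predict is redundant and is inhibited for 10 ms,
   forcing competitors to take over and the pool to learn non-overlapping
   features.

The result is fully unsupervised specialization: distinct moving-bar
orientations (or jittered digit shapes) each recruit their own predictor,
and a surplus pool recruits only as many networks as there are features.

The emulator (`evsn.simulate`) renders log-luminance movies of moving
oriented bars and randomly jittered bitmaps, converts them to events by
per-pixel threshold crossing with interpolated µs timestamps, and adds
Poisson background noise.  Streams round-trip through a plain CSV dialect
(`t_us,x,y,p`).

## Worked example

```bash
python examples/05_orientation_learning.py
```

```
orientation -> modal winning ESN (frozen test phase):
     ori0: ESN 3
    ori60: ESN 4
   ori120: ESN 1
training samples per ESN: [1192, 788, 816, 556, 508, 0, 0, 3]
recruited (count > 1% of gated training ticks): 5
```

Three bar orientations were presented twice each to a pool of eight
predictors; in the frozen test phase each orientation is detected by a
stable, distinct ESN.  The training-sample counts show the winner-take-all
concentrating learning on a subset of the pool (three specialists plus two
networks that absorbed transition ticks); the remaining networks stay
untrained and available.  `examples/01–04` demonstrate the individual
stages (sensor emulation, analog conversion, ESN prediction, spiking
selection) in isolation.

A thin CLI wraps the same machinery:

```bash
evsn simulate --stimulus bar --orientation 40 --out events.csv
evsn train --events events.csv --out run/
evsn report run/
```

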