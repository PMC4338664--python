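"""DVS emulator: log-luminance movies to address events, plus stimuli.

The sensor model follows the change-detector principle of an event camera:
each pixel remembers the log-luminance level at its last emitted event and
fires one ON (OFF) event every time the current level exceeds (falls below)
that reference by the contrast threshold ``dI``.  Event times are obtained
by linear interpolation between movie frames, so a fine rendering grid
(default 0.1 ms) yields microsecond-resolution timestamps.

Two stimulus generators emulate the recorded scenes used to train the
feature-learning architecture: an oriented bar translating at constant
speed across the field of view, and a static bitmap (e.g. a digit) animated
by random jitter around a central position, mimicking microsaccades.
Both render a high-contrast log-luminance movie and push it through the
same threshold-crossing converter, then merge Poisson background noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .events import EventStream, SensorModel

__all__ = [
    "StimulusSpec",
    "ThresholdCrossingConverter",
    "luminance_to_events",
    "simulate_moving_bar",
    "simulate_jittered_pattern",
    "simulate_noise",
]

#: movie frame period used when rendering stimuli (10x finer than the 1 ms tick)
FRAME_DT_US = 100

#: stimulus contrast in units of the contrast threshold; a passing edge thus
#: emits a burst of this many events per pixel
CONTRAST_STEPS = 10


@dataclass(frozen=True)
class StimulusSpec:
    """Description of one stimulus presentation.

    ``kind`` selects the generator: ``"bar"`` (translating oriented bar) or
    ``"bitmap"`` (jittered binary pattern).  ``orientation_deg`` is the
    bar's axis; the bar translates along its normal at ``speed_px_s``.
    ``start_offset_px`` shifts the bar's starting position along the normal
    (0 = just outside the field of view).  For bitmaps, the pattern jumps
    to a uniformly drawn integer offset within ``jitter_amplitude_px``
    (Chebyshev) of the centre, ``jitter_rate_hz`` times per second.
    """

    kind: str
    duration_s: float = 1.0
    orientation_deg: float = 0.0
    speed_px_s: float = 0.0
    bar_width_px: float = 3.0
    start_offset_px: float = 0.0
    bitmap: np.ndarray | None = None
    jitter_amplitude_px: int = 0
    jitter_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("bar", "bitmap"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.speed_px_s < 0 or self.jitter_amplitude_px < 0:
            raise ValueError("speed and jitter amplitude must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


class ThresholdCrossingConverter:
    """Stateful log-luminance -> event converter for one sensor.

    Holds the per-pixel reference level (log-luminance at the last emitted
    event) so a long movie can be processed in chunks, optionally restricted
    to the subset of pixels that can change during the chunk.  Pixels are
    initialised at the first luminance value they are seen with, so the
    initial appearance of a static scene emits nothing.
    """

    def __init__(self, sensor: SensorModel):
        self.sensor = sensor
        self._ref = np.zeros(sensor.n_pixels)
        self._seen = np.zeros(sensor.n_pixels, dtype=bool)

    def process(
        self,
        frames: np.ndarray,
        times_us: np.ndarray,
        flat_idx: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Convert a chunk of frames; returns ``(t_us, flat_pixel, polarity)``.

        ``frames`` has shape ``(F, P)`` where ``P`` is either the full pixel
        count (``flat_idx is None``) or the length of ``flat_idx``, the flat
        indices of the pixels covered.  ``times_us`` gives each frame's
        timestamp.  The first frame of the first chunk touching a pixel only
        sets its reference.
        """
        frames = np.asarray(frames, dtype=np.float64)
        times_us = np.asarray(times_us, dtype=np.int64)
        if frames.ndim != 2 or frames.shape[0] != len(times_us):
            raise ValueError("frames must be (F, P) with one timestamp per frame")
        if not np.all(np.isfinite(frames)):
            raise ValueError("log-luminance must be finite")
        if flat_idx is None:
            flat_idx = np.arange(self.sensor.n_pixels)
        dI = self.sensor.contrast_threshold

        ref = self._ref[flat_idx]
        fresh = ~self._seen[flat_idx]
        ref[fresh] = frames[0, fresh]
        self._seen[flat_idx] = True

        out_t: list[np.ndarray] = []
        out_pix: list[np.ndarray] = []
        out_pol: list[np.ndarray] = []
        for i in range(1, frames.shape[0]):
            v1 = frames[i]
            d = v1 - ref
            hit = np.flatnonzero(np.abs(d) >= dI * (1 - 1e-9))
            if hit.size == 0:
                continue
            dh = d[hit]
            sign = np.sign(dh)
            n = np.floor(np.abs(dh) / dI + 1e-9).astype(np.int64)
            total = int(n.sum())
            rep = np.repeat(np.arange(hit.size), n)
            # m-th crossing level above/below the reference, m = 1..n
            m = np.arange(total) - np.repeat(np.cumsum(n) - n, n) + 1
            levels = ref[hit][rep] + m * dI * sign[rep]
            v0 = frames[i - 1]
            dv = v1[hit][rep] - v0[hit][rep]
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(dv != 0, (levels - v0[hit][rep]) / dv, 1.0)
            frac = np.clip(frac, 0.0, 1.0)
            t0, t1 = times_us[i - 1], times_us[i]
            out_t.append((t0 + frac * (t1 - t0)).astype(np.int64))
            out_pix.append(flat_idx[hit][rep])
            out_pol.append(sign[rep].astype(np.int8))
            ref[hit] += n * dI * sign
        self._ref[flat_idx] = ref
        if not out_t:
            z = np.empty(0, dtype=np.int64)
            return z, z.copy(), np.empty(0, dtype=np.int8)
        return np.concatenate(out_t), np.concatenate(out_pix), np.concatenate(out_pol)


def _to_stream(sensor, t, pix, pol) -> EventStream:
    order = np.argsort(t, kind="stable")
    t, pix, pol = t[order], pix[order], pol[order]
    return EventStream(
        t, pix % sensor.width, pix // sensor.width, pol,
        sensor.width, sensor.height, validate=False,
    )


def luminance_to_events(
    movie: np.ndarray,
    sensor: SensorModel,
    frame_dt_us: int = FRAME_DT_US,
    t0_us: int = 0,
) -> EventStream:
    """Convert a log-luminance movie ``(F, H, W)`` into an event stream.

    One event is emitted per contrast-threshold crossing of the log-luminance
    relative to the level at the pixel's last event: ON for increases, OFF
    for decreases.  Crossing times are linearly interpolated between frames
    and rounded to integer microseconds.  Non-finite input is rejected.
    """
    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim != 3 or movie.shape[1:] != (sensor.height, sensor.width):
        raise ValueError(f"movie must be (F, {sensor.height}, {sensor.width})")
    conv = ThresholdCrossingConverter(sensor)
    times = t0_us + frame_dt_us * np.arange(movie.shape[0], dtype=np.int64)
    t, pix, pol = conv.process(movie.reshape(movie.shape[0], -1), times)
    return _to_stream(sensor, t, pix, pol)


def simulate_noise(
    sensor: SensorModel, duration_s: float, rng: np.random.Generator
) -> EventStream:
    """Stationary Poisson background activity, polarity balanced."""
    mean = sensor.noise_rate * sensor.n_pixels * duration_s
    n = int(rng.poisson(mean))
    t = np.sort(rng.integers(0, max(int(duration_s * 1e6), 1), size=n))
    x = rng.integers(0, sensor.width, size=n)
    y = rng.integers(0, sensor.height, size=n)
    p = rng.choice(np.array([-1, 1], dtype=np.int8), size=n)
    return EventStream(t, x, y, p, sensor.width, sensor.height, validate=False)


def _with_noise(signal: EventStream, sensor, duration_s, rng) -> EventStream:
    if sensor.noise_rate == 0:
        return signal
    return EventStream.merge([signal, simulate_noise(sensor, duration_s, rng)])


def bar_projection(spec: StimulusSpec, sensor: SensorModel) -> np.ndarray:
    """Signed pixel coordinate along the bar's translation normal (flat)."""
    phi = math.radians(spec.orientation_deg + 90.0)
    xs = np.arange(sensor.width)
    ys = np.arange(sensor.height)
    X, Y = np.meshgrid(xs, ys)
    return (X * math.cos(phi) + Y * math.sin(phi)).ravel()


def bar_support(spec: StimulusSpec, sensor: SensorModel) -> tuple[float, float]:
    """Interval swept by the bar's centre line over the presentation."""
    proj = bar_projection(spec, sensor)
    s_start = proj.min() - spec.bar_width_px / 2 - 1.0 + spec.start_offset_px
    return s_start, s_start + spec.speed_px_s * spec.duration_s


def simulate_moving_bar(
    spec: StimulusSpec, sensor: SensorModel, seed: int | np.random.Generator
) -> EventStream:
    """Events from a high-contrast bar translating across the field of view.

    The bar is rendered as a log-luminance movie (stripe of width
    ``bar_width_px`` and contrast ``CONTRAST_STEPS * dI``) on a
    ``FRAME_DT_US`` grid and converted with the threshold-crossing model;
    Poisson background noise is merged in.  Deterministic per seed.
    """
    if spec.kind != "bar":
        raise ValueError("spec.kind must be 'bar'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    proj = bar_projection(spec, sensor)
    hw = spec.bar_width_px / 2
    amp = CONTRAST_STEPS * sensor.contrast_threshold
    s0, _ = bar_support(spec, sensor)
    n_frames = int(round(spec.duration_s * 1e6 / FRAME_DT_US))
    conv = ThresholdCrossingConverter(sensor)
    out: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    chunk = 500  # frames per chunk (50 ms)
    start = 0
    while start < n_frames:
        stop = min(start + chunk, n_frames)
        f_lo = max(start - 1, 0)  # re-feed last frame so chunk joins are seamless
        times = FRAME_DT_US * np.arange(f_lo, stop, dtype=np.int64)
        s_t = s0 + spec.speed_px_s * (times * 1e-6)
        idx = np.flatnonzero(
            (proj >= s_t.min() - hw - 1.0) & (proj <= s_t.max() + hw + 1.0)
        )
        if idx.size:
            frames = amp * (np.abs(proj[idx][None, :] - s_t[:, None]) <= hw)
            out.append(conv.process(frames, times, idx))
        start = stop
    if out:
        t = np.concatenate([o[0] for o in out])
        pix = np.concatenate([o[1] for o in out])
        pol = np.concatenate([o[2] for o in out])
    else:
        t = pix = np.empty(0, dtype=np.int64)
        pol = np.empty(0, dtype=np.int8)
    signal = _to_stream(sensor, t, pix, pol)
    return _with_noise(signal, sensor, spec.duration_s, rng)


def simulate_jittered_pattern(
    spec: StimulusSpec, sensor: SensorModel, seed: int | np.random.Generator
) -> EventStream:
    """Events from a binary pattern jittering around the sensor centre.

    The bitmap jumps to a new uniformly drawn integer offset (Chebyshev
    radius ``jitter_amplitude_px``) ``jitter_rate_hz`` times per second;
    each jump is rendered as a luminance step and converted to events.
    With zero amplitude the scene is static and only noise is emitted.
    """
    if spec.kind != "bitmap":
        raise ValueError("spec.kind must be 'bitmap'")
    if spec.bitmap is None:
        raise ValueError("bitmap stimulus needs a bitmap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bmp = np.asarray(spec.bitmap, dtype=bool)
    bh, bw = bmp.shape
    a = spec.jitter_amplitude_px
    if bh + 2 * a > sensor.height or bw + 2 * a > sensor.width:
        raise ValueError("bitmap (plus jitter) larger than sensor")
    amp = CONTRAST_STEPS * sensor.contrast_threshold
    y0 = (sensor.height - bh) // 2
    x0 = (sensor.width - bw) // 2

    def render(off: tuple[int, int]) -> np.ndarray:
        lum = np.zeros((sensor.height, sensor.width))
        oy, ox = off
        lum[y0 + oy : y0 + oy + bh, x0 + ox : x0 + ox + bw] = amp * bmp
        return lum.ravel()

    conv = ThresholdCrossingConverter(sensor)
    cur = (0, 0)
    cur_lum = render(cur)
    conv.process(cur_lum[None, :], np.array([0], dtype=np.int64))  # set references
    out = []
    n_jumps = int(spec.duration_s * spec.jitter_rate_hz)
    period_us = 1e6 / spec.jitter_rate_hz if spec.jitter_rate_hz > 0 else 0
    for k in range(1, n_jumps + 1):
        nxt = tuple(rng.integers(-a, a + 1, size=2)) if a > 0 else (0, 0)
        if nxt == cur:
            continue
        new_lum = render(nxt)
        idx = np.flatnonzero(new_lum != cur_lum)
        t_jump = int(k * period_us)
        times = np.array([t_jump - FRAME_DT_US, t_jump], dtype=np.int64)
        out.append(conv.process(np.stack([cur_lum[idx], new_lum[idx]]), times, idx))
        cur, cur_lum = nxt, new_lum
    if out:
        t = np.concatenate([o[0] for o in out])
        pix = np.concatenate([o[1] for o in out])
        pol = np.concatenate([o[2] for o in out])
    else:
        t = pix = np.empty(0, dtype=np.int64)
        pol = np.empty(0, dtype=np.int8)
    signal = _to_stream(sensor, t, pix, pol)
    return _with_noise(signal, sensor, spec.duration_s, rng)
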