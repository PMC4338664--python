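"""Address-event data model and canonical CSV I/O.

A DVS-style sensor reports visual change as an asynchronous stream of
*address events*: tuples ``(t, x, y, p)`` where ``t`` is a microsecond
timestamp, ``(x, y)`` a pixel address and ``p`` the polarity (+1 for a
log-luminance increase, -1 for a decrease).  :class:`EventStream` is the
package's only raw-input container; everything downstream consumes it.

The canonical on-disk form is a UTF-8 CSV with header ``t_us,x,y,p`` and
rows sorted by timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "EventStream",
    "SensorModel",
    "EventStreamError",
    "EventFileError",
    "read_events",
    "write_events",
]


class EventStreamError(ValueError):
    """A stream violates the address-event invariants."""


class EventFileError(EventStreamError):
    """A canonical event file failed to parse or validate."""


class Event(NamedTuple):
    """A single address event (timestamp in µs, pixel address, polarity)."""

    t: int
    x: int
    y: int
    p: int


@dataclass(frozen=True)
class SensorModel:
    """Geometry and physics of the emulated event camera.

    Parameters
    ----------
    width, height:
        Pixel-array size (128 x 128 for a DVS128).
    contrast_threshold:
        Log-luminance step ``dI`` that triggers one event.  The default,
        0.14 ~ ln(1.15), corresponds to ~15% relative contrast.
    noise_rate:
        Stationary background-activity rate, events per pixel per second,
        polarity balanced.
    """

    width: int = 128
    height: int = 128
    contrast_threshold: float = 0.14
    noise_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("sensor must have at least one pixel")
        if not self.contrast_threshold > 0:
            raise ValueError("contrast_threshold must be positive")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.width * self.height


class EventStream:
    """Time-ordered sequence of address events with sensor geometry.

    Coordinates are 0-based and half-open: ``0 <= x < width``,
    ``0 <= y < height``.  Timestamps are non-negative integer microseconds
    and non-decreasing.
    """

    __slots__ = ("t", "x", "y", "p", "width", "height")

    def __init__(self, t, x, y, p, width: int, height: int, validate: bool = True):
        self.t = np.asarray(t, dtype=np.int64)
        self.x = np.asarray(x, dtype=np.int32)
        self.y = np.asarray(y, dtype=np.int32)
        self.p = np.asarray(p, dtype=np.int8)
        self.width = int(width)
        self.height = int(height)
        if validate:
            self._validate()

    def _validate(self) -> None:
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.p) == n):
            raise EventStreamError("t, x, y, p must have equal length")
        if n == 0:
            return
        if self.t[0] < 0:
            raise EventStreamError("timestamps must be non-negative")
        if np.any(np.diff(self.t) < 0):
            raise EventStreamError("timestamps must be non-decreasing")
        if np.any((self.x < 0) | (self.x >= self.width)):
            raise EventStreamError("x out of range [0, width)")
        if np.any((self.y < 0) | (self.y >= self.height)):
            raise EventStreamError("y out of range [0, height)")
        if np.any(np.abs(self.p) != 1):
            raise EventStreamError("polarity must be +1 or -1")

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.t)

    def __iter__(self) -> Iterator[Event]:
        for i in range(len(self)):
            yield Event(int(self.t[i]), int(self.x[i]), int(self.y[i]), int(self.p[i]))

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventStream):
            return NotImplemented
        return (
            self.width == other.width
            and self.height == other.height
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.p, other.p)
        )

    def __repr__(self) -> str:
        span = f"[{self.t[0]}, {self.t[-1]}] us" if len(self) else "empty"
        return f"EventStream({len(self)} events, {self.width}x{self.height}, {span})"

    # -- constructors -------------------------------------------------------

    @classmethod
    def empty(cls, width: int, height: int) -> "EventStream":
        z = np.empty(0, dtype=np.int64)
        return cls(z, z, z, z, width, height, validate=False)

    @classmethod
    def merge(cls, streams: list["EventStream"]) -> "EventStream":
        """Merge streams on one sensor into a single time-sorted stream."""
        streams = [s for s in streams if s is not None]
        if not streams:
            raise ValueError("nothing to merge")
        w, h = streams[0].width, streams[0].height
        if any(s.width != w or s.height != h for s in streams):
            raise EventStreamError("cannot merge streams with different geometry")
        t = np.concatenate([s.t for s in streams])
        x = np.concatenate([s.x for s in streams])
        y = np.concatenate([s.y for s in streams])
        p = np.concatenate([s.p for s in streams])
        order = np.argsort(t, kind="stable")
        return cls(t[order], x[order], y[order], p[order], w, h, validate=False)

    # -- views --------------------------------------------------------------

    def slice(self, t0: int, t1: int) -> "EventStream":
        """Events with ``t0 <= t < t1`` (no copy of geometry)."""
        i0 = np.searchsorted(self.t, t0, side="left")
        i1 = np.searchsorted(self.t, t1, side="left")
        return EventStream(
            self.t[i0:i1], self.x[i0:i1], self.y[i0:i1], self.p[i0:i1],
            self.width, self.height, validate=False,
        )

    def shifted(self, dt_us: int = 0, dx: int = 0, dy: int = 0) -> "EventStream":
        """Stream translated in time and/or space (re-validated)."""
        return EventStream(
            self.t + dt_us, self.x + dx, self.y + dy, self.p,
            self.width, self.height,
        )

    @property
    def duration_us(self) -> int:
        return int(self.t[-1] - self.t[0]) if len(self) else 0


# -- canonical CSV dialect --------------------------------------------------

_COLUMNS = ["t_us", "x", "y", "p"]


def write_events(stream: EventStream, path) -> None:
    """Write a stream in the canonical CSV dialect (header ``t_us,x,y,p``)."""
    df = pd.DataFrame({"t_us": stream.t, "x": stream.x, "y": stream.y, "p": stream.p})
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# sensor {stream.width}x{stream.height}\n")
        df.to_csv(fh, index=False)


def read_events(path, width: int | None = None, height: int | None = None) -> EventStream:
    """Read the canonical CSV dialect, validating every row.

    Geometry is taken from the ``# sensor WxH`` comment line if present,
    else from the ``width``/``height`` arguments.  Violations (decreasing
    timestamps, out-of-range coordinates, polarity not in {-1, +1}) raise
    :class:`EventFileError` naming the offending line number.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        header_lines = 1
        if first.startswith("# sensor "):
            try:
                w_s, h_s = first.strip().removeprefix("# sensor ").split("x")
                width, height = int(w_s), int(h_s)
            except Exception as exc:  # noqa: BLE001
                raise EventFileError(f"line 1: bad sensor comment {first!r}") from exc
            header_lines = 2
            first = fh.readline()
        if first.strip() != ",".join(_COLUMNS):
            raise EventFileError(
                f"line {header_lines}: expected header {','.join(_COLUMNS)!r}"
            )
        try:
            df = pd.read_csv(fh, header=None, names=_COLUMNS, dtype=np.int64)
        except (ValueError, pd.errors.ParserError) as exc:
            raise EventFileError(f"failed to parse {path}: {exc}") from exc
    if width is None or height is None:
        raise EventFileError("sensor geometry unknown: no comment line and no arguments")

    def _fail(mask: np.ndarray, what: str) -> None:
        idx = int(np.flatnonzero(mask)[0])
        raise EventFileError(f"line {idx + header_lines + 1}: {what}")

    t = df["t_us"].to_numpy()
    if len(t):
        if t[0] < 0:
            _fail(t < 0, "negative timestamp")
        dec = np.zeros(len(t), dtype=bool)
        dec[1:] = np.diff(t) < 0
        if dec.any():
            _fail(dec, "decreasing timestamp")
    for col, hi, name in (("x", width, "x"), ("y", height, "y")):
        v = df[col].to_numpy()
        bad = (v < 0) | (v >= hi)
        if bad.any():
            _fail(bad, f"{name} out of range [0, {hi})")
    p = df["p"].to_numpy()
    if np.any(np.abs(p) != 1):
        _fail(np.abs(p) != 1, "polarity not in {-1, +1}")
    return EventStream(t, df["x"], df["y"], p, width, height, validate=False)
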