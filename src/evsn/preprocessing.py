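"""Spatial subsampling and causal exponential filtering of event streams.

The sensor's pixel array is tiled into non-overlapping square cells of
``cell_size x cell_size`` pixels; a receptive field (RF) is a rectangular
block of cells around a centre cell.  Events falling in an RF's cells are
converted to an analog vector ``A(t)`` by a causal exponential kernel
``G(t, t_i) = exp(-(t - t_i)/tau)`` applied per cell: one filtered trace
per member cell, in fixed row-major order.  ``A(t)`` is what the echo-state
predictors consume, normalized to [0, 1] by a running per-RF maximum.

The filter state is updated incrementally — decay the previous value, add
one kernel per new event — which is algebraically identical to re-summing
the kernel over the whole event history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .events import Event, EventStream

__all__ = [
    "CellGrid",
    "ReceptiveField",
    "ExponentialKernel",
    "AnalogState",
    "AnalogPipeline",
    "map_event_to_cell",
    "update_analog",
    "sample_vector",
    "batch_analog",
]

#: sentinel cell index for events outside the tiled region
UNASSIGNED = -1


@dataclass(frozen=True)
class ExponentialKernel:
    """Causal exponential filter ``exp(-dt/tau) * H(dt)``, tau in seconds."""

    tau_s: float = 0.010

    def __post_init__(self) -> None:
        if not self.tau_s > 0:
            raise ValueError("tau must be positive")

    @property
    def tau_us(self) -> float:
        return self.tau_s * 1e6

    def __call__(self, dt_us) -> np.ndarray:
        dt_us = np.asarray(dt_us, dtype=np.float64)
        return np.where(dt_us >= 0, np.exp(-dt_us / self.tau_us), 0.0)


class CellGrid:
    """Non-overlapping tiling of the pixel array into square cells.

    Cells are ``cell_size x cell_size`` pixel blocks anchored at the
    top-left corner; pixels in the cropped remainder (when the sensor size
    is not a multiple of the cell size) map to :data:`UNASSIGNED`.
    Cell indices are row-major over the cell grid.
    """

    def __init__(self, width: int, height: int, cell_size: int):
        if cell_size < 1:
            raise ValueError("cell_size must be >= 1")
        self.width = width
        self.height = height
        self.cell_size = cell_size
        self.n_cols = width // cell_size
        self.n_rows = height // cell_size

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def cell_index(self, x, y) -> np.ndarray:
        """Vectorized pixel -> cell index map (UNASSIGNED outside tiling)."""
        x = np.asarray(x)
        y = np.asarray(y)
        cx = x // self.cell_size
        cy = y // self.cell_size
        idx = cy * self.n_cols + cx
        bad = (cx >= self.n_cols) | (cy >= self.n_rows) | (x < 0) | (y < 0)
        return np.where(bad, UNASSIGNED, idx)

    def cell_center(self, cell: int) -> tuple[float, float]:
        """Pixel coordinates of a cell's centre."""
        cy, cx = divmod(cell, self.n_cols)
        half = (self.cell_size - 1) / 2
        return (cx * self.cell_size + half, cy * self.cell_size + half)


def map_event_to_cell(event: Event, grid: CellGrid) -> int:
    """Cell index of one event, or UNASSIGNED if outside the tiled region."""
    return int(grid.cell_index(event.x, event.y))


@dataclass(frozen=True)
class ReceptiveField:
    """A rectangular block of cells: centre cell +- half extents (in cells)."""

    center_col: int
    center_row: int
    half_extent_cols: int
    half_extent_rows: int

    def member_cells(self, grid: CellGrid) -> np.ndarray:
        """Member cell indices in fixed row-major order.

        The RF must lie fully inside the cell grid; members are exactly the
        cells whose centre is within the half extents of the RF centre.
        """
        c0, r0 = self.center_col, self.center_row
        dc, dr = self.half_extent_cols, self.half_extent_rows
        if c0 - dc < 0 or c0 + dc >= grid.n_cols or r0 - dr < 0 or r0 + dr >= grid.n_rows:
            raise ValueError("receptive field extends beyond the cell grid")
        cols = np.arange(c0 - dc, c0 + dc + 1)
        rows = np.arange(r0 - dr, r0 + dr + 1)
        return (rows[:, None] * grid.n_cols + cols[None, :]).ravel()

    @property
    def n_cells(self) -> int:
        return (2 * self.half_extent_cols + 1) * (2 * self.half_extent_rows + 1)

    @classmethod
    def centered(cls, grid: CellGrid, half_extent: int) -> "ReceptiveField":
        return cls(grid.n_cols // 2, grid.n_rows // 2, half_extent, half_extent)


class AnalogState:
    """Exponentially filtered per-cell activity of one receptive field.

    ``values[i]`` is the kernel sum over all past events in member cell
    ``i``; ``sample()`` returns the vector normalized by the running
    maximum component seen so far (floored at 1 so silence is not
    amplified), guaranteeing components in [0, 1].
    """

    def __init__(self, dim: int, kernel: ExponentialKernel, t0_us: int = 0):
        self.values = np.zeros(dim)
        self.kernel = kernel
        self.t_us = int(t0_us)
        self.running_max = 0.0

    @property
    def dim(self) -> int:
        return len(self.values)

    def update(self, t_us: int, ev_t_us=None, ev_idx=None) -> None:
        """Advance to ``t_us``, folding in events at ``ev_t_us`` (sorted,
        all within ``(previous t, t_us]``) landing on components ``ev_idx``."""
        t_us = int(t_us)
        if t_us < self.t_us:
            raise ValueError("cannot update analog state backwards in time")
        self.values *= math.exp(-(t_us - self.t_us) / self.kernel.tau_us)
        if ev_t_us is not None and len(ev_t_us):
            w = np.exp(-(t_us - np.asarray(ev_t_us, dtype=np.float64)) / self.kernel.tau_us)
            np.add.at(self.values, np.asarray(ev_idx), w)
        self.t_us = t_us

    def sample(self) -> np.ndarray:
        """Normalized copy of the current vector (components in [0, 1])."""
        self.running_max = max(self.running_max, float(self.values.max(initial=0.0)))
        return self.values / max(self.running_max, 1.0)


def update_analog(state: AnalogState, t_us: int, ev_t_us=None, ev_idx=None) -> AnalogState:
    """Functional wrapper around :meth:`AnalogState.update` (returns state)."""
    state.update(t_us, ev_t_us, ev_idx)
    return state


def sample_vector(state: AnalogState) -> np.ndarray:
    """Normalized analog vector A(t) of the receptive field."""
    return state.sample()


def batch_analog(dim: int, kernel: ExponentialKernel, ev_t_us, ev_idx, t_us: int) -> np.ndarray:
    """Direct kernel summation over the full event history (reference path).

    Evaluates ``A_i(t) = sum_{events j in cell i} exp(-(t - t_j)/tau)`` from
    scratch; the incremental update must agree with this to rounding error.
    """
    values = np.zeros(dim)
    ev_t_us = np.asarray(ev_t_us, dtype=np.float64)
    if len(ev_t_us):
        w = np.exp(-(t_us - ev_t_us) / kernel.tau_us)
        np.add.at(values, np.asarray(ev_idx), w)
    return values


class AnalogPipeline:
    """Event stream -> analog vector for one receptive field.

    Binds a cell grid, an RF and a filter state; maps each event's pixel to
    a local component index (dropping events outside the RF) and keeps the
    fixed row-major component order stable across calls.
    """

    def __init__(
        self,
        grid: CellGrid,
        rf: ReceptiveField,
        kernel: ExponentialKernel,
        t0_us: int = 0,
    ):
        self.grid = grid
        self.rf = rf
        self.kernel = kernel
        members = rf.member_cells(grid)
        self._local = np.full(grid.n_cells + 1, UNASSIGNED, dtype=np.int64)
        self._local[members] = np.arange(len(members))
        self.members = members
        self.state = AnalogState(len(members), kernel, t0_us)

    @property
    def dim(self) -> int:
        return self.state.dim

    def local_indices(self, x, y) -> np.ndarray:
        """Component index per event (UNASSIGNED if outside the RF)."""
        cells = self.grid.cell_index(x, y)
        return np.where(cells == UNASSIGNED, UNASSIGNED, self._local[cells])

    def update(self, events: EventStream, t_us: int) -> None:
        idx = self.local_indices(events.x, events.y)
        keep = idx != UNASSIGNED
        self.state.update(t_us, events.t[keep], idx[keep])

    def sample(self) -> np.ndarray:
        return self.state.sample()
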