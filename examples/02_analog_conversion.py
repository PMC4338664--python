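"""From events to the analog vector A(t) fed to the predictors.

Maps events into 5x5-pixel cells, collects a 17x17-cell receptive field
and filters each cell's events with a causal exponential kernel
(tau = 10 ms), sampling the normalized vector once per millisecond.
"""

import numpy as np

from evsn import AnalogPipeline, CellGrid, ExponentialKernel, ReceptiveField, SensorModel
from evsn.architecture import make_bar_spec
from evsn.simulate import simulate_moving_bar

sensor = SensorModel(noise_rate=0.0)
grid = CellGrid(sensor.width, sensor.height, cell_size=5)
rf = ReceptiveField.centered(grid, half_extent=8)  # 17 x 17 cells
pipe = AnalogPipeline(grid, rf, ExponentialKernel(0.010))
print(f"receptive field: {rf.n_cells} components (17 x 17 cells of 5 x 5 px)")

stream = simulate_moving_bar(make_bar_spec(0.0, 1.0, sensor), sensor, seed=1)
peak, peak_t = 0.0, 0
for t_us in range(1000, 1_000_001, 1000):
    pipe.update(stream.slice(t_us - 1000, t_us + 1), t_us)
    a = pipe.sample()
    if a.mean() > peak:
        peak, peak_t = a.mean(), t_us
print(f"peak mean activity {peak:.3f} at t = {peak_t/1e6:.3f} s "
      f"(bar crossing the field centre)")
# Components are normalized to [0, 1] by a running per-field maximum; the
# mean activity drives the output gate of the selection circuit.
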