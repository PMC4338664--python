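"""One echo-state network predicting its input one step ahead.

A 15-neuron reservoir (spectral radius 0.7) with a linear readout is
trained online by recursive least squares to predict the next sample of a
smooth input; prediction error falls as the readout adapts.
"""

import numpy as np

from evsn import ESNParams, prediction_error
from evsn.esn import ESN

params = ESNParams(n_reservoir=15, input_dim=4)
net = ESN(params, seed=0)

t = np.arange(4000)
signal = 0.5 + 0.4 * np.sin(2 * np.pi * t / 80.0)

errors = []
for k in range(len(t) - 1):
    net.step(np.full(4, signal[k]))          # prediction for t+1 issued here
    target = np.full(4, signal[k + 1])       # ... compared with the next input
    errors.append(prediction_error(target, net.state.out))
    net.train(target)                        # one RLS step on the readout

early, late = np.mean(errors[:200]), np.mean(errors[-200:])
print(f"mean one-step prediction error: first 200 ticks {early:.4f}, "
      f"last 200 ticks {late:.4f}")
# Only the readout weights are trained; reservoir, input and feedback
# weights keep their random initial values, as in reservoir computing.
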