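import pathlib

import numpy as np
import pytest

from evsn.events import EventStream, SensorModel

FIXTURES = pathlib.Path(__file__).parent / "fixtures"


@pytest.fixture
def small_sensor() -> SensorModel:
    """A 16x16 sensor with noise disabled, for deterministic signal tests."""
    return SensorModel(16, 16, contrast_threshold=0.14, noise_rate=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_stream(rng: np.random.Generator, sensor: SensorModel, n: int = 200,
                  t_max: int = 100_000) -> EventStream:
    """A valid random event stream on the given sensor."""
    t = np.sort(rng.integers(0, t_max, size=n))
    x = rng.integers(0, sensor.width, size=n)
    y = rng.integers(0, sensor.height, size=n)
    p = rng.choice([-1, 1], size=n)
    return EventStream(t, x, y, p, sensor.width, sensor.height)
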