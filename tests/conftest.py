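import numpy as np
import pytest

from gazealign.gaze import VisualUnit
from gazealign.narrative import LinguisticUnit
from gazealign.simulate import ObserverParams


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def vunits():
    # two visits to r1 split by r2; durations chosen unequal for selection tests
    return [
        VisualUnit("r1", 0.0, 0.5),
        VisualUnit("r2", 0.6, 0.3),
        VisualUnit("r2", 0.9, 0.2),
        VisualUnit("r1", 1.2, 0.8),
        VisualUnit("r3", 2.1, 0.4),
    ]


@pytest.fixture
def lunits():
    return [LinguisticUnit("bear", 0.2), LinguisticUnit("log", 1.4)]


def random_units(rng, n_labels=4, n_units=12, span=10.0):
    """Random time-stamped visual units for property tests."""
    t = 0.0
    units = []
    for _ in range(n_units):
        dur = float(rng.uniform(0.1, 0.6))
        units.append(VisualUnit(f"r{rng.integers(1, n_labels + 1)}", t, dur))
        t += dur + float(rng.uniform(0.0, span / n_units))
    return units


@pytest.fixture(scope="session")
def zero_noise_params():
    return ObserverParams(
        lag_mean=0.0, lag_sd=0.0, filler_rate=0.0, synonym_use=0.0
    )
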