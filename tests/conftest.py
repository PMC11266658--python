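import numpy as np
import pytest

from burstcycle.kinetics import ClockModel
from burstcycle.simulate import ObservationParams, synthesize_cohort, wildtype_like


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent draws)."""
    return np.random.default_rng(20240723)


@pytest.fixture(scope="session")
def clock():
    """A generic irreversible clock model with distinct rates."""
    return ClockModel(w21=1.3, w32=0.7, w13=0.9, w12=0.4, alpha=0.2)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-cell wild-type-like cohort (session-scoped: simulation is the
    expensive part of most segmentation/survival tests)."""
    return synthesize_cohort(wildtype_like(), ObservationParams(), 40, seed=123)


def random_clock(rng, alpha_mode="free"):
    """Random positive rates over two decades; alpha per mode."""
    w21, w32, w13, w12 = 10 ** rng.uniform(-1.5, 0.8, size=4)
    m = ClockModel(w21=w21, w32=w32, w13=w13, w12=w12, alpha=0.0)
    if alpha_mode == "zero":
        return m
    from burstcycle.kinetics import alpha_eq

    if alpha_mode == "eq":
        return ClockModel(w21=w21, w32=w32, w13=w13, w12=w12, alpha=alpha_eq(m))
    return ClockModel(
        w21=w21, w32=w32, w13=w13, w12=w12,
        alpha=float(rng.uniform(0.0, 1.5)) * alpha_eq(m),
    )
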