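import pytest

from satnet import (ModelParameters, default_conditions, run_batch)
from satnet.params import EpochSchedule


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def conditions():
    return default_conditions()


@pytest.fixture(scope="session")
def fast_sched():
    """Coarse integration step for quick stochastic smoke runs."""
    return EpochSchedule(dt=0.5)


@pytest.fixture(scope="session")
def small_result(conditions, fast_sched):
    """A small batch shared by behavioral/observer plumbing tests.

    3 conditions x {0, 8, 32}% x 50 trials at the coarse step; enough
    structure for paired re-detection and trace-based analyses without
    meaningful runtime.
    """
    return run_batch(conditions, [0.0, 8.0, 32.0], 50, fast_sched,
                     master_seed=424242)
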