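import numpy as np
import pytest

from afoflex.experiments import run_grid
from afoflex.gait_synth import synth_gait, synth_support
from afoflex.leg_afo_model import apply_weakening, build_model


@pytest.fixture(scope="session")
def model():
    return build_model()


@pytest.fixture(scope="session")
def grid_report():
    """The full 84-condition study grid for one synthetic subject.

    Session-scoped: this is the expensive fixture (about a minute) that all
    grid-level property checks share.
    """
    return run_grid(subjects=(1,))


@pytest.fixture(scope="session")
def pf25_result(model):
    """One simulated PF25/slow/aligned condition (full trace record)."""
    from afoflex.dynamics_engine import run_gait_cycle

    mod = apply_weakening(model, "PF25")
    trial = synth_gait("slow", 1).with_support(synth_support("PF25", "slow", 1))
    return run_gait_cycle(mod, trial, metadata={"level": "PF25", "direction": "zero"})


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
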