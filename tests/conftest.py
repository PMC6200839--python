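import numpy as np
import pytest

from echopipe.simulate import (
    AcquisitionSpec,
    TaskDesign,
    build_trial_schedule,
    default_truth,
    render_echoes,
    simulate_behavior,
    simulate_session,
    GROUP_PROFILES,
)


@pytest.fixture(scope="session")
def small_acq() -> AcquisitionSpec:
    """Desk-scale acquisition: protocol TEs/TR, shortened run, small grid."""
    return AcquisitionSpec(n_volumes=100, grid_shape=(10, 10, 6))


@pytest.fixture(scope="session")
def small_design() -> TaskDesign:
    """Task design scaled to the shortened run (40 trials)."""
    return TaskDesign(n_trials=40)


@pytest.fixture(scope="session")
def session(small_acq, small_design):
    """One fully simulated small session, shared across read-only tests."""
    return simulate_session(acq=small_acq, design=small_design, seed=11)


@pytest.fixture()
def clean_session(small_acq, small_design):
    """A session with activation only: no physio, no noise."""
    events = build_trial_schedule(small_design, seed=5,
                                  run_duration_s=small_acq.duration_s)
    events = simulate_behavior(events, GROUP_PROFILES["HOA"], accuracy=1.0, seed=5)
    truth = default_truth(
        small_acq, seed=5, physio_amplitude=0.0, thermal_sd=0.0,
        structured_sd=0.0, t2star_ms=45.0,
    )
    return render_echoes(truth, small_acq, events)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
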