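import numpy as np
import pytest

from helibelief.observer import ObserverConfig, run_observer
from helibelief.taskgen import (
    HC_PARAMS,
    TaskConfig,
    generate_schedule,
    simulate_agent,
)


@pytest.fixture(scope="session")
def default_schedule():
    """The study-sized schedule: 4 runs x 70 trials, alternating noise."""
    return generate_schedule(TaskConfig(seed=11))


@pytest.fixture(scope="session")
def short_schedule():
    """Single low-noise run of 70 trials for quick checks."""
    return generate_schedule(
        TaskConfig(n_runs=1, trials_per_run=70, noise_sd_by_run=(2.3,), seed=5)
    )


@pytest.fixture(scope="session")
def hc_record(default_schedule):
    return simulate_agent(default_schedule, HC_PARAMS, seed=21)


@pytest.fixture(scope="session")
def hc_trace(default_schedule, hc_record):
    cfg = ObserverConfig(noise_sd=2.3, conditioning="empirical")
    return run_observer(
        hc_record.outcome,
        cfg,
        predictions=hc_record.prediction,
        run=hc_record.run,
        run_noise_map=list(default_schedule.config.noise_sd_by_run),
        missing=hc_record.missing,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
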