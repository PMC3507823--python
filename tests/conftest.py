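import numpy as np
import pytest

from loomkit import LoomingStimulus
from loomkit.synth import EtaModelParams, SimulationConfig, scenario_battery

# The 13 disc l/|v| values (ms) produced by a 0.08 m disc at 0.5-15 m/s.
DISC_LOVS = [80.0, 40.0, 26.7, 20.0, 16.0, 13.3, 10.0, 8.0, 6.0, 5.3, 4.0, 3.2, 2.7]


def disc_for_lov(lov_ms: float, half_size: float = 0.04) -> LoomingStimulus:
    """Disc stimulus with the given l/|v| (speed set from the ratio)."""
    return LoomingStimulus(
        half_size_l=half_size,
        speed_v=half_size * 1000.0 / lov_ms,
        stim_id=f"lov{lov_ms:05.1f}",
    )


@pytest.fixture(scope="session")
def disc_stimuli():
    return [disc_for_lov(l) for l in DISC_LOVS]


@pytest.fixture(scope="session")
def dcmd_battery(disc_stimuli):
    """Electrophysiology-style battery: default rate model, many reps.

    30 presentations per stimulus keep the peak-time estimator's
    noise-induced bias small enough for parameter recovery.
    """
    config = SimulationConfig(
        stimuli=tuple(disc_stimuli),
        n_individuals=10,
        n_presentations=30,
        rng_seed=1,
    )
    return scenario_battery(config)


@pytest.fixture(scope="session")
def flight_battery(disc_stimuli):
    """Flight-behaviour battery: hotter rate model so glides span the range."""
    config = SimulationConfig(
        stimuli=tuple(disc_stimuli),
        n_individuals=15,
        n_presentations=20,
        rng_seed=1,
        eta=EtaModelParams(scale_C=300.0),
    )
    return scenario_battery(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
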