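import numpy as np
import pytest

import dddtraj as dt


@pytest.fixture
def config1():
    return dt.ScenarioConfig(scenario=1)


@pytest.fixture
def config2():
    return dt.ScenarioConfig(scenario=2)


@pytest.fixture
def config3():
    return dt.ScenarioConfig(scenario=3)


@pytest.fixture
def small_cohort():
    """A 150-pregnancy synthetic cohort with mixed dispensing regimes."""
    spec = dt.CohortSpec(n_pregnancies=150, exposure_fraction=0.9, seed=42)
    pregnancies, dispensations, planted = dt.generate(spec)
    return spec, pregnancies, dispensations, planted


def make_trajectory(pid, values, scenario=2, start_week=-4):
    return dt.WeeklyTrajectory(
        pregnancy_id=pid, scenario=scenario, start_week=start_week,
        values=np.asarray(values, dtype=float),
    )
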