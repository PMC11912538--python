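"""Shared fixtures: small deterministic cohorts and seeded generators."""

import numpy as np
import pytest

from adaptlrt import Cohort, ScenarioSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def hand_cohort():
    """Four subjects, all enrolled at 0: times (1,2,3,4), status (1,1,0,1)."""
    return Cohort.from_observed(entry=[0, 0, 0, 0], group=[0, 1, 0, 1],
                                time=[1, 2, 3, 4], status=[1, 1, 0, 1])


@pytest.fixture
def staggered_cohort(rng):
    """A medium random cohort with staggered entry and random dropout."""
    n = 120
    return Cohort(entry_time=rng.uniform(0, 4, n),
                  group=rng.integers(0, 2, n),
                  event_time=rng.exponential(2.0, n) + 1e-9,
                  dropout_time=np.where(rng.random(n) < 0.3,
                                        rng.exponential(5.0, n) + 1e-9,
                                        np.inf))


@pytest.fixture
def null_cohort():
    """Null scenario draw at moderate size (both arms exponential)."""
    return simulate_cohort(ScenarioSpec(theta=0.0, n_per_group=100), rng=42)


@pytest.fixture
def effect_cohort():
    """Proportional-hazards benefit draw (theta = -0.5)."""
    return simulate_cohort(ScenarioSpec(theta=-0.5, n_per_group=100), rng=7)
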