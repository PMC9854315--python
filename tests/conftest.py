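"""Shared fixtures: hand-built patterns and session-scoped simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from wmquality.core_model import (DEFAULT_GEOMETRY, POOL_MODALITY,
                                  RECORD_COLUMNS, DataPattern, TaskGeometry)
from wmquality.simulate import (ARCHETYPES, ArchetypeParams, preset_scenario,
                                simulate_participant, simulate_pool,
                                simulate_study)

settings.register_profile(
    "suite", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


def build_pattern(participant_id: str = "p0", pool: str = "student_web",
                  rt=800.0, correct=1, probe_present: str = "yes",
                  geometry: TaskGeometry = DEFAULT_GEOMETRY) -> DataPattern:
    """Construct a full-geometry pattern with controlled RTs and correctness.

    ``rt`` and ``correct`` may be scalars, arrays of length n_records, or
    callables ``f(trial_index, trial_type, phase, serial_position)``.
    ``probe_present`` is applied to every memory response.
    """
    g = geometry
    rows = []
    for trial in range(1, g.n_trials + 1):
        ttype = "disruption" if trial > g.n_regular else "regular"
        for phase, count in (("processing", g.processing_per_trial),
                             ("memory", g.probes_per_trial)):
            for sp in range(1, count + 1):
                rows.append((trial, ttype, phase, sp,
                             probe_present if phase == "memory" else "na"))
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS[:5])

    def materialise(spec, dtype):
        if callable(spec):
            vals = [spec(*row[:4]) for row in rows]
        elif np.isscalar(spec):
            vals = [spec] * len(rows)
        else:
            vals = list(spec)
        return np.asarray(vals, dtype=dtype)

    df["correct"] = materialise(correct, int)
    df["rt_ms"] = materialise(rt, float)
    return DataPattern(participant_id=participant_id, pool=pool,
                       modality=POOL_MODALITY[pool], records=df)


@pytest.fixture(scope="session")
def compliant_pattern():
    return simulate_participant(ARCHETYPES["compliant"], seed=42,
                                participant_id="c0042")


@pytest.fixture(scope="session")
def compliant_cohort_500():
    """500 compliant participants (disruption + primacy effects planted)."""
    return [simulate_participant(ARCHETYPES["compliant"], seed=20_000 + i,
                                 participant_id=f"c{i:04d}")
            for i in range(500)]


@pytest.fixture(scope="session")
def null_cohort_500():
    """500 participants with no disruption decrement and no primacy advantage."""
    null = ArchetypeParams("non_complier", rt_mu=700, rt_sigma=120, rt_tau=250,
                           sp1_advantage=0, acc_regular=0.9,
                           disruption_decrement=0.0, p_lapse=0.0,
                           lapse_scale=2000, p_guess=0.0)
    return [simulate_participant(null, seed=10_000 + i,
                                 participant_id=f"n{i:04d}")
            for i in range(500)]


@pytest.fixture(scope="session")
def prolific_cohort_300():
    """Preset Prolific scenario (n=300) with ground-truth labels."""
    return simulate_pool(preset_scenario("prolific", seed=11))


@pytest.fixture(scope="session")
def study_cohort():
    """All four preset pools simulated at the published sample sizes."""
    return simulate_study(seed=1)
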