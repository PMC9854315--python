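"""Synthetic participant-data generator.

Generates :class:`~wmquality.core_model.DataPattern` objects with the
behavioural structure the screening pipeline assumes: ex-Gaussian RTs with
a heavy right tail, an RT advantage at serial position 1 for participants
who rehearse sequentially, an accuracy decrement on the final
verbal-disruption block for compliant participants, and contamination
archetypes (fast guessing, distraction lapses, uniformly slow responding,
low performance, instruction non-compliance).

Participants are drawn from archetype mixtures (:class:`PoolScenario`);
:func:`preset_scenario` provides per-pool mixtures whose screening and
benchmark failure rates approximate those observed across MTurk, Prolific,
web-tested and lab-tested student pools.  Ground-truth archetype labels are
returned alongside the data so detection operating characteristics can be
measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core_model import (DEFAULT_GEOMETRY, POOL_MODALITY, POOLS,
                         RECORD_COLUMNS, DataPattern, TaskGeometry)
from .errors import ValidationError

logger = logging.getLogger(__name__)

ARCHETYPE_NAMES = ("compliant", "non_complier", "fast_guesser",
                   "distracted", "slow_responder", "low_performer")

#: RTs never drop below this physiological floor (ms).
RT_FLOOR_MS = 150.0
#: Fast guesses are uniform on this interval (ms), strictly below the
#: 400 ms small-RT fence so planted guessers are detectable by construction.
GUESS_RT_RANGE = (150.0, 350.0)


@dataclass(frozen=True)
class ArchetypeParams:
    """Generative parameters of one participant archetype.

    RTs follow an ex-Gaussian: Normal(``rt_mu``, ``rt_sigma``) plus an
    exponential tail with mean ``rt_tau`` (all ms).  ``sp1_advantage`` is
    subtracted from memory responses at serial position 1 (the rehearsal
    primacy benefit).  ``acc_regular`` is the per-response probability of a
    correct answer; on disruption-trial memory responses it drops by
    ``disruption_decrement`` for every archetype except ``non_complier``,
    which by definition ignores the changed instructions.  Each response is
    independently a fast guess with probability ``p_guess`` (uniform RT in
    :data:`GUESS_RT_RANGE`, coin-flip correctness) or is delayed by a
    distraction lapse with probability ``p_lapse`` (adds an exponential
    with mean ``lapse_scale``).
    """

    name: str
    rt_mu: float
    rt_sigma: float
    rt_tau: float
    sp1_advantage: float
    acc_regular: float
    disruption_decrement: float
    p_lapse: float
    lapse_scale: float
    p_guess: float

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPE_NAMES:
            raise ValidationError(f"unknown archetype {self.name!r}")
        if min(self.rt_mu, self.rt_sigma, self.rt_tau, self.lapse_scale) <= 0:
            raise ValidationError("rt_mu, rt_sigma, rt_tau, lapse_scale must be > 0")
        if self.sp1_advantage < 0:
            raise ValidationError("sp1_advantage must be >= 0")
        for attr in ("acc_regular", "disruption_decrement", "p_lapse", "p_guess"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{attr} must lie in [0, 1]")
        if self.acc_regular - self.disruption_decrement < 0:
            raise ValidationError("acc_regular - disruption_decrement must be >= 0")

    @property
    def complies(self) -> bool:
        """Whether the archetype follows the disruption-block instructions."""
        return self.name != "non_complier"


#: Default archetype parameterisations (ms / proportions).
ARCHETYPES: dict[str, ArchetypeParams] = {
    "compliant": ArchetypeParams(
        "compliant", rt_mu=700, rt_sigma=120, rt_tau=250, sp1_advantage=120,
        acc_regular=0.90, disruption_decrement=0.20,
        p_lapse=0.01, lapse_scale=2000, p_guess=0.01),
    # does not rehearse: no disruption decrement, no primacy benefit
    "non_complier": ArchetypeParams(
        "non_complier", rt_mu=700, rt_sigma=120, rt_tau=250, sp1_advantage=0,
        acc_regular=0.88, disruption_decrement=0.0,
        p_lapse=0.01, lapse_scale=2000, p_guess=0.01),
    "fast_guesser": ArchetypeParams(
        "fast_guesser", rt_mu=700, rt_sigma=120, rt_tau=250, sp1_advantage=120,
        acc_regular=0.85, disruption_decrement=0.15,
        p_lapse=0.01, lapse_scale=2000, p_guess=0.85),
    "distracted": ArchetypeParams(
        "distracted", rt_mu=750, rt_sigma=140, rt_tau=300, sp1_advantage=120,
        acc_regular=0.82, disruption_decrement=0.18,
        p_lapse=0.22, lapse_scale=3000, p_guess=0.02),
    "slow_responder": ArchetypeParams(
        "slow_responder", rt_mu=1800, rt_sigma=300, rt_tau=600, sp1_advantage=120,
        acc_regular=0.88, disruption_decrement=0.18,
        p_lapse=0.02, lapse_scale=2000, p_guess=0.0),
    "low_performer": ArchetypeParams(
        "low_performer", rt_mu=800, rt_sigma=150, rt_tau=300, sp1_advantage=60,
        acc_regular=0.55, disruption_decrement=0.05,
        p_lapse=0.02, lapse_scale=2000, p_guess=0.02),
}


@dataclass(frozen=True)
class PoolScenario:
    """A pool of participants drawn from an archetype mixture."""

    pool: str
    n_participants: int
    mixture: Mapping[str, float]
    geometry: TaskGeometry = DEFAULT_GEOMETRY
    seed: int = 0
    archetypes: Mapping[str, ArchetypeParams] = field(default_factory=lambda: ARCHETYPES)

    def __post_init__(self) -> None:
        if self.pool not in POOLS:
            raise ValidationError(f"unknown pool {self.pool!r}")
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        weights = np.array(list(self.mixture.values()), dtype=float)
        if (weights < 0).any():
            raise ValidationError("mixture weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValidationError("mixture weights must sum to 1")
        for name in self.mixture:
            if name not in self.archetypes:
                raise ValidationError(f"unknown archetype {name!r} in mixture")


def simulate_participant(arch: ArchetypeParams,
                         geometry: TaskGeometry = DEFAULT_GEOMETRY,
                         seed: int | np.random.SeedSequence = 0,
                         participant_id: str = "sim_0000",
                         pool: str = "student_web") -> DataPattern:
    """Simulate one participant's complete data pattern.

    Deterministic given ``seed``.  Per response, a guess event (probability
    ``p_guess``) yields RT ~ U(150, 350) and coin-flip correctness;
    otherwise RT is ex-Gaussian minus the primacy advantage where it
    applies, plus a lapse delay with probability ``p_lapse``, floored at
    150 ms, and correctness is Bernoulli with the archetype's accuracy
    (reduced by the disruption decrement on disruption-trial memory
    responses for compliant archetypes).
    """
    rng = np.random.default_rng(seed)
    g = geometry
    per_trial = g.records_per_trial
    n = g.n_records

    trial_index = np.repeat(np.arange(1, g.n_trials + 1), per_trial)
    is_memory = np.tile(
        np.r_[np.zeros(g.processing_per_trial, bool),
              np.ones(g.probes_per_trial, bool)], g.n_trials)
    serial_position = np.tile(
        np.r_[np.arange(1, g.processing_per_trial + 1),
              np.arange(1, g.probes_per_trial + 1)], g.n_trials)
    is_disruption = trial_index > g.n_regular

    probe_present = np.where(is_memory,
                             np.where(rng.random(n) < g.probe_present_rate,
                                      "yes", "no"),
                             "na")

    # RT: ex-Gaussian base, primacy advantage, lapses, floor; guesses override
    base = (rng.normal(arch.rt_mu, arch.rt_sigma, n)
            + rng.exponential(arch.rt_tau, n))
    sp1 = is_memory & (serial_position == 1)
    base = base - arch.sp1_advantage * sp1
    lapse = rng.random(n) < arch.p_lapse
    base = base + lapse * rng.exponential(arch.lapse_scale, n)
    rt = np.maximum(RT_FLOOR_MS, base)

    guess = rng.random(n) < arch.p_guess
    rt = np.where(guess, rng.uniform(*GUESS_RT_RANGE, n), rt)

    decrement = arch.disruption_decrement if arch.complies else 0.0
    p_correct = np.where(is_disruption & is_memory,
                         arch.acc_regular - decrement, arch.acc_regular)
    p_correct = np.where(guess, 0.5, p_correct)
    correct = (rng.random(n) < p_correct).astype(int)

    records = pd.DataFrame({
        "trial_index": trial_index,
        "trial_type": np.where(is_disruption, "disruption", "regular"),
        "phase": np.where(is_memory, "memory", "processing"),
        "serial_position": serial_position,
        "probe_present": probe_present,
        "correct": correct,
        "rt_ms": rt,
    })[RECORD_COLUMNS]
    return DataPattern(participant_id=participant_id, pool=pool,
                       modality=POOL_MODALITY[pool], records=records)


@dataclass
class SimulatedCohort:
    """Simulated patterns plus the ground-truth archetype of each."""

    patterns: list[DataPattern]
    labels: dict[str, str]

    def __iter__(self):
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)


def simulate_pool(scenario: PoolScenario) -> SimulatedCohort:
    """Simulate one pool; archetypes assigned by mixture draw.

    Reproducible given ``scenario.seed``; returns ground-truth labels for
    recovery tests.
    """
    rng = np.random.default_rng(scenario.seed)
    names = sorted(scenario.mixture)
    weights = np.array([scenario.mixture[k] for k in names], dtype=float)
    weights = weights / weights.sum()  # guard rounding in validated weights
    assignment = rng.choice(len(names), size=scenario.n_participants, p=weights)
    child_seeds = rng.integers(0, 2**31, size=scenario.n_participants)

    patterns, labels = [], {}
    for i, (k, s) in enumerate(zip(assignment, child_seeds)):
        pid = f"{scenario.pool}_{i:04d}"
        arch = scenario.archetypes[names[k]]
        patterns.append(simulate_participant(
            arch, scenario.geometry, int(s), participant_id=pid,
            pool=scenario.pool))
        labels[pid] = names[k]
    return SimulatedCohort(patterns, labels)


#: Archetype mixtures per pool.  Calibration choices, not observed facts:
#: non-compliers fail the disruption benchmark with probability ~1/2 (their
#: presence rate is coin-flip noise), so a pool with printed no-disruption
#: rate r needs a non_complier weight near 2r; contaminant weights were set
#: to the printed anomalous-pattern rates.
PRESET_MIXTURES: dict[str, dict[str, float]] = {
    "student_lab": {"compliant": 0.93, "distracted": 0.04,
                    "slow_responder": 0.03},
    "student_web": {"compliant": 0.62, "non_complier": 0.30,
                    "fast_guesser": 0.03, "distracted": 0.02,
                    "slow_responder": 0.01, "low_performer": 0.02},
    "prolific": {"compliant": 0.60, "non_complier": 0.31,
                 "fast_guesser": 0.04, "distracted": 0.02,
                 "slow_responder": 0.01, "low_performer": 0.02},
    "mturk": {"compliant": 0.16, "non_complier": 0.70,
              "fast_guesser": 0.06, "distracted": 0.03,
              "slow_responder": 0.02, "low_performer": 0.03},
}

#: Default pool sizes, matching the published study's samples.
PRESET_N: dict[str, int] = {
    "student_lab": 40, "student_web": 215, "prolific": 300, "mturk": 196,
}


def preset_scenario(pool: str, n_participants: int | None = None,
                    seed: int = 0,
                    geometry: TaskGeometry = DEFAULT_GEOMETRY) -> PoolScenario:
    """Documented default scenario for a pool.

    The lab preset contains no non-compliers (monitored testing enforces
    compliance); the MTurk preset carries the heaviest contamination, then
    Prolific/web students, mirroring the ordering of observed flag rates.
    """
    if pool not in PRESET_MIXTURES:
        raise ValidationError(
            f"unknown pool {pool!r}; expected one of {sorted(PRESET_MIXTURES)}")
    return PoolScenario(
        pool=pool,
        n_participants=PRESET_N[pool] if n_participants is None else n_participants,
        mixture=dict(PRESET_MIXTURES[pool]),
        geometry=geometry,
        seed=seed,
    )


def simulate_study(seed: int = 0,
                   n_by_pool: Mapping[str, int] | None = None) -> SimulatedCohort:
    """Simulate all four preset pools into one multi-pool cohort."""
    patterns: list[DataPattern] = []
    labels: dict[str, str] = {}
    for offset, pool in enumerate(("student_lab", "student_web",
                                   "prolific", "mturk")):
        n = None if n_by_pool is None else n_by_pool.get(pool)
        cohort = simulate_pool(preset_scenario(pool, n_participants=n,
                                               seed=seed + offset))
        patterns.extend(cohort.patterns)
        labels.update(cohort.labels)
    return SimulatedCohort(patterns, labels)


# ---------------------------------------------------------------------------
# Scenario files (YAML key-value with nested mixture map)


def scenario_from_dict(data: Mapping) -> PoolScenario:
    geometry = DEFAULT_GEOMETRY
    if "geometry" in data:
        geometry = TaskGeometry(**data["geometry"])
    archetypes = dict(ARCHETYPES)
    for name, overrides in (data.get("archetypes") or {}).items():
        archetypes[name] = replace(archetypes[name], **overrides)
    return PoolScenario(
        pool=data["pool"],
        n_participants=int(data["n_participants"]),
        mixture={k: float(v) for k, v in data["mixture"].items()},
        geometry=geometry,
        seed=int(data.get("seed", 0)),
        archetypes=archetypes,
    )


def load_scenario(path: str | Path) -> PoolScenario:
    """Load a :class:`PoolScenario` from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: scenario file must be a mapping")
    return scenario_from_dict(data)
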