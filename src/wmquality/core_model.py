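"""Domain types and tidy-CSV I/O for per-response working-memory data.

The interchange unit is one row per keypress response in a Brown-Peterson
style complex-span task: a participant sees four letters, verifies four
arithmetic problems during the retention interval, and is then probed on
each of the four letter positions.  A participant's complete response set
is a *data pattern* (:class:`DataPattern`); all screening and benchmark
operations consume data patterns.

The single interchange format is a tidy CSV (RFC-4180, UTF-8, '.' decimal)
with the columns::

    participant_id,pool,modality,trial_index,trial_type,phase,
    serial_position,probe_present,correct,rt_ms

Booleans are encoded 0/1 and enums as lowercase strings so that
``read_dataset(write_dataset(x)) == x`` bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

POOLS = ("mturk", "prolific", "student_web", "student_lab")
MODALITIES = ("web", "lab")
TRIAL_TYPES = ("regular", "disruption")
PHASES = ("processing", "memory")
PROBE_VALUES = ("yes", "no", "na")

#: Modality implied by each participant pool.
POOL_MODALITY = {
    "mturk": "web",
    "prolific": "web",
    "student_web": "web",
    "student_lab": "lab",
}

CSV_COLUMNS = [
    "participant_id",
    "pool",
    "modality",
    "trial_index",
    "trial_type",
    "phase",
    "serial_position",
    "probe_present",
    "correct",
    "rt_ms",
]

#: Per-response columns held inside a :class:`DataPattern`.
RECORD_COLUMNS = CSV_COLUMNS[3:]


@dataclass(frozen=True)
class TaskGeometry:
    """Structural parameters of the task.

    Defaults describe the reference design: 70 trials of which the final 10
    are verbal-disruption trials, 4 sequentially presented letters, 4
    arithmetic verifications and 4 local-recognition probes per trial,
    48.2% of probes drawn from the memorised list and 50% of arithmetic
    problems correct.
    """

    n_trials: int = 70
    n_disruption: int = 10
    letters_per_trial: int = 4
    processing_per_trial: int = 4
    probes_per_trial: int = 4
    probe_present_rate: float = 0.482
    processing_correct_rate: float = 0.50

    def __post_init__(self) -> None:
        if self.n_disruption > self.n_trials:
            raise ValidationError("n_disruption must not exceed n_trials")
        if min(self.n_trials, self.letters_per_trial,
               self.processing_per_trial, self.probes_per_trial) < 1:
            raise ValidationError("geometry counts must be positive")
        for name in ("probe_present_rate", "processing_correct_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")

    @property
    def n_regular(self) -> int:
        return self.n_trials - self.n_disruption

    @property
    def records_per_trial(self) -> int:
        return self.processing_per_trial + self.probes_per_trial

    @property
    def n_records(self) -> int:
        return self.n_trials * self.records_per_trial


DEFAULT_GEOMETRY = TaskGeometry()


@dataclass(frozen=True)
class ResponseRecord:
    """One keypress outcome with its trial/phase/position context.

    ``serial_position`` is the probed box's presentation rank for memory
    responses and the episode rank for processing responses.
    ``probe_present`` is ``"na"`` for processing responses.
    """

    trial_index: int
    trial_type: str
    phase: str
    serial_position: int
    probe_present: str
    correct: bool
    rt: float

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValidationError(f"unknown trial_type {self.trial_type!r}")
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.probe_present not in PROBE_VALUES:
            raise ValidationError(f"unknown probe_present {self.probe_present!r}")
        if (self.probe_present == "na") != (self.phase == "processing"):
            raise ValidationError(
                "probe_present must be 'na' exactly for processing responses")
        if self.rt <= 0:
            raise ValidationError("rt must be positive")


@dataclass
class DataPattern:
    """The complete response dataset of one participant.

    ``records`` is a tidy DataFrame with :data:`RECORD_COLUMNS`, ordered as
    recorded (trial, processing before memory, serial position).
    """

    participant_id: str
    pool: str
    modality: str
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)

    # -- derived views -------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.records)

    def subset(self, *, trial_type: str | None = None,
               phase: str | None = None) -> pd.DataFrame:
        """Rows matching the given trial type and/or phase."""
        df = self.records
        if trial_type is not None:
            df = df[df["trial_type"] == trial_type]
        if phase is not None:
            df = df[df["phase"] == phase]
        return df

    # -- validation ----------------------------------------------------

    def validate(self, geometry: TaskGeometry | None = None) -> None:
        """Check structural invariants; raise :class:`ValidationError`.

        Generic invariants are always checked.  When ``geometry`` is given,
        the exact trial/record counts are enforced as well.
        """
        df = self.records
        pid = self.participant_id

        def fail(rule: str) -> None:
            raise ValidationError(f"participant {pid!r}: {rule}")

        if self.pool not in POOLS:
            fail(f"unknown pool {self.pool!r}")
        if self.modality != POOL_MODALITY[self.pool]:
            fail(f"pool {self.pool!r} implies modality "
                 f"{POOL_MODALITY[self.pool]!r}, got {self.modality!r}")
        if df.empty:
            fail("pattern has no records")
        for col in RECORD_COLUMNS:
            if col not in df.columns:
                fail(f"missing record column {col!r}")
        if not df["trial_type"].isin(TRIAL_TYPES).all():
            fail("invalid trial_type value")
        if not df["phase"].isin(PHASES).all():
            fail("invalid phase value")
        if not df["probe_present"].isin(PROBE_VALUES).all():
            fail("invalid probe_present value")
        if (df["rt_ms"] <= 0).any():
            fail("rt_ms must be positive")

        # probe_present == 'na' iff processing phase
        is_proc = df["phase"] == "processing"
        if ((df["probe_present"] == "na") != is_proc).any():
            fail("probe_present must be 'na' exactly for processing responses")

        # disruption trials form the trailing block
        disr = df.loc[df["trial_type"] == "disruption", "trial_index"]
        regl = df.loc[df["trial_type"] == "regular", "trial_index"]
        if len(disr) and len(regl) and disr.min() <= regl.max():
            fail("disruption trials must come after all regular trials")

        # each memory phase probes each serial position at most once
        mem = df[df["phase"] == "memory"]
        if mem.groupby("trial_index")["serial_position"].nunique().lt(
                mem.groupby("trial_index").size()).any():
            fail("duplicate serial position within a memory phase")

        if geometry is not None:
            if df["trial_index"].nunique() != geometry.n_trials:
                fail(f"expected {geometry.n_trials} trials, "
                     f"found {df['trial_index'].nunique()}")
            if len(df) != geometry.n_records:
                fail(f"expected {geometry.n_records} records, found {len(df)}")
            n_disr_trials = disr.nunique()
            if n_disr_trials != geometry.n_disruption:
                fail(f"expected {geometry.n_disruption} disruption trials, "
                     f"found {n_disr_trials}")
            sizes = mem.groupby("trial_index")["serial_position"].nunique()
            if not (sizes == geometry.probes_per_trial).all():
                fail("memory phase must probe each serial position exactly once")


# ---------------------------------------------------------------------------
# CSV I/O


def _patterns_from_frame(df: pd.DataFrame,
                         validate: bool = True) -> list[DataPattern]:
    patterns: list[DataPattern] = []
    for pid, group in df.groupby("participant_id", sort=False):
        pools = group["pool"].unique()
        mods = group["modality"].unique()
        if len(pools) > 1 or len(mods) > 1:
            raise ValidationError(
                f"participant {pid!r}: inconsistent pool/modality labels")
        pattern = DataPattern(
            participant_id=str(pid),
            pool=pools[0],
            modality=mods[0],
            records=group[RECORD_COLUMNS].reset_index(drop=True),
        )
        if validate:
            pattern.validate()
        patterns.append(pattern)
    return patterns


def read_dataset(path: str | Path, validate: bool = True) -> list[DataPattern]:
    """Read a tidy per-response CSV into one :class:`DataPattern` per participant.

    Row order within each participant is preserved.  Raises
    :class:`FormatError` for a malformed file and :class:`ValidationError`
    when a pattern violates an invariant; an empty file yields an empty
    list with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"participant_id": str},
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        logger.warning("dataset %s is empty; returning no patterns", path)
        return []
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if df.empty:
        logger.warning("dataset %s has a header but no rows", path)
        return []
    df = df[CSV_COLUMNS].copy()
    df["trial_index"] = df["trial_index"].astype(int)
    df["serial_position"] = df["serial_position"].astype(int)
    df["correct"] = df["correct"].astype(int)
    df["rt_ms"] = df["rt_ms"].astype(float)
    return _patterns_from_frame(df, validate=validate)


_PHASE_ORDER = {"processing": 0, "memory": 1}


def patterns_to_frame(patterns: Iterable[DataPattern]) -> pd.DataFrame:
    """Concatenate patterns into one tidy frame in canonical row order.

    Canonical order is (participant_id, trial_index, processing before
    memory, serial_position).
    """
    frames = []
    for p in patterns:
        df = p.records.copy()
        df.insert(0, "participant_id", p.participant_id)
        df.insert(1, "pool", p.pool)
        df.insert(2, "modality", p.modality)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=CSV_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out["_phase_rank"] = out["phase"].map(_PHASE_ORDER)
    out = out.sort_values(
        ["participant_id", "trial_index", "_phase_rank", "serial_position"],
        kind="mergesort",
    ).drop(columns="_phase_rank").reset_index(drop=True)
    return out


def write_dataset(patterns: Sequence[DataPattern], path: str | Path) -> None:
    """Write patterns to a tidy CSV in canonical, reproducible row order."""
    out = patterns_to_frame(patterns)
    out["correct"] = out["correct"].astype(int)
    out.to_csv(path, index=False, lineterminator="\n")
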