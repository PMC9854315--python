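"""Benchmark-effect presence tests: verbal disruption and rehearsal primacy.

Two well-established working-memory effects serve as per-participant
compliance criteria.  A participant who rehearses the letter sequence
verbally should (a) remember worse on the final block of trials where
rehearsal is replaced by uttering task-irrelevant syllables (articulatory
suppression / verbal disruption), and (b) recognise the first-presented
letter faster than later letters (rehearsal primacy).  Both criteria are
strict inequalities: a tie counts as the effect being absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_model import DataPattern
from .errors import EligibilityError, SummaryError

PRIMACY_YES = "yes"
PRIMACY_NO = "no"
PRIMACY_INELIGIBLE = "ineligible"


@dataclass(frozen=True)
class DisruptionResult:
    """Memory accuracy on regular vs disruption trials, and effect presence."""

    regular_memory_accuracy: float
    disruption_memory_accuracy: float
    present: bool


@dataclass(frozen=True)
class PrimacyResult:
    """Per-serial-position median RTs and primacy presence.

    ``sp_median_rts`` holds one median per serial position (NaN where the
    position has no qualifying response, in which case the pattern is
    ineligible). ``present`` is ``"yes"``/``"no"``/``"ineligible"``.
    """

    sp_median_rts: tuple[float, ...]
    present: str


@dataclass(frozen=True)
class BenchmarkResult:
    """Both benchmark outcomes for one participant."""

    participant_id: str
    regular_memory_accuracy: float
    disruption_memory_accuracy: float
    disruption_present: bool
    sp_median_rts: tuple[float, ...]
    primacy_present: str


def disruption_effect(pattern: DataPattern) -> DisruptionResult:
    """Verbal-disruption benchmark for one pattern.

    Accuracies are means over memory-phase responses only (the processing
    task is unaffected by suppressing rehearsal).  The effect is present
    iff disruption accuracy is strictly lower than regular accuracy.
    """
    regular = pattern.subset(trial_type="regular", phase="memory")
    disrupted = pattern.subset(trial_type="disruption", phase="memory")
    if regular.empty or disrupted.empty:
        raise EligibilityError(
            f"participant {pattern.participant_id!r} lacks "
            f"{'regular' if regular.empty else 'disruption'} memory responses")
    reg_acc = float(regular["correct"].mean())
    dis_acc = float(disrupted["correct"].mean())
    return DisruptionResult(reg_acc, dis_acc, present=dis_acc < reg_acc)


def _primacy_medians(pattern: DataPattern) -> np.ndarray:
    """Median RT per serial position on the qualifying response subset.

    Qualifying responses are regular-trial, memory-phase, probe-present,
    correct.  Positions run 1..max memory serial position; NaN where a
    position has no qualifying response.
    """
    mem = pattern.subset(phase="memory")
    n_pos = int(mem["serial_position"].max()) if len(mem) else 0
    qual = mem[(mem["probe_present"] == "yes") & (mem["correct"] == 1)
               & (mem["trial_type"] == "regular")]
    medians = np.full(n_pos, np.nan)
    for pos, grp in qual.groupby("serial_position"):
        medians[int(pos) - 1] = float(grp["rt_ms"].median())
    return medians


def primacy_effect(pattern: DataPattern) -> PrimacyResult:
    """RT rehearsal-primacy benchmark for one pattern.

    Present iff the median RT at serial position 1 is strictly lower than
    the mean of the remaining positions' medians; ineligible (not an
    error) when any position lacks a qualifying response.
    """
    medians = _primacy_medians(pattern)
    if medians.size < 2 or np.isnan(medians).any():
        return PrimacyResult(tuple(medians), PRIMACY_INELIGIBLE)
    present = medians[0] < float(np.mean(medians[1:]))
    return PrimacyResult(tuple(medians), PRIMACY_YES if present else PRIMACY_NO)


def benchmark_pattern(pattern: DataPattern) -> BenchmarkResult:
    """Evaluate both benchmarks on one pattern."""
    d = disruption_effect(pattern)
    p = primacy_effect(pattern)
    return BenchmarkResult(
        participant_id=pattern.participant_id,
        regular_memory_accuracy=d.regular_memory_accuracy,
        disruption_memory_accuracy=d.disruption_memory_accuracy,
        disruption_present=d.present,
        sp_median_rts=p.sp_median_rts,
        primacy_present=p.present,
    )


def benchmarks_frame(patterns: Sequence[DataPattern]) -> pd.DataFrame:
    """Tidy one-row-per-participant benchmark table."""
    rows = []
    for pattern in patterns:
        r = benchmark_pattern(pattern)
        row = {
            "participant_id": r.participant_id,
            "regular_memory_accuracy": r.regular_memory_accuracy,
            "disruption_memory_accuracy": r.disruption_memory_accuracy,
            "disruption_present": int(r.disruption_present),
            "primacy_present": r.primacy_present,
        }
        for i, m in enumerate(r.sp_median_rts, start=1):
            row[f"sp{i}_median_rt"] = m
        rows.append(row)
    return pd.DataFrame(rows)


def serial_position_curve(patterns: Sequence[DataPattern],
                          conf: float = 0.95) -> pd.DataFrame:
    """Cohort serial-position curve: mean of per-pattern median RTs.

    Uses the same qualifying subset as the primacy criterion; patterns
    with an empty serial-position cell are excluded.  Confidence intervals
    are symmetric t-based intervals around the mean.
    """
    per_pattern = [m for m in (_primacy_medians(p) for p in patterns)
                   if m.size and not np.isnan(m).any()]
    if len(per_pattern) < 2:
        raise SummaryError("serial-position curve needs >= 2 eligible patterns")
    mat = np.vstack(per_pattern)
    n = mat.shape[0]
    means = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n)
    half = sps.t.ppf(0.5 + conf / 2, df=n - 1) * sem
    return pd.DataFrame({
        "position": np.arange(1, mat.shape[1] + 1),
        "mean_ms": means,
        "ci_lo": means - half,
        "ci_hi": means + half,
        "n": n,
    })
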