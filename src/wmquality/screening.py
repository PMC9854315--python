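"""Anomalous-pattern screening (extreme-value profiling + univariate clustering).

Each participant's pattern is reduced to a small profile: the number of
extremely small RTs (below a fixed 400 ms fence), the number of extremely
large RTs (above a within-pattern fence of Q2 + 1.5*IQR, with a
Q3 + 1.5*IQR dialect selectable), the overall median RT, the accuracy on
regular trials, and the accuracy on disruption-trial memory responses.

Anomalies are then detected cohort-relatively, one dimension at a time:
the cohort's values on a dimension are split into two groups by exact
univariate 2-means, and the group on the extreme side is flagged only if
it is a minority and it is separated from the bulk group by an empty
interval that is wide relative to the bulk group's spread (unimodal
cohorts split at a dense boundary and so produce no flags).  Screening
proceeds in three sequential
sub-stages: (i) extreme-RT counts, (ii) accuracy and median RT among the
survivors, (iii) a fixed disruption-accuracy floor among the remaining
survivors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import DataPattern
from .errors import ProfilingError, ValidationError

logger = logging.getLogger(__name__)

LARGE_FENCE_RULES = ("q2_plus_1p5iqr", "q3_plus_1p5iqr")
PROFILE_SCOPES = ("regular_only", "all_trials")
CLUSTER_METHODS = ("two_means_univariate", "gaussian_mixture_2")
ACCURACY_STATS = ("mean", "median")

#: Flagging direction of each profile dimension: high counts of extreme
#: RTs, high median RT and low accuracy are the anomalous sides.
FLAG_DIRECTIONS = {
    "n_small": "high",
    "n_large": "high",
    "median_rt": "high",
    "accuracy": "low",
}

STAGE_EXTREME_COUNTS = "extreme_counts"
STAGE_CENTRAL_TENDENCY = "central_tendency"
STAGE_DISRUPTION_FLOOR = "disruption_floor"


@dataclass(frozen=True)
class ScreeningConfig:
    """Tunable parameters of the screening stage.

    ``small_fence`` (ms) is absolute; the large fence is computed within
    each pattern from its own quartiles.  ``profile_scope`` restricts
    profiling to regular trials (480 responses under the default geometry)
    or uses all trials.  ``separation_ratio`` and ``max_flag_fraction``
    guard the univariate clustering: the extreme cluster is flagged only
    if the empty interval separating it from the bulk cluster is wider
    than ``separation_ratio`` bulk standard deviations and it holds at
    most ``max_flag_fraction`` of the cohort.
    """

    small_fence: float = 400.0
    large_fence_rule: str = "q2_plus_1p5iqr"
    profile_scope: str = "regular_only"
    disruption_floor: float = 0.425
    cluster_method: str = "two_means_univariate"
    accuracy_stat: str = "mean"
    separation_ratio: float = 3.5
    max_flag_fraction: float = 0.25
    flag_directions: dict = field(default_factory=lambda: dict(FLAG_DIRECTIONS))

    def __post_init__(self) -> None:
        if self.small_fence <= 0:
            raise ValidationError("small_fence must be > 0")
        if not 0.0 <= self.disruption_floor <= 1.0:
            raise ValidationError("disruption_floor must lie in [0, 1]")
        if self.large_fence_rule not in LARGE_FENCE_RULES:
            raise ValidationError(f"unknown large_fence_rule {self.large_fence_rule!r}")
        if self.profile_scope not in PROFILE_SCOPES:
            raise ValidationError(f"unknown profile_scope {self.profile_scope!r}")
        if self.cluster_method not in CLUSTER_METHODS:
            raise ValidationError(f"unknown cluster_method {self.cluster_method!r}")
        if self.accuracy_stat not in ACCURACY_STATS:
            raise ValidationError(f"unknown accuracy_stat {self.accuracy_stat!r}")
        if self.separation_ratio <= 0 or not 0 < self.max_flag_fraction <= 0.5:
            raise ValidationError("invalid clustering guard parameters")


DEFAULT_CONFIG = ScreeningConfig()


@dataclass(frozen=True)
class ExtremeProfile:
    """Per-pattern screening profile (the clustering dimensions)."""

    n_small: int
    n_large: int
    median_rt: float
    mean_accuracy_regular: float
    disruption_accuracy: float

    def __post_init__(self) -> None:
        if self.n_small < 0 or self.n_large < 0:
            raise ValidationError("extreme counts must be non-negative")
        if not 0.0 <= self.mean_accuracy_regular <= 1.0:
            raise ValidationError("mean_accuracy_regular must lie in [0, 1]")
        if not (math.isnan(self.disruption_accuracy)
                or 0.0 <= self.disruption_accuracy <= 1.0):
            raise ValidationError("disruption_accuracy must lie in [0, 1]")


def compute_fences(rts: Sequence[float],
                   config: ScreeningConfig = DEFAULT_CONFIG) -> tuple[float, float]:
    """Small and large RT fences for one pattern's profiled RTs.

    Quartiles use linear interpolation between order statistics.  The
    large fence is Q2 + 1.5*(Q3-Q1) by default, or Q3 + 1.5*(Q3-Q1)
    under the alternative dialect.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 4:
        raise ProfilingError(
            f"need at least 4 RTs to compute quartile fences, got {rts.size}")
    q1, q2, q3 = np.quantile(rts, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    anchor = q2 if config.large_fence_rule == "q2_plus_1p5iqr" else q3
    return config.small_fence, anchor + 1.5 * iqr


def profile_pattern(pattern: DataPattern,
                    config: ScreeningConfig = DEFAULT_CONFIG) -> ExtremeProfile:
    """Profile one pattern: extreme-RT counts, median RT, accuracies.

    Fences are computed *within* the pattern from its own profiled RTs.
    With the default ``regular_only`` scope, profiled responses are the
    480 regular-trial responses; disruption accuracy is always computed on
    disruption-trial memory responses (NaN when the pattern has none).
    """
    if config.profile_scope == "regular_only":
        profiled = pattern.subset(trial_type="regular")
    else:
        profiled = pattern.records
    rts = profiled["rt_ms"].to_numpy(dtype=float)
    small_fence, large_fence = compute_fences(rts, config)

    acc = profiled["correct"].to_numpy(dtype=float)
    accuracy = float(np.mean(acc)) if config.accuracy_stat == "mean" \
        else float(np.median(acc))

    disr_mem = pattern.subset(trial_type="disruption", phase="memory")
    disruption_accuracy = (float(disr_mem["correct"].mean())
                           if len(disr_mem) else float("nan"))

    return ExtremeProfile(
        n_small=int((rts < small_fence).sum()),
        n_large=int((rts > large_fence).sum()),
        median_rt=float(np.median(rts)),
        mean_accuracy_regular=accuracy,
        disruption_accuracy=disruption_accuracy,
    )


# ---------------------------------------------------------------------------
# Univariate two-group clustering


def _two_means_split(sorted_values: np.ndarray) -> tuple[int, float]:
    """Optimal 2-means split of sorted values.

    Returns (k, ssw): the lower cluster is ``sorted_values[:k]`` and ssw
    is the total within-cluster sum of squares.  Exhaustive over the n-1
    contiguous split points (optimal 1-D clusters are contiguous), using
    prefix sums; first optimum wins on exact ties.
    """
    n = sorted_values.size
    csum = np.cumsum(sorted_values)
    csq = np.cumsum(sorted_values ** 2)
    k = np.arange(1, n)
    left_ssw = csq[k - 1] - csum[k - 1] ** 2 / k
    rsum = csum[-1] - csum[k - 1]
    rsq = csq[-1] - csq[k - 1]
    right_ssw = rsq - rsum ** 2 / (n - k)
    ssw = left_ssw + right_ssw
    best = int(np.argmin(ssw))
    return int(k[best]), float(ssw[best])


def _gmm_split(values: np.ndarray) -> np.ndarray:
    """Two-component Gaussian-mixture partition (boolean upper mask)."""
    from sklearn.mixture import GaussianMixture

    gmm = GaussianMixture(n_components=2, random_state=0, n_init=3)
    labels = gmm.fit_predict(values.reshape(-1, 1))
    means = gmm.means_.ravel()
    return labels == int(np.argmax(means))


def flag_dimension(values: Sequence[float], direction: str,
                   method: str = "two_means_univariate",
                   separation_ratio: float = 3.5,
                   max_flag_fraction: float = 0.25) -> np.ndarray:
    """Cohort-level anomaly flags on one profile dimension.

    Splits the cohort's values into two groups; the group on the extreme
    side (``direction`` ``"high"`` or ``"low"``) is flagged iff it holds
    at most ``max_flag_fraction`` of the cohort and the empty interval
    between the two groups is wider than ``separation_ratio`` standard
    deviations of the bulk group.  A unimodal cohort splits at a dense
    boundary (narrow inter-group interval), so no qualifying split exists
    and nothing is flagged; the same holds when all values are identical.
    """
    if direction not in ("high", "low"):
        raise ValidationError(f"direction must be 'high' or 'low', got {direction!r}")
    values = np.asarray(values, dtype=float)
    n = values.size
    flags = np.zeros(n, dtype=bool)
    if n < 2 or np.unique(values).size < 2:
        if n:
            logger.info("dimension has < 2 distinct values; nothing flagged")
        return flags

    if method == "two_means_univariate":
        order = np.argsort(values, kind="mergesort")
        k, _ = _two_means_split(values[order])
        upper = np.zeros(n, dtype=bool)
        upper[order[k:]] = True
    elif method == "gaussian_mixture_2":
        upper = _gmm_split(values)
    else:
        raise ValidationError(f"unknown cluster method {method!r}")

    extreme = upper if direction == "high" else ~upper
    if not extreme.any() or extreme.all():
        return flags
    if extreme.sum() > max_flag_fraction * n:
        return flags
    gap = float(values[upper].min() - values[~upper].max())
    bulk_sd = float(values[~extreme].std())
    if gap > 0 and (gap > separation_ratio * bulk_sd):
        flags = extreme
    return flags


# ---------------------------------------------------------------------------
# Sequential cohort screening

STATUS_ANOMALOUS = "anomalous"
STATUS_RETAINED = "retained"
STATUS_UNPROFILED = "unprofiled"


@dataclass
class ScreeningVerdict:
    """Per-participant outcome of the three-sub-stage screening."""

    participant_id: str
    pool: str
    profile: ExtremeProfile | None
    stage: str | None  # which sub-stage fired, None if retained
    status: str


def screen_cohort(patterns: Sequence[DataPattern],
                  config: ScreeningConfig = DEFAULT_CONFIG) -> list[ScreeningVerdict]:
    """Apply the three sequential anomaly sub-stages to a cohort.

    (i) cluster-flag on the counts of extremely small and large RTs;
    (ii) on the survivors, cluster-flag on accuracy (low) and median RT
    (high); (iii) on the remaining survivors, flag disruption accuracy
    below the fixed floor.  Clustering is pooled over the whole cohort
    (all pools together).  Patterns that cannot be profiled are excluded
    with status ``"unprofiled"``.
    """
    if len(patterns) < 2:
        raise ValidationError("screening needs at least 2 patterns")

    verdicts: list[ScreeningVerdict] = []
    profiled_idx: list[int] = []
    for i, pattern in enumerate(patterns):
        try:
            profile = profile_pattern(pattern, config)
        except ProfilingError as exc:
            logger.warning("could not profile %s: %s", pattern.participant_id, exc)
            verdicts.append(ScreeningVerdict(
                pattern.participant_id, pattern.pool, None, None,
                STATUS_UNPROFILED))
            continue
        verdicts.append(ScreeningVerdict(
            pattern.participant_id, pattern.pool, profile, None,
            STATUS_RETAINED))
        profiled_idx.append(i)

    def cluster(dim_values: np.ndarray, dimension: str) -> np.ndarray:
        return flag_dimension(
            dim_values, config.flag_directions[dimension],
            method=config.cluster_method,
            separation_ratio=config.separation_ratio,
            max_flag_fraction=config.max_flag_fraction)

    def mark(indices: list[int], flags: np.ndarray, stage: str) -> list[int]:
        survivors = []
        for idx, flagged in zip(indices, flags):
            if flagged:
                verdicts[idx].stage = stage
                verdicts[idx].status = STATUS_ANOMALOUS
            else:
                survivors.append(idx)
        return survivors

    # sub-stage (i): extreme-RT counts
    idx = profiled_idx
    if len(idx) >= 2:
        n_small = np.array([verdicts[i].profile.n_small for i in idx], float)
        n_large = np.array([verdicts[i].profile.n_large for i in idx], float)
        idx = mark(idx, cluster(n_small, "n_small") | cluster(n_large, "n_large"),
                   STAGE_EXTREME_COUNTS)

    # sub-stage (ii): accuracy and central RT among survivors
    if len(idx) >= 2:
        acc = np.array([verdicts[i].profile.mean_accuracy_regular for i in idx])
        med = np.array([verdicts[i].profile.median_rt for i in idx])
        idx = mark(idx, cluster(acc, "accuracy") | cluster(med, "median_rt"),
                   STAGE_CENTRAL_TENDENCY)

    # sub-stage (iii): disruption-accuracy floor
    floor_flags = np.array([
        not math.isnan(verdicts[i].profile.disruption_accuracy)
        and verdicts[i].profile.disruption_accuracy < config.disruption_floor
        for i in idx])
    if len(idx):
        mark(idx, floor_flags, STAGE_DISRUPTION_FLOOR)

    return verdicts


def verdicts_frame(verdicts: Sequence[ScreeningVerdict]) -> pd.DataFrame:
    """Tidy one-row-per-participant view of screening verdicts."""
    rows = []
    for v in verdicts:
        p = v.profile
        rows.append({
            "participant_id": v.participant_id,
            "pool": v.pool,
            "n_small": p.n_small if p else pd.NA,
            "n_large": p.n_large if p else pd.NA,
            "median_rt": p.median_rt if p else float("nan"),
            "accuracy": p.mean_accuracy_regular if p else float("nan"),
            "disruption_accuracy": p.disruption_accuracy if p else float("nan"),
            "stage_flagged": v.stage or "",
            "status": v.status,
        })
    return pd.DataFrame(rows)
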