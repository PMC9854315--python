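"""Sequential-filter orchestration and the summary report.

Runs the three-part filter over a multi-pool dataset — (1) anomalous-
pattern screening, (2) verbal-disruption benchmark on the survivors,
(3) rehearsal-primacy benchmark on the remaining survivors — and emits a
per-pool, per-step summary with Wilson intervals plus pairwise Fisher
exact comparisons between adjacent pools (lab vs web students, web
students vs Prolific, Prolific vs MTurk).
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .benchmarks import (PRIMACY_INELIGIBLE, PRIMACY_YES, disruption_effect,
                         primacy_effect)
from .core_model import POOLS, DataPattern
from .errors import DomainError, ValidationError
from .screening import (DEFAULT_CONFIG, STATUS_RETAINED, STATUS_UNPROFILED,
                        ScreeningConfig, screen_cohort)
from .stats import ProportionSummary, fisher_exact, round_half_up

logger = logging.getLogger(__name__)

STEPS = ("anomalous", "no_disruption", "no_primacy", "final_retained")

#: Adjacent-pool comparison scheme: modality effect (lab vs web students),
#: then pool effects (students vs Prolific, Prolific vs MTurk).
DEFAULT_PAIRS = (
    ("student_lab", "student_web"),
    ("student_web", "prolific"),
    ("prolific", "mturk"),
)

POOL_ORDER = ("student_lab", "student_web", "prolific", "mturk")


@dataclass(frozen=True)
class StepRow:
    """One (filter step, pool) cell of the summary table.

    For the three filter steps ``n_flagged`` counts patterns failing the
    criterion out of the ``n_in`` evaluated; for ``final_retained`` it
    counts retained patterns out of the pool's initial N.
    """

    step: str
    pool: str
    n_in: int
    n_flagged: int
    pct_flagged: float
    wilson: ProportionSummary


@dataclass(frozen=True)
class PairComparison:
    """Fisher exact comparison of one step's flag rates in two pools."""

    step: str
    pool_a: str
    pool_b: str
    k_a: int
    n_a: int
    k_b: int
    n_b: int
    p_value: float
    marker: str


@dataclass
class PipelineReport:
    """Full outcome of the sequential filter."""

    rows: list[StepRow]
    comparisons: list[PairComparison]
    retained_ids: dict[str, list[str]]
    ineligible_ids: dict[str, list[str]] = field(default_factory=dict)
    unprofiled_ids: dict[str, list[str]] = field(default_factory=dict)

    def row(self, step: str, pool: str) -> StepRow:
        for r in self.rows:
            if r.step == step and r.pool == pool:
                return r
        raise KeyError((step, pool))


def significance_marker(p: float) -> str:
    """Printed significance granularity: '≈', 'p < .05' or 'p < .001'."""
    if p < 0.001:
        return "p < .001"
    if p < 0.05:
        return "p < .05"
    return "≈"


def relative_loss(reference_pct: float, comparison_pct: float) -> float:
    """Relative loss of the comparison vs the reference, in percent.

    E.g. retention falling from 87.6% (reference) to 72.6% is a relative
    loss of 17.1%.  One-decimal half-up display rounding.
    """
    if reference_pct <= 0:
        raise DomainError("reference percentage must be positive")
    return round_half_up(100.0 * (reference_pct - comparison_pct) / reference_pct)


def run_pipeline(patterns: Sequence[DataPattern],
                 config: ScreeningConfig = DEFAULT_CONFIG,
                 pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS) -> PipelineReport:
    """Run the three-part sequential filter and summarise it per pool.

    Screening thresholds are cohort-relative (clustering pools all
    patterns together); benchmark criteria are per-pattern.  Pools with no
    patterns are excluded from the table; comparisons are computed for the
    requested pairs whose pools are both present.
    """
    pools_present: list[str] = []
    for p in patterns:
        if p.pool not in POOLS:
            raise ValidationError(f"unknown pool label {p.pool!r}")
        if p.pool not in pools_present:
            pools_present.append(p.pool)
    pools_present.sort(key=POOL_ORDER.index)

    by_id = {p.participant_id: p for p in patterns}

    # Part 1: anomaly screening on the full cohort
    verdicts = screen_cohort(patterns, config)
    anomalous = {v.participant_id for v in verdicts if v.status == "anomalous"}
    unprofiled = {v.participant_id for v in verdicts
                  if v.status == STATUS_UNPROFILED}
    survivors1 = [v.participant_id for v in verdicts
                  if v.status == STATUS_RETAINED]

    # Part 2: verbal-disruption benchmark on the survivors
    no_disruption: set[str] = set()
    survivors2: list[str] = []
    for pid in survivors1:
        if disruption_effect(by_id[pid]).present:
            survivors2.append(pid)
        else:
            no_disruption.add(pid)

    # Part 3: rehearsal-primacy benchmark on the remaining survivors
    no_primacy: set[str] = set()
    ineligible: set[str] = set()
    retained: list[str] = []
    for pid in survivors2:
        outcome = primacy_effect(by_id[pid]).present
        if outcome == PRIMACY_INELIGIBLE:
            ineligible.add(pid)
        elif outcome == PRIMACY_YES:
            retained.append(pid)
        else:
            no_primacy.add(pid)

    def pool_ids(ids, pool):
        return [pid for pid in ids if by_id[pid].pool == pool]

    rows: list[StepRow] = []
    counts: dict[tuple[str, str], tuple[int, int]] = {}
    for pool in pools_present:
        n0 = sum(1 for p in patterns if p.pool == pool)
        k1 = len(pool_ids(anomalous, pool))
        n_unprof = len(pool_ids(unprofiled, pool))
        n2 = n0 - k1 - n_unprof
        k2 = len(pool_ids(no_disruption, pool))
        n3 = n2 - k2 - len(pool_ids(ineligible, pool))
        k3 = len(pool_ids(no_primacy, pool))
        kr = len(pool_ids(retained, pool))
        for step, n_in, k in (("anomalous", n0, k1),
                              ("no_disruption", n2, k2),
                              ("no_primacy", n3, k3),
                              ("final_retained", n0, kr)):
            counts[(step, pool)] = (k, n_in)
            rows.append(StepRow(
                step=step, pool=pool, n_in=n_in, n_flagged=k,
                pct_flagged=100.0 * k / n_in if n_in else float("nan"),
                wilson=ProportionSummary.from_counts(k, n_in) if n_in else
                ProportionSummary(0, 0, float("nan"), float("nan"), float("nan")),
            ))

    comparisons: list[PairComparison] = []
    for pool_a, pool_b in pairs:
        if pool_a not in pools_present or pool_b not in pools_present:
            continue
        for step in STEPS:
            k_a, n_a = counts[(step, pool_a)]
            k_b, n_b = counts[(step, pool_b)]
            if min(n_a, n_b) == 0 or (k_a + k_b == 0) or \
                    (k_a == n_a and k_b == n_b):
                p = 1.0  # degenerate margin: no evidence of a difference
            else:
                p = fisher_exact(k_a, n_a - k_a, k_b, n_b - k_b)
            comparisons.append(PairComparison(
                step=step, pool_a=pool_a, pool_b=pool_b,
                k_a=k_a, n_a=n_a, k_b=k_b, n_b=n_b,
                p_value=p, marker=significance_marker(p)))

    return PipelineReport(
        rows=rows,
        comparisons=comparisons,
        retained_ids={pool: pool_ids(retained, pool) for pool in pools_present},
        ineligible_ids={pool: pool_ids(ineligible, pool) for pool in pools_present},
        unprofiled_ids={pool: pool_ids(unprofiled, pool) for pool in pools_present},
    )


# ---------------------------------------------------------------------------
# Rendering

STEP_LABELS = {
    "anomalous": "% anomalous samples",
    "no_disruption": "% no verbal disruption effect",
    "no_primacy": "% no rehearsal primacy effect",
    "final_retained": "% of total remaining",
}


def _report_dict(report: PipelineReport) -> dict:
    return {
        "rows": [asdict(r) for r in report.rows],
        "comparisons": [asdict(c) for c in report.comparisons],
        "retained_ids": report.retained_ids,
        "ineligible_ids": report.ineligible_ids,
        "unprofiled_ids": report.unprofiled_ids,
    }


def _render_csv(report: PipelineReport) -> str:
    records = []
    for r in report.rows:
        records.append({
            "record_type": "step", "step": r.step, "pool": r.pool,
            "n_in": r.n_in, "n_flagged": r.n_flagged,
            "pct_flagged": r.pct_flagged,
            "wilson_lo": r.wilson.wilson_lo, "wilson_hi": r.wilson.wilson_hi,
            "pool_b": "", "p_value": "", "marker": "",
        })
    for c in report.comparisons:
        records.append({
            "record_type": "comparison", "step": c.step, "pool": c.pool_a,
            "n_in": c.n_a, "n_flagged": c.k_a, "pct_flagged": "",
            "wilson_lo": "", "wilson_hi": "",
            "pool_b": c.pool_b, "p_value": c.p_value, "marker": c.marker,
        })
    buf = io.StringIO()
    pd.DataFrame(records).to_csv(buf, index=False, lineterminator="\n")
    return buf.getvalue()


def _render_text(report: PipelineReport) -> str:
    pools = [p for p in POOL_ORDER
             if any(r.pool == p for r in report.rows)]
    markers = {(c.step, c.pool_a, c.pool_b): c.marker
               for c in report.comparisons}
    width = 14
    lines = []
    header = ["criterion".ljust(28)]
    for i, pool in enumerate(pools):
        header.append(pool.center(width))
        if i + 1 < len(pools):
            header.append(" " * 9)
    lines.append("".join(header))
    for step in STEPS:
        n_line = [f"step N".ljust(28)]
        pct_line = [STEP_LABELS[step].ljust(28)]
        ci_line = ["95% CI".ljust(28)]
        for i, pool in enumerate(pools):
            try:
                r = report.row(step, pool)
            except KeyError:
                continue
            n_line.append(str(r.n_in).center(width))
            pct_line.append(f"{round_half_up(r.pct_flagged):.1f}".center(width))
            ci_line.append(
                f"[{round_half_up(r.wilson.wilson_lo):.1f}, "
                f"{round_half_up(r.wilson.wilson_hi):.1f}]".center(width))
            if i + 1 < len(pools):
                mark = markers.get((step, pool, pools[i + 1]), "")
                n_line.append(" " * 9)
                pct_line.append(" " * 9)
                ci_line.append(mark.center(9))
        lines.extend(["".join(n_line), "".join(pct_line), "".join(ci_line), ""])
    return "\n".join(lines)


def render_report(report: PipelineReport, format: str = "text",
                  path: str | Path | None = None) -> str:
    """Render the report as ``csv``, ``json`` or a Table-2-style ``text`` table.

    The text table shows percentages at one decimal and significance at
    the printed granularity; raw p-values and unrounded percentages are in
    the CSV/JSON renderings.  Returns the rendered string and writes it to
    ``path`` when given.
    """
    if format == "json":
        out = json.dumps(_report_dict(report), indent=2, ensure_ascii=False)
    elif format == "csv":
        out = _render_csv(report)
    elif format in ("text", "text-table"):
        out = _render_text(report)
    else:
        raise ValidationError(f"unsupported report format {format!r}")
    if path is not None:
        Path(path).write_text(out, encoding="utf-8")
    return out


def reconstruct_step_counts(n_initial: int,
                            pct_flagged: Sequence[float]) -> list[tuple[int, int]]:
    """Reconstruct a sequential-filter N-chain from printed percentages.

    Given the initial N and the printed per-step flagged percentages,
    returns [(n_in, n_flagged), ...] per step with flagged counts rounded
    half-up to integers — the arithmetic needed to recover counts from a
    published summary table.
    """
    if n_initial < 1:
        raise DomainError("n_initial must be >= 1")
    chain = []
    n = n_initial
    for pct in pct_flagged:
        k = int(round_half_up(n * pct / 100.0, 0))
        chain.append((n, k))
        n -= k
    return chain
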