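"""Verbal-disruption and rehearsal-primacy benchmark criteria."""

import numpy as np
import pytest

from wmquality.benchmarks import (disruption_effect, primacy_effect,
                                  benchmarks_frame, serial_position_curve)
from wmquality.errors import EligibilityError, SummaryError

from conftest import build_pattern


def _acc(regular: float, disruption: float):
    """Correctness schedule hitting the given memory accuracies exactly.

    Rates must be multiples of 0.1; memory responses are numbered
    consecutively and every block of 10 holds exactly rate*10 correct ones
    (240 regular and 40 disruption memory responses are both divisible by
    10, so the means are exact).
    """
    def correct(trial, ttype, phase, sp):
        if phase != "memory":
            return 1
        rate = disruption if ttype == "disruption" else regular
        idx = (trial - 1) * 4 + (sp - 1)
        return int(idx % 10 < round(rate * 10))
    return correct


def test_disruption_present_when_strictly_lower():
    pattern = build_pattern(correct=_acc(regular=0.90, disruption=0.70))
    result = disruption_effect(pattern)
    assert result.disruption_memory_accuracy < result.regular_memory_accuracy
    assert result.present


def test_disruption_tie_counts_as_absent():
    pattern = build_pattern(correct=_acc(regular=0.80, disruption=0.80))
    result = disruption_effect(pattern)
    assert result.regular_memory_accuracy == pytest.approx(
        result.disruption_memory_accuracy)
    assert not result.present


def test_disruption_ignores_processing_responses():
    """Part-2 accuracy uses memory responses only."""
    base = build_pattern(correct=_acc(0.90, 0.70))
    flipped = build_pattern(correct=lambda t, tt, ph, sp:
                            0 if ph == "processing"
                            else _acc(0.90, 0.70)(t, tt, ph, sp))
    a, b = disruption_effect(base), disruption_effect(flipped)
    assert a == b


def test_disruption_requires_both_trial_types():
    from wmquality.core_model import DataPattern
    pattern = build_pattern()
    regular_only = DataPattern(
        "p0", "student_web", "web",
        pattern.subset(trial_type="regular").reset_index(drop=True))
    with pytest.raises(EligibilityError):
        disruption_effect(regular_only)


def _sp_rt(sp_values):
    def rt(trial, ttype, phase, sp):
        if phase == "memory":
            return float(sp_values[sp - 1])
        return 900.0
    return rt


def test_primacy_present_for_faster_first_position():
    pattern = build_pattern(rt=_sp_rt([900, 1100, 1150, 1200]))
    result = primacy_effect(pattern)
    assert result.sp_median_rts == (900.0, 1100.0, 1150.0, 1200.0)
    assert result.present == "yes"  # 900 < mean(1100, 1150, 1200) = 1150


def test_primacy_tie_counts_as_absent():
    result = primacy_effect(build_pattern(rt=1000.0))
    assert result.present == "no"


def test_primacy_ineligible_when_a_position_has_no_qualifying_response():
    def correct(trial, ttype, phase, sp):
        if phase == "memory" and sp == 4:
            return 0  # never correct at SP4 -> empty cell
        return 1
    result = primacy_effect(build_pattern(rt=_sp_rt([900, 1100, 1150, 1200]),
                                          correct=correct))
    assert result.present == "ineligible"
    assert np.isnan(result.sp_median_rts[3])


def test_primacy_uses_only_probe_present_correct_regular_memory():
    """Corrupting every non-qualifying response leaves the medians unchanged."""
    pattern = build_pattern(rt=_sp_rt([900, 1100, 1150, 1200]))
    corrupted = pattern.records.copy()
    non_qualifying = ~((corrupted["phase"] == "memory")
                       & (corrupted["probe_present"] == "yes")
                       & (corrupted["correct"] == 1)
                       & (corrupted["trial_type"] == "regular"))
    corrupted.loc[non_qualifying, "rt_ms"] *= 10
    from wmquality.core_model import DataPattern
    noisy = DataPattern("p0", "student_web", "web", corrupted)
    assert primacy_effect(noisy) == primacy_effect(pattern)


def test_compliant_cohort_shows_both_effects(compliant_cohort_500):
    """The generative disruption decrement makes presence near-certain."""
    frame = benchmarks_frame(compliant_cohort_500)
    assert frame["disruption_present"].mean() > 0.95
    assert (frame["primacy_present"] == "yes").mean() > 0.80


def test_null_simulator_presence_rates_are_coin_flips(null_cohort_500):
    """With no decrement and no primacy advantage, both presence rates sit
    at chance - a type-I calibration of the strict-inequality criteria."""
    frame = benchmarks_frame(null_cohort_500)
    n = len(frame)
    tol = 3 * np.sqrt(0.25 / n)
    assert abs(frame["disruption_present"].mean() - 0.5) <= tol
    assert abs((frame["primacy_present"] == "yes").mean() - 0.5) <= tol


def test_curve_identical_patterns_zero_halfwidth():
    patterns = [build_pattern(f"p{i}", rt=_sp_rt([900, 1100, 1150, 1200]))
                for i in range(2)]
    curve = serial_position_curve(patterns)
    assert curve["mean_ms"].tolist() == [900.0, 1100.0, 1150.0, 1200.0]
    assert np.allclose(curve["ci_hi"] - curve["ci_lo"], 0.0)
    assert (curve["n"] == 2).all()


def test_curve_shows_primacy_for_compliant_cohort(compliant_cohort_500):
    curve = serial_position_curve(compliant_cohort_500[:200])
    sp1 = curve.loc[curve["position"] == 1, "mean_ms"].item()
    assert all(sp1 < curve.loc[curve["position"] == p, "mean_ms"].item()
               for p in (2, 3, 4))


def test_curve_of_primacy_present_patterns_satisfies_criterion(
        compliant_cohort_500):
    keep = [p for p in compliant_cohort_500[:100]
            if primacy_effect(p).present == "yes"]
    curve = serial_position_curve(keep)
    means = curve["mean_ms"].to_numpy()
    assert means[0] < means[1:].mean()


def test_curve_needs_two_patterns():
    with pytest.raises(SummaryError):
        serial_position_curve([build_pattern()])
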