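"""Extreme-value fences, univariate cluster flagging, sequential screening."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wmquality.errors import ProfilingError, ValidationError
from wmquality.screening import (ScreeningConfig, compute_fences,
                                 flag_dimension, profile_pattern,
                                 screen_cohort)
from wmquality.simulate import ARCHETYPES, simulate_participant

from conftest import build_pattern


# ---------------------------------------------------------------------------
# Fences and profiles


def test_large_fence_formula_q2_dialect():
    """Q1=600, Q2=800, Q3=1000 -> fence 800 + 1.5*400 = 1400 ms."""
    rts = [400, 600, 800, 1000, 1200]
    small, large = compute_fences(rts, ScreeningConfig())
    assert small == 400
    assert large == pytest.approx(1400.0)
    _, large_q3 = compute_fences(
        rts, ScreeningConfig(large_fence_rule="q3_plus_1p5iqr"))
    assert large_q3 == pytest.approx(1600.0)


def test_identical_rts_give_no_extremes():
    pattern = build_pattern(rt=500.0)
    profile = profile_pattern(pattern)
    assert profile.n_small == 0 and profile.n_large == 0
    assert profile.median_rt == 500.0


def test_profile_counts_and_scope(compliant_pattern):
    """Default scope profiles only the 480 regular-trial responses."""
    profile = profile_pattern(compliant_pattern)
    regular = compliant_pattern.subset(trial_type="regular")
    rts = regular["rt_ms"].to_numpy()
    _, fence = compute_fences(rts)
    assert profile.n_small == int((rts < 400).sum())
    assert profile.n_large == int((rts > fence).sum())
    assert profile.n_small + profile.n_large <= 480
    assert profile.median_rt == pytest.approx(np.median(rts))
    assert profile.mean_accuracy_regular == pytest.approx(
        regular["correct"].mean())


def test_small_fence_monotonicity(compliant_pattern):
    """Raising the small fence never decreases n_small; Q2 fence >= Q3 counts."""
    n_small = [profile_pattern(compliant_pattern,
                               ScreeningConfig(small_fence=f)).n_small
               for f in (200.0, 400.0, 600.0, 900.0)]
    assert n_small == sorted(n_small)
    q2 = profile_pattern(compliant_pattern,
                         ScreeningConfig(large_fence_rule="q2_plus_1p5iqr"))
    q3 = profile_pattern(compliant_pattern,
                         ScreeningConfig(large_fence_rule="q3_plus_1p5iqr"))
    assert q2.n_large >= q3.n_large


def test_too_few_responses_is_a_profiling_error():
    with pytest.raises(ProfilingError):
        compute_fences([500.0, 600.0, 700.0])


# ---------------------------------------------------------------------------
# Univariate cluster flagging


def test_flag_single_high_outlier():
    flags = flag_dimension([1, 2, 1, 3, 2, 45], "high")
    assert flags.tolist() == [False, False, False, False, False, True]


def test_flag_single_low_outlier():
    flags = flag_dimension([0.91, 0.88, 0.90, 0.35], "low")
    assert flags.tolist() == [False, False, False, True]


def test_identical_values_give_no_flags():
    assert not flag_dimension([5.0] * 8, "high").any()


def test_unimodal_cohort_gives_no_flags():
    rng = np.random.default_rng(0)
    values = rng.normal(40, 6, size=200)
    assert not flag_dimension(values, "high").any()
    assert not flag_dimension(values, "low").any()


def test_majority_group_is_never_flagged():
    # a 50/50 bimodal cohort has no minority extreme cluster
    values = [1.0] * 10 + [100.0] * 10
    assert not flag_dimension(values, "high").any()


def test_gaussian_mixture_method_agrees_on_separated_cohort():
    values = [1, 2, 1, 3, 2, 3, 45, 50]
    km = flag_dimension(values, "high", method="two_means_univariate")
    gm = flag_dimension(values, "high", method="gaussian_mixture_2")
    assert km.tolist() == gm.tolist() == [False] * 6 + [True, True]


def test_two_means_matches_sklearn_kmeans_partition():
    """The exhaustive 1-D split equals scikit-learn's 2-means clustering."""
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(4)
    values = np.concatenate([rng.normal(10, 2, 30), rng.normal(60, 3, 6)])
    from wmquality.screening import _two_means_split
    order = np.argsort(values)
    k, _ = _two_means_split(values[order])
    ours = np.zeros(values.size, bool)
    ours[order[k:]] = True
    labels = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(
        values.reshape(-1, 1))
    upper_label = labels[np.argmax(values)]
    assert np.array_equal(ours, labels == upper_label)


def _oracle_flags(values, direction, ratio=3.5, max_frac=0.25):
    """Brute-force reference: scan every contiguous split of the sorted
    values, pick the minimum within-group sum of squares, apply the same
    minority + gap guards."""
    vals = np.asarray(values, float)
    n = vals.size
    flags = np.zeros(n, bool)
    if n < 2 or np.unique(vals).size < 2:
        return flags
    order = np.argsort(vals, kind="mergesort")
    s = vals[order]
    best_k, best_ssw = None, math.inf
    for k in range(1, n):
        ssw = float(np.var(s[:k]) * k + np.var(s[k:]) * (n - k))
        if ssw < best_ssw - 1e-12:
            best_k, best_ssw = k, ssw
    lower, upper = s[:best_k], s[best_k:]
    ext_idx = order[best_k:] if direction == "high" else order[:best_k]
    ext = upper if direction == "high" else lower
    bulk = lower if direction == "high" else upper
    if ext.size > max_frac * n:
        return flags
    gap = upper.min() - lower.max()
    if gap > 0 and gap > ratio * bulk.std():
        flags[ext_idx] = True
    return flags


@given(st.lists(st.integers(min_value=0, max_value=30), min_size=2,
                max_size=20),
       st.sampled_from(["high", "low"]))
def test_flag_dimension_matches_brute_force_oracle(values, direction):
    ours = flag_dimension(values, direction)
    ref = _oracle_flags(values, direction)
    assert ours.tolist() == ref.tolist()


# ---------------------------------------------------------------------------
# Sequential cohort screening


def test_clean_compliant_cohort_has_no_anomalies():
    patterns = [simulate_participant(ARCHETYPES["compliant"], seed=i,
                                     participant_id=f"c{i:03d}",
                                     pool="student_lab")
                for i in range(40)]
    verdicts = screen_cohort(patterns)
    assert sum(v.status == "anomalous" for v in verdicts) == 0


def test_planted_pure_guesser_is_the_only_flag():
    guesser = dataclasses.replace(ARCHETYPES["fast_guesser"], p_guess=1.0)
    patterns = [simulate_participant(ARCHETYPES["compliant"], seed=i,
                                     participant_id=f"c{i:03d}")
                for i in range(99)]
    patterns.append(simulate_participant(guesser, seed=7,
                                         participant_id="guesser"))
    verdicts = screen_cohort(patterns)
    flagged = [(v.participant_id, v.stage)
               for v in verdicts if v.status == "anomalous"]
    assert flagged == [("guesser", "extreme_counts")]


def test_disruption_floor_fires_on_stage_three():
    """A pattern below the 0.425 disruption-accuracy floor is flagged even
    when its regular-trial profile is unremarkable."""
    def low_disruption_correct(trial, ttype, phase, sp):
        if ttype == "disruption" and phase == "memory":
            return int((trial * 4 + sp) % 10 < 3)  # ~0.30 accuracy
        return 1

    rng = np.random.default_rng(2)
    cohort = [build_pattern(f"ok{i}", rt=rng.normal(800, 30, 560))
              for i in range(20)]
    cohort.append(build_pattern("floor", rt=rng.normal(800, 30, 560),
                                correct=low_disruption_correct))
    verdicts = screen_cohort(cohort)
    by_id = {v.participant_id: v for v in verdicts}
    assert by_id["floor"].status == "anomalous"
    assert by_id["floor"].stage == "disruption_floor"
    assert by_id["floor"].profile.disruption_accuracy < 0.425
    assert all(v.status == "retained" for v in verdicts
               if v.participant_id != "floor")


def test_screening_conservation(prolific_cohort_300):
    verdicts = screen_cohort(prolific_cohort_300.patterns)
    counts = {"anomalous": 0, "retained": 0, "unprofiled": 0}
    for v in verdicts:
        counts[v.status] += 1
    assert sum(counts.values()) == len(prolific_cohort_300.patterns)


def test_contaminant_recovery_at_preset_scale(prolific_cohort_300):
    """Planted guessers/slow/low performers are caught; compliants are not."""
    status = {v.participant_id: v.status
              for v in screen_cohort(prolific_cohort_300.patterns)}
    labels = prolific_cohort_300.labels

    def rate(archetypes):
        ids = [pid for pid, a in labels.items() if a in archetypes]
        return np.mean([status[pid] == "anomalous" for pid in ids]), len(ids)

    caught, n_planted = rate({"fast_guesser", "slow_responder", "low_performer"})
    assert n_planted >= 10
    assert caught >= 0.90
    false_alarms, _ = rate({"compliant"})
    assert false_alarms <= 0.05


def test_config_validation():
    with pytest.raises(ValidationError):
        ScreeningConfig(small_fence=-1)
    with pytest.raises(ValidationError):
        ScreeningConfig(large_fence_rule="q4")
    with pytest.raises(ValidationError):
        flag_dimension([1, 2], "sideways")
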