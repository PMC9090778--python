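"""Event matching, metrics, by-subject statistics, split selection."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import spindleseg as sg
from spindleseg.events import EventList
from spindleseg.evaluate import (
    MatchCounts,
    compare_summaries,
    f1_curve_and_bar,
    fisher_z_difference,
    match_events,
    pooled_match,
    prf,
    relative_overlap,
    select_test_split,
    sigma_baseline_detector,
    subject_summary,
)
from spindleseg.preprocess import EEGSegment


def optimal_tp(detected, reference, threshold):
    """Independent oracle: maximum one-to-one matching of above-threshold
    pairs via optimal assignment."""
    nd, nr = len(detected), len(reference)
    if nd == 0 or nr == 0:
        return 0
    eligible = np.zeros((nd, nr))
    for i, d in enumerate(detected):
        for j, r in enumerate(reference):
            if relative_overlap(d, r) > threshold:
                eligible[i, j] = 1
    rows, cols = linear_sum_assignment(-eligible)
    return int(eligible[rows, cols].sum())


def random_events(rng, n_max=6, span=30.0):
    n = rng.integers(0, n_max + 1)
    events = []
    t = 0.0
    for _ in range(n):
        t += rng.uniform(0.1, span / max(n, 1))
        d = rng.uniform(0.2, 2.0)
        events.append((t, d))
        t += d
    return EventList(events)


def test_relative_overlap_examples():
    assert relative_overlap((2.0, 1.0), (2.0, 1.0)) == 1.0
    assert relative_overlap((0.0, 1.0), (5.0, 1.0)) == 0.0
    assert relative_overlap((0.0, 1.0), (0.5, 1.0)) == pytest.approx(1 / 3)
    with pytest.raises(ValueError, match="positive"):
        relative_overlap((0.0, 0.0), (0.0, 1.0))


def test_match_events_trivial_cases():
    ref = EventList([(1.0, 0.5), (3.0, 0.7), (6.0, 1.0)])
    perfect = match_events(ref, ref, 0.9)
    assert (perfect.tp, perfect.fp, perfect.fn) == (3, 0, 0)
    empty = match_events(EventList([]), ref, 0.2)
    assert (empty.tp, empty.fp, empty.fn) == (0, 0, 3)


def test_greedy_matching_close_to_optimal_assignment():
    rng = np.random.default_rng(0)
    mismatches = 0
    trials = 300
    for _ in range(trials):
        det, ref = random_events(rng), random_events(rng)
        threshold = rng.choice([0.0, 0.2, 0.5])
        greedy = match_events(det, ref, threshold).tp
        optimal = optimal_tp(det, ref, threshold)
        assert greedy <= optimal
        assert optimal - greedy <= 1
        mismatches += greedy != optimal
    assert mismatches / trials < 0.05


def test_match_counts_invariants():
    rng = np.random.default_rng(1)
    for _ in range(50):
        det, ref = random_events(rng), random_events(rng)
        c = match_events(det, ref, 0.2)
        assert c.tp <= len(ref) and c.tp <= len(det)
        assert c.fn == len(ref) - c.tp
        assert c.fp == len(det) - c.tp


def test_prf_formulas_and_conventions():
    m = prf(MatchCounts(1, 1, 1, 0.2))
    assert (m.recall, m.precision, m.f1) == (0.5, 0.5, 0.5)
    perfect_empty = prf(MatchCounts(0, 0, 0, 0.2))
    assert (perfect_empty.recall, perfect_empty.precision, perfect_empty.f1) == (1, 1, 1)
    assert prf(MatchCounts(0, 2, 0, 0.2)).precision == 0.0
    assert prf(MatchCounts(0, 0, 2, 0.2)).recall == 0.0


def test_f1_is_harmonic_mean():
    rng = np.random.default_rng(2)
    for _ in range(30):
        tp, fp, fn = rng.integers(1, 20, 3)
        m = prf(MatchCounts(int(tp), int(fp), int(fn), 0.2))
        harmonic = 2 * m.precision * m.recall / (m.precision + m.recall)
        assert m.f1 == pytest.approx(harmonic)


def test_metric_symmetry_under_swap():
    rng = np.random.default_rng(3)
    det, ref = random_events(rng), random_events(rng)
    a = prf(match_events(det, ref, 0.2))
    b = prf(match_events(ref, det, 0.2))
    assert a.recall == pytest.approx(b.precision)
    assert a.precision == pytest.approx(b.recall)
    assert a.f1 == pytest.approx(b.f1)


def test_f1_bar_normalization():
    ref = EventList([(1.0, 0.5), (3.0, 0.7)])
    m = f1_curve_and_bar(ref, ref)
    # perfect detection: F1 = 1 up to the last grid point; the strict
    # overlap rule zeroes the 1.0 endpoint, costing half the last interval
    assert all(f == 1.0 for _, f in m.f1_curve[:-1])
    assert m.f1_bar == pytest.approx((0.90 + 0.025) / 0.95)
    # a truly constant curve normalizes to its own value
    const = [(t, 0.6) for t, _ in m.f1_curve]
    f1s = [f for _, f in const]
    grid = [t for t, _ in const]
    assert np.trapezoid(f1s, grid) / (grid[-1] - grid[0]) == pytest.approx(0.6)
    with pytest.raises(ValueError, match="grid"):
        f1_curve_and_bar(ref, ref, grid=[0.2])


def test_f1_curve_monotone_non_increasing():
    rng = np.random.default_rng(4)
    for _ in range(100):
        det, ref = random_events(rng), random_events(rng)
        m = f1_curve_and_bar(det, ref)
        f1s = [f for _, f in m.f1_curve]
        assert all(a >= b - 1e-12 for a, b in zip(f1s, f1s[1:]))


def test_subject_summary_density_arithmetic():
    events = [EventList([(1, 0.5), (3, 0.6)]), EventList([(2, 0.7)]), EventList([(0.5, 0.8), (9, 0.5), (20, 0.6)])]
    s = subject_summary(events, total_minutes=3 * 115 / 60, subject_id="x")
    assert s.density == pytest.approx(6 / (345 / 60))
    assert s.density == pytest.approx(1.043, abs=1e-3)
    assert s.mean_duration == pytest.approx(np.mean([0.5, 0.6, 0.7, 0.8, 0.5, 0.6]))
    none = subject_summary([EventList([])], 5.0)
    assert none.density == 0.0 and none.mean_duration is None
    with pytest.raises(ValueError, match="positive"):
        subject_summary(events, 0.0)


def test_compare_summaries_identity_scaling_and_errors():
    ref = [1.0, 2.0, 3.0, 4.0, 5.0]
    out = compare_summaries(ref, ref)
    assert out["r"] == pytest.approx(1.0)
    assert out["slope"] == pytest.approx(1.0)
    out2 = compare_summaries([2 * v for v in ref], ref)
    assert out2["r"] == pytest.approx(1.0)
    assert out2["slope"] == pytest.approx(2.0)
    with pytest.raises(ValueError, match="variance"):
        compare_summaries([1.0, 1.0, 1.0, 1.0], ref[:4])


def test_compare_summaries_parameter_recovery():
    """OLS recovers a known slope and correlation under additive noise."""
    rng = np.random.default_rng(5)
    ref = rng.uniform(1, 6, 200)
    pred = 0.9 * ref + 0.5 + rng.normal(0, 0.2, 200)
    out = compare_summaries(list(pred), list(ref))
    assert out["slope"] == pytest.approx(0.9, abs=0.05)
    expected_r = 1 / np.sqrt(1 + 0.2**2 / (0.9**2 * np.var(ref)))
    assert out["r"] == pytest.approx(expected_r, abs=0.02)


def test_fisher_z_values():
    assert compare_summaries([1, 2, 3, 4.1], [4, 3, 2, 1.2])["fisher_z"] < 0
    rng = np.random.default_rng(6)
    a = rng.standard_normal(50)
    b = rng.standard_normal(50)
    out = compare_summaries(list(a), list(b))
    assert out["fisher_z"] == pytest.approx(np.arctanh(out["r"]))
    z = fisher_z_difference(0.5, 30, 0.5, 30)
    assert z["z"] == pytest.approx(0.0)
    assert z["p"] == pytest.approx(1.0)


def _mini_split_inputs(seed=0):
    cfg = sg.SynthConfig(snr=10.0, segment_length_s=30.0)
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(10):
        cohort = "younger" if i < 6 else "older"
        subjects.append(
            sg.generate_subject(cfg, 2, rng, subject_id=f"s{i}", cohort=cohort)
        )
    records = [
        {"subject_id": s.subject_id, "cohort": s.cohort, "n_segments": s.n_segments}
        for s in subjects
    ]
    by_subject = {
        s.subject_id: list(zip(s.segments, s.annotations)) for s in subjects
    }
    return records, by_subject


def test_select_test_split_constraints_and_determinism():
    records, by_subject = _mini_split_inputs()
    out1 = select_test_split(
        records, sigma_baseline_detector, by_subject,
        n_test_per_cohort=2, n_candidates=5, seed=3,
    )
    out2 = select_test_split(
        records, sigma_baseline_detector, by_subject,
        n_test_per_cohort=2, n_candidates=5, seed=3,
    )
    assert out1["test_ids"] == out2["test_ids"]
    cohorts = {r["subject_id"]: r["cohort"] for r in records}
    test_cohorts = [cohorts[s] for s in out1["test_ids"]]
    assert test_cohorts.count("younger") == 2 and test_cohorts.count("older") == 2
    assert set(out1["train_ids"]) | set(out1["test_ids"]) == set(cohorts)
    # selected score is the median order statistic
    assert out1["selected_score"] == sorted(out1["candidate_scores"])[2]


def test_select_test_split_single_candidate_and_unsatisfiable():
    records, by_subject = _mini_split_inputs(1)
    out = select_test_split(
        records, sigma_baseline_detector, by_subject,
        n_test_per_cohort=2, n_candidates=1, seed=0,
    )
    assert out["selected_score"] == out["candidate_scores"][0]
    with pytest.raises(ValueError, match="eligible"):
        select_test_split(
            records, sigma_baseline_detector, by_subject,
            n_test_per_cohort=7, n_candidates=2, seed=0,
        )


def test_sigma_baseline_on_high_snr_and_background():
    cfg = sg.SynthConfig(snr=10.0)
    rng = np.random.default_rng(7)
    subject = sg.generate_subject(cfg, 3, rng, subject_id="hs")
    det = [sigma_baseline_detector(s) for s in subject.segments]
    counts = pooled_match(det, subject.annotations, 0.2)
    m = prf(counts)
    assert m.recall >= 0.9

    minutes = 0.0
    false_alarms = 0
    for i in range(3):
        bg = sg.generate_background(cfg, 11500, np.random.default_rng(100 + i))
        seg = EEGSegment(sg.zscore(bg), cfg.fs)
        false_alarms += len(sigma_baseline_detector(seg))
        minutes += 115 / 60
    assert false_alarms / minutes <= 1.0

    quiet = sigma_baseline_detector(subject.segments[0], rel_threshold=1e9)
    assert len(quiet) == 0
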