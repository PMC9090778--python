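"""Event-level and subject-level evaluation of spindle detections.

Detections are compared with reference annotations by event: each
detected/reference pair is scored by its relative overlap (intersection
length over the joined span of both events), pairs are matched one-to-one
greedily by descending overlap, and pairs whose overlap strictly exceeds
the threshold count as true positives. Recall, precision and F1 follow
from the counts; integrating F1 over a grid of overlap thresholds and
normalizing by the grid span yields the threshold-free summary F1-bar.

Subject-level analysis reduces each subject's detections to a spindle
density (events per minute of scored signal) and a mean event duration,
then relates detector-derived and reference-derived values through Pearson
correlation and an ordinary least-squares slope, with Fisher's z-transform
for comparing correlations between detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .events import EventList
from .preprocess import EEGSegment

DEFAULT_THRESHOLD = 0.2
DEFAULT_GRID = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))


@dataclass
class MatchCounts:
    """True/false positive and false negative counts at one threshold."""

    tp: int
    fp: int
    fn: int
    overlap_threshold: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        if other.overlap_threshold != self.overlap_threshold:
            raise ValueError("cannot pool counts across thresholds")
        return MatchCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.overlap_threshold,
        )


@dataclass
class EventMetrics:
    recall: float
    precision: float
    f1: float
    f1_curve: list[tuple[float, float]] = field(default_factory=list)
    f1_bar: float | None = None


@dataclass
class SubjectSummary:
    subject_id: str
    density: float  # spindles per minute
    mean_duration: float | None  # seconds; None when no events
    cohort: str = ""


def relative_overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Intersection over union of two (onset, duration) intervals."""
    if a[1] <= 0 or b[1] <= 0:
        raise ValueError("intervals must have positive duration")
    a0, a1 = a[0], a[0] + a[1]
    b0, b1 = b[0], b[0] + b[1]
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    union = max(a1, b1) - min(a0, b0)
    return inter / union


def _overlap_pairs(detected: EventList, reference: EventList):
    """All (overlap, det_idx, ref_idx) with positive overlap, sorted by
    descending overlap; ties break on indices for determinism."""
    pairs = []
    for i, d in enumerate(detected):
        for j, r in enumerate(reference):
            ov = relative_overlap(d, r)
            if ov > 0:
                pairs.append((ov, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    return pairs


def match_events(
    detected: EventList, reference: EventList, threshold: float
) -> MatchCounts:
    """One-to-one greedy matching by descending relative overlap.

    Pairs whose overlap strictly exceeds ``threshold`` are eligible; each
    event participates in at most one match. Unmatched reference events are
    false negatives, unmatched detections false positives.
    """
    used_d: set[int] = set()
    used_r: set[int] = set()
    tp = 0
    for ov, i, j in _overlap_pairs(detected, reference):
        if ov <= threshold:
            break
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        tp += 1
    return MatchCounts(
        tp=tp,
        fp=len(detected) - tp,
        fn=len(reference) - tp,
        overlap_threshold=threshold,
    )


def pooled_match(
    detected: list[EventList], reference: list[EventList], threshold: float
) -> MatchCounts:
    """Sum per-segment match counts over paired segment lists."""
    if len(detected) != len(reference):
        raise ValueError("detected/reference segment lists differ in length")
    total = MatchCounts(0, 0, 0, threshold)
    for d, r in zip(detected, reference):
        total = total + match_events(d, r, threshold)
    return total


def prf(counts: MatchCounts) -> EventMetrics:
    """Recall, precision, F1 from match counts.

    Empty-denominator conventions: with neither detections nor reference
    events everything is perfect (1.0); with no detections but existing
    reference events precision is 0; symmetrically for recall.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp == 0 and fp == 0 and fn == 0:
        return EventMetrics(recall=1.0, precision=1.0, f1=1.0)
    recall = tp / (tp + fn) if (tp + fn) else (1.0 if fp == 0 else 0.0)
    precision = tp / (tp + fp) if (tp + fp) else (1.0 if fn == 0 else 0.0)
    f1 = 2 * tp / (2 * tp + fp + fn)
    return EventMetrics(recall=recall, precision=precision, f1=f1)


def f1_curve_and_bar(
    detected: EventList | list[EventList],
    reference: EventList | list[EventList],
    grid=DEFAULT_GRID,
) -> EventMetrics:
    """F1 at each overlap threshold plus the normalized trapezoidal integral.

    ``f1_bar`` is the trapezoidal integral of the curve divided by the grid
    span, so a constant curve integrates to its own value. Also reports
    recall/precision/F1 at the 20% threshold used for headline numbers.
    """
    grid = sorted(grid)
    if len(grid) < 2:
        raise ValueError("threshold grid needs at least 2 points for f1_bar")
    if not all(0 < t <= 1 for t in grid):
        raise ValueError("thresholds must lie in (0, 1]")
    if isinstance(detected, EventList):
        detected = [detected]
    if isinstance(reference, EventList):
        reference = [reference]
    curve = [(t, prf(pooled_match(detected, reference, t)).f1) for t in grid]
    f1s = [f for _, f in curve]
    f1_bar = float(np.trapezoid(f1s, grid) / (grid[-1] - grid[0]))
    at_default = prf(pooled_match(detected, reference, DEFAULT_THRESHOLD))
    return EventMetrics(
        recall=at_default.recall,
        precision=at_default.precision,
        f1=at_default.f1,
        f1_curve=curve,
        f1_bar=f1_bar,
    )


# -- subject-level analysis ------------------------------------------------


def subject_summary(
    events_by_segment: list[EventList],
    total_minutes: float,
    subject_id: str = "",
    cohort: str = "",
) -> SubjectSummary:
    """Spindle density (min^-1) and mean duration pooled over all segments."""
    if total_minutes <= 0:
        raise ValueError("total scored time must be positive")
    durations = [d for ev in events_by_segment for _, d in ev]
    density = len(durations) / total_minutes
    mean_dur = float(np.mean(durations)) if durations else None
    return SubjectSummary(
        subject_id=subject_id, density=density, mean_duration=mean_dur, cohort=cohort
    )


def compare_summaries(
    pred: list[float], ref: list[float]
) -> dict[str, float]:
    """Relate detector-derived to reference-derived per-subject values.

    Returns Pearson ``r`` and ``r2``, the OLS slope ``m`` and intercept of
    pred regressed on ref, and Fisher's ``z = atanh(r)``.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if len(pred) != len(ref) or len(pred) < 4:
        raise ValueError("need >= 4 paired subjects")
    if np.std(pred) == 0 or np.std(ref) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, _ = stats.pearsonr(pred, ref)
    slope, intercept, *_ = stats.linregress(ref, pred)
    return {
        "r": float(r),
        "r2": float(r**2),
        "slope": float(slope),
        "intercept": float(intercept),
        "fisher_z": float(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)))
        if abs(r) < 1
        else float("inf") * np.sign(r),
    }


def fisher_z_difference(r1: float, n1: int, r2: float, n2: int) -> dict[str, float]:
    """Two-sample test for a difference between independent correlations."""
    if min(n1, n2) < 4:
        raise ValueError("need at least 4 subjects per group")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    z = (z1 - z2) / se
    p = 2 * stats.norm.sf(abs(z))
    return {"z": float(z), "p": float(p)}


# -- test-split selection --------------------------------------------------


def select_test_split(
    subjects: list[dict],
    detector,
    segments_by_subject: dict[str, list[tuple[EEGSegment, EventList]]],
    n_test_per_cohort: int = 18,
    n_candidates: int = 25,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
):
    """Draw candidate test splits and keep the detector-median one.

    ``subjects`` holds dicts with ``subject_id``, ``cohort`` and
    ``n_segments``. Constraints: splits are by subject, every ten-segment
    subject stays in training, and the test set has equal younger/older
    counts. Each of ``n_candidates`` admissible candidates is scored by the
    pluggable ``detector`` (segment -> EventList) through the pooled F1 at
    ``threshold``; the candidate with the median score is returned, so the
    held-out set neither flatters nor punishes that detector.
    """
    rng = np.random.default_rng(seed)
    eligible = {
        c: [s["subject_id"] for s in subjects if s["cohort"] == c and s["n_segments"] < 10]
        for c in ("younger", "older")
    }
    for cohort, pool in eligible.items():
        if len(pool) < n_test_per_cohort:
            raise ValueError(
                f"only {len(pool)} eligible {cohort} subjects for a test set "
                f"of {n_test_per_cohort}"
            )

    candidates = []
    for _ in range(n_candidates):
        test_ids = set()
        for cohort in ("younger", "older"):
            test_ids.update(
                rng.choice(eligible[cohort], size=n_test_per_cohort, replace=False)
            )
        candidates.append(test_ids)

    scores = []
    for test_ids in candidates:
        det, ref = [], []
        for sid in sorted(test_ids):
            for segment, events in segments_by_subject[sid]:
                det.append(detector(segment))
                ref.append(events)
        scores.append(prf(pooled_match(det, ref, threshold)).f1)

    order = np.argsort(scores, kind="stable")
    median_idx = order[(n_candidates - 1) // 2]
    test_ids = candidates[median_idx]
    train_ids = {s["subject_id"] for s in subjects} - test_ids
    return {
        "train_ids": sorted(train_ids),
        "test_ids": sorted(test_ids),
        "candidate_scores": scores,
        "selected_score": scores[median_idx],
    }


# -- simple sigma-power baseline detector ---------------------------------


def sigma_baseline_detector(
    segment: EEGSegment,
    band: tuple[float, float] = (11.0, 16.0),
    rel_threshold: float = 2.5,
    rms_window_s: float = 0.3,
    min_duration_s: float = 0.5,
) -> EventList:
    """Threshold detector on sigma-band RMS power.

    Band-passes to the sigma band, computes a moving RMS envelope, marks
    samples whose envelope exceeds ``rel_threshold`` times the segment's
    median envelope, joins runs and drops events shorter than the 0.5 s
    scoring minimum. A deliberately simple feature-based stand-in used as a
    pluggable reference detector for split selection and sanity checks.
    """
    fs = segment.fs
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    sigma = signal.sosfiltfilt(sos, segment.samples)
    w = max(3, int(round(rms_window_s * fs)) | 1)
    power = np.convolve(np.pad(sigma**2, w // 2, mode="reflect"),
                        np.full(w, 1.0 / w), mode="valid")
    envelope = np.sqrt(power)
    threshold = rel_threshold * np.median(envelope)
    indicator = envelope > threshold
    from .postprocess import indicator_to_events  # local import avoids cycle

    events = indicator_to_events(indicator, fs)
    kept = [(o, d) for o, d in events if d >= min_duration_s]
    return EventList(events=kept, fs_origin=fs)
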