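"""From raw probability tracks to spindle annotations.

The inference chain is: moving-average smoothing of both probability
channels, a pointwise class decision (spindle wins when its probability
strictly exceeds the no-spindle probability, i.e. exceeds 0.5 under the
sum-to-one constraint), and joining of consecutive positive samples into
(onset, duration) events on the half-open convention.
"""

from __future__ import annotations

import numpy as np

from .events import EventList
from .model import ModelConfig, ProbabilityTrack, SpindleUNet, forward
from .preprocess import EEGSegment


def _odd(width: int) -> int:
    return width if width % 2 else width + 1


def smooth(track: ProbabilityTrack, width: int) -> ProbabilityTrack:
    """Moving-average smoothing of both channels with a centered kernel.

    ``width`` is forced odd (42 -> 43) so the kernel is symmetric and
    introduces no phase shift; edges are mirrored (symmetric padding, edge
    sample included), which keeps constant tracks constant. Because both
    channels are convolved with the same kernel, the pointwise sum-to-one
    constraint survives smoothing.
    """
    if width < 1:
        raise ValueError("smoothing width must be >= 1")
    w = _odd(width)
    if w > len(track):
        raise ValueError(
            f"smoothing width {w} exceeds track length {len(track)}"
        )
    if w == 1:
        return track
    kernel = np.full(w, 1.0 / w)
    half = w // 2

    def _run(x: np.ndarray) -> np.ndarray:
        padded = np.pad(x, half, mode="symmetric")
        return np.convolve(padded, kernel, mode="valid")

    return ProbabilityTrack(
        spindle_prob=_run(track.spindle_prob),
        no_spindle_prob=_run(track.no_spindle_prob),
        fs=track.fs,
    )


def to_indicator(track: ProbabilityTrack) -> np.ndarray:
    """Pointwise class decision: 1 where spindle probability wins.

    Exact ties (both channels at 0.5) resolve to no-spindle, which makes
    the rule equivalent to a strict 0.5 threshold on the spindle channel.
    """
    return (track.spindle_prob > track.no_spindle_prob).astype(np.int8)


def indicator_to_events(indicator: np.ndarray, fs: float) -> EventList:
    """Join maximal runs of positive indicator samples into events."""
    indicator = np.asarray(indicator).astype(bool)
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    padded = np.concatenate([[False], indicator, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    events = [(s / fs, (e - s) / fs) for s, e in zip(starts, ends)]
    return EventList(events=events, fs_origin=fs)


def events_to_indicator(events: EventList, n_samples: int, fs: float) -> np.ndarray:
    """Rasterize events onto a sample grid (inverse of run-joining)."""
    out = np.zeros(n_samples, dtype=np.int8)
    for onset, dur in events:
        i0 = int(round(onset * fs))
        i1 = int(round((onset + dur) * fs))
        out[max(i0, 0) : min(i1, n_samples)] = 1
    return out


def predict_events(
    network: SpindleUNet,
    segment: EEGSegment,
    config: ModelConfig | None = None,
    min_duration: float = 0.0,
) -> EventList:
    """Full inference chain on one preprocessed segment.

    forward -> smooth(moving_avg_width) -> indicator -> run-joining. An
    optional minimum duration drops very short detections; it defaults off
    because the detector is trained on annotations that already respect the
    0.5 s scoring convention.
    """
    config = config or network.config
    track = forward(network, segment)
    track = smooth(track, config.moving_avg_width)
    events = indicator_to_events(to_indicator(track), segment.fs)
    if min_duration > 0:
        events = EventList(
            [(o, d) for o, d in events if d >= min_duration], fs_origin=segment.fs
        )
    return events
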