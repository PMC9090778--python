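"""Spindle event annotations.

Events are (onset, duration) pairs in seconds from segment start, with the
half-open convention: an event occupies [onset, onset + duration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field


@dataclass
class EventList:
    """Ordered spindle annotations on one segment.

    Parameters
    ----------
    events
        List of ``(onset_s, duration_s)`` tuples. Sorted by onset on
        construction; durations must be positive.
    fs_origin
        Sampling rate (Hz) of the track the events were derived from, if any.
    """

    events: list[tuple[float, float]] = field(default_factory=list)
    fs_origin: float | None = None

    def __post_init__(self) -> None:
        for onset, dur in self.events:
            if dur <= 0:
                raise ValueError(f"event duration must be > 0, got {dur}")
        self.events = sorted(self.events, key=lambda e: (e[0], e[1]))
        for (o1, d1), (o2, _) in zip(self.events, self.events[1:]):
            if o1 + d1 > o2:
                warnings.warn(
                    f"overlapping reference events at {o1:.3f}s and {o2:.3f}s "
                    "kept as-is",
                    stacklevel=2,
                )
                break

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    @property
    def onsets(self) -> list[float]:
        return [o for o, _ in self.events]

    @property
    def durations(self) -> list[float]:
        return [d for _, d in self.events]

    def total_duration(self) -> float:
        return sum(d for _, d in self.events)
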