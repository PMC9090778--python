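"""Signal conditioning for single-channel N2 EEG segments.

The pipeline mirrors the MODA preparation of MASS C3 excerpts: a
phase-preserving 10th-order Butterworth band-pass (0.3-30 Hz), downsampling
to 100 Hz, and a per-segment z-transform. The order is fixed:
``bandpass -> resample -> zscore``; the z-transform must come last so the
network always sees zero-mean unit-variance input regardless of recording
gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

TARGET_FS = 100.0


@dataclass
class EEGSegment:
    """One single-channel EEG excerpt.

    ``samples`` are in microvolts before :func:`zscore` and dimensionless
    after. ``cohort`` is ``"younger"`` or ``"older"``.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    cohort: str = ""
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("segment contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def bandpass(
    samples: np.ndarray,
    fs: float,
    low: float = 0.3,
    high: float = 30.0,
    order: int = 10,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of effective order ``order``.

    Realized as forward-backward (filtfilt) application of an
    ``order // 2``-order design in second-order sections; squaring the
    magnitude response yields the effective 10th-order characteristic.
    """
    samples = np.asarray(samples, dtype=float)
    if fs <= 2 * high:
        raise ValueError(
            f"sampling rate {fs} Hz must exceed twice the upper edge {high} Hz"
        )
    if order < 2 or order % 2:
        raise ValueError("order must be an even integer >= 2")
    sos = signal.butter(order // 2, [low, high], btype="bandpass", fs=fs, output="sos")
    # sosfiltfilt pads by reflection; require enough samples for the warm-up.
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(samples) <= padlen:
        raise ValueError(
            f"segment of {len(samples)} samples is shorter than the filter "
            f"warm-up length ({padlen})"
        )
    return signal.sosfiltfilt(sos, samples)


def resample_to(samples: np.ndarray, fs_in: float, fs_out: float = TARGET_FS) -> np.ndarray:
    """Polyphase rational downsampling to ``fs_out``.

    Assumes anti-aliasing was handled upstream (the 30 Hz low-pass edge of
    :func:`bandpass` is below the 50 Hz Nyquist of the 100 Hz target); the
    polyphase filter adds its own protection for other ratios. Output length
    is ``round(len(samples) * fs_out / fs_in)``. Upsampling is refused.
    """
    samples = np.asarray(samples, dtype=float)
    if fs_in < fs_out:
        raise ValueError(f"no upsampling path: fs_in={fs_in} < fs_out={fs_out}")
    if fs_in == fs_out:
        return samples
    ratio = Fraction(fs_out / fs_in).limit_denominator(10000)
    out = signal.resample_poly(samples, ratio.numerator, ratio.denominator)
    n_target = round(len(samples) * fs_out / fs_in)
    return out[:n_target]


def zscore(samples: np.ndarray) -> np.ndarray:
    """Standardize to zero mean and unit population variance (divisor N)."""
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to standardize")
    mu = samples.mean()
    sd = samples.std()  # population convention
    if sd < 1e-12 * max(1.0, abs(mu)):
        raise ValueError("constant segment cannot be z-scored")
    return (samples - mu) / sd


def preprocess_segment(segment: EEGSegment) -> EEGSegment:
    """Full conditioning chain: band-pass, resample to 100 Hz, z-score."""
    x = bandpass(segment.samples, segment.fs)
    x = resample_to(x, segment.fs, TARGET_FS)
    x = zscore(x)
    return EEGSegment(
        samples=x,
        fs=TARGET_FS,
        subject_id=segment.subject_id,
        cohort=segment.cohort,
        segment_id=segment.segment_id,
    )
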