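"""File formats and run configuration.

Signals travel as EDF (reading goes through MNE; writing uses a compact
16-bit EDF writer so synthetic datasets can round-trip through the same
reader real recordings use). Annotations are CSV with header
``onset_s,duration_s`` in seconds at 1 ms precision, with a JSON mirror for
programmatic use. A dataset manifest (YAML) ties subjects, cohorts and
per-segment file pairs together; a run configuration (YAML) freezes every
hyperparameter plus the seed so runs are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import EventList
from .model import ModelConfig
from .train import TrainConfig


class EDFFormatError(RuntimeError):
    """Raised when an EDF file cannot be parsed."""


# -- EDF -------------------------------------------------------------------


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(
    path: str | Path,
    channels: list[tuple[str, np.ndarray]],
    fs: float,
    physical_dim: str = "uV",
) -> None:
    """Write channels to a minimal single-record EDF file.

    Samples are quantized to 16 bits over each channel's physical range, so
    the round-trip error is bounded by range / 65535. All channels must
    share the sampling rate and length.
    """
    if not channels:
        raise ValueError("need at least one channel")
    n = len(channels[0][1])
    if any(len(x) != n for _, x in channels):
        raise ValueError("all channels must have equal length")
    ns = len(channels)
    duration = n / fs
    header_bytes = 256 * (1 + ns)

    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))
        f.write(_pad("Startdate X X X X", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(header_bytes), 8))
        f.write(_pad("", 44))
        f.write(_pad("1", 8))  # one data record
        f.write(_pad(f"{duration:.8g}"[:8], 8))
        f.write(_pad(str(ns), 4))  # ns field is 4 ascii chars

        digital_min, digital_max = -32768, 32767
        phys_ranges = []
        for label, x in channels:
            x = np.asarray(x, dtype=float)
            lo, hi = float(x.min()), float(x.max())
            if hi == lo:
                hi = lo + 1.0
            phys_ranges.append((lo, hi))
        for label, _ in channels:
            f.write(_pad(label, 16))
        for _ in channels:
            f.write(_pad("", 80))  # transducer
        for _ in channels:
            f.write(_pad(physical_dim, 8))
        for lo, _ in phys_ranges:
            f.write(_pad(f"{lo:.8g}"[:8], 8))
        for _, hi in phys_ranges:
            f.write(_pad(f"{hi:.8g}"[:8], 8))
        for _ in channels:
            f.write(_pad(str(digital_min), 8))
        for _ in channels:
            f.write(_pad(str(digital_max), 8))
        for _ in channels:
            f.write(_pad("", 80))  # prefiltering
        for _ in channels:
            f.write(_pad(str(n), 8))
        for _ in channels:
            f.write(_pad("", 32))

        for (label, x), (lo, hi) in zip(channels, phys_ranges):
            scale = (digital_max - digital_min) / (hi - lo)
            digital = np.round((np.asarray(x, dtype=float) - lo) * scale) + digital_min
            digital = np.clip(digital, digital_min, digital_max).astype("<i2")
            f.write(digital.tobytes())


def read_edf(
    path: str | Path, channel: str | None = None
) -> tuple[np.ndarray, float, str]:
    """Read one channel from an EDF file.

    Returns ``(samples_in_uV, fs, channel_label)``; the first channel is
    used when none is requested. Physical values are returned on the
    microvolt scale under the EDF convention that EEG signals carry a 'uV'
    physical dimension.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on malformed files
        raise EDFFormatError(f"cannot parse EDF file {path}: {exc}") from exc
    if channel is None:
        channel = raw.ch_names[0]
    if channel not in raw.ch_names:
        raise KeyError(
            f"channel {channel!r} not found; available: {raw.ch_names}"
        )
    data = raw.get_data(picks=[channel])[0]
    return np.ascontiguousarray(data * 1e6), float(raw.info["sfreq"]), channel


# -- annotations -----------------------------------------------------------


def write_annotations(path: str | Path, events: EventList) -> None:
    """CSV with header ``onset_s,duration_s``, 1 ms precision, or the JSON
    mirror when the path ends in .json."""
    path = Path(path)
    if path.suffix == ".json":
        payload = [
            {"onset_s": round(o, 3), "duration_s": round(d, 3)} for o, d in events
        ]
        path.write_text(json.dumps(payload, indent=0) + "\n")
        return
    lines = ["onset_s,duration_s"]
    lines += [f"{o:.3f},{d:.3f}" for o, d in events]
    path.write_text("\n".join(lines) + "\n")


def read_annotations(path: str | Path) -> EventList:
    """Read events from CSV (or JSON); sorted by onset, durations > 0."""
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text() or "[]")
        events = [(float(r["onset_s"]), float(r["duration_s"])) for r in rows]
        return EventList(events=events)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return EventList(events=[])
    if frame.empty:
        return EventList(events=[])
    missing = {"onset_s", "duration_s"} - set(frame.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns {sorted(missing)}")
    events = [
        (float(r.onset_s), float(r.duration_s)) for r in frame.itertuples(index=False)
    ]
    return EventList(events=events)


# -- manifest --------------------------------------------------------------


@dataclass
class SubjectPaths:
    subject_id: str
    cohort: str
    segment_paths: list[str]
    annotation_paths: list[str]


@dataclass
class DatasetManifest:
    """Paths and identities for a dataset on disk."""

    records: list[SubjectPaths]
    sampling_rate: float

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.subject_id in seen:
                raise ValueError(f"duplicate subject id {rec.subject_id}")
            seen.add(rec.subject_id)
            if rec.cohort not in ("younger", "older"):
                raise ValueError(
                    f"subject {rec.subject_id} has invalid cohort {rec.cohort!r}"
                )
            if len(rec.segment_paths) != len(rec.annotation_paths):
                raise ValueError(
                    f"subject {rec.subject_id}: segment/annotation path "
                    "counts differ"
                )

    def subject_records(self) -> list[dict]:
        return [
            {
                "subject_id": r.subject_id,
                "cohort": r.cohort,
                "n_segments": len(r.segment_paths),
            }
            for r in self.records
        ]

    @property
    def n_segments(self) -> int:
        return sum(len(r.segment_paths) for r in self.records)


def save_manifest(path: str | Path, manifest: DatasetManifest) -> None:
    payload = {
        "sampling_rate": manifest.sampling_rate,
        "records": [dataclasses.asdict(r) for r in manifest.records],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_manifest(path: str | Path) -> DatasetManifest:
    payload = yaml.safe_load(Path(path).read_text())
    return DatasetManifest(
        records=[SubjectPaths(**r) for r in payload["records"]],
        sampling_rate=float(payload["sampling_rate"]),
    )


def write_dataset(dataset, out_dir: str | Path, channel_label: str = "C3") -> Path:
    """Write a synthetic dataset as EDF + CSV pairs plus a YAML manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for subject in dataset.subjects:
        seg_paths, ann_paths = [], []
        for segment, events in zip(subject.segments, subject.annotations):
            stem = segment.segment_id
            seg_path = out_dir / f"{stem}.edf"
            ann_path = out_dir / f"{stem}.csv"
            write_edf(seg_path, [(channel_label, segment.samples)], segment.fs)
            write_annotations(ann_path, events)
            seg_paths.append(seg_path.name)
            ann_paths.append(ann_path.name)
        records.append(
            SubjectPaths(
                subject_id=subject.subject_id,
                cohort=subject.cohort,
                segment_paths=seg_paths,
                annotation_paths=ann_paths,
            )
        )
    manifest = DatasetManifest(records=records, sampling_rate=dataset.config.fs)
    manifest_path = out_dir / "manifest.yaml"
    save_manifest(manifest_path, manifest)
    return manifest_path


def load_dataset(manifest_path: str | Path, channel: str | None = None):
    """Load all segments and annotations referenced by a manifest.

    Returns ``(samples_by_subject, subject_records)`` where samples are
    ``(EEGSegment, EventList)`` pairs; EDF quantization noise aside, this is
    the inverse of :func:`write_dataset`.
    """
    from .preprocess import EEGSegment

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = load_manifest(manifest_path)
    samples_by_subject: dict[str, list] = {}
    for rec in manifest.records:
        pairs = []
        for seg_name, ann_name in zip(rec.segment_paths, rec.annotation_paths):
            samples, fs, _ = read_edf(base / seg_name, channel)
            segment = EEGSegment(
                samples=samples,
                fs=fs,
                subject_id=rec.subject_id,
                cohort=rec.cohort,
                segment_id=Path(seg_name).stem,
            )
            pairs.append((segment, read_annotations(base / ann_name)))
        samples_by_subject[rec.subject_id] = pairs
    return samples_by_subject, manifest.subject_records()


# -- run configuration -----------------------------------------------------


@dataclass
class RunConfig:
    """Everything a training/evaluation run needs, serializable to YAML."""

    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    threshold_grid: list[float] = field(
        default_factory=lambda: [round(0.05 * i, 2) for i in range(1, 21)]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 < t <= 1 for t in self.threshold_grid):
            raise ValueError("threshold grid must lie in (0, 1]")


def save_run_config(path: str | Path, config: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))


def load_run_config(path: str | Path) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text())
    return RunConfig(
        model=ModelConfig(**payload.get("model", {})),
        train=TrainConfig(**payload.get("train", {})),
        threshold_grid=payload.get("threshold_grid", RunConfig().threshold_grid),
        seed=int(payload.get("seed", 0)),
    )
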