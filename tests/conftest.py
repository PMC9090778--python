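"""Shared fixtures.

The expensive fixture is ``recovery_run``: one parameter-recovery training
session on a high-SNR synthetic dataset, shared session-wide by every test
that needs a trained detector.
"""

from __future__ import annotations

import numpy as np
import pytest

import spindleseg as sg
from spindleseg.train import TrainConfig, train_fold


HIGH_SNR = 10.0
RECOVERY_SEED = 20240


@pytest.fixture(scope="session")
def high_snr_config() -> sg.SynthConfig:
    return sg.SynthConfig(snr=HIGH_SNR)


@pytest.fixture(scope="session")
def small_dataset(high_snr_config) -> sg.SyntheticDataset:
    """8 subjects x 3 segments, high SNR; cheap enough for I/O round-trips."""
    return sg.generate_dataset(
        high_snr_config, n_younger=4, n_older=4, rng=11
    )


@pytest.fixture(scope="session")
def recovery_run(high_snr_config):
    """Train a reduced U-Net on a 24-subject high-SNR synthetic set.

    Subjects split by identity into 16 training / 4 validation (early
    stopping) / 4 held-out test; at most 50 epochs. Returns the trained
    network together with the splits so downstream tests can score it.
    """
    rng = np.random.default_rng(RECOVERY_SEED)
    subjects = [
        sg.generate_subject(
            high_snr_config,
            3,
            rng,
            subject_id=f"s{i:02d}",
            cohort="younger" if i % 2 else "older",
        )
        for i in range(24)
    ]

    def flatten(subs):
        return [
            (seg, ann)
            for s in subs
            for seg, ann in zip(s.segments, s.annotations)
        ]

    train_s = flatten(subjects[:16])
    val_s = flatten(subjects[16:20])
    test_s = flatten(subjects[20:])

    model_config = sg.ModelConfig(filters_per_level=[8, 16, 32])
    train_config = TrainConfig(max_epochs=50, patience=50)
    network, history = train_fold(
        train_s, val_s, model_config, train_config, seed=RECOVERY_SEED
    )
    return {
        "network": network,
        "history": history,
        "model_config": model_config,
        "train_samples": train_s,
        "val_samples": val_s,
        "test_samples": test_s,
        "synth_config": sg.SynthConfig(snr=HIGH_SNR),
    }
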