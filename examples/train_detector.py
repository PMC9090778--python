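"""Train a reduced spindle U-Net on synthetic data and score it held-out.

Generates twelve 3-segment subjects at high SNR, trains a narrow
three-level model for up to 20 epochs with generalized dice loss and Adam,
and reports the event-level F1 at the 20% overlap threshold on four
held-out subjects. An F1 near 1 shows the network recovers the planted
spindles almost perfectly at this signal-to-noise ratio.
"""

import numpy as np

from spindleseg import ModelConfig, SynthConfig, generate_subject, predict_events
from spindleseg.evaluate import pooled_match, prf
from spindleseg.train import TrainConfig, train_fold

config = SynthConfig(snr=10.0)
rng = np.random.default_rng(7)
subjects = [
    generate_subject(config, 3, rng, subject_id=f"s{i:02d}") for i in range(12)
]

flatten = lambda subs: [
    (seg, ann) for s in subs for seg, ann in zip(s.segments, s.annotations)
]
train_samples = flatten(subjects[:8])
held_out = flatten(subjects[8:])

model_config = ModelConfig(filters_per_level=[8, 16, 32])
train_config = TrainConfig(max_epochs=20, patience=20)
network, history = train_fold(
    train_samples, held_out, model_config, train_config, seed=3
)

print(history.tail(3).to_string(index=False))
detected = [predict_events(network, seg) for seg, _ in held_out]
metrics = prf(pooled_match(detected, [ev for _, ev in held_out], 0.2))
print(f"held-out recall@20%    {metrics.recall:.3f}")
print(f"held-out precision@20% {metrics.precision:.3f}")
print(f"held-out F1@20%        {metrics.f1:.3f}")
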