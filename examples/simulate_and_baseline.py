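"""Generate synthetic N2 EEG and score the sigma-power baseline detector.

Builds a small high-SNR dataset with exactly known spindle annotations,
runs the simple band-power threshold detector on every segment, and prints
event-level metrics: recall/precision/F1 at the 20% overlap threshold plus
the threshold-integrated F1-bar. High recall with near-perfect precision
means nearly every planted sigma burst is found with few false alarms.
"""

import numpy as np

from spindleseg import (
    SynthConfig,
    f1_curve_and_bar,
    generate_subject,
    sigma_baseline_detector,
)

config = SynthConfig(snr=10.0)
rng = np.random.default_rng(1)

detected, reference = [], []
for i in range(4):
    subject = generate_subject(config, 3, rng, subject_id=f"s{i}")
    for segment, events in zip(subject.segments, subject.annotations):
        detected.append(sigma_baseline_detector(segment))
        reference.append(events)

m = f1_curve_and_bar(detected, reference)
print(f"events: {sum(len(r) for r in reference)} reference, "
      f"{sum(len(d) for d in detected)} detected")
print(f"recall@20%    {m.recall:.3f}")
print(f"precision@20% {m.precision:.3f}")
print(f"F1@20%        {m.f1:.3f}")
print(f"F1-bar        {m.f1_bar:.3f}")
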