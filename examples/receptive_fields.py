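"""Receptive-field accounting for the three-level spindle U-Net.

The deepest encoder neurons integrate an EEG span controlled by the second
max-pool width w2; spindles live on 0.5-1.5 s time scales, so the ~3.5 s
field of the default w2=4 comfortably covers one spindle plus context.
"""

from spindleseg import ModelConfig, receptive_field

for w2 in (1, 2, 4, 8):
    cfg = ModelConfig(pool_widths=[4, w2])
    samples = receptive_field(cfg)
    print(f"w2={w2}: receptive field {samples:4d} samples = {samples / 100:.2f} s at 100 Hz")

# Expected output:
#   w2=1: receptive field  148 samples = 1.48 s at 100 Hz
#   w2=2: receptive field  216 samples = 2.16 s at 100 Hz
#   w2=4: receptive field  352 samples = 3.52 s at 100 Hz
#   w2=8: receptive field  624 samples = 6.24 s at 100 Hz
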