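"""Slim fully-convolutional 1D U-Net for per-sample spindle probabilities.

The network maps a z-scored 100 Hz EEG segment of length T to two
probability channels (spindle / no-spindle) of the same length T. The
encoder compresses temporal structure into channels through ``levels``
resolution levels (the last one acting as the bottleneck); the decoder
mirrors the compression and receives shortcut (skip) connections from the
matching encoder level.

Each level is built from two composite layers of convolution -> ReLU ->
batch normalization with equal channel counts. Compression is max pooling;
expansion is nearest-neighbor upsampling followed by a convolution to half
the incoming channels ("up-conv"), after which the encoder skip is
concatenated. A width-1 convolution and a channel softmax produce the
probability head.

The default convolution has kernel 9 and dilation 1, giving every composite
layer an effective extent of (9-1)*1 = 8 samples. With pool widths (4, 4)
this calibrates the third-level receptive field to 3.52 s at 100 Hz; see
:func:`receptive_field`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import prod

import numpy as np

from . import nn
from .preprocess import EEGSegment


@dataclass
class ModelConfig:
    """Architecture and post-processing hyperparameters.

    ``levels`` counts encoder depth including the bottleneck; there are
    ``levels - 1`` pooling steps, so ``pool_widths`` has that length.
    ``moving_avg_width`` is the nominal smoothing width in samples at
    100 Hz (the filter itself is forced odd, so 42 acts as 43).
    """

    levels: int = 3
    filters_per_level: list[int] = field(default_factory=lambda: [16, 32, 64])
    conv_kernel: int = 9
    conv_dilation: int = 1
    pool_widths: list[int] = field(default_factory=lambda: [4, 4])
    moving_avg_width: int = 42
    prob_threshold: float = 0.5

    def __post_init__(self) -> None:
        if len(self.filters_per_level) != self.levels:
            raise ValueError(
                f"filters_per_level has {len(self.filters_per_level)} entries "
                f"for {self.levels} levels"
            )
        if len(self.pool_widths) != self.levels - 1:
            raise ValueError(
                f"pool_widths needs {self.levels - 1} entries, got "
                f"{len(self.pool_widths)}"
            )
        if any(w < 1 for w in self.pool_widths):
            raise ValueError("pool widths must be >= 1")
        if self.conv_kernel < 1 or self.conv_dilation < 1:
            raise ValueError("conv kernel and dilation must be >= 1")
        if not 0 < self.prob_threshold < 1:
            raise ValueError("prob_threshold must lie in (0, 1)")

    @property
    def pool_product(self) -> int:
        return prod(self.pool_widths)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


@dataclass
class ProbabilityTrack:
    """Per-sample class probabilities for one segment."""

    spindle_prob: np.ndarray
    no_spindle_prob: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        s = np.asarray(self.spindle_prob, dtype=float)
        n = np.asarray(self.no_spindle_prob, dtype=float)
        if s.shape != n.shape:
            raise ValueError("probability channels differ in length")
        if not np.allclose(s + n, 1.0, atol=1e-6):
            raise ValueError("channel probabilities must sum to 1 pointwise")
        self.spindle_prob = s
        self.no_spindle_prob = n

    def __len__(self) -> int:
        return len(self.spindle_prob)


def _composite(in_ch: int, out_ch: int, kernel: int, dilation: int) -> nn.Sequential:
    # Composite layer order: Conv -> ReLU -> BN.
    return nn.Sequential(
        nn.Conv1d(in_ch, out_ch, kernel, dilation),
        nn.ReLU(),
        nn.BatchNorm1d(out_ch),
    )


def _level_block(in_ch: int, out_ch: int, kernel: int, dilation: int) -> nn.Sequential:
    return nn.Sequential(
        _composite(in_ch, out_ch, kernel, dilation),
        _composite(out_ch, out_ch, kernel, dilation),
    )


class SpindleUNet(nn.Layer):
    """Encoder-decoder network with skip connections.

    ``forward_batch`` maps logits of shape (B, T) -> probabilities of shape
    (B, 2, T); channel 0 is no-spindle, channel 1 is spindle. Input lengths
    that are not divisible by the pooling product are right-padded with
    zeros internally and the output is cropped back, so the temporal shape
    contract holds for arbitrary T.
    """

    SPINDLE_CHANNEL = 1

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        f = config.filters_per_level
        k, d = config.conv_kernel, config.conv_dilation

        self.enc_blocks = []
        in_ch = 1
        for level in range(config.levels):
            self.enc_blocks.append(_level_block(in_ch, f[level], k, d))
            in_ch = f[level]
        self.pools = [nn.MaxPool1d(w) for w in config.pool_widths]

        self.up_samplers = []
        self.up_convs = []
        self.dec_blocks = []
        for level in range(config.levels - 2, -1, -1):
            w = config.pool_widths[level]
            self.up_samplers.append(nn.UpsampleNearest(w))
            # Up-conv: kernel equals the matching pool width, dilation 1,
            # mapping to half the incoming channels.
            self.up_convs.append(nn.Conv1d(f[level + 1], f[level + 1] // 2, w, 1))
            self.dec_blocks.append(
                _level_block(f[level + 1] // 2 + f[level], f[level], k, d)
            )
        self.head = nn.Conv1d(f[0], 2, 1, 1)
        self.softmax = nn.SoftmaxChannels()

        self.children_: list[nn.Layer] = (
            self.enc_blocks
            + self.pools
            + self.up_samplers
            + self.up_convs
            + self.dec_blocks
            + [self.head, self.softmax]
        )

    # -- forward / backward ------------------------------------------------

    def forward_batch(self, x: np.ndarray) -> np.ndarray:
        """(B, T) float input -> (B, 2, T) probabilities."""
        x = np.asarray(x)
        if x.dtype != np.float64:
            x = x.astype(nn.DTYPE)
        if x.ndim != 2:
            raise ValueError("expected (batch, time) input")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in network input")
        B, T = x.shape
        m = self.config.pool_product
        self._pad_T = (-T) % m
        if self._pad_T:
            x = np.pad(x, ((0, 0), (0, self._pad_T)))
        h = x[:, None, :]

        skips = []
        for level, block in enumerate(self.enc_blocks):
            h = block.forward(h)
            if level < self.config.levels - 1:
                skips.append(h)
                h = self.pools[level].forward(h)

        self._skip_channels = []
        for i, (ups, upc, dec) in enumerate(
            zip(self.up_samplers, self.up_convs, self.dec_blocks)
        ):
            h = upc.forward(ups.forward(h))
            skip = skips[-(i + 1)]
            self._skip_channels.append(h.shape[1])
            h = np.concatenate([h, skip], axis=1)
            h = dec.forward(h)

        p = self.softmax.forward(self.head.forward(h))
        if self._pad_T:
            p = p[:, :, :T]
        return p

    def backward_batch(self, dprob: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the (cropped) probabilities."""
        if self._pad_T:
            dprob = np.pad(dprob, ((0, 0), (0, 0), (0, self._pad_T)))
        dprob = np.asarray(dprob)
        if dprob.dtype != np.float64:
            dprob = dprob.astype(nn.DTYPE)
        dh = self.head.backward(self.softmax.backward(dprob))

        dskips = []
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            dh = self.dec_blocks[i].backward(dh)
            ch = self._skip_channels[i]
            dup, dskip = dh[:, :ch, :], dh[:, ch:, :]
            dskips.append(dskip)
            dh = self.up_samplers[i].backward(self.up_convs[i].backward(dup))

        # dskips[j] belongs to encoder level (levels - 2 - (len-1-j)) ... walk
        # the encoder in reverse, merging pooled and skip gradients.
        for level in range(self.config.levels - 1, -1, -1):
            if level < self.config.levels - 1:
                dh = self.pools[level].backward(dh)
                dh = dh + dskips[level]  # dskips reversed order == level order
            dh = self.enc_blocks[level].backward(dh)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward_batch(x)


def build_model(config: ModelConfig) -> SpindleUNet:
    """Construct an (uninitialized) spindle U-Net from a configuration."""
    return SpindleUNet(config)


def forward(network: SpindleUNet, segment: EEGSegment) -> ProbabilityTrack:
    """Run one segment through the network in inference mode."""
    nn.set_training(network, False)
    p = network.forward_batch(segment.samples[None, :])
    return ProbabilityTrack(
        spindle_prob=p[0, SpindleUNet.SPINDLE_CHANNEL],
        no_spindle_prob=p[0, 1 - SpindleUNet.SPINDLE_CHANNEL],
        fs=segment.fs,
    )


def receptive_field(config: ModelConfig) -> int:
    """Receptive field, in samples, of a neuron at the deepest level.

    Accumulates ``1 + sum((extent - 1) * stride)`` along the encoder path:
    each composite convolution contributes ``(kernel - 1) * dilation`` at
    the current cumulative stride and each pool contributes ``width - 1`` at
    the pre-pool stride. With two convolutions of effective extent 8 per
    level and pools (4, w2), this is ``80 + 68 * w2`` — e.g. 148, 352 and
    624 samples (1.48, 3.52, 6.24 s at 100 Hz) for w2 = 1, 4, 8.
    """
    extent = (config.conv_kernel - 1) * config.conv_dilation
    rf = 1
    stride = 1
    for level in range(config.levels):
        rf += 2 * extent * stride  # two composite convolutions per level
        if level < config.levels - 1:
            w = config.pool_widths[level]
            rf += (w - 1) * stride
            stride *= w
    return rf
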