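"""Modality-specific feature encoders.

``EEGEncoder`` follows the compact convolutional recipe that is standard for
motor-imagery EEG: a temporal convolution learning band-pass-like filters, a
depthwise spatial convolution across all electrodes, and a separable
convolution mixing the resulting feature maps, with ELU nonlinearities and
average pooling.

``EMGEncoder`` follows the LSTM+CNN design for multichannel sEMG: one LSTM
(shared weights) applied channel by channel to extract per-channel temporal
features, two convolutional layers over those features, and a depthwise
convolution across muscles extracting inter-muscle synergy features.

Both encoders expose ``output_shape`` computing the output dimensions in
closed form from the input shape and config, independent of a forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor


@dataclass(frozen=True)
class EEGEncoderConfig:
    """Defaults follow the canonical 8/2/16 compact-EEG recipe; the temporal
    kernel length (in samples) and pool sizes are configurable because the
    package runs at several sampling rates."""

    n_temporal_filters: int = 8      # F1
    depth_multiplier: int = 2        # D
    n_separable_filters: int = 16    # F2
    temporal_kernel_len: int = 64
    separable_kernel_len: int = 16
    pool_sizes: tuple = (4, 8)
    dropout_rate: float = 0.25

    def __post_init__(self):
        if min(self.n_temporal_filters, self.depth_multiplier,
               self.n_separable_filters, self.temporal_kernel_len) < 1:
            raise ValueError("all filter counts and kernel lengths must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


#: Reduced configuration for fast CPU experiments on downsampled signals.
TINY_EEG = EEGEncoderConfig(n_temporal_filters=4, depth_multiplier=2,
                            n_separable_filters=8, temporal_kernel_len=13,
                            separable_kernel_len=7, pool_sizes=(2, 4))


@dataclass(frozen=True)
class EMGEncoderConfig:
    lstm_hidden: int = 300
    cnn_channels: tuple = (8, 16)
    kernel_sizes: tuple = (9, 5)
    pool_sizes: tuple = (2, 2)
    depthwise_multiplier: int = 2
    dropout_rate: float = 0.25

    def __post_init__(self):
        if self.lstm_hidden < 1:
            raise ValueError("lstm_hidden must be >= 1")
        if len(self.cnn_channels) != 2 or len(self.kernel_sizes) != 2:
            raise ValueError("two CNN layers expected")


TINY_EMG = EMGEncoderConfig(lstm_hidden=16, cnn_channels=(4, 8),
                            kernel_sizes=(5, 3), pool_sizes=(2, 2),
                            depthwise_multiplier=2)


class EEGEncoder(nn.Module):
    """Temporal conv -> depthwise spatial conv -> separable conv.

    Input ``(B, C, T)``; output ``(B, F2, n_pos)`` with
    ``n_pos = (T // p1) // p2``.
    """

    def __init__(self, n_channels: int, n_samples: int,
                 config: EEGEncoderConfig = EEGEncoderConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c = config
        if c.temporal_kernel_len > n_samples:
            raise ValueError(
                f"temporal kernel {c.temporal_kernel_len} exceeds input length "
                f"{n_samples}")
        self.config = c
        self.n_channels, self.n_samples = n_channels, n_samples
        f1, d, f2 = c.n_temporal_filters, c.depth_multiplier, c.n_separable_filters
        self.conv_temporal = nn.Conv2d(1, f1, (1, c.temporal_kernel_len),
                                       padding="same", rng=rng)
        self.bn_temporal = nn.BatchNorm2d(f1)
        self.conv_spatial = nn.Conv2d(f1, f1 * d, (n_channels, 1),
                                      groups=f1, rng=rng)
        self.bn_spatial = nn.BatchNorm2d(f1 * d)
        self.pool1 = nn.AvgPool2d((1, c.pool_sizes[0]))
        self.conv_sep_depth = nn.Conv2d(f1 * d, f1 * d,
                                        (1, c.separable_kernel_len),
                                        groups=f1 * d, padding="same", rng=rng)
        self.conv_sep_point = nn.Conv2d(f1 * d, f2, (1, 1), rng=rng)
        self.bn_sep = nn.BatchNorm2d(f2)
        self.pool2 = nn.AvgPool2d((1, c.pool_sizes[1]))
        self.dropout1 = nn.Dropout(c.dropout_rate)
        self.dropout2 = nn.Dropout(c.dropout_rate)

    def output_shape(self) -> tuple:
        c = self.config
        n_pos = (self.n_samples // c.pool_sizes[0]) // c.pool_sizes[1]
        return (c.n_separable_filters, n_pos)

    @property
    def n_features(self) -> int:
        f, n = self.output_shape()
        return f * n

    def forward(self, x: Tensor) -> Tensor:
        B, C, T = x.shape
        if (C, T) != (self.n_channels, self.n_samples):
            raise ValueError(
                f"EEGEncoder built for input {(self.n_channels, self.n_samples)}, "
                f"got {(C, T)}")
        h = x.reshape(B, 1, C, T)
        h = self.conv_temporal(h)            # (B, F1, C, T)
        h = self.bn_temporal(h)
        h = self.conv_spatial(h)             # (B, F1*D, 1, T)
        h = self.bn_spatial(h)
        h = h.elu()
        h = self.pool1(h)
        h = self.dropout1(h)
        h = self.conv_sep_depth(h)
        h = self.conv_sep_point(h)           # (B, F2, 1, T//p1)
        h = self.bn_sep(h)
        h = h.elu()
        h = self.pool2(h)
        h = self.dropout2(h)
        f2, n_pos = self.output_shape()
        return h.reshape(B, f2, n_pos)


class EMGEncoder(nn.Module):
    """Shared-weight LSTM per muscle channel -> two convolutions over the
    per-channel features -> depthwise convolution across muscles.

    Input ``(B, C, T)``; output ``(B, q2 * m, n_pos)`` with
    ``n_pos = (H // p1) // p2`` where H is the LSTM hidden size.
    """

    def __init__(self, n_channels: int, n_samples: int,
                 config: EMGEncoderConfig = EMGEncoderConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c = config
        self.config = c
        self.n_channels, self.n_samples = n_channels, n_samples
        q1, q2 = c.cnn_channels
        self.lstm = nn.LSTM(1, c.lstm_hidden, rng=rng)
        self.conv1 = nn.Conv2d(1, q1, (1, c.kernel_sizes[0]), padding="same",
                               rng=rng)
        self.pool1 = nn.AvgPool2d((1, c.pool_sizes[0]))
        self.conv2 = nn.Conv2d(q1, q2, (1, c.kernel_sizes[1]), padding="same",
                               rng=rng)
        self.pool2 = nn.AvgPool2d((1, c.pool_sizes[1]))
        self.conv_depth = nn.Conv2d(q2, q2 * c.depthwise_multiplier,
                                    (n_channels, 1), groups=q2, rng=rng)
        self.dropout = nn.Dropout(c.dropout_rate)

    def output_shape(self) -> tuple:
        c = self.config
        n_pos = (c.lstm_hidden // c.pool_sizes[0]) // c.pool_sizes[1]
        return (c.cnn_channels[1] * c.depthwise_multiplier, n_pos)

    @property
    def n_features(self) -> int:
        f, n = self.output_shape()
        return f * n

    def channel_features(self, x: Tensor) -> Tensor:
        """Per-channel LSTM features ``(B, C, H)`` (channel-equivariant)."""
        B, C, T = x.shape
        if (C, T) != (self.n_channels, self.n_samples):
            raise ValueError(
                f"EMGEncoder built for input {(self.n_channels, self.n_samples)}, "
                f"got {(C, T)}")
        flat = x.reshape(B * C, T, 1)
        h = self.lstm(flat)                  # (B*C, H)
        return h.reshape(B, C, self.config.lstm_hidden)

    def forward(self, x: Tensor) -> Tensor:
        B = x.shape[0]
        h = self.channel_features(x)
        h = h.reshape(B, 1, self.n_channels, self.config.lstm_hidden)
        h = self.conv1(h).elu()
        h = self.pool1(h)
        h = self.conv2(h).elu()
        h = self.pool2(h)
        h = self.conv_depth(h).elu()         # (B, q2*m, 1, n_pos)
        h = self.dropout(h)
        f, n_pos = self.output_shape()
        return h.reshape(B, f, n_pos)
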