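"""Temporal convolutional encoder over alignment columns.

The encoder stacks residual blocks of dilated causal convolutions
(weight-normalized, ReLU, dropout x2 per block, with a 1x1 skip
projection when channel counts change), global-average-pools the final
feature map over positions, and maps through a tanh fully connected
layer to two linear heads producing the mean and log-variance of the
approximate posterior.

Dilations double per block (1, 2, 4, ...), so the receptive field grows
exponentially with depth while each output position depends only on
alignment columns at or before it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Parameter, Tensor, causal_conv1d


@dataclass
class TcnConfig:
    """Encoder hyperparameters.

    Defaults follow the reference configuration for this architecture:
    kernel size 2, stride 1, dilation base 2, dropout 0.2, three
    residual blocks, and a 100-channel output feature map feeding a
    100-unit tanh layer before the latent heads.
    """

    kernel_size: int = 2
    stride: int = 1
    dilation_base: int = 2
    n_blocks: int = 3
    in_channels: int = 21
    hidden_channels: int = 100
    out_channels: int = 100
    dropout: float = 0.2
    hidden_layer: int = 100
    dim_z: int = 3

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.dilation_base < 1 or self.n_blocks < 1:
            raise ValueError("kernel size, dilation base and block count must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    def block_dilations(self) -> list[int]:
        return [self.dilation_base**i for i in range(self.n_blocks)]

    def conv_layers(self) -> list[tuple[int, int, int]]:
        """(kernel, stride, dilation) for every convolution in the stack."""
        return [(self.kernel_size, self.stride, d) for d in self.block_dilations() for _ in range(2)]


# ---------------------------------------------------------------------------
# Receptive field accounting


@dataclass
class ReceptiveFieldLedger:
    """Per-layer receptive-field bookkeeping for a causal conv stack."""

    per_layer: list[tuple[int, int, int, int, int]] = field(default_factory=list)
    # entries: (k_i, s_i, d_i, RF_i, S_i)

    @property
    def receptive_field(self) -> int:
        return self.per_layer[-1][3] if self.per_layer else 1


def receptive_field(layers: list[tuple[int, int]]) -> int:
    """Receptive field of stacked convolutions, ignoring dilation.

    ``layers`` is a list of (kernel, stride); the recursion is
    RF_i = RF_{i-1} + (k_i - 1) * S_i with S_i the product of the
    strides of all earlier layers.  This is the textbook stride-only
    recursion; for dilated stacks use
    :func:`receptive_field_dilated`, which is what the encoder itself
    reports.
    """
    if not layers:
        raise ValueError("layer list must be nonempty")
    rf, stride_prod = 1, 1
    for k, s in layers:
        rf += (k - 1) * stride_prod
        stride_prod *= s
    return rf


def receptive_field_dilated(layers: list[tuple[int, int, int]]) -> ReceptiveFieldLedger:
    """Dilation-aware receptive field: RF_i = RF_{i-1} + (k_i-1)*d_i*S_i.

    ``layers`` is a list of (kernel, stride, dilation).  With gaps of
    size d between kernel taps each new layer widens the span by
    (k-1)*d input strides, so dilations doubling per layer give
    exponential growth in depth.
    """
    if not layers:
        raise ValueError("layer list must be nonempty")
    ledger = ReceptiveFieldLedger()
    rf, stride_prod = 1, 1
    for k, s, d in layers:
        rf += (k - 1) * d * stride_prod
        ledger.per_layer.append((k, s, d, rf, stride_prod))
        stride_prod *= s
    return ledger


# ---------------------------------------------------------------------------
# Layers


class WeightNormConv1d:
    """Causal dilated convolution with weight normalization.

    The kernel is reparameterized as W = g * v / ||v||, the norm taken
    per output channel over (in_channels, kernel) — the standard
    weight-norm trick that decouples the kernel's direction from its
    magnitude.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, dilation: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / (in_ch * kernel))
        v = rng.normal(0.0, scale, size=(out_ch, in_ch, kernel))
        self.v = Parameter(v)
        self.g = Parameter(np.linalg.norm(v.reshape(out_ch, -1), axis=1))
        self.b = Parameter(np.zeros(out_ch))
        self.dilation = dilation
        self.kernel = kernel

    def params(self) -> list[Parameter]:
        return [self.v, self.g, self.b]

    def _weight(self) -> Tensor:
        out_ch = self.v.data.shape[0]
        norm = (self.v * self.v).sum(axis=(1, 2), keepdims=True).sqrt()
        return self.v * (self.g.reshape(out_ch, 1, 1) / norm)

    def __call__(self, x: Tensor) -> Tensor:
        return causal_conv1d(x, self._weight(), self.b, self.dilation)


class ResidualBlock:
    """Two weight-normalized dilated causal convs + skip connection.

    output = ReLU(skip(x) + F(x)) with
    F = [conv -> ReLU -> dropout] x 2; the skip path is the identity
    when channel counts match and a 1x1 convolution otherwise.
    Dropout is active only in training mode.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, dilation: int,
                 dropout: float, rng: np.random.Generator):
        self.conv1 = WeightNormConv1d(in_ch, out_ch, kernel, dilation, rng)
        self.conv2 = WeightNormConv1d(out_ch, out_ch, kernel, dilation, rng)
        self.skip = None if in_ch == out_ch else WeightNormConv1d(in_ch, out_ch, 1, 1, rng)
        self.dropout = dropout

    def params(self) -> list[Parameter]:
        out = self.conv1.params() + self.conv2.params()
        if self.skip is not None:
            out += self.skip.params()
        return out

    def __call__(self, x: Tensor, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        h = self.conv1(x).relu()
        h = self._drop(h, train, rng)
        h = self.conv2(h).relu()
        h = self._drop(h, train, rng)
        s = x if self.skip is None else self.skip(x)
        out = (s + h).relu()
        if s.data.shape != h.data.shape:  # bug guard
            raise RuntimeError("skip/residual shape mismatch")
        return out

    def _drop(self, h: Tensor, train: bool, rng: np.random.Generator | None) -> Tensor:
        if not train or self.dropout == 0.0:
            return h
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.dropout
        mask = (rng.random(h.data.shape) < keep) / keep
        return h * mask


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / n_in)
        self.w = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def params(self) -> list[Parameter]:
        return [self.w, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class TcnEncoder:
    """One-hot stack (B, 21, L) -> posterior mean and log-variance (B, dim_z)."""

    def __init__(self, cfg: TcnConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.blocks: list[ResidualBlock] = []
        in_ch = cfg.in_channels
        dils = cfg.block_dilations()
        for i, d in enumerate(dils):
            out_ch = cfg.out_channels if i == len(dils) - 1 else cfg.hidden_channels
            self.blocks.append(ResidualBlock(in_ch, out_ch, cfg.kernel_size, d, cfg.dropout, rng))
            in_ch = out_ch
        self.fc = Linear(cfg.out_channels, cfg.hidden_layer, rng)
        self.head_mu = Linear(cfg.hidden_layer, cfg.dim_z, rng)
        self.head_logvar = Linear(cfg.hidden_layer, cfg.dim_z, rng)

    def params(self) -> list[Parameter]:
        out: list[Parameter] = []
        for b in self.blocks:
            out += b.params()
        return out + self.fc.params() + self.head_mu.params() + self.head_logvar.params()

    def receptive_field(self) -> int:
        return receptive_field_dilated(self.cfg.conv_layers()).receptive_field

    def __call__(self, x: Tensor, train: bool = False,
                 rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        if x.data.ndim != 3 or x.data.shape[1] != self.cfg.in_channels:
            raise ValueError("encoder input must be (batch, 21, L)")
        if x.data.shape[2] < 1:
            raise ValueError("sequence length must be at least 1")
        h = x
        for block in self.blocks:
            h = block(h, train=train, rng=rng)
        pooled = h.mean(axis=2)  # global average pool over positions
        hidden = self.fc(pooled).tanh()
        return self.head_mu(hidden), self.head_logvar(hidden)
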