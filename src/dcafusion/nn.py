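"""Neural-network layers and the Adam optimizer on top of ``autograd``.

Conventions follow the usual deep-learning ones: images are ``(B, C, H, W)``,
sequences ``(B, T, F)``.  Convolutions are implemented by patch extraction
(im2col) plus a matrix product, so their gradients come for free from the
autograd primitives.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, pad_last2


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True
        self._buffer_names: list = []

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{prefix}{name}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        """Non-trainable state (e.g. normalization running statistics)."""
        for name in self._buffer_names:
            yield f"{prefix}{name}", getattr(self, name)
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v.named_buffers(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    def state_dict(self) -> dict:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": np.asarray(v).copy()
                      for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - {k for k in state if not k.startswith("buffer:")}
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(
                    f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()
        buffers = dict(self.named_buffers())
        for k in buffers:
            key = f"buffer:{k}"
            if key in state:
                *path, attr = k.split(".")
                obj = self
                for part in path:
                    obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
                setattr(obj, attr, np.asarray(state[key]).copy())

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = glorot(rng, (in_features, out_features),
                             in_features, out_features)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """Grouped 2-D convolution, stride 1, ``padding`` 'valid' or 'same'
    (same-padding applies to the width axis only, matching the temporal
    convolutions used here)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: tuple,
                 groups: int = 1, padding: str = "valid",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must divide groups")
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        rng = rng or np.random.default_rng(0)
        kh, kw = kernel_size
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.groups, self.padding = (kh, kw), groups, padding
        cg = in_channels // groups
        fan_in, fan_out = cg * kh * kw, (out_channels // groups) * kh * kw
        # one weight matrix per group: (cg*kh*kw, out_per_group)
        self.weight = glorot(rng, (groups, cg * kh * kw, out_channels // groups),
                             fan_in, fan_out)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    @staticmethod
    def out_size(size: int, k: int, padding: str) -> int:
        return size if padding == "same" else size - k + 1

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if C != self.in_channels:
            raise ValueError(
                f"Conv2d expected {self.in_channels} input channels, got {C}")
        kh, kw = self.kernel_size
        if self.padding == "same":
            if kh != 1:
                raise ValueError("'same' padding supported for kh=1 kernels only")
            lo = (kw - 1) // 2
            x = pad_last2(x, (0, 0), (lo, kw - 1 - lo))
            B, C, H, W = x.shape
        oh, ow = H - kh + 1, W - kw + 1
        if oh < 1 or ow < 1:
            raise ValueError(
                f"Conv2d kernel {self.kernel_size} larger than input {(H, W)}")

        ii = (np.arange(oh)[:, None, None, None] + np.arange(kh)[None, None, :, None])
        jj = (np.arange(ow)[None, :, None, None] + np.arange(kw)[None, None, None, :])
        ii = np.broadcast_to(ii, (oh, ow, kh, kw))
        jj = np.broadcast_to(jj, (oh, ow, kh, kw))
        # patches: (B, C, oh, ow, kh, kw)
        patches = x[:, :, ii, jj]

        g, cg = self.groups, C // self.groups
        opg = self.out_channels // g
        # (B, g, cg, oh, ow, kh, kw) -> (B, g, oh*ow, cg*kh*kw)
        p = patches.reshape(B, g, cg, oh, ow, kh, kw)
        p = p.transpose((0, 1, 3, 4, 2, 5, 6)).reshape(B, g, oh * ow, cg * kh * kw)
        out = p @ self.weight  # broadcast over B: (B, g, oh*ow, opg)
        out = out.transpose((0, 1, 3, 2)).reshape(B, self.out_channels, oh, ow)
        return out + self.bias.reshape(1, self.out_channels, 1, 1)


class AvgPool2d(Module):
    """Non-overlapping average pooling; trailing rows/columns that do not
    fill a cell are dropped."""

    def __init__(self, pool_size: tuple):
        super().__init__()
        self.pool_size = tuple(pool_size)

    def forward(self, x: Tensor) -> Tensor:
        ph, pw = self.pool_size
        B, C, H, W = x.shape
        oh, ow = H // ph, W // pw
        if oh < 1 or ow < 1:
            raise ValueError(f"pool {self.pool_size} larger than input {(H, W)}")
        x = x[:, :, :oh * ph, :ow * pw]
        return x.reshape(B, C, oh, ph, ow, pw).mean(axis=(3, 5))


class BatchNorm2d(Module):
    """Per-feature-map batch normalization with running statistics for
    inference, as in the canonical compact-convnet recipes."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.n_features = n_features
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self._buffer_names = ["running_mean", "running_var"]

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        if C != self.n_features:
            raise ValueError(f"BatchNorm2d built for {self.n_features} maps, got {C}")
        shape = (1, C, 1, 1)
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xn = (x - mean) * (var + self.eps) ** -0.5
        else:
            mean = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xn = (x - mean) * (var + self.eps) ** -0.5
        return xn * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Dropout(Module):
    def __init__(self, p: float = 0.25):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class LSTM(Module):
    """Single-layer LSTM; returns the final hidden state ``(B, hidden)``.

    Gate order i, f, g, o; forget-gate bias initialized to 1 (standard
    remedy for early vanishing of the cell gradient).
    """

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        H = hidden_size
        self.hidden_size = H
        self.w_ih = glorot(rng, (input_size, 4 * H), input_size + H, H)
        self.w_hh = glorot(rng, (H, 4 * H), input_size + H, H)
        bias = np.zeros(4 * H)
        bias[H:2 * H] = 1.0
        self.bias = Tensor(bias, requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        B, T, F = x.shape
        H = self.hidden_size
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        # input projections for every step in one product: (B, T, 4H)
        xw = x @ self.w_ih + self.bias
        for t in range(T):
            gates = xw[:, t, :] + h @ self.w_hh
            i = gates[:, 0 * H:1 * H].sigmoid()
            f = gates[:, 1 * H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


def softmax(logits: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-subtraction; the max is a constant
    w.r.t. differentiation, which leaves the gradient unchanged)."""
    shift = logits - Tensor(logits.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of integer labels ``y`` under
    ``logits`` (B, K)."""
    y = np.asarray(y, dtype=int)
    shift = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    lse = shift.exp().sum(axis=1, keepdims=True).log()
    logp = shift - lse
    picked = logp[np.arange(len(y)), y]
    return -picked.mean()


class Adam:
    """Adam with the standard defaults (lr 1e-3, betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
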