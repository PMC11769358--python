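"""Layer building blocks (dense, convolution, normalization, LSTM) used by the
translation networks and the IED classifier.

Parameter initialization is Glorot-uniform and always driven by an explicit
``numpy.random.Generator``, so every network is a deterministic function of
its seed.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, concat


class Module:
    """Base class with recursive parameter collection.

    Submodules are discovered from instance attributes (including lists and
    tuples of modules/tensors) in sorted attribute order, giving a stable
    parameter ordering for optimizers and checkpoints.
    """

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for key in sorted(vars(self)):
            val = getattr(self, key)
            out.extend(_collect(f"{prefix}{key}", val))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _collect(name: str, val) -> list[tuple[str, Tensor]]:
    if isinstance(val, Tensor):
        return [(name, val)] if val.requires_grad else []
    if isinstance(val, Module):
        return val.named_parameters(prefix=name + ".")
    if isinstance(val, (list, tuple)):
        out = []
        for i, item in enumerate(val):
            out.extend(_collect(f"{name}.{i}", item))
        return out
    return []


def _param(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> Tensor:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    t = Tensor(rng.uniform(-bound, bound, size=shape))
    t.requires_grad = True
    return t


def _zeros(shape) -> Tensor:
    t = Tensor(np.zeros(shape))
    t.requires_grad = True
    return t


def _ones(shape) -> Tensor:
    t = Tensor(np.ones(shape))
    t.requires_grad = True
    return t


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = _param(rng, (n_in, n_out), n_in, n_out)
        self.b = _zeros((n_out,))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class ConvTime(Module):
    """k x 1 convolution along the time axis of (B, C, L, M) activations."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding="same", bias: bool = True):
        self.w = _param(rng, (c_out, c_in, kernel), c_in * kernel, c_out * kernel)
        self.b = _zeros((c_out,)) if bias else None
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv_time(self.w, self.b, stride=self.stride, padding=self.padding)


class InstanceNorm(Module):
    """Per-sample, per-channel normalization over time and sensors, with affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = _ones((channels,))
        self.beta = _zeros((channels,))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        xhat = xc / (var + self.eps) ** 0.5
        c = x.shape[1]
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


def sensor_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize activations per (channel, sensor) over batch and time.

    This is the parameter-free normalization inside a spatially-adaptive
    denormalization block: statistics are shared across the batch, in the
    manner of batch normalization, but kept separate per sensor column so the
    spatial (sensor) structure is preserved.
    """
    mu = x.mean(axis=(0, 2), keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=(0, 2), keepdims=True)
    return xc / (var + eps) ** 0.5


class LSTM(Module):
    """Single-layer LSTM over (B, L, F) -> (B, L, H) with zero initial state."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.w = _param(rng, (n_in + hidden, 4 * hidden), n_in + hidden, 4 * hidden)
        self.b = _zeros((4 * hidden,))
        self.hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        from ._autograd import stack

        B, L, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs = []
        for t in range(L):
            xt = x[:, t, :]
            gates = concat([xt, h], axis=1) @ self.w + self.b
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return stack(outs, axis=1)
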