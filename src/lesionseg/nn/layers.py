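"""Layer/module system on top of the autodiff tensor.

Modules hold parameters as ``Tensor`` objects with ``requires_grad=True``
and are discovered recursively through attributes and lists, mirroring the
conventions of the mainstream deep-learning frameworks at desk scale.
"""

from __future__ import annotations

import numpy as np

from . import tensor as F
from .tensor import Tensor


class Module:
    """Base class; subclasses define ``forward``."""

    training: bool = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def modules(self):
        """Yield self and all submodules, depth-first."""
        yield self
        for child in self._children():
            yield from child.modules()

    def parameters(self) -> list[Tensor]:
        params = []
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # checkpointing -------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        """All parameter and buffer arrays, in deterministic walk order."""
        out = []
        for m in self.modules():
            for name in sorted(vars(m)):
                v = vars(m)[name]
                if isinstance(v, Tensor) and v.requires_grad:
                    out.append(v.data)
                elif isinstance(v, np.ndarray):
                    out.append(v)
        return out

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for m in self.modules():
            for name in sorted(vars(m)):
                v = vars(m)[name]
                if isinstance(v, Tensor) and v.requires_grad:
                    v.data = np.asarray(next(it), dtype=np.float32).reshape(v.data.shape)
                elif isinstance(v, np.ndarray):
                    vars(m)[name] = np.asarray(next(it), dtype=v.dtype).reshape(v.shape)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return F.sigmoid(x)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Conv2d(Module):
    """3x3/1x1 convolution, stride/dilation configurable, replicate padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 dilation: int = 1, bias: bool = True):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride, self.dilation = stride, dilation
        self.weight = _he_init(rng, (out_ch, in_ch, kernel, kernel),
                               in_ch * kernel * kernel)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias,
                        stride=self.stride, dilation=self.dilation)


class ConvTranspose2d(Module):
    """2x2-kernel, stride-2 transposed convolution (spatial doubling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 bias: bool = True):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = _he_init(rng, (in_ch, out_ch, 2, 2), in_ch * 4)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv_transpose2d_2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.gamma = Tensor(np.ones((1, ch, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, ch, 1, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, ch, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, ch, 1, 1), dtype=np.float32)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
            xhat = xc * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * Tensor(
                (self.running_var + self.eps) ** -0.5)
        return self.gamma * xhat + self.beta


class Dense(Module):
    """Fully connected layer on (N, D) inputs (used in SE blocks only)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.weight = _he_init(rng, (in_dim, out_dim), in_dim)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias


class MaxPool2d(Module):
    def forward(self, x):
        return F.maxpool2d_2x2(x)


class UpsampleNearest2d(Module):
    def forward(self, x):
        return F.upsample_nearest_2x(x)
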