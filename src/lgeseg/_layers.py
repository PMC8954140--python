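"""Neural-network building blocks over the in-repo autodiff engine.

Conventions follow the two network families used in the pipeline: the
anatomical family (instance norm, leaky ReLU, strided-conv down-sampling)
and the pathological family (batch norm, ReLU, max-pool down-sampling).
Parameters are float32; inputs are cast on entry.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, convnd

__all__ = [
    "Parameter", "Module", "Conv", "Linear", "InstanceNorm", "BatchNorm",
    "Adam", "polynomial_lr",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Container with recursive parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def modules(self):
        out = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def freeze(self):
        for p in self.parameters():
            p.requires_grad = False
        return self.eval()

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # checkpoint (de)serialization -----------------------------------------
    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv(Module):
    """N-dim convolution, He-initialised; padding defaults to 'same'."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 padding: int | None = None, nd: int = 3, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * k ** nd
        scale = np.sqrt(2.0 / fan_in)
        self.w = Parameter(rng.normal(0.0, scale, size=(out_ch, in_ch) + (k,) * nd))
        self.b = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = k // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return convnd(x, self.w, self.b, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        self.w = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


def _affine_shape(c: int, ndim: int) -> tuple:
    return (1, c) + (1,) * (ndim - 2)


class InstanceNorm(Module):
    """Per-sample, per-channel normalisation over spatial axes."""

    def __init__(self, c: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(2, x.ndim))
        m = x.mean(axis=axes, keepdims=True)
        xc = x - m
        v = (xc * xc).mean(axis=axes, keepdims=True)
        y = xc * (v + self.eps) ** -0.5
        shp = _affine_shape(self.gamma.data.size, x.ndim)
        return y * self.gamma.reshape(shp) + self.beta.reshape(shp)


class BatchNorm(Module):
    """Batch normalisation over batch + spatial axes with running stats."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0,) + tuple(range(2, x.ndim))
        shp = _affine_shape(self.gamma.data.size, x.ndim)
        if self.training:
            m = x.mean(axis=axes, keepdims=True)
            xc = x - m
            v = (xc * xc).mean(axis=axes, keepdims=True)
            mom = self.momentum
            self.running_mean = ((1 - mom) * self.running_mean
                                 + mom * m.data.reshape(-1).astype(np.float32))
            self.running_var = ((1 - mom) * self.running_var
                                + mom * v.data.reshape(-1).astype(np.float32))
        else:
            m = Tensor(self.running_mean.reshape(shp))
            xc = x - m
            v = Tensor(self.running_var.reshape(shp))
        y = xc * (v + self.eps) ** -0.5
        return y * self.gamma.reshape(shp) + self.beta.reshape(shp)


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def polynomial_lr(lr0: float, step: int, total: int, power: float = 0.9) -> float:
    """Polynomially decayed learning rate, as used for the anatomical stage."""
    frac = min(step, total) / max(total, 1)
    return lr0 * (1.0 - frac) ** power
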