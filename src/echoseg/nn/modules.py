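"""Layer/module abstractions on top of the autodiff engine.

Modules own :class:`Parameter` leaves and child modules, expose
``named_parameters`` / ``state_dict`` with dotted keys, and carry a
``training`` flag (batch normalization switches between batch and running
statistics).  Weight initialisation is He-uniform driven by an explicit
``numpy.random.Generator`` so that building a model from a seed is
reproducible bit for bit.
"""

from __future__ import annotations

import math

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = [
    "Parameter", "Module", "ModuleList",
    "Conv2d", "ConvTranspose2d", "Linear", "BatchNorm2d", "ReLU", "Sigmoid",
    "MaxPool2d", "Sequential", "Identity",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: np.ndarray):
        arr = np.asarray(value, dtype=np.float32)
        self._buffers[name] = arr
        object.__setattr__(self, name, arr)

    # -- traversal -------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: p.data for k, p in self.named_parameters()}
        out.update({k: b for k, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = {k: p for k, p in self.named_parameters()}
        bufs = dict(self.named_buffers())
        for key, val in state.items():
            if key in own:
                if own[key].data.shape != val.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{own[key].data.shape} vs {val.shape}")
                own[key].data[...] = val
            elif key in bufs:
                bufs[key][...] = val
            else:
                raise KeyError(f"unexpected key in state dict: {key}")
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    """Stride-1, 'same'-padded square convolution."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, *,
                 bias: bool = True, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.weight = Parameter(_he_uniform(rng, (out_ch, in_ch, kernel, kernel),
                                            in_ch * kernel * kernel))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias)

    def flops(self, h: int, w: int) -> float:
        f = 2.0 * self.kernel ** 2 * self.in_ch * self.out_ch * h * w
        if self.bias is not None:
            f += self.out_ch * h * w
        return f


class ConvTranspose2d(Module):
    """2x2-kernel, stride-2 transposed convolution (doubles resolution)."""

    def __init__(self, in_ch: int, out_ch: int, *, bias: bool = True,
                 rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Parameter(_he_uniform(rng, (in_ch, out_ch, 2, 2), in_ch * 4))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x):
        return T.conv_transpose2x2(x, self.weight, self.bias)

    def flops(self, h: int, w: int) -> float:
        # h, w: *input* resolution
        f = 2.0 * 4 * self.in_ch * self.out_ch * h * w
        if self.bias is not None:
            f += self.out_ch * 4 * h * w
        return f


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, *, bias: bool = True,
                 rng: np.random.Generator):
        super().__init__()
        self.in_f, self.out_f = in_f, out_f
        self.weight = Parameter(_he_uniform(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros(out_f, dtype=np.float32)) if bias else None

    def forward(self, x):
        out = T.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out

    def flops(self) -> float:
        f = 2.0 * self.in_f * self.out_f
        if self.bias is not None:
            f += self.out_f
        return f


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.weight = Parameter(np.ones(ch, dtype=np.float32))
        self.bias = Parameter(np.zeros(ch, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(ch))
        self.register_buffer("running_var", np.ones(ch))

    def forward(self, x):
        n, c, h, w = x.shape
        if self.training:
            m = x.mean(axis=(0, 2, 3), keepdims=True)
            v = ((x - m) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            cnt = n * h * w
            unbias = cnt / max(cnt - 1, 1)
            mom = self.momentum
            self.running_mean[...] = (1 - mom) * self.running_mean + mom * m.data.ravel()
            self.running_var[...] = (1 - mom) * self.running_var + mom * unbias * v.data.ravel()
        else:
            m = Tensor(self.running_mean.reshape(1, c, 1, 1))
            v = Tensor(self.running_var.reshape(1, c, 1, 1))
        xn = (x - m) * ((v + Tensor(np.float32(self.eps))) ** -0.5)
        return xn * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)

    def flops(self, h: int, w: int) -> float:
        return 2.0 * self.ch * h * w


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return T.sigmoid(x)


class MaxPool2d(Module):
    def forward(self, x):
        return T.maxpool2x2(x)


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.steps = ModuleList(mods)

    def forward(self, x):
        for m in self.steps:
            x = m(x)
        return x
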