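"""Layers and modules built on the autograd core.

Mirrors the familiar NCHW module conventions: parameters are
:class:`~radiclen.nnet.autograd.Tensor` objects with ``requires_grad=True``,
modules expose ``named_parameters`` / ``state_dict`` / ``train`` / ``eval``.
Weight initialization is He-normal driven by an explicit RNG so every model
build is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, bilinear_resize, conv2d

DTYPE = np.float32


class Module:
    """Minimal module base with parameter registration by attribute."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def train(self, mode: bool = True):
        for mod in self.modules():
            mod.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state["buffer:" + name] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, arr in state.items():
            if name.startswith("buffer:"):
                self._assign_buffer(name[len("buffer:"):], arr)
            else:
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r}")
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                params[name].data = arr.astype(params[name].dtype).copy()

    def _assign_buffer(self, dotted: str, arr: np.ndarray) -> None:
        mod: Module = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            mod = mod._modules[part]
        mod._buffers[parts[-1]][...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def parameter(rng: np.random.Generator, shape, fan_in: int | None = None,
              zero: bool = False) -> Tensor:
    """He-normal initialized trainable tensor."""
    if zero:
        data = np.zeros(shape, dtype=DTYPE)
    else:
        if fan_in is None:
            fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
        std = np.sqrt(2.0 / max(fan_in, 1))
        data = rng.normal(0.0, std, size=shape).astype(DTYPE)
    return Tensor(data, requires_grad=True)


class Conv2d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int,
                 stride: int = 1, padding: int | None = None,
                 bias: bool = True):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.stride = stride
        self.padding = padding
        self.weight = parameter(rng, (out_ch, in_ch, kernel, kernel))
        self.bias = parameter(rng, (out_ch,), zero=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


class Linear(Module):
    def __init__(self, rng, in_f: int, out_f: int, bias: bool = True):
        super().__init__()
        self.weight = parameter(rng, (in_f, out_f), fan_in=in_f)
        self.bias = parameter(rng, (out_f,), zero=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Batch statistics while training, running statistics in eval."""

    def __init__(self, num_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_ch, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(num_ch, dtype=DTYPE), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(num_ch, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(num_ch, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean *= 1.0 - self.momentum
            self.running_mean += self.momentum * mu.data.reshape(-1)
            self.running_var *= 1.0 - self.momentum
            self.running_var += self.momentum * var.data.reshape(-1)
            xhat = centered / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            var = self.running_var.reshape(1, -1, 1, 1)
            xhat = (x - mu) / np.sqrt(var + self.eps)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class ConvBNReLU(Module):
    def __init__(self, rng, in_ch, out_ch, kernel=3, stride=1):
        super().__init__()
        self.conv = Conv2d(rng, in_ch, out_ch, kernel, stride=stride, bias=False)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._seq = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x


def downsample2(x: Tensor) -> Tensor:
    """Factor-2 spatial downsampling (bilinear, ceil-mode shapes)."""
    h, w = x.shape[-2], x.shape[-1]
    return bilinear_resize(x, max(1, -(-h // 2)), max(1, -(-w // 2)))
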