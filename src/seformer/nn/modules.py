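"""Layer / container abstractions over the autodiff engine.

Modules register parameters and submodules by attribute assignment and
expose ``named_parameters`` in deterministic insertion order, which is what
makes seeded re-initialization bitwise reproducible: ``initialize(rng)``
visits every layer in a fixed order and draws He-normal weights from the
single generator passed in.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import functional as F
from .tensor import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
            self._modules.pop(name, None)
        elif isinstance(value, Module):
            self._modules[name] = value
            self._params.pop(name, None)
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        self._buffers[name] = np.asarray(value, dtype=DTYPE)
        object.__setattr__(self, name, self._buffers[name])

    # -- traversal ------------------------------------------------------------
    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_parameters(sub)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield (f"{prefix}.{name}" if prefix else name), b
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_buffers(sub)

    # -- modes ----------------------------------------------------------------
    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- init / serialization -------------------------------------------------
    def reset_parameters(self, rng: np.random.Generator):  # pragma: no cover - default no-op
        pass

    def initialize(self, rng: np.random.Generator):
        """He-normal (re)initialization of every layer, in deterministic order."""
        for _, mod in self.named_modules():
            mod.reset_parameters(rng)
        return self

    def state_dict(self) -> dict:
        out = {f"param.{k}": v.data.copy() for k, v in self.named_parameters()}
        out.update({f"buffer.{k}": v.copy() for k, v in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, _, name = key.partition(".")
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unexpected parameter {name!r} in checkpoint")
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                params[name].data[...] = value
            elif kind == "buffer":
                self._set_buffer(name, value)
        return self

    def _set_buffer(self, dotted: str, value):
        mod = self
        *path, leaf = dotted.split(".")
        for part in path:
            mod = mod._modules[part]
        mod._buffers[leaf][...] = value
        object.__setattr__(mod, leaf, mod._buffers[leaf])

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def count_parameters(module: Module) -> int:
    """Total number of trainable scalars."""
    return sum(p.size for p in module.parameters())


# -- concrete layers ----------------------------------------------------------

class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 bias_init: float = 0.0, init_std: float | None = None):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.bias_init = bias_init
        self.init_std = init_std  # None -> He normal sqrt(2 / fan_in)
        self.weight = Parameter(np.zeros((in_features, out_features)))
        self.bias = Parameter(np.full(out_features, bias_init)) if bias else None

    def reset_parameters(self, rng):
        std = self.init_std if self.init_std is not None else np.sqrt(2.0 / self.in_features)
        self.weight.data[...] = rng.normal(0.0, std, self.weight.shape)
        if self.bias is not None:
            self.bias.data[...] = self.bias_init

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(np.zeros((out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def reset_parameters(self, rng):
        _, in_ch, kh, kw = self.weight.shape
        std = np.sqrt(2.0 / (in_ch * kh * kw))
        self.weight.data[...] = rng.normal(0.0, std, self.weight.shape)
        if self.bias is not None:
            self.bias.data[...] = 0.0

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def reset_parameters(self, rng):
        self.weight.data[...] = 1.0
        self.bias.data[...] = 0.0
        self.running_mean[...] = 0.0
        self.running_var[...] = 1.0

    def forward(self, x):
        C = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.size // C
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu.data.reshape(C)
            unbiased = var.data.reshape(C) * (n / max(n - 1, 1))
            self.running_var[...] = (1 - m) * self.running_var + m * unbiased
            y = xc / (var + self.eps).sqrt()
        else:
            mu = Tensor(self.running_mean.reshape(1, C, 1, 1))
            var = Tensor(self.running_var.reshape(1, C, 1, 1))
            y = (x - mu) / (var + self.eps).sqrt()
        return y * self.weight.reshape(1, C, 1, 1) + self.bias.reshape(1, C, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def reset_parameters(self, rng):
        self.weight.data[...] = 1.0
        self.bias.data[...] = 0.0

    def forward(self, x):
        return F.layer_norm(x, self.weight, self.bias, self.eps)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class GELU(Module):
    def forward(self, x):
        return F.gelu(x)


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self._order = []
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)
            self._order.append(layer)

    def forward(self, x):
        for layer in self._order:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self._order)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items = []
        for mod in modules:
            self.append(mod)

    def append(self, mod: Module):
        setattr(self, f"item{len(self._items)}", mod)
        self._items.append(mod)
        return self

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]
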