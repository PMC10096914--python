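"""Layer/module abstractions over the functional ops."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from . import functional as F

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Sequential", "DEFAULT_DTYPE"]

# float32 halves memory traffic and roughly doubles matmul throughput on
# CPU, at precision far beyond what SGD training needs
DEFAULT_DTYPE = np.float32


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialisation."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # state: every Tensor attribute plus numpy buffers (running stats)
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                if isinstance(v, Tensor):
                    state[f"{i}.{k}"] = v.data.copy()
                elif isinstance(v, np.ndarray):
                    state[f"{i}.{k}"] = v.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                key = f"{i}.{k}"
                if key not in state:
                    continue
                if isinstance(v, Tensor):
                    if v.data.shape != state[key].shape:
                        raise ValueError(f"shape mismatch for {key}")
                    v.data = state[key].copy()
                elif isinstance(v, np.ndarray):
                    v[...] = state[key]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 convolution with 'same' padding by default and He init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 pad: int | None = None, bias: bool = True):
        super().__init__()
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.weight = Tensor(w.astype(DEFAULT_DTYPE), requires_grad=True)
        self.bias = (Tensor(np.zeros(out_ch, dtype=DEFAULT_DTYPE), requires_grad=True)
                     if bias else None)

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=DEFAULT_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DEFAULT_DTYPE), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=DEFAULT_DTYPE)
        self.running_var = np.ones(channels, dtype=DEFAULT_DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return F.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training, self.momentum, self.eps)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x
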