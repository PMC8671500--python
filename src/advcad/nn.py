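"""Neural-network building blocks and the Adam optimizer.

Thin module layer over :mod:`advcad.autodiff`: convolutions, group
normalization, dropout, pooling, bilinear upsampling and linear layers, plus
parameter bookkeeping. Layers follow the conventions of the study's networks:
LeakyReLU slope 0.2, GroupNorm with a configurable group count, dropout rate
0.2, and no batch normalization anywhere (batch-norm-free backbones behave
better in GAN training).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: parameter traversal and train/eval mode propagation."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + k, v) for k, v in self._params.items()]
        for name, child in self._children.items():
            out.extend(child.named_parameters(prefix + name + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k, v in self.named_parameters():
            v.data = np.asarray(state[k], dtype=v.data.dtype).copy()

    def parameter_dtype(self) -> np.dtype:
        return self.parameters()[0].data.dtype

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._children[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = cin * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for leaky/ReLU stacks
        self.stride, self.padding = stride, padding
        self.register("weight", rng.normal(0.0, scale, (cout, cin, kernel, kernel)))
        self.register("bias", np.zeros(cout))

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        super().__init__()
        rng = rng or np.random.default_rng()
        w = np.zeros((cin, cout)) if zero_init else rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout))
        self.register("weight", w)
        self.register("bias", np.zeros(cout))

    def forward(self, x):
        return ad.matmul(x, self.weight) + ad.reshape(self.bias, (1, -1))


class GroupNorm(Module):
    """Per-sample normalization over channel groups; works on 2-D or 4-D input."""

    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % groups:
            raise ValueError("channels must divide evenly into groups")
        self.groups, self.channels, self.eps = groups, channels, eps
        self.register("gamma", np.ones(channels))
        self.register("beta", np.zeros(channels))

    def forward(self, x):
        b = x.shape[0]
        orig = x.shape
        g = self.groups
        grouped = ad.reshape(x, (b, g, -1))
        mean = grouped.mean(axis=2, keepdims=True)
        centered = grouped - mean
        var = (centered ** 2).mean(axis=2, keepdims=True)
        norm = centered * ((var + self.eps) ** -0.5)
        norm = ad.reshape(norm, orig)
        shape = (1, self.channels) + (1,) * (len(orig) - 2)
        return norm * ad.reshape(self.gamma, shape) + ad.reshape(self.beta, shape)


class Dropout(Module):
    def __init__(self, rate: float = 0.2, rng: np.random.Generator | None = None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return ad.leaky_relu(x, self.slope)


class Sigmoid(Module):
    def forward(self, x):
        return ad.sigmoid(x)


class AvgPool2d(Module):
    def __init__(self, kernel: int = 2, stride: int | None = None):
        super().__init__()
        self.kernel = kernel
        self.stride = kernel if stride is None else stride

    def forward(self, x):
        return ad.avg_pool2d(x, self.kernel, self.stride)


class GlobalMaxPool(Module):
    def forward(self, x):
        return ad.global_max_pool(x)


class UpsampleBilinear2x(Module):
    def forward(self, x):
        return ad.upsample_bilinear_2x(x)


class Adam:
    """Adam over parameter groups: ``[{"params": [...], "lr": float}, ...]``."""

    def __init__(self, param_groups, beta1: float = 0.5, beta2: float = 0.9,
                 eps: float = 1e-8):
        if param_groups and isinstance(param_groups[0], Tensor):
            raise TypeError("pass parameter groups, e.g. [{'params': ps, 'lr': 1e-4}]")
        self.groups = param_groups
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state = {}
        for group in self.groups:
            for p in group["params"]:
                self.state[id(p)] = (np.zeros_like(p.data), np.zeros_like(p.data))

    def step(self, grads: dict[int, Tensor | np.ndarray]):
        """Apply one update; ``grads`` maps id(param) -> gradient."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for group in self.groups:
            lr = group["lr"]
            for p in group["params"]:
                g = grads.get(id(p))
                if g is None:
                    continue
                g = g.data if isinstance(g, Tensor) else np.asarray(g)
                m, v = self.state[id(p)]
                m += (1 - b1) * (g - m)
                v += (1 - b2) * (g * g - v)
                p.data = p.data - lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def compute_grads(loss: Tensor, params: list[Tensor]) -> dict[int, Tensor]:
    """Convenience: grads of a scalar loss keyed by parameter identity."""
    gs = ad.grad(loss, params)
    return {id(p): g for p, g in zip(params, gs)}
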