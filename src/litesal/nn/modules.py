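"""Layer containers over the autodiff primitives.

A :class:`Module` owns parameters (leaf tensors with ``requires_grad``),
non-trainable buffers (batch-norm running statistics) and sub-modules, and
walks them recursively in deterministic attribute order — enough for
initialization, optimization, and flat state-dict checkpointing.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor, no_grad, relu


class Module:
    def __init__(self) -> None:
        self.training = True

    # -- traversal ---------------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    # -- mode / grad -------------------------------------------------------
    def train(self) -> "Module":
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state dict --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {name: name for name, _ in self.named_buffers()}
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = np.asarray(value, dtype=np.float32).copy()
            elif key in buffers:
                obj = self
                *path, leaf = key.split(".")
                for part in path:
                    obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
                setattr(obj, leaf, np.asarray(value, dtype=np.float32).copy())
            else:
                raise KeyError(f"unknown state entry {key}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    """Indexable list of sub-modules."""

    def __init__(self, modules=()):
        super().__init__()
        self._items = list(modules)

    def _children(self):
        for i, m in enumerate(self._items):
            yield str(i), m

    def append(self, module: Module) -> None:
        self._items.append(module)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


def kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        k = kernel_size
        fan_in = in_channels * k * k
        self.weight = Tensor(
            kaiming_uniform(rng, (out_channels, in_channels, k, k), fan_in), requires_grad=True
        )
        if bias:
            bound = 1.0 / np.sqrt(fan_in)
            self.bias = Tensor(
                rng.uniform(-bound, bound, size=out_channels).astype(np.float32),
                requires_grad=True,
            )
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(
            x, self.weight, self.bias,
            stride=self.stride, padding=self.padding, dilation=self.dilation,
        )


class BatchNorm2d(Module):
    """Per-channel normalization; batch statistics in training, running in eval."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._buffer_names = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
            return F.batch_norm(x, self.weight, self.bias, mean, var, self.eps, True)
        return F.batch_norm(
            x, self.weight, self.bias, self.running_mean, self.running_var, self.eps, False
        )


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(
            kaiming_uniform(rng, (in_features, out_features), in_features), requires_grad=True
        )
        bound = 1.0 / np.sqrt(in_features)
        self.bias = Tensor(
            rng.uniform(-bound, bound, size=out_features).astype(np.float32), requires_grad=True
        )

    def forward(self, x: Tensor) -> Tensor:
        from .tensor import matmul

        return matmul(x, self.weight) + self.bias


class ConvBNReLU(Module):
    """3x3 conv + batch norm + ReLU, the stock block of the network."""

    def __init__(self, cin, cout, rng, stride=1, dilation=1, kernel_size=3):
        super().__init__()
        pad = dilation * (kernel_size - 1) // 2
        self.conv = Conv2d(cin, cout, kernel_size, rng, stride=stride,
                           padding=pad, dilation=dilation, bias=False)
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.bn(self.conv(x)))


def zero_module(module: Module) -> Module:
    """Set every parameter of `module` to zero (identity-path probes)."""
    for p in module.parameters():
        p.data[...] = 0.0
    return module
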