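"""Trainable modules: thin parameter containers over the functional ops."""

from __future__ import annotations

import numpy as np

from voxsr.nn import functional as F
from voxsr.nn.tensor import Tensor


class Parameter(Tensor):
    """A trainable tensor with a fan-in record for initialisation."""

    def __init__(self, data, fan_in: int, name: str = ""):
        super().__init__(data, requires_grad=True, name=name)
        self.fan_in = int(fan_in)


class Module:
    """Base class: tracks child modules and parameters by attribute order."""

    def named_parameters(self, prefix=""):
        for key, val in vars(self).items():
            name = f"{prefix}{key}" if not prefix else f"{prefix}.{key}"
            if isinstance(val, Parameter):
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(name)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    """'Same'-padded stride-1 3D convolution with bias."""

    def __init__(self, cin: int, cout: int, k: int):
        self.weight = Parameter(
            np.zeros((cout, cin, k, k, k), dtype=np.float32), fan_in=cin * k ** 3
        )
        self.bias = Parameter(np.zeros(cout, dtype=np.float32), fan_in=cin * k ** 3)

    def forward(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias)


class ConvTranspose3d(Module):
    """Kernel-2 stride-2 transposed convolution (doubles each spatial dim)."""

    def __init__(self, cin: int, cout: int):
        self.weight = Parameter(
            np.zeros((cin, cout, 2, 2, 2), dtype=np.float32), fan_in=cin * 8
        )
        self.bias = Parameter(np.zeros(cout, dtype=np.float32), fan_in=cin * 8)

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose3d(x, self.weight, self.bias)


class ConvBlock(Module):
    """conv -> ReLU (the repeated unit of every architecture here)."""

    def __init__(self, cin: int, cout: int, k: int = 3, activate: bool = True):
        self.conv = Conv3d(cin, cout, k)
        self.activate = activate

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        return F.relu(y) if self.activate else y


class DoubleConv(Module):
    """Two 3x3x3 conv+ReLU layers with an explicit hidden width."""

    def __init__(self, cin: int, hidden: int, cout: int):
        self.a = ConvBlock(cin, hidden)
        self.b = ConvBlock(hidden, cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.b(self.a(x))


class PerturbationSite(Module):
    """An identity layer where inference-time perturbations can be switched on.

    ``configure`` arms the site with a mode (``"dropout"`` or ``"noise"``),
    a parameter (rate or sigma) and a seeded generator; ``disarm`` returns
    it to the identity.  Training never arms sites.
    """

    def __init__(self, name: str):
        self.site_name = name
        self.mode = None
        self.param = 0.0
        self.rng = None

    def configure(self, mode: str, param: float, rng: np.random.Generator):
        if mode not in ("dropout", "noise"):
            raise ValueError(f"unknown perturbation mode {mode!r}")
        self.mode = mode
        self.param = float(param)
        self.rng = rng

    def disarm(self):
        self.mode = None
        self.param = 0.0
        self.rng = None

    def forward(self, x: Tensor) -> Tensor:
        if self.mode == "dropout":
            return F.dropout(x, self.param, self.rng)
        if self.mode == "noise":
            return F.gaussian_noise(x, self.param, self.rng)
        return x


def init_xavier_uniform(module: Module, seed: int) -> Module:
    """Initialise all weights from U(-1/sqrt(n), 1/sqrt(n)), n = layer fan-in.

    Biases are set to zero.  Deterministic given ``seed``: parameters are
    visited in declaration order with a single generator.
    """
    rng = np.random.default_rng(seed)
    for name, p in module.named_parameters():
        if p.data.ndim <= 1:  # bias
            p.data[...] = 0.0
        else:
            bound = 1.0 / np.sqrt(p.fan_in)
            p.data[...] = rng.uniform(-bound, bound, p.data.shape).astype(np.float32)
    return module
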