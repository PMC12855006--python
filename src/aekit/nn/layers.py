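"""Neural-network layers built on the autograd tensors."""

from __future__ import annotations

import copy

import numpy as np

from .autograd import Tensor
from .conv import conv2d, conv_transpose2d

__all__ = [
    "Module", "Linear", "MaskedLinear", "BatchNorm1d", "BatchNorm2d",
    "Dropout", "ReLU", "Sigmoid", "Identity", "Sequential",
    "Conv2d", "ConvTranspose2d", "Flatten",
]


class Module:
    """Base class with recursive parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

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
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()] + [
            m.running_mean.copy() for m in self.modules() if isinstance(m, _BatchNormBase)
        ] + [
            m.running_var.copy() for m in self.modules() if isinstance(m, _BatchNormBase)
        ]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        bns = [m for m in self.modules() if isinstance(m, _BatchNormBase)]
        expected = len(params) + 2 * len(bns)
        if len(state) != expected:
            raise ValueError(f"state has {len(state)} arrays, expected {expected}")
        i = 0
        for p in params:
            p.data = state[i].copy()
            i += 1
        for m in bns:
            m.running_mean = state[i].copy()
            i += 1
        for m in bns:
            m.running_var = state[i].copy()
            i += 1

    def clone_state(self) -> list[np.ndarray]:
        return copy.deepcopy(self.state_dict())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _linear_init(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in) if fan_in > 0 else 0.0
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Tensor(_linear_init(rng, in_features, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(_linear_init(rng, in_features, (out_features,)),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MaskedLinear(Linear):
    """Linear layer whose weight support is restricted to a fixed 0/1 mask.

    ``mask`` has shape (in_features, out_features); positions with mask 0 are
    zeroed at construction and must be re-zeroed (``apply_mask``) after every
    optimizer step so they stay exactly 0 throughout training.
    """

    def __init__(self, in_features, out_features, mask: np.ndarray,
                 rng: np.random.Generator):
        super().__init__(in_features, out_features, rng)
        mask = np.asarray(mask, dtype=np.float64)
        if mask.shape != (in_features, out_features):
            raise ValueError(f"mask shape {mask.shape} != {(in_features, out_features)}")
        self.mask = mask
        self.apply_mask()

    def apply_mask(self) -> None:
        self.weight.data *= self.mask


class _BatchNormBase(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def _normalize_2d(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            n = x.shape[0]
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            xhat = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class BatchNorm1d(_BatchNormBase):
    def forward(self, x: Tensor) -> Tensor:
        return self._normalize_2d(x)


class BatchNorm2d(_BatchNormBase):
    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        flat = x.transpose((0, 2, 3, 1)).reshape(n * h * w, c)
        out = self._normalize_2d(flat)
        return out.reshape(n, h, w, c).transpose((0, 3, 1, 2))


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, rng, kernel_size=4, stride=2, padding=1):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = in_channels * kernel_size ** 2
        self.weight = Tensor(
            _linear_init(rng, fan_in, (out_channels, in_channels, kernel_size, kernel_size)),
            requires_grad=True)
        self.bias = Tensor(_linear_init(rng, fan_in, (out_channels,)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_channels, out_channels, rng, kernel_size=4, stride=2, padding=1):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = in_channels * kernel_size ** 2
        self.weight = Tensor(
            _linear_init(rng, fan_in, (in_channels, out_channels, kernel_size, kernel_size)),
            requires_grad=True)
        self.bias = Tensor(_linear_init(rng, fan_in, (out_channels,)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)
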