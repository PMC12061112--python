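"""Layer modules built on the autodiff Tensor."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: a named tree of parameter tensors."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, attr in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(attr, Tensor) and attr.requires_grad:
                out.append((full, attr))
            elif isinstance(attr, Module):
                out.extend(attr.named_parameters(full))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}"))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k])
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(arr.dtype if arr.dtype.kind == "f"
                                else np.float64, copy=True)

    def astype(self, dtype) -> "Module":
        """Cast every parameter in place (e.g. float32 for training speed)."""
        for _, p in self.named_parameters():
            p.data = p.data.astype(dtype)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, zero_init: bool = False):
        fan_in = in_ch * kernel * kernel
        if zero_init:
            w = np.zeros((out_ch, in_ch, kernel, kernel))
        else:
            w = kaiming_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias)


class GroupNorm(Module):
    def __init__(self, channels: int, num_groups: int | None = None,
                 eps: float = 1e-5):
        if num_groups is None:
            num_groups = 4 if channels % 4 == 0 else 1
        self.num_groups = num_groups
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return T.group_norm(x, self.gamma, self.beta, self.num_groups, self.eps)


class ConvBlock(Module):
    """conv 3x3 -> group norm -> ReLU, the basic feature unit."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv = Conv2d(in_ch, out_ch, 3, rng)
        self.norm = GroupNorm(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return T.relu(self.norm(self.conv(x)))
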