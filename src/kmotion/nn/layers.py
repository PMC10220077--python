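"""Layer/module abstractions over the autograd ops."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d"]


class Module:
    """Parameter container with recursive discovery, torch-Module style."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            params.extend(_collect(value))
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers (for checkpoints)."""
        out: dict[str, np.ndarray] = {}
        _collect_state(self, "", out)
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        current = {}
        _collect_state_refs(self, "", current)
        missing = set(current) ^ set(state)
        if missing:
            raise KeyError(f"checkpoint keys do not match model: {sorted(missing)}")
        for name, (owner, attr) in current.items():
            arr = np.asarray(state[name]).astype(np.float32)
            if isinstance(owner, (list, tuple)):
                owner[attr].data = arr
                continue
            target = getattr(owner, attr)
            if isinstance(target, Tensor):
                target.data = arr
            else:
                setattr(owner, attr, arr.copy())


def _collect(value) -> list[Tensor]:
    if isinstance(value, Tensor):
        return [value] if value.requires_grad else []
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out: list[Tensor] = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _walk(module, prefix, visit):
    for name, value in vars(module).items():
        full = f"{prefix}{name}"
        if isinstance(value, Tensor) or (
            isinstance(value, np.ndarray) and name.startswith("running_")
        ):
            visit(full, module, name, value)
        elif isinstance(value, Module):
            _walk(value, full + ".", visit)
        elif isinstance(value, (list, tuple)):
            for i, v in enumerate(value):
                if isinstance(v, Module):
                    _walk(v, f"{full}.{i}.", visit)
                elif isinstance(v, Tensor):
                    visit(f"{full}.{i}", value, i, v)


def _collect_state(module, prefix, out):
    def visit(full, owner, attr, value):
        out[full] = value.data.copy() if isinstance(value, Tensor) else value.copy()

    _walk(module, prefix, visit)


def _collect_state_refs(module, prefix, out):
    def visit(full, owner, attr, value):
        out[full] = (owner, attr)

    _walk(module, prefix, visit)


class Conv2d(Module):
    """2-D convolution with He-normal init and optional same-size padding.

    ``pad="same"`` preserves the spatial size at stride 1 (asymmetric for
    even kernels); an integer pads symmetrically.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | str = "same", bias: bool = True):
        self.stride = stride
        if pad == "same":
            total = kernel - 1
            before, after = total // 2, total - total // 2
            self.pad = (before, after, before, after)
        else:
            self.pad = (pad, pad, pad, pad)
        std = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.weight = Tensor(rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch), requires_grad=True)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ag.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, training, self.momentum, self.eps)
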