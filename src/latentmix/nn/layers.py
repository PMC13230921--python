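"""Layers, initialisation and optimisation for the numpy autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import DTYPE, Parameter, Tensor

__all__ = ["Dense", "Conv2d", "LayerNorm", "Module", "AdamW"]


class Module:
    """Lightweight parameter container; subclasses register layers as attributes."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=DTYPE)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.w = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    """3x3 (default) convolution over NHWC tensors."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        kernel: int = 3,
        stride: int = 1,
        pad: int = 1,
    ):
        fan_in = kernel * kernel * c_in
        self.w = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, c_in, c_out)))
        self.b = Parameter(np.zeros(c_out))
        self.stride = stride
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.w, self.b, stride=self.stride, pad=self.pad)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2.0).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class AdamW:
    """Decoupled-weight-decay Adam with an optional linear learning-rate decay to zero."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 5e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
        total_steps: int | None = None,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.total_steps = total_steps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def current_lr(self) -> float:
        if not self.total_steps:
            return self.lr
        frac = 1.0 - self.t / self.total_steps
        return self.lr * max(frac, 0.0)

    def step(self) -> None:
        lr = self.current_lr()
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
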