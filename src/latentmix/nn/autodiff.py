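"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the package's models need: broadcasted
arithmetic, (batched) matmul, elementwise nonlinearities, reductions,
reshapes, strided 2-D convolution with nearest-neighbour upsampling, and
fused softmax / cross-entropy heads. Gradients follow the standard
vector-Jacobian-product formulation; broadcasting is undone by summing over
the broadcast axes.

Float64 throughout: model sizes here are small and exact run-to-run
reproducibility matters more than speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "DTYPE"]

#: computation dtype; float32 keeps the conv workloads in cache, and results
#: remain bit-reproducible run to run on one machine
DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape` from `shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph: a value plus how to backpropagate through it."""

    __slots__ = ("data", "grad", "_parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        # parents: sequence of (Tensor, fn(upstream_grad) -> grad_wrt_parent)
        self._parents = tuple(parents)
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)

    # -- graph plumbing -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, fn in node._parents:
                if not parent.requires_grad:
                    continue
                g = fn(node.grad)
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        return Tensor(
            self.data + other.data,
            parents=(
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor(
            self.data * other.data,
            parents=(
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self**-1.0

    def __pow__(self, exponent: float):
        out = self.data**exponent
        return Tensor(
            out,
            parents=((self, lambda g: g * exponent * self.data ** (exponent - 1)),),
        )

    def __matmul__(self, other):
        other = self._wrap(other)
        out = self.data @ other.data

        def grad_a(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            return _unbroadcast(ga, self.data.shape)

        def grad_b(g):
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(gb, other.data.shape)

        return Tensor(out, parents=((self, grad_a), (other, grad_b)))

    # -- elementwise nonlinearities -----------------------------------------

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=((self, lambda g: g * out),))

    def log(self):
        return Tensor(np.log(self.data), parents=((self, lambda g: g / self.data),))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(out, parents=((self, lambda g: g * (1 - out**2)),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        return Tensor(out, parents=((self, lambda g: g * out * (1 - out)),))

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=((self, lambda g: g * mask),))

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)
        return Tensor(self.data * factor, parents=((self, lambda g: g * factor),))

    # -- reductions & reshapes ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return np.broadcast_to(g, self.data.shape).copy()

        return Tensor(out, parents=((self, grad),))

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor(
            self.data.reshape(shape),
            parents=((self, lambda g: g.reshape(self.data.shape)),),
        )

    def swapaxes(self, a: int, b: int):
        return Tensor(
            np.swapaxes(self.data, a, b),
            parents=((self, lambda g: np.swapaxes(g, a, b)),),
        )

    # -- fused heads ---------------------------------------------------------

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def grad(g):
            return (g - (g * s).sum(axis=axis, keepdims=True)) * s

        return Tensor(s, parents=((self, grad),))

    def cross_entropy(self, labels: np.ndarray):
        """Mean softmax cross-entropy of logits (rows) against integer labels."""
        labels = np.asarray(labels, dtype=np.intp)
        n = self.data.shape[0]
        shifted = self.data - self.data.max(axis=1, keepdims=True)
        logsumexp = np.log(np.exp(shifted).sum(axis=1))
        loss = (logsumexp - shifted[np.arange(n), labels]).mean()
        probs = np.exp(shifted) / np.exp(shifted).sum(axis=1, keepdims=True)

        def grad(g):
            d = probs.copy()
            d[np.arange(n), labels] -= 1.0
            return g * d / n

        return Tensor(loss, parents=((self, grad),))

    def bce_with_logits(self, targets: np.ndarray):
        """Mean binary cross-entropy of logits against {0,1} targets."""
        t = np.asarray(targets, dtype=np.float64)
        x = self.data
        # log(1+exp(-|x|)) formulation for numerical stability
        loss = (np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))).mean()
        sig = 1.0 / (1.0 + np.exp(-x))

        def grad(g):
            return g * (sig - t) / x.size

        return Tensor(loss, parents=((self, grad),))

    # -- spatial ops (NHWC layout) -------------------------------------------

    @staticmethod
    def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
        """(B, OH*OW, KH*KW*C) patch matrix of a padded NHWC array."""
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x
        windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
        windows = windows[:, ::stride, ::stride]  # (B, OH, OW, C, KH, KW)
        b, oh, ow = windows.shape[:3]
        return windows.transpose(0, 1, 2, 4, 5, 3).reshape(b, oh * ow, kh * kw * x.shape[3]), oh, ow

    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int = 1, pad: int = 0):
        """2-D convolution. Input (B,H,W,C), weight (KH,KW,C,F), bias (F,)."""
        x = self.data
        kh, kw, c, f = weight.data.shape
        b, h, w, _ = x.shape
        cols, oh, ow = self._im2col(x, kh, kw, stride, pad)
        wmat = weight.data.reshape(kh * kw * c, f)
        out = (cols @ wmat + bias.data).reshape(b, oh, ow, f)

        def grad_x(g):
            if stride == 1:
                # dX = correlation of dY with the spatially flipped,
                # channel-transposed kernel (full-padding counterpart)
                wg = weight.data[::-1, ::-1].transpose(0, 1, 3, 2).reshape(kh * kw * f, c)
                gcols, gh, gw = self._im2col(
                    np.ascontiguousarray(g), kh, kw, 1, kh - 1 - pad
                )
                return (gcols @ wg).reshape(b, gh, gw, c)
            gmat = g.reshape(b, oh * ow, f)
            dcols = (gmat @ wmat.T).reshape(b, oh, ow, kh, kw, c)
            xp_shape = (b, h + 2 * pad, w + 2 * pad, c)
            dxp = np.zeros(xp_shape, dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i : i + oh * stride : stride, j : j + ow * stride : stride] += dcols[
                        :, :, :, i, j, :
                    ]
            if pad:
                return dxp[:, pad:-pad, pad:-pad]
            return dxp

        def grad_w(g):
            gmat = g.reshape(b * oh * ow, f)
            dw = cols.reshape(b * oh * ow, kh * kw * c).T @ gmat
            return dw.reshape(kh, kw, c, f)

        def grad_b(g):
            return g.sum(axis=(0, 1, 2))

        return Tensor(out, parents=((self, grad_x), (weight, grad_w), (bias, grad_b)))

    def upsample2x(self):
        """Nearest-neighbour 2x spatial upsampling of a (B,H,W,C) tensor."""
        out = self.data.repeat(2, axis=1).repeat(2, axis=2)

        def grad(g):
            b, h2, w2, c = g.shape
            return g.reshape(b, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))

        return Tensor(out, parents=((self, grad),))


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self):
        self.grad = None
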