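"""Compact reverse-mode automatic differentiation on NumPy arrays.

The networks in this package are small (a handful of 1-D convolutions and
narrow MLPs trained full-batch), so a dependency-free engine is both
sufficient and keeps the whole computation in float64, which makes the
finite-difference gradient checks in the test suite tight.

Contents, in dependency order:

* :class:`Tensor` — an ndarray wrapper carrying the backward graph;
* functional ops — arithmetic, ``matmul``, reductions, shaping, ``conv1d``,
  activations, fused softmax cross-entropy, adaptive average pooling, and
  :func:`gradient_reversal` (identity forward, ``-lambda`` scaled backward);
* :class:`Module` and the layers ``Linear``, ``Conv1d``, ``BatchNorm``;
* the optimizers :class:`Adam` and :class:`SGD`.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv1d",
    "elu",
    "sigmoid",
    "softmax",
    "softmax_cross_entropy",
    "gradient_reversal",
    "adaptive_avg_pool1d",
    "Module",
    "Linear",
    "Conv1d",
    "BatchNorm",
    "MLP",
    "Adam",
    "SGD",
]


# ---------------------------------------------------------------------------
# Tensor and graph machinery
# ---------------------------------------------------------------------------


class Tensor:
    """An ndarray with an optional backward closure.

    ``requires_grad`` marks participation in differentiation; after
    :meth:`backward`, every participating tensor holds its accumulated
    gradient in ``.grad``.
    """

    __array_priority__ = 100.0

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], tuple] | None = None

    # -- introspection ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff -----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float64)
        if grad.shape != self.data.shape:
            raise ValueError("seed gradient shape mismatch")

        # iterative topological sort (graphs can be a few hundred nodes deep)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = np.asarray(pg, dtype=np.float64)

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, power(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, key):
        return getitem(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# Primitive ops
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data * b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        ),
    )


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    return _node(a.data**p, (a,), lambda g: (g * p * a.data ** (p - 1.0),))


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return _node(
        a.data @ b.data,
        (a, b),
        lambda g: (g @ b.data.T, a.data.T @ g),
    )


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        return (np.broadcast_to(gg, a.shape).copy(),)

    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        count = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.shape[ax] for ax in axes]))
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / count)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return _node(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def getitem(a, key) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        out = np.zeros_like(a.data)
        np.add.at(out, key, g)
        return (out,)

    return _node(a.data[key], (a,), backward)


def elu(a) -> Tensor:
    a = as_tensor(a)
    neg = a.data < 0
    out = a.data.copy()
    out[neg] = np.expm1(a.data[neg])

    def backward(g):
        ga = g.copy()
        ga[neg] *= out[neg] + 1.0
        return (ga,)

    return _node(out, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data))
    return _node(out, (a,), lambda g: (g * out * (1.0 - out),))


def softmax(logits: Tensor | np.ndarray) -> np.ndarray:
    """Row-wise softmax of raw data (no graph; for predictions/diagnostics)."""
    z = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray, reduction: str = "mean") -> Tensor:
    """Fused log-softmax + negative log-likelihood for integer labels."""
    labels = np.asarray(labels)
    if labels.ndim != 1 or logits.ndim != 2 or labels.shape[0] != logits.shape[0]:
        raise ValueError("logits must be [N, K] and labels [N]")
    if labels.min() < 0 or labels.max() >= logits.shape[1]:
        raise ValueError("label outside the valid class range")
    n = labels.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    per_sample = lse - z[np.arange(n), labels]
    if reduction == "mean":
        value, scale = per_sample.mean(), 1.0 / n
    elif reduction == "sum":
        value, scale = per_sample.sum(), 1.0
    else:
        raise ValueError(f"unknown reduction {reduction!r}")

    def backward(g):
        p = np.exp(z - np.log(np.exp(z).sum(axis=1, keepdims=True)))
        p[np.arange(n), labels] -= 1.0
        return (g * scale * p,)

    return _node(np.float64(value), (logits,), backward)


def gradient_reversal(a: Tensor, lambda_grl: float) -> Tensor:
    """Identity in the forward pass; multiplies gradients by ``-lambda_grl``."""
    a = as_tensor(a)
    return _node(a.data.copy(), (a,), lambda g: (-lambda_grl * g,))


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """Valid-mode 1-D correlation: x [N,Cin,T], w [Cout,Cin,K] -> [N,Cout,L].

    L = floor((T - K) / stride) + 1.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, cin, t = x.shape
    cout, cin_w, k = w.shape
    if cin != cin_w:
        raise ValueError("input channel mismatch")
    if t < k:
        raise ValueError("input shorter than kernel")
    cols = sliding_window_view(x.data, k, axis=2)[:, :, ::stride, :]  # [N,Cin,L,K]
    out = np.einsum("nclk,ock->nol", cols, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None]
    length = out.shape[2]

    def backward(g):
        gw = np.einsum("nclk,nol->ock", cols, g, optimize=True)
        gcols = np.einsum("nol,ock->nclk", g, w.data, optimize=True)
        gx = np.zeros_like(x.data)
        for j in range(k):
            gx[:, :, j : j + stride * length : stride] += gcols[:, :, :, j]
        gb = g.sum(axis=(0, 2)) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return _node(out, parents, backward)


def adaptive_avg_pool1d(x: Tensor, out_width: int) -> Tensor:
    """Average-pool the last axis into ``out_width`` near-equal bins."""
    x = as_tensor(x)
    t = x.shape[-1]
    if out_width > t:
        raise ValueError("output width exceeds input length")
    edges = np.linspace(0, t, out_width + 1).astype(int)
    pieces = [x.data[..., a:b].mean(axis=-1) for a, b in zip(edges[:-1], edges[1:])]
    out = np.stack(pieces, axis=-1)

    def backward(g):
        gx = np.zeros_like(x.data)
        for j, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
            gx[..., a:b] += g[..., j : j + 1] / (b - a)
        return (gx,)

    return _node(out, (x,), backward)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    """Light container tracking parameters, sub-modules and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float64)
        self._buffers[name] = arr
        object.__setattr__(self, name, arr)
        return arr

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- (de)serialization --------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {prefix + k: v.data.copy() for k, v in self._params.items()}
        for k, v in self._buffers.items():
            state[prefix + k] = getattr(self, k).copy()
        for name, m in self._modules.items():
            state.update(m.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, t in self._params.items():
            t.data = np.asarray(state[prefix + k], dtype=np.float64).copy()
        for k in self._buffers:
            arr = np.asarray(state[prefix + k], dtype=np.float64).copy()
            self._buffers[k] = arr
            object.__setattr__(self, k, arr)
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")


def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.register_parameter(
            "weight", _glorot(rng, (in_features, out_features), in_features, out_features)
        )
        self.register_parameter("bias", np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class Conv1d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
    ):
        super().__init__()
        self.stride = stride
        fan_in = in_channels * kernel_size
        self.register_parameter(
            "weight",
            _glorot(rng, (out_channels, in_channels, kernel_size), fan_in, out_channels),
        )
        self.register_parameter("bias", np.zeros(out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm(Module):
    """Batch normalization over all axes except channel axis 1 (2-D or 3-D input)."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.register_parameter("gamma", np.ones(num_features))
        self.register_parameter("beta", np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim == 2:
            axes, pshape = (0,), (1, -1)
        elif x.ndim == 3:
            axes, pshape = (0, 2), (1, -1, 1)
        else:
            raise ValueError("BatchNorm expects 2-D or 3-D input")
        gamma = reshape(self.gamma, pshape)
        beta = reshape(self.beta, pshape)
        if self.training:
            m = tmean(x, axis=axes, keepdims=True)
            centered = x - m
            v = tmean(centered * centered, axis=axes, keepdims=True)
            # track running statistics outside the graph
            bm = self._buffers["running_mean"]
            bv = self._buffers["running_var"]
            bm += self.momentum * (m.data.reshape(-1) - bm)
            bv += self.momentum * (v.data.reshape(-1) - bv)
            xhat = centered * power(v + self.eps, -0.5)
        else:
            rm = self._buffers["running_mean"].reshape(pshape)
            rv = self._buffers["running_var"].reshape(pshape)
            xhat = (x - rm) * ((rv + self.eps) ** -0.5)
        return gamma * xhat + beta


class MLP(Module):
    """Linear stack with ELU between layers and a linear head."""

    def __init__(self, widths: Sequence[int], rng: np.random.Generator):
        super().__init__()
        self.n_layers = len(widths) - 1
        for i in range(self.n_layers):
            setattr(self, f"layer{i}", Linear(widths[i], widths[i + 1], rng))

    def __call__(self, x: Tensor) -> Tensor:
        for i in range(self.n_layers):
            x = getattr(self, f"layer{i}")(x)
            if i < self.n_layers - 1:
                x = elu(x)
        return x


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------


class SGD:
    def __init__(self, params: Iterable[Tensor], lr: float):
        self.params = list(params)
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class Adam:
    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 0.005,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
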