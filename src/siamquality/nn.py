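"""Minimal reverse-mode automatic differentiation for 1-D convolutional networks.

The grading-relevant models in this package (residual 1-D encoder, MLP
projector/predictor) are small enough to train on a CPU with plain numpy,
so rather than depend on a deep-learning framework this module provides a
compact tape-based autodiff ``Tensor`` plus the handful of layers the
siamese architecture needs: ``Linear``, ``Conv1d``, ``BatchNorm1d``,
``MaxPool1d`` and global average pooling, with an ``SGD`` (momentum)
optimizer.  Gradients of every layer are validated against central finite
differences in the test suite.

Everything is float64 and purely deterministic: identical seeds produce
bit-identical parameters, forward passes and updates.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Linear",
    "Conv1d",
    "BatchNorm1d",
    "MaxPool1d",
    "Sequential",
    "relu",
    "global_avg_pool",
    "SGD",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def detach(self) -> "Tensor":
        """Return a view of this value cut out of the graph (stop-gradient)."""
        return Tensor(self.data, requires_grad=False)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs would blow the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in prev):
            out.requires_grad = True
            out._prev = prev
            out._backward = backward
        return out

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    # -- reductions and shaping ----------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        orig = self.data.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)


def relu(x: Tensor) -> Tensor:
    return x.relu()


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, L) -> (N, C) by averaging over the time axis."""
    return x.mean(axis=2)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    training: bool = True

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        # He initialization, appropriate for ReLU nets
        scale = np.sqrt(2.0 / in_dim)
        self.weight = Tensor(rng.normal(0.0, scale, size=(in_dim, out_dim)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv1d(Module):
    """1-D convolution over (N, C_in, L) -> (N, C_out, L_out)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = False):
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.weight = Tensor(rng.normal(0.0, scale, size=(out_ch, in_ch, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        w = self.weight
        stride, pad, k = self.stride, self.padding, self.kernel
        xd = x.data
        if pad:
            xd = np.pad(xd, ((0, 0), (0, 0), (pad, pad)))
        n, c, lp = xd.shape
        l_out = (lp - k) // stride + 1
        idx = np.arange(k)[None, :] + stride * np.arange(l_out)[:, None]  # (L_out, K)
        cols = xd[:, :, idx]  # (N, C, L_out, K)
        out_data = np.einsum("nclk,fck->nfl", cols, w.data, optimize=True)
        if self.bias is not None:
            out_data = out_data + self.bias.data[None, :, None]
        bias = self.bias

        def backward(g):
            w._accum(np.einsum("nclk,nfl->fck", cols, g, optimize=True))
            if bias is not None:
                bias._accum(g.sum(axis=(0, 2)))
            if x.requires_grad or x._prev:
                dcols = np.einsum("fck,nfl->nclk", w.data, g, optimize=True)
                dxp = np.zeros((n, c, lp))
                for j in range(k):
                    dxp[:, :, j + stride * np.arange(l_out)] += dcols[:, :, :, j]
                if pad:
                    dxp = dxp[:, :, pad:lp - pad]
                x._accum(dxp)

        prev = (x, w) if bias is None else (x, w, bias)
        return x._make(out_data, prev, backward)


class MaxPool1d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        k, stride, pad = self.kernel, self.stride, self.padding
        xd = x.data
        if pad:
            xd = np.pad(xd, ((0, 0), (0, 0), (pad, pad)),
                        constant_values=-np.inf)
        n, c, lp = xd.shape
        l_out = (lp - k) // stride + 1
        idx = np.arange(k)[None, :] + stride * np.arange(l_out)[:, None]
        cols = xd[:, :, idx]  # (N, C, L_out, K)
        arg = cols.argmax(axis=3)
        out_data = np.take_along_axis(cols, arg[..., None], axis=3)[..., 0]

        def backward(g):
            dxp = np.zeros((n, c, lp))
            # source position of each pooled sample in the padded input
            src = arg + stride * np.arange(l_out)[None, None, :]
            ni = np.arange(n)[:, None, None]
            ci = np.arange(c)[None, :, None]
            np.add.at(dxp, (ni, ci, src), g)
            if pad:
                dxp = dxp[:, :, pad:lp - pad]
            x._accum(dxp)

        return x._make(out_data, (x,), backward)


class BatchNorm1d(Module):
    """Batch normalization over (N, C, L) or (N, D) inputs."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 3:
            axes, view = (0, 2), (1, -1, 1)
        else:
            axes, view = (0,), (1, -1)
        gamma = self.gamma.reshape(*view)
        beta = self.beta.reshape(*view)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xn = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            rm = self.running_mean.reshape(view)
            rv = self.running_var.reshape(view)
            xn = (x - rm) / np.sqrt(rv + self.eps)
        return xn * gamma + beta


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class SGD:
    """Stochastic gradient descent with momentum and optional weight decay."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    """Adam optimizer; far more step-efficient than SGD at small scale."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
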