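"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains two stochastic variational models (a hierarchical
negative-binomial VAE and a functional basis decomposition).  Both need
gradients of Monte-Carlo ELBO estimates with respect to neural-network
weights.  This module provides exactly the primitives those models use:
a :class:`Tensor` wrapping an ``ndarray`` with a backward tape, dense
layers, batch normalization, and an Adam optimizer.

Broadcasting is supported in the elementwise ops; gradients are
un-broadcast by summation over the broadcast axes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node on the autodiff tape."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")
    __array_priority__ = 100  # so ndarray + Tensor defers to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None
        self.requires_grad = requires_grad

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,), lambda g: (g * out_data * (1 - out_data),))

    def softplus(self):
        # numerically stable: log1p(exp(-|x|)) + max(x, 0)
        out_data = np.log1p(np.exp(-np.abs(self.data))) + np.maximum(self.data, 0.0)
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,), lambda g: (g * sig,))

    def log_softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self.data - m
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True)) + m
        out_data = self.data - lse
        sm = np.exp(out_data)

        def backward(g):
            return (g - sm * g.sum(axis=axis, keepdims=True),)

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def max(self, axis: int = -1, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        arg = np.expand_dims(self.data.argmax(axis=axis), axis)
        one_hot = np.zeros_like(self.data)
        np.put_along_axis(one_hot, arg, 1.0, axis=axis)

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (one_hot * g,)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        return self._make(out_data, (self,), lambda g: (g.reshape(self.shape),))

    def transpose(self):
        return self._make(self.data.T, (self,), lambda g: (g.T,))

    def slice(self, idx):
        """Static slice/index; gradients scatter back into place."""
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(out_data, (self,), backward)

    # -- backprop -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order of the tape
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
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, pg in zip(node._parents, node._backward(g)):
                if not p.requires_grad:
                    continue
                key = id(p)
                grads[key] = grads[key] + pg if key in grads else pg


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along `axis`."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def nb_log_prob_op(x: np.ndarray, log_mean: Tensor, log_theta: Tensor) -> Tensor:
    """Negative-binomial log-pmf as a differentiable node.

    Mean/dispersion parameterization: variance = mean + mean^2 / theta.
    `x` is constant data; gradients flow to `log_mean` and `log_theta`.
    """
    mean = np.exp(log_mean.data)
    theta = np.exp(np.broadcast_to(log_theta.data, mean.shape))
    lp = (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(x + 1.0)
        + theta * (np.log(theta) - np.log(theta + mean))
        + x * (np.log(mean) - np.log(theta + mean))
    )

    def backward(g):
        # d lp / d mean = x/mean - (x + theta)/(theta + mean)
        dmean = x / mean - (x + theta) / (theta + mean)
        # d lp / d theta
        dtheta = (
            digamma(x + theta)
            - digamma(theta)
            + np.log(theta)
            + 1.0
            - np.log(theta + mean)
            - (x + theta) / (theta + mean)
        )
        return (
            _unbroadcast(g * dmean * mean, log_mean.shape),
            _unbroadcast(g * dtheta * theta, log_theta.shape),
        )

    out = Tensor(lp)
    if log_mean.requires_grad or log_theta.requires_grad:
        out.requires_grad = True
        out._parents = (log_mean, log_theta)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# layers


class Parameter(Tensor):
    """A leaf tensor that accumulates gradients."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Linear:
    """Dense affine layer with Kaiming-style fan-in initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / n_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self):
        return [self.weight, self.bias]


class BatchNorm1d:
    """Batch normalization over axis 0 with running statistics.

    Training mode normalizes by batch statistics (differentiably);
    eval mode uses the running moments, making encode/decode
    deterministic functions of their input.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.ravel()
            )
            n = x.shape[0]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            )
            xhat = centered / (var + self.eps).sqrt()
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class MLP:
    """Feed-forward network: Linear (+ BatchNorm + ReLU) per hidden layer."""

    def __init__(
        self,
        n_in: int,
        hidden: list[int],
        n_out: int,
        rng: np.random.Generator,
        batch_norm: bool = True,
        activation: str = "relu",
    ):
        self.layers: list = []
        last = n_in
        for h in hidden:
            self.layers.append(Linear(last, h, rng))
            if batch_norm:
                self.layers.append(BatchNorm1d(h))
            self.layers.append(activation)
            last = h
        self.layers.append(Linear(last, n_out, rng))

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            if layer == "relu":
                x = x.relu()
            elif layer == "tanh":
                x = x.tanh()
            else:
                x = layer(x)
        return x

    def parameters(self):
        out = []
        for layer in self.layers:
            if not isinstance(layer, str):
                out.extend(layer.parameters())
        return out

    def set_training(self, mode: bool):
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                layer.training = mode


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 5e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
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
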