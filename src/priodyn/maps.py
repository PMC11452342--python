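"""Trainable parameter maps and the Adam optimizer.

Every element of the state-space model (recursion, neural input, readouts) is a
:class:`ParamMap`: a deterministic function of a batch of inputs with trainable
weights, a ``forward`` pass that returns a cache, and a ``vjp`` (vector-Jacobian
product) used by backpropagation-through-time.  A map with no hidden layers is
exactly a matrix multiplication, which recovers the linear state-space special
case.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ParamMap", "LinearMap", "MLPMap", "Adam", "glorot"]


def glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    """Glorot/Xavier-uniform weight initialization."""
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_out, fan_in))


class ParamMap:
    """Base class for trainable input->output maps.

    Subclasses hold ``params`` (list of arrays, updated in place by the
    optimizer) and matching ``grads`` accumulators.
    """

    in_dim: int
    out_dim: int

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def forward(self, X: np.ndarray):  # pragma: no cover - interface
        raise NotImplementedError

    def vjp(self, cache, g_out: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients, return gradient w.r.t. the input."""
        raise NotImplementedError  # pragma: no cover - interface

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


class LinearMap(ParamMap):
    """``out = X @ W.T (+ b)`` — the linear special case (no bias by default)."""

    def __init__(self, in_dim, out_dim, rng=None, bias=False, W=None, b=None):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.has_bias = bias or b is not None
        if W is None:
            rng = np.random.default_rng() if rng is None else rng
            W = glorot(rng, out_dim, in_dim)
        self.W = np.asarray(W, dtype=float).reshape(out_dim, in_dim)
        self.params = [self.W]
        if self.has_bias:
            self.b = np.zeros(out_dim) if b is None else np.asarray(b, float)
            self.params.append(self.b)
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, X):
        out = X @ self.W.T
        if self.has_bias:
            out = out + self.b
        return out, X

    def vjp(self, cache, g_out):
        X = cache
        self.grads[0] += g_out.T @ X
        if self.has_bias:
            self.grads[1] += g_out.sum(axis=0)
        return g_out @ self.W


class MLPMap(ParamMap):
    """Feed-forward network with ReLU hidden layers and a linear output layer.

    ``hidden_layers`` of ``hidden_units`` each; hidden activations are
    rectified-linear and all layers carry an additive bias.
    """

    def __init__(self, in_dim, out_dim, hidden_layers=1, hidden_units=64, rng=None):
        super().__init__()
        if hidden_layers < 1:
            raise ValueError("use LinearMap for zero hidden layers")
        rng = np.random.default_rng() if rng is None else rng
        self.in_dim, self.out_dim = in_dim, out_dim
        self.hidden_layers, self.hidden_units = hidden_layers, hidden_units
        dims = [in_dim] + [hidden_units] * hidden_layers + [out_dim]
        self.Ws = [glorot(rng, dims[i + 1], dims[i]) for i in range(len(dims) - 1)]
        self.bs = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self.params = [*self.Ws, *self.bs]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, X):
        h = X
        hiddens = []  # (input to layer, pre-activation) per hidden layer
        for W, b in zip(self.Ws[:-1], self.bs[:-1]):
            a = h @ W.T + b
            hiddens.append((h, a))
            h = np.maximum(a, 0.0)
        out = h @ self.Ws[-1].T + self.bs[-1]
        return out, (hiddens, h)

    def vjp(self, cache, g_out):
        hiddens, h_last = cache
        n_layers = len(self.Ws)
        g = g_out
        self.grads[n_layers - 1] += g.T @ h_last
        self.grads[2 * n_layers - 1] += g.sum(axis=0)
        g = g @ self.Ws[-1]
        for i in range(n_layers - 2, -1, -1):
            h_in, a = hiddens[i]
            g = g * (a > 0)
            self.grads[i] += g.T @ h_in
            self.grads[n_layers + i] += g.sum(axis=0)
            g = g @ self.Ws[i]
        return g


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
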