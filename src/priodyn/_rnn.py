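"""Recurrent cells for the two-section state-space model.

A section's state update has one of three realizations, selected automatically
from the nonlinearity settings:

- additive: ``x' = A(x) + K(u)`` whenever at least one of recursion/input is
  linear;
- combined: ``x' = A''([x; u])`` with a single feed-forward network when both
  recursion and input are nonlinear;
- LSTM recursion: the recursion is a standard LSTM cell whose input is
  ``K(u)``.  The hidden and cell vectors jointly form the internal carry; the
  declared state dimension counts hidden units and readouts see only the
  hidden part.

Each cell implements ``step`` (with cache) and ``step_vjp`` so that truncated
backpropagation-through-time can accumulate gradients for all weights.
"""

from __future__ import annotations

import numpy as np

from .maps import LinearMap, MLPMap, ParamMap, glorot


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class AdditiveCell:
    """``carry' = A(carry) + K(u)``; the carry is the latent state itself."""

    def __init__(self, A: ParamMap, K: ParamMap):
        self.A, self.K = A, K
        self.n = A.out_dim
        self.carry_dim = self.n

    @property
    def params(self):
        return [*self.A.params, *self.K.params]

    @property
    def grads(self):
        return [*self.A.grads, *self.K.grads]

    def maps(self):
        return [self.A, self.K]

    def step(self, carry, u):
        a, cA = self.A.forward(carry)
        k, cK = self.K.forward(u)
        return a + k, (cA, cK)

    def step_vjp(self, cache, g_next):
        cA, cK = cache
        g_carry = self.A.vjp(cA, g_next)
        self.K.vjp(cK, g_next)
        return g_carry


class CombinedCell:
    """General recursion ``carry' = F([carry; u])`` (both A' and K nonlinear)."""

    def __init__(self, F: ParamMap, n: int, u_dim: int):
        self.F = F
        self.n = n
        self.u_dim = u_dim
        self.carry_dim = n

    @property
    def params(self):
        return self.F.params

    @property
    def grads(self):
        return self.F.grads

    def maps(self):
        return [self.F]

    def step(self, carry, u):
        z = np.concatenate([carry, u], axis=-1)
        out, c = self.F.forward(z)
        return out, c

    def step_vjp(self, cache, g_next):
        g_z = self.F.vjp(cache, g_next)
        return g_z[:, : self.n]


class LSTMRecursionCell:
    """LSTM recursion with input ``v = K(u)``; carry is ``[h, c]`` (2n)."""

    def __init__(self, n: int, K: ParamMap, rng: np.random.Generator):
        self.n = n
        self.K = K
        self.carry_dim = 2 * n
        dv = K.out_dim
        self.Wx = glorot(rng, 4 * n, dv)
        self.Wh = glorot(rng, 4 * n, n)
        self.b = np.zeros(4 * n)
        self.b[n : 2 * n] = 1.0  # forget-gate bias init
        self._own = [self.Wx, self.Wh, self.b]
        self._own_grads = [np.zeros_like(p) for p in self._own]

    @property
    def params(self):
        return [*self._own, *self.K.params]

    @property
    def grads(self):
        return [*self._own_grads, *self.K.grads]

    def maps(self):
        return [self.K]

    def zero_grad(self):
        for g in self._own_grads:
            g[...] = 0.0

    def step(self, carry, u):
        n = self.n
        h, c = carry[:, :n], carry[:, n:]
        v, cK = self.K.forward(u)
        z = v @ self.Wx.T + h @ self.Wh.T + self.b
        i = _sigmoid(z[:, :n])
        f = _sigmoid(z[:, n : 2 * n])
        o = _sigmoid(z[:, 2 * n : 3 * n])
        g = np.tanh(z[:, 3 * n :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        carry_new = np.concatenate([h_new, c_new], axis=1)
        return carry_new, (h, c, v, cK, i, f, o, g, tc)

    def step_vjp(self, cache, g_next):
        n = self.n
        h, c, v, cK, i, f, o, g, tc = cache
        gh, gc_out = g_next[:, :n], g_next[:, n:]
        go = gh * tc
        gc = gc_out + gh * o * (1.0 - tc * tc)
        gi = gc * g
        gf = gc * c
        gg = gc * i
        gc_prev = gc * f
        gz = np.concatenate(
            [gi * i * (1 - i), gf * f * (1 - f), go * o * (1 - o), gg * (1 - g * g)],
            axis=1,
        )
        self._own_grads[0] += gz.T @ v
        self._own_grads[1] += gz.T @ h
        self._own_grads[2] += gz.sum(axis=0)
        gv = gz @ self.Wx
        gh_prev = gz @ self.Wh
        self.K.vjp(cK, gv)
        return np.concatenate([gh_prev, gc_prev], axis=1)


class RNNSection:
    """One section of the two-section RNN: a recurrent cell plus its state.

    ``n`` is the declared latent dimension; ``carry_dim`` may be larger (LSTM).
    The exposed state read by the readouts is always the first ``n`` carry
    coordinates.
    """

    def __init__(self, n, u_dim, recursion_setting, input_setting, rng):
        self.n = n
        self.u_dim = u_dim
        self.recursion_setting = recursion_setting
        self.input_setting = input_setting

        def make_map(setting, in_dim, out_dim):
            if setting.form == "linear":
                return LinearMap(in_dim, out_dim, rng=rng)
            return MLPMap(
                in_dim, out_dim, setting.hidden_layers, setting.hidden_units, rng=rng
            )

        if recursion_setting.form == "lstm":
            K = make_map(input_setting, u_dim, u_dim if input_setting.form != "linear" else u_dim)
            self.cell = LSTMRecursionCell(n, K, rng)
        elif recursion_setting.form != "linear" and input_setting.form != "linear":
            # general form: both recursion and input nonlinear -> one network
            F = MLPMap(
                n + u_dim,
                n,
                recursion_setting.hidden_layers,
                recursion_setting.hidden_units,
                rng=rng,
            )
            self.cell = CombinedCell(F, n, u_dim)
        else:
            A = make_map(recursion_setting, n, n)
            if recursion_setting.form == "linear":
                # stable initialization: scaled random orthogonal recursion
                M = rng.standard_normal((n, n)) if n > 1 else rng.standard_normal((1, 1))
                Q_, _ = np.linalg.qr(M)
                A.W[...] = 0.9 * Q_
            K = make_map(input_setting, u_dim, n)
            self.cell = AdditiveCell(A, K)

    @property
    def carry_dim(self):
        return self.cell.carry_dim

    @property
    def params(self):
        return self.cell.params

    @property
    def grads(self):
        return self.cell.grads

    def zero_grad(self):
        for m in self.cell.maps():
            m.zero_grad()
        if isinstance(self.cell, LSTMRecursionCell):
            self.cell.zero_grad()

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w

    def init_carry(self, batch: int) -> np.ndarray:
        return np.zeros((batch, self.carry_dim))

    def exposed(self, carry: np.ndarray) -> np.ndarray:
        return carry[..., : self.n]

    def step(self, carry, u):
        return self.cell.step(carry, u)

    def step_vjp(self, cache, g_next):
        return self.cell.step_vjp(cache, g_next)

    def run(self, U: np.ndarray, carry0: np.ndarray | None = None) -> np.ndarray:
        """Filter a single continuous series ``U`` (T x u_dim).

        Returns the exposed states for k = 0..T (T+1 entries: the state at time
        k is a function of inputs 0..k-1; entry T is the one-step-ahead state).
        """
        T = U.shape[0]
        carry = self.init_carry(1) if carry0 is None else carry0.copy()
        X = np.empty((T + 1, self.n))
        for t in range(T):
            X[t] = self.exposed(carry)[0]
            carry, _ = self.step(carry, U[t : t + 1])
        X[T] = self.exposed(carry)[0]
        return X
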