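"""Minimal dense neural-network layer stack with manual backpropagation.

Sized for desk-scale tabular survival problems (a few thousand rows, tens of
features); forward/backward are plain numpy matrix products.  Parameters
live in per-layer arrays; gradients accumulate in matching ``g_*`` arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]

_ACT = {
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
    "relu": (lambda x: np.maximum(x, 0.0), lambda a: (a > 0).astype(float)),
    "linear": (lambda x: x, lambda a: np.ones_like(a)),
}


class MLP:
    """Fully-connected network with a fixed activation on hidden layers.

    The output layer is linear.  ``dropout`` (inverted, seeded via the rng
    passed to :meth:`forward`) applies after each hidden activation in
    training mode only, so evaluation is deterministic.
    """

    def __init__(self, sizes, activation="tanh", dropout=0.0, rng=None, init_scale=None):
        if activation not in _ACT:
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.dropout = float(dropout)
        rng = rng or np.random.default_rng(0)
        self.W, self.b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = init_scale if init_scale is not None else np.sqrt(1.0 / fan_in)
            self.W.append(rng.normal(0.0, scale, (fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self.gW = [np.zeros_like(w) for w in self.W]
        self.gb = [np.zeros_like(b) for b in self.b]
        self._cache = None

    @property
    def params(self):
        return self.W + self.b

    @property
    def grads(self):
        return self.gW + self.gb

    def zero_grad(self):
        for g in self.gW:
            g[...] = 0.0
        for g in self.gb:
            g[...] = 0.0

    def forward(self, X, train=False, rng=None, return_cache=False):
        act, _ = _ACT[self.activation]
        caches = []
        H = np.asarray(X, float)
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            Z_in = H
            Z = H @ W + b
            if i < last:
                A = act(Z)
                mask = None
                caches.append((Z_in, A, None))
                if train and self.dropout > 0:
                    keep = 1.0 - self.dropout
                    mask = (rng.random(A.shape) < keep) / keep
                    caches[-1] = (Z_in, A, mask)
                    A = A * mask
                H = A
            else:
                caches.append((Z_in, Z, None))
                H = Z
        self._cache = caches
        if return_cache:
            return H, caches
        return H

    def backward(self, dY, cache=None):
        """Backprop ``dY`` (grad of loss wrt output); returns grad wrt input.

        Pass the ``cache`` returned by ``forward(..., return_cache=True)``
        when several forward passes ran before this backward pass.
        """
        _, dact = _ACT[self.activation]
        caches = cache if cache is not None else self._cache
        last = len(self.W) - 1
        delta = np.asarray(dY, float)
        for i in range(last, -1, -1):
            Z_in, A, mask = caches[i]
            if i < last:
                if mask is not None:
                    delta = delta * mask
                delta = delta * dact(A)  # A cached pre-dropout
            self.gW[i] += Z_in.T @ delta
            self.gb[i] += delta.sum(axis=0)
            delta = delta @ self.W[i].T
        return delta


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params, lr=1e-2, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            if self.weight_decay:
                p -= self.lr * self.weight_decay * p  # decoupled decay
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
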