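"""Minimal NumPy building blocks for the trainable models in this package.

Everything here is deliberately small and fully deterministic given a seed:
a monotone piecewise-linear intensity curve (used as the generator of the
cycle-adversarial translator), a tiny fully-connected net (used as the
discriminator), and an Adam optimizer.  Gradients are hand-derived; the
parameter counts are tiny, so plain float64 NumPy is fast enough on one CPU.
"""

from __future__ import annotations

import numpy as np


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class Adam:
    """Adam over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MonotoneCurve:
    """Learnable monotone piecewise-linear map [0, 1] -> R on K equal knots.

    Knot values are ``v_0 = b`` and ``v_k = v_{k-1} + softplus(w_k) * dx``,
    so the curve is strictly increasing for any parameter values — exactly
    the class of maps relating two modality renderings of the same tissue.
    """

    def __init__(self, n_knots: int = 32, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.n_knots = n_knots
        # initialize near the identity: softplus(w) ~ 1
        self.b = np.zeros(1)
        self.w = np.full(n_knots, np.log(np.e - 1.0)) + 0.01 * rng.standard_normal(n_knots)
        self._cache: tuple | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.b, self.w]

    def knot_values(self) -> np.ndarray:
        dx = 1.0 / self.n_knots
        return self.b[0] + np.concatenate([[0.0], np.cumsum(softplus(self.w)) * dx])

    def forward(self, u: np.ndarray) -> np.ndarray:
        u = np.clip(u, 0.0, 1.0)
        v = self.knot_values()
        pos = u * self.n_knots
        i0 = np.minimum(pos.astype(np.int64), self.n_knots - 1)
        frac = pos - i0
        self._cache = (i0, frac)
        return v[i0] * (1.0 - frac) + v[i0 + 1] * frac

    def backward(self, grad_out: np.ndarray) -> list[np.ndarray]:
        """Gradients of sum(grad_out * output) w.r.t. (b, w)."""
        i0, frac = self._cache
        go = np.broadcast_to(grad_out, frac.shape)
        gv = np.zeros(self.n_knots + 1)
        np.add.at(gv, i0.ravel(), (go * (1.0 - frac)).ravel())
        np.add.at(gv, (i0 + 1).ravel(), (go * frac).ravel())
        gb = np.array([gv.sum()])
        dx = 1.0 / self.n_knots
        suffix = np.cumsum(gv[::-1])[::-1]          # sum_{j >= k} dL/dv_j
        gw = sigmoid(self.w) * dx * suffix[1:]
        return [gb, gw]

    def state(self) -> dict:
        return {"curve_b": self.b.copy(), "curve_w": self.w.copy()}

    @classmethod
    def from_state(cls, state: dict, prefix: str = "curve") -> "MonotoneCurve":
        obj = cls(n_knots=len(state[f"{prefix}_w"]))
        obj.b = np.asarray(state[f"{prefix}_b"], dtype=np.float64).copy()
        obj.w = np.asarray(state[f"{prefix}_w"], dtype=np.float64).copy()
        return obj


class TinyMLP:
    """Fully connected net with leaky-ReLU hidden layers (scalar-in, scalar-out
    by default); used as a per-pixel discriminator."""

    def __init__(self, sizes=(1, 16, 16, 1), rng: np.random.Generator | None = None,
                 slope: float = 0.2):
        rng = rng or np.random.default_rng(0)
        self.slope = slope
        self.weights = [rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
                        for a, b in zip(sizes[:-1], sizes[1:])]
        self.biases = [np.zeros(b) for b in sizes[1:]]
        self._cache: list | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x.reshape(-1, self.weights[0].shape[0])
        acts = [h]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < len(self.weights) - 1:
                h = np.where(h > 0, h, self.slope * h)
            acts.append(h)
        self._cache = acts
        return h

    def backward(self, grad_out: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Return (parameter grads, input grad)."""
        acts = self._cache
        g = grad_out.reshape(acts[-1].shape)
        gw, gb = [], []
        for i in range(len(self.weights) - 1, -1, -1):
            if i < len(self.weights) - 1:
                pre = acts[i + 1]
                g = g * np.where(pre > 0, 1.0, self.slope)
            gw.append(acts[i].T @ g)
            gb.append(g.sum(axis=0))
            g = g @ self.weights[i].T
        return [*gw[::-1], *gb[::-1]], g

    def state(self, prefix: str = "disc") -> dict:
        out = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"{prefix}_w{i}"] = w.copy()
            out[f"{prefix}_b{i}"] = b.copy()
        return out
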