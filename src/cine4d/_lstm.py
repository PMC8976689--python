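"""A small LSTM sequence regressor in plain NumPy (hand-derived BPTT).

Maps a window of per-frame feature vectors to one output vector (here: the
3N-dimensional future displacement of the tracked voxel set).  Sized for
desk-scale problems — a few hundred training windows, feature dimension of a
few hundred — where float64 NumPy matmuls train in seconds on one CPU and
results are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from ._nets import Adam, sigmoid


class LSTMRegressor:
    """Stacked LSTM layers + linear head; trained with Adam on MSE."""

    def __init__(self, n_features: int, n_outputs: int, hidden: int = 64,
                 layers: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_features, self.n_outputs = n_features, n_outputs
        self.hidden, self.layers = hidden, layers
        self.wx, self.wh, self.b = [], [], []
        f_in = n_features
        for _ in range(layers):
            self.wx.append(rng.standard_normal((f_in, 4 * hidden)) / np.sqrt(f_in))
            self.wh.append(rng.standard_normal((hidden, 4 * hidden)) / np.sqrt(hidden))
            bias = np.zeros(4 * hidden)
            bias[hidden:2 * hidden] = 1.0     # forget-gate bias
            self.b.append(bias)
            f_in = hidden
        self.w_out = rng.standard_normal((hidden, n_outputs)) / np.sqrt(hidden)
        self.b_out = np.zeros(n_outputs)

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.wx, *self.wh, *self.b, self.w_out, self.b_out]

    def set_params(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.params, values):
            p[...] = v

    # -- forward ------------------------------------------------------------
    def _forward(self, x: np.ndarray, keep_cache: bool):
        """x: (B, T, F) -> output (B, O); optionally cache per-step tensors."""
        bsz, t_len, _ = x.shape
        h_prev = [np.zeros((bsz, self.hidden)) for _ in range(self.layers)]
        c_prev = [np.zeros((bsz, self.hidden)) for _ in range(self.layers)]
        cache = [] if keep_cache else None
        for t in range(t_len):
            inp = x[:, t, :]
            step_cache = []
            for l in range(self.layers):
                z = inp @ self.wx[l] + h_prev[l] @ self.wh[l] + self.b[l]
                hh = self.hidden
                i, f, g, o = (sigmoid(z[:, :hh]), sigmoid(z[:, hh:2 * hh]),
                              np.tanh(z[:, 2 * hh:3 * hh]), sigmoid(z[:, 3 * hh:]))
                c = f * c_prev[l] + i * g
                tc = np.tanh(c)
                h = o * tc
                if keep_cache:
                    step_cache.append((inp, h_prev[l], c_prev[l], i, f, g, o, c, tc))
                h_prev[l], c_prev[l] = h, c
                inp = h
            if keep_cache:
                cache.append(step_cache)
        out = h_prev[-1] @ self.w_out + self.b_out
        return out, h_prev, cache

    def predict(self, x: np.ndarray) -> np.ndarray:
        out, _, _ = self._forward(np.asarray(x, dtype=np.float64), keep_cache=False)
        return out

    # -- backward (MSE) ------------------------------------------------------
    def _grads(self, x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None):
        bsz, t_len, _ = x.shape
        out, h_last, cache = self._forward(x, keep_cache=True)
        err = out - y
        if w is None:
            loss = float(np.mean(err ** 2))
            g_out = 2.0 * err / err.size
        else:
            loss = float(np.mean(w[:, None] * err ** 2))
            g_out = 2.0 * w[:, None] * err / err.size

        gwx = [np.zeros_like(w) for w in self.wx]
        gwh = [np.zeros_like(w) for w in self.wh]
        gb = [np.zeros_like(b) for b in self.b]
        gw_out = h_last[-1].T @ g_out
        gb_out = g_out.sum(axis=0)

        dh_next = [np.zeros((bsz, self.hidden)) for _ in range(self.layers)]
        dc_next = [np.zeros((bsz, self.hidden)) for _ in range(self.layers)]
        dh_next[-1] = g_out @ self.w_out.T
        for t in range(t_len - 1, -1, -1):
            dx_from_above = None
            for l in range(self.layers - 1, -1, -1):
                inp, h_prev, c_prev, i, f, g, o, c, tc = cache[t][l]
                dh = dh_next[l] + (dx_from_above if dx_from_above is not None else 0.0)
                dc = dc_next[l] + dh * o * (1.0 - tc ** 2)
                di = dc * g * i * (1.0 - i)
                df = dc * c_prev * f * (1.0 - f)
                dg = dc * i * (1.0 - g ** 2)
                do = dh * tc * o * (1.0 - o)
                dz = np.concatenate([di, df, dg, do], axis=1)
                gwx[l] += inp.T @ dz
                gwh[l] += h_prev.T @ dz
                gb[l] += dz.sum(axis=0)
                dh_next[l] = dz @ self.wh[l].T
                dc_next[l] = dc * f
                dx_from_above = dz @ self.wx[l].T if l > 0 else None
        return loss, [*gwx, *gwh, *gb, gw_out, gb_out]

    # -- training ------------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray, *, epochs: int = 400,
            batch_size: int = 32, lr: float = 3e-3, val_fraction: float = 0.2,
            patience: int = 60, seed: int = 0, clip: float = 5.0,
            sample_weight: np.ndarray | None = None):
        """Train with Adam + early stopping; returns (train curve, val curve)."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if sample_weight is not None:
            sample_weight = np.asarray(sample_weight, dtype=np.float64)
            sample_weight = sample_weight * (len(sample_weight) / sample_weight.sum())
        rng = np.random.default_rng(seed)
        n = len(x)
        perm = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n))) if n > 4 else 0
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) == 0:
            tr_idx, val_idx = perm, perm
        opt = Adam(self.params, lr=lr)
        best = (np.inf, [p.copy() for p in self.params], 0)
        train_curve, val_curve = [], []
        for epoch in range(epochs):
            order = rng.permutation(len(tr_idx))
            losses = []
            for start in range(0, len(order), batch_size):
                sel = tr_idx[order[start:start + batch_size]]
                wsel = None if sample_weight is None else sample_weight[sel]
                loss, grads = self._grads(x[sel], y[sel], wsel)
                gn = np.sqrt(sum(float(np.sum(g ** 2)) for g in grads))
                if not np.isfinite(gn):
                    raise FloatingPointError("non-finite gradient during LSTM training")
                if gn > clip:
                    grads = [g * (clip / gn) for g in grads]
                opt.step(grads)
                losses.append(loss)
            train_curve.append(float(np.mean(losses)))
            if n_val:
                val_pred = self.predict(x[val_idx])
                val_loss = float(np.mean((val_pred - y[val_idx]) ** 2))
            else:
                val_loss = train_curve[-1]
            val_curve.append(val_loss)
            if val_loss < best[0] - 1e-12:
                best = (val_loss, [p.copy() for p in self.params], epoch)
            elif epoch - best[2] > patience:
                break
        self.set_params(best[1])
        return train_curve, val_curve

    # -- persistence ---------------------------------------------------------
    def state(self) -> dict:
        out = {"meta": np.array([self.n_features, self.n_outputs, self.hidden, self.layers])}
        for l in range(self.layers):
            out[f"wx{l}"], out[f"wh{l}"], out[f"b{l}"] = self.wx[l], self.wh[l], self.b[l]
        out["w_out"], out["b_out"] = self.w_out, self.b_out
        return out

    @classmethod
    def from_state(cls, state: dict) -> "LSTMRegressor":
        nf, no, hid, lay = (int(v) for v in state["meta"])
        obj = cls(nf, no, hidden=hid, layers=lay, seed=0)
        for l in range(lay):
            obj.wx[l] = np.asarray(state[f"wx{l}"], dtype=np.float64).copy()
            obj.wh[l] = np.asarray(state[f"wh{l}"], dtype=np.float64).copy()
            obj.b[l] = np.asarray(state[f"b{l}"], dtype=np.float64).copy()
        obj.w_out = np.asarray(state["w_out"], dtype=np.float64).copy()
        obj.b_out = np.asarray(state["b_out"], dtype=np.float64).copy()
        return obj
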