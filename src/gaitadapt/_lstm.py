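"""Minimal batched LSTM regressor with full backpropagation through time.

Implements exactly what the adaptation estimator needs: stacked LSTM
layers over a (time, batch, feature) tensor, a linear output head
producing one regression value per time step, masked mean-squared-error
loss, analytic gradients and an Adam optimizer.  The time loop keeps only
one matrix product per step (input projections are precomputed and the
weight-gradient contractions are batched over all steps), which makes
training desk-scale sequences (~10^3 windows per subject) fast on a
single CPU.  Computation is float32.

Gate order in the packed weight matrices is (input, forget, output, cell):
the three sigmoid gates first, so one fused activation covers them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LSTMRegressor", "Adam", "clip_gradients"]

DTYPE = np.float32


def forward_loop(
    xproj: np.ndarray, Wh: np.ndarray, H: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recurrent time loop over precomputed input projections.

    ``xproj`` is X @ Wx + b of shape (T, B, 4H); returns (gates, C, Hs)
    with the gate activations packed (i, f, o, g) so one fused call covers
    the three logistic gates (computed as 0.5 * (1 + tanh(x / 2))).
    """
    T, B, _ = xproj.shape
    gates = np.empty_like(xproj)
    C = np.empty((T, B, H), dtype=xproj.dtype)
    Hs = np.empty((T, B, H), dtype=xproj.dtype)
    h = np.zeros((B, H), dtype=xproj.dtype)
    c = np.zeros((B, H), dtype=xproj.dtype)
    s3 = 3 * H
    for t in range(T):
        z = xproj[t] + h @ Wh
        z[:, :s3] = 0.5 * (1.0 + np.tanh(0.5 * z[:, :s3]))  # i, f, o
        z[:, s3:] = np.tanh(z[:, s3:])  # g
        c = z[:, H : 2 * H] * c + z[:, :H] * z[:, s3:]
        h = z[:, 2 * H : s3] * np.tanh(c)
        gates[t] = z
        C[t] = c
        Hs[t] = h
    return gates, C, Hs


def backward_loop(
    gates: np.ndarray, C: np.ndarray, dH: np.ndarray, Wh: np.ndarray, H: int
) -> np.ndarray:
    """Reverse-time gradient loop; returns dLoss/d(pre-activations).

    Weight-gradient contractions are deferred to the caller so they run
    as two large matrix products instead of per-step outer products.
    """
    T, B, _ = gates.shape
    s3 = 3 * H
    tanhC = np.tanh(C)
    dZ = np.empty_like(gates)
    dh = np.zeros((B, H), dtype=gates.dtype)
    dc = np.zeros((B, H), dtype=gates.dtype)
    WhT = np.ascontiguousarray(Wh.T)
    zero = np.zeros((B, H), dtype=gates.dtype)
    for t in range(T - 1, -1, -1):
        z = gates[t]
        i, f, o, g = z[:, :H], z[:, H : 2 * H], z[:, 2 * H : s3], z[:, s3:]
        th = tanhC[t]
        dh_total = dh + dH[t]
        do = dh_total * th
        dct = dh_total * o * (1.0 - th * th) + dc
        c_prev = C[t - 1] if t > 0 else zero
        zt = dZ[t]
        zt[:, :H] = (dct * g) * i * (1.0 - i)
        zt[:, H : 2 * H] = (dct * c_prev) * f * (1.0 - f)
        zt[:, 2 * H : s3] = do * o * (1.0 - o)
        zt[:, s3:] = (dct * i) * (1.0 - g * g)
        dc = dct * f
        dh = zt @ WhT
    return dZ


class _LSTMLayer:
    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(hidden)
        self.Wx = rng.uniform(-k, k, size=(n_in, 4 * hidden)).astype(DTYPE)
        self.Wh = rng.uniform(-k, k, size=(hidden, 4 * hidden)).astype(DTYPE)
        self.b = np.zeros(4 * hidden, dtype=DTYPE)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.hidden = hidden
        self._cache: dict | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """X: (T, B, n_in) -> hidden states (T, B, H)."""
        xproj = np.ascontiguousarray(X @ self.Wx + self.b, dtype=DTYPE)
        gates, C, Hs = forward_loop(xproj, self.Wh, self.hidden)
        self._cache = {"X": X, "gates": gates, "C": C, "H": Hs}
        return Hs

    def backward(self, dH: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """dH: (T, B, H) loss gradient w.r.t. hidden states.

        Returns (dX, [dWx, dWh, db]).  Weight gradients are contracted in
        two large matrix products after the reverse time loop.
        """
        cache = self._cache
        if cache is None:
            raise RuntimeError("backward called before forward")
        X, gates, C, Hs = cache["X"], cache["gates"], cache["C"], cache["H"]
        T, B, H = Hs.shape
        dZ = backward_loop(
            gates, C, np.ascontiguousarray(dH, dtype=DTYPE), self.Wh, H
        )
        dZf = dZ.reshape(T * B, 4 * H)
        dWx = X.reshape(T * B, -1).T @ dZf
        Hprev = np.concatenate(
            [np.zeros((1, B, H), dtype=DTYPE), Hs[:-1]], axis=0
        )
        dWh = Hprev.reshape(T * B, H).T @ dZf
        db = dZf.sum(axis=0)
        dX = dZ @ self.Wx.T
        return dX, [dWx, dWh, db]


class LSTMRegressor:
    """Stacked LSTM + linear head mapping (T, B, F) -> (T, B) outputs."""

    def __init__(
        self,
        n_features: int,
        hidden: int = 128,
        num_layers: int = 1,
        seed: int = 0,
    ):
        if hidden <= 0 or num_layers < 1:
            raise ValueError("hidden > 0 and num_layers >= 1 required")
        rng = np.random.default_rng(seed)
        self.layers = [
            _LSTMLayer(n_features if l == 0 else hidden, hidden, rng)
            for l in range(num_layers)
        ]
        k = 1.0 / np.sqrt(hidden)
        self.Wy = rng.uniform(-k, k, size=(hidden, 1)).astype(DTYPE)
        self.by = np.zeros(1, dtype=DTYPE)
        self.n_features = n_features
        self.hidden = hidden
        self.num_layers = num_layers

    @property
    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend(layer.params)
        out.extend([self.Wy, self.by])
        return out

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Causal forward pass: output at step t depends on steps <= t."""
        if X.ndim != 3 or X.shape[2] != self.n_features:
            raise ValueError(
                f"expected (T, B, {self.n_features}) input, got {X.shape}"
            )
        h = np.asarray(X, dtype=DTYPE)
        for layer in self.layers:
            h = layer.forward(h)
        self._H = h
        return (h @ self.Wy + self.by)[..., 0]

    def backward(self, dY: np.ndarray) -> list[np.ndarray]:
        """Gradients for all params given dLoss/dY of shape (T, B)."""
        T, B = dY.shape
        H = self._H
        dYe = dY[..., None].astype(DTYPE)
        dWy = H.reshape(T * B, self.hidden).T @ dYe.reshape(T * B, 1)
        dby = dYe.sum(axis=(0, 1))
        dH = dYe @ self.Wy.T
        layer_grads: list[list[np.ndarray]] = []
        d = dH
        for layer in reversed(self.layers):
            d, g = layer.backward(d)
            layer_grads.append(g)
        out: list[np.ndarray] = []
        for g in reversed(layer_grads):
            out.extend(g)
        out.extend([dWy, dby])
        return out

    def masked_mse(
        self, Y: np.ndarray, target: np.ndarray, mask: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Mean squared error over masked steps and its gradient."""
        n = mask.sum()
        if n == 0:
            return 0.0, np.zeros_like(Y)
        diff = (Y - target) * mask
        loss = float(np.sum(diff * diff) / n)
        return loss, (2.0 / n) * diff

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for li, layer in enumerate(self.layers):
            out[f"l{li}.Wx"] = layer.Wx
            out[f"l{li}.Wh"] = layer.Wh
            out[f"l{li}.b"] = layer.b
        out["Wy"] = self.Wy
        out["by"] = self.by
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            layer.Wx = np.array(state[f"l{li}.Wx"], dtype=DTYPE)
            layer.Wh = np.array(state[f"l{li}.Wh"], dtype=DTYPE)
            layer.b = np.array(state[f"l{li}.b"], dtype=DTYPE)
        self.Wy = np.array(state["Wy"], dtype=DTYPE)
        self.by = np.array(state["by"], dtype=DTYPE)


@dataclass
class Adam:
    """Adam optimizer over a fixed list of parameter arrays."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: list[np.ndarray] = field(default_factory=list)
    _v: list[np.ndarray] = field(default_factory=list)
    _t: int = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self._m:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1t = 1.0 - self.beta1**self._t
        b2t = 1.0 - self.beta2**self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


def clip_gradients(grads: list[np.ndarray], max_norm: float) -> None:
    """Global-norm gradient clipping, in place."""
    total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads))
    if total > max_norm > 0:
        scale = DTYPE(max_norm / total)
        for g in grads:
            g *= scale
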