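"""Minimal NumPy recurrent sequence model with exact backpropagation.

Implements the stacked LSTM/GRU language model that acts as the molecule
generator (the RL policy), together with a coefficient-weighted categorical
cross-entropy whose gradient doubles as the REINFORCE surrogate gradient:

    L = sum_{b,t} c[b,t] * ( -ln softmax(z[b,t]/T)[y[b,t]] )

With c = 1/(#tokens) this is the teacher-forcing loss; with
c[b,t] = R_b * gamma^t * mask[b,t] / n it is the policy-gradient surrogate.
Everything runs in float64 so analytic gradients can be validated against
central finite differences to tight tolerances.
"""

from __future__ import annotations

import copy

import numpy as np


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class SequenceModel:
    """Stacked recurrent (LSTM or GRU) next-token model over a fixed vocabulary.

    Parameters are plain float64 arrays in ``self.params``:
    ``W{l}`` input->gates, ``U{l}`` hidden->gates, ``b{l}`` gate bias for each
    layer ``l``, plus the softmax head ``Wd``/``bd``.  Inputs are token-id
    arrays; the first layer's ``W`` is applied by row gather, which is the
    one-hot product without materializing one-hot vectors.
    """

    def __init__(self, vocab_size: int, layers: int = 2, units: int = 256,
                 cell: str = "lstm", rng: np.random.Generator | None = None):
        if cell not in ("lstm", "gru"):
            raise ValueError(f"unknown cell type {cell!r}")
        self.V = int(vocab_size)
        self.L = int(layers)
        self.H = int(units)
        self.cell = cell
        self.gates = 4 if cell == "lstm" else 3
        rng = rng or np.random.default_rng(0)
        p: dict[str, np.ndarray] = {}
        for layer in range(self.L):
            in_dim = self.V if layer == 0 else self.H
            g = self.gates * self.H
            p[f"W{layer}"] = _glorot(rng, in_dim, g, (in_dim, g))
            p[f"U{layer}"] = _glorot(rng, self.H, g, (self.H, g))
            p[f"b{layer}"] = np.zeros(g)
            if cell == "lstm":
                p[f"b{layer}"][self.H:2 * self.H] = 1.0  # forget-gate bias
        p["Wd"] = _glorot(rng, self.H, self.V, (self.H, self.V))
        p["bd"] = np.zeros(self.V)
        self.params = p

    # ---------------------------------------------------------------- state
    def zero_state(self, batch: int) -> list[dict[str, np.ndarray]]:
        state = []
        for _ in range(self.L):
            s = {"h": np.zeros((batch, self.H))}
            if self.cell == "lstm":
                s["c"] = np.zeros((batch, self.H))
            state.append(s)
        return state

    # ----------------------------------------------------------- cell steps
    def _cell_forward(self, layer: int, x_proj: np.ndarray,
                      state: dict[str, np.ndarray]):
        H = self.H
        p = self.params
        h_prev = state["h"]
        if self.cell == "lstm":
            c_prev = state["c"]
            z = x_proj + h_prev @ p[f"U{layer}"] + p[f"b{layer}"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            new_state = {"h": h, "c": c}
            cache = (h_prev, c_prev, i, f, g, o, tc)
        else:
            hu = h_prev @ p[f"U{layer}"]
            zb = x_proj + p[f"b{layer}"]
            zg = _sigmoid(zb[:, :H] + hu[:, :H])
            r = _sigmoid(zb[:, H:2 * H] + hu[:, H:2 * H])
            hn = hu[:, 2 * H:]
            n = np.tanh(zb[:, 2 * H:] + r * hn)
            h = (1.0 - zg) * n + zg * h_prev
            new_state = {"h": h}
            cache = (h_prev, zg, r, n, hn)
        return h, new_state, cache

    def _cell_backward(self, layer: int, dh: np.ndarray, carry: dict,
                       cache) -> tuple[np.ndarray, dict, np.ndarray]:
        """Returns (dz wrt gate pre-activations stacked, new carry, dh_prev)."""
        H = self.H
        U = self.params[f"U{layer}"]
        if self.cell == "lstm":
            h_prev, c_prev, i, f, g, o, tc = cache
            dc = carry.get("dc", 0.0)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_prev = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            dh_prev = dz @ U.T
            return dz, {"dc": dc_prev}, dh_prev
        h_prev, zg, r, n, hn = cache
        dzg = dh * (h_prev - n)
        dn = dh * (1.0 - zg)
        dh_prev = dh * zg
        dn_pre = dn * (1.0 - n * n)
        dr = dn_pre * hn
        d_hn = dn_pre * r
        dz_pre = dzg * zg * (1 - zg)
        dr_pre = dr * r * (1 - r)
        dz = np.concatenate([dz_pre, dr_pre, dn_pre], axis=1)
        # U columns see (dz_pre, dr_pre, d_hn): the n gate couples through r*hn
        dU_cols = np.concatenate([dz_pre, dr_pre, d_hn], axis=1)
        dh_prev = dh_prev + dU_cols @ U.T
        return np.concatenate([dz_pre, dr_pre, dn_pre, d_hn], axis=1), \
            {"dU_cols": dU_cols}, dh_prev

    # ------------------------------------------------------------- sampling
    def step(self, ids: np.ndarray, state: list[dict[str, np.ndarray]]):
        """One autoregressive step: token ids -> (logits, new state)."""
        p = self.params
        x_proj = p["W0"][ids]
        new_state = []
        h = None
        for layer in range(self.L):
            h, st, _ = self._cell_forward(layer, x_proj, state[layer])
            new_state.append(st)
            if layer + 1 < self.L:
                x_proj = h @ p[f"W{layer + 1}"]
        logits = h @ p["Wd"] + p["bd"]
        return logits, new_state

    # ------------------------------------------------- loss + exact gradient
    def loss_and_grads(self, X: np.ndarray, Y: np.ndarray, coeffs: np.ndarray,
                       temperature: float = 1.0, dropout_rate: float = 0.0,
                       dropout_rng: np.random.Generator | None = None):
        """Weighted NLL over a teacher-forced batch and its exact gradient.

        X, Y, coeffs: (B, T) arrays of input ids, target ids and per-step
        loss coefficients (0 on padding).  Dropout, when enabled, uses one
        mask per inter-layer boundary held fixed across time steps.
        """
        B, T = X.shape
        p = self.params
        masks = None
        if dropout_rate > 0.0:
            if dropout_rng is None:
                raise ValueError("dropout requires an RNG")
            keep = 1.0 - dropout_rate
            masks = [
                (dropout_rng.random((B, self.H)) < keep) / keep
                for _ in range(self.L - 1)
            ]

        state = self.zero_state(B)
        caches: list[list] = [[] for _ in range(self.L)]
        inputs: list[list[np.ndarray]] = [[] for _ in range(self.L)]
        h_top = np.empty((B, T, self.H))
        for t in range(T):
            x_proj = p["W0"][X[:, t]]
            h = None
            for layer in range(self.L):
                h, st, cache = self._cell_forward(layer, x_proj, state[layer])
                caches[layer].append(cache)
                state[layer] = st
                if layer + 1 < self.L:
                    out = h * masks[layer] if masks is not None else h
                    inputs[layer + 1].append(out)
                    x_proj = out @ p[f"W{layer + 1}"]
            h_top[:, t] = h

        logits = np.einsum("bth,hv->btv", h_top, p["Wd"]) + p["bd"]
        probs = softmax(logits / temperature, axis=-1)
        picked = np.take_along_axis(probs, Y[..., None], axis=-1)[..., 0]
        nll = -np.log(np.clip(picked, 1e-300, None))
        loss = float(np.sum(coeffs * nll))

        # dL/dlogits for tempered softmax cross-entropy
        dlogits = probs.copy()
        np.put_along_axis(
            dlogits, Y[..., None],
            np.take_along_axis(dlogits, Y[..., None], axis=-1) - 1.0, axis=-1)
        dlogits *= (coeffs / temperature)[..., None]

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wd"] = np.einsum("bth,btv->hv", h_top, dlogits)
        grads["bd"] = dlogits.sum(axis=(0, 1))
        dh_above = np.einsum("btv,hv->bth", dlogits, p["Wd"])

        carries = [{} for _ in range(self.L)]
        dh_next = [np.zeros((B, self.H)) for _ in range(self.L)]
        dx_below = np.zeros((B, T, self.H))  # d wrt (masked) output of layer below
        for t in range(T - 1, -1, -1):
            dx_next_layer = None
            for layer in range(self.L - 1, -1, -1):
                if layer == self.L - 1:
                    dh = dh_above[:, t] + dh_next[layer]
                else:
                    d_out = dx_below[:, t] if dx_next_layer is None else dx_next_layer
                    if masks is not None:
                        d_out = d_out * masks[layer]
                    dh = d_out + dh_next[layer]
                dz, carry, dh_prev = self._cell_backward(
                    layer, dh, carries[layer], caches[layer][t])
                carries[layer] = carry
                dh_next[layer] = dh_prev
                if self.cell == "gru":
                    dz_wx = dz[:, :3 * self.H]
                    dU_cols = carry.pop("dU_cols")
                    grads[f"U{layer}"] += caches[layer][t][0].T @ dU_cols
                    carries[layer] = {}
                else:
                    dz_wx = dz
                    grads[f"U{layer}"] += caches[layer][t][0].T @ dz
                grads[f"b{layer}"] += dz_wx.sum(axis=0)
                if layer == 0:
                    np.add.at(grads["W0"], X[:, t], dz_wx)
                else:
                    x_in = inputs[layer][t]
                    grads[f"W{layer}"] += x_in.T @ dz_wx
                    dx_next_layer = dz_wx @ p[f"W{layer}"].T
            if self.L > 1:
                dx_below[:, t] = 0.0  # consumed
        return loss, grads

    # ------------------------------------------------------------- plumbing
    def clone(self) -> "SequenceModel":
        other = copy.copy(self)
        other.params = {k: v.copy() for k, v in self.params.items()}
        return other

    def state_arrays(self) -> dict[str, np.ndarray]:
        return self.params


class Adam:
    """Adam optimizer over a named parameter dict, with gradient clipping.

    ``clip_mode`` is either "norm" (rescale so the global L2 norm is at most
    ``clip``) for supervised training, or "value" (clamp each component to
    [-clip, clip]) as used during RL fine-tuning.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip: float | None = None, clip_mode: str = "norm"):
        if clip_mode not in ("norm", "value"):
            raise ValueError("clip_mode must be 'norm' or 'value'")
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip, self.clip_mode = clip, clip_mode
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        if self.clip is not None:
            if self.clip_mode == "norm":
                total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
                if total > self.clip:
                    scale = self.clip / (total + 1e-12)
                    grads = {k: g * scale for k, g in grads.items()}
            else:
                grads = {k: np.clip(g, -self.clip, self.clip)
                         for k, g in grads.items()}
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)
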