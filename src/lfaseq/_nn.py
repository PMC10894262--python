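"""Seeded numpy neural-net primitives: 3x3 conv blocks, LSTM, linear, Adam.

Everything here is deliberately small and single-threaded-deterministic: the
sequence model operates on tiny ROI crops, so an im2col convolution and a
plain BPTT LSTM in float64 train in seconds on one CPU while giving
bit-reproducible results for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SeqNet", "Adam"]


def _im2col(x: np.ndarray) -> np.ndarray:
    # x: (B, C, H, W) -> (B, C*9, H*W) for a 3x3 kernel, pad 1, stride 1
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (B, C, 3, 3, H, W), (s[0], s[1], s[2], s[3], s[2], s[3]))
    return win.reshape(B, C * 9, H * W)


def _col2im(dcols: np.ndarray, B: int, C: int, H: int, W: int) -> np.ndarray:
    dcols = dcols.reshape(B, C, 3, 3, H, W)
    dxp = np.zeros((B, C, H + 2, W + 2))
    for ki in range(3):
        for kj in range(3):
            dxp[:, :, ki:ki + H, kj:kj + W] += dcols[:, :, ki, kj]
    return dxp[:, :, 1:H + 1, 1:W + 1]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SeqNet:
    """Per-frame conv encoder -> stacked LSTM -> linear head.

    Input: float array (B, T, C_in, H, W); output: (B, out_dim).  The encoder
    applies conv3x3 -> ReLU -> 2x2 average pool per stage, global average
    pool, then a linear projection with ReLU to ``feature_dim``.  The LSTM
    consumes the per-frame feature sequence in timestamp order; the final
    hidden state of the top layer feeds the output head.
    """

    def __init__(self, input_hw, in_channels, encoder_channels, feature_dim,
                 recurrent_hidden, recurrent_layers, out_dim, rng):
        h, w = input_hw
        n_pool = len(encoder_channels)
        if h % (2 ** n_pool) or w % (2 ** n_pool):
            raise ValueError(
                f"input size {input_hw} not divisible by 2^{n_pool} pooling")
        self.input_hw = (int(h), int(w))
        self.in_channels = int(in_channels)
        self.encoder_channels = tuple(int(c) for c in encoder_channels)
        self.feature_dim = int(feature_dim)
        self.hidden = int(recurrent_hidden)
        self.n_layers = int(recurrent_layers)
        self.out_dim = int(out_dim)
        if min(self.feature_dim, self.hidden, self.n_layers,
               self.out_dim, *self.encoder_channels) < 1:
            raise ValueError("all model dimensions must be positive")

        self.params: dict[str, np.ndarray] = {}
        cin = self.in_channels
        for i, cout in enumerate(self.encoder_channels):
            fan_in = cin * 9
            self.params[f"conv{i}_W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (cout, cin, 3, 3))
            self.params[f"conv{i}_b"] = np.zeros(cout)
            cin = cout
        self.params["proj_W"] = rng.normal(
            0.0, np.sqrt(2.0 / cin), (self.feature_dim, cin))
        self.params["proj_b"] = np.zeros(self.feature_dim)
        fin = self.feature_dim
        for l in range(self.n_layers):
            bound = 1.0 / np.sqrt(self.hidden)
            self.params[f"lstm{l}_Wx"] = rng.uniform(
                -bound, bound, (4 * self.hidden, fin))
            self.params[f"lstm{l}_Wh"] = rng.uniform(
                -bound, bound, (4 * self.hidden, self.hidden))
            b = np.zeros(4 * self.hidden)
            b[self.hidden:2 * self.hidden] = 1.0  # forget-gate bias
            self.params[f"lstm{l}_b"] = b
            fin = self.hidden
        self.params["head_W"] = rng.normal(
            0.0, np.sqrt(1.0 / self.hidden), (self.out_dim, self.hidden))
        self.params["head_b"] = np.zeros(self.out_dim)

        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    # ---- forward -----------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        B, T, C, H, W = x.shape
        flat = x.reshape(B * T, C, H, W)
        conv_caches = []
        z = flat
        for i in range(len(self.encoder_channels)):
            Wc = self.params[f"conv{i}_W"]
            cols = _im2col(z)
            W2 = Wc.reshape(Wc.shape[0], -1)
            pre = np.matmul(W2, cols) + self.params[f"conv{i}_b"][:, None]
            n, co, hw = pre.shape
            hh, ww = z.shape[2], z.shape[3]
            pre = pre.reshape(n, co, hh, ww)
            act = np.maximum(pre, 0.0)
            pooled = act.reshape(n, co, hh // 2, 2, ww // 2, 2).mean((3, 5))
            conv_caches.append((cols, pre > 0, z.shape))
            z = pooled
        gap_in_shape = z.shape
        gap = z.mean((2, 3))  # (BT, C)
        proj_pre = gap @ self.params["proj_W"].T + self.params["proj_b"]
        feats = np.maximum(proj_pre, 0.0).reshape(B, T, self.feature_dim)

        lstm_caches = []
        seq = feats
        for l in range(self.n_layers):
            seq, cache = self._lstm_forward(l, seq)
            lstm_caches.append(cache)
        h_last = seq[:, -1]  # (B, H)
        out = h_last @ self.params["head_W"].T + self.params["head_b"]
        if train:
            self._cache = (x.shape, conv_caches, gap_in_shape, gap,
                           proj_pre > 0, feats, lstm_caches, seq, h_last)
        return out

    def _lstm_forward(self, l: int, x: np.ndarray):
        Wx = self.params[f"lstm{l}_Wx"]
        Wh = self.params[f"lstm{l}_Wh"]
        b = self.params[f"lstm{l}_b"]
        B, T, F = x.shape
        Hd = self.hidden
        h = np.zeros((B, Hd))
        c = np.zeros((B, Hd))
        hs = np.empty((B, T, Hd))
        steps = []
        for t in range(T):
            z = x[:, t] @ Wx.T + h @ Wh.T + b
            i = _sigmoid(z[:, :Hd])
            f = _sigmoid(z[:, Hd:2 * Hd])
            g = np.tanh(z[:, 2 * Hd:3 * Hd])
            o = _sigmoid(z[:, 3 * Hd:])
            c_prev, h_prev = c, h
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            steps.append((i, f, g, o, c_prev, h_prev, tc))
        return hs, (x, steps)

    # ---- backward ----------------------------------------------------

    def backward(self, dout: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(output)."""
        if self._cache is None:
            raise RuntimeError("forward(train=True) must precede backward")
        (x_shape, conv_caches, gap_in_shape, gap, proj_mask, feats,
         lstm_caches, seq, h_last) = self._cache
        B, T, C, H, W = x_shape
        g = {k: np.zeros_like(v) for k, v in self.params.items()}

        g["head_W"] = dout.T @ h_last
        g["head_b"] = dout.sum(0)
        dh_last = dout @ self.params["head_W"]
        dseq = np.zeros_like(seq)
        dseq[:, -1] = dh_last
        for l in range(self.n_layers - 1, -1, -1):
            dseq = self._lstm_backward(l, lstm_caches[l], dseq, g)

        dfeat = dseq.reshape(B * T, self.feature_dim)
        dproj = dfeat * proj_mask
        g["proj_W"] = dproj.T @ gap
        g["proj_b"] = dproj.sum(0)
        dgap = dproj @ self.params["proj_W"]  # (BT, C)
        n, co, ph, pw = gap_in_shape
        dz = np.broadcast_to(
            dgap[:, :, None, None] / (ph * pw), gap_in_shape)

        for i in range(len(self.encoder_channels) - 1, -1, -1):
            cols, relu_mask, in_shape = conv_caches[i]
            nb, ci, hh, ww = in_shape
            # un-pool: each output cell spreads evenly over its 2x2 window
            dact = np.repeat(np.repeat(dz, 2, axis=2), 2, axis=3) / 4.0
            dpre = dact * relu_mask
            dflat = dpre.reshape(nb, dpre.shape[1], hh * ww)
            Wc = self.params[f"conv{i}_W"]
            W2 = Wc.reshape(Wc.shape[0], -1)
            g[f"conv{i}_W"] = np.einsum(
                "boh,bch->oc", dflat, cols).reshape(Wc.shape)
            g[f"conv{i}_b"] = dflat.sum((0, 2))
            dcols = np.matmul(W2.T, dflat)
            dz = _col2im(dcols, nb, ci, hh, ww)

        self.grads = g
        self._cache = None

    def _lstm_backward(self, l, cache, dh_seq, g):
        x, steps = cache
        Wx = self.params[f"lstm{l}_Wx"]
        Wh = self.params[f"lstm{l}_Wh"]
        B, T, F = x.shape
        Hd = self.hidden
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * Hd)
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, Hd))
        dc_next = np.zeros((B, Hd))
        for t in range(T - 1, -1, -1):
            i, f, gg, o, c_prev, h_prev, tc = steps[t]
            dh = dh_seq[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * gg
            df = dc * c_prev
            dg_ = dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg_ * (1 - gg * gg), do * o * (1 - o)], axis=1)
            dWx += dz.T @ x[:, t]
            dWh += dz.T @ h_prev
            db += dz.sum(0)
            dx[:, t] = dz @ Wx
            dh_next = dz @ Wh
            dc_next = dc * f
        g[f"lstm{l}_Wx"] = dWx
        g[f"lstm{l}_Wh"] = dWh
        g[f"lstm{l}_b"] = db
        return dx

    # ---- state -------------------------------------------------------

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in self.params.items():
            if k not in state or state[k].shape != v.shape:
                raise ValueError(f"checkpoint mismatch for parameter {k!r}")
        self.params = {k: np.asarray(state[k], dtype=np.float64).copy()
                       for k in self.params}


class Adam:
    """Adaptive-moment optimizer with bias correction."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k in params:
            gk = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * gk
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * gk * gk
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)
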