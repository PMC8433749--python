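"""Minimal neural-network engine for the temporal bubble detector.

Implements exactly the pieces the detector needs — 3x3 convolutions,
stride-2 max pooling, dense layers, a single LSTM layer, sigmoid
cross-entropy and Adam — as plain numpy with hand-written backward
passes. Sequences are short (tens of frames) and images small (64x48),
so im2col convolutions on the CPU are entirely adequate.

Everything is deterministic given the initialization seed; there is no
threading, no fused kernels, no hidden global state.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CRNN", "Adam", "sigmoid", "bce_loss"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-9) -> float:
    """Mean binary cross-entropy between probabilities and 0/1 labels.

    Computed in float64: in float32 the clip bound 1 - eps would round
    back to 1.0 and produce log(0)."""
    p = np.clip(np.asarray(p, dtype=np.float64), eps, 1.0 - eps)
    y = np.asarray(y, dtype=np.float64)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# layer primitives (forward returns cache for backward)
# ---------------------------------------------------------------------------

def _conv3x3_forward(x, W, b):
    """x: (N, C, H, W4); W: (O, C, 3, 3) -> out (N, O, H, W4), same padding."""
    N, C, H, Wd = x.shape
    O = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    patches = np.empty((N, C, 9, H, Wd), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            patches[:, :, k] = xp[:, :, di : di + H, dj : dj + Wd]
            k += 1
    Wr = W.reshape(O, C, 9)
    out = np.einsum("ock,nckhw->nohw", Wr, patches, optimize=True)
    out += b[None, :, None, None]
    return out, (patches, Wr, x.shape)


def _conv3x3_backward(dy, cache):
    patches, Wr, xshape = cache
    N, C, H, Wd = xshape
    dW = np.einsum("nohw,nckhw->ock", dy, patches, optimize=True).reshape(-1, C, 3, 3)
    db = dy.sum(axis=(0, 2, 3))
    dpatch = np.einsum("nohw,ock->nckhw", dy, Wr, optimize=True)
    dxp = np.zeros((N, C, H + 2, Wd + 2), dtype=dy.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di : di + H, dj : dj + Wd] += dpatch[:, :, k]
            k += 1
    return dxp[:, :, 1:-1, 1:-1], dW, db


def _pool2_forward(x):
    """2x2 stride-2 max pooling (keeps small bright features such as a
    near-LED bubble disc alive through the stack)."""
    N, C, H, W = x.shape
    xr = (
        x.reshape(N, C, H // 2, 2, W // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(N, C, H // 2, W // 2, 4)
    )
    idx = np.argmax(xr, axis=-1)  # ties: first element wins
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _pool2_backward(dy, cache):
    idx, xshape = cache
    N, C, H, W = xshape
    dxr = np.zeros((N, C, H // 2, W // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    return (
        dxr.reshape(N, C, H // 2, W // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(N, C, H, W)
    )


class CRNN:
    """Convolutional-recurrent bubble detector.

    Three conv blocks (3x3 conv + ReLU + stride-2 max pool) extract
    optical features (bright spots, dark rims, edges); a dense bottleneck
    feeds one LSTM layer whose memory carries the temporal context that
    single frames lack; a sigmoid head emits a per-frame bubble
    probability. With ``recurrent=False`` the LSTM is bypassed and the
    head reads the bottleneck directly — the per-frame-only baseline.
    """

    def __init__(
        self,
        input_hw: tuple[int, int] = (48, 64),
        conv_channels: tuple[int, ...] = (8, 16, 32),
        feature_dim: int = 64,
        hidden: int = 64,
        recurrent: bool = True,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.input_hw = tuple(input_hw)
        self.dtype = np.dtype(dtype)
        self.conv_channels = tuple(conv_channels)
        self.feature_dim = feature_dim
        self.hidden = hidden
        self.recurrent = recurrent
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}

        def init(*args):
            return rng.normal(*args).astype(self.dtype)

        cin = 1
        h, w = self.input_hw
        for i, cout in enumerate(conv_channels):
            fan_in = cin * 9
            self.params[f"Wc{i}"] = init(0, np.sqrt(2.0 / fan_in), (cout, cin, 3, 3))
            self.params[f"bc{i}"] = np.zeros(cout, dtype=self.dtype)
            cin = cout
            h, w = h // 2, w // 2
        self.flat_dim = cin * h * w
        self.params["Wd"] = init(0, np.sqrt(2.0 / self.flat_dim), (feature_dim, self.flat_dim))
        self.params["bd"] = np.zeros(feature_dim, dtype=self.dtype)
        if recurrent:
            H, D = hidden, feature_dim
            s = np.sqrt(1.0 / D)
            self.params["Wx"] = init(0, s, (4 * H, D))
            self.params["Wh"] = init(0, np.sqrt(1.0 / H), (4 * H, H))
            b = np.zeros(4 * H, dtype=self.dtype)
            b[H : 2 * H] = 1.0  # forget-gate bias: retain memory early in training
            self.params["bl"] = b
            self.params["Wo"] = init(0, np.sqrt(1.0 / H), (1, H))
        else:
            self.params["Wo"] = init(0, np.sqrt(1.0 / feature_dim), (1, feature_dim))
        self.params["bo"] = np.zeros(1, dtype=self.dtype)

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward --------------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (T, H, W) floats in [0, 1] -> per-frame probabilities (T,)."""
        if x.ndim != 3 or x.shape[0] == 0:
            raise ValueError("expected a non-empty (T, H, W) stack")
        T = x.shape[0]
        a = x[:, None, :, :].astype(self.dtype)
        conv_caches = []
        for i in range(len(self.conv_channels)):
            z, ccache = _conv3x3_forward(a, self.params[f"Wc{i}"], self.params[f"bc{i}"])
            r = np.maximum(z, 0.0)
            p, pshape = _pool2_forward(r)
            conv_caches.append((ccache, z > 0, pshape))
            a = p
        flat = a.reshape(T, -1)
        fz = flat @ self.params["Wd"].T + self.params["bd"]
        feat = np.maximum(fz, 0.0)

        if self.recurrent:
            H = self.hidden
            Wx, Wh, bl = self.params["Wx"], self.params["Wh"], self.params["bl"]
            h = np.zeros(H, dtype=self.dtype)
            c = np.zeros(H, dtype=self.dtype)
            hs = np.zeros((T, H), dtype=self.dtype)
            lstm_cache = []
            for t in range(T):
                z = Wx @ feat[t] + Wh @ h + bl
                i_g = sigmoid(z[:H])
                f_g = sigmoid(z[H : 2 * H])
                g_g = np.tanh(z[2 * H : 3 * H])
                o_g = sigmoid(z[3 * H :])
                c_new = f_g * c + i_g * g_g
                tc = np.tanh(c_new)
                h_new = o_g * tc
                lstm_cache.append((h, c, i_g, f_g, g_g, o_g, c_new, tc))
                h, c = h_new, c_new
                hs[t] = h
            head_in = hs
        else:
            lstm_cache = None
            head_in = feat

        logits = head_in @ self.params["Wo"].T[:, 0] + self.params["bo"][0]
        probs = sigmoid(logits)
        if not want_cache:
            return probs
        cache = (conv_caches, flat, fz > 0, feat, lstm_cache, head_in, probs)
        return probs, cache

    # -- backward -------------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Convenience: forward + BCE + full backward in one call."""
        probs, cache = self.forward(x, want_cache=True)
        loss = bce_loss(probs, y)
        grads = self._backward_full(cache, y)
        return loss, probs, grads

    def _backward_full(self, cache, y: np.ndarray) -> dict[str, np.ndarray]:
        conv_caches, flat, fz_mask, feat, lstm_cache, head_in, probs = cache
        T = len(probs)
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dlogit = (probs - y) / T

        grads["Wo"] = (dlogit @ head_in)[None, :]
        grads["bo"] = np.array([dlogit.sum()])
        dhead = dlogit[:, None] * self.params["Wo"][0][None, :]

        if self.recurrent:
            H = self.hidden
            Wx, Wh = self.params["Wx"], self.params["Wh"]
            dfeat = np.zeros_like(feat)
            dh_next = np.zeros(H, dtype=self.dtype)
            dc_next = np.zeros(H, dtype=self.dtype)
            for t in range(T - 1, -1, -1):
                h_prev, c_prev, i_g, f_g, g_g, o_g, c_new, tc = lstm_cache[t]
                dh = dhead[t] + dh_next
                do = dh * tc
                dc = dh * o_g * (1 - tc**2) + dc_next
                di = dc * g_g
                df = dc * c_prev
                dg = dc * i_g
                dz = np.concatenate(
                    [
                        di * i_g * (1 - i_g),
                        df * f_g * (1 - f_g),
                        dg * (1 - g_g**2),
                        do * o_g * (1 - o_g),
                    ]
                )
                grads["Wx"] += np.outer(dz, feat[t])
                grads["Wh"] += np.outer(dz, h_prev)
                grads["bl"] += dz
                dfeat[t] = Wx.T @ dz
                dh_next = Wh.T @ dz
                dc_next = dc * f_g
        else:
            dfeat = dhead

        dfz = dfeat * fz_mask
        grads["Wd"] = dfz.T @ flat
        grads["bd"] = dfz.sum(axis=0)

        # shape of the pooled activation that fed the dense layer
        last_shape = (T, self.conv_channels[-1],
                      self.input_hw[0] >> len(self.conv_channels),
                      self.input_hw[1] >> len(self.conv_channels))
        da = (dfz @ self.params["Wd"]).reshape(last_shape)
        for i in range(len(self.conv_channels) - 1, -1, -1):
            ccache, relu_mask, pshape = conv_caches[i]
            dr = _pool2_backward(da, pshape)
            dz = dr * relu_mask
            da, dW, db = _conv3x3_backward(dz, ccache)
            grads[f"Wc{i}"] += dW
            grads[f"bc{i}"] += db
        return grads


class Adam:
    """Adam optimizer with global-norm gradient clipping."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 3e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float = 5.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        norm = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
        scale = 1.0
        if self.clip_norm and norm > self.clip_norm:
            scale = self.clip_norm / (norm + 1e-12)
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            g = g * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
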