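"""Minimal numpy building blocks for the 1-D U-Net retina model.

Forward and backward passes are written explicitly (im2col + GEMM for
the convolutions) so training is deterministic given a seed and runs on
plain BLAS with no deep-learning runtime.  Only what the U-Net needs is
implemented: same-padding 1-D convolution, 2x average pooling, nearest
2x upsampling, ReLU, sigmoid, mean-squared-error loss, and Adam.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1d", "Adam", "UNet1D", "mse_loss"]


class Conv1d:
    """Same-padding 1-D convolution with odd kernel size."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        assert k % 2 == 1
        self.k = k
        self.W = (rng.standard_normal((c_out, c_in, k))
                  * np.sqrt(2.0 / (c_in * k))).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, Cin, L = x.shape
        k, pad = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # cols[c*k + j, b*L + l] = xp[b, c, l + j]
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B,Cin,L,k)
        cols = np.ascontiguousarray(win.transpose(1, 3, 0, 2)).reshape(Cin * k, B * L)
        Wm = self.W.reshape(-1, Cin * k)
        y = (Wm @ cols).reshape(-1, B, L).transpose(1, 0, 2)
        self._cache = (cols, (B, Cin, L))
        return y + self.b[None, :, None]

    def backward(self, dy: np.ndarray):
        cols, (B, Cin, L) = self._cache
        k, pad = self.k, self.k // 2
        Cout = self.W.shape[0]
        dym = np.ascontiguousarray(dy.transpose(1, 0, 2)).reshape(Cout, B * L)
        dW = (dym @ cols.T).reshape(Cout, Cin, k)
        db = dym.sum(axis=1)
        dcols = (self.W.reshape(Cout, -1).T @ dym).reshape(Cin, k, B, L)
        dxp = np.zeros((B, Cin, L + 2 * pad), dtype=np.float32)
        for j in range(k):
            dxp[:, :, j : j + L] += dcols[:, j].transpose(1, 0, 2)
        return dxp[:, :, pad : pad + L], [dW, db]


def avgpool2(x: np.ndarray) -> np.ndarray:
    return 0.5 * (x[:, :, 0::2] + x[:, :, 1::2])


def avgpool2_backward(dy: np.ndarray) -> np.ndarray:
    return 0.5 * np.repeat(dy, 2, axis=2)


def upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(x, 2, axis=2)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    return dy[:, :, 0::2] + dy[:, :, 1::2]


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    return float(np.mean(diff * diff)), (2.0 / diff.size) * diff


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class UNet1D:
    """1-D U-Net-like encoder-decoder for per-A-scan heatmap regression.

    Four down-pooling and four upsampling steps with one 3-tap
    convolution per step, skip connections by channel concatenation, and
    a linear 1x1 output head regressing the heatmap.  Channel widths
    double per level starting from ``base_channels``.  Input length
    must be divisible by 16.
    """

    def __init__(self, base_channels: int = 16, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        C = base_channels
        self.base_channels = C
        enc = [(1, C), (C, 2 * C), (2 * C, 4 * C), (4 * C, 8 * C)]
        dec = [(16 * C, 4 * C), (8 * C, 2 * C), (4 * C, C), (2 * C, C)]
        self.enc = [Conv1d(a, b, 3, rng) for a, b in enc]
        self.dec = [Conv1d(a, b, 3, rng) for a, b in dec]
        self.head = Conv1d(C, 1, 1, rng)
        self.layers = self.enc + self.dec + [self.head]

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] % 16:
            raise ValueError("input length must be divisible by 16")
        cache = {"skips": [], "relu": []}
        h = x.astype(np.float32)
        for conv in self.enc:
            a = conv.forward(h)
            r = np.maximum(a, 0.0)
            cache["relu"].append(a > 0)
            cache["skips"].append(r)
            h = avgpool2(r)
        for conv, skip in zip(self.dec, reversed(cache["skips"])):
            u = upsample2(h)
            cat = np.concatenate([u, skip], axis=1)
            cache["relu"].append(None)  # placeholder alignment
            a = conv.forward(cat)
            cache["relu"][-1] = a > 0
            h = np.maximum(a, 0.0)
        # linear head: MSE heatmap regression trains poorly through a
        # saturating sigmoid (the sparse foreground gradient vanishes);
        # predictions are clipped to [0, 1] by the caller when needed.
        y = self.head.forward(h)
        if train:
            cache["out"] = y
            cache["up_channels"] = [c.W.shape[1] - s.shape[1]
                                    for c, s in zip(self.dec, reversed(cache["skips"]))]
            self._cache = cache
        return y

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        cache = self._cache
        grads_rev: list[np.ndarray] = []
        dh, g = self.head.backward(dy.astype(np.float32))
        grads_rev.extend(reversed(g))
        relu_masks = cache["relu"]
        for i in range(len(self.dec) - 1, -1, -1):
            conv = self.dec[i]
            mask = relu_masks[len(self.enc) + i]
            dcat, g = conv.backward(dh * mask)
            grads_rev.extend(reversed(g))
            n_up = cache["up_channels"][i]
            du, dskip = dcat[:, :n_up], dcat[:, n_up:]
            dh = upsample2_backward(du)
            # stash the skip gradient on the matching encoder level
            cache.setdefault("dskips", [None] * len(self.enc))
            cache["dskips"][len(self.enc) - 1 - i] = dskip
        for i in range(len(self.enc) - 1, -1, -1):
            conv = self.enc[i]
            dr = avgpool2_backward(dh) + cache["dskips"][i]
            dh, g = conv.backward(dr * relu_masks[i])
            grads_rev.extend(reversed(g))
        return list(reversed(grads_rev))
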