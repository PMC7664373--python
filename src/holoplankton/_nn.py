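"""A compact convolutional network in plain numpy.

Desk-scale backend for the classifier module: stacked 3x3 conv + ReLU +
2x2 max-pool blocks followed by a linear softmax head, trained with
mini-batch SGD (momentum + weight decay).  Deliberately small (~10^5
parameters) so that training from scratch on a single CPU core takes
minutes, not hours; the surrounding training protocol — not the network
size — is what the package exercises.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["TinyCNN", "SGDState", "softmax_cross_entropy"]


def _conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padding 3x3 convolution. x: (N,C,H,W), w: (F,C,3,3) -> (N,F,H,W)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))
    return np.einsum("nchwuv,fcuv->nfhw", win, w, optimize=True) + b[None, :, None, None]


def _conv3x3_backward(dout: np.ndarray, x: np.ndarray, w: np.ndarray):
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))
    dw = np.einsum("nfhw,nchwuv->fcuv", dout, win, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dp = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dwin = sliding_window_view(dp, (3, 3), axis=(2, 3))
    dx = np.einsum(
        "nfhwuv,fcuv->nchw", dwin, w[:, :, ::-1, ::-1], optimize=True
    )
    return dx, dw, db


def _pool2_forward(x: np.ndarray):
    n, c, h, w = x.shape
    r = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = r.max(axis=(3, 5))
    mask = r == out[:, :, :, None, :, None]
    return out, mask


def _pool2_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    counts = mask.sum(axis=(3, 5), keepdims=True)
    dr = mask * (dout[:, :, :, None, :, None] / counts)
    n, c, h2, _, w2, _ = dr.shape
    return dr.reshape(n, c, h2 * 2, w2 * 2)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(np.maximum(p[np.arange(n), labels], 1e-300)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n, p


class SGDState:
    """Momentum buffers for SGD, one per parameter."""

    def __init__(self, params: dict[str, np.ndarray]):
        self.velocity = {k: np.zeros_like(v) for k, v in params.items()}


class TinyCNN:
    """3-block 3x3-conv network with a linear softmax head.

    Input: (N, 1, H, W) gray images, H and W divisible by 8.
    """

    def __init__(
        self,
        n_classes: int,
        in_shape: tuple[int, int] = (32, 32),
        channels: tuple[int, ...] = (8, 16, 32),
        seed: int = 0,
    ):
        h, w = in_shape
        if h % (2 ** len(channels)) or w % (2 ** len(channels)):
            raise ValueError(
                f"input shape {in_shape} must be divisible by {2 ** len(channels)}"
            )
        self.n_classes = int(n_classes)
        self.in_shape = (int(h), int(w))
        self.channels = tuple(int(c) for c in channels)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for i, c_out in enumerate(self.channels):
            fan_in = c_in * 9
            self.params[f"w{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3)
            )
            self.params[f"b{i}"] = np.zeros(c_out)
            c_in = c_out
        feat = c_in * (h // 2 ** len(channels)) * (w // 2 ** len(channels))
        self.params["wfc"] = rng.normal(0.0, np.sqrt(2.0 / feat), size=(feat, n_classes))
        self.params["bfc"] = np.zeros(n_classes)

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def forward(self, x: np.ndarray, want_cache: bool = False):
        cache = []
        for i in range(len(self.channels)):
            pre = _conv3x3_forward(x, self.params[f"w{i}"], self.params[f"b{i}"])
            act = np.maximum(pre, 0.0)
            out, mask = _pool2_forward(act)
            if want_cache:
                cache.append((x, pre > 0, mask))
            x = out
        flat = x.reshape(x.shape[0], -1)
        logits = flat @ self.params["wfc"] + self.params["bfc"]
        if want_cache:
            return logits, (cache, x.shape, flat)
        return logits

    def loss_and_grads(self, x: np.ndarray, labels: np.ndarray):
        logits, (cache, pooled_shape, flat) = self.forward(x, want_cache=True)
        loss, dlogits, _ = softmax_cross_entropy(logits, labels)
        grads = {
            "wfc": flat.T @ dlogits,
            "bfc": dlogits.sum(axis=0),
        }
        dx = (dlogits @ self.params["wfc"].T).reshape(pooled_shape)
        for i in reversed(range(len(self.channels))):
            x_in, relu_mask, pool_mask = cache[i]
            dact = _pool2_backward(dx, pool_mask)
            dpre = dact * relu_mask
            dx, grads[f"w{i}"], grads[f"b{i}"] = _conv3x3_backward(
                dpre, x_in, self.params[f"w{i}"]
            )
        return loss, grads

    def sgd_step(
        self,
        grads: dict[str, np.ndarray],
        state: SGDState,
        lr: float,
        momentum: float,
        weight_decay: float,
    ) -> None:
        for k, p in self.params.items():
            g = grads[k] + weight_decay * p
            v = state.velocity[k]
            v *= momentum
            v -= lr * g
            p += v

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i : i + batch_size])
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()
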