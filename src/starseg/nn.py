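"""Minimal numpy encoder-decoder for desk-scale training of the losses.

A deliberately small U-shaped network (two 2x pooling levels, skip
connections, sigmoid head) with hand-written forward/backward passes and an
Adam optimizer.  The loss layer of the package supplies analytic gradients
with respect to the predicted probability map, so no autodiff framework is
needed; this module only has to backpropagate that per-pixel gradient
through the convolutions.  It is a test harness, not a segmentation model
for real images.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ToySegNet", "Adam"]


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """3x3 same-padding convolution; x (N,C,H,W), W (F,C,3,3) -> (N,F,H,W)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    out = np.tensordot(win, W, axes=([1, 4, 5], [1, 2, 3]))  # (N,H,W,F)
    out = np.transpose(out, (0, 3, 1, 2)) + b[None, :, None, None]
    return out, (x, win)


def _conv_backward(dout: np.ndarray, W: np.ndarray, cache):
    x, win = cache
    dW = np.tensordot(dout, win, axes=([0, 2, 3], [0, 2, 3]))  # (F,C,3,3)
    db = dout.sum(axis=(0, 2, 3))
    dp = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dwin = sliding_window_view(dp, (3, 3), axis=(2, 3))  # (N,F,H,W,3,3)
    Wf = W[:, :, ::-1, ::-1]
    dx = np.tensordot(dwin, Wf, axes=([1, 4, 5], [0, 2, 3]))  # (N,H,W,C)
    return np.transpose(dx, (0, 3, 1, 2)), dW, db


def _pool_forward(x: np.ndarray):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    return flat.max(axis=-1), (idx, x.shape)


def _pool_backward(dout: np.ndarray, cache):
    idx, shape = cache
    n, c, h, w = shape
    dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
    dxr = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dxr.reshape(n, c, h, w)


def _up2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _up2_backward(dout: np.ndarray) -> np.ndarray:
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ToySegNet:
    """Two-level encoder-decoder with skip connections and a sigmoid head."""

    ENCODER = ("c1", "c2", "c3")

    def __init__(self, seed: int = 0, width: int = 4):
        rng = np.random.default_rng(seed)
        w = width

        def he(f, c, k):
            W = rng.normal(0.0, np.sqrt(2.0 / (c * k * k)), (f, c, k, k))
            return W, np.zeros(f)

        self.params = {}
        for name, (f, c, k) in {
            "c1": (w, 1, 3), "c2": (2 * w, w, 3), "c3": (2 * w, 2 * w, 3),
            "d2": (w, 4 * w, 3), "d1": (w, 2 * w, 3), "out": (1, w, 1),
        }.items():
            W, b = he(f, c, k)
            self.params[f"{name}_W"] = W
            self.params[f"{name}_b"] = b
        self.width = w

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, want_cache: bool = True):
        """x: (N,1,H,W) with H, W divisible by 4 -> probabilities (N,1,H,W)."""
        p = self.params
        caches = {}

        def conv(name, inp):
            out, cache = _conv_forward(inp, p[f"{name}_W"], p[f"{name}_b"])
            relu = out > 0
            caches[name] = (cache, relu)
            return out * relu

        e1 = conv("c1", x)
        p1, caches["pool1"] = _pool_forward(e1)
        e2 = conv("c2", p1)
        p2, caches["pool2"] = _pool_forward(e2)
        bott = conv("c3", p2)
        k2 = np.concatenate([_up2(bott), e2], axis=1)
        d2 = conv("d2", k2)
        k1 = np.concatenate([_up2(d2), e1], axis=1)
        d1 = conv("d1", k1)
        logit, out_cache = self._head(d1)
        caches["out"] = out_cache
        prob = 1.0 / (1.0 + np.exp(-logit))
        if not want_cache:
            return prob, None
        caches["prob"] = prob
        return prob, caches

    def _head(self, d1: np.ndarray):
        W = self.params["out_W"][:, :, 0, 0]  # (1, w)
        logit = np.tensordot(d1, W, axes=([1], [1])).transpose(0, 3, 1, 2)
        return logit + self.params["out_b"][None, :, None, None], d1

    # -- backward ----------------------------------------------------------
    def backward(self, dprob: np.ndarray, caches) -> dict[str, np.ndarray]:
        """Gradient of the loss w.r.t. all parameters given dL/dP."""
        p = self.params
        prob = caches["prob"]
        dlogit = dprob * prob * (1.0 - prob)
        grads = {}

        d1 = caches["out"]
        W = p["out_W"][:, :, 0, 0]
        grads["out_W"] = np.tensordot(dlogit, d1, axes=([0, 2, 3], [0, 2, 3]))[:, :, None, None]
        grads["out_b"] = dlogit.sum(axis=(0, 2, 3))
        dd1 = np.tensordot(dlogit, W, axes=([1], [0])).transpose(0, 3, 1, 2)

        def dconv(name, dout):
            cache, relu = caches[name]
            dout = dout * relu
            dx, dW, db = _conv_backward(dout, p[f"{name}_W"], cache)
            grads[f"{name}_W"] = dW
            grads[f"{name}_b"] = db
            return dx

        dk1 = dconv("d1", dd1)
        w = self.width
        dd2 = _up2_backward(dk1[:, :w])
        de1_skip = dk1[:, w:]
        dk2 = dconv("d2", dd2)
        dbott = _up2_backward(dk2[:, : 2 * w])
        de2_skip = dk2[:, 2 * w:]
        dp2 = dconv("c3", dbott)
        de2 = _pool_backward(dp2, caches["pool2"]) + de2_skip
        dp1 = dconv("c2", de2)
        de1 = _pool_backward(dp1, caches["pool1"]) + de1_skip
        dconv("c1", de1)
        return grads


class Adam:
    """Standard Adam over a parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, frozen: set[str] = frozenset()):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            if any(k.startswith(f) for f in frozen):
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
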