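"""Minimal convolutional network with Adam, in numpy.

Implements exactly what the metabolic estimator needs: stride-1 "same"
3x3 convolutions (im2col), ReLU, 2x2 max-pooling, dense layers, a
softplus output head and the Adam optimizer, with full backpropagation.
Sized for spectrogram inputs of a few hundred pixels, where CPU training
takes seconds to minutes.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["CNNRegressorNet", "Adam"]


def _conv2d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """x: (B, C, H, W); w: (F, C, 3, 3) -> (B, F, H, W), zero padding 1."""
    B, C, H, W = x.shape
    F = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    patches = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B,C,H,W,3,3)
    cols = patches.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * 9)
    out = cols @ w.reshape(F, C * 9).T  # (B, H*W, F)
    if b is not None:
        out = out + b
    return out.transpose(0, 2, 1).reshape(B, F, H, W), cols


def _conv2d_same_grad_w(cols: np.ndarray, dout: np.ndarray, shape) -> np.ndarray:
    """cols from forward; dout: (B, F, H, W) -> dW (F, C, 3, 3)."""
    F, C = shape
    B = dout.shape[0]
    d = dout.reshape(B, F, -1)  # (B, F, HW)
    dw = np.einsum("bfp,bpk->fk", d, cols)
    return dw.reshape(F, C, 3, 3)


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class Adam:
    """Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CNNRegressorNet:
    """Per-channel conv trunks -> concat -> dense -> softplus scalar.

    Each input channel passes through its own two conv blocks (3x3
    filters, ReLU, 2x2 max-pool); the flattened trunk outputs are
    concatenated and mapped through one hidden dense layer to a scalar
    whose softplus keeps predictions non-negative.
    """

    def __init__(self, n_channels: int, height: int, width: int,
                 f1: int = 8, f2: int = 16, hidden: int = 64,
                 seed: int = 0, out_bias: float = 0.0):
        self.n_channels = n_channels
        self.f1, self.f2, self.hidden = f1, f2, hidden
        h1, w1 = height // 2, width // 2
        h2, w2 = h1 // 2, w1 // 2
        self.trunk_dim = f2 * h2 * w2
        rng = np.random.default_rng(seed)
        p = {}
        for c in range(n_channels):
            p[f"w1_{c}"] = rng.normal(0, np.sqrt(2.0 / 9), (f1, 1, 3, 3))
            p[f"b1_{c}"] = np.zeros(f1)
            p[f"w2_{c}"] = rng.normal(0, np.sqrt(2.0 / (9 * f1)), (f2, f1, 3, 3))
            p[f"b2_{c}"] = np.zeros(f2)
        cat = self.trunk_dim * n_channels
        p["wd"] = rng.normal(0, np.sqrt(2.0 / cat), (hidden, cat))
        p["bd"] = np.zeros(hidden)
        # zero output weights: predictions start exactly at
        # softplus(out_bias), typically initialized to the target mean
        p["wo"] = np.zeros((1, hidden))
        p["bo"] = np.full(1, out_bias)
        self.params = p

    # -- pooling helpers ---------------------------------------------------
    @staticmethod
    def _pool(x: np.ndarray):
        B, F, H, W = x.shape
        H2, W2 = H // 2, W // 2
        xc = x[:, :, : H2 * 2, : W2 * 2]
        r = xc.reshape(B, F, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(B, F, H2, W2, 4)
        idx = np.argmax(r, axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        return out, (idx, x.shape)

    @staticmethod
    def _pool_back(dout: np.ndarray, cache) -> np.ndarray:
        idx, shape = cache
        B, F, H, W = shape
        H2, W2 = H // 2, W // 2
        dr = np.zeros((B, F, H2, W2, 4))
        np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
        dr = dr.reshape(B, F, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(shape)
        dx[:, :, : H2 * 2, : W2 * 2] = dr.reshape(B, F, H2 * 2, W2 * 2)
        return dx

    # -- forward / backward -------------------------------------------------
    def forward(self, X: np.ndarray, cache: bool = False):
        """X: (B, n_channels, H, W) -> predictions (B,)."""
        p = self.params
        feats, caches = [], []
        for c in range(self.n_channels):
            xc = X[:, c : c + 1]
            z1, cols1 = _conv2d_same(xc, p[f"w1_{c}"], p[f"b1_{c}"])
            a1 = np.maximum(z1, 0)
            p1, pc1 = self._pool(a1)
            z2, cols2 = _conv2d_same(p1, p[f"w2_{c}"], p[f"b2_{c}"])
            a2 = np.maximum(z2, 0)
            p2, pc2 = self._pool(a2)
            feats.append(p2.reshape(X.shape[0], -1))
            caches.append((cols1, z1, pc1, p1, cols2, z2, pc2, p2.shape))
        h_in = np.concatenate(feats, axis=1)
        zd = h_in @ p["wd"].T + p["bd"]
        ad = np.maximum(zd, 0)
        zo = (ad @ p["wo"].T + p["bo"]).ravel()
        yhat = _softplus(zo)
        if not cache:
            return yhat
        return yhat, (X, caches, h_in, zd, ad, zo)

    def backward(self, cache, dyhat: np.ndarray) -> dict:
        p = self.params
        X, caches, h_in, zd, ad, zo = cache
        g = {}
        dzo = dyhat * _sigmoid(zo)  # softplus'
        g["wo"] = dzo[None, :] @ ad
        g["bo"] = np.array([dzo.sum()])
        dad = np.outer(dzo, p["wo"].ravel())
        dzd = dad * (zd > 0)
        g["wd"] = dzd.T @ h_in
        g["bd"] = dzd.sum(axis=0)
        dh = dzd @ p["wd"]
        td = self.trunk_dim
        for c in range(self.n_channels):
            cols1, z1, pc1, p1, cols2, z2, pc2, p2shape = caches[c]
            dp2 = dh[:, c * td : (c + 1) * td].reshape(p2shape)
            da2 = self._pool_back(dp2, pc2)
            dz2 = da2 * (z2 > 0)
            g[f"w2_{c}"] = _conv2d_same_grad_w(cols2, dz2, (self.f2, self.f1))
            g[f"b2_{c}"] = dz2.sum(axis=(0, 2, 3))
            # grad wrt conv2 input: convolve dz2 with spatially flipped,
            # channel-transposed weights (stride-1 same-padding identity)
            w2 = p[f"w2_{c}"]
            w2_t = w2.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
            dp1, _ = _conv2d_same(dz2, w2_t, None)
            da1 = self._pool_back(dp1, pc1)
            dz1 = da1 * (z1 > 0)
            g[f"w1_{c}"] = _conv2d_same_grad_w(cols1, dz1, (self.f1, 1))
            g[f"b1_{c}"] = dz1.sum(axis=(0, 2, 3))
        return g

    def train(
        self,
        X: np.ndarray,
        y: np.ndarray,
        lr: float = 1e-3,
        epochs: int = 40,
        batch_size: int = 32,
        seed: int = 0,
    ) -> list[float]:
        """Minibatch Adam on mean-squared error; returns the loss curve."""
        rng = np.random.default_rng(seed)
        opt = Adam(self.params, lr=lr)
        n = len(y)
        curve = []
        for _ in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, batch_size):
                sel = order[start : start + batch_size]
                yhat, cache = self.forward(X[sel], cache=True)
                err = yhat - y[sel]
                total += float(np.sum(err**2))
                dyhat = 2.0 * err / len(sel)
                grads = self.backward(cache, dyhat)
                opt.step(self.params, grads)
            curve.append(total / n)
        return curve
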