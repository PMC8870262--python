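"""Minimal CPU neural-network layers with explicit forward/backward passes.

Everything runs in float32 on NumPy. Convolutions use im2col plus a single
BLAS matmul; each layer caches what its backward pass needs during a
training-mode forward call. Inference-mode forwards cache nothing.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    """Base class: a named container of parameters and their gradients."""

    name: str = ""

    def parameters(self) -> dict[str, np.ndarray]:
        return {}

    def gradients(self) -> dict[str, np.ndarray]:
        return {}

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state (e.g. batch-norm running statistics)."""
        return {}

    def zero_grad(self) -> None:
        for g in self.gradients().values():
            g[...] = 0.0


class Conv2d(Layer):
    """2D convolution, stride 1, zero padding (default: 'same' for odd kernels)."""

    def __init__(self, cin: int, cout: int, k: int = 3, pad: int | None = None,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2 if pad is None else pad
        self.name = name
        rng = rng or np.random.default_rng(0)
        # He-normal fan-in init, suited to ReLU networks
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((cout, cin, k, k)) * scale).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def parameters(self):
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def gradients(self):
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"{self.name}: expected {self.cin} channels, got {C}")
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        Ho, Wo = xp.shape[2] - k + 1, xp.shape[3] - k + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,Ho,Wo,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B, Ho * Wo, C * k * k)
        Wmat = self.W.reshape(self.cout, C * k * k)
        out = cols @ Wmat.T + self.b
        out = out.transpose(0, 2, 1).reshape(B, self.cout, Ho, Wo)
        if train:
            self._cache = (cols, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        B, C, H, W = xshape
        k, p = self.k, self.pad
        Ho, Wo = dout.shape[2], dout.shape[3]
        dmat = dout.reshape(B, self.cout, Ho * Wo).transpose(0, 2, 1)  # (B,HW,cout)
        Wmat = self.W.reshape(self.cout, C * k * k)
        self.dW += np.einsum("bpo,bpc->oc", dmat, cols,
                             optimize=True).reshape(self.W.shape)
        self.db += dout.sum(axis=(0, 2, 3))
        dcols = (dmat.reshape(B * Ho * Wo, self.cout) @ Wmat).reshape(
            B, Ho, Wo, C, k, k)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=DTYPE)
        for a in range(k):
            for c in range(k):
                dxp[:, :, a:a + Ho, c:c + Wo] += dcols[:, :, :, :, a, c].transpose(
                    0, 3, 1, 2)
        self._cache = None
        return dxp[:, :, p:H + p, p:W + p] if p else dxp


class ConvTranspose2d(Layer):
    """Transposed convolution with 2x2 kernel and stride 2 (doubles H and W)."""

    def __init__(self, cin: int, cout: int,
                 rng: np.random.Generator | None = None, name: str = "tconv"):
        self.cin, self.cout = cin, cout
        self.name = name
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / cin)
        self.W = (rng.standard_normal((cin, cout, 2, 2)) * scale).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def parameters(self):
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def gradients(self):
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        t = np.tensordot(x, self.W, axes=([1], [0]))  # (B,H,W,cout,2,2)
        out = t.transpose(0, 3, 1, 4, 2, 5).reshape(B, self.cout, 2 * H, 2 * W)
        out += self.b[None, :, None, None]
        if train:
            self._cache = x
        return np.ascontiguousarray(out, dtype=DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        B, C, H, W = x.shape
        dt = dout.reshape(B, self.cout, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5)
        self.dW += np.einsum("bchw,bhwdps->cdps", x, dt, optimize=True)
        self.db += dout.sum(axis=(0, 2, 3))
        dx = np.tensordot(dt, self.W, axes=([3, 4, 5], [1, 2, 3]))  # (B,H,W,cin)
        self._cache = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2), dtype=DTYPE)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.name = name
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self._cache = None

    def parameters(self):
        return {f"{self.name}.gamma": self.gamma, f"{self.name}.beta": self.beta}

    def gradients(self):
        return {f"{self.name}.gamma": self.dgamma, f"{self.name}.beta": self.dbeta}

    def buffers(self):
        return {f"{self.name}.running_mean": self.running_mean,
                f"{self.name}.running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[...] = ((1 - self.momentum) * self.running_mean
                                      + self.momentum * mean)
            self.running_var[...] = ((1 - self.momentum) * self.running_var
                                     + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        out = self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]
        if train:
            self._cache = (xhat, invstd)
        return out.astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        N = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma += (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dout.sum(axis=(0, 2, 3))
        dxh = dout * self.gamma[None, :, None, None]
        s1 = dxh.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxh * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (invstd[None, :, None, None] / N) * (N * dxh - s1 - xhat * s2)
        self._cache = None
        return dx.astype(DTYPE)


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; H and W must be even."""

    def __init__(self, name: str = "pool"):
        self.name = name
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(B, C, H // 2, W // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (B, C, H, W) = self._cache
        d4 = np.zeros((B, C, H // 2, W // 2, 4), dtype=DTYPE)
        np.put_along_axis(d4, idx[..., None], dout[..., None], axis=-1)
        dx = d4.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return np.ascontiguousarray(dx.reshape(B, C, H, W))


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in params.items():
            g = grads[k]
            if k not in self.m:
                self.m[k] = np.zeros_like(p)
                self.v[k] = np.zeros_like(p)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": {k: v.copy() for k, v in self.m.items()},
                "v": {k: v.copy() for k, v in self.v.items()}}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = {k: np.asarray(v).copy() for k, v in state["m"].items()}
        self.v = {k: np.asarray(v).copy() for k, v in state["v"].items()}
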