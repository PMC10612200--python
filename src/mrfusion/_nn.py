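"""Compact reverse-mode neural-network layers on numpy.

Just enough machinery for the two small architectures in this package: the
feature-matrix attention net and the shallow SE-CNN.  Layers expose
``forward(x, train)`` and ``backward(grad_out)``; a :class:`Sequential`
runs them in order, caches every intermediate activation by layer name
(which is what Grad-CAM consumes) and returns parameter gradients for the
Adam optimizer.  Parameters and activations are float32 and fully
deterministic for a fixed numpy ``Generator``.
"""

from __future__ import annotations

import numpy as np

# float32 keeps the conv nets fast and deterministic; statistics that need
# float64 (AUCs, losses) are accumulated outside the layer stack
DTYPE = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    name: str = ""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Fully connected layer on flattened input."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "fc"):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.name = name

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train):
        self._shape = x.shape
        self._x = x.reshape(x.shape[0], -1)
        return self._x @ self.W + self.b

    def backward(self, g):
        self.gW[...] = self._x.T @ g
        self.gb[...] = g.sum(axis=0)
        return (g @ self.W.T).reshape(self._shape)


class Conv2d(Layer):
    """2D convolution (stride 1, 'valid' unless padded) via im2col + matmul."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kh: int,
        kw: int,
        rng: np.random.Generator,
        pad: int = 0,
        name: str = "conv",
    ):
        fan_in = c_in * kh * kw
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kh, kw)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.kh, self.kw, self.pad = kh, kw, pad
        self.skip_input_grad = False  # set on a first layer whose upstream has no params
        self.name = name

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def _im2col(self, x):
        n, c, h, w = x.shape
        kh, kw = self.kh, self.kw
        oh, ow = h - kh + 1, w - kw + 1
        s = x.strides
        windows = np.lib.stride_tricks.as_strided(
            x, shape=(n, c, oh, ow, kh, kw), strides=(s[0], s[1], s[2], s[3], s[2], s[3])
        )
        return windows.reshape(n, c, oh * ow, kh * kw), oh, ow

    def forward(self, x, train):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        self._x = x
        n, c, h, w = x.shape
        cols, oh, ow = self._im2col(x)
        # one GEMM: (n*oh*ow, c*kh*kw) @ (c*kh*kw, c_out)
        cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(n * oh * ow, -1)
        self._cols2 = cols2
        Wf = self.W.reshape(self.W.shape[0], -1).T
        out = cols2 @ Wf + self.b
        self._oh, self._ow = oh, ow
        return out.reshape(n, oh * ow, -1).transpose(0, 2, 1).reshape(n, -1, oh, ow)

    def backward(self, g):
        n, c_out, oh, ow = g.shape
        gf = np.ascontiguousarray(
            g.reshape(n, c_out, oh * ow).transpose(0, 2, 1)
        ).reshape(n * oh * ow, c_out)
        self.gb[...] = gf.sum(axis=0)
        self.gW[...] = (self._cols2.T @ gf).T.reshape(self.W.shape)
        if self.skip_input_grad:
            return np.zeros_like(self._x) if not self.pad else np.zeros(
                (n, self._x.shape[1], self._x.shape[2] - 2 * self.pad,
                 self._x.shape[3] - 2 * self.pad), dtype=g.dtype)
        # input grad as a full correlation of g with the flipped kernel
        # (stride 1): one channels-last GEMM per kernel offset
        kh, kw = self.kh, self.kw
        h_in, w_in = self._x.shape[2], self._x.shape[3]
        c_in = self._x.shape[1]
        gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
        gpt = np.ascontiguousarray(gp.transpose(0, 2, 3, 1))  # n, H, W, c_out
        gx = np.zeros((n, h_in, w_in, c_in), dtype=g.dtype)
        for i in range(kh):
            for j in range(kw):
                win = gpt[:, kh - 1 - i : kh - 1 - i + h_in, kw - 1 - j : kw - 1 - j + w_in, :]
                gx += win.reshape(-1, c_out).dot(self.W[:, :, i, j]).reshape(gx.shape)
        gx = gx.transpose(0, 3, 1, 2)
        if self.pad:
            gx = gx[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return np.ascontiguousarray(gx)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.ggamma = np.zeros(c, dtype=DTYPE)
        self.gbeta = np.zeros(c, dtype=DTYPE)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self.name = name

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            xhat = x - mean[None, :, None, None]
            var = np.mean(xhat * xhat, axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat *= inv_std[None, :, None, None]
        else:
            mean, var = self.running_mean, self.running_var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._inv_std = inv_std
        self._xhat = xhat
        self._train = train
        out = xhat * self.gamma[None, :, None, None]
        out += self.beta[None, :, None, None]
        return out

    def backward(self, g):
        self.ggamma[...] = (g * self._xhat).sum(axis=(0, 2, 3))
        self.gbeta[...] = g.sum(axis=(0, 2, 3))
        gxhat = g * self.gamma[None, :, None, None]
        scale = self._inv_std[None, :, None, None]
        if not self._train:
            gxhat *= scale
            return gxhat
        m = g.shape[0] * g.shape[2] * g.shape[3]
        gxhat -= self.gbeta[None, :, None, None] * (self.gamma[None, :, None, None] / m)
        gxhat -= self._xhat * (self.ggamma * self.gamma / m)[None, :, None, None]
        gxhat *= scale
        return gxhat


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name

    def forward(self, x, train):
        self._m = x > 0
        return np.maximum(x, 0)

    def backward(self, g):
        g = g * self._m
        return g


class MaxPool2x2(Layer):
    def __init__(self, name: str = "pool"):
        self.name = name

    def forward(self, x, train):
        n, c, h, w = x.shape
        xv = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xv.max(axis=(3, 5))
        self._mask = xv == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, g):
        n, c, h, w = self._shape
        gv = self._mask * g[:, :, :, None, :, None]
        # split gradient between tied maxima to keep backward exact
        counts = self._mask.sum(axis=(3, 5), keepdims=True)
        return (gv / counts).reshape(n, c, h, w)


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class SEBlock(Layer):
    """Squeeze-and-excitation channel gate.

    ``out[c] = s_c * x[c]`` with ``s = sigmoid(W2 relu(W1 avgpool(x) + b1) + b2)``
    and hidden width ``C / r``.  ``force_gate`` pins every gate to a
    constant (1.0 reproduces the attention-free network exactly), used for
    ablation checks.  The most recent per-sample gates are kept on
    ``last_gates`` for inspection.
    """

    def __init__(self, c: int, r: int, rng: np.random.Generator, name: str = "se"):
        if r > c:
            raise ValueError(f"SE reduction r={r} exceeds channel count C={c}")
        hidden = max(1, c // r)
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / c), size=(c, hidden)).astype(DTYPE)
        self.b1 = np.zeros(hidden, dtype=DTYPE)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / hidden), size=(hidden, c)).astype(DTYPE)
        self.b2 = np.zeros(c, dtype=DTYPE)
        self.gW1 = np.zeros_like(self.W1)
        self.gb1 = np.zeros_like(self.b1)
        self.gW2 = np.zeros_like(self.W2)
        self.gb2 = np.zeros_like(self.b2)
        self.force_gate: float | None = None
        self.last_gates: np.ndarray | None = None
        self.name = name

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def grads(self):
        return [self.gW1, self.gb1, self.gW2, self.gb2]

    def forward(self, x, train):
        self._x = x
        if self.force_gate is not None:
            self._forced = True
            self.last_gates = np.full((x.shape[0], x.shape[1]), self.force_gate)
            return x * self.force_gate
        self._forced = False
        z = x.mean(axis=(2, 3))  # squeeze: n, C
        self._z = z
        h = z @ self.W1 + self.b1
        self._hm = h > 0
        hr = h * self._hm
        self._hr = hr
        s = sigmoid(hr @ self.W2 + self.b2)
        self._s = s
        self.last_gates = s
        return x * s[:, :, None, None]

    def backward(self, g):
        if self._forced:
            return g * self.force_gate
        x, s = self._x, self._s
        gs = (g * x).sum(axis=(2, 3))  # n, C
        gx_direct = g * s[:, :, None, None]
        glogit = gs * s * (1 - s)
        self.gW2[...] = self._hr.T @ glogit
        self.gb2[...] = glogit.sum(axis=0)
        gh = (glogit @ self.W2.T) * self._hm
        self.gW1[...] = self._z.T @ gh
        self.gb1[...] = gh.sum(axis=0)
        gz = gh @ self.W1.T  # n, C
        hw = x.shape[2] * x.shape[3]
        gx_pool = gz[:, :, None, None] / hw
        return gx_direct + gx_pool


class Sequential:
    """Ordered named layers with activation caching for Grad-CAM."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        names = [l.name for l in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        self.activations: dict[str, np.ndarray] = {}
        self.activation_grads: dict[str, np.ndarray] = {}

    def layer(self, name: str) -> Layer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(f"no layer named {name!r}")

    def forward(self, x: np.ndarray, train: bool = False, cache: bool = False) -> np.ndarray:
        if cache:
            self.activations = {"input": x}
        for l in self.layers:
            x = l.forward(x, train)
            if cache:
                self.activations[l.name] = x
        return x

    def backward(self, g: np.ndarray, cache: bool = False) -> np.ndarray:
        if cache:
            self.activation_grads = {}
        for l in reversed(self.layers):
            if cache:
                self.activation_grads[l.name] = g
            g = l.backward(g)
        if cache:
            self.activation_grads["input"] = g
        return g

    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
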