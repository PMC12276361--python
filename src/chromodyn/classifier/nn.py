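"""Minimal CPU neural-network framework (numpy, float32, fully seeded).

Implements exactly the pieces the trajectory classifier needs: stride-1
'same' convolution via im2col + BLAS matmul, 2x2 max pooling, batch
normalization, ReLU, adaptive max pooling, a dense head, softmax
cross-entropy and Adam. Everything is deterministic given the seed.

Activations use the channels-last (N, H, W, C) layout throughout: im2col
then reduces to contiguous block copies and the whole forward/backward
pass is BLAS-bound, which is what makes scaled-down training runs
tractable on a single CPU core.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _fft


class Layer:
    """Base class; layers with parameters expose ``params`` as a list of
    dicts with keys w (array), grad (array)."""

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 'same' convolution, kernel k x k, via im2col.

    Even kernels pad asymmetrically ((k-1)//2 before, k//2 after), so the
    output spatial size always equals the input size. Weights use He
    initialization; the weight matrix has layout (k*k*C_in, C_out) matching
    the im2col column order (kernel position major, channel minor).

    Two mathematically identical engines: im2col + matmul, and an FFT
    (circular-embedding) path used automatically for large kernels on
    large feature maps, where it cuts both FLOPs and cache memory by an
    order of magnitude. ``engine`` may force "im2col" or "fft".
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 first_layer: bool = False, engine: str = "auto"):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.first_layer = first_layer  # input gradient not needed
        self.engine = engine
        fan_in = in_ch * k * k
        self.w = (rng.standard_normal((fan_in, out_ch)) *
                  np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.params = [{"w": self.w, "grad": self.dw},
                       {"w": self.b, "grad": self.db}]
        self._buffers: dict = {}

    def _buffer(self, name: str, shape: tuple) -> np.ndarray:
        """Persistent scratch arrays: repeated large allocations would be
        dominated by page faults, so buffers are reused across steps."""
        buf = self._buffers.get(name)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=np.float32)
            self._buffers[name] = buf
        return buf

    def _im2col(self, xp: np.ndarray, h: int, w_: int) -> np.ndarray:
        # row-wise gather: for a fixed vertical kernel offset i, the k*c
        # values under the kernel row are contiguous in memory, so each of
        # the k copies below moves long runs instead of per-pixel scraps
        n = xp.shape[0]
        c, k = self.in_ch, self.k
        kc = k * c
        cols = self._buffer("cols", (n, h, w_, k * kc))
        s0, s1, s2, s3 = xp.strides
        for i in range(k):
            rows = np.lib.stride_tricks.as_strided(
                xp[:, i:, :, :], shape=(n, h, w_, kc),
                strides=(s0, s1, s2, s3), writeable=False)
            cols[:, :, :, i * kc:(i + 1) * kc] = rows
        return cols.reshape(n * h * w_, k * kc)

    def _use_fft(self, h: int) -> bool:
        if self.engine != "auto":
            return self.engine == "fft"
        # benchmarked on this architecture: BLAS im2col edges out the FFT
        # path at batch 16 (both are exact; "fft" remains selectable)
        return False

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if self._use_fft(x.shape[1]):
            return self._forward_fft(x, train)
        n, h, w_, c = x.shape
        k = self.k
        p0, p1 = (k - 1) // 2, k // 2
        xp = self._buffer("xp", (n, h + p0 + p1, w_ + p0 + p1, c))
        xp[:] = 0.0
        xp[:, p0:p0 + h, p0:p0 + w_, :] = x
        cols = self._im2col(xp, h, w_)
        self._cache = ("im2col", cols, (n, h, w_, c)) if train else (None, None)
        out = self._buffer("out", (n * h * w_, self.out_ch))
        np.matmul(cols, self.w, out=out)
        out += self.b
        return out.reshape(n, h, w_, self.out_ch)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cache[0] == "fft":
            return self._backward_fft(dout)
        _, cols, (n, h, w_, c) = self._cache
        k = self.k
        dm = np.ascontiguousarray(dout).reshape(-1, self.out_ch)
        self.db[...] = dm.sum(axis=0)
        np.matmul(cols.T, dm, out=self.dw)
        if self.first_layer:
            self._cache = None
            return None
        dcols = self._buffer("dcols", (n * h * w_, k * k * c))
        np.matmul(dm, self.w.T, out=dcols)
        dcols = dcols.reshape(n, h, w_, k * k * c)
        p0, p1 = (k - 1) // 2, k // 2
        dxp = self._buffer("dxp", (n, h + p0 + p1, w_ + p0 + p1, c))
        dxp[:] = 0.0
        for i in range(k):
            for j in range(k):
                idx = (i * k + j) * c
                dxp[:, i:i + h, j:j + w_, :] += dcols[:, :, :, idx:idx + c]
        self._cache = None
        return dxp[:, p0:p0 + h, p0:p0 + w_, :]

    # -- FFT engine -------------------------------------------------------
    # 'same' correlation with asymmetric zero padding embeds exactly in a
    # circular correlation of period S >= H + k - 1: the end padding
    # supplies the zeros and a phase multiply realigns the output (a roll
    # in real space). All three products (forward, input gradient, weight
    # gradient) are per-frequency batched complex matmuls over channels,
    # carried out in a frequency-major (P, ., .) layout.

    def _kernel(self) -> np.ndarray:
        """Stored (k*k*c, f) matrix viewed as (f, c, k, k)."""
        k, c = self.k, self.in_ch
        return self.w.reshape(k, k, c, self.out_ch).transpose(3, 2, 0, 1)

    def _fft_setup(self, h: int, w_: int):
        k = self.k
        p0 = (k - 1) // 2
        s1 = _fft.next_fast_len(h + k - 1, real=True)
        s2 = _fft.next_fast_len(w_ + k - 1, real=True)
        key = (s1, s2)
        if self._buffers.get("fft_key") != key:
            x1 = np.arange(s1)
            x2 = np.arange(s2 // 2 + 1)
            ph1 = np.exp(-2j * np.pi * p0 * x1 / s1)
            ph2 = np.exp(-2j * np.pi * p0 * x2 / s2)
            self._buffers["phase"] = (ph1[:, None] * ph2[None, :]).astype(np.complex64)
            self._buffers["fft_key"] = key
        return s1, s2, self._buffers["phase"]

    @staticmethod
    def _to_freq_major(a: np.ndarray) -> np.ndarray:
        """(A, B, s1, s2r) complex -> contiguous (P, A, B)."""
        na, nb = a.shape[0], a.shape[1]
        return np.ascontiguousarray(a.reshape(na, nb, -1).transpose(2, 0, 1))

    def _forward_fft(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w_, c = x.shape
        k = self.k
        s1, s2, phase = self._fft_setup(h, w_)
        s2r = s2 // 2 + 1
        xt = np.ascontiguousarray(x.transpose(0, 3, 1, 2))
        xf = self._to_freq_major(_fft.rfft2(xt, s=(s1, s2)))   # (P, n, c)
        wf = self._to_freq_major(
            np.conj(_fft.rfft2(self._kernel(), s=(s1, s2))
                    ).transpose(1, 0, 2, 3))                   # (P, c, f)
        yf = np.matmul(xf, wf)                                 # (P, n, f)
        # phase multiply realigns the asymmetric padding (roll by p0)
        yf *= phase.reshape(-1, 1, 1)
        yf = yf.transpose(1, 2, 0).reshape(n, self.out_ch, s1, s2r)
        y = _fft.irfft2(yf, s=(s1, s2))[:, :, :h, :w_]
        self._cache = ("fft", xf, wf, (n, h, w_, c)) if train else (None,)
        out = np.ascontiguousarray(y.transpose(0, 2, 3, 1))
        out += self.b
        return out

    def _backward_fft(self, dout: np.ndarray) -> np.ndarray:
        _, xf, wf, (n, h, w_, c) = self._cache
        k = self.k
        s1, s2, phase = self._fft_setup(h, w_)
        s2r = s2 // 2 + 1
        f = self.out_ch
        self.db[...] = dout.sum(axis=(0, 1, 2))
        dyp = self._buffer("dyp", (n, f, s1, s2))
        dyp[:] = 0.0
        dyp[:, :, :h, :w_] = dout.transpose(0, 3, 1, 2)
        dyf = self._to_freq_major(_fft.rfft2(dyp))             # (P, n, f)
        # weight gradient: (P, c, f) = xf^T conj(dyf), rolled by p0
        gf = np.matmul(xf.conj().transpose(0, 2, 1), dyf).conj()
        gf *= phase.reshape(-1, 1, 1)
        gf = gf.transpose(1, 2, 0).reshape(c, f, s1, s2r)
        g = _fft.irfft2(gf, s=(s1, s2))[:, :, :k, :k]          # (c, f, k, k)
        self.dw[...] = np.ascontiguousarray(
            g.transpose(2, 3, 0, 1)).reshape(k * k * c, f)
        self._cache = None
        if self.first_layer:
            return None
        # input gradient: convolution with the kernel = conj(wf) spectrum,
        # shifted by -p0 (the conjugate phase)
        dxf = np.matmul(dyf, np.conj(wf.transpose(0, 2, 1)))   # (P, n, c)
        dxf *= np.conj(phase).reshape(-1, 1, 1)
        dxf = dxf.transpose(1, 2, 0).reshape(n, c, s1, s2r)
        dx = _fft.irfft2(dxf, s=(s1, s2))[:, :, :h, :w_]
        return np.ascontiguousarray(dx.transpose(0, 2, 3, 1))


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (input spatial size must be even)."""

    def __init__(self) -> None:
        self._buffers: dict = {}

    def _buffer(self, name: str, shape: tuple, dtype=np.float32) -> np.ndarray:
        buf = self._buffers.get(name)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=dtype)
            self._buffers[name] = buf
        return buf

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w_, c = x.shape
        v = self._buffer("v", (n, h // 2, w_ // 2, c, 4))
        src = x.reshape(n, h // 2, 2, w_ // 2, 2, c)
        v[..., 0] = src[:, :, 0, :, 0, :]
        v[..., 1] = src[:, :, 0, :, 1, :]
        v[..., 2] = src[:, :, 1, :, 0, :]
        v[..., 3] = src[:, :, 1, :, 1, :]
        idx = np.argmax(v, axis=-1)
        if train:
            self._idx = idx.astype(np.int8)
            self._shape = (n, h, w_, c)
        return np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w_, c = self._shape
        dv = self._buffer("dv", (n, h // 2, w_ // 2, c, 4))
        dv[:] = 0.0
        np.put_along_axis(dv, self._idx[..., None].astype(np.intp),
                          dout[..., None], axis=-1)
        dx = self._buffer("dx", (n, h, w_, c))
        dst = dx.reshape(n, h // 2, 2, w_ // 2, 2, c)
        dst[:, :, 0, :, 0, :] = dv[..., 0]
        dst[:, :, 0, :, 1, :] = dv[..., 1]
        dst[:, :, 1, :, 0, :] = dv[..., 2]
        dst[:, :, 1, :, 1, :] = dv[..., 3]
        return dx


class BatchNorm2D(Layer):
    """Per-channel batch normalization with affine parameters and running
    statistics (momentum 0.1, eps 1e-5)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.params = [{"w": self.gamma, "grad": self.dgamma},
                       {"w": self.beta, "grad": self.dbeta}]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2), dtype=np.float64)
            var = x.var(axis=(0, 1, 2), dtype=np.float64)
            self.running_mean += self.momentum * \
                (mean.astype(np.float32) - self.running_mean)
            self.running_var += self.momentum * \
                (var.astype(np.float32) - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean.astype(np.float32)) * inv
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[1] * shape[2]
        self.dgamma[...] = np.sum(dout * xhat, axis=(0, 1, 2))
        self.dbeta[...] = np.sum(dout, axis=(0, 1, 2))
        dx = (self.gamma * inv / m) * \
            (m * dout - self.dbeta - xhat * self.dgamma)
        self._cache = None
        return dx.astype(np.float32, copy=False)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        self._mask = out > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class AdaptiveMaxPool(Layer):
    """Max-pool any spatial size down to ``out_size`` x ``out_size`` using
    the standard overlapping-bin rule start = floor(i*H/o), end = ceil((i+1)*H/o)."""

    def __init__(self, out_size: int = 3):
        self.out = out_size

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w_, c = x.shape
        o = self.out
        out = np.empty((n, o, o, c), dtype=np.float32)
        self._argidx = np.empty((n, o, o, c), dtype=np.int64)
        self._bins = []
        self._shape = x.shape
        for i in range(o):
            a, b = (i * h) // o, -(-(i + 1) * h // o)
            for j in range(o):
                cdx, d = (j * w_) // o, -(-(j + 1) * w_ // o)
                win = x[:, a:b, cdx:d, :].reshape(n, -1, c)
                idx = np.argmax(win, axis=1)
                out[:, i, j, :] = np.take_along_axis(win, idx[:, None, :], axis=1)[:, 0, :]
                self._argidx[:, i, j, :] = idx
                self._bins.append((a, b, cdx, d))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w_, c = self._shape
        o = self.out
        dx = np.zeros((n, h, w_, c), dtype=np.float32)
        for i in range(o):
            for j in range(o):
                a, b, cdx, d = self._bins[i * o + j]
                win = np.zeros((n, (b - a) * (d - cdx), c), dtype=np.float32)
                np.put_along_axis(win, self._argidx[:, i, j, :][:, None, :],
                                  dout[:, i, j, :][:, None, :], axis=1)
                dx[:, a:b, cdx:d, :] += win.reshape(n, b - a, d - cdx, c)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_in, n_out)) *
                  np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.params = [{"w": self.w, "grad": self.dw},
                       {"w": self.b, "grad": self.db}]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x if train else None
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        self._x = None
        return dout @ self.w.T


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    @property
    def params(self) -> list:
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def n_parameters(self) -> int:
        return int(sum(p["w"].size for p in self.params))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def state_dict(self) -> list:
        state = []
        for layer in self.layers:
            entry = [p["w"].copy() for p in layer.params]
            if isinstance(layer, BatchNorm2D):
                entry.extend([layer.running_mean.copy(), layer.running_var.copy()])
            state.append(entry)
        return state

    def load_state(self, state: list) -> None:
        for layer, entry in zip(self.layers, state):
            for p, w in zip(layer.params, entry):
                p["w"][...] = w
            if isinstance(layer, BatchNorm2D):
                layer.running_mean[...] = entry[-2]
                layer.running_var[...] = entry[-1]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = len(labels)
    probs = softmax(logits)
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-12)))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32), probs


class Adam:
    def __init__(self, params: list, lr: float = 5e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p["w"]) for p in params]
        self.v = [np.zeros_like(p["w"]) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p["w"] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
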