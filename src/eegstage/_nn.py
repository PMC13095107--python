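"""Minimal CNN engine (float32, CPU).

Layers: valid 2-D convolution (stride 1), ReLU, max-pooling, inverted
dropout, flatten, dense, softmax cross-entropy; Adam optimizer.
Convolutions run as single large BLAS matmuls over im2col patch matrices;
the patch gather works row-wise on a merged (width x channel) axis so each
copied span is contiguous, and all large intermediates live in per-layer
buffers reused across batches — on one core this is several times faster
than naive per-offset matmuls and keeps allocation churn out of the inner
loop. All randomness (init, shuffling, dropout) flows through seeded
generators, so training is bitwise reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Network", "Adam", "softmax", "softmax_xent"]

_swv = np.lib.stride_tricks.sliding_window_view


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.float32(1e-12)
    loss = float(-np.mean(np.log(p[np.arange(n), y] + eps)))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / np.float32(n)


class Layer:
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """Valid convolution, stride 1, kernel (kh, kw), NHWC layout.

    Runs as a single im2col matmul. The patch matrix is gathered row-wise
    into a buffer that is kept on the layer and reused across batches of
    the same shape (and reused again for the weight gradient), which avoids
    both repeated large allocations and a second gather in the backward
    pass. ``input_grad=False`` (first layer) skips the input-gradient pass.
    """

    def __init__(self, kh, kw, c_in, c_out, rng, input_grad=True):
        fan_in = kh * kw * c_in
        self.W = (rng.standard_normal((kh, kw, c_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, np.float32)
        self.input_grad = input_grad
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._bufs: dict[str, np.ndarray] = {}

    def _buf(self, name: str, shape: tuple[int, ...], zero: bool = False) -> np.ndarray:
        arr = self._bufs.get(name)
        if arr is None or arr.shape != shape:
            arr = np.zeros(shape, np.float32)
            self._bufs[name] = arr
        elif zero:
            arr[...] = 0.0
        return arr

    @staticmethod
    def _row_windows(x4, i, ho, kw):
        # (B, ho, wo, kw*c) strided view of kernel-row i's receptive spans,
        # built on the merged (width*channel) axis so each span is contiguous
        b, h, w, c = x4.shape
        xf = x4.reshape(b, h, w * c)
        return _swv(xf[:, i : i + ho], kw * c, axis=2)[:, :, ::c]

    def _gather(self, x4, name):
        kh, kw, ci, _ = self.W.shape
        b, h, w, _ = x4.shape
        ho, wo = h - kh + 1, w - kw + 1
        col = self._buf(name, (b * ho * wo, kh * kw * ci))
        col5 = col.reshape(b, ho, wo, kh, kw * ci)
        for i in range(kh):
            np.copyto(col5[:, :, :, i, :], self._row_windows(x4, i, ho, kw))
        return col

    def forward(self, x, train=False, rng=None):
        x = np.ascontiguousarray(x, dtype=np.float32)
        kh, kw, ci, co = self.W.shape
        b, h, w, _ = x.shape
        ho, wo = h - kh + 1, w - kw + 1
        self._shape = x.shape
        col = self._gather(x, "col")
        out = self._buf("out", (b * ho * wo, co))
        np.matmul(col, self.W.reshape(-1, co), out=out)
        out += self.b
        return out.reshape(b, ho, wo, co)

    def backward(self, dy):
        kh, kw, ci, co = self.W.shape
        b, h, w, _ = self._shape
        ho, wo = dy.shape[1], dy.shape[2]
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        dy2 = dy.reshape(-1, co)
        col = self._bufs["col"]  # still holds this batch's patches
        np.matmul(col.T, dy2, out=self.grads[0].reshape(-1, co))
        self.grads[1][:] = dy2.sum(axis=0)
        if not self.input_grad:
            return None
        # input gradient = full correlation of the zero-padded output
        # gradient with the 180°-rotated kernel, as one more im2col matmul
        pad = self._buf("pad", (b, h + kh - 1, (w + kw - 1) * co), zero=True)
        pad4 = pad.reshape(b, h + kh - 1, w + kw - 1, co)
        pad4[:, kh - 1 : kh - 1 + ho, kw - 1 : kw - 1 + wo] = dy
        gcol = self._buf("gcol", (b * h * w, kh * kw * co))
        gcol5 = gcol.reshape(b, h, w, kh, kw * co)
        for i in range(kh):
            np.copyto(gcol5[:, :, :, i, :], self._row_windows(pad4, i, h, kw))
        wrot = np.ascontiguousarray(self.W[::-1, ::-1].transpose(0, 1, 3, 2)).reshape(-1, ci)
        dx = self._buf("dx", (b * h * w, ci))
        np.matmul(gcol, wrot, out=dx)
        return dx.reshape(b, h, w, ci)


class ReLU(Layer):
    """Rectifier, applied in place (conv outputs are private buffers)."""

    def forward(self, x, train=False, rng=None):
        np.maximum(x, 0.0, out=x)
        if train:
            self._mask = x > 0
        return x

    def backward(self, dy):
        dy *= self._mask
        return dy


class MaxPool(Layer):
    """Max pooling with floor truncation of ragged edges."""

    def __init__(self, ph, pw):
        self.ph, self.pw = ph, pw

    def forward(self, x, train=False, rng=None):
        b, h, w, c = x.shape
        ph, pw = self.ph, self.pw
        ho, wo = h // ph, w // pw
        self._in_shape = x.shape
        if ph == 2 and pw == 1:
            # the baseline 2x1 time pool: a branch-free elementwise max
            r = x[:, : 2 * ho].reshape(b, ho, 2, w, c)
            a, z = r[:, :, 0], r[:, :, 1]
            self._mask = z > a  # ties go to the earlier sample
            out = getattr(self, "_out", None)
            if out is None or out.shape != a.shape:
                out = self._out = np.empty(a.shape, np.float32)
            np.copyto(out, a)
            np.copyto(out, z, where=self._mask)
            return out
        r = x[:, : ho * ph, : wo * pw].reshape(b, ho, ph, wo, pw, c)
        r = r.transpose(0, 1, 3, 5, 2, 4).reshape(b, ho, wo, c, ph * pw)
        self._idx = r.argmax(axis=-1)
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        b, h, w, c = self._in_shape
        ph, pw = self.ph, self.pw
        ho, wo = h // ph, w // pw
        if ph == 2 and pw == 1:
            dx = getattr(self, "_dx", None)
            if dx is None or dx.shape != self._in_shape:
                dx = self._dx = np.empty(self._in_shape, np.float32)
            dx[...] = 0.0
            dr = dx[:, : 2 * ho].reshape(b, ho, 2, w, c)
            np.copyto(dr[:, :, 1], dy, where=self._mask)
            np.copyto(dr[:, :, 0], dy, where=~self._mask)
            return dx
        dx = np.zeros(self._in_shape, np.float32)
        dr = np.zeros((b, ho, wo, c, ph * pw), np.float32)
        np.put_along_axis(dr, self._idx[..., None], dy[..., None], axis=-1)
        dr = dr.reshape(b, ho, wo, c, ph, pw).transpose(0, 1, 4, 2, 5, 3)
        dx[:, : ho * ph, : wo * pw] = dr.reshape(b, ho * ph, wo * pw, c)
        return dx


class Dropout(Layer):
    """Inverted dropout; a no-op outside training.

    Operates in place: inputs are upstream layers' private buffers.
    """

    def __init__(self, p):
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = rng.random(x.shape, dtype=np.float32) >= self.p
        self._scale = np.float32(1.0 / (1.0 - self.p))
        x *= self._mask
        x *= self._scale
        return x

    def backward(self, dy):
        if self._mask is not None:
            dy *= self._mask
            dy *= self._scale
        return dy


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in, d_out, rng):
        self.W = (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(np.float32)
        self.b = np.zeros(d_out, np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][:] = self._x.T @ dy
        self.grads[1][:] = dy.sum(axis=0)
        dx = dy @ self.W.T
        self._x = None
        return dx


class Network:
    """A plain sequential stack ending in raw logits."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dlogits):
        dy = dlogits
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def gradients(self):
        out = []
        for layer in self.layers:
            out.extend(layer.grads)
        return out

    def get_weights(self):
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights):
        params = self.parameters()
        if len(params) != len(weights):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(params, weights):
            p[...] = w

    def predict_proba(self, x, batch_size=256):
        chunks = [
            softmax(self.forward(x[i : i + batch_size].astype(np.float32)))
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(chunks, axis=0)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = np.float32(lr)
        self.b1, self.b2, self.eps = np.float32(beta1), np.float32(beta2), np.float32(eps)
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
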