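"""Minimal CPU neural-network layers with hand-written backpropagation.

Only the operations needed by the depth-2 denoising U-Net are provided:
size-preserving convolutions, 2x2/stride-2 max pooling and transposed
convolutions, channel-wise batch normalization and ReLU.  Arrays are NCHW
float32; each layer caches what its backward pass needs, so a layer instance
services one forward/backward pair at a time.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32
F16 = np.float16


class Layer:
    """Base class: parameter dict, matching gradient dict, state buffers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Conv2d(Layer):
    """Size-preserving convolution with odd kernel, zero interior padding."""

    def __init__(self, cin: int, cout: int, ksize: int | tuple[int, int],
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        kh, kw = (ksize, ksize) if isinstance(ksize, int) else ksize
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("size-preserving convolution needs odd kernels")
        self.cin, self.cout, self.kh, self.kw = cin, cout, kh, kw
        self.ph, self.pw = kh // 2, kw // 2
        rng = rng or np.random.default_rng(0)
        self.params["W"] = he_normal(rng, (cout, cin, kh, kw), cin * kh * kw)
        self.params["b"] = np.zeros(cout, dtype=F32)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cols: np.ndarray | None = None
        self._hw: tuple[int, int] | None = None

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if self.ph == 0 and self.pw == 0:
            return x
        return np.pad(x, ((0, 0), (0, 0), (self.ph, self.ph), (self.pw, self.pw)))

    def _im2col(self, xp: np.ndarray, h: int, w: int) -> np.ndarray:
        """(N, C, Hp, Wp) padded input -> (N, C*kh*kw, h*w) column matrix."""
        n, c = xp.shape[:2]
        if self.kh == 1 and self.kw == 1:
            return xp.reshape(n, c, h * w)
        cols = np.empty((n, c, self.kh * self.kw, h, w), dtype=xp.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                cols[:, :, i * self.kw + j] = xp[:, :, i:i + h, j:j + w]
        return cols.reshape(n, c * self.kh * self.kw, h * w)

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=F32)
        n, _, h, w = x.shape
        cols = self._im2col(self._pad(x), h, w)
        self._cols, self._hw = cols, (h, w)
        w2 = self.params["W"].reshape(self.cout, -1)
        out = np.matmul(w2, cols).reshape(n, self.cout, h, w)
        out += self.params["b"][None, :, None, None]
        return out

    def backward(self, g):
        if self._cols is None:
            raise RuntimeError("backward called without a cached forward")
        g = np.ascontiguousarray(g, dtype=F32)
        n, _, h, w = g.shape
        g2 = g.reshape(n, self.cout, h * w)
        dw = np.matmul(g2, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.grads["W"] += dw.reshape(self.params["W"].shape)
        self.grads["b"] += g.sum(axis=(0, 2, 3))
        gcols = self._im2col(self._pad(g), h, w)
        w_flip = np.ascontiguousarray(self.params["W"][:, :, ::-1, ::-1])
        wt = w_flip.transpose(1, 0, 2, 3).reshape(self.cin, -1)
        dx = np.matmul(wt, gcols).reshape(n, self.cin, h, w)
        return dx

    def forward_inference(self, x: np.ndarray, scale: np.ndarray | None = None,
                          shift: np.ndarray | None = None, half: bool = False) -> np.ndarray:
        """Inference forward, optionally with folded affine (BN) and fp16 storage.

        ``scale``/``shift`` fold a per-output-channel affine y = scale*conv + shift
        into the weights, matching fused deployment.  In half mode, weights and
        activations are rounded to float16 while sums accumulate in float32.
        """
        w = self.params["W"]
        b = self.params["b"]
        if scale is not None:
            w = w * scale[:, None, None, None]
            b = b * scale + shift
        n, _, h, wd = x.shape
        # einsum keeps the per-pixel accumulation order independent of the
        # image width, so sub-buffer and whole-buffer inference agree bitwise
        if not half:
            cols = self._im2col(self._pad(np.ascontiguousarray(x, dtype=F32)), h, wd)
            out = np.einsum("ok,nkp->nop", w.astype(F32).reshape(self.cout, -1),
                            cols)
            out = out.reshape(n, self.cout, h, wd)
            out += b.astype(F32)[None, :, None, None]
            return out
        cols = self._im2col(self._pad(x.astype(F16)), h, wd)
        out = np.einsum("ok,nkp->nop", w.astype(F16).astype(F32).reshape(self.cout, -1),
                        cols.astype(F32))
        out = out.reshape(n, self.cout, h, wd)
        out += b.astype(F16).astype(F32)[None, :, None, None]
        return out.astype(F16)


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.cin, self.cout = cin, cout
        rng = rng or np.random.default_rng(0)
        self.params["W"] = he_normal(rng, (cin, cout, 2, 2), cin)
        self.params["b"] = np.zeros(cout, dtype=F32)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x: np.ndarray | None = None

    def _apply(self, x: np.ndarray, w: np.ndarray, b: np.ndarray,
               half: bool = False, deterministic: bool = False) -> np.ndarray:
        n, c, h, wd = x.shape
        out = np.empty((n, self.cout, 2 * h, 2 * wd), dtype=F32)
        xin = x.astype(F32) if half else x
        for i in range(2):
            for j in range(2):
                wij = w[:, :, i, j].astype(F32)
                if deterministic:
                    t = np.einsum("nchw,co->nohw", xin, wij)
                    out[:, :, i::2, j::2] = t
                else:
                    t = np.tensordot(xin, wij, axes=(1, 0))
                    out[:, :, i::2, j::2] = t.transpose(0, 3, 1, 2)
        out += b.astype(F32)[None, :, None, None]
        return out.astype(F16) if half else out

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=F32)
        self._x = x
        return self._apply(x, self.params["W"], self.params["b"])

    def backward(self, g):
        if self._x is None:
            raise RuntimeError("backward called without a cached training forward")
        g = np.ascontiguousarray(g, dtype=F32)
        w = self.params["W"]
        dx = np.zeros_like(self._x)
        for i in range(2):
            for j in range(2):
                gij = np.ascontiguousarray(g[:, :, i::2, j::2])
                self.grads["W"][:, :, i, j] += np.tensordot(
                    self._x, gij, axes=((0, 2, 3), (0, 2, 3)))
                dx += np.tensordot(gij, w[:, :, i, j], axes=(1, 1)).transpose(0, 3, 1, 2)
        self.grads["b"] += g.sum(axis=(0, 2, 3))
        return dx

    def forward_inference(self, x, half: bool = False):
        w16 = self.params["W"].astype(F16) if half else self.params["W"]
        b16 = self.params["b"].astype(F16) if half else self.params["b"]
        return self._apply(x.astype(F16) if half else np.asarray(x, dtype=F32),
                           w16, b16, half=half, deterministic=True)


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2; gradient routed to the arg-max entry."""

    def __init__(self) -> None:
        super().__init__()
        self._idx: np.ndarray | None = None
        self._shape: tuple | None = None

    @staticmethod
    def _windows(x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max pooling needs even spatial dims, got {h}x{w}")
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        return r.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)

    def forward(self, x, train=False):
        r = self._windows(x)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        self._idx, self._shape = idx, x.shape
        return np.ascontiguousarray(out)

    def backward(self, g):
        if self._idx is None:
            raise RuntimeError("backward called without a cached training forward")
        n, c, h, w = self._shape
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(gr, self._idx[..., None], g[..., None].astype(F32), axis=-1)
        gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(gr.reshape(n, c, h, w))

    def forward_inference(self, x, half: bool = False):
        return self.forward(x, train=False)


class BatchNorm2d(Layer):
    """Channel-wise batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.c, self.momentum, self.eps = c, momentum, eps
        self.params["gamma"] = np.ones(c, dtype=F32)
        self.params["beta"] = np.zeros(c, dtype=F32)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.buffers["running_mean"] = np.zeros(c, dtype=F32)
        self.buffers["running_var"] = np.ones(c, dtype=F32)
        self._cache = None

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=F32)
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.buffers["running_mean"] = ((1 - m) * self.buffers["running_mean"]
                                            + m * mu).astype(F32)
            self.buffers["running_var"] = ((1 - m) * self.buffers["running_var"]
                                           + m * var).astype(F32)
        else:
            mu = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * istd[None, :, None, None]
        out = (self.params["gamma"][None, :, None, None] * xhat
               + self.params["beta"][None, :, None, None])
        self._cache = (xhat, istd.astype(F32), train)
        return out.astype(F32)

    def backward(self, g):
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        xhat, istd, train = self._cache
        g = np.ascontiguousarray(g, dtype=F32)
        self.grads["gamma"] += (g * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += g.sum(axis=(0, 2, 3))
        gam = self.params["gamma"][None, :, None, None]
        if not train:
            return g * gam * istd[None, :, None, None]
        n, _, h, w = g.shape
        m = n * h * w
        dxhat = g * gam
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (istd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)

    def fold(self) -> tuple[np.ndarray, np.ndarray]:
        """Return per-channel (scale, shift) equivalent to eval-mode BN."""
        istd = 1.0 / np.sqrt(self.buffers["running_var"] + self.eps)
        scale = self.params["gamma"] * istd
        shift = self.params["beta"] - self.buffers["running_mean"] * scale
        return scale.astype(F32), shift.astype(F32)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, g):
        if self._mask is None:
            raise RuntimeError("backward called without a cached training forward")
        return g * self._mask

    def forward_inference(self, x, half: bool = False):
        return np.maximum(x, x.dtype.type(0))


class Sequential:
    """Plain layer chain; enough for probe models in receptive-field tests."""

    def __init__(self, *layers: Layer) -> None:
        self.layer_list = list(layers)

    def layers(self):
        return list(self.layer_list)

    def forward(self, x, train=False):
        for lyr in self.layer_list:
            x = lyr.forward(x, train=train)
        return x

    def backward(self, g):
        for lyr in reversed(self.layer_list):
            g = lyr.backward(g)
        return g

    def zero_grad(self):
        for lyr in self.layer_list:
            lyr.zero_grad()
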