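"""Minimal CPU neural-network layer stack (numpy, NCHW, float32).

Implements exactly the primitives the modified fully convolutional
segmentation network needs — zero padding, 3x3/1x1 convolution, ReLU,
2x2 max pooling (floor mode), inverted dropout, strided transposed
convolution, center crop — each with an explicit backward pass, plus
SGD with momentum and weight decay. Convolutions are evaluated as k*k
shifted channel-mixing matrix products; the backward data pass reuses
the same kernel as a full correlation with the spatially flipped,
channel-transposed weights, so both directions go through BLAS.
"""

from __future__ import annotations

import numpy as np


F32 = np.float32


def _corr2d(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Cross-correlate ``x`` (N,C,H,W) with ``w`` (O,C,k,k), stride 1.

    Evaluated as k*k shifted channel-mixing matrix products, which keeps
    the working set small on a single CPU (no k^2-fold im2col blowup).
    """
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, hp, wp = x.shape
    o, _, k, _ = w.shape
    ho, wo = hp - k + 1, wp - k + 1
    if k == 1:
        sl = x.transpose(1, 0, 2, 3).reshape(c, -1)
        acc = w[:, :, 0, 0] @ sl
    else:
        acc = np.zeros((o, n * ho * wo), F32)
        for a in range(k):
            for b in range(k):
                sl = x[:, :, a : a + ho, b : b + wo]
                acc += w[:, :, a, b] @ sl.transpose(1, 0, 2, 3).reshape(c, -1)
    return acc.reshape(o, n, ho, wo).transpose(1, 0, 2, 3)


class Layer:
    """Base class: stateless unless it owns parameters."""

    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x, train=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class ZeroPad2d(Layer):
    def __init__(self, pad: int):
        super().__init__()
        self.pad = int(pad)

    def forward(self, x, train=False, rng=None):
        p = self.pad
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))

    def backward(self, dy):
        p = self.pad
        return dy[:, :, p:-p, p:-p] if p else dy


class Conv2d(Layer):
    """kxk convolution, stride 1, symmetric zero padding ``pad``."""

    def __init__(self, in_ch, out_ch, kernel=3, pad=1, rng=None, init="he"):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel, self.pad = in_ch, out_ch, kernel, pad
        fan_in = in_ch * kernel * kernel
        if init == "zero":
            w = np.zeros((out_ch, in_ch, kernel, kernel), F32)
        else:
            rng = rng or np.random.default_rng(0)
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           (out_ch, in_ch, kernel, kernel)).astype(F32)
        self.params = {"weight": w, "bias": np.zeros(out_ch, F32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x = None

    def forward(self, x, train=False, rng=None):
        self._x = x
        y = _corr2d(x, self.params["weight"], self.pad)
        return y + self.params["bias"][None, :, None, None]

    def backward(self, dy):
        w = self.params["weight"]
        k, p = self.kernel, self.pad
        x = self._x
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        n, c, hp, wp = xp.shape
        ho, wo = hp - k + 1, wp - k + 1
        dy_m = dy.transpose(1, 0, 2, 3).reshape(self.out_ch, -1)
        gw = self.grads["weight"]
        for a in range(k):
            for b in range(k):
                sl = xp[:, :, a : a + ho, b : b + wo]
                gw[:, :, a, b] += dy_m @ sl.transpose(1, 0, 2, 3).reshape(c, -1).T
        self.grads["bias"] += dy.sum(axis=(0, 2, 3))
        # data gradient: full correlation with flipped, transposed kernel
        w_t = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        return _corr2d(dy, np.ascontiguousarray(w_t), k - 1 - p)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class MaxPool2d(Layer):
    """2x2, stride 2, floor mode (trailing odd row/col dropped)."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xr = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._idx = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        scat = np.zeros((n, c, h2, w2, 4), F32)
        np.put_along_axis(scat, self._idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros(self._in_shape, F32)
        dx[:, :, : h2 * 2, : w2 * 2] = (
            scat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2 * 2, w2 * 2)
        )
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float):
        super().__init__()
        self.p = float(p)

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.p).astype(F32) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class ConvTranspose2d(Layer):
    """Transposed convolution (kernel k, stride s); out = (in-1)*s + k."""

    def __init__(self, in_ch, out_ch, kernel, stride, init="bilinear"):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        w = np.zeros((in_ch, out_ch, kernel, kernel), F32)
        if init == "bilinear":
            f = bilinear_kernel(kernel)
            for c in range(min(in_ch, out_ch)):
                w[c, c] = f
        self.params = {"weight": w}
        self.grads = {"weight": np.zeros_like(w)}

    def forward(self, x, train=False, rng=None):
        self._x = x
        n, c, hi, wi = x.shape
        k, s = self.kernel, self.stride
        ho, wo = (hi - 1) * s + k, (wi - 1) * s + k
        patches = np.einsum("ncij,cokl->noijkl", x, self.params["weight"])
        y = np.zeros((n, self.out_ch, ho, wo), F32)
        for i in range(hi):
            for j in range(wi):
                y[:, :, i * s : i * s + k, j * s : j * s + k] += patches[:, :, i, j]
        return y

    def backward(self, dy):
        x = self._x
        n, c, hi, wi = x.shape
        k, s = self.kernel, self.stride
        patches = np.empty((n, self.out_ch, hi, wi, k, k), F32)
        for i in range(hi):
            for j in range(wi):
                patches[:, :, i, j] = dy[:, :, i * s : i * s + k, j * s : j * s + k]
        self.grads["weight"] += np.einsum("ncij,noijkl->cokl", x, patches)
        return np.einsum("noijkl,cokl->ncij", patches, self.params["weight"])


class CenterCrop(Layer):
    def __init__(self, target: int):
        super().__init__()
        self.target = int(target)

    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        t = self.target
        oy = (x.shape[2] - t) // 2
        ox = (x.shape[3] - t) // 2
        self._off = (oy, ox)
        return x[:, :, oy : oy + t, ox : ox + t]

    def backward(self, dy):
        dx = np.zeros(self._in_shape, F32)
        oy, ox = self._off
        t = self.target
        dx[:, :, oy : oy + t, ox : ox + t] = dy
        return dx


class Sequential:
    """Ordered layer container with named parameters."""

    def __init__(self, layers: list[tuple[str, Layer]]):
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        for _, layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for _, layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def named_params(self):
        for lname, layer in self.layers:
            for pname, val in layer.params.items():
                yield f"{lname}.{pname}", val, layer.grads[pname]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: val.copy() for name, val, _ in self.named_params()}

    def load_state(self, state: dict[str, np.ndarray]):
        for lname, layer in self.layers:
            for pname in layer.params:
                key = f"{lname}.{pname}"
                if key in state:
                    layer.params[pname][...] = state[key]

    def zero_grad(self):
        for _, layer in self.layers:
            for g in layer.grads.values():
                g[...] = 0.0


def bilinear_kernel(size: int) -> np.ndarray:
    """Standard bilinear-interpolation filter used to seed the upsampler."""
    factor = (size + 1) // 2
    center = factor - 1.0 if size % 2 == 1 else factor - 0.5
    og = np.arange(size, dtype=np.float64)
    f = (1 - np.abs(og - center) / factor)
    return np.outer(f, f).astype(F32)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_with_logits(logits, target, ignore_label=255, reduction="sum"):
    """Loss and logit gradient; ``target`` pixels == ignore_label contribute
    exactly zero to both.

    logits: (N, C, H, W); target: (N, H, W) integer labels.
    Returns (loss, dlogits, n_valid).
    """
    prob = softmax(logits, axis=1)
    valid = target != ignore_label
    n_valid = int(valid.sum())
    tgt = np.where(valid, target, 0).astype(np.int64)
    p_true = np.take_along_axis(prob, tgt[:, None], axis=1)[:, 0]
    logp = np.log(np.clip(p_true, 1e-12, None))
    loss = -float(logp[valid].sum())
    onehot = np.zeros_like(prob)
    np.put_along_axis(onehot, tgt[:, None], 1.0, axis=1)
    dlogits = (prob - onehot) * valid[:, None].astype(F32)
    if reduction == "mean":
        denom = max(n_valid, 1)
        loss /= denom
        dlogits /= denom
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return loss, dlogits.astype(F32), n_valid


class SGD:
    """Stochastic gradient descent with momentum and L2 weight decay."""

    def __init__(self, model: Sequential, lr, momentum=0.9, weight_decay=0.0):
        self.model = model
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = {name: np.zeros_like(v) for name, v, _ in model.named_params()}

    def step(self):
        for name, val, grad in self.model.named_params():
            g = grad + self.weight_decay * val
            v = self.velocity[name]
            v *= self.momentum
            v -= self.lr * g
            val += v
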