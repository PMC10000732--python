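"""Minimal differentiable models for image classification and white-box attacks.

This module implements a compact convolutional network in pure NumPy with
explicit backpropagation. Besides the usual parameter gradients needed for
SGD training, every model exposes the gradient of its cross-entropy loss
with respect to the *input* pixels, which is the primitive that gradient
sign attacks (FGSM/PGD/BIM) consume.

Two models are provided:

``SmallCNN``
    A 3-block convolutional classifier (conv-relu-pool x2, conv-relu-global
    average pool, linear head). The globally pooled activations of the last
    convolutional block are the network's "deep features", used by the
    feature-based adversarial detectors.

``LogisticModel``
    A frozen logistic-regression scorer ``p(y=1|x) = sigma(w.x)``. Its loss
    gradient has a closed form, which makes it the analytic ground truth for
    attack unit tests and worked examples.
"""

from __future__ import annotations

import hashlib
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import convolve as _ndconvolve

__all__ = [
    "DifferentiableModel",
    "SmallCNN",
    "LogisticModel",
    "ModelFrozenError",
    "softmax",
    "derive_seed",
]


class ModelFrozenError(RuntimeError):
    """Raised when training a frozen model or attacking an unfrozen one."""


def derive_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from a global seed and a stage name."""
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@runtime_checkable
class DifferentiableModel(Protocol):
    """Contract required by the attack functions.

    A model maps inputs to class probabilities and, once frozen, exposes a
    deterministic gradient of its cross-entropy loss w.r.t. the input.
    """

    frozen: bool

    def predict_proba(self, x: np.ndarray) -> np.ndarray: ...

    def loss_gradient(self, x: np.ndarray, y) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# layers


class _Conv2d:
    """Same-padded 2-D convolution via im2col."""

    def __init__(self, in_ch, out_ch, k, rng, dtype):
        fan_in = in_ch * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, k, k)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.k = k
        self.pad = k // 2
        self._cache = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        n, c, h, w = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, -1)
        out_ch = self.W.shape[0]
        out = cols @ self.W.reshape(out_ch, -1).T + self.b
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, xshape = self._cache
        n, c, h, w = xshape
        out_ch = self.W.shape[0]
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, out_ch)
        self.dW[...] = (dflat.T @ cols).reshape(self.W.shape)
        self.db[...] = dflat.sum(axis=0)
        dcols = (dflat @ self.W.reshape(out_ch, -1)).reshape(n, h, w, c, self.k, self.k)
        p = self.pad
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]


class _ReLU:
    params: Sequence = ()
    grads: Sequence = ()

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _MaxPool2:
    """2x2, stride-2 max pooling; tied maxima share the gradient equally."""

    params: Sequence = ()
    grads: Sequence = ()

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = (xr == out[:, :, :, None, :, None]).astype(x.dtype)
        self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        self._shape = x.shape
        return out

    def backward(self, dout):
        dx = self._mask * dout[:, :, :, None, :, None]
        return dx.reshape(self._shape)


class _GlobalAvgPool:
    params: Sequence = ()
    grads: Sequence = ()

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).astype(dout.dtype)


def _gaussian_kernel(sigma: float = 1.0, radius: int = 2) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    k = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma**2))
    return (k / k.sum())[None, None]  # (1, 1, 2r+1, 2r+1) for (n, c, h, w) input


class _Unsharp:
    """Fixed unsharp-mask front end: ``y = x + gain * (x - G x)``.

    Pretrained backbones open with strong oriented edge filters; a network
    trained from scratch on smooth synthetic lesions sometimes converges to a
    low-pass template instead, which changes the character of its input
    gradients entirely. This fixed contrast-enhancement stage pins the
    classifier's first operation to an edge-sensitive one.

    The operator is linear with a symmetric, zero-padded kernel, hence
    exactly self-adjoint: the backward pass applies the same operator, and
    input gradients stay exact.
    """

    params: Sequence = ()
    grads: Sequence = ()
    _kernel = _gaussian_kernel()

    def __init__(self, gain: float):
        self.gain = float(gain)

    def _op(self, x):
        blur = _ndconvolve(x, self._kernel.astype(x.dtype), mode="constant")
        return x + x.dtype.type(self.gain) * (x - blur)

    def forward(self, x):
        return self._op(x)

    def backward(self, dout):
        return self._op(dout)


class _Dense:
    def __init__(self, d_in, d_out, rng, dtype):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out)).astype(dtype)
        self.b = np.zeros(d_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


# ---------------------------------------------------------------------------
# models


class SmallCNN:
    """Small convolutional binary classifier trained from scratch.

    Architecture: ``conv(1->c1)-relu-maxpool2 -> conv(c1->c2)-relu-maxpool2 ->
    conv(c2->c3)-relu-global_avg_pool -> linear(c3->2)``. All convolutions are
    3x3 with same padding, so the spatial shape is controlled entirely by the
    two pooling stages and any square input with side divisible by 4 works.

    Parameters
    ----------
    image_size:
        Side length of the (square, single-channel) input images.
    channels:
        Widths of the three convolutional blocks. The last entry is the
        dimensionality of the deep-feature vector.
    seed:
        Seed for weight initialization.
    dtype:
        Computation dtype. float32 is the training default; float64 is used
        where gradients are checked against finite differences.
    """

    def __init__(self, image_size: int = 32, channels=(8, 16, 32), n_classes: int = 2,
                 seed: int = 0, dtype=np.float32, in_channels: int = 1,
                 input_shift: float = 0.5, unsharp_gain: float = 0.0):
        if image_size % 4 != 0:
            raise ValueError("image_size must be divisible by 4 (two 2x2 pooling stages)")
        rng = np.random.default_rng(seed)
        c1, c2, c3 = channels
        self.dtype = np.dtype(dtype)
        self.image_size = int(image_size)
        self.channels = tuple(int(c) for c in channels)
        self.n_classes = int(n_classes)
        self.seed = int(seed)
        self.in_channels = int(in_channels)
        # fixed centering applied before the first convolution; a constant
        # shift, so it changes no input gradient and no L-inf geometry
        self.input_shift = float(input_shift)
        self.unsharp_gain = float(unsharp_gain)
        front = [_Unsharp(unsharp_gain)] if unsharp_gain else []
        self.layers = front + [
            _Conv2d(in_channels, c1, 3, rng, self.dtype), _ReLU(), _MaxPool2(),
            _Conv2d(c1, c2, 3, rng, self.dtype), _ReLU(), _MaxPool2(),
            _Conv2d(c2, c3, 3, rng, self.dtype), _ReLU(), _GlobalAvgPool(),
        ]
        self.head = _Dense(c3, n_classes, rng, self.dtype)
        self.frozen = False
        self._velocity = None
        self._adam_state = None

    # -- plumbing ----------------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.channels[-1]

    def _as_batch(self, x: np.ndarray):
        """Accepts (h, w) / (n, h, w) for single-channel nets, or
        (c, h, w) / (n, c, h, w) for multichannel ones."""
        x = np.asarray(x, dtype=self.dtype)
        want = 3 if self.in_channels == 1 else 4
        single = x.ndim == want - 1
        if single:
            x = x[None]
        if self.in_channels == 1 and x.ndim == 3:
            x = x[:, None, :, :]
        return x - self.dtype.type(self.input_shift), single

    def _forward(self, xb: np.ndarray):
        h = xb
        for layer in self.layers:
            h = layer.forward(h)
        feats = h
        logits = self.head.forward(feats)
        return logits, feats

    # -- inference ---------------------------------------------------------

    def features(self, x: np.ndarray) -> np.ndarray:
        """Deep features: globally pooled activations of the last conv block."""
        xb, single = self._as_batch(x)
        _, feats = self._forward(xb)
        return feats[0] if single else feats

    def block_features(self, x: np.ndarray) -> np.ndarray:
        """Globally pooled activations of every conv block, concatenated.

        Richer than the penultimate features alone: the early blocks carry
        fine-scale image statistics that late pooling discards.
        """
        xb, single = self._as_batch(x)
        h = xb
        pooled = []
        for layer in self.layers:
            h = layer.forward(h)
            if isinstance(layer, _ReLU):
                pooled.append(h.mean(axis=(2, 3)))
        feats = np.concatenate(pooled, axis=1)
        return feats[0] if single else feats

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        xb, single = self._as_batch(x)
        logits, _ = self._forward(xb)
        p = softmax(logits.astype(np.float64))
        return p[0] if single else p

    def predict(self, x: np.ndarray) -> np.ndarray:
        p = self.predict_proba(x)
        return np.argmax(p, axis=-1)  # argmax ties resolve to label 0

    # -- training ----------------------------------------------------------

    def train_batch(self, x: np.ndarray, y: np.ndarray, lr: float, momentum: float = 0.9,
                    optimizer: str = "sgd") -> float:
        """One optimizer step on mean cross-entropy; returns the batch loss.

        ``optimizer`` is "sgd" (momentum SGD, the classifier recipe) or
        "adam" (used for the detector discriminators, whose loss landscape
        has a long plateau that plain SGD escapes only erratically).
        """
        if self.frozen:
            raise ModelFrozenError("model is frozen; cannot train")
        xb, _ = self._as_batch(x)
        y = np.asarray(y, dtype=int)
        logits, _ = self._forward(xb)
        n = logits.shape[0]
        p = softmax(logits.astype(np.float64))
        loss = float(-np.mean(np.log(np.clip(p[np.arange(n), y], 1e-12, None))))
        dz = p.copy()
        dz[np.arange(n), y] -= 1.0
        dz = (dz / n).astype(self.dtype)
        grad = self.head.backward(dz)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        params = [p_ for lyr in (*self.layers, self.head) for p_ in lyr.params]
        grads = [g for lyr in (*self.layers, self.head) for g in lyr.grads]
        if optimizer == "sgd":
            if self._velocity is None:
                self._velocity = [np.zeros_like(p_) for p_ in params]
            for p_, g, v in zip(params, grads, self._velocity):
                v *= momentum
                v -= lr * g
                p_ += v
        elif optimizer == "adam":
            if self._adam_state is None:
                self._adam_state = {"t": 0, "m": [np.zeros_like(p_) for p_ in params],
                                    "v": [np.zeros_like(p_) for p_ in params]}
            st = self._adam_state
            st["t"] += 1
            b1, b2, eps_ = 0.9, 0.999, 1e-8
            bc1 = 1.0 - b1 ** st["t"]
            bc2 = 1.0 - b2 ** st["t"]
            for p_, g, m, v in zip(params, grads, st["m"], st["v"]):
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p_ -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps_)
        else:
            raise ValueError(f"unknown optimizer {optimizer!r}")
        return loss

    def freeze(self) -> "SmallCNN":
        self.frozen = True
        return self

    # -- attack interface --------------------------------------------------

    def loss(self, x: np.ndarray, y) -> float:
        """Mean cross-entropy of the true class over the batch."""
        p = self.predict_proba(x)
        p = np.atleast_2d(p)
        y = np.atleast_1d(np.asarray(y, dtype=int))
        return float(-np.mean(np.log(np.clip(p[np.arange(len(y)), y], 1e-12, None))))

    def loss_gradient(self, x: np.ndarray, y) -> np.ndarray:
        """Gradient of the per-image cross-entropy w.r.t. the input pixels.

        For a batch, row ``i`` of the result is the gradient of image ``i``'s
        own loss (images do not interact through the network).
        """
        if not self.frozen:
            raise ModelFrozenError("attack target must be frozen before taking input gradients")
        in_dtype = np.asarray(x).dtype
        xb, single = self._as_batch(x)
        y = np.atleast_1d(np.asarray(y, dtype=int))
        logits, _ = self._forward(xb)
        n = logits.shape[0]
        p = softmax(logits.astype(np.float64))
        dz = p
        dz[np.arange(n), y] -= 1.0
        grad = self.head.backward(dz.astype(self.dtype))
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        if self.in_channels == 1:
            grad = grad[:, 0, :, :]
        out = grad[0] if single else grad
        return out.astype(in_dtype if in_dtype.kind == "f" else np.float64)

    # -- serialization -----------------------------------------------------

    def state_dict(self) -> dict:
        state = {}
        for i, lyr in enumerate((*self.layers, self.head)):
            for j, p_ in enumerate(lyr.params):
                state[f"p{i}_{j}"] = p_
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, lyr in enumerate((*self.layers, self.head)):
            for j, p_ in enumerate(lyr.params):
                p_[...] = state[f"p{i}_{j}"]

    def descriptor(self) -> dict:
        return {
            "arch": "small_cnn",
            "image_size": self.image_size,
            "channels": list(self.channels),
            "n_classes": self.n_classes,
            "dtype": self.dtype.name,
            "in_channels": self.in_channels,
            "input_shift": self.input_shift,
            "unsharp_gain": self.unsharp_gain,
        }


class LogisticModel:
    """Frozen logistic scorer ``p(y=1|x) = sigma(w.x)`` with analytic gradients.

    The cross-entropy loss for label ``y`` is ``-log p(y|x)`` and its input
    gradient is ``(sigma(w.x) - y) * w``, so attack outputs on this model can
    be computed by hand.
    """

    def __init__(self, w):
        self.w = np.asarray(w, dtype=np.float64)
        self.frozen = True

    def _z(self, x):
        return np.asarray(x, dtype=np.float64) @ self.w

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p1 = 1.0 / (1.0 + np.exp(-self._z(x)))
        return np.stack([1.0 - p1, p1], axis=-1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=-1)

    def loss_gradient(self, x: np.ndarray, y) -> np.ndarray:
        p1 = 1.0 / (1.0 + np.exp(-self._z(x)))
        resid = p1 - np.asarray(y, dtype=np.float64)
        return np.multiply.outer(resid, self.w) if np.ndim(resid) else resid * self.w
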