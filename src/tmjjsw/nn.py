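"""Minimal numpy neural-network layer library for 2D segmentation.

Implements exactly the pieces the residual U-Net needs — 2D convolution
and transposed convolution (im2col/col2im), affine-free instance
normalization, PReLU with a single shared slope, dropout, residual
units, concatenating skip connections — together with hand-written
backpropagation, the Adam optimizer and a reduce-on-plateau learning
rate scheduler. Tensors are float64 arrays in NCHW layout; the library
is single-threaded and caches forward activations on the layer objects.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------- conv core

def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, oh, ow), dtype=xp.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, ki, kj] = xp[:, :, ki:ki + stride * oh:stride,
                                    kj:kj + stride * ow:stride]
    return cols.reshape(n, c * k * k, oh * ow)


def _col2im(cols: np.ndarray, padded_shape, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    n, c, hp, wp = padded_shape
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, oh, ow)
    for ki in range(k):
        for kj in range(k):
            xp[:, :, ki:ki + stride * oh:stride, kj:kj + stride * ow:stride] += cols[:, :, ki, kj]
    return xp


def _conv_forward(x, w, b, stride, pad):
    n, _, h, wid = x.shape
    o, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    oh = (h + 2 * pad - k) // stride + 1
    ow = (wid + 2 * pad - k) // stride + 1
    cols = _im2col(xp, k, stride, oh, ow)
    y = np.matmul(w.reshape(o, -1)[None], cols)
    if b is not None:
        y += b[None, :, None]
    cache = (xp.shape, cols, w.shape, stride, pad, oh, ow)
    return y.reshape(n, o, oh, ow), cache


def _conv_backward(gout, cache, w):
    padded_shape, cols, wshape, stride, pad, oh, ow = cache
    n, o = gout.shape[:2]
    gm = gout.reshape(n, o, -1)
    dw = np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0).reshape(wshape)
    db = gm.sum(axis=(0, 2))
    dcols = np.matmul(w.reshape(o, -1).T[None], gm)
    dxp = _col2im(dcols, padded_shape, wshape[2], stride, oh, ow)
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad]
    return dxp, dw, db


# ------------------------------------------------------------------- layers

class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: int = 3, stride: int = 1,
                 padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_ch * kernel_size * kernel_size
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Param(rng.uniform(-bound, bound, (out_ch, in_ch, kernel_size, kernel_size)))
        self.bias = Param(rng.uniform(-bound, bound, out_ch)) if bias else None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, training=False):
        y, self._cache = _conv_forward(x, self.weight.value,
                                       self.bias.value if self.bias is not None else None,
                                       self.stride, self.padding)
        return y

    def backward(self, gout):
        dx, dw, db = _conv_backward(gout, self._cache, self.weight.value)
        self.weight.grad += dw
        if self.bias is not None:
            self.bias.grad += db
        return dx


class ConvTranspose2d(Layer):
    """Stride-s transposed convolution via zero-stuffing + ordinary convolution."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int = 3, stride: int = 2,
                 padding: int = 1, output_padding: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.k, self.stride = kernel_size, stride
        self.padding, self.output_padding = padding, output_padding
        fan_in = in_ch * kernel_size * kernel_size
        bound = 1.0 / np.sqrt(fan_in)
        # torch layout: (in_ch, out_ch, k, k)
        self.weight = Param(rng.uniform(-bound, bound, (in_ch, out_ch, kernel_size, kernel_size)))
        self.bias = Param(rng.uniform(-bound, bound, out_ch)) if bias else None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _equiv_weight(self):
        return self.weight.value.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        s, op = self.stride, self.output_padding
        hs, ws = (h - 1) * s + 1 + op, (w - 1) * s + 1 + op
        xs = np.zeros((n, c, hs, ws), dtype=x.dtype)
        xs[:, :, ::s, ::s] = x
        y, self._cache = _conv_forward(xs, self._equiv_weight(),
                                       self.bias.value if self.bias is not None else None,
                                       1, self.k - 1 - self.padding)
        return y

    def backward(self, gout):
        dxs, dw_eq, db = _conv_backward(gout, self._cache, self._equiv_weight())
        self.weight.grad += dw_eq[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        if self.bias is not None:
            self.bias.grad += db
        return dxs[:, :, ::self.stride, ::self.stride]


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization without learned affine."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x, training=False):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._y = (x - mu) * self._inv
        return self._y

    def backward(self, gout):
        y, inv = self._y, self._inv
        gm = gout.mean(axis=(2, 3), keepdims=True)
        gym = (gout * y).mean(axis=(2, 3), keepdims=True)
        return inv * (gout - gm - y * gym)


class PReLU(Layer):
    """PReLU with one shared learnable negative slope (init 0.25)."""

    def __init__(self, init: float = 0.25):
        self.alpha = Param(np.array(init))

    def params(self):
        return [self.alpha]

    def forward(self, x, training=False):
        self._x = x
        a = self.alpha.value
        return np.where(x > 0, x, a * x)

    def backward(self, gout):
        x = self._x
        neg = x <= 0
        self.alpha.grad += float((gout * x * neg).sum())
        return gout * np.where(neg, self.alpha.value, 1.0)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class Identity(Layer):
    def forward(self, x, training=False):
        return x

    def backward(self, gout):
        return gout


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout


class ResidualUnit(Layer):
    """A chain of conv(+norm/dropout/PReLU) subunits with one residual skip.

    The first subunit applies the stride and the channel change; the
    skip is identity when shape-preserving, otherwise a projection conv
    (kernel 1 for pure channel change, the full kernel when strided).
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1, subunits: int = 2,
                 kernel_size: int = 3, dropout: float = 0.0, last_conv_only: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        units = []
        c_in, s = in_ch, stride
        subunits = max(1, subunits)
        for i in range(subunits):
            conv_only = last_conv_only and i == subunits - 1
            units.append(_conv_unit(c_in, out_ch, kernel_size, s, dropout, conv_only, rng))
            c_in, s = out_ch, 1
        self.conv = Sequential(*units)
        if stride != 1 or in_ch != out_ch:
            rk = kernel_size if stride != 1 else 1
            self.residual: Layer = Conv2d(in_ch, out_ch, rk, stride, rk // 2, rng=rng)
        else:
            self.residual = Identity()

    def params(self):
        return self.conv.params() + self.residual.params()

    def forward(self, x, training=False):
        return self.conv.forward(x, training) + self.residual.forward(x, training)

    def backward(self, gout):
        return self.conv.backward(gout) + self.residual.backward(gout)


class SkipConnection(Layer):
    """Concatenate the block input with its submodule's output (channel dim)."""

    def __init__(self, submodule: Layer):
        self.submodule = submodule

    def params(self):
        return self.submodule.params()

    def forward(self, x, training=False):
        self._c = x.shape[1]
        return np.concatenate([x, self.submodule.forward(x, training)], axis=1)

    def backward(self, gout):
        return gout[:, :self._c] + self.submodule.backward(gout[:, self._c:])


def _conv_unit(in_ch, out_ch, kernel_size, stride, dropout, conv_only, rng):
    """Conv followed by norm → dropout → activation (unless conv_only)."""
    layers: list[Layer] = [Conv2d(in_ch, out_ch, kernel_size, stride, rng=rng)]
    if not conv_only:
        layers.append(InstanceNorm2d())
        if dropout > 0:
            layers.append(Dropout(dropout, rng))
        layers.append(PReLU())
    return Sequential(*layers)


# -------------------------------------------------------------------- U-Net

class ResidualUNet(Layer):
    """Residual U-Net with concatenating skips, built recursively.

    Each resolution level is (down residual-unit, skip(sub-block), up
    transposed-conv + residual-unit); the bottom level is a single
    stride-1 residual unit. ``channels[i]`` are the encoder feature
    counts, ``strides[i]`` the downsampling factor between levels.
    """

    def __init__(self, in_channels: int = 1, out_channels: int = 4,
                 channels=(16, 32, 64, 128), strides=(2, 2, 2),
                 num_res_units: int = 16, kernel_size: int = 3,
                 dropout: float = 0.3, seed: int = 0):
        if len(channels) < 2:
            raise ValueError("need at least two channel levels")
        if len(strides) != len(channels) - 1:
            raise ValueError(f"len(strides) must be len(channels)-1, got {len(strides)}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.channels = tuple(channels)
        self.strides = tuple(strides)
        self.num_res_units = num_res_units
        self.kernel_size = kernel_size
        self.dropout = dropout
        self.rng = np.random.default_rng(seed)
        self.model = self._build(in_channels, out_channels, self.channels, self.strides, True)
        self._params = self.model.params()

    def _ru(self, in_ch, out_ch, stride, subunits, last_conv_only=False):
        return ResidualUnit(in_ch, out_ch, stride, subunits, self.kernel_size,
                            self.dropout, last_conv_only, rng=self.rng)

    def _up(self, in_ch, out_ch, stride, is_top):
        layers: list[Layer] = [
            ConvTranspose2d(in_ch, out_ch, self.kernel_size, stride,
                            padding=self.kernel_size // 2, output_padding=stride - 1,
                            rng=self.rng),
            InstanceNorm2d(),
        ]
        if self.dropout > 0:
            layers.append(Dropout(self.dropout, self.rng))
        layers.append(PReLU())
        layers.append(self._ru(out_ch, out_ch, 1, 1, last_conv_only=is_top))
        return Sequential(*layers)

    def _build(self, in_ch, out_ch, channels, strides, is_top):
        c, s = channels[0], strides[0]
        if len(channels) > 2:
            sub = self._build(c, c, channels[1:], strides[1:], False)
            up_in = c * 2
        else:
            sub = self._ru(c, channels[1], 1, self.num_res_units)
            up_in = c + channels[1]
        down = self._ru(in_ch, c, s, self.num_res_units)
        return Sequential(down, SkipConnection(sub), self._up(up_in, out_ch, s, is_top))

    # Layer protocol
    def params(self):
        return self._params

    def forward(self, x, training=False):
        factor = int(np.prod(self.strides))
        if x.shape[2] % factor or x.shape[3] % factor:
            raise ValueError(f"spatial dims {x.shape[2:]} must be divisible by {factor}")
        return self.model.forward(x, training)

    def backward(self, gout):
        return self.model.backward(gout)

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self._params))

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self._params]

    def set_state(self, state) -> None:
        for p, v in zip(self._params, state, strict=True):
            p.value = v.copy()


# ----------------------------------------------------------- loss & softmax

def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray, axis: int = 1) -> np.ndarray:
    inner = (probs * dprobs).sum(axis=axis, keepdims=True)
    return probs * (dprobs - inner)


def one_hot(mask: np.ndarray, n_classes: int) -> np.ndarray:
    """(N,H,W) integer mask -> (N,C,H,W) one-hot float array."""
    return np.moveaxis(np.eye(n_classes, dtype=np.float64)[mask], -1, 1)


def soft_dice(probs: np.ndarray, onehot: np.ndarray, include_background: bool = False,
              eps: float = 1e-5) -> tuple[float, np.ndarray]:
    """Soft Dice loss and its gradient with respect to the probabilities.

    loss = 1 − mean over (sample, included class) of
           (2·Σ p·g + ε) / (Σ p + Σ g + ε).
    """
    if probs.shape != onehot.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {onehot.shape}")
    start = 0 if include_background else 1
    p = probs[:, start:]
    g = onehot[:, start:]
    inter = (p * g).sum(axis=(2, 3))
    denom = p.sum(axis=(2, 3)) + g.sum(axis=(2, 3))
    score = (2.0 * inter + eps) / (denom + eps)
    loss = 1.0 - float(score.mean())
    dprobs = np.zeros_like(probs)
    scale = 1.0 / score.size
    dprobs[:, start:] = -scale * (2.0 * g * (denom + eps)[..., None, None]
                                  - (2.0 * inter + eps)[..., None, None]
                                  ) / ((denom + eps) ** 2)[..., None, None]
    return loss, dprobs


# ---------------------------------------------------------------- optimizer

class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = np.zeros_like(p.value)

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Multiply the lr by ``factor`` after ``patience`` epochs without improvement."""

    def __init__(self, optimizer: Adam, mode: str = "max", factor: float = 0.5,
                 patience: int = 10, min_delta: float = 1e-8):
        if mode not in ("max", "min"):
            raise ValueError("mode must be 'max' or 'min'")
        self.optimizer = optimizer
        self.sign = 1.0 if mode == "max" else -1.0
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = -np.inf
        self.bad_epochs = 0
        self.reductions: list[int] = []
        self._epoch = 0

    def step(self, metric: float) -> None:
        self._epoch += 1
        value = self.sign * metric
        if value > self.best + self.min_delta:
            self.best = value
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr *= self.factor
                self.reductions.append(self._epoch)
                self.bad_epochs = 0
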