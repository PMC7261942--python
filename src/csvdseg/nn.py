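"""A compact numpy CNN engine: layers with explicit backprop, a U-Net, Adam.

Everything operates on batches shaped ``(N, C, H, W)`` in float64. Layers
cache what their backward pass needs on ``forward`` and accumulate parameter
gradients on ``backward``; :meth:`UNet.forward` / :meth:`UNet.backward` wire
them into the encoder–decoder with skip connections. The engine is small by
design — 3×3 same-padding convolutions, 2×2 max-pooling, 2×2 stride-2
transpose convolutions, ReLU, sigmoid — which is exactly the vocabulary the
segmentation networks need, and it is exercised by finite-difference gradient
checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Conv2d:
    """k×k convolution with same zero-padding (odd k), He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        fan_in = in_ch * k * k
        self.k = k
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, k, k)))
        self.b = Param(np.zeros(out_ch))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, (self.k - 1) // 2
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp, self._hw = xp, (h, w)
        y = np.empty((n, self.W.value.shape[0], h, w))
        y[:] = self.b.value[None, :, None, None]
        for i in range(k):
            for j in range(k):
                y += np.einsum(
                    "nchw,oc->nohw",
                    xp[:, :, i : i + h, j : j + w],
                    self.W.value[:, :, i, j],
                    optimize=True,
                )
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, (self.k - 1) // 2
        h, w = self._hw
        xp = self._xp
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                self.W.grad[:, :, i, j] += np.einsum(
                    "nohw,nchw->oc", dy, xp[:, :, i : i + h, j : j + w],
                    optimize=True,
                )
                dxp[:, :, i : i + h, j : j + w] += np.einsum(
                    "nohw,oc->nchw", dy, self.W.value[:, :, i, j], optimize=True
                )
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class LeakyReLU:
    """Rectifier with a small negative slope.

    The slope keeps a gradient path open for units whose pre-activation goes
    negative everywhere — with sparse segmentation targets a plain rectifier
    can die wholesale early in training and freeze the network.
    """

    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy)


class MaxPool2:
    """2×2 max-pooling, stride 2; gradient routes to the first max of a tie."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 needs even spatial dims")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        xr = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return xr.reshape(n, c, h, w)


class ConvTranspose2:
    """2×2 transpose convolution, stride 2: doubles the spatial size."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        fan_in = in_ch * 4
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (in_ch, out_ch, 2, 2)))
        self.b = Param(np.zeros(out_ch))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._x = x
        y = np.einsum("nchw,coab->nohawb", x, self.W.value, optimize=True)
        y = y.reshape(n, -1, 2 * h, 2 * w)
        y += self.b.value[None, :, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, o, h2, w2 = dy.shape
        dyr = dy.reshape(n, o, h2 // 2, 2, w2 // 2, 2)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        self.W.grad += np.einsum(
            "nchw,nohawb->coab", self._x, dyr, optimize=True
        )
        return np.einsum("nohawb,coab->nchw", dyr, self.W.value, optimize=True)


class _ConvBlock:
    """conv → leaky ReLU → conv → leaky ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.layers = [
            Conv2d(in_ch, out_ch, 3, rng),
            LeakyReLU(),
            Conv2d(out_ch, out_ch, 3, rng),
            LeakyReLU(),
        ]

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class UNet:
    """Encoder–decoder segmentation network with skip connections.

    ``depth`` encoder levels with channel counts ``base * growth**level``,
    each two 3×3 convolutions + ReLU followed by 2×2 max-pooling; a
    bottleneck block at ``base * growth**depth`` channels; a symmetric
    decoder of stride-2 transpose convolutions that halve the channel count,
    concatenation with the matching encoder feature map, and two more
    convolutions; finally a 1×1 convolution to a single sigmoid probability
    channel. Output spatial size equals input spatial size.
    """

    def __init__(
        self,
        in_channels: int,
        depth: int = 2,
        base_channels: int = 8,
        growth: int = 2,
        seed: int = 0,
    ):
        if depth < 1:
            raise ValueError("depth must be at least 1")
        rng = np.random.default_rng(seed)
        chans = [base_channels * growth**i for i in range(depth + 1)]
        self.depth = depth
        self.encoder_channels = chans[:depth]
        self.enc = []
        prev = in_channels
        for i in range(depth):
            self.enc.append(_ConvBlock(prev, chans[i], rng))
            prev = chans[i]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = _ConvBlock(chans[depth - 1], chans[depth], rng)
        self.ups = []
        self.dec = []
        for i in reversed(range(depth)):
            self.ups.append(ConvTranspose2(chans[i + 1], chans[i], rng))
            self.dec.append(_ConvBlock(2 * chans[i], chans[i], rng))
        self.head = Conv2d(chans[0], 1, 1, rng)
        self.in_channels = in_channels

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        out = []
        for blk in self.enc:
            out += blk.params()
        out += self.bottleneck.params()
        for up, blk in zip(self.ups, self.dec):
            out += up.params()
            out += blk.params()
        out += self.head.params()
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state_arrays(self, arrays) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("state does not match architecture")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError("state shape mismatch")
            p.value[...] = a

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Return per-pixel probabilities, shape (N, 1, H, W)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N, {self.in_channels}, H, W) input, got {x.shape}"
            )
        if x.shape[2] % 2**self.depth or x.shape[3] % 2**self.depth:
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by 2**depth"
            )
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([skip, h], axis=1)
            h = blk.forward(h)
        logits = self.head.forward(h)
        self._probs = expit(logits)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        p = self._probs
        self.backward_logits(dprobs * p * (1.0 - p))

    def backward_logits(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the pre-sigmoid logits.

        Losses that know their logit gradient in closed form (binary
        cross-entropy in particular) must use this entry point: composing
        their probability gradient with the sigmoid derivative underflows to
        zero exactly when the network saturates, which is when the gradient
        is needed most.
        """
        skip_grads = []  # filled shallow-to-deep as the decoder unwinds
        dy = self.head.backward(dlogits)
        for up, blk in zip(reversed(self.ups), reversed(self.dec)):
            dy = blk.backward(dy)
            c = up.W.value.shape[1]  # skip half | upsampled half
            dskip, dup = dy[:, :c], dy[:, c:]
            dy = up.backward(dup)
            skip_grads.append(dskip)
        dy = self.bottleneck.backward(dy)
        # encoder unwinds deep-to-shallow, so pair with skip grads reversed
        for blk, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(skip_grads)
        ):
            dy = pool.backward(dy) + dskip
            dy = blk.backward(dy)

    def loss_and_grad(self, x: np.ndarray, target: np.ndarray) -> float:
        """Soft-dice loss of forward(x) vs target; accumulates param grads."""
        probs = self.forward(x)
        loss, dprobs = soft_dice_loss(probs, target)
        self.backward(dprobs)
        return loss


def soft_dice_loss(
    probs: np.ndarray, target: np.ndarray, smooth: float = 1.0
) -> tuple[float, np.ndarray]:
    """Mean per-item soft dice loss and its gradient w.r.t. probs.

    Per item: ``1 - (2·Σpg + s) / (Σp + Σg + s)``; the smoothing constant
    makes empty-target items well behaved (loss → 0 as probs → 0).
    """
    if probs.shape != target.shape:
        raise ValueError("probs and target shapes differ")
    n = probs.shape[0]
    axes = tuple(range(1, probs.ndim))
    g = np.asarray(target, dtype=np.float64)
    inter = (probs * g).sum(axis=axes)
    denom = probs.sum(axis=axes) + g.sum(axis=axes) + smooth
    num = 2.0 * inter + smooth
    loss = float(np.mean(1.0 - num / denom))
    # d/dp of -(num/denom), broadcast per item, averaged over the batch
    shape = (n,) + (1,) * (probs.ndim - 1)
    dprobs = -(2.0 * g * denom.reshape(shape) - num.reshape(shape)) / (
        denom.reshape(shape) ** 2
    )
    return loss, dprobs / n


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
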