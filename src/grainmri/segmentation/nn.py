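"""A compact encoder-decoder CNN (U-Net style) in pure numpy.

Architecture: three resolution levels with a constant channel width,
two 3x3 conv + ReLU blocks per level, 2x2 max pooling, nearest-neighbour
upsampling followed by convolution, skip connections by concatenation, and
a 1x1 convolution to the 5 class scores.  Convolutions run as im2col +
matmul; gradients are propagated analytically layer by layer and updated
with Adam.  Deliberately small: it trains on a CPU in minutes at phantom
scale while keeping the published recipe (Adam, cross-entropy, best-epoch
selection) intact.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, ksize: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) with same-size zero padding."""
    n, c, h, w = x.shape
    if ksize == 1:
        return x.reshape(n, c, h * w)
    pad = ksize // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (ksize, ksize), axis=(2, 3))  # (N,C,H,W,k,k)
    return np.ascontiguousarray(
        win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * ksize * ksize, h * w))


class Conv2d:
    """Same-padding 2D convolution with bias."""

    def __init__(self, in_ch, out_ch, ksize, rng):
        fan_in = in_ch * ksize * ksize
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (out_ch, in_ch, ksize, ksize)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.ksize = ksize
        self._cache = None
        self.dW = None
        self.db = None

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        cols = _im2col(x, self.ksize)
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = np.matmul(wmat[None], cols) + self.b[None, :, None]
        if train:
            self._cache = (cols, (n, c, h, w))
        return out.reshape(n, self.W.shape[0], h, w)

    def backward(self, grad):
        cols, (n, c, h, w) = self._cache
        self._cache = None
        out_ch = self.W.shape[0]
        g = grad.reshape(n, out_ch, h * w)
        self.dW = np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0).reshape(self.W.shape)
        self.db = g.sum(axis=(0, 2))
        # dx = convolution of grad with the spatially flipped, channel-swapped kernel
        if self.ksize == 1:
            wback = self.W.reshape(out_ch, c).T.reshape(c, out_ch, 1, 1)
        else:
            wback = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        gcols = _im2col(g.reshape(n, out_ch, h, w), self.ksize)
        dx = np.matmul(wback.reshape(c, -1)[None], gcols)
        return dx.reshape(n, c, h, w)

    def params(self):
        return [("W", self), ("b", self)]


class ReLU:
    def forward(self, x, train=True):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2:
    """2x2 max pooling with argmax routing on the backward pass."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        if train:
            self._idx, self._shape = idx, (n, c, h, w)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(out, self._idx[..., None], grad[..., None], axis=-1)
        return (out.reshape(n, c, h // 2, w // 2, 2, 2)
                   .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w))


class Upsample2:
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x, train=True):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet2D:
    """Three-level U-Net with constant channel width and 5-class output."""

    def __init__(self, in_channels, n_classes=5, channels=64, seed=0):
        rng = np.random.default_rng(seed)
        c = channels
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.channels = channels
        self.e1a, self.e1b = Conv2d(in_channels, c, 3, rng), Conv2d(c, c, 3, rng)
        self.e2a, self.e2b = Conv2d(c, c, 3, rng), Conv2d(c, c, 3, rng)
        self.ba, self.bb = Conv2d(c, c, 3, rng), Conv2d(c, c, 3, rng)
        self.d2a, self.d2b = Conv2d(2 * c, c, 3, rng), Conv2d(c, c, 3, rng)
        self.d1a, self.d1b = Conv2d(2 * c, c, 3, rng), Conv2d(c, c, 3, rng)
        self.out = Conv2d(c, n_classes, 1, rng)
        self._relus = [ReLU() for _ in range(10)]
        self._pools = [MaxPool2(), MaxPool2()]
        self._ups = [Upsample2(), Upsample2()]

    @property
    def convs(self):
        return [self.e1a, self.e1b, self.e2a, self.e2b, self.ba, self.bb,
                self.d2a, self.d2b, self.d1a, self.d1b, self.out]

    def forward(self, x, train=True):
        r = self._relus
        s1 = r[1].forward(self.e1b.forward(r[0].forward(self.e1a.forward(x, train), train), train), train)
        p1 = self._pools[0].forward(s1, train)
        s2 = r[3].forward(self.e2b.forward(r[2].forward(self.e2a.forward(p1, train), train), train), train)
        p2 = self._pools[1].forward(s2, train)
        b = r[5].forward(self.bb.forward(r[4].forward(self.ba.forward(p2, train), train), train), train)
        u2 = np.concatenate([self._ups[0].forward(b, train), s2], axis=1)
        d2 = r[7].forward(self.d2b.forward(r[6].forward(self.d2a.forward(u2, train), train), train), train)
        u1 = np.concatenate([self._ups[1].forward(d2, train), s1], axis=1)
        d1 = r[9].forward(self.d1b.forward(r[8].forward(self.d1a.forward(u1, train), train), train), train)
        return self.out.forward(d1, train)

    def backward(self, grad):
        c = self.channels
        r = self._relus
        g = self.out.backward(grad)
        g = self.d1a.backward(r[8].backward(self.d1b.backward(r[9].backward(g))))
        g_up1, g_s1 = g[:, :c], g[:, c:]
        g = self._ups[1].backward(g_up1)
        g = self.d2a.backward(r[6].backward(self.d2b.backward(r[7].backward(g))))
        g_up2, g_s2 = g[:, :c], g[:, c:]
        g = self._ups[0].backward(g_up2)
        g = self.ba.backward(r[4].backward(self.bb.backward(r[5].backward(g))))
        g = self._pools[1].backward(g) + g_s2
        g = self.e2a.backward(r[2].backward(self.e2b.backward(r[3].backward(g))))
        g = self._pools[0].backward(g) + g_s1
        self.e1a.backward(r[0].backward(self.e1b.backward(r[1].backward(g))))

    def get_weights(self):
        return [(conv.W.copy(), conv.b.copy()) for conv in self.convs]

    def set_weights(self, weights):
        for conv, (w, b) in zip(self.convs, weights):
            conv.W = w.copy()
            conv.b = b.copy()


class Adam:
    """Adam optimizer over all convolution parameters of a UNet2D."""

    def __init__(self, net: UNet2D, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.m = [(np.zeros_like(c.W), np.zeros_like(c.b)) for c in net.convs]
        self.v = [(np.zeros_like(c.W), np.zeros_like(c.b)) for c in net.convs]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for conv, (mw, mb), (vw, vb) in zip(self.net.convs, self.m, self.v):
            for param, grad, m, v in ((conv.W, conv.dW, mw, vw), (conv.b, conv.db, mb, vb)):
                m *= self.b1
                m += (1 - self.b1) * grad
                v *= self.b2
                v += (1 - self.b2) * grad * grad
                param -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax_cross_entropy(logits, targets, class_weights=None):
    """Mean cross-entropy over all pixels; returns (loss, dlogits).

    ``logits`` is (N, K, H, W), ``targets`` (N, H, W) integer classes.
    """
    n, k, h, w = logits.shape
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    probs = e / e.sum(axis=1, keepdims=True)
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, targets[:, None], 1.0, axis=1)
    logp = np.log(np.take_along_axis(probs, targets[:, None], axis=1)[:, 0] + 1e-12)
    if class_weights is not None:
        wmap = np.asarray(class_weights, dtype=np.float32)[targets]
        total = wmap.sum()
        loss = -(wmap * logp).sum() / total
        grad = (probs - onehot) * wmap[:, None] / total
    else:
        total = n * h * w
        loss = -logp.sum() / total
        grad = (probs - onehot) / total
    return float(loss), grad.astype(logits.dtype)
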