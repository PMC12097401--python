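"""Minimal CPU conv-net engine (float32, NCHW) with manual backprop.

Layers expose ``forward(x, train)`` and ``backward(dy)``; trainable arrays
live in ``.params`` with matching ``.grads``. The networks used by the
repair and detection stages are composed from these layers explicitly so
skip connections and multi-branch heads stay easy to differentiate by hand.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


# ---------------------------------------------------------------------------
# im2col helpers

def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """(B,C,H,W) -> (B, C*k*k, Ho*Wo) patch matrix."""
    xp = _pad(x, pad)
    b, c, h, w = xp.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    sb, sc, sh, sw = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, c, k, k, ho, wo),
        strides=(sb, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    )
    return np.ascontiguousarray(cols).reshape(b, c * k * k, ho * wo), ho, wo


def col2im(cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of im2col: scatter-add patches back to (B,C,H,W)."""
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    cols = cols.reshape(b, c, k, k, ho, wo)
    out = np.zeros((b, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


# ---------------------------------------------------------------------------
# layers

class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, cin, cout, k, stride=1, pad=0, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin * k * k))
        self.w = w.astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._xshape = x.shape
        cols, ho, wo = im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        out = np.einsum("ok,bkn->bon", self.w, cols, optimize=True)
        out += self.b[None, :, None]
        return out.reshape(x.shape[0], self.cout, ho, wo)

    def backward(self, dy):
        b, _, ho, wo = dy.shape
        dyf = dy.reshape(b, self.cout, ho * wo)
        self.grads[0] += np.einsum("bon,bkn->ok", dyf, self._cols, optimize=True)
        self.grads[1] += dyf.sum(axis=(0, 2))
        dcols = np.einsum("ok,bon->bkn", self.w, dyf, optimize=True)
        return col2im(dcols, self._xshape, self.k, self.stride, self.pad)


class DepthwiseConv2d(Layer):
    """Per-channel k x k convolution (stride 1, same padding)."""

    def __init__(self, c, k, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.w = rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(c, k * k)).astype(F32)
        self.b = np.zeros(c, dtype=F32)
        self.c, self.k = c, k
        self.pad = k // 2
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._xshape = x.shape
        bsz, c, h, w = x.shape
        xp = _pad(x, self.pad)
        sb, sc, sh, sw = xp.strides
        k = self.k
        patches = np.lib.stride_tricks.as_strided(
            xp, shape=(bsz, c, k, k, h, w), strides=(sb, sc, sh, sw, sh, sw),
            writeable=False)
        self._patches = np.ascontiguousarray(patches).reshape(bsz, c, k * k, h * w)
        out = np.einsum("bckn,ck->bcn", self._patches, self.w, optimize=True)
        out += self.b[None, :, None]
        return out.reshape(bsz, c, h, w)

    def backward(self, dy):
        bsz, c, h, w = dy.shape
        dyf = dy.reshape(bsz, c, h * w)
        self.grads[0] += np.einsum("bcn,bckn->ck", dyf, self._patches, optimize=True)
        self.grads[1] += dyf.sum(axis=(0, 2))
        dpatch = np.einsum("bcn,ck->bckn", dyf, self.w, optimize=True)
        dpatch = dpatch.reshape(bsz * c, self.k * self.k, h * w)
        out = col2im(dpatch[:, None].reshape(bsz * c, 1 * self.k * self.k, h * w),
                     (bsz * c, 1, h, w), self.k, 1, self.pad)
        return out.reshape(self._xshape)


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=False):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, dy):
        return np.where(self._neg, self.slope * dy, dy)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._neg = x < 0
        return np.where(self._neg, 0.0, x).astype(F32)

    def backward(self, dy):
        return np.where(self._neg, 0.0, dy).astype(F32)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p, rng):
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(F32) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        b, c, h, w = dy.shape
        return dy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def _resize_matrix(n_out: int, n_in: int, mode: str = "bilinear") -> np.ndarray:
    """Interpolation matrix (n_out, n_in).

    bilinear: 2-tap, half-pixel centres (for upsampling). area: exact
    box-overlap averaging, so every input pixel contributes to the output
    cell(s) covering it — the right pooling when downscaling feature maps
    onto label-grid cells, where thin-structure evidence must not be
    skipped over."""
    m = np.zeros((n_out, n_in), dtype=F32)
    if mode == "area":
        span = n_in / n_out
        for o in range(n_out):
            lo, hi = o * span, (o + 1) * span
            for i in range(int(np.floor(lo)), min(int(np.ceil(hi)), n_in)):
                m[o, i] = (min(hi, i + 1) - max(lo, i)) / span
        return m
    for o in range(n_out):
        src = (o + 0.5) * n_in / n_out - 0.5
        i0 = int(np.floor(src))
        t = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        m[o, i0c] += 1.0 - t
        m[o, i1c] += t
    return m


class BilinearResize(Layer):
    """Fixed resize to (h_out, w_out) as two matrix products."""

    def __init__(self, h_in, w_in, h_out, w_out, mode: str = "bilinear"):
        super().__init__()
        self.ar = _resize_matrix(h_out, h_in, mode)
        self.ac = _resize_matrix(w_out, w_in, mode)

    def forward(self, x, train=False):
        return np.einsum("oh,bchw,pw->bcop", self.ar, x, self.ac, optimize=True)

    def backward(self, dy):
        return np.einsum("oh,bcop,pw->bchw", self.ar, dy, self.ac, optimize=True)


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for l in self.layers:
            self.params += l.params
            self.grads += l.grads

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# optimiser

class Adam:
    def __init__(self, params, grads, lr=1e-3, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1.0 - self.b1) * g
            v[...] = self.b2 * v + (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# networks

class UNetGenerator:
    """Strided-conv encoder / nearest-upsample decoder with skips at two scales.

    Input: (B, cin, H, W) occluded stack; output: (B, 1, H, W) in (0,1).
    """

    def __init__(self, cin, base=8, dropout=0.5, rng=None):
        rng = rng or np.random.default_rng()
        b = base
        self.c0 = Sequential(Conv2d(cin, b, 3, 1, 1, rng), LeakyReLU())
        self.d1 = Sequential(Conv2d(b, 2 * b, 3, 2, 1, rng), LeakyReLU())
        self.c1 = Sequential(Conv2d(2 * b, 2 * b, 3, 1, 1, rng), LeakyReLU())
        self.d2 = Sequential(Conv2d(2 * b, 4 * b, 3, 2, 1, rng), LeakyReLU())
        self.c2 = Sequential(Conv2d(4 * b, 4 * b, 3, 1, 1, rng), LeakyReLU(),
                             Dropout(dropout, rng))
        self.u1 = Sequential(Upsample2x(), Conv2d(4 * b, 2 * b, 3, 1, 1, rng), LeakyReLU())
        self.f1 = Sequential(Conv2d(4 * b, 2 * b, 3, 1, 1, rng), LeakyReLU())
        self.u2 = Sequential(Upsample2x(), Conv2d(2 * b, b, 3, 1, 1, rng), LeakyReLU())
        self.f2 = Sequential(Conv2d(2 * b, b, 3, 1, 1, rng), LeakyReLU())
        self.out = Sequential(Conv2d(b, 1, 3, 1, 1, rng), Sigmoid())
        self._parts = [self.c0, self.d1, self.c1, self.d2, self.c2,
                       self.u1, self.f1, self.u2, self.f2, self.out]
        self.params = sum((p.params for p in self._parts), [])
        self.grads = sum((p.grads for p in self._parts), [])
        self.nbase = b

    def forward(self, x, train=False):
        a0 = self.c0.forward(x, train)
        a1 = self.c1.forward(self.d1.forward(a0, train), train)
        a2 = self.c2.forward(self.d2.forward(a1, train), train)
        u1 = self.u1.forward(a2, train)
        m1 = self.f1.forward(np.concatenate([u1, a1], axis=1), train)
        u2 = self.u2.forward(m1, train)
        m2 = self.f2.forward(np.concatenate([u2, a0], axis=1), train)
        return self.out.forward(m2, train)

    def backward(self, dy):
        b2 = self.nbase * 2
        dm2 = self.out.backward(dy)
        dcat2 = self.f2.backward(dm2)
        du2, da0_skip = dcat2[:, :self.nbase], dcat2[:, self.nbase:]
        dm1 = self.u2.backward(du2)
        dcat1 = self.f1.backward(dm1)
        du1, da1_skip = dcat1[:, :b2], dcat1[:, b2:]
        da2 = self.u1.backward(du1)
        da1 = self.d2.backward(self.c2.backward(da2)) + da1_skip
        da0 = self.d1.backward(self.c1.backward(da1)) + da0_skip
        return self.c0.backward(da0)


class PatchDiscriminator:
    """Three-stride conv stack emitting a patch logit map."""

    def __init__(self, cin=1, base=8, dropout=0.0, rng=None):
        rng = rng or np.random.default_rng()
        b = base
        self.net = Sequential(
            Conv2d(cin, b, 3, 2, 1, rng), LeakyReLU(),
            Conv2d(b, 2 * b, 3, 2, 1, rng), LeakyReLU(),
            Dropout(dropout, rng),
            Conv2d(2 * b, 2 * b, 3, 2, 1, rng), LeakyReLU(),
            Conv2d(2 * b, 1, 3, 1, 1, rng),
        )
        self.params, self.grads = self.net.params, self.net.grads

    def forward(self, x, train=False):
        return self.net.forward(x, train)

    def backward(self, dy):
        return self.net.backward(dy)


class RandomFeatureNet:
    """Small frozen conv feature extractor for the perceptual loss.

    Weights are drawn once from the given seed and never trained; random
    convolutional features preserve enough image geometry to make a useful
    perceptual distance at desk scale.
    """

    def __init__(self, seed=0, cin=1):
        rng = np.random.default_rng(seed)
        self.l1 = Sequential(Conv2d(cin, 8, 3, 1, 1, rng), ReLU())
        self.pool = Conv2dFixedAvg(8)
        self.l2 = Sequential(Conv2d(8, 16, 3, 1, 1, rng), ReLU())

    def features(self, x):
        f1 = self.l1.forward(x)
        f2 = self.l2.forward(self.pool.forward(f1))
        return [f1, f2]

    def backward_to_input(self, dfs):
        """Input gradient given grads on each feature map (params frozen)."""
        d1 = self.l1.backward(dfs[0] + self.pool.backward(self.l2.backward(dfs[1])))
        for g in self.l1.grads + self.l2.grads:
            g[...] = 0.0
        return d1


class Conv2dFixedAvg(Layer):
    """2x2 mean pooling (as a fixed linear map)."""

    def __init__(self, c):
        super().__init__()
        self.c = c

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy):
        return (dy[:, :, :, None, :, None] / 4.0 * np.ones((1, 1, 1, 2, 1, 2), dtype=F32)
                ).reshape(self._shape)


class ConvNeXtBlock:
    """Depthwise 7x7 -> pointwise 4x expand -> ReLU -> pointwise back,
    layer-scaled residual."""

    def __init__(self, c, rng, layer_scale=1e-1):
        self.dw = DepthwiseConv2d(c, 7, rng)
        self.pw1 = Conv2d(c, 4 * c, 1, 1, 0, rng)
        self.act = ReLU()
        self.pw2 = Conv2d(4 * c, c, 1, 1, 0, rng)
        self.gamma = np.full((c,), layer_scale, dtype=F32)
        self.ggrad = np.zeros_like(self.gamma)
        self.params = self.dw.params + self.pw1.params + self.pw2.params + [self.gamma]
        self.grads = self.dw.grads + self.pw1.grads + self.pw2.grads + [self.ggrad]

    def forward(self, x, train=False):
        self._x = x
        h = self.pw2.forward(self.act.forward(self.pw1.forward(self.dw.forward(x))))
        self._h = h
        return x + self.gamma[None, :, None, None] * h

    def backward(self, dy):
        self.ggrad += np.einsum("bchw,bchw->c", dy, self._h, optimize=True)
        dh = dy * self.gamma[None, :, None, None]
        dx = self.dw.backward(self.pw1.backward(self.act.backward(self.pw2.backward(dh))))
        return dy + dx


class ConvNeXtFPNDetector:
    """Three-stage ConvNeXt-style backbone + FPN head emitting a grid logit map.

    Each pyramid level is laterally projected, fused top-down, resized to the
    label grid, 1x1-projected, and the concatenation is reduced to one logit
    per grid cell — the map has "the same size as the labels".
    """

    def __init__(self, cin=2, widths=(32, 64, 128), input_size=64, grid=9,
                 dropout=0.5, stem_stride=4, rng=None):
        rng = rng or np.random.default_rng()
        w1, w2, w3 = widths
        s = input_size // stem_stride
        self.stem = Conv2d(cin, w1, stem_stride, stem_stride, 0, rng)
        self.stage1 = ConvNeXtBlock(w1, rng)
        self.down2 = Conv2d(w1, w2, 2, 2, 0, rng)
        self.stage2 = ConvNeXtBlock(w2, rng)
        self.down3 = Conv2d(w2, w3, 2, 2, 0, rng)
        self.stage3 = ConvNeXtBlock(w3, rng)
        fc = 32  # FPN channel width
        self.lat1 = Conv2d(w1, fc, 1, 1, 0, rng)
        self.lat2 = Conv2d(w2, fc, 1, 1, 0, rng)
        self.lat3 = Conv2d(w3, fc, 1, 1, 0, rng)
        self.up32 = Upsample2x()
        self.up21 = Upsample2x()
        self.rs1 = BilinearResize(s, s, grid, grid, mode="area")
        self.rs2 = BilinearResize(s // 2, s // 2, grid, grid, mode="area")
        self.rs3 = BilinearResize(s // 4, s // 4, grid, grid, mode="area")
        self.proj1 = Conv2d(fc, 8, 1, 1, 0, rng)
        self.proj2 = Conv2d(fc, 8, 1, 1, 0, rng)
        self.proj3 = Conv2d(fc, 8, 1, 1, 0, rng)
        self.drop = Dropout(dropout, rng)
        self.head = Conv2d(24, 1, 1, 1, 0, rng)
        self._parts = [self.stem, self.stage1, self.down2, self.stage2, self.down3,
                       self.stage3, self.lat1, self.lat2, self.lat3,
                       self.proj1, self.proj2, self.proj3, self.head]
        self.params = sum((p.params for p in self._parts), [])
        self.grads = sum((p.grads for p in self._parts), [])

    def forward(self, x, train=False):
        c1 = self.stage1.forward(self.stem.forward(x), train)
        c2 = self.stage2.forward(self.down2.forward(c1), train)
        c3 = self.stage3.forward(self.down3.forward(c2), train)
        p3 = self.lat3.forward(c3)
        p2 = self.lat2.forward(c2) + self.up32.forward(p3)
        p1 = self.lat1.forward(c1) + self.up21.forward(p2)
        g1 = self.proj1.forward(self.rs1.forward(p1))
        g2 = self.proj2.forward(self.rs2.forward(p2))
        g3 = self.proj3.forward(self.rs3.forward(p3))
        cat = np.concatenate([g1, g2, g3], axis=1)
        return self.head.forward(self.drop.forward(cat, train))[:, 0]

    def backward(self, dy):
        return detector_backward(self, dy)


def detector_backward(net: ConvNeXtFPNDetector, dy: np.ndarray) -> np.ndarray:
    """FPN gradients: lateral paths and the top-down chain both feed the backbone."""
    dcat = net.drop.backward(net.head.backward(dy[:, None]))
    dp1 = net.rs1.backward(net.proj1.backward(dcat[:, :8]))
    dp2 = net.rs2.backward(net.proj2.backward(dcat[:, 8:16]))
    dp3 = net.rs3.backward(net.proj3.backward(dcat[:, 16:]))
    dp2 = dp2 + net.up21.backward(dp1)
    dp3 = dp3 + net.up32.backward(dp2)
    dc1 = net.lat1.backward(dp1)
    dc2 = net.lat2.backward(dp2)
    dc3 = net.lat3.backward(dp3)
    dc2 = dc2 + net.down3.backward(net.stage3.backward(dc3))
    dc1 = dc1 + net.down2.backward(net.stage2.backward(dc2))
    return net.stem.backward(net.stage1.backward(dc1))


def zero_grads(net) -> None:
    for g in net.grads:
        g[...] = 0.0


def get_state(net) -> list[np.ndarray]:
    return [p.copy() for p in net.params]


def set_state(net, state) -> None:
    for p, s in zip(net.params, state):
        p[...] = s
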