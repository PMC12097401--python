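"""Auxiliary conditioning channels for the repair model.

Two channels accompany each crop into the inpainting network: an edge map
(Canny or Sobel baselines, or a small trainable multi-scale edge net fitted
to phantom cortex geometry) and a high-frequency texture map obtained by a
Gaussian high-pass filter in the 2-D Fourier domain,

    H(u, v) = 1 - exp(-d(u, v)^2 / (2 lambda^2)),

with d the Euclidean distance from the centred DC component and lambda = 10
(dimensionless frequency-distance units). The filtered spectrum is
inverse-transformed, the magnitude kept, and min-max normalized to [0,1] so
channels are comparable across crops. Normal cortical margins produce
strong responses in both channels; hairline cracks are deliberately near or
below the edge detector's threshold — subtlety is the regime of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import feature as _skfeature
from skimage import filters as _skfilters

__all__ = ["HighPassFilterSpec", "AuxChannels", "edge_map", "highfreq_texture",
           "compose_aux", "gaussian_highpass", "ideal_highpass"]


@dataclass(frozen=True)
class HighPassFilterSpec:
    lam: float = 10.0      # cutoff constant, frequency-distance units
    centered: bool = True  # DC at array centre
    transfer: str = "gaussian"  # or "ideal" (hard cutoff)

    def validate(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")


@dataclass(frozen=True)
class AuxChannels:
    edge: np.ndarray
    texture: np.ndarray
    edge_method: str
    texture_method: str


def gaussian_highpass(d: np.ndarray, lam: float) -> np.ndarray:
    return 1.0 - np.exp(-(d ** 2) / (2.0 * lam ** 2))


def ideal_highpass(d: np.ndarray, lam: float) -> np.ndarray:
    return (d > lam).astype(np.float64)


_TRANSFERS = {"gaussian": gaussian_highpass, "ideal": ideal_highpass}


def _dc_distance(shape, centered: bool) -> np.ndarray:
    m, n = shape
    u = np.arange(m, dtype=np.float64)
    v = np.arange(n, dtype=np.float64)
    if centered:
        u -= m // 2
        v -= n // 2
    else:  # distance in unshifted FFT index space (wrap-around)
        u = np.minimum(u, m - u)
        v = np.minimum(v, n - v)
    return np.hypot(u[:, None], v[None, :])


def highfreq_texture(crop: np.ndarray, filt: HighPassFilterSpec = HighPassFilterSpec(),
                     normalize: bool = True) -> np.ndarray:
    """High-frequency texture map: FFT -> high-pass -> inverse FFT -> |.|.

    With ``normalize`` the map is min-max scaled to [0,1]; without it the raw
    magnitude is returned (a constant image then comes back ~0 everywhere,
    since the filter fully suppresses the DC component).
    """
    filt.validate()
    x = np.asarray(crop, dtype=np.float64)
    spec = np.fft.fft2(x)
    if filt.centered:
        spec = np.fft.fftshift(spec)
    h = _TRANSFERS[filt.transfer](_dc_distance(x.shape, filt.centered), filt.lam)
    spec = spec * h
    if filt.centered:
        spec = np.fft.ifftshift(spec)
    out = np.abs(np.fft.ifft2(spec))
    if normalize:
        lo, hi = out.min(), out.max()
        out = (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)
    return out.astype(np.float32)


def edge_map(crop: np.ndarray, method: str = "canny", *, sigma: float = 1.0,
             low: float = 0.10, high: float = 0.25, model=None) -> np.ndarray:
    """Edge channel in [0,1].

    canny: binary {0,1} map (thresholds on the gradient magnitude, relative
    to the intensity range); sobel: gradient magnitude scaled to [0,1];
    learned: a trained multi-scale edge net (see ``train_edge_model``).
    """
    x = np.asarray(crop, dtype=np.float64)
    if method == "canny":
        e = _skfeature.canny(x, sigma=sigma, low_threshold=low, high_threshold=high)
        return e.astype(np.float32)
    if method == "sobel":
        g = _skfilters.sobel(x)
        mx = g.max()
        return (g / mx if mx > 0 else g).astype(np.float32)
    if method == "learned":
        if model is None:
            raise ValueError("edge method 'learned' requires a trained edge model")
        return model.predict(x)
    raise ValueError(f"unknown edge method {method!r}")


def compose_aux(crop: np.ndarray, edge_method: str = "canny",
                filt: HighPassFilterSpec | None = HighPassFilterSpec(),
                edge_model=None, **edge_kw) -> AuxChannels:
    """Bundle the conditioning stack; either component can be ablated.

    ``edge_method=None`` zeroes the edge channel; ``filt=None`` zeroes the
    texture channel (both flagged in the method tags)."""
    if edge_method is None:
        edge = np.zeros_like(crop, dtype=np.float32)
        etag = "none"
    else:
        edge = edge_map(crop, edge_method, model=edge_model, **edge_kw)
        etag = edge_method
    if filt is None:
        tex = np.zeros_like(crop, dtype=np.float32)
        ttag = "none"
    else:
        tex = highfreq_texture(crop, filt)
        ttag = f"{filt.transfer}-highpass(lambda={filt.lam:g})"
    return AuxChannels(edge=edge, texture=tex, edge_method=etag, texture_method=ttag)


class LearnedEdgeModel:
    """Small multi-scale side-output edge net trained on phantom geometry.

    A desk-scale stand-in for a pretrained holistic edge detector: two conv
    scales each emit a side output; the fused sigmoid map is trained with BCE
    against edge labels rasterized from phantom cortex-edge records.
    """

    def __init__(self, seed: int = 0):
        from . import _nn
        rng = np.random.default_rng(seed)
        self.b1 = _nn.Sequential(_nn.Conv2d(1, 8, 3, 1, 1, rng), _nn.ReLU(),
                                 _nn.Conv2d(8, 8, 3, 1, 1, rng), _nn.ReLU())
        self.side1 = _nn.Conv2d(8, 1, 1, 1, 0, rng)
        self.down = _nn.Conv2d(8, 16, 3, 2, 1, rng)
        self.b2 = _nn.Sequential(_nn.ReLU(), _nn.Conv2d(16, 16, 3, 1, 1, rng), _nn.ReLU())
        self.side2 = _nn.Conv2d(16, 1, 1, 1, 0, rng)
        self.up = _nn.Upsample2x()
        self._parts = [self.b1, self.side1, self.down, self.b2, self.side2]
        self.params = sum((p.params for p in self._parts), [])
        self.grads = sum((p.grads for p in self._parts), [])

    def _logits(self, x4, train=False):
        f1 = self.b1.forward(x4, train)
        s1 = self.side1.forward(f1)
        f2 = self.b2.forward(self.down.forward(f1), train)
        s2 = self.up.forward(self.side2.forward(f2))
        return s1 + s2

    def predict(self, img: np.ndarray) -> np.ndarray:
        x = img[None, None].astype(np.float32)
        z = self._logits(x, train=False)[0, 0]
        return (1.0 / (1.0 + np.exp(-z))).astype(np.float32)


def rasterize_edge_label(geometry: dict, size: int) -> np.ndarray:
    """Binary cortex-edge label from a phantom geometry record."""
    lab = np.zeros((size, size), dtype=np.float32)
    rows = np.arange(size)
    for k in range(4):
        cols = np.round(geometry["cortex_edges"][:, k]).astype(int)
        ok = (cols >= 0) & (cols < size)
        lab[rows[ok], cols[ok]] = 1.0
    return lab


def train_edge_model(images, labels, seed: int = 0, epochs: int = 20,
                     lr: float = 1e-3) -> LearnedEdgeModel:
    """Fit the edge net with pixelwise BCE (positive pixels up-weighted by
    the inverse class frequency)."""
    from . import _nn
    model = LearnedEdgeModel(seed=seed)
    opt = _nn.Adam(model.params, model.grads, lr=lr, beta1=0.9)
    x = np.stack(images)[:, None].astype(np.float32)
    y = np.stack(labels)[:, None].astype(np.float32)
    pos_w = max(1.0, float((1.0 - y.mean()) / max(y.mean(), 1e-6)))
    rng = np.random.default_rng(seed)
    for _ in range(epochs):
        order = rng.permutation(len(x))
        for i in range(0, len(x), 8):
            idx = order[i:i + 8]
            xb, yb = x[idx], y[idx]
            opt.zero_grad()
            z = model._logits(xb, train=True)
            p = 1.0 / (1.0 + np.exp(-z))
            w = np.where(yb > 0.5, pos_w, 1.0).astype(np.float32)
            dz = (w * (p - yb) / z.size).astype(np.float32)
            d1 = dz
            ds2 = model.up.backward(dz)
            df2 = model.b2.backward(model.side2.backward(ds2))
            df1 = model.side1.backward(d1) + model.down.backward(df2)
            model.b1.backward(df1)
            opt.step()
    return model
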