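"""Patch-grid fracture detection from (crop, residual) pairs.

The crop and its reconstruction residual are stacked as input channels to a
small ConvNeXt-style backbone whose multi-scale features are fused by a
feature-pyramid head into a 9x9 logit map — one logit per grid cell, the
same size as the labels. Ground-truth cell values are the exact pixel
overlap fraction of cell x fracture-bbox x repair-mask; since ~95% of cells
are background, training uses a weighted binary cross-entropy whose weight
rho is the per-image fraction of non-fracture cells:

    L = -(1/N) sum_ij [ rho * y * log p + (1 - rho) * (1 - y) * log(1 - p) ]

with p = sigmoid(logit), so the rare fracture cells are up-weighted by the
imbalance itself.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import _nn

__all__ = [
    "GridGeometry", "PatchGrid", "DetectorConfig", "DetectorModel",
    "ImageDecision", "grid_label", "wbce_loss", "wbce_grad",
    "train_detector", "predict_grid", "image_decision", "heatmap",
    "save_detector", "load_detector",
]

_EPS = 1e-7


@dataclass(frozen=True)
class GridGeometry:
    """Cells tile the full crop: base cell = size // n, last row/col absorb
    the remainder (28 px cells with a 32 px last cell at 256)."""

    crop_size: int = 256
    n: int = 9

    @property
    def edges(self) -> np.ndarray:
        base = self.crop_size // self.n
        e = np.arange(self.n + 1) * base
        e[-1] = self.crop_size
        return e

    def cell_areas(self) -> np.ndarray:
        e = self.edges
        d = np.diff(e)
        return d[:, None] * d[None, :]


@dataclass
class PatchGrid:
    values: np.ndarray  # (n, n)
    kind: str           # label | logit | probability
    geometry: GridGeometry

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.geometry.n, self.geometry.n):
            raise ValueError("grid shape does not match geometry")
        if self.kind in ("label", "probability") and (
                self.values.min() < 0 or self.values.max() > 1):
            raise ValueError(f"{self.kind} grid values must lie in [0,1]")

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "values": self.values.tolist(),
                           "crop_size": self.geometry.crop_size,
                           "n": self.geometry.n})


@dataclass(frozen=True)
class ImageDecision:
    score: float
    is_fracture: bool
    threshold: float


# ---------------------------------------------------------------------------
# labels

def grid_label(ann, repair_mask: np.ndarray,
               geometry: GridGeometry | None = None) -> PatchGrid:
    """Per-cell overlap fraction |cell ∩ bbox ∩ repair-mask| / |cell| by
    exact pixel counting. Healthy images (or a bbox entirely outside the
    crop) give the all-zero grid."""
    size = repair_mask.shape[0]
    geometry = geometry or GridGeometry(crop_size=size)
    if geometry.crop_size != size:
        raise ValueError("geometry does not match the repair mask")
    vals = np.zeros((geometry.n, geometry.n), dtype=np.float64)
    if ann.present and ann.bbox is not None:
        r0, c0, r1, c1 = ann.bbox
        if r1 > 0 and c1 > 0 and r0 < size and c0 < size:
            member = np.zeros((size, size), dtype=bool)
            member[max(r0, 0):min(r1, size), max(c0, 0):min(c1, size)] = True
            member &= repair_mask > 0
            e = geometry.edges
            counts = np.add.reduceat(np.add.reduceat(member.astype(np.int64),
                                                     e[:-1], axis=0), e[:-1], axis=1)
            vals = counts / geometry.cell_areas()
    return PatchGrid(values=vals, kind="label", geometry=geometry)


# ---------------------------------------------------------------------------
# loss

def _binarize(gt: np.ndarray, binarize_at: float) -> np.ndarray:
    return (np.asarray(gt, dtype=np.float64) >= binarize_at).astype(np.float64)


def wbce_loss(logits: np.ndarray, gt: np.ndarray,
              binarize_at: float = 1e-9, rho: float | None = None) -> float:
    """Weighted BCE on a grid of any shape; rho (the non-fracture cell
    fraction) is computed per image unless given explicitly. The default
    ``binarize_at`` makes any nonzero overlap a positive cell.

    Note the all-negative degeneracy: a grid with no fracture cells has
    rho = 1, which zeroes the negative-class weight and with it the whole
    loss. Training therefore passes the dataset-level rho explicitly for
    such images (see ``train_detector``); as a standalone scoring function
    the per-image formula is used verbatim."""
    z = np.asarray(logits, dtype=np.float64)
    if np.isnan(z).all():
        raise ValueError("all-NaN logits")
    y = _binarize(gt, binarize_at)
    ncells = y.size
    if rho is None:
        rho = float((ncells - y.sum()) / ncells)
    p = np.clip(1.0 / (1.0 + np.exp(-z)), _EPS, 1.0 - _EPS)
    terms = rho * y * np.log(p) + (1.0 - rho) * (1.0 - y) * np.log(1.0 - p)
    return float(-terms.sum() / ncells)


def wbce_grad(logits: np.ndarray, gt: np.ndarray,
              binarize_at: float = 1e-9, rho: float | None = None) -> np.ndarray:
    """dL/dlogits for one grid (matches ``wbce_loss``)."""
    z = np.asarray(logits, dtype=np.float64)
    y = _binarize(gt, binarize_at)
    ncells = y.size
    if rho is None:
        rho = float((ncells - y.sum()) / ncells)
    p = np.clip(1.0 / (1.0 + np.exp(-z)), _EPS, 1.0 - _EPS)
    return -(rho * y * (1.0 - p) - (1.0 - rho) * (1.0 - y) * p) / ncells


# ---------------------------------------------------------------------------
# model + training

@dataclass
class DetectorConfig:
    """Full-scale defaults follow the shared training recipe (Adam, lr 1e-4,
    batch 8, dropout 0.5, 100 epochs max, early stopping on validation
    loss); ``desk()`` is the reduced CPU preset."""

    scale: str = "full"
    input_size: int = 256
    widths: tuple = (96, 192, 384)
    learning_rate: float = 1e-4
    batch_size: int = 8
    dropout: float = 0.5
    max_epochs: int = 100
    patience: int = 10
    binarize_at: float = 1e-9
    grid_n: int = 9
    stem_stride: int = 4
    # input channels: "ir" = crop + residual; "irr" adds the composited
    # reconstruction so the head can learn shift-tolerant comparisons
    channels: str = "ir"
    # label-consistent augmentation (flips mirror the label grid; photometric
    # jitter applies to the image channel only)
    augment: bool = True
    aug_noise_sigma: float = 0.01
    aug_brightness: float = 0.05
    # exponential moving average of the weights; the averaged model is the
    # one evaluated and returned (0 disables)
    ema_decay: float = 0.98

    @classmethod
    def desk(cls, max_epochs: int = 20) -> "DetectorConfig":
        return cls(scale="desk", input_size=64, widths=(32, 64, 128),
                   learning_rate=2e-3, max_epochs=max_epochs, patience=5,
                   stem_stride=2, channels="irr")


@dataclass
class DetectorModel:
    net: _nn.ConvNeXtFPNDetector
    config: DetectorConfig
    loss_history: list = dataclasses.field(default_factory=list)


def _detector_inputs(items, size, channels="ir"):
    xs, ys = [], []
    for it in items:
        crop, res = it["crop"], it["residual"]
        if crop.shape != (size, size) or res.shape != (size, size):
            raise ValueError("crop/residual shape does not match config")
        chans = [crop, res]
        if channels == "irr":
            chans.insert(1, it.get("reconstruction",
                                   np.clip(crop - res, 0.0, 1.0)))
        g = it["grid"]
        gv = g.values if isinstance(g, PatchGrid) else np.asarray(g)
        xs.append(np.stack(chans))
        ys.append(gv)
    return np.asarray(xs, dtype=np.float32), np.asarray(ys, dtype=np.float64)


def train_detector(items, config: DetectorConfig | None = None, seed: int = 0,
                   val_items=None, val_fraction: float = 0.15) -> DetectorModel:
    """Train the grid detector with W-BCE + Adam and early stopping.

    Each item is ``{'crop', 'residual', 'grid'}``; when no explicit
    validation items are given, a seeded ``val_fraction`` split is held out.
    The best-validation parameters are restored at the end."""
    config = config or DetectorConfig()
    rng = np.random.default_rng(seed)
    x, y = _detector_inputs(items, config.input_size, config.channels)
    if val_items is not None:
        xv, yv = _detector_inputs(val_items, config.input_size, config.channels)
    else:
        nval = max(1, int(round(val_fraction * len(x))))
        perm = rng.permutation(len(x))
        xv, yv = x[perm[:nval]], y[perm[:nval]]
        x, y = x[perm[nval:]], y[perm[nval:]]

    net = _nn.ConvNeXtFPNDetector(cin=x.shape[1], widths=config.widths,
                                  input_size=config.input_size,
                                  grid=config.grid_n, dropout=config.dropout,
                                  stem_stride=config.stem_stride, rng=rng)
    opt = _nn.Adam(net.params, net.grads, lr=config.learning_rate, beta1=0.9)
    model = DetectorModel(net, config)
    best_val, best_state, since_best = np.inf, _nn.get_state(net), 0
    ema = _nn.get_state(net) if config.ema_decay > 0 else None

    def _with_ema(fn):
        """Evaluate fn with the EMA weights swapped in."""
        if ema is None:
            return fn()
        raw = _nn.get_state(net)
        _nn.set_state(net, ema)
        try:
            return fn()
        finally:
            _nn.set_state(net, raw)

    # dataset-level non-fracture cell fraction: the fallback rho for grids
    # with no positive cells, whose per-image rho of 1 would zero their loss
    ybin = (y >= config.binarize_at)
    rho_ds = float(1.0 - ybin.mean())

    def _rho(yi):
        return None if (yi >= config.binarize_at).any() else rho_ds

    def _augment(xb, yb):
        """Seeded flips + photometric jitter; labels follow the flips.

        Grid cells tile uniformly except the last row/column, so a flipped
        label grid is misaligned by at most one pixel at the far border —
        negligible at augmentation strength."""
        xb, yb = xb.copy(), yb.copy()
        nimg = 2 if config.channels == "irr" else 1  # intensity-space channels
        for j in range(len(xb)):
            if rng.random() < 0.5:
                xb[j] = xb[j, :, :, ::-1]
                yb[j] = yb[j, :, ::-1]
            if rng.random() < 0.5:
                xb[j] = xb[j, :, ::-1, :]
                yb[j] = yb[j, ::-1, :]
            xb[j, :nimg] += rng.uniform(-config.aug_brightness,
                                        config.aug_brightness)
            if config.aug_noise_sigma > 0:
                xb[j, 0] += rng.normal(0, config.aug_noise_sigma,
                                       xb[j, 0].shape).astype(np.float32)
        return np.clip(xb, 0.0, 1.0), yb

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x))
        tr_sum, nb = 0.0, 0
        for i in range(0, len(x), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = x[idx], y[idx]
            if config.augment:
                xb, yb = _augment(xb, yb)
            opt.zero_grad()
            z = net.forward(xb, train=True)
            loss = np.mean([wbce_loss(z[j], yb[j], config.binarize_at, _rho(yb[j]))
                            for j in range(len(idx))])
            dz = np.stack([wbce_grad(z[j], yb[j], config.binarize_at, _rho(yb[j]))
                           for j in range(len(idx))]) / len(idx)
            net.backward(dz.astype(np.float32))
            opt.step()
            if ema is not None:
                d = config.ema_decay
                for e_p, p in zip(ema, net.params):
                    e_p *= d
                    e_p += (1.0 - d) * p
            tr_sum += loss
            nb += 1
        zv = _with_ema(lambda: net.forward(xv, train=False))
        val = float(np.mean([wbce_loss(zv[j], yv[j], config.binarize_at, _rho(yv[j]))
                             for j in range(len(xv))]))
        model.loss_history.append({"epoch": epoch + 1, "train_wbce": tr_sum / nb,
                                   "val_wbce": val})
        if val < best_val - 1e-6:
            best_val, since_best = val, 0
            best_state = [p.copy() for p in (ema if ema is not None
                                             else _nn.get_state(net))]
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    _nn.set_state(net, best_state)
    return model


def predict_grid(model: DetectorModel, crop: np.ndarray,
                 residual: np.ndarray,
                 reconstruction: np.ndarray | None = None) -> PatchGrid:
    """Fracture probability per grid cell (deterministic: dropout off)."""
    size = model.config.input_size
    if crop.shape != (size, size):
        raise ValueError("crop size does not match the model's training scale")
    chans = [crop, residual]
    if model.config.channels == "irr":
        if reconstruction is None:
            reconstruction = np.clip(crop - residual, 0.0, 1.0)
        chans.insert(1, reconstruction)
    x = np.stack(chans)[None].astype(np.float32)
    z = model.net.forward(x, train=False)[0]
    p = 1.0 / (1.0 + np.exp(-z))
    return PatchGrid(values=p, kind="probability",
                     geometry=GridGeometry(crop_size=size, n=model.config.grid_n))


def image_decision(grid: PatchGrid, threshold: float = 0.5) -> ImageDecision:
    """Image-level call: score = max cell probability, thresholded."""
    score = float(grid.values.max())
    return ImageDecision(score=score, is_fracture=bool(score >= threshold),
                         threshold=threshold)


def heatmap(grid: PatchGrid, crop: np.ndarray, alpha: float = 0.4,
            cmap: str = "jet", out_path=None) -> np.ndarray:
    """RGB overlay: the grid is bilinearly upsampled to the crop size,
    mapped through a matplotlib colormap and alpha-blended over the crop.
    Returns a uint8 (H, W, 3) array; optionally written as PNG."""
    import matplotlib
    from skimage.transform import resize as _resize

    size = crop.shape[0]
    up = _resize(grid.values.astype(np.float64), (size, size), order=1,
                 mode="edge", anti_aliasing=False)
    colors = matplotlib.colormaps[cmap](np.clip(up, 0, 1))[..., :3]
    gray = np.repeat(crop[..., None].astype(np.float64), 3, axis=2)
    blend = (1.0 - alpha) * gray + alpha * colors
    out = (np.clip(blend, 0, 1) * 255 + 0.5).astype(np.uint8)
    if out_path is not None:
        import imageio.v3 as iio
        iio.imwrite(out_path, out, extension=".png")
    return out


# ---------------------------------------------------------------------------
# checkpointing

def save_detector(model: DetectorModel, path) -> None:
    meta = {"config": dataclasses.asdict(model.config),
            "loss_history": model.loss_history}
    arrays = {f"p{i}": p for i, p in enumerate(model.net.params)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_detector(path) -> DetectorModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        cfgd = meta["config"]
        cfgd["widths"] = tuple(cfgd["widths"])
        config = DetectorConfig(**cfgd)
        cin = 3 if config.channels == "irr" else 2
        net = _nn.ConvNeXtFPNDetector(cin=cin, widths=config.widths,
                                      input_size=config.input_size,
                                      grid=config.grid_n, dropout=config.dropout,
                                      stem_stride=config.stem_stride)
        for i, p in enumerate(net.params):
            p[...] = z[f"p{i}"]
    return DetectorModel(net, config, loss_history=meta["loss_history"])
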