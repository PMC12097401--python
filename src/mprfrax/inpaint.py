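"""Adversarial inpainting of the masked skeletal region.

The repair model learns the distribution of *healthy* bone: a centred
square region of each crop (160x160 of a 256x256 crop at full scale, scaled
proportionally at desk scale) is tiled into a 5x5 grid of sub-regions, each
filled with a solid intensity, and an encoder-decoder generator is trained
adversarially to restore it, conditioned on the unmasked remainder plus the
auxiliary edge/texture channels. At inference the residual

    Diff = |I - R|

between input and reconstruction is near zero for normal anatomy and
elevated where the input deviates from the healthy distribution — i.e. at
fractures. Training never sees fracture images; that asymmetry is the whole
detection principle.

Generator-side loss:  alpha * adversarial + beta * perceptual + gamma * region
(region = mean absolute error inside the mask). The discriminator trains on
the standard real/fake cross-entropy.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _nn

__all__ = [
    "MaskSpec", "LossWeights", "RepairConfig", "RepairModel", "RepairResult",
    "make_mask", "apply_mask", "adversarial_loss", "perceptual_loss",
    "region_loss", "total_loss", "train_repair", "reconstruct",
    "save_repair_model", "load_repair_model",
]

_EPS = 1e-7


@dataclass(frozen=True)
class MaskSpec:
    """Centred square occlusion split into a grid of solid-fill sub-regions.

    ``active`` selects which sub-regions are occluded (None = all of them):
    joint masking fills the whole central square at once, while per-region
    repair occludes one sub-region at a time so the generator reconstructs
    each hole from the full remaining context."""

    crop_size: int = 256
    mask_size: int = 160
    grid: tuple[int, int] = (5, 5)
    fill: object = None  # None -> 0.5 (or per-slot dataset means set in training)
    active: tuple | None = None

    def validate(self) -> None:
        if self.mask_size > self.crop_size:
            raise ValueError("mask_size must be <= crop_size")
        gr, gc = self.grid
        if self.mask_size % gr or self.mask_size % gc:
            raise ValueError("grid must divide mask_size exactly")
        if self.active is not None:
            nreg = gr * gc
            if any(not (0 <= a < nreg) for a in self.active):
                raise ValueError("active sub-region index out of range")

    @classmethod
    def for_crop(cls, crop_size: int, fill=None) -> "MaskSpec":
        """Scale the full-size geometry (160/256) to another crop size."""
        m = int(round(crop_size * 160 / 256))
        gr = 5
        m -= m % gr
        return cls(crop_size=crop_size, mask_size=m, fill=fill)


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 0.1   # adversarial
    beta: float = 1.0    # perceptual
    gamma: float = 1.0   # region reconstruction

    def validate(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.alpha == self.beta == self.gamma == 0:
            raise ValueError("loss weights must not all be zero")


@dataclass
class RepairConfig:
    """Training configuration. Defaults are the full-scale settings
    (Adam, lr 1e-4 decayed 5% every 5 epochs, batch 8, dropout 0.5, 100
    epochs); ``desk()`` gives the reduced desk-scale preset that trains on
    one CPU in minutes (64x64 crops, narrow channels, fewer epochs,
    proportionally larger lr)."""

    scale: str = "full"
    crop_size: int = 256
    learning_rate: float = 1e-4
    batch_size: int = 8
    dropout: float = 0.5
    max_epochs: int = 100
    lr_decay: float = 0.95
    lr_decay_every: int = 5
    base_width: int = 32
    weights: LossWeights = dataclasses.field(default_factory=LossWeights)
    perceptual_seed: int = 7
    # "joint": all 25 sub-regions occluded at once; "per_region": sweep the
    # grid one target sub-region at a time — the targeted regional repair
    # reading. guard_rings widens each occlusion to the (2g+1)^2 block
    # around the target so that an anomaly centred in the target cannot
    # stay visible just outside the hole and be copied back in; only the
    # target region's reconstruction is kept when stitching.
    repair_mode: str = "joint"
    guard_rings: int = 1
    # per_region only: random target regions drawn per image per epoch
    region_draws: int = 1

    @classmethod
    def desk(cls, max_epochs: int = 30) -> "RepairConfig":
        return cls(scale="desk", crop_size=64, learning_rate=1e-3,
                   max_epochs=max_epochs, base_width=8,
                   repair_mode="per_region")


@dataclass
class RepairModel:
    generator: _nn.UNetGenerator
    discriminator: _nn.PatchDiscriminator
    feature_net: _nn.RandomFeatureNet
    mask_spec: MaskSpec
    config: RepairConfig
    loss_history: list = dataclasses.field(default_factory=list)
    epoch: int = 0


@dataclass
class RepairResult:
    reconstruction: np.ndarray  # R, in [0,1]
    residual: np.ndarray        # Diff = |I - R|
    mask_spec: MaskSpec


# ---------------------------------------------------------------------------
# masking

def make_mask(spec: MaskSpec):
    """Binary occlusion indicator plus a sub-region index map.

    The indicator is 1 inside the centred ``mask_size`` square; the index
    map labels each masked pixel with its sub-region id (row-major, 0..24
    for the default 5x5 grid) and is -1 outside."""
    spec.validate()
    n, m = spec.crop_size, spec.mask_size
    off = (n - m) // 2
    ind = np.zeros((n, n), dtype=np.float32)
    ind[off:off + m, off:off + m] = 1.0
    regions = np.full((n, n), -1, dtype=np.int32)
    gr, gc = spec.grid
    sr, sc = m // gr, m // gc
    rr, cc = np.mgrid[0:m, 0:m]
    regions[off:off + m, off:off + m] = (rr // sr) * gc + (cc // sc)
    if spec.active is not None:
        keep = np.isin(regions, np.asarray(spec.active, dtype=np.int32))
        ind = np.where(keep, ind, 0.0).astype(np.float32)
    return ind, regions


def _fill_image(spec: MaskSpec, regions: np.ndarray) -> np.ndarray:
    gr, gc = spec.grid
    nreg = gr * gc
    fill = spec.fill
    if fill is None:
        vals = np.full(nreg, 0.5, dtype=np.float32)
    else:
        vals = np.broadcast_to(np.asarray(fill, dtype=np.float32).ravel(), (nreg,))
    out = np.zeros(regions.shape, dtype=np.float32)
    inside = regions >= 0
    out[inside] = vals[regions[inside]]
    return out


def apply_mask(crop: np.ndarray, aux, spec: MaskSpec) -> np.ndarray:
    """Occluded input stack (4, H, W): solid-filled image, edge and texture
    channels (passed through unmasked), and the mask indicator."""
    ind, regions = make_mask(spec)
    if crop.shape != ind.shape or aux.edge.shape != ind.shape:
        raise ValueError("crop/aux shape does not match the mask spec")
    fill_img = _fill_image(spec, regions)
    masked = crop * (1.0 - ind) + fill_img * ind
    return np.stack([masked, aux.edge, aux.texture, ind]).astype(np.float32)


# ---------------------------------------------------------------------------
# losses

def adversarial_loss(scores_real, scores_fake):
    """Non-saturating GAN cross-entropy on discriminator probability scores.

    Returns ``(generator_term, discriminator_term)``: the discriminator term
    is the mean BCE of real-vs-fake classification, the generator term is
    -mean log p(fake judged real)."""
    pr = np.clip(np.asarray(scores_real, dtype=np.float64), _EPS, 1 - _EPS)
    pf = np.clip(np.asarray(scores_fake, dtype=np.float64), _EPS, 1 - _EPS)
    disc = -0.5 * (np.mean(np.log(pr)) + np.mean(np.log(1.0 - pf)))
    gen = -np.mean(np.log(pf))
    return float(gen), float(disc)


def perceptual_loss(r: np.ndarray, gt: np.ndarray, feature_provider) -> float:
    """Sum over layers of the element-count-normalized squared activation
    difference; ``feature_provider`` maps an image to a list of maps."""
    fr = feature_provider(r)
    fg = feature_provider(gt)
    return float(sum(np.mean((a.astype(np.float64) - b.astype(np.float64)) ** 2)
                     for a, b in zip(fr, fg)))


def region_loss(r: np.ndarray, gt: np.ndarray, mask: np.ndarray) -> float:
    """Mean absolute pixel error restricted to the masked region."""
    m = mask > 0
    if not m.any():
        raise ValueError("empty mask")
    return float(np.abs(r[..., m] - gt[..., m]).mean())


def total_loss(adv_g: float, adv_d: float, perceptual: float, region: float,
               weights: LossWeights):
    """Generator-side weighted sum and discriminator-side loss."""
    weights.validate()
    gen = weights.alpha * adv_g + weights.beta * perceptual + weights.gamma * region
    return float(gen), float(adv_d)


# ---------------------------------------------------------------------------
# training

def _neighborhood(k: int, grid: tuple[int, int], rings: int) -> np.ndarray:
    """Sub-region ids of the (2*rings+1)^2 block around region k (clipped)."""
    gr, gc = grid
    r, c = divmod(k, gc)
    out = []
    for dr in range(-rings, rings + 1):
        for dc in range(-rings, rings + 1):
            rr, cc = r + dr, c + dc
            if 0 <= rr < gr and 0 <= cc < gc:
                out.append(rr * gc + cc)
    return np.asarray(out, dtype=np.int32)


def _as_arrays(items):
    """Accept a phantom manifest dict (with in-memory images attached) or a
    plain list of {'image': ..., 'label': ...} / bare arrays."""
    out = []
    seq = items["items"] if isinstance(items, dict) else items
    for it in seq:
        if isinstance(it, np.ndarray):
            out.append({"image": it, "label": "healthy"})
        else:
            out.append({"image": it["image"], "label": it.get("label", "healthy")})
    return out


def train_repair(items, aux_list, config: RepairConfig | None = None,
                 mask_spec: MaskSpec | None = None, seed: int = 0,
                 log_path=None) -> RepairModel:
    """Alternating discriminator / encoder-decoder optimization on healthy
    crops. ``items`` must be healthy-only (the repair model's entire premise
    is that it has never seen a fracture); ``aux_list`` carries one
    ``AuxChannels`` per item.
    """
    data = _as_arrays(items)
    if any(d["label"] != "healthy" for d in data):
        raise ValueError("repair training data must contain only healthy items")
    config = config or RepairConfig()
    imgs = np.stack([d["image"] for d in data]).astype(np.float32)
    n, hw = imgs.shape[0], imgs.shape[1]
    if hw != config.crop_size:
        raise ValueError(f"items are {hw}px but config.crop_size={config.crop_size}")
    if mask_spec is None:
        mask_spec = MaskSpec.for_crop(hw)
    ind, regions = make_mask(mask_spec)
    if mask_spec.fill is None:
        # default solid fill: dataset mean intensity per sub-region slot
        nreg = mask_spec.grid[0] * mask_spec.grid[1]
        vals = np.array([imgs[:, regions == k].mean() for k in range(nreg)],
                        dtype=np.float32)
        mask_spec = dataclasses.replace(mask_spec, fill=vals)

    rng = np.random.default_rng(seed)
    gen = _nn.UNetGenerator(cin=4, base=config.base_width,
                            dropout=config.dropout, rng=rng)
    disc = _nn.PatchDiscriminator(cin=1, base=config.base_width,
                                  dropout=config.dropout, rng=rng)
    fnet = _nn.RandomFeatureNet(seed=config.perceptual_seed)
    fill_img = _fill_image(mask_spec, regions)
    nreg = mask_spec.grid[0] * mask_spec.grid[1]
    per_region = config.repair_mode == "per_region"
    if per_region:
        region_inds = np.stack([
            np.isin(regions, _neighborhood(k, mask_spec.grid,
                                           config.guard_rings)).astype(np.float32)
            for k in range(nreg)])
    auxs = np.stack([np.stack([a.edge, a.texture]) for a in aux_list]
                    ).astype(np.float32)
    targets = imgs[:, None]
    w = config.weights
    w.validate()

    def batch_inputs(idx):
        """Occluded stacks + per-sample mask indicators for one batch."""
        if per_region:
            ks = rng.integers(0, nreg, size=len(idx))
            ind_b = region_inds[ks]
        else:
            ind_b = np.broadcast_to(ind, (len(idx),) + ind.shape)
        masked = imgs[idx] * (1.0 - ind_b) + fill_img[None] * ind_b
        x = np.concatenate([masked[:, None], auxs[idx], ind_b[:, None]],
                           axis=1).astype(np.float32)
        return x, ind_b[:, None]

    opt_g = _nn.Adam(gen.params, gen.grads, lr=config.learning_rate)
    opt_d = _nn.Adam(disc.params, disc.grads, lr=config.learning_rate)
    model = RepairModel(gen, disc, fnet, mask_spec, config)

    draws = config.region_draws if per_region else 1
    for epoch in range(config.max_epochs):
        lr = config.learning_rate * config.lr_decay ** (epoch // config.lr_decay_every)
        opt_g.lr = opt_d.lr = lr
        order = np.concatenate([rng.permutation(n) for _ in range(draws)])
        sums = np.zeros(4)
        nb = 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            x, mask_b = batch_inputs(idx)
            y = targets[idx]
            bsz = len(idx)
            npix_mask = mask_b.sum(axis=(1, 2, 3), keepdims=True)  # per sample

            r = gen.forward(x, train=True)

            # -- discriminator step (generator output detached)
            opt_d.zero_grad()
            d_real = disc.forward(y, train=True)
            p_real = 1.0 / (1.0 + np.exp(-d_real))
            disc.backward(((p_real - 1.0) / (2.0 * d_real.size)).astype(np.float32))
            d_fake = disc.forward(r, train=True)
            p_fake = 1.0 / (1.0 + np.exp(-d_fake))
            disc.backward((p_fake / (2.0 * d_fake.size)).astype(np.float32))
            opt_d.step()
            adv_g_val, adv_d_val = adversarial_loss(p_real, p_fake)

            # -- generator step
            opt_g.zero_grad()
            _nn.zero_grads(disc)
            d_fake2 = disc.forward(r, train=False)
            p_fake2 = 1.0 / (1.0 + np.exp(-d_fake2))
            dr_adv = disc.backward(
                (-(1.0 - p_fake2) / d_fake2.size).astype(np.float32))

            f_gt = fnet.features(y)
            f_gt = [f.copy() for f in f_gt]
            f_r = fnet.features(r)
            perc_val = float(sum(np.mean((a - b) ** 2)
                                 for a, b in zip(f_r, f_gt)))
            dfs = [((a - b) * (2.0 / a.size)).astype(np.float32)
                   for a, b in zip(f_r, f_gt)]
            dr_perc = fnet.backward_to_input(dfs)

            diff = r - y
            reg_val = float((np.abs(diff * mask_b).sum(axis=(1, 2, 3), keepdims=True)
                             / npix_mask).mean())
            dr_reg = (np.sign(diff) * mask_b / (bsz * npix_mask)).astype(np.float32)

            dr = (w.alpha * dr_adv + w.beta * dr_perc + w.gamma * dr_reg).astype(np.float32)
            gen.backward(dr)
            opt_g.step()

            sums += (adv_g_val, adv_d_val, perc_val, reg_val)
            nb += 1
        adv_g_m, adv_d_m, perc_m, reg_m = sums / nb
        total_m = w.alpha * adv_g_m + w.beta * perc_m + w.gamma * reg_m
        model.loss_history.append({
            "epoch": epoch + 1, "adv_g": adv_g_m, "adv_d": adv_d_m,
            "perceptual": perc_m, "region": reg_m, "total": total_m,
        })
        model.epoch = epoch + 1

    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            wtr = csv.DictWriter(fh, fieldnames=list(model.loss_history[0]))
            wtr.writeheader()
            wtr.writerows(model.loss_history)
    return model


# ---------------------------------------------------------------------------
# inference

def reconstruct(model: RepairModel, crop: np.ndarray, aux,
                mask_spec: MaskSpec | None = None,
                composite: bool = True) -> RepairResult:
    """Reconstruct the healthy state of a crop and form the residual map.

    With ``composite`` (default) the reconstruction outside the mask is
    replaced by the original pixels, so the residual is attributable to the
    repaired region and is exactly zero outside it."""
    spec = mask_spec or model.mask_spec
    if crop.shape[0] != model.config.crop_size:
        raise ValueError("crop size does not match the model's training scale")
    sweep = (model.config.repair_mode == "per_region" and spec.active is None
             and spec.mask_size > 0)
    if sweep:
        # occlude the guarded block around each target sub-region (batched)
        # and stitch only the target regions' reconstructions
        ind_all, regions = make_mask(spec)
        fill_img = _fill_image(spec, regions)
        nreg = spec.grid[0] * spec.grid[1]
        rings = model.config.guard_rings
        targets = np.stack([(regions == k).astype(np.float32) for k in range(nreg)])
        blocks = np.stack([
            np.isin(regions, _neighborhood(k, spec.grid, rings)).astype(np.float32)
            for k in range(nreg)])
        masked = crop[None] * (1.0 - blocks) + fill_img[None] * blocks
        x = np.concatenate([
            masked[:, None],
            np.broadcast_to(np.stack([aux.edge, aux.texture]), (nreg, 2) + crop.shape),
            blocks[:, None]], axis=1).astype(np.float32)
        out = model.generator.forward(x, train=False)[:, 0]
        r = (out * targets).sum(axis=0) + out.mean(axis=0) * (1.0 - ind_all)
        ind = ind_all
    else:
        x = apply_mask(crop, aux, spec)
        r = model.generator.forward(x[None], train=False)[0, 0]
        ind, _ = make_mask(spec)
    r = np.clip(r, 0.0, 1.0)
    if composite:
        r = crop * (1.0 - ind) + r * ind
    return RepairResult(reconstruction=r.astype(np.float32),
                        residual=np.abs(crop - r).astype(np.float32),
                        mask_spec=spec)


# ---------------------------------------------------------------------------
# checkpointing

def save_repair_model(model: RepairModel, path) -> None:
    """Single-file archive: all parameter arrays + embedded JSON config."""
    meta = {
        "config": dataclasses.asdict(model.config),
        "mask_spec": {**dataclasses.asdict(model.mask_spec),
                      "fill": np.asarray(model.mask_spec.fill).tolist()
                      if model.mask_spec.fill is not None else None},
        "epoch": model.epoch,
        "loss_history": model.loss_history,
    }
    arrays = {f"g{i}": p for i, p in enumerate(model.generator.params)}
    arrays |= {f"d{i}": p for i, p in enumerate(model.discriminator.params)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_repair_model(path) -> RepairModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        cfgd = meta["config"]
        cfgd["weights"] = LossWeights(**cfgd["weights"])
        config = RepairConfig(**cfgd)
        msd = meta["mask_spec"]
        if msd["fill"] is not None:
            msd["fill"] = np.asarray(msd["fill"], dtype=np.float32)
        msd["grid"] = tuple(msd["grid"])
        spec = MaskSpec(**msd)
        gen = _nn.UNetGenerator(cin=4, base=config.base_width, dropout=config.dropout)
        disc = _nn.PatchDiscriminator(cin=1, base=config.base_width,
                                      dropout=config.dropout)
        for i, p in enumerate(gen.params):
            p[...] = z[f"g{i}"]
        for i, p in enumerate(disc.params):
            p[...] = z[f"d{i}"]
    model = RepairModel(gen, disc, _nn.RandomFeatureNet(seed=config.perceptual_seed),
                        spec, config, loss_history=meta["loss_history"],
                        epoch=meta["epoch"])
    return model
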