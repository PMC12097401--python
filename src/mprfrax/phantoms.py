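"""Synthetic elbow-like radiograph phantoms with ground-truth geometry.

The generator emulates the statistical structure of a paediatric elbow
radiograph crop — a bright bone shaft with brighter cortical margins on a
darker soft-tissue background, an epiphyseal-line-like bright band,
ossification-centre blobs, additive noise — and, for positive samples, a
thin low-contrast crack crossing the cortex with a known bounding box.
Appearance is deliberately parametric and low-fidelity: what matters for
the pipeline is the presence of strong normal edges that mimic fracture
lines and of genuinely subtle true fracture lines, not anatomical realism.

Coordinate convention (shared by the whole package): 0-based, half-open,
(row, col) order; bounding boxes are (r0, c0, r1, c1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "PhantomSpec", "FractureSpec", "FractureAnnotation",
    "generate_healthy_phantom", "inject_fracture", "build_phantom_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the healthy phantom renderer.

    Intensities are in [0,1]; lengths in pixels unless noted.
    """

    image_size: int = 64
    bone_width_range: tuple[float, float] = (0.30, 0.42)  # fraction of width
    soft_tissue: float = 0.22
    bone_interior: float = 0.52
    cortex_contrast: float = 0.30          # added on top of interior at the margins
    cortex_thickness_frac: float = 0.045   # fraction of image size
    epiphyseal_band: bool = True
    epiphyseal_intensity: float = 0.12
    ossification_blobs: tuple[int, int] = (0, 2)  # inclusive count range
    blob_intensity: float = 0.14
    noise_sigma: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lo, hi = self.bone_width_range
        if not (0 < lo <= hi < 1):
            raise ValueError("bone_width_range must satisfy 0 < lo <= hi < 1")
        peak = self.bone_interior + self.cortex_contrast + self.epiphyseal_intensity \
            + self.blob_intensity
        if not (0 <= self.soft_tissue <= 1) or peak > 1.5:
            raise ValueError("intensity parameters must keep pixels clampable to [0,1]")


@dataclass(frozen=True)
class FractureSpec:
    """A hairline crack: a short dark line crossing the cortical margin."""

    amplitude: float = 0.15       # intensity depth of the lucent line
    thickness: float = 1.0        # pixels
    length: float = 14.0          # pixels
    angle: float | None = None    # radians; None -> drawn near-perpendicular to the bone
    displacement: float = 0.0     # sub-pixel shear across the crack
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.amplitude <= 1.0):
            raise ValueError("amplitude must be in [0,1]")
        if self.amplitude > 0 and self.thickness < 1:
            raise ValueError("thickness must be >= 1 when amplitude > 0")
        if self.length <= 0:
            raise ValueError("length must be positive")


@dataclass(frozen=True)
class FractureAnnotation:
    """Tight bbox of all crack-modified pixels, dilated by 2 px.

    bbox is (r0, c0, r1, c1), 0-based half-open, in crop coordinates;
    ``present`` is False (and bbox None) for healthy images.
    """

    present: bool
    bbox: tuple[int, int, int, int] | None = None


def _smoothstep(x: np.ndarray) -> np.ndarray:
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def generate_healthy_phantom(spec: PhantomSpec, seed: int | None = None):
    """Render a healthy phantom; returns ``(image, geometry)``.

    ``geometry`` records the bone axis (per-row centre column), bone
    half-width, the four cortical edge columns per row, the epiphyseal band
    row (or None) and blob centres — everything a downstream oracle needs.
    Fully determined by ``(spec, seed)``.
    """
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    n = spec.image_size
    rows = np.arange(n, dtype=np.float64)
    cols = np.arange(n, dtype=np.float64)

    width_frac = rng.uniform(*spec.bone_width_range)
    half_w = 0.5 * width_frac * n
    slope = rng.uniform(-0.12, 0.12)
    bow = rng.uniform(-0.0008, 0.0008)  # gentle curvature
    c_mid = n / 2 + rng.uniform(-0.06, 0.06) * n
    centre = c_mid + slope * (rows - n / 2) + bow * (rows - n / 2) ** 2

    ct = max(1.0, spec.cortex_thickness_frac * n)
    # signed distance from the bone centre line, per pixel
    d = np.abs(cols[None, :] - centre[:, None])
    aa = 0.8  # anti-aliasing width in px
    inside = _smoothstep((half_w - d) / aa + 0.5)
    img = spec.soft_tissue + (spec.bone_interior - spec.soft_tissue) * inside
    # cortical margins: bright bands centred on +-half_w
    cortex = _smoothstep((ct / 2 - np.abs(d - (half_w - ct / 2))) / aa + 0.5)
    img = img + spec.cortex_contrast * cortex

    band_row = None
    if spec.epiphyseal_band:
        band_row = float(rng.uniform(0.60, 0.78) * n)
        bh = max(1.2, 0.018 * n)
        band = np.exp(-0.5 * ((rows[:, None] - band_row) / bh) ** 2)
        img = img + spec.epiphyseal_intensity * band * inside

    lo, hi = spec.ossification_blobs
    nblobs = int(rng.integers(lo, hi + 1))
    blob_centres = []
    for _ in range(nblobs):
        br = rng.uniform(0.15, 0.85) * n
        bc = centre[int(br)] + rng.uniform(-1.2, 1.2) * half_w
        bs = rng.uniform(0.025, 0.05) * n
        blob_centres.append((float(br), float(bc), float(bs)))
        g = np.exp(-0.5 * (((rows[:, None] - br) / bs) ** 2
                           + ((cols[None, :] - bc) / bs) ** 2))
        img = img + spec.blob_intensity * g

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    geometry = {
        "centre": centre,                  # per-row bone centre column
        "half_width": float(half_w),
        "cortex_thickness": float(ct),
        # per-row outer/inner columns of the left and right cortical bands
        "cortex_edges": np.stack([
            centre - half_w, centre - half_w + ct,
            centre + half_w - ct, centre + half_w,
        ], axis=1),
        "band_row": band_row,
        "blobs": blob_centres,
        "seed": int(seed),
    }
    return img, geometry


def _crack_coverage(shape, p0, p1, thickness):
    """Anti-aliased coverage in [0,1] of the segment p0->p1 with given width."""
    rr, cc = np.meshgrid(np.arange(shape[0], dtype=np.float64),
                         np.arange(shape[1], dtype=np.float64), indexing="ij")
    p0 = np.asarray(p0, dtype=np.float64)
    v = np.asarray(p1, dtype=np.float64) - p0
    l2 = float(v @ v)
    t = np.clip(((rr - p0[0]) * v[0] + (cc - p0[1]) * v[1]) / l2, 0.0, 1.0)
    dr = rr - (p0[0] + t * v[0])
    dc = cc - (p0[1] + t * v[1])
    dist = np.hypot(dr, dc)
    return np.clip(thickness / 2.0 + 0.5 - dist, 0.0, 1.0)


def inject_fracture(phantom: np.ndarray, geometry: dict, frac: FractureSpec,
                    seed: int | None = None):
    """Draw a subtle lucent crack crossing a cortical margin.

    The crack centre sits on a cortex band within the central half of the
    image (so it falls inside the repair mask downstream), oriented roughly
    perpendicular to the bone axis. Returns ``(image, FractureAnnotation)``;
    the bbox is the tight box of every modified pixel, dilated by 2 px.
    """
    frac.validate()
    if frac.amplitude == 0.0:
        return phantom.copy(), FractureAnnotation(present=False)
    if seed is None:
        seed = frac.seed
    rng = np.random.default_rng(seed)
    n = phantom.shape[0]
    centre = geometry["centre"]
    half_w = geometry["half_width"]
    ct = geometry["cortex_thickness"]

    r0 = rng.uniform(0.38, 0.62) * n  # keep the crack inside the central mask
    side = rng.choice([-1.0, 1.0])
    c0 = centre[int(r0)] + side * (half_w - ct / 2)
    if not (0 <= c0 < n):
        raise ValueError("crack placement falls outside the bone")
    if frac.angle is not None:
        theta = frac.angle
    else:
        # near-perpendicular to the (near-vertical) bone axis
        theta = rng.uniform(-0.45, 0.45)
    dvec = np.array([np.sin(theta), np.cos(theta)])
    half = frac.length / 2.0
    p0 = np.array([r0, c0]) - half * dvec
    p1 = np.array([r0, c0]) + half * dvec
    # the crack must overlap the bone footprint
    mid_inside = abs(c0 - centre[int(np.clip(r0, 0, n - 1))]) <= half_w + 1
    if not mid_inside:
        raise ValueError("crack placement falls outside the bone")

    if frac.displacement != 0.0:
        # shear: offset the two halves perpendicular to the crack direction
        perp = np.array([dvec[1], -dvec[0]]) * frac.displacement
        mid = np.array([r0, c0])
        cov = np.maximum(
            _crack_coverage(phantom.shape, p0 + perp, mid + perp, frac.thickness),
            _crack_coverage(phantom.shape, mid - perp, p1 - perp, frac.thickness),
        )
    else:
        cov = _crack_coverage(phantom.shape, p0, p1, frac.thickness)

    out = np.clip(phantom.astype(np.float64) - frac.amplitude * cov, 0.0, 1.0)
    out = out.astype(np.float32)
    changed = np.argwhere(out != phantom)
    if changed.size == 0:
        return phantom.copy(), FractureAnnotation(present=False)
    rmin, cmin = changed.min(axis=0)
    rmax, cmax = changed.max(axis=0)
    bbox = (max(0, int(rmin) - 2), max(0, int(cmin) - 2),
            min(n, int(rmax) + 3), min(n, int(cmax) + 3))
    return out, FractureAnnotation(present=True, bbox=bbox)


def _write_png16(path: Path, img: np.ndarray) -> None:
    iio.imwrite(path, (np.clip(img, 0, 1) * 65535.0 + 0.5).astype(np.uint16),
                extension=".png")


def read_image(path) -> np.ndarray:
    """Read a grayscale image (PNG/TIFF; DICOM if pydicom is installed) to [0,1]."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom  # optional
        arr = pydicom.dcmread(path).pixel_array.astype(np.float32)
    else:
        arr = iio.imread(path).astype(np.float32)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    mx = arr.max()
    if mx > 1.0:
        arr = arr / (65535.0 if mx > 255 else 255.0)
    return np.clip(arr, 0.0, 1.0)


def build_phantom_dataset(n_healthy: int, n_fractured: int, spec: PhantomSpec,
                          frac: FractureSpec, seed: int, out_dir,
                          splits=(0.7, 0.15, 0.15)) -> dict:
    """Write a seeded phantom dataset (16-bit PNGs + JSON manifest).

    Split proportions apply to each label independently; assignment is a
    deterministic function of ``(args, seed)``, so a rerun reproduces the
    manifest and the image bytes exactly.
    """
    if n_healthy < 0 or n_fractured < 0:
        raise ValueError("counts must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(entropy=seed)
    items = []

    def split_of(i, total, rng):
        u = rng.random()
        return "train" if u < splits[0] else ("val" if u < splits[0] + splits[1] else "test")

    split_rng = np.random.default_rng(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
    child = ss.spawn(n_healthy + n_fractured)
    for i in range(n_healthy + n_fractured):
        item_seed = int(child[i].generate_state(1)[0] % (2**31))
        img, geom = generate_healthy_phantom(spec, seed=item_seed)
        label = "healthy" if i < n_healthy else "fracture"
        ann = FractureAnnotation(present=False)
        if label == "fracture":
            img, ann = inject_fracture(img, geom, frac, seed=item_seed + 1)
        name = f"{label}_{i:05d}.png"
        _write_png16(out_dir / name, img)
        items.append({
            "id": f"{label}_{i:05d}",
            "path": name,
            "label": label,
            "bbox": list(ann.bbox) if ann.bbox else None,
            "split": split_of(i, n_healthy + n_fractured, split_rng),
            "seed": item_seed,
        })
    manifest = {
        "seed": int(seed),
        "spec": asdict(spec),
        "fracture_spec": asdict(frac),
        "n_healthy": int(n_healthy),
        "n_fractured": int(n_fractured),
        "items": items,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
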