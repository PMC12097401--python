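"""Elbow region localization and standardized cropping.

The production system this mirrors localizes the elbow with an object
detector and crops it to a standardized square input. Detector weights are
not part of this package: ``detect_roi`` accepts any callable plug-in with
the contract ``image -> iterable of (box, confidence)`` and falls back to a
deterministic intensity-centroid detector, which is exact on phantoms whose
bone dominates the foreground.

Boxes are (r0, c0, r1, c1), 0-based half-open, in source-image pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = ["RoiBox", "RoiCrop", "detect_roi", "crop_roi", "centroid_detector"]


@dataclass(frozen=True)
class RoiBox:
    box: tuple[int, int, int, int]
    confidence: float = 1.0

    def validate(self, shape=None) -> None:
        r0, c0, r1, c1 = self.box
        if r1 <= r0 or c1 <= c0:
            raise ValueError("RoiBox must be nonempty")
        if shape is not None and (r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]):
            raise ValueError("RoiBox outside image")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must be in [0,1]")


@dataclass(frozen=True)
class RoiCrop:
    pixels: np.ndarray            # (size, size) float in [0,1]
    source_box: RoiBox
    resample: str = "bicubic"


def centroid_detector(image: np.ndarray, side_frac: float = 0.8):
    """Fallback detector: square box centred on the intensity-weighted
    foreground centroid, side = ``side_frac * min(image dims)``.

    Foreground weight is intensity above the image median, so the bright
    bone dominates the centroid. A blank image yields the centred default
    box with confidence 0.
    """
    h, w = image.shape
    side = int(round(side_frac * min(h, w)))
    weights = np.clip(image - np.median(image), 0.0, None)
    total = weights.sum()
    if total <= 0:
        rc, cc = (h - 1) / 2.0, (w - 1) / 2.0
        conf = 0.0
    else:
        rr, cc_idx = np.mgrid[0:h, 0:w]
        rc = float((weights * rr).sum() / total)
        cc = float((weights * cc_idx).sum() / total)
        conf = 1.0
    r0 = int(round(rc - side / 2.0))
    c0 = int(round(cc - side / 2.0))
    r0 = min(max(r0, 0), h - side)
    c0 = min(max(c0, 0), w - side)
    return [((r0, c0, r0 + side, c0 + side), conf)]


def detect_roi(image: np.ndarray, detector=None, side_frac: float = 0.8) -> RoiBox:
    """Run the (pluggable) detector; fall back to the centroid detector."""
    if image.size == 0:
        raise ValueError("empty image")
    boxes = []
    if detector is not None:
        boxes = list(detector(image))
    if not boxes:
        boxes = centroid_detector(image, side_frac)
    box, conf = max(boxes, key=lambda bc: bc[1])
    return RoiBox(box=tuple(int(v) for v in box), confidence=float(conf))


def crop_roi(image: np.ndarray, box: RoiBox, out_size: int = 256) -> RoiCrop:
    """Crop the box and resample to ``out_size`` square with bicubic
    interpolation, clamping to [0,1] afterwards (bicubic can overshoot).

    Boxes reaching outside the image are clipped to it first; a box that is
    empty after clipping is an error. A crop already at the target size is
    returned exactly (no resampling)."""
    box.validate()
    h, w = image.shape
    r0, c0, r1, c1 = box.box
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, h), min(c1, w)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("RoiBox empty after clipping to the image")
    sub = image[r0:r1, c0:c1]
    if sub.shape == (out_size, out_size):
        return RoiCrop(pixels=sub.astype(np.float32).copy(), source_box=box,
                       resample="none")
    out = _sk_resize(sub.astype(np.float64), (out_size, out_size), order=3,
                     mode="reflect", anti_aliasing=sub.shape[0] > out_size)
    return RoiCrop(pixels=np.clip(out, 0.0, 1.0).astype(np.float32),
                   source_box=box, resample="bicubic")
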