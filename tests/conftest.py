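import numpy as np
import pytest

from mprfrax import auxmaps, phantoms, roi


@pytest.fixture(scope="session")
def desk_spec():
    return phantoms.PhantomSpec(image_size=80)


@pytest.fixture(scope="session")
def healthy_crop64(desk_spec):
    """One ROI-cropped 64x64 healthy phantom with aux channels."""
    img, geom = phantoms.generate_healthy_phantom(desk_spec, seed=11)
    box = roi.detect_roi(img, side_frac=64 / 80)
    crop = roi.crop_roi(img, box, out_size=64)
    aux = auxmaps.compose_aux(crop.pixels)
    return crop.pixels, aux


def make_crop_set(n_healthy, n_fractured, seed, size=80, crop=64,
                  amplitude=0.15):
    """Seeded helper shared by training-dependent tests."""
    spec = phantoms.PhantomSpec(image_size=size)
    frac = phantoms.FractureSpec(amplitude=amplitude)
    ss = np.random.SeedSequence(entropy=seed)
    children = ss.spawn(n_healthy + n_fractured)
    items, auxs = [], []
    for i in range(n_healthy + n_fractured):
        s = int(children[i].generate_state(1)[0] % (2 ** 31))
        img, geom = phantoms.generate_healthy_phantom(spec, seed=s)
        ann = phantoms.FractureAnnotation(present=False)
        label = "healthy"
        if i >= n_healthy:
            img, ann = phantoms.inject_fracture(img, geom, frac, seed=s + 1)
            label = "fracture"
        box = roi.detect_roi(img, side_frac=crop / size)
        c = roi.crop_roi(img, box, out_size=crop)
        bbox = None
        if ann.present:
            r0, c0, r1, c1 = ann.bbox
            br, bc = box.box[0], box.box[1]
            bbox = tuple(int(np.clip(v, 0, crop)) for v in
                         (r0 - br, c0 - bc, r1 - br, c1 - bc))
        items.append({"image": c.pixels, "label": label,
                      "ann": phantoms.FractureAnnotation(present=ann.present,
                                                         bbox=bbox)})
        auxs.append(auxmaps.compose_aux(c.pixels))
    return items, auxs
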