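"""Grid labels, weighted BCE, detector training contract, heatmaps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mprfrax import inpaint, phantoms, residual_detect as rd


def brute_force_label(bbox, mask, geometry):
    """Triple-membership pixel scan oracle."""
    n = geometry.n
    e = geometry.edges
    size = mask.shape[0]
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            cnt, area = 0, 0
            for r in range(e[i], e[i + 1]):
                for c in range(e[j], e[j + 1]):
                    area += 1
                    if (bbox[0] <= r < bbox[2] and bbox[1] <= c < bbox[3]
                            and mask[r, c] > 0):
                        cnt += 1
            vals[i, j] = cnt / area
    return vals


def wbce_oracle(logits, gt):
    """Independent summation oracle for the weighted BCE."""
    y = (np.asarray(gt) >= 1e-9).astype(float)
    n = y.size
    rho = (n - y.sum()) / n
    total = 0.0
    for zij, yij in zip(np.ravel(logits), np.ravel(y)):
        p = min(max(1 / (1 + np.exp(-zij)), 1e-7), 1 - 1e-7)
        total += rho * yij * np.log(p) + (1 - rho) * (1 - yij) * np.log(1 - p)
    return -total / n


class TestGridGeometry:
    def test_cells_tile_the_crop(self):
        g = rd.GridGeometry(crop_size=256)
        assert list(g.edges) == [0, 28, 56, 84, 112, 140, 168, 196, 224, 256]
        assert g.cell_areas().sum() == 256 * 256

    def test_desk_scale_geometry(self):
        g = rd.GridGeometry(crop_size=64)
        assert g.edges[-1] == 64 and len(g.edges) == 10
        assert g.cell_areas().sum() == 64 * 64


class TestGridLabel:
    def test_healthy_gives_81_zeros(self):
        mask, _ = inpaint.make_mask(inpaint.MaskSpec())
        grid = rd.grid_label(phantoms.FractureAnnotation(present=False), mask)
        assert grid.values.shape == (9, 9)
        assert (grid.values == 0).all()

    def test_aligned_interior_cell_is_one(self):
        mask, _ = inpaint.make_mask(inpaint.MaskSpec())
        # cell (4,4) spans rows/cols [112,140): inside the mask [48,208)
        ann = phantoms.FractureAnnotation(present=True, bbox=(112, 112, 140, 140))
        grid = rd.grid_label(ann, mask)
        assert grid.values[4, 4] == 1.0
        assert grid.values.sum() == 1.0

    def test_matches_pixel_scan_oracle(self):
        mask, _ = inpaint.make_mask(inpaint.MaskSpec())
        geometry = rd.GridGeometry(crop_size=256)
        ann = phantoms.FractureAnnotation(present=True, bbox=(60, 60, 120, 100))
        grid = rd.grid_label(ann, mask, geometry)
        want = brute_force_label(ann.bbox, mask, geometry)
        np.testing.assert_allclose(grid.values, want, atol=0)

    def test_area_conservation_on_random_boxes(self):
        mask, _ = inpaint.make_mask(inpaint.MaskSpec())
        geometry = rd.GridGeometry(crop_size=256)
        areas = geometry.cell_areas()
        rng = np.random.default_rng(0)
        for _ in range(25):
            r0, c0 = rng.integers(0, 250, 2)
            r1 = int(r0) + int(rng.integers(1, 80))
            c1 = int(c0) + int(rng.integers(1, 80))
            bbox = (int(r0), int(c0), min(r1, 256), min(c1, 256))
            ann = phantoms.FractureAnnotation(present=True, bbox=bbox)
            grid = rd.grid_label(ann, mask, geometry)
            member = np.zeros((256, 256), dtype=bool)
            member[bbox[0]:bbox[2], bbox[1]:bbox[3]] = True
            exact = int((member & (mask > 0)).sum())
            assert int(round((grid.values * areas).sum())) == exact

    def test_bbox_outside_crop_gives_zero_grid(self):
        mask, _ = inpaint.make_mask(inpaint.MaskSpec())
        ann = phantoms.FractureAnnotation(present=True, bbox=(300, 300, 310, 310))
        assert (rd.grid_label(ann, mask).values == 0).all()


class TestWbce:
    def test_hand_computed_2x2_case(self):
        logits = np.zeros((2, 2))
        gt = np.array([[1.0, 0.0], [0.0, 0.0]])
        want = 0.375 * np.log(2)
        assert rd.wbce_loss(logits, gt) == pytest.approx(want, rel=1e-12)

    def test_matches_summation_oracle_on_random_grids(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            z = rng.normal(0, 3, (9, 9))
            gt = (rng.random((9, 9)) < 0.1) * rng.random((9, 9))
            assert rd.wbce_loss(z, gt) == pytest.approx(wbce_oracle(z, gt),
                                                        abs=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_balanced_rho_is_half_unweighted_bce(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(0, 2, (4, 4))
        y = np.zeros(16)
        y[rng.permutation(16)[:8]] = 1.0  # exactly half positive -> rho = 0.5
        y = y.reshape(4, 4)
        p = np.clip(1 / (1 + np.exp(-z)), 1e-7, 1 - 1e-7)
        bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert rd.wbce_loss(z, y) == pytest.approx(0.5 * bce, rel=1e-12)

    def test_perfect_predictions_vanish(self):
        gt = np.zeros((9, 9))
        gt[4, 4] = 1.0
        logits = np.where(gt > 0, 20.0, -20.0)
        assert rd.wbce_loss(logits, gt) <= 1e-6

    def test_monotone_in_positive_cell_logit(self):
        gt = np.zeros((3, 3))
        gt[1, 1] = 1.0
        rng = np.random.default_rng(2)
        z = rng.normal(size=(3, 3))
        prev = rd.wbce_loss(z, gt)
        for bump in (0.5, 1.0, 2.0, 5.0):
            z2 = z.copy()
            z2[1, 1] += bump
            cur = rd.wbce_loss(z2, gt)
            assert cur <= prev + 1e-12
            prev = cur

    def test_explicit_rho_overrides_per_image(self):
        z = np.zeros((2, 2))
        gt = np.zeros((2, 2))  # all-negative: per-image rho = 1 -> loss 0
        assert rd.wbce_loss(z, gt) == 0.0
        assert rd.wbce_loss(z, gt, rho=0.75) == pytest.approx(
            0.25 * np.log(2))

    def test_all_nan_logits_rejected(self):
        with pytest.raises(ValueError):
            rd.wbce_loss(np.full((2, 2), np.nan), np.zeros((2, 2)))

    def test_grad_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(3, 3))
        gt = (rng.random((3, 3)) < 0.3).astype(float)
        g = rd.wbce_grad(z, gt)
        eps = 1e-6
        for i in range(3):
            for j in range(3):
                zp, zm = z.copy(), z.copy()
                zp[i, j] += eps
                zm[i, j] -= eps
                num = (rd.wbce_loss(zp, gt) - rd.wbce_loss(zm, gt)) / (2 * eps)
                assert g[i, j] == pytest.approx(num, abs=1e-8)


def _toy_items(n, seed, size=32):
    """Synthetic detector inputs: a bright blob in the residual marks the
    'fracture'; labels put the blob's cell at 1."""
    rng = np.random.default_rng(seed)
    geometry = rd.GridGeometry(crop_size=size)
    items = []
    for i in range(n):
        crop = rng.random((size, size), dtype=np.float32) * 0.2
        res = np.zeros((size, size), dtype=np.float32)
        grid = np.zeros((9, 9))
        if i % 2:
            ci, cj = rng.integers(1, 8, 2)
            e = geometry.edges
            res[e[ci]:e[ci + 1], e[cj]:e[cj + 1]] = 1.0
            grid[ci, cj] = 1.0
        items.append({"crop": crop, "residual": res,
                      "grid": rd.PatchGrid(grid, "label", geometry)})
    return items


class TestDetector:
    def test_smoke_training_records_losses(self):
        items = _toy_items(16, seed=0)
        cfg = rd.DetectorConfig.desk(max_epochs=2)
        cfg.input_size = 32
        model = rd.train_detector(items, cfg, seed=0)
        assert 1 <= len(model.loss_history) <= 2
        assert all(np.isfinite(r["train_wbce"]) for r in model.loss_history)

    def test_early_stopping_triggers(self):
        items = _toy_items(12, seed=1)
        cfg = rd.DetectorConfig.desk(max_epochs=50)
        cfg.input_size = 32
        cfg.patience = 2
        cfg.learning_rate = 0.0  # no progress -> patience must fire
        model = rd.train_detector(items, cfg, seed=0)
        assert len(model.loss_history) <= 4

    def test_default_config_recipe(self):
        cfg = rd.DetectorConfig()
        assert cfg.learning_rate == pytest.approx(1e-4)
        assert cfg.batch_size == 8 and cfg.dropout == 0.5
        assert cfg.max_epochs == 100 and cfg.patience > 0

    def test_predict_deterministic_and_finite(self):
        items = _toy_items(12, seed=2)
        cfg = rd.DetectorConfig.desk(max_epochs=2)
        cfg.input_size = 32
        model = rd.train_detector(items, cfg, seed=1)
        zero = np.zeros((32, 32), dtype=np.float32)
        g1 = rd.predict_grid(model, zero, zero)
        g2 = rd.predict_grid(model, zero, zero)
        assert np.array_equal(g1.values, g2.values)
        assert np.isfinite(g1.values).all()
        assert g1.values.min() >= 0 and g1.values.max() <= 1
        with pytest.raises(ValueError):
            rd.predict_grid(model, np.zeros((64, 64), dtype=np.float32), zero)

    def test_checkpoint_roundtrip(self, tmp_path):
        items = _toy_items(12, seed=3)
        cfg = rd.DetectorConfig.desk(max_epochs=1)
        cfg.input_size = 32
        model = rd.train_detector(items, cfg, seed=2)
        rd.save_detector(model, tmp_path / "det.npz")
        loaded = rd.load_detector(tmp_path / "det.npz")
        x = np.random.default_rng(0).random((32, 32), dtype=np.float32)
        a = rd.predict_grid(model, x, x).values
        b = rd.predict_grid(loaded, x, x).values
        assert np.array_equal(a, b)


class TestDecisionAndHeatmap:
    def _grid(self, vals):
        return rd.PatchGrid(vals, "probability", rd.GridGeometry(crop_size=64))

    def test_image_decision_cases(self):
        g0 = self._grid(np.zeros((9, 9)))
        d = rd.image_decision(g0)
        assert not d.is_fracture and d.score == 0.0
        v = np.zeros((9, 9))
        v[2, 3] = 0.9
        d = rd.image_decision(self._grid(v), threshold=0.5)
        assert d.is_fracture and d.score == pytest.approx(0.9)
        d = rd.image_decision(self._grid(v * 0.99), threshold=1.0)
        assert not d.is_fracture

    def test_heatmap_zero_grid_is_uniform_tint(self):
        crop = np.random.default_rng(0).random((64, 64)).astype(np.float32)
        out = rd.heatmap(self._grid(np.zeros((9, 9))), crop, alpha=0.4)
        import matplotlib
        tint = matplotlib.colormaps["jet"](0.0)[:3]
        want = 0.6 * crop[..., None] + 0.4 * np.asarray(tint)[None, None]
        np.testing.assert_allclose(out / 255.0, want, atol=0.01)

    def test_heatmap_zero_alpha_is_grayscale(self):
        crop = np.random.default_rng(1).random((64, 64)).astype(np.float32)
        out = rd.heatmap(self._grid(np.random.default_rng(2).random((9, 9))),
                         crop, alpha=0.0)
        np.testing.assert_allclose(out[..., 0], out[..., 1])
        np.testing.assert_allclose(out / 255.0,
                                   np.repeat(crop[..., None], 3, axis=2), atol=0.01)

    def test_heatmap_peak_at_hot_cell(self, tmp_path):
        v = np.zeros((9, 9))
        v[6, 2] = 1.0
        crop = np.zeros((64, 64), dtype=np.float32)
        out = rd.heatmap(self._grid(v), crop, alpha=1.0,
                         out_path=tmp_path / "h.png")
        # red channel of the jet colormap peaks where the grid peaks
        r, c = np.unravel_index(np.argmax(out[..., 0].astype(int)
                                          - out[..., 2].astype(int)),
                                (64, 64))
        e = rd.GridGeometry(crop_size=64).edges
        assert e[6] - 4 <= r <= e[7] + 4
        assert e[2] - 4 <= c <= e[3] + 4
        assert (tmp_path / "h.png").exists()
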