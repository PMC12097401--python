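"""Mask geometry, repair losses, and the adversarial training contract."""

import numpy as np
import pytest

from mprfrax import auxmaps, inpaint
from conftest import make_crop_set


class TestMaskGeometry:
    def test_default_mask_covers_exactly_160_square(self):
        ind, regions = inpaint.make_mask(inpaint.MaskSpec())
        assert ind.sum() == 160 * 160 == 25_600
        assert ind.shape == (256, 256)

    def test_25_subregions_of_1024_pixels(self):
        _, regions = inpaint.make_mask(inpaint.MaskSpec())
        ids, counts = np.unique(regions[regions >= 0], return_counts=True)
        assert list(ids) == list(range(25))
        assert (counts == 32 * 32).all()
        assert (counts == 1024).all()

    def test_degenerate_1x1_grid(self):
        ind, regions = inpaint.make_mask(inpaint.MaskSpec(grid=(1, 1)))
        assert (regions[ind > 0] == 0).all()
        assert ind.sum() == 25_600

    def test_non_divisible_grid_rejected(self):
        with pytest.raises(ValueError):
            inpaint.make_mask(inpaint.MaskSpec(mask_size=160, grid=(7, 7)))

    def test_mask_is_centred(self):
        ind, _ = inpaint.make_mask(inpaint.MaskSpec(crop_size=64, mask_size=40))
        assert ind[12:52, 12:52].all()
        assert ind.sum() == 40 * 40


class TestApplyMask:
    def _aux(self, n):
        rng = np.random.default_rng(0)
        return auxmaps.AuxChannels(edge=rng.random((n, n)).astype(np.float32),
                                   texture=rng.random((n, n)).astype(np.float32),
                                   edge_method="t", texture_method="t")

    def test_zero_fill_blacks_out_mask_only(self):
        rng = np.random.default_rng(1)
        crop = rng.random((64, 64)).astype(np.float32)
        spec = inpaint.MaskSpec(crop_size=64, mask_size=40, fill=0.0)
        stack = inpaint.apply_mask(crop, self._aux(64), spec)
        ind, _ = inpaint.make_mask(spec)
        assert (stack[0][ind > 0] == 0.0).all()
        assert np.array_equal(stack[0][ind == 0], crop[ind == 0])
        assert np.array_equal(stack[3], ind)

    def test_changed_pixel_count_bounded_by_mask_area(self):
        rng = np.random.default_rng(2)
        crop = rng.random((256, 256)).astype(np.float32)
        spec = inpaint.MaskSpec(fill=0.0)  # no pixel equals its fill a.s.
        stack = inpaint.apply_mask(crop, self._aux(256), spec)
        assert int((stack[0] != crop).sum()) == 25_600

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        crop = rng.random((64, 64)).astype(np.float32)
        spec = inpaint.MaskSpec(crop_size=64, mask_size=40, fill=0.3)
        once = inpaint.apply_mask(crop, self._aux(64), spec)
        twice = inpaint.apply_mask(once[0], self._aux(64), spec)
        assert np.array_equal(once[0], twice[0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            inpaint.apply_mask(np.zeros((32, 32)), self._aux(64),
                               inpaint.MaskSpec(crop_size=64, mask_size=40))


class TestLosses:
    def test_adversarial_half_scores_give_log2(self):
        g, d = inpaint.adversarial_loss(np.full(10, 0.5), np.full(10, 0.5))
        assert g == pytest.approx(np.log(2))
        assert d == pytest.approx(np.log(2))

    def test_perfect_discriminator_limit(self):
        eps = 1e-5
        _, d = inpaint.adversarial_loss(np.full(4, 1 - eps), np.full(4, eps))
        assert d <= 2 * eps * abs(np.log(eps))

    def test_label_swap_symmetry(self):
        real, fake = np.full(4, 0.9), np.full(4, 0.1)
        _, d_good = inpaint.adversarial_loss(real, fake)
        _, d_bad = inpaint.adversarial_loss(fake, real)
        assert d_good < d_bad

    def test_perceptual_identity_and_offset(self):
        rng = np.random.default_rng(0)
        a = rng.random((16, 16))
        assert inpaint.perceptual_loss(a, a, lambda x: [x]) == 0.0
        c = 0.37
        assert inpaint.perceptual_loss(a, a + c, lambda x: [x]) == pytest.approx(c * c)

    def test_perceptual_symmetric(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((8, 8)), rng.random((8, 8))
        f = lambda x: [x, x ** 2]
        assert inpaint.perceptual_loss(a, b, f) == pytest.approx(
            inpaint.perceptual_loss(b, a, f))

    def test_region_loss_masked_mean(self):
        rng = np.random.default_rng(2)
        gt = rng.random((32, 32))
        mask = np.zeros((32, 32))
        mask[8:24, 8:24] = 1
        assert inpaint.region_loss(gt, gt, mask) == 0.0
        r = gt + 0.1 * mask
        assert inpaint.region_loss(r, gt, mask) == pytest.approx(0.1, abs=1e-7)
        r2 = gt + 5.0 * (1 - mask)  # changes outside the mask are invisible
        assert inpaint.region_loss(r2, gt, mask) == 0.0
        with pytest.raises(ValueError):
            inpaint.region_loss(gt, gt, np.zeros((32, 32)))

    def test_total_loss_arithmetic(self):
        w = inpaint.LossWeights(alpha=0.1, beta=1.0, gamma=1.0)
        gen, disc = inpaint.total_loss(0.7, 0.4, 0.2, 0.05, w)
        assert gen == pytest.approx(0.32)
        assert disc == pytest.approx(0.4)

    def test_total_loss_reduces_and_scales(self):
        w = inpaint.LossWeights(alpha=1.0, beta=0.0, gamma=0.0)
        gen, _ = inpaint.total_loss(0.7, 0.0, 9.9, 9.9, w)
        assert gen == pytest.approx(0.7)
        w2 = inpaint.LossWeights(alpha=0.2, beta=2.0, gamma=2.0)
        g1, _ = inpaint.total_loss(0.7, 0, 0.2, 0.05, inpaint.LossWeights(0.1, 1, 1))
        g2, _ = inpaint.total_loss(0.7, 0, 0.2, 0.05, w2)
        assert g2 == pytest.approx(2 * g1)
        with pytest.raises(ValueError):
            inpaint.LossWeights(0, 0, 0).validate()


class TestTraining:
    def test_default_config_matches_published_recipe(self):
        cfg = inpaint.RepairConfig()
        assert cfg.learning_rate == pytest.approx(1e-4)
        assert cfg.batch_size == 8
        assert cfg.dropout == 0.5
        assert cfg.max_epochs == 100
        assert cfg.lr_decay == pytest.approx(0.95)
        assert cfg.lr_decay_every == 5

    def test_smoke_run_records_finite_losses(self):
        items, auxs = make_crop_set(16, 0, seed=42)
        cfg = inpaint.RepairConfig.desk(max_epochs=2)
        model = inpaint.train_repair(items, auxs, cfg, seed=0)
        assert len(model.loss_history) == 2
        for row in model.loss_history:
            assert all(np.isfinite(v) for k, v in row.items() if k != "epoch")

    def test_fractured_items_rejected(self):
        items, auxs = make_crop_set(4, 2, seed=1)
        with pytest.raises(ValueError):
            inpaint.train_repair(items, auxs,
                                 inpaint.RepairConfig.desk(max_epochs=1))

    def test_seeded_training_reproducible(self):
        items, auxs = make_crop_set(8, 0, seed=3)
        cfg = inpaint.RepairConfig.desk(max_epochs=1)
        m1 = inpaint.train_repair(items, auxs, cfg, seed=5)
        m2 = inpaint.train_repair(items, auxs, cfg, seed=5)
        assert m1.loss_history == m2.loss_history
        for p, q in zip(m1.generator.params, m2.generator.params):
            assert np.array_equal(p, q)


class _IdentityGen:
    """Stub generator returning the image channel unchanged."""

    def forward(self, x, train=False):
        return x[:, :1].copy()


class TestReconstruct:
    @pytest.fixture(scope="class")
    def tiny_model(self):
        items, auxs = make_crop_set(8, 0, seed=7)
        cfg = inpaint.RepairConfig.desk(max_epochs=2)
        return inpaint.train_repair(items, auxs, cfg, seed=1), items, auxs

    def test_identity_stub_gives_zero_residual(self, tiny_model, healthy_crop64):
        """Diff(I, I) = 0: bypassing the generator with an identity stub (and
        an empty mask, so the stub sees the unoccluded crop) yields an
        all-zero residual."""
        model, _, _ = tiny_model
        crop, aux = healthy_crop64
        patched = inpaint.RepairModel(_IdentityGen(), model.discriminator,
                                      model.feature_net, model.mask_spec,
                                      model.config)
        spec = inpaint.MaskSpec(crop_size=64, mask_size=0, grid=(1, 1))
        res = inpaint.reconstruct(patched, crop, aux, mask_spec=spec,
                                  composite=False)
        assert np.abs(res.residual).max() == 0.0

    def test_composite_residual_zero_outside_mask(self, tiny_model, healthy_crop64):
        model, _, _ = tiny_model
        crop, aux = healthy_crop64
        res = inpaint.reconstruct(model, crop, aux, composite=True)
        ind, _ = inpaint.make_mask(model.mask_spec)
        assert np.abs(res.residual[ind == 0]).max() == 0.0
        assert res.residual.min() >= 0.0
        assert 0.0 <= res.reconstruction.min() and res.reconstruction.max() <= 1.0

    def test_scale_mismatch_rejected(self, tiny_model):
        model, _, _ = tiny_model
        with pytest.raises(ValueError):
            inpaint.reconstruct(model, np.zeros((32, 32), dtype=np.float32), None)

    def test_checkpoint_roundtrip(self, tiny_model, healthy_crop64, tmp_path):
        model, _, _ = tiny_model
        crop, aux = healthy_crop64
        p = tmp_path / "repair.npz"
        inpaint.save_repair_model(model, p)
        loaded = inpaint.load_repair_model(p)
        a = inpaint.reconstruct(model, crop, aux).reconstruction
        b = inpaint.reconstruct(loaded, crop, aux).reconstruction
        assert np.array_equal(a, b)
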