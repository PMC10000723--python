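"""GAN core: SSIM, loss closed forms, augmentation, networks, training."""

import numpy as np
import pytest

import spinefs as sf
from spinefs import nn
from spinefs.gan_core import (NO_AUGMENT, AugmentParams, DiscriminatorSpec,
                              GeneratorSpec, PatchDiscriminator, SsimParams,
                              TrainConfig, UNetGenerator, augment, crop_to,
                              discriminator_loss, generator_loss,
                              load_checkpoint, make_generator_from_checkpoint,
                              pad_to_multiple, save_checkpoint, ssim,
                              ssim_tensor, train)
from spinefs.nn import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(7)


class TestSsim:
    def test_identity_is_one(self, rng):
        x = rng.uniform(-1, 1, (32, 32))
        assert ssim(x, x) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a = rng.uniform(-1, 1, (24, 24))
        b = rng.uniform(-1, 1, (24, 24))
        assert ssim(a, b) == pytest.approx(ssim(b, a), rel=1e-12)

    def test_constant_images_closed_form(self):
        # zero variance saturates the contrast term: SSIM collapses to
        # (2 mx my + C1) / (mx^2 + my^2 + C1)
        p = SsimParams()
        mx, my = 0.3, -0.5
        a = np.full((20, 20), mx)
        b = np.full((20, 20), my)
        expect = (2 * mx * my + p.c1) / (mx ** 2 + my ** 2 + p.c1)
        assert ssim(a, b, p) == pytest.approx(expect, rel=1e-12)

    def test_matches_skimage(self, rng):
        from skimage.metrics import structural_similarity
        a = rng.uniform(-1, 1, (40, 40))
        b = np.clip(a + rng.normal(0, 0.3, a.shape), -1, 1)
        ref = structural_similarity(a, b, win_size=11, data_range=2.0)
        assert ssim(a, b) == pytest.approx(ref, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape mismatch"):
            ssim(np.zeros((10, 10)), np.zeros((12, 12)))

    def test_tensor_forward_agrees_with_numpy(self, rng):
        a = rng.uniform(-1, 1, (28, 28))
        b = rng.uniform(-1, 1, (28, 28))
        tv = ssim_tensor(Tensor(a[None, None]), Tensor(b[None, None])).item()
        assert tv == pytest.approx(ssim(a, b), abs=1e-9)


class TestLossClosedForms:
    def test_perfect_generator_and_fooled_discriminator_give_zero(self, rng):
        img = rng.uniform(-1, 1, (32, 32))
        scores = np.ones((4, 4))
        assert generator_loss(img, img, scores, 50.0) == pytest.approx(0.0)

    def test_uncertain_discriminator_gives_lambda_ln2(self, rng):
        img = rng.uniform(-1, 1, (32, 32))
        scores = np.full((4, 4), 0.5)
        loss = generator_loss(img, img, scores, 50.0)
        assert loss == pytest.approx(50 * np.log(2), rel=1e-12)
        assert loss == pytest.approx(34.657, abs=5e-4)

    def test_generator_loss_monotone_in_scores(self, rng):
        img = rng.uniform(-1, 1, (32, 32))
        losses = [generator_loss(img, img, np.full((3, 3), s), 50.0)
                  for s in (0.1, 0.4, 0.7, 0.99)]
        assert losses == sorted(losses, reverse=True)

    def test_discriminator_perfect_scores_zero_loss(self):
        assert discriminator_loss(np.ones((3, 3)), np.zeros((3, 3))) == 0.0

    def test_discriminator_uniform_scores_two_ln2(self):
        loss = discriminator_loss(np.full((3, 3), 0.5), np.full((3, 3), 0.5))
        assert loss == pytest.approx(2 * np.log(2), rel=1e-12)

    def test_discriminator_loss_nonnegative(self, rng):
        for _ in range(10):
            sr = rng.uniform(0.01, 0.99, (4, 4))
            ss = rng.uniform(0.01, 0.99, (4, 4))
            assert discriminator_loss(sr, ss) >= 0

    def test_invalid_scores_rejected(self, rng):
        img = rng.uniform(-1, 1, (32, 32))
        with pytest.raises(ValueError, match="finite"):
            generator_loss(img, img, np.array([[np.nan]]), 50.0)
        with pytest.raises(ValueError):
            discriminator_loss(np.array([[1.5]]), np.array([[0.5]]))


class TestAugment:
    def _record(self, rng):
        return (rng.uniform(-1, 1, (2, 32, 32)).astype(np.float32),
                rng.uniform(-1, 1, (1, 32, 32)).astype(np.float32))

    def test_no_op_params_leave_record_unchanged(self, rng):
        x, y = self._record(rng)
        ax, ay = augment((x, y), NO_AUGMENT, seed=3)
        assert np.array_equal(ax, x) and np.array_equal(ay, y)

    def test_flip_is_involution(self, rng):
        x, y = self._record(rng)
        p = AugmentParams(flip_prob=1.0, rotate_prob=0, smooth_prob=0,
                          noise_prob=0)
        ax, ay = augment((x, y), p, seed=1)
        bx, by = augment((ax, ay), p, seed=2)
        assert np.array_equal(bx, x) and np.array_equal(by, y)

    def test_deterministic_given_seed(self, rng):
        rec = self._record(rng)
        a = augment(rec, AugmentParams(), seed=9)
        b = augment(rec, AugmentParams(), seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_spatial_transform_hits_target_intensity_does_not(self, rng):
        x, y = self._record(rng)
        spatial = AugmentParams(flip_prob=1.0, rotate_prob=0, smooth_prob=0,
                                noise_prob=0)
        _, ay = augment((x, y), spatial, seed=1)
        assert np.array_equal(ay, y[..., ::-1])
        intensity = AugmentParams(flip_prob=0, rotate_prob=0, smooth_prob=1.0,
                                  noise_prob=1.0)
        ix, iy = augment((x, y), intensity, seed=1)
        assert np.array_equal(iy, y)            # target untouched
        assert not np.array_equal(ix, x)        # inputs perturbed

    def test_invalid_rotation_range_rejected(self):
        with pytest.raises(ValueError, match="rotation range"):
            AugmentParams(max_rotation_deg=90)


class TestNetworks:
    @pytest.mark.parametrize("depth,base", [(1, 4), (2, 8), (3, 4)])
    def test_generator_output_shape_and_range(self, depth, base, rng):
        gen = UNetGenerator(GeneratorSpec(depth=depth, base_channels=base), seed=1)
        x = rng.uniform(-1, 1, (2, 2, 32, 32)).astype(np.float32)
        y = gen.predict(x)
        assert y.shape == (2, 1, 32, 32)
        assert np.abs(y).max() <= 1.0

    def test_generator_rejects_indivisible_input(self, rng):
        gen = UNetGenerator(GeneratorSpec(depth=3), seed=1)
        with pytest.raises(ValueError, match="divisible"):
            gen.predict(rng.uniform(size=(1, 2, 30, 30)).astype(np.float32))

    def test_pad_to_multiple_roundtrip(self, rng):
        x = rng.uniform(size=(1, 2, 30, 27))
        padded, hw = pad_to_multiple(x, 8)
        assert padded.shape[-2] % 8 == 0 and padded.shape[-1] % 8 == 0
        assert np.array_equal(crop_to(padded, hw), x)

    def test_discriminator_grid_smaller_than_plane(self, rng):
        d = PatchDiscriminator(DiscriminatorSpec(), seed=1)
        cond = rng.uniform(-1, 1, (1, 2, 64, 64)).astype(np.float32)
        cand = rng.uniform(-1, 1, (1, 1, 64, 64)).astype(np.float32)
        s = d.scores(cond, cand)
        assert s.shape == (1, 1, 8, 8)
        assert np.all((s > 0) & (s < 1)) and np.all(np.isfinite(s))

    def test_dropout_only_active_in_training_mode(self, rng):
        gen = UNetGenerator(GeneratorSpec(depth=2, base_channels=4,
                                          dropout_rate=0.5), seed=1)
        x = rng.uniform(-1, 1, (1, 2, 16, 16)).astype(np.float32)
        a = gen.predict(x)
        b = gen.predict(x)
        assert np.array_equal(a, b)
        t1 = gen.forward(x, training=True, rng=np.random.default_rng(1)).data
        t2 = gen.forward(x, training=True, rng=np.random.default_rng(2)).data
        assert not np.array_equal(t1, t2)


class TestTraining:
    def test_history_bookkeeping_ten_slices_batch_one(self):
        from spinefs.config import PhantomConfig, make_phantom_dataset, \
            build_training_dataset
        ds = build_training_dataset(
            make_phantom_dataset(2, PhantomConfig(shape=(10, 32, 32),
                                                  n_vertebrae=3), 1))
        assert len(ds) == 10
        tc = TrainConfig(epochs=1, batch_size=1, seed=2, augment=None,
                         generator=GeneratorSpec(depth=2, base_channels=4),
                         discriminator=DiscriminatorSpec(n_blocks=2,
                                                         base_channels=4))
        _, history = train(ds, tc)
        assert len(history) == 1
        assert history[0]["n_g_updates"] == 10

    def test_training_is_deterministic(self, tiny_trained):
        _, history = train(tiny_trained["dataset"], tiny_trained["config"])
        ref = tiny_trained["history"]
        assert history[-1]["g_loss"] == ref[-1]["g_loss"]
        assert history[-1]["d_loss"] == ref[-1]["d_loss"]

    def test_loss_decomposition_exact(self, tiny_trained):
        for row in tiny_trained["history"]:
            assert row["g_loss"] == row["g_ssim_term"] + row["g_adv_term"]

    def test_empty_dataset_rejected(self):
        from spinefs.preprocess import PairedSliceDataset
        ds = PairedSliceDataset(np.zeros((0, 2, 8, 8)), np.zeros((0, 1, 8, 8)),
                                np.zeros(0))
        with pytest.raises(ValueError, match="empty"):
            train(ds, TrainConfig(epochs=1))

    def test_checkpoint_roundtrip(self, tiny_trained, tmp_path):
        path = tmp_path / "gan.npz"
        save_checkpoint(tiny_trained["checkpoint"], path)
        loaded = load_checkpoint(path)
        gen_a = make_generator_from_checkpoint(tiny_trained["checkpoint"])
        gen_b = make_generator_from_checkpoint(loaded)
        x = np.random.default_rng(0).uniform(-1, 1, (1, 2, 16, 16)
                                             ).astype(np.float32)
        assert np.array_equal(gen_a.predict(x), gen_b.predict(x))
        assert loaded["seed"] == tiny_trained["config"].seed

    def test_missing_checkpoint_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_checkpoint(tmp_path / "nope.npz")
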