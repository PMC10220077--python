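"""Model architectures, loss formulas, and short reduced-scale training runs."""

import math

import numpy as np
import pytest

from kmotion import (
    AESpec,
    CGANSpec,
    ImageGrid,
    TrainingConfig,
    UNetSpec,
    build_autoencoder,
    build_discriminator,
    build_unet,
    cgan_adversarial_loss,
    cgan_generator_objective,
    correct_image,
)
from kmotion.dataset import DatasetSplit
from kmotion.models import load_checkpoint, train
from kmotion.nn.autograd import Tensor
from kmotion.types import InvalidConfigError, PairedSample

DESK_AE = AESpec(n_stacks=3, first_channels=8)
DESK_UNET = UNetSpec(depth=2, first_channels=8)
DESK_CGAN = CGANSpec(generator=UNetSpec(depth=2, first_channels=8, dropout_p=0.5,
                                        use_batchnorm=True),
                     disc_first_channels=8)


def _tiny_split(n=6, size=32, seed=0):
    """A few genuinely corrupted pairs at miniature scale."""
    from kmotion import (
        CorruptionConfig,
        MotionBankConfig,
        PhantomConfig,
        generate_phantom,
        simulate_pair,
    )

    src = generate_phantom(PhantomConfig(size=size, seed=seed))
    bank = MotionBankConfig(max_shift=3, shift_step=1, max_rot=1.0, rot_step=0.5)
    pairs = [simulate_pair(src, bank_config=bank,
                           corruption_config=CorruptionConfig(
                               p_motion=0.6, seed=100 + i, pe_direction="vertical"),
                           provenance=f"p{i}")
             for i in range(n)]
    return DatasetSplit(train=pairs[:-2], validation=[], test=pairs[-2:])


class TestArchitectures:
    def test_autoencoder_bottleneck_and_shape(self):
        model = build_autoencoder(AESpec(), 256)
        assert model.bottleneck_size == 16  # 256 / 2^4
        small = build_autoencoder(DESK_AE, 64, seed=1)
        out = small.forward(Tensor(np.random.default_rng(0)
                                   .random((1, 1, 64, 64)).astype(np.float32)))
        assert out.shape == (1, 1, 64, 64)
        assert np.all((out.data >= 0) & (out.data <= 1))

    def test_autoencoder_indivisible_size_rejected(self):
        with pytest.raises(InvalidConfigError):
            build_autoencoder(AESpec(), 100)

    def test_unet_shape_preserved(self):
        model = build_unet(DESK_UNET, 32, seed=2)
        x = np.random.default_rng(1).random((1, 1, 32, 32)).astype(np.float32)
        assert model.forward(Tensor(x)).shape == (1, 1, 32, 32)

    def test_unet_depth_one_degenerates(self):
        model = build_unet(UNetSpec(depth=1, first_channels=4), 16, seed=0)
        x = np.random.default_rng(1).random((1, 1, 16, 16)).astype(np.float32)
        assert model.forward(Tensor(x)).shape == (1, 1, 16, 16)

    def test_unet_indivisible_size_rejected(self):
        with pytest.raises(InvalidConfigError):
            build_unet(UNetSpec(depth=4), 100)

    def test_unet_output_varies_with_input(self):
        model = build_unet(DESK_UNET, 32, seed=3)
        rng = np.random.default_rng(0)
        a = model.forward(Tensor(rng.random((1, 1, 32, 32)).astype(np.float32)))
        b = model.forward(Tensor(rng.random((1, 1, 32, 32)).astype(np.float32)))
        assert np.any(a.data != b.data)

    def test_discriminator_outputs_patch_map(self):
        disc = build_discriminator(DESK_CGAN, 64, seed=4)
        x = np.zeros((1, 1, 64, 64), np.float32)
        out = disc.forward(Tensor(x), Tensor(x))
        # 4 stride-2 convolutions: 64 -> 4 spatial, 1 channel, in [0, 1]
        assert out.shape == (1, 1, 4, 4)
        assert np.all((out.data >= 0) & (out.data <= 1))


class TestLossFormulas:
    def test_uniform_half_probabilities(self):
        d = np.full((1, 1, 4, 4), 0.5)
        assert cgan_adversarial_loss(d, d) == pytest.approx(-2 * math.log(2), abs=1e-9)

    def test_discriminator_optimum_approaches_zero(self):
        val = cgan_adversarial_loss(np.full((2, 2), 1.0), np.full((2, 2), 0.0))
        assert -1e-5 < val <= 0.0

    def test_always_nonpositive(self, rng):
        for _ in range(20):
            d_real = rng.random((3, 3))
            d_fake = rng.random((3, 3))
            assert cgan_adversarial_loss(d_real, d_fake) <= 0.0

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            cgan_adversarial_loss(np.array([[1.5]]), np.array([[0.5]]))

    def test_l1_term_zero_at_perfect_reconstruction(self, rng):
        img = rng.random((8, 8))
        assert cgan_generator_objective(-1.3, img, img, 100.0) == pytest.approx(-1.3)

    def test_lambda_zero_reduces_to_adversarial(self, rng):
        a, b = rng.random((4, 4)), rng.random((4, 4))
        assert cgan_generator_objective(-0.7, a, b, 0.0) == pytest.approx(-0.7)

    def test_unit_error_contributes_lambda(self):
        g = np.zeros((4, 4))
        t = np.ones((4, 4))
        assert cgan_generator_objective(0.0, g, t, 100.0) == pytest.approx(100.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(Exception):
            cgan_generator_objective(0.0, np.zeros((2, 2)), np.zeros((3, 3)), 1.0)


@pytest.fixture(scope="module")
def split():
    return _tiny_split()


class TestTraining:
    def _config(self, epochs=3):
        return TrainingConfig(learning_rate=2e-3, epochs=epochs, seed=5,
                              image_size=32, clip_grad_norm=1.0)

    @pytest.mark.parametrize("kind,spec", [("ae", DESK_AE), ("unet", DESK_UNET)])
    def test_reconstruction_loss_decreases(self, split, kind, spec):
        trained = train(kind, split, self._config(), spec=spec)
        hist = trained.history
        assert hist.loss.iloc[-1] < hist.loss.iloc[0]

    def test_cgan_history_records_components(self, split):
        trained = train("cgan", split, self._config(epochs=2), spec=DESK_CGAN)
        assert {"loss_d", "loss_g_adv", "loss_g_l1", "loss_g"} <= set(trained.history)

    def test_training_deterministic_for_seed(self, split):
        a = train("unet", split, self._config(epochs=2), spec=DESK_UNET)
        b = train("unet", split, self._config(epochs=2), spec=DESK_UNET)
        assert np.allclose(a.history.loss, b.history.loss)

    def test_empty_split_rejected(self):
        empty = DatasetSplit(train=[], validation=[], test=[])
        with pytest.raises(InvalidConfigError):
            train("unet", empty, self._config())

    def test_correct_image_contract(self, split):
        from kmotion.dataset import normalize_input

        trained = train("unet", split, self._config(epochs=1), spec=DESK_UNET)
        x = normalize_input(split.test[0].corrupted)
        out = correct_image(trained, x)
        assert out.shape == x.shape
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 255.0

    def test_correct_image_rejects_unnormalized(self, split):
        trained = train("unet", split, self._config(epochs=1), spec=DESK_UNET)
        with pytest.raises(ValueError):
            correct_image(trained, split.test[0].corrupted)

    def test_checkpoint_round_trip(self, split, tmp_path):
        from kmotion.dataset import normalize_input

        trained = train("cgan", split, self._config(epochs=1), spec=DESK_CGAN)
        trained.save(tmp_path / "ckpt.npz")
        back = load_checkpoint(tmp_path / "ckpt.npz")
        x = normalize_input(split.test[0].corrupted)
        np.testing.assert_allclose(correct_image(trained, x).pixels,
                                   correct_image(back, x).pixels, atol=1e-5)
        assert back.kind == "cgan" and back.discriminator is not None
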