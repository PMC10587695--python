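"""Translator architectures, losses, schedule and training contracts."""

import numpy as np
import pytest

import polstain.translator as tr
from polstain.translator import (
    DiscriminatorSpec,
    GeneratorSpec,
    TrainConfig,
    adversarial_loss,
    build_discriminator,
    build_generator,
    cycle_loss,
    discriminator_output_size,
    learning_rate,
    load_checkpoint,
    receptive_field,
    save_checkpoint,
    total_objective,
    train,
    transfer_init,
    translate,
)

from conftest import TOY_DISC_WIDTHS, toy_disc_spec, toy_gen_spec, toy_train_config


class _StubD:
    """Duck-typed discriminator returning a fixed raw (logit) map."""

    def __init__(self, raw):
        self.raw = np.asarray(raw, dtype=np.float32)

    def forward(self, batch):
        return np.broadcast_to(self.raw, (len(batch),) + self.raw.shape).copy(), None


class _StubNet:
    def __init__(self, fn):
        self.fn = fn

    def forward(self, x):
        return self.fn(x), None


class TestGenerator:
    def test_single_channel_input_to_rgb(self):
        g = build_generator(GeneratorSpec(in_channels=1, base_width=8), np.random.default_rng(0))
        y, _ = g.forward(np.zeros((1, 1, 256, 256), dtype=np.float32))
        assert y.shape == (1, 3, 256, 256)

    def test_output_within_tanh_range(self, rng):
        g = build_generator(toy_gen_spec(), np.random.default_rng(0))
        y, _ = g.forward(rng.normal(size=(2, 3, 32, 32)).astype(np.float32))
        assert y.min() >= -1.0 and y.max() <= 1.0

    def test_last_upsampling_width_is_base_width(self):
        """The feature map feeding the output projection has base_width
        channels at full resolution."""
        from polstain.nn import Conv2d, ReflectPad2d

        spec = GeneratorSpec(in_channels=3, base_width=16)
        g = build_generator(spec, np.random.default_rng(0))
        final_conv = [l for l in g.net.layers if isinstance(l, Conv2d)][-1]
        assert final_conv.c_in == spec.base_width
        assert final_conv.c_out == 3

    @pytest.mark.parametrize("size", [(32, 32), (64, 32), (48, 80)])
    def test_output_matches_input_size(self, size):
        g = build_generator(toy_gen_spec(), np.random.default_rng(0))
        y, _ = g.forward(np.zeros((1, 3) + size, dtype=np.float32))
        assert y.shape == (1, 3) + size

    def test_invalid_channels_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(in_channels=2)


class TestDiscriminator:
    def test_patch_map_size_recursion(self):
        spec = DiscriminatorSpec()
        d = build_discriminator(DiscriminatorSpec(widths=TOY_DISC_WIDTHS), np.random.default_rng(0))
        for n in (64, 96, 128):
            m, _ = d.forward(np.zeros((1, 3, n, n), dtype=np.float32))
            assert m.shape[-1] == discriminator_output_size(spec, n)

    def test_receptive_field_is_70(self):
        assert receptive_field(DiscriminatorSpec()) == 70

    def test_half_size_input_gives_14(self):
        assert discriminator_output_size(DiscriminatorSpec(), 128) == 14


class TestLosses:
    def test_uninformative_discriminator_log_value(self):
        d = _StubD(np.zeros((1, 4, 4)))  # sigmoid(0) = 0.5 everywhere
        x = np.zeros((2, 3, 8, 8), dtype=np.float32)
        assert adversarial_loss(d, x, x, "log") == pytest.approx(-2 * np.log(2), abs=1e-6)

    def test_perfect_discriminator_log_value(self):
        d = _PerfectD()
        real = np.ones((1, 3, 8, 8), dtype=np.float32)
        fake = -np.ones((1, 3, 8, 8), dtype=np.float32)
        assert adversarial_loss(d, real, fake, "log") == pytest.approx(0.0, abs=1e-6)

    def test_matches_manual_expansion_on_2x2_map(self):
        raw = np.array([[0.3, -0.1], [1.2, 0.4]], dtype=np.float32)[None]
        d = _StubD(raw)
        x = np.zeros((1, 3, 8, 8), dtype=np.float32)
        p = 1 / (1 + np.exp(-raw))
        expected = np.mean(np.log(p)) + np.mean(np.log(1 - p))
        assert adversarial_loss(d, x, x, "log") == pytest.approx(expected, rel=1e-5)

    def test_least_squares_mode(self):
        d = _StubD(np.full((1, 2, 2), 0.25))
        x = np.zeros((1, 3, 8, 8), dtype=np.float32)
        assert adversarial_loss(d, x, x, "least_squares") == pytest.approx(0.75**2 + 0.25**2)

    def test_cycle_loss_identity_maps(self, rng):
        ident = _StubNet(lambda x: x)
        x = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
        assert cycle_loss(ident, ident, x) == 0.0

    def test_cycle_loss_constant_offset(self, rng):
        g = _StubNet(lambda x: x + 0.37)
        f = _StubNet(lambda x: x)
        x = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
        assert cycle_loss(g, f, x) == pytest.approx(0.37, rel=1e-5)

    def test_cycle_loss_elementwise_oracle(self, rng):
        noise = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
        g = _StubNet(lambda x: x)
        f = _StubNet(lambda x: x + noise[: len(x)])
        x = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
        assert cycle_loss(g, f, x) == pytest.approx(np.mean(np.abs(noise)), rel=1e-5)

    def test_total_objective_affine_in_lambda(self):
        losses = {"adv_g": 0.4, "adv_f": 0.1, "cyc_forward": 0.2, "cyc_backward": 0.3}
        vals = [total_objective(losses, lam) for lam in (0.0, 5.0, 10.0)]
        assert vals[0] == pytest.approx(0.5)
        assert vals[2] - vals[1] == pytest.approx(vals[1] - vals[0])
        zero_cyc = {**losses, "cyc_forward": 0.0, "cyc_backward": 0.0}
        assert total_objective(zero_cyc, 3.0) == total_objective(zero_cyc, 99.0)


class _PerfectD:
    def forward(self, batch):
        val = 500.0 if batch.max() > 0 else -500.0
        return np.full((len(batch), 1, 2, 2), val, dtype=np.float32), None


class TestSchedule:
    def test_flat_then_linear_decay(self):
        cfg = TrainConfig(epochs=100, flat_epochs=50)
        assert learning_rate(cfg, 25) == cfg.lr0
        assert learning_rate(cfg, 50) == cfg.lr0
        assert learning_rate(cfg, 75) == pytest.approx(0.5 * cfg.lr0)
        assert learning_rate(cfg, 100) == pytest.approx(0.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=10, flat_epochs=20)
        with pytest.raises(ValueError):
            TrainConfig(gan_mode="wasserstein")


@pytest.fixture(scope="module")
def tiny_run():
    """A deterministic 2-epoch toy run shared by contract tests."""
    rng = np.random.default_rng(5)
    x = rng.uniform(-1, 1, (6, 32, 32, 3)).astype(np.float32)
    y = rng.uniform(-1, 1, (6, 32, 32, 3)).astype(np.float32)
    cfg = TrainConfig(epochs=2, flat_epochs=1, batch_size=2, seed=9)
    gspec = GeneratorSpec(in_channels=3, base_width=4, n_res_blocks=2)
    dspec = DiscriminatorSpec(widths=(4, 8, 8, 8, 1))
    pair = train(x, y, cfg, gspec, dspec)
    return x, y, cfg, gspec, dspec, pair


class TestTraining:
    def test_history_records_schedule_and_lengths(self, tiny_run):
        _, _, cfg, _, _, pair = tiny_run
        assert len(pair.history.epochs) == cfg.epochs
        for e in pair.history.epochs:
            assert e["lr"] == learning_rate(cfg, e["epoch"])

    def test_same_seed_bitwise_identical_history(self, tiny_run):
        x, y, cfg, gspec, dspec, pair = tiny_run
        again = train(x, y, cfg, gspec, dspec)
        assert pair.history.epochs == again.history.epochs

    def test_one_step_touches_every_trainable_tensor(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(-1, 1, (2, 32, 32, 3)).astype(np.float32)
        y = rng.uniform(-1, 1, (2, 32, 32, 3)).astype(np.float32)
        cfg = TrainConfig(epochs=1, flat_epochs=1, batch_size=2, seed=1)
        gspec = GeneratorSpec(in_channels=3, base_width=4, n_res_blocks=1)
        dspec = DiscriminatorSpec(widths=(4, 8, 8, 8, 1))
        before = {}
        pair = train(x, y, cfg, gspec, dspec)
        # rebuild initial weights with the same seed to compare
        init = np.random.default_rng(cfg.seed)
        fresh = tr.ModelPair(
            g=build_generator(gspec, init),
            f=build_generator(GeneratorSpec(in_channels=3, base_width=4, n_res_blocks=1), init),
            d_x=build_discriminator(DiscriminatorSpec(in_channels=3, widths=dspec.widths), init),
            d_y=build_discriminator(DiscriminatorSpec(in_channels=3, widths=dspec.widths), init),
            g_spec=gspec, f_spec=gspec, d_spec=dspec,
        )
        for name in ("g", "f", "d_x", "d_y"):
            for w0, w1 in zip(getattr(fresh, name).get_weights(), getattr(pair, name).get_weights()):
                assert not np.array_equal(w0, w1), f"dead tensor in {name}"

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(np.zeros((0, 32, 32, 3)), np.zeros((2, 32, 32, 3)), TrainConfig(epochs=1))

    def test_channel_mismatch_rejected(self, rng):
        x = rng.uniform(-1, 1, (2, 32, 32, 3)).astype(np.float32)
        with pytest.raises(ValueError, match="channels"):
            train(x, x, TrainConfig(epochs=1, flat_epochs=1), GeneratorSpec(in_channels=1))


class TestTranslateAndTransfer:
    def test_translate_shape_range_determinism(self, tiny_run):
        *_, pair = tiny_run
        rng = np.random.default_rng(2)
        enc = rng.uniform(-1, 1, (40, 28, 3)).astype(np.float32)
        out1 = translate(pair.g, enc)
        out2 = translate(pair.g, enc)
        assert out1.shape == (40, 28, 3) and out1.dtype == np.uint8
        assert np.array_equal(out1, out2)

    def test_untrained_generator_output_in_range(self):
        g = build_generator(toy_gen_spec(), np.random.default_rng(0))
        out = translate(g, np.zeros((32, 32, 3), dtype=np.float32))
        assert out.min() >= 0 and out.max() <= 255

    def test_channel_and_size_validation(self, tiny_run):
        *_, pair = tiny_run
        with pytest.raises(ValueError, match="channels"):
            translate(pair.g, np.zeros((32, 32, 1), dtype=np.float32))
        with pytest.raises(ValueError, match="divisible"):
            translate(pair.g, np.zeros((30, 32, 3), dtype=np.float32))

    def test_transfer_copies_all_weights(self, tiny_run):
        x, y, cfg, gspec, dspec, pair = tiny_run
        rng = np.random.default_rng(99)
        fresh = train(x, y, TrainConfig(epochs=1, flat_epochs=1, batch_size=2, seed=42),
                      gspec, dspec)
        transfer_init(fresh, pair)
        for name in ("g", "f", "d_x", "d_y"):
            for a, b in zip(getattr(fresh, name).get_weights(), getattr(pair, name).get_weights()):
                assert np.array_equal(a, b)

    def test_transfer_architecture_mismatch_rejected(self, tiny_run):
        x, y, cfg, gspec, dspec, pair = tiny_run
        other = train(
            x[..., :1], y, TrainConfig(epochs=1, flat_epochs=1, batch_size=2, seed=1),
            GeneratorSpec(in_channels=1, base_width=4, n_res_blocks=2), dspec,
        )
        with pytest.raises(ValueError, match="shape"):
            transfer_init(other, pair)

    def test_checkpoint_round_trip(self, tiny_run, tmp_path):
        *_, pair = tiny_run
        save_checkpoint(pair, tmp_path / "ck.npz")
        loaded = load_checkpoint(tmp_path / "ck.npz")
        for a, b in zip(loaded.g.get_weights(), pair.g.get_weights()):
            assert np.array_equal(a, b)
        enc = np.zeros((32, 32, 3), dtype=np.float32)
        assert np.array_equal(translate(loaded.g, enc), translate(pair.g, enc))
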