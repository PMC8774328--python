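"""Schedule, losses, ternary forward, and the training loop."""

import numpy as np
import pytest

from wtdfn import models, synthetic, training
from wtdfn.exceptions import ConfigError, InvalidInputError
from wtdfn.training import TrainConfig, compute_loss, lr_at_epoch, ternary_forward


class TestSchedule:
    def test_linear_warmup(self):
        cfg = TrainConfig()
        assert lr_at_epoch(cfg, 0) == pytest.approx(0.005)
        assert lr_at_epoch(cfg, 1) == pytest.approx(0.01)

    def test_first_post_warmup_block_holds_base_lr(self):
        cfg = TrainConfig()
        assert lr_at_epoch(cfg, 2) == pytest.approx(0.01)
        assert lr_at_epoch(cfg, 3) == pytest.approx(0.01)

    def test_stepped_decay_closed_form(self):
        cfg = TrainConfig()
        assert lr_at_epoch(cfg, 6) == pytest.approx(0.01 * 0.95 ** 2)
        for epoch in range(2, 120):
            expected = 0.01 * 0.95 ** ((epoch - 2) // 2)
            assert lr_at_epoch(cfg, epoch) == pytest.approx(expected)


class TestConfig:
    def test_defaults_are_valid(self):
        TrainConfig().validate()

    @pytest.mark.parametrize("field,value", [
        ("epochs", 0), ("batch_size", 0), ("base_lr", -1.0),
        ("decay_factor", 0.0), ("decay_factor", 1.5), ("optimizer", "ranger"),
    ])
    def test_invalid_values_rejected(self, field, value):
        cfg = TrainConfig(**{field: value})
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_yaml_roundtrip(self, tmp_path):
        cfg = TrainConfig(epochs=10, batch_size=3, seed=4)
        cfg.to_yaml(tmp_path / "c.yaml")
        loaded = TrainConfig.from_yaml(tmp_path / "c.yaml")
        assert loaded == cfg

    def test_unknown_yaml_key_rejected(self, tmp_path):
        (tmp_path / "c.yaml").write_text("epohcs: 10\n")
        with pytest.raises(ConfigError):
            TrainConfig.from_yaml(tmp_path / "c.yaml")


class TestComputeLoss:
    def test_perfect_predictions_give_zero(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert compute_loss(p, p, p, [0, 1]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_binary_predictions_give_log_two(self):
        p = np.full((3, 2), 0.5)
        assert compute_loss(p, p, p, [0, 1, 0]) == pytest.approx(np.log(2))

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(0)
        streams = [rng.dirichlet(np.ones(3), size=4) for _ in range(3)]
        labels = rng.integers(0, 3, size=4)
        expected = 0.0
        for probs in streams:
            for i, label in enumerate(labels):
                expected -= np.log(probs[i, label])
        expected /= 3 * 4
        assert compute_loss(*streams, labels) == pytest.approx(expected)

    def test_out_of_range_label_rejected(self):
        p = np.full((2, 2), 0.5)
        with pytest.raises(InvalidInputError):
            compute_loss(p, p, p, [0, 2])

    def test_loss_nonnegative_and_finite(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            streams = [rng.dirichlet(np.ones(2), size=5) for _ in range(3)]
            loss = compute_loss(*streams, rng.integers(0, 2, size=5))
            assert np.isfinite(loss) and loss >= 0


class TestTernaryForward:
    @pytest.fixture()
    def frozen_model(self):
        return models.build_wtdfn("toy_cnn", M=4, c=2, seed=2)

    @pytest.fixture()
    def batch(self):
        rng = np.random.default_rng(3)
        return rng.random((4, 32, 32, 3)).astype(np.float32)

    def test_seeded_determinism(self, frozen_model, batch):
        out1 = ternary_forward(frozen_model, batch, rng=np.random.default_rng(7))
        out2 = ternary_forward(frozen_model, batch, rng=np.random.default_rng(7))
        for a, b in zip(out1[:3], out2[:3]):
            np.testing.assert_array_equal(a, b)

    def test_probabilities_normalized(self, frozen_model, batch):
        p_raw, p_crop, p_erase, _ = ternary_forward(
            frozen_model, batch, rng=np.random.default_rng(0))
        for p in (p_raw, p_crop, p_erase):
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
            assert (p >= 0).all()

    def test_constant_attention_degenerates_to_raw_stream(self, frozen_model, batch):
        # constant maps normalize to zero: crop falls back to the full image
        # and the erase mask keeps every pixel
        frozen_model.attention_head.weight.data[...] = 0.0
        frozen_model.attention_head.bias.data[...] = 1.0
        p_raw, p_crop, p_erase, A = ternary_forward(
            frozen_model, batch, rng=np.random.default_rng(0))
        assert np.ptp(A) == 0.0
        np.testing.assert_allclose(p_crop, p_raw, atol=1e-6)
        np.testing.assert_allclose(p_erase, p_raw, atol=1e-6)

    def test_empty_batch_rejected(self, frozen_model):
        with pytest.raises(InvalidInputError):
            ternary_forward(frozen_model, np.zeros((0, 32, 32, 3)))


def tiny_sets(n=10, size=32, seed=0):
    spec = synthetic.SyntheticSpec(image_size=size)
    images, labels, _, splits = synthetic.generate_arrays(n, seed=seed, spec=spec)
    splits = np.array(splits)
    train = (images[splits == "train"], labels[splits == "train"])
    val = (images[splits == "val"], labels[splits == "val"])
    return train, val


class TestTrainLoop:
    def test_history_lr_column_matches_schedule(self):
        train_set, val_set = tiny_sets()
        model = models.build_wtdfn("toy_cnn", M=2, c=2, seed=0, input_resolution=32)
        cfg = TrainConfig(epochs=3, batch_size=4, M=2, seed=0, base_lr=0.003)
        _, history = training.train(model, train_set, val_set, cfg)
        for rec in history.records:
            assert rec["lr"] == pytest.approx(lr_at_epoch(cfg, rec["epoch"]))
        assert all(np.isfinite(rec["train_loss"]) and rec["train_loss"] >= 0
                   for rec in history.records)

    def test_identical_seeds_reproduce_validation_wf1s(self):
        results = []
        for _ in range(2):
            train_set, val_set = tiny_sets()
            model = models.build_wtdfn("toy_cnn", M=2, c=2, seed=1, input_resolution=32)
            cfg = TrainConfig(epochs=2, batch_size=4, M=2, seed=1, base_lr=0.003)
            _, history = training.train(model, train_set, val_set, cfg)
            results.append(history.column("val_wf1s"))
        assert results[0] == results[1]

    def test_single_stream_ablation_runs_plain_backbone_training(self):
        train_set, val_set = tiny_sets()
        model = models.build_wtdfn("toy_cnn", c=2, seed=0, use_attention=False,
                                   input_resolution=32)
        cfg = TrainConfig(epochs=2, batch_size=4, seed=0, base_lr=0.003, ternary=False)
        _, history = training.train(model, train_set, val_set, cfg)
        assert len(history.records) == 2

    def test_empty_dataset_rejected(self):
        model = models.build_wtdfn("toy_cnn", M=2, c=2, seed=0)
        with pytest.raises(ConfigError):
            training.train(model, (np.zeros((0, 32, 32, 3)), np.zeros(0, dtype=int)),
                           (np.zeros((0, 32, 32, 3)), np.zeros(0, dtype=int)),
                           TrainConfig(epochs=1))

    def test_history_csv_export(self, tmp_path):
        train_set, val_set = tiny_sets()
        model = models.build_wtdfn("toy_cnn", M=2, c=2, seed=0, input_resolution=32)
        cfg = TrainConfig(epochs=1, batch_size=4, M=2, seed=0, base_lr=0.003)
        _, history = training.train(model, train_set, val_set, cfg)
        history.to_csv(tmp_path / "h.csv")
        text = (tmp_path / "h.csv").read_text().splitlines()
        assert text[0] == "epoch,lr,train_loss,train_err,val_err,val_wf1s"
        assert len(text) == 2
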