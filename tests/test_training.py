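"""Loss assembly, scalers, the training loop, checkpoints."""

import numpy as np
import pytest

from deepcrop.factors import FACTORS
from deepcrop.model import DeepCropModel
from deepcrop.nn import Tensor
from deepcrop.training import (
    Scaler,
    TrainingSettings,
    assemble_loss,
    load_checkpoint,
    save_checkpoint,
    train,
)

from conftest import tiny_model_config


def unit_scaler(n=len(FACTORS)):
    return Scaler(np.zeros(n), np.ones(n))


def perfect_predictions(cfg, target):
    return {
        name: Tensor(target[:, :, cfg.factor_columns(name)])
        for name in cfg.decoder_map
    }


class TestLossAssembly:
    cfg = tiny_model_config()

    def test_perfect_predictions_zero_everywhere(self):
        target = np.random.default_rng(0).normal(size=(2, 3, len(FACTORS)))
        lb = assemble_loss(
            perfect_predictions(self.cfg, target), target, self.cfg, unit_scaler()
        )
        assert lb.total == 0.0
        assert all(v == 0.0 for v in lb.terms.values())

    def test_exactly_eight_terms_in_multitask_mode(self):
        target = np.zeros((1, 3, len(FACTORS)))
        lb = assemble_loss(
            perfect_predictions(self.cfg, target), target, self.cfg, unit_scaler()
        )
        assert lb.n_terms == 8
        assert set(lb.terms) == set(self.cfg.decoder_map) | {
            "vegetative_fw", "vegetative_dw"
        }

    def test_hand_computed_single_day_toy(self):
        """One day, unit scales: an error e on leaf FW gives a leaf-decoder
        MSE of e^2/4 (4 leaf factors) and vegetative FW term (e/3)^2
        (three summed scales); total is the mean of the eight terms."""
        cfg = tiny_model_config(memory_length=1)
        target = np.zeros((1, 1, len(FACTORS)))
        preds = perfect_predictions(cfg, target)
        e = 0.6
        leaf_cols = cfg.decoder_map["leaf"]
        pos = leaf_cols.index("leaf_fw_g")
        data = preds["leaf"].data.copy()
        data[0, 0, pos] = e
        preds["leaf"] = Tensor(data)
        lb = assemble_loss(preds, target, cfg, unit_scaler())
        assert lb.terms["leaf"] == pytest.approx(e**2 / len(leaf_cols))
        assert lb.terms["vegetative_fw"] == pytest.approx((e / 3) ** 2)
        assert lb.terms["vegetative_dw"] == 0.0
        expected_total = (e**2 / len(leaf_cols) + (e / 3) ** 2) / 8
        assert lb.total == pytest.approx(expected_total)

    def test_conservation_vanishes_for_compensating_errors(self):
        """If organ FW errors cancel in natural units the conservation term
        is zero even though each organ is wrong."""
        cfg = tiny_model_config(memory_length=1)
        scaler = unit_scaler()
        target = np.zeros((1, 1, len(FACTORS)))
        preds = perfect_predictions(cfg, target)
        idx = {f: cfg.decoder_map[d].index(f)
               for d, fs in cfg.decoder_map.items() for f in fs}
        leaf = preds["leaf"].data.copy()
        stem = preds["stem"].data.copy()
        leaf[0, 0, idx["leaf_fw_g"]] = +1.0
        stem[0, 0, idx["stem_fw_g"]] = -1.0
        preds["leaf"], preds["stem"] = Tensor(leaf), Tensor(stem)
        lb = assemble_loss(preds, target, cfg, scaler)
        assert lb.terms["vegetative_fw"] == 0.0
        assert lb.terms["leaf"] > 0 and lb.terms["stem"] > 0

    def test_total_invariant_to_decoder_order(self):
        rng = np.random.default_rng(1)
        target = rng.normal(size=(2, 3, len(FACTORS)))
        preds = {
            name: Tensor(rng.normal(size=(2, 3, len(group))))
            for name, group in self.cfg.decoder_map.items()
        }
        lb1 = assemble_loss(preds, target, self.cfg, unit_scaler())
        reversed_preds = dict(reversed(list(preds.items())))
        lb2 = assemble_loss(reversed_preds, target, self.cfg, unit_scaler())
        assert lb1.total == pytest.approx(lb2.total, rel=1e-12)

    def test_single_mode_has_one_term(self):
        target = np.zeros((1, 3, len(FACTORS)))
        lb = assemble_loss(
            perfect_predictions(self.cfg, target), target, self.cfg,
            unit_scaler(), mode="single",
        )
        assert lb.n_terms == 1

    def test_unknown_mode_rejected(self):
        target = np.zeros((1, 3, len(FACTORS)))
        with pytest.raises(ValueError, match="loss mode"):
            assemble_loss(
                perfect_predictions(self.cfg, target), target, self.cfg,
                unit_scaler(), mode="bogus",
            )


class TestScaler:
    def test_transform_standardizes_and_inverts(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5, 3, size=(100, 4))
        sc = Scaler.fit(x)
        z = sc.transform(x)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(sc.inverse(z), x, atol=1e-9)

    def test_zero_variance_column_warns_and_uses_unit_scale(self):
        x = np.ones((10, 2))
        x[:, 0] = np.arange(10)
        with pytest.warns(UserWarning, match="zero-variance"):
            sc = Scaler.fit(x)
        assert sc.scale[1] == 1.0

    def test_validation_uses_training_statistics(self):
        rng = np.random.default_rng(1)
        train_x = rng.normal(0, 1, size=(50, 3))
        val_x = rng.normal(10, 1, size=(50, 3))  # deliberately shifted
        sc = Scaler.fit(train_x)
        z = sc.transform(val_x)
        assert z.mean() > 5  # not re-centered on its own statistics


def _toy_dataset(cfg, n_days=24, n_draws=2, seed=0):
    rng = np.random.default_rng(seed)
    n_f = len(FACTORS)
    features = rng.normal(size=(n_days, 24, 7)).cumsum(axis=0) * 0.05
    labels = np.abs(rng.normal(size=(n_draws, n_days, n_f)).cumsum(axis=1))
    from deepcrop.growth_records import make_training_windows

    return make_training_windows(
        {"toy": (features, labels)}, cfg.memory_length, split=0.75, seed=seed
    )


class TestTrainingLoop:
    def test_loss_descends_on_toy_problem(self):
        cfg = tiny_model_config()
        train_set, val_set = _toy_dataset(cfg)
        trained, trace = train(
            train_set, val_set, cfg,
            TrainingSettings(epochs=8, batch_size=16, seed=0),
        )
        assert trace["total"].iloc[-1] < trace["total"].iloc[0]

    def test_fixed_seed_reproduces_first_epoch_loss(self):
        cfg = tiny_model_config()
        train_set, val_set = _toy_dataset(cfg)
        settings = TrainingSettings(epochs=1, batch_size=16, seed=3)
        _, trace_a = train(train_set, val_set, cfg, settings)
        _, trace_b = train(train_set, val_set, cfg, settings)
        assert trace_a["total"].iloc[0] == trace_b["total"].iloc[0]
        assert trace_a["val_total"].iloc[0] == trace_b["val_total"].iloc[0]

    def test_best_state_is_validation_argmin(self):
        cfg = tiny_model_config()
        train_set, val_set = _toy_dataset(cfg)
        trained, trace = train(
            train_set, val_set, cfg,
            TrainingSettings(epochs=5, batch_size=16, seed=1),
        )
        assert trace.attrs["best_val"] == pytest.approx(trace["val_total"].min())
        assert trace.attrs["best_epoch"] == int(trace["val_total"].idxmin())

    def test_gradient_step_reduces_loss_on_frozen_batch(self):
        cfg = tiny_model_config(dropout=0.0)
        model = DeepCropModel(cfg)
        rng = np.random.default_rng(0)
        env = rng.normal(size=(8, cfg.input_steps, 7))
        prev = rng.normal(size=(8, cfg.memory_length, len(FACTORS)))
        target = rng.normal(size=(8, cfg.memory_length, len(FACTORS)))
        from deepcrop.nn import Adam

        opt = Adam(model.parameters(), lr=1e-3)
        losses = []
        for _ in range(8):
            preds, _ = model.forward(env, prev, train=True, rng=rng)
            lb = assemble_loss(preds, target, cfg, unit_scaler())
            losses.append(lb.total)
            opt.zero_grad()
            lb.total_tensor.backward()
            opt.step()
        assert losses[-1] < losses[0]


@pytest.fixture(scope="module")
def trained():
    cfg = tiny_model_config()
    train_set, val_set = _toy_dataset(cfg)
    trained, _ = train(
        train_set, val_set, cfg, TrainingSettings(epochs=1, batch_size=16)
    )
    return trained


class TestCheckpoints:
    def test_round_trip_forward_identical(self, trained, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(trained, path)
        loaded = load_checkpoint(path)
        rng = np.random.default_rng(0)
        env = rng.normal(size=(2, trained.cfg.input_steps, 7))
        prev = rng.normal(size=(2, trained.cfg.memory_length, len(FACTORS)))
        a = trained.model.predict(env, prev)
        b = loaded.model.predict(env, prev)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])
        np.testing.assert_array_equal(
            loaded.factor_scaler.mean, trained.factor_scaler.mean
        )

    def test_mismatched_decoder_map_rejected(self, trained, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(trained, path)
        wrong = {"all": tuple(FACTORS)}
        with pytest.raises(ValueError, match="decoder map"):
            load_checkpoint(path, expect_decoder_map=wrong)

    def test_missing_or_corrupt_file_raises(self, tmp_path):
        with pytest.raises((ValueError, FileNotFoundError)):
            load_checkpoint(tmp_path / "nope.npz")
        bad = tmp_path / "bad.npz"
        bad.write_bytes(b"not a checkpoint")
        with pytest.raises(ValueError):
            load_checkpoint(bad)

    def test_checkpoint_contains_scaler_statistics(self, trained, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(trained, path)
        archive = np.load(path)
        # simulation cannot run without the scalers; they must be embedded
        data = {k: archive[k] for k in archive.files if not k.startswith("scaler/")}
        stripped = tmp_path / "stripped.npz"
        np.savez(stripped, **data)
        with pytest.raises(ValueError, match="scaler"):
            load_checkpoint(stripped)
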