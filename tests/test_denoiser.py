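"""Residual U-Net contracts: bypass identity, output range, tiled
inference, patient-level splitting, early stopping, checkpointing."""

import numpy as np
import pytest

from petbf.denoiser import (
    FoldAssignment,
    TrainConfig,
    UNetSpec,
    build_model,
    denoise_volume,
    load_checkpoint,
    save_checkpoint,
    split_patients,
    train,
)
from petbf.errors import ConfigurationError, ValidationError
from petbf.preprocess import PatchPair
from petbf.volume_io import Volume


def _zero_body(model):
    """Zero all body weights so the model is exactly the bypass."""
    for p in model.params():
        p.value[...] = 0.0
    return model


class TestBypassIdentity:
    def test_zero_body_is_identity_on_clamped_range(self, rng):
        model = _zero_body(build_model(UNetSpec(depth=2, base_channels=4), seed=0))
        eps = model.spec.bypass_epsilon
        x = rng.uniform(0, 1, (2, 8, 8, 8, 1)).astype(np.float32)
        y = model.predict(x)
        np.testing.assert_allclose(y, np.clip(x, eps, 1 - eps), atol=1e-6)

    def test_untrained_model_is_identity(self, rng):
        # zero-initialized head: fresh models start at the bypass identity
        model = build_model(UNetSpec(depth=2, base_channels=4), seed=1)
        x = rng.uniform(0.1, 0.9, (1, 8, 8, 8, 1)).astype(np.float32)
        np.testing.assert_allclose(model.predict(x), x, atol=1e-6)

    def test_output_range_for_random_weights(self, rng):
        model = build_model(UNetSpec(depth=2, base_channels=4), seed=2)
        # randomize the head too (He init leaves it zero) so the body is active
        for p in model.head.params():
            p.value[...] = 0.3 * rng.standard_normal(p.value.shape).astype(np.float32)
        y = model.predict(rng.uniform(0, 1, (1, 8, 8, 8, 1)).astype(np.float32))
        assert (y > 0).all() and (y < 1).all()
        assert float(np.abs(y - model.predict(y * 0 + 0.5)).max()) >= 0  # body active, finite

    def test_incompatible_depth_rejected(self):
        model = build_model(UNetSpec(depth=4, base_channels=2), seed=0)
        with pytest.raises(ConfigurationError):
            model.predict(np.zeros((1, 4, 4, 4, 1), dtype=np.float32))


class TestTiledInference:
    def test_zero_body_tiling_is_seam_free(self, rng):
        model = _zero_body(build_model(UNetSpec(depth=2, base_channels=4), seed=0))
        vol = Volume(rng.random((40, 40, 24)) * 6, (3.3, 3.3, 2.0))
        out = denoise_volume(model, vol, tile=16, overlap=4)
        # identity propagated through overlapping tiles and blending
        np.testing.assert_allclose(out.data, vol.data, rtol=1e-4, atol=1e-3)

    def test_small_axis_reflect_padded(self, rng):
        model = _zero_body(build_model(UNetSpec(depth=2, base_channels=4), seed=0))
        vol = Volume(rng.random((20, 20, 10)), (3.3, 3.3, 2.0))
        out = denoise_volume(model, vol, tile=16, overlap=4)
        assert out.shape == vol.shape

    def test_bad_tile_config_rejected(self, rng):
        model = build_model(UNetSpec(depth=3, base_channels=2), seed=0)
        vol = Volume(rng.random((16, 16, 16)), (1, 1, 1))
        with pytest.raises(ConfigurationError):
            denoise_volume(model, vol, tile=18, overlap=4)
        with pytest.raises(ConfigurationError):
            denoise_volume(model, vol, tile=16, overlap=16)


class TestSplitPatients:
    def test_ten_patients_five_folds(self):
        fa = split_patients(list(range(10)), k=5, seed=0)
        assert len(fa.folds) == 5
        for f in fa.folds:
            assert len(f["test"]) == 2
            assert len(f["validation"]) == 2
            assert len(f["train"]) == 6

    def test_every_patient_tested_exactly_once(self):
        ids = [f"p{i}" for i in range(23)]
        fa = split_patients(ids, k=5, seed=3)
        tested = [p for f in fa.folds for p in f["test"]]
        assert sorted(tested) == sorted(ids)

    def test_disjointness_enforced_by_container(self):
        with pytest.raises(ValidationError):
            FoldAssignment([{"train": [1, 2], "validation": [2], "test": [3]}])

    def test_proportions_64_16_20(self):
        fa = split_patients(list(range(100)), k=5, seed=1)
        for f in fa.folds:
            assert len(f["train"]) == 64
            assert len(f["validation"]) == 16
            assert len(f["test"]) == 20

    def test_deterministic_given_seed(self):
        a = split_patients(list(range(17)), seed=9)
        b = split_patients(list(range(17)), seed=9)
        assert a.folds == b.folds

    def test_too_few_patients(self):
        with pytest.raises(ValidationError):
            split_patients([1, 2, 3], k=5)


def _pairs(rng, n):
    out = []
    for _ in range(n):
        a = rng.uniform(0.2, 0.8, (8, 8, 8)).astype(np.float32)
        out.append(PatchPair(a, np.clip(a + 0.05, 0, 1), (0, 0, 0)))
    return out


class TestTrainingLoop:
    def test_frozen_optimizer_patience_stops_after_two_epochs(self, rng):
        model = build_model(UNetSpec(depth=2, base_channels=2), seed=0)
        pairs = _pairs(rng, 4)
        cfg = TrainConfig(max_epochs=50, batch_size=2, patience=1,
                          optimizer_name="frozen", augment=False, seed=0)
        _, hist = train(model, pairs, pairs, cfg)
        # frozen optimizer: epoch 1 sets the stopping baseline, epoch 2
        # records no improvement and exhausts patience 1 -> exactly 2 epochs
        trained_epochs = len(hist["val_mse"]) - 1  # entry 0 is the untrained baseline
        assert trained_epochs == 2

    def test_selection_returns_best_epoch_weights(self, rng):
        model = build_model(UNetSpec(depth=2, base_channels=2), seed=0)
        pairs = _pairs(rng, 6)
        cfg = TrainConfig(max_epochs=3, batch_size=2, patience=2,
                          optimizer_name="adam", learning_rate=1e-3, augment=False, seed=0)
        model, hist = train(model, pairs, pairs, cfg)
        from petbf.denoiser import _eval_mse

        assert _eval_mse(model, pairs, 2) == pytest.approx(hist["best_val_mse"], rel=1e-5)

    def test_empty_dataset_rejected(self, rng):
        model = build_model(UNetSpec(depth=2, base_channels=2), seed=0)
        with pytest.raises(ValidationError):
            train(model, [], _pairs(rng, 2), TrainConfig(max_epochs=2, batch_size=1, patience=1))


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tmp_path, rng):
        model = build_model(UNetSpec(depth=2, base_channels=3), seed=4)
        x = rng.uniform(0.1, 0.9, (1, 8, 8, 8, 1)).astype(np.float32)
        y = model.predict(x)
        save_checkpoint(model, tmp_path / "m.npz", extra={"note": "test"})
        again, extra = load_checkpoint(tmp_path / "m.npz")
        np.testing.assert_allclose(again.predict(x), y, atol=1e-7)
        assert extra["note"] == "test"
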