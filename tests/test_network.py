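"""Reconstruction cascade: configs, shapes, training, fine-tuning, inference."""

import numpy as np
import pytest

import mcftwin as m
from mcftwin.network import (ArrayDataset, NetworkConfig, TrainConfig,
                             TrainedModel, build_cascade, fine_tune,
                             reconstruct, train)


@pytest.fixture(scope="module")
def overfit_setup():
    """Four simulated pairs on a small fiber, smooth scenes."""
    lay = m.generate_fiber_layout((32, 32), 4.0, 0.4, 14.0, seed=0)
    tmap = m.sample_transmissivity(lay, seed=1)
    scenes = [m.generate_texture_scene(64, 12.0, seed=s) for s in range(4)]
    mcfs = [m.simulate(s, lay, tmap).pixels for s in scenes]
    x = ArrayDataset.stack_inputs(np.asarray(mcfs, dtype=np.float32), None)
    y = np.asarray(scenes, dtype=np.float32)[:, None]
    return ArrayDataset(x, y, x, y)


@pytest.fixture(scope="module")
def overfit_model(overfit_setup):
    model = build_cascade(NetworkConfig(in_channels=1, base_width=8), seed=0)
    return train(model, overfit_setup,
                 TrainConfig(lr=5e-3, epochs=400, batch_size=2, seed=0))


class TestBuildCascade:
    def test_shape_contract_upscale_two(self):
        model = build_cascade(NetworkConfig(in_channels=1, upscale=2), seed=0)
        out = model.forward(np.zeros((1, 1, 64, 64), dtype=np.float32), train=False)
        assert out.shape == (1, 1, 128, 128)
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert model.param_count > 0

    def test_reference_channel_requires_two_planes(self):
        model = build_cascade(NetworkConfig(in_channels=2, use_reference_channel=True),
                              seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 1, 32, 32), dtype=np.float32))

    @pytest.mark.parametrize("kwargs", [
        {"in_channels": 2, "use_reference_channel": False},
        {"in_channels": 1, "use_reference_channel": True},
        {"upscale": 3},
        {"upscale": 0},
        {"depth": 5},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NetworkConfig(**kwargs)

    def test_same_seed_gives_identical_initial_parameters(self):
        cfg = NetworkConfig(in_channels=1)
        a = build_cascade(cfg, seed=5)
        b = build_cascade(cfg, seed=5)
        c = build_cascade(cfg, seed=6)
        for (pa, _), (pb, _) in zip(a.params(), b.params()):
            assert np.array_equal(pa, pb)
        assert any(not np.array_equal(pa, pc)
                   for (pa, _), (pc, _) in zip(a.params(), c.params()))


class TestTrain:
    def test_overfit_reduces_loss_below_tenth_of_first_epoch(self, overfit_model):
        h = overfit_model.history["train_loss"]
        assert h[-1] < 0.1 * h[0]

    def test_reconstruct_overfit_set_above_30db(self, overfit_model, overfit_setup):
        psnrs = []
        for x, y in zip(overfit_setup.train_x, overfit_setup.train_y):
            out = reconstruct(overfit_model, x[0])
            psnrs.append(m.psnr(out, y[0].astype(float)))
        assert np.mean(psnrs) > 30.0

    def test_zero_epochs_returns_identical_model(self, overfit_setup):
        model = build_cascade(NetworkConfig(in_channels=1), seed=0)
        before = model.get_weights()
        trained = train(model, overfit_setup, TrainConfig(epochs=0, seed=0))
        for w0, w1 in zip(before, trained.weights):
            assert np.array_equal(w0, w1)
        assert trained.history["train_loss"] == []

    def test_same_seed_reproduces_loss_curve(self, overfit_setup):
        cfg = TrainConfig(lr=3e-3, epochs=3, batch_size=2, seed=7)
        a = train(build_cascade(NetworkConfig(in_channels=1), seed=7),
                  overfit_setup, cfg)
        b = train(build_cascade(NetworkConfig(in_channels=1), seed=7),
                  overfit_setup, cfg)
        assert a.history["train_loss"] == b.history["train_loss"]
        assert a.history["val_psnr"] == b.history["val_psnr"]

    def test_empty_dataset_rejected(self):
        model = build_cascade(NetworkConfig(in_channels=1), seed=0)
        empty = ArrayDataset(np.zeros((0, 1, 8, 8), np.float32),
                             np.zeros((0, 1, 16, 16), np.float32),
                             np.zeros((0, 1, 8, 8), np.float32),
                             np.zeros((0, 1, 16, 16), np.float32))
        with pytest.raises(ValueError):
            train(model, empty, TrainConfig(epochs=1))

    def test_target_shape_mismatch_rejected(self, overfit_setup):
        model = build_cascade(NetworkConfig(in_channels=1, upscale=4), seed=0)
        with pytest.raises(ValueError):
            train(model, overfit_setup, TrainConfig(epochs=1))


class TestFineTune:
    def test_learning_rate_zero_keeps_weights(self, overfit_model, overfit_setup):
        tuned = fine_tune(overfit_model, overfit_setup,
                          TrainConfig(lr=0.0, epochs=2, batch_size=2, seed=0,
                                      lr_schedule="constant"))
        for w0, w1 in zip(overfit_model.weights, tuned.weights):
            assert np.array_equal(w0, w1)

    def test_finetune_on_same_distribution_does_not_degrade(self, overfit_model,
                                                            overfit_setup):
        tuned = fine_tune(overfit_model, overfit_setup,
                          TrainConfig(lr=1e-4, epochs=3, batch_size=2, seed=1))
        pre = tuned.history["pre_finetune_val_psnr"]
        post_best = max(tuned.history["val_psnr"])
        final = post_best if not tuned.no_improvement else pre
        assert final > pre - 0.5

    def test_finetune_flag_set_in_config(self, overfit_model, overfit_setup):
        tuned = fine_tune(overfit_model, overfit_setup,
                          TrainConfig(lr=1e-4, epochs=1, batch_size=2, seed=1))
        assert tuned.train_config.fine_tune


class TestReconstructAndSerialization:
    def test_all_zero_input_finite_bounded_output(self, overfit_model):
        out = reconstruct(overfit_model, np.zeros((32, 32)))
        assert np.isfinite(out).all()
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert out.shape == (64, 64)

    def test_deterministic_inference(self, overfit_model, rng):
        x = rng.random((32, 32))
        a = reconstruct(overfit_model, x)
        b = reconstruct(overfit_model, x)
        assert np.array_equal(a, b)

    def test_reference_mismatch_errors(self, overfit_model, rng):
        with pytest.raises(ValueError):
            reconstruct(overfit_model, rng.random((32, 32)),
                        reference=rng.random((32, 32)))

    def test_save_load_round_trip(self, overfit_model, tmp_path, rng):
        path = tmp_path / "model.npz"
        overfit_model.save(path)
        loaded = TrainedModel.load(path)
        assert loaded.net_config == overfit_model.net_config
        assert loaded.train_config == overfit_model.train_config
        assert loaded.history["train_loss"] == overfit_model.history["train_loss"]
        x = rng.random((32, 32))
        assert np.array_equal(reconstruct(loaded, x), reconstruct(overfit_model, x))

    def test_throughput_reported(self, overfit_model, rng):
        _, info = reconstruct(overfit_model, rng.random((32, 32)), return_info=True)
        assert info["fps"] > 0
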