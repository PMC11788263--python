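import numpy as np
import pytest

from ribsep.edge_targets import combine_category_masks, distance_transform_encode
from ribsep.metrics import bsr
from ribsep.networks import (
    DenseSuppressionNet,
    ModelBundle,
    TrainConfig,
    TrainingDivergedError,
    _loss_and_grad,
    assemble_input,
    cosine_warm_restart_lr,
    predict,
    predict_decomposition,
    train_edge_model,
    train_suppressor,
    validation_loss,
)
from ribsep.phantom import PhantomConfig, generate_phantom
from scipy.ndimage import binary_erosion

SMALL = dict(
    shape=(64, 64), n_anterior=1, n_posterior=1, n_clavicle=0, bone_halfwidth=3.0
)


def small_scene(seed):
    return generate_phantom(PhantomConfig(seed=seed, **SMALL))


def scene_sample(seed):
    s = small_scene(seed)
    mask = combine_category_masks(list(s.edge_masks.values()))
    return s, assemble_input(s.cxr, mask), mask


class TestAssembleInput:
    def test_constant_image_zero_gradients(self):
        x = assemble_input(np.full((32, 32), 0.5), np.zeros((32, 32)))
        np.testing.assert_allclose(x[1], 0.0, atol=1e-12)
        np.testing.assert_allclose(x[2], 0.0, atol=1e-12)

    def test_column_ramp(self):
        cc = np.tile(np.arange(32.0), (32, 1)) / 32.0
        x = assemble_input(cc, np.zeros((32, 32)))
        interior = x[:, 2:-2, 2:-2]
        assert np.ptp(interior[1]) < 1e-9  # d/dx constant
        np.testing.assert_allclose(interior[2], 0.0, atol=1e-9)  # d/dy zero

    def test_shape_and_order(self, rng):
        img = rng.random((24, 24))
        mask = rng.random((24, 24)) < 0.2
        x = assemble_input(img, mask)
        assert x.shape == (4, 24, 24)
        np.testing.assert_array_equal(x[0], img)
        np.testing.assert_array_equal(x[3], mask.astype(float))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            assemble_input(np.zeros((8, 8)), np.zeros((9, 9)))


class TestSchedule:
    def test_restarts_return_to_lr0(self):
        lr0 = 1e-4
        for epoch in (0, 10, 30, 70):  # periods 10, 20, 40
            np.testing.assert_allclose(cosine_warm_restart_lr(epoch, lr0), lr0)

    def test_decays_to_zero_before_restart(self):
        assert cosine_warm_restart_lr(10 - 1e-9, 1e-4) < 1e-12
        assert cosine_warm_restart_lr(30 - 1e-9, 1e-4) < 1e-12

    def test_cosine_midpoints(self):
        lr0 = 2e-3
        np.testing.assert_allclose(cosine_warm_restart_lr(5, lr0), 0.5 * lr0)
        np.testing.assert_allclose(cosine_warm_restart_lr(20, lr0), 0.5 * lr0)  # mid of [10,30)


class TestBackprop:
    def test_gradient_check(self):
        rng = np.random.default_rng(0)
        net = DenseSuppressionNet(2, 3, seed=1)
        x = rng.normal(size=(2, 2, 8, 8))
        y = rng.normal(size=(2, 1, 8, 8))
        _, g = _loss_and_grad(net.forward(x), y, "mse")
        grads = net.backward(g)
        params = net.params
        rng_idx = np.random.default_rng(42)
        for k in rng_idx.choice(len(params), size=4, replace=False):
            p = params[k]
            flat = rng_idx.integers(p.size)
            idx = np.unravel_index(flat, p.shape)
            eps = 1e-6
            orig = p[idx]
            p[idx] = orig + eps
            l1, _ = _loss_and_grad(net.forward(x), y, "mse")
            p[idx] = orig - eps
            l2, _ = _loss_and_grad(net.forward(x), y, "mse")
            p[idx] = orig
            num = (l1 - l2) / (2 * eps)
            np.testing.assert_allclose(grads[k][idx], num, rtol=1e-4, atol=1e-8)


class TestTraining:
    def test_overfit_single_phantom(self):
        s, x, _ = scene_sample(5)
        cfg = TrainConfig(image_size=64, batch_size=1, epochs=200, lr0=3e-3, seed=0)
        bundle = train_suppressor([(x, s.bone)], cfg)
        assert bundle.history[-1] < 0.1 * bundle.history[0]

    def test_seeded_determinism(self):
        s, x, _ = scene_sample(6)
        cfg = TrainConfig(image_size=64, batch_size=1, epochs=15, lr0=1e-3, seed=3)
        a = train_suppressor([(x, s.bone)], cfg)
        b = train_suppressor([(x, s.bone)], cfg)
        np.testing.assert_array_equal(a.history, b.history)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_divergence_aborts(self):
        s, x, _ = scene_sample(7)
        cfg = TrainConfig(image_size=64, batch_size=1, epochs=10, lr0=1e200, seed=0)
        with pytest.raises(TrainingDivergedError), np.errstate(all="ignore"):
            train_suppressor([(x, s.bone)], cfg)

    def test_zero_bone_dataset(self):
        ds = []
        for seed in range(4):
            s = generate_phantom(
                PhantomConfig(seed=seed, shape=(64, 64), n_anterior=0, n_posterior=0, n_clavicle=0)
            )
            ds.append((assemble_input(s.cxr, np.zeros_like(s.cxr)), s.bone))
        cfg = TrainConfig(image_size=64, batch_size=2, epochs=30, lr0=3e-3, seed=0)
        bundle = train_suppressor(ds, cfg)
        s, x, mask = scene_sample(99)
        pred = predict(bundle, assemble_input(s.cxr, np.zeros_like(s.cxr)))
        assert np.abs(pred).mean() < 0.05

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_suppressor([], TrainConfig())


class TestEdgeModel:
    def test_overfit_mse(self):
        s = small_scene(7)
        target = distance_transform_encode(
            combine_category_masks(list(s.edge_masks.values())), 5.0
        ).values
        cfg = TrainConfig(image_size=64, batch_size=1, epochs=200, lr0=3e-3, seed=1)
        bundle = train_edge_model([(s.cxr, target)], cfg)
        assert bundle.history[-1] < 0.1 * bundle.history[0]
        pred = predict(bundle, s.cxr)
        assert pred.min() >= 0.0 and pred.max() <= 1.0  # clipped range contract

    def test_bce_baseline_trains(self):
        s = small_scene(8)
        target = combine_category_masks(list(s.edge_masks.values())).astype(float)
        cfg = TrainConfig(
            image_size=64, batch_size=1, epochs=60, lr0=3e-3, seed=1, loss="bce"
        )
        bundle = train_edge_model([(s.cxr, target)], cfg)
        assert bundle.history[-1] < bundle.history[0]
        pred = predict(bundle, s.cxr)
        assert pred.min() >= 0.0 and pred.max() <= 1.0  # sigmoid output


class TestTransfer:
    def test_finetune_starts_no_worse_than_scratch(self):
        train = [scene_sample(i) for i in range(8)]
        ds = [(x, s.bone) for s, x, _ in train]
        cfg = TrainConfig(image_size=64, batch_size=4, epochs=15, lr0=3e-3, seed=0)
        pretrained = train_suppressor(ds, cfg)
        val = [(x, s.bone) for s, x, _ in [scene_sample(i) for i in range(50, 53)]]
        scratch = ModelBundle(
            architecture={"in_channels": 4, "base_channels": 8, "loss": "mse"},
            weights=[p.copy() for p in DenseSuppressionNet(4, 8, seed=0).params],
        )
        assert validation_loss(pretrained, val) <= validation_loss(scratch, val)

    def test_finetune_provenance(self):
        s, x, _ = scene_sample(3)
        cfg = TrainConfig(image_size=64, batch_size=1, epochs=3, lr0=1e-3, seed=0)
        base = train_suppressor([(x, s.bone)], cfg)
        tuned = train_suppressor([(x, s.bone)], cfg, init=base)
        assert "pretrained_on" in tuned.provenance

    def test_channel_mismatch_rejected(self):
        s, x, _ = scene_sample(3)
        cfg = TrainConfig(image_size=64, batch_size=1, epochs=2, lr0=1e-3, seed=0)
        edge_bundle = train_edge_model([(s.cxr, s.bone)], cfg)  # 1-channel
        with pytest.raises(ValueError):
            train_suppressor([(x, s.bone)], cfg, init=edge_bundle)


class TestBundleAndPredict:
    def test_save_load_identical_predictions(self, tmp_path):
        s, x, _ = scene_sample(4)
        cfg = TrainConfig(image_size=64, batch_size=1, epochs=5, lr0=1e-3, seed=0)
        bundle = train_suppressor([(x, s.bone)], cfg)
        bundle.save(tmp_path / "model")
        loaded = ModelBundle.load(tmp_path / "model")
        np.testing.assert_array_equal(predict(bundle, x), predict(loaded, x))

    def test_decomposition_identity(self):
        s, x, mask = scene_sample(4)
        cfg = TrainConfig(image_size=64, batch_size=1, epochs=5, lr0=1e-3, seed=0)
        bundle = train_suppressor([(x, s.bone)], cfg)
        bone, soft = predict_decomposition(bundle, s.cxr, mask)
        np.testing.assert_array_equal(soft, s.cxr - bone)
        assert bone.min() >= 0.0
        b2, s2 = predict_decomposition(bundle, s.cxr, mask)
        np.testing.assert_array_equal(bone, b2)

    def test_held_out_generalization(self):
        # scaled-down learning check: BSR > 0.5 on an unseen phantom
        train = [scene_sample(i) for i in range(30)]
        ds = [(x, s.bone) for s, x, _ in train]
        cfg = TrainConfig(image_size=64, batch_size=6, epochs=20, lr0=3e-3, seed=0)
        bundle = train_suppressor(ds, cfg)
        s, x, mask = scene_sample(100)
        bone, soft = predict_decomposition(bundle, s.cxr, mask)
        ob = binary_erosion(s.bone > 1e-9, structure=np.ones((3, 3), dtype=bool))
        assert bsr(s.soft, soft, s.bone, ob) > 0.5
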