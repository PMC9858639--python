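import numpy as np
import pytest

from woundkit import nn
from woundkit.augment import AugmentConfig, augment
from woundkit.errors import ConfigError
from woundkit.segmentation import (NetworkConfig, TrainConfig, build_model,
                                   inverse_frequency_weights,
                                   load_checkpoint, predict,
                                   save_checkpoint, train, weighted_ce_loss)
from woundkit.synthetic import SceneParams, generate_scene


def tiny_samples(n=6, side=32, seed=0):
    out = []
    for sq in np.random.SeedSequence(seed).spawn(n):
        r = np.random.default_rng(sq)
        p = SceneParams(image_shape=(side, side), px_per_mm=1.0,
                        include_chart=False,
                        wound_center_px=(side / 2, side / 2),
                        wound_radius_mm=float(r.uniform(8, 12)),
                        seed=int(r.integers(2 ** 31)))
        sc = generate_scene(p)
        out.append((sc.image, sc.wound_mask, sc.tissue_labels))
    return out


class TestBuildModel:
    @pytest.mark.parametrize("kind", ["efficientnet_b2_style",
                                      "mobilenet_v2_style"])
    def test_paper_mode_branch_widths(self, kind):
        cfg = NetworkConfig(encoder_kind=kind, input_side=64)
        model = build_model(cfg)
        x = np.random.default_rng(0).random((1, 3, 64, 64))
        wound_logits, tissue_logits = model.forward(x)
        assert wound_logits.shape == (1, 2, 64, 64)
        assert tissue_logits.shape == (1, 4, 64, 64)

    def test_tiny_forward_shape_contract(self):
        model = build_model(NetworkConfig.tiny(input_side=64))
        x = np.random.default_rng(1).random((2, 3, 64, 64))
        lw, lt = model.forward(x)
        assert lw.shape == (2, 2, 64, 64) and lt.shape == (2, 4, 64, 64)

    def test_encoder_sizes_rank_as_expected(self):
        b2 = build_model(NetworkConfig(encoder_kind="efficientnet_b2_style",
                                       input_side=64)).n_parameters()
        mnv2 = build_model(NetworkConfig(encoder_kind="mobilenet_v2_style",
                                         input_side=64)).n_parameters()
        tiny = build_model(NetworkConfig.tiny(input_side=64)).n_parameters()
        assert tiny < mnv2 < b2

    def test_incompatible_input_side_raises(self):
        with pytest.raises(ConfigError):
            NetworkConfig(encoder_kind="mobilenet_v2_style", input_side=100)

    def test_unknown_encoder_raises(self):
        with pytest.raises(ConfigError):
            NetworkConfig(encoder_kind="resnet50")


class TestLossAndWeights:
    def test_total_loss_is_sum_of_branches(self):
        rng = np.random.default_rng(2)
        lw = rng.normal(0, 1, (1, 2, 4, 4))
        lt = rng.normal(0, 1, (1, 4, 4, 4))
        wl = rng.integers(0, 2, (1, 4, 4))
        tl = rng.integers(0, 4, (1, 4, 4))
        total, gw, gt = weighted_ce_loss(lw, lt, wl, tl, np.ones(2),
                                         np.ones(4))
        a, _ = nn.weighted_cross_entropy(lw, wl, np.ones(2))
        b, _ = nn.weighted_cross_entropy(lt, tl, np.ones(4))
        assert total == pytest.approx(a + b)
        assert gw.shape == lw.shape and gt.shape == lt.shape

    def test_inverse_frequency_upweights_rare_classes(self):
        labels = np.array([0] * 90 + [1] * 10)
        w = inverse_frequency_weights(labels, 2)
        assert w[1] > w[0]
        assert w.min() >= 0.25 and w.max() <= 8.0


class TestAugment:
    def test_all_toggles_off_is_identity(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 255, (32, 32, 3)).astype(np.uint8)
        mask = rng.integers(0, 4, (32, 32)).astype(np.uint8)
        out, masks = augment(img, {"m": mask}, AugmentConfig.disabled(),
                             rng)
        assert np.array_equal(out, img)
        assert np.array_equal(masks["m"], mask)

    def test_hflip_is_an_involution(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 255, (16, 16, 3)).astype(np.uint8)
        flipped = img[:, ::-1]
        assert np.array_equal(flipped[:, ::-1], img)

    def test_geometric_ops_keep_masks_integer(self):
        rng = np.random.default_rng(5)
        cfg = AugmentConfig(crop=24, resize_to=None, gaussian_noise=0.0,
                            brightness=0.0, contrast=0.0)
        img = rng.integers(0, 255, (32, 32, 3)).astype(np.uint8)
        mask = rng.integers(0, 4, (32, 32)).astype(np.uint8)
        out, masks = augment(img, {"m": mask}, cfg, rng)
        assert out.shape[:2] == (24, 24)
        assert masks["m"].dtype == mask.dtype
        assert set(np.unique(masks["m"])) <= {0, 1, 2, 3}

    def test_grid_distortion_preserves_class_areas(self):
        # a large blob's pixel count should move by at most ~2 percent
        from woundkit.augment import _grid_distort
        yy, xx = np.mgrid[0:128, 0:128]
        mask = ((yy - 64) ** 2 + (xx - 64) ** 2 < 40 ** 2).astype(np.uint8)
        img = np.stack([mask * 200.0] * 3, axis=-1)
        rng = np.random.default_rng(6)
        _, masks = _grid_distort(img, {"m": mask}, cells=4, magnitude=0.25,
                                 rng=rng)
        drift = abs(int(masks["m"].sum()) - int(mask.sum())) / mask.sum()
        assert drift <= 0.02

    def test_crop_larger_than_image_raises(self):
        img = np.zeros((16, 16, 3), np.uint8)
        with pytest.raises(ValueError):
            augment(img, {}, AugmentConfig(crop=32), np.random.default_rng(0))


class TestTraining:
    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        samples = tiny_samples(4)
        model = build_model(NetworkConfig.tiny(input_side=32))
        before = [p.value.copy() for p in model.params()]
        cfg = TrainConfig(learning_rate=1e-30, weight_decay=0.0, epochs=1,
                          batch_size=2, augment=AugmentConfig.disabled(),
                          seed=0)
        train(model, samples, cfg, [0, 1, 2], [3])
        after = model.params()
        for b, a in zip(before, after):
            assert np.allclose(b, a.value, atol=1e-20)

    def test_same_seed_gives_identical_history(self):
        samples = tiny_samples(4)
        histories = []
        for _ in range(2):
            model = build_model(NetworkConfig.tiny(input_side=32, seed=1))
            cfg = TrainConfig(epochs=2, batch_size=2,
                              augment=AugmentConfig.disabled(), seed=1)
            res = train(model, samples, cfg, [0, 1, 2], [3])
            histories.append(res.history)
        assert histories[0].equals(histories[1])

    def test_empty_split_raises(self):
        samples = tiny_samples(2)
        model = build_model(NetworkConfig.tiny(input_side=32))
        with pytest.raises(ValueError):
            train(model, samples, TrainConfig(epochs=1), [], [0])

    def test_overlapping_splits_raise(self):
        samples = tiny_samples(2)
        model = build_model(NetworkConfig.tiny(input_side=32))
        with pytest.raises(ValueError):
            train(model, samples, TrainConfig(epochs=1), [0, 1], [1])


class TestPredict:
    def test_probabilities_normalised_and_consistent(self, recovery_run):
        model = recovery_run.model
        img, _, _ = recovery_run.samples[recovery_run.test_idx[0]]
        pred = predict(model, img)
        assert np.abs(pred.wound_probs.sum(axis=0) - 1).max() < 1e-5
        assert np.abs(pred.tissue_probs.sum(axis=0) - 1).max() < 1e-5
        assert np.array_equal(pred.tissue_labels,
                              pred.tissue_probs.argmax(axis=0))

    def test_constant_image_is_handled(self, recovery_run):
        img = np.full((128, 128, 3), 120, np.uint8)
        pred = predict(recovery_run.model, img)
        assert pred.tissue_labels.shape == (128, 128)
        assert np.abs(pred.tissue_probs.sum(axis=0) - 1).max() < 1e-5

    def test_identity_calibration_changes_nothing(self, recovery_run):
        from woundkit.calibration import (CalibrationResult,
                                          fit_color_transform)
        from woundkit.chart import reference_palette
        pal = reference_palette().colors.astype(float)
        ident = CalibrationResult(
            transform=fit_color_transform(pal, pal), mm_per_px=0.5,
            homography=np.eye(3))
        img, _, _ = recovery_run.samples[recovery_run.test_idx[0]]
        a = predict(recovery_run.model, img)
        b = predict(recovery_run.model, img, calibration=ident)
        assert np.array_equal(a.tissue_labels, b.tissue_labels)
        assert np.array_equal(a.wound_mask, b.wound_mask)

    def test_hflip_equivariance_of_trained_model(self, converged_run):
        # flip-augmented training should make predictions consistent
        # between an image and its mirrored version
        from woundkit.evaluation import confusion_counts, iou
        img, _, _ = converged_run.samples[converged_run.test_idx[0]]
        direct = predict(converged_run.model, img)
        flipped = predict(converged_run.model,
                          np.ascontiguousarray(img[:, ::-1]))
        unflipped = flipped.wound_mask[:, ::-1]
        score = iou(confusion_counts(unflipped, direct.wound_mask))
        assert score >= 0.95

    def test_tissue_in_wound_view_is_masked(self, recovery_run):
        img, _, _ = recovery_run.samples[recovery_run.test_idx[0]]
        pred = predict(recovery_run.model, img)
        fused = pred.tissue_labels_in_wound
        assert not (fused[~pred.wound_mask] > 0).any()


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, recovery_run):
        model = recovery_run.model
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, extra={"note": "test"})
        loaded, meta = load_checkpoint(path)
        assert meta["extra"]["note"] == "test"
        img, _, _ = recovery_run.samples[0]
        a = predict(model, img)
        b = predict(loaded, img)
        assert np.array_equal(a.tissue_labels, b.tissue_labels)
        assert np.allclose(a.wound_probs, b.wound_probs)
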