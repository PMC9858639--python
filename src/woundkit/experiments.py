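"""Reproducible desk-scale experiments composing the full pipeline.

These are the package's own study designs on synthetic cohorts: a
segmentation recovery run (can the two-branch U-Net recover known masks
from scratch on a small cohort?) and a calibration-benefit comparison
(does training and evaluating on color-calibrated frames beat raw frames
when every photograph carries a different strong color cast?).  Problem
sizes default to CPU scale: 16 scenes of 128 x 128, a 3-level tiny
encoder, 15 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augment import AugmentConfig
from .calibration import calibrate
from .chart import ChartSpec
from .errors import ChartNotFoundError
from .evaluation import confusion_counts, iou
from .segmentation import (NetworkConfig, TrainConfig, build_model, predict,
                           train)
from .synthetic import SceneParams, generate_scene, random_cast

TISSUE_CODES = {"epithelial": 1, "granulation": 2, "necrotic": 3}


def _light_augment() -> AugmentConfig:
    """Flips only: geometric variety without photometric interference."""
    return AugmentConfig(crop=None, hflip=True, vflip=True,
                         grid_distortion=False, brightness=0.0,
                         contrast=0.0, gaussian_noise=0.0, resize_to=None)


def make_recovery_scenes(n_scenes: int = 16, seed: int = 42,
                         side: int = 128) -> list:
    """Chartless wound scenes rendered directly at the network input size,
    with per-scene variation in wound size, position, and shape."""
    samples = []
    for sq in np.random.SeedSequence(seed).spawn(n_scenes):
        r = np.random.default_rng(sq)
        p = SceneParams(
            image_shape=(side, side), px_per_mm=2.0, include_chart=False,
            wound_radius_mm=float(r.uniform(12, 20)),
            wound_center_px=(side / 2 + float(r.uniform(-8, 8)),
                             side / 2 + float(r.uniform(-8, 8))),
            wound_aspect=float(r.uniform(0.7, 1.0)),
            seed=int(r.integers(2 ** 31)))
        sc = generate_scene(p)
        samples.append((sc.image, sc.wound_mask, sc.tissue_labels))
    return samples


def evaluate_samples(model, samples, idx) -> dict:
    """Mean per-class IoU of ``model`` over ``samples[idx]``."""
    sums = {"wound": 0.0, **{k: 0.0 for k in TISSUE_CODES}}
    for i in idx:
        img, wm, tl = samples[i]
        pred = predict(model, img)
        sums["wound"] += iou(confusion_counts(pred.wound_mask, wm))
        for name, code in TISSUE_CODES.items():
            sums[name] += iou(confusion_counts(pred.tissue_labels == code,
                                               np.asarray(tl) == code))
    return {k: v / len(idx) for k, v in sums.items()}


@dataclass
class RecoveryResult:
    mean_iou: dict            # per class, held-out test scenes
    best_epoch: int
    history: "object"
    n_scenes: int
    epochs: int
    model: "object" = None
    samples: list = None
    test_idx: list = None


def run_recovery(seed: int = 0, n_scenes: int = 16, epochs: int = 15,
                 side: int = 128, scene_seed: int = 42) -> RecoveryResult:
    """Scaled-down segmentation recovery: train the tiny two-branch U-Net
    on synthetic scenes and measure held-out per-class IoU.

    The last two scenes are the test set, the two before validation, the
    rest training (each scene is its own synthetic subject, so the split
    is subject-grouped by construction).
    """
    samples = make_recovery_scenes(n_scenes, seed=scene_seed, side=side)
    n_test = max(2, n_scenes // 8)
    n_val = max(2, n_scenes // 8)
    train_idx = list(range(n_scenes - n_val - n_test))
    val_idx = list(range(n_scenes - n_val - n_test, n_scenes - n_test))
    test_idx = list(range(n_scenes - n_test, n_scenes))
    model = build_model(NetworkConfig.tiny(input_side=side, seed=seed))
    cfg = TrainConfig(epochs=epochs, batch_size=4, augment=_light_augment(),
                      seed=seed)
    res = train(model, samples, cfg, train_idx, val_idx)
    return RecoveryResult(
        mean_iou=evaluate_samples(model, samples, test_idx),
        best_epoch=res.best_epoch, history=res.history,
        n_scenes=n_scenes, epochs=epochs, model=model, samples=samples,
        test_idx=test_idx)


# ---------------------------------------------------------------------------
# calibration benefit
# ---------------------------------------------------------------------------

def make_cast_scene_pairs(n_scenes: int = 16, seed: int = 42,
                          cast_strength: float = 0.3,
                          crop_side: int = 128) -> list:
    """Scenes with the chart composited and a strong random cast per frame.

    Returns ``(raw_crop, calibrated_crop, wound, tissue)`` per scene: the
    full 256 x 256 frame is calibrated from its chart, then a fixed
    wound-centred crop of ``crop_side`` is taken from both versions.
    """
    out = []
    for sq in np.random.SeedSequence(seed).spawn(n_scenes):
        r = np.random.default_rng(sq)
        cast = random_cast(r, strength=cast_strength)
        center = (168 + float(r.uniform(-6, 6)), 128 + float(r.uniform(-10, 10)))
        p = SceneParams(
            image_shape=(256, 256), px_per_mm=2.0, include_chart=True,
            wound_center_px=center,
            wound_radius_mm=float(r.uniform(12, 20)),
            wound_aspect=float(r.uniform(0.7, 1.0)),
            cast=tuple(map(tuple, cast)),
            seed=int(r.integers(2 ** 31)))
        sc = generate_scene(p)
        corrected, _ = calibrate(sc.image)
        r0 = 256 - crop_side - 8
        c0 = (256 - crop_side) // 2
        sl = (slice(r0, r0 + crop_side), slice(c0, c0 + crop_side))
        out.append((sc.image[sl], corrected[sl], sc.wound_mask[sl],
                    sc.tissue_labels[sl]))
    return out


def run_calibration_benefit(seeds=(0, 1, 2), n_scenes: int = 16,
                            epochs: int = 15, scene_seed: int = 42,
                            cast_strength: float = 0.3) -> dict:
    """Directional comparison: mean held-out wound IoU of models trained
    and evaluated on calibrated vs raw frames, averaged over seeds.

    One scene set (one cast per frame) serves both arms, so the only
    difference is whether calibration removed the casts.
    """
    pairs = make_cast_scene_pairs(n_scenes, seed=scene_seed,
                                  cast_strength=cast_strength)
    raw = [(p[0], p[2], p[3]) for p in pairs]
    cal = [(p[1], p[2], p[3]) for p in pairs]
    n_test = max(2, n_scenes // 8)
    n_val = max(2, n_scenes // 8)
    train_idx = list(range(n_scenes - n_val - n_test))
    val_idx = list(range(n_scenes - n_val - n_test, n_scenes - n_test))
    test_idx = list(range(n_scenes - n_test, n_scenes))
    side = pairs[0][0].shape[0]
    per_seed = {"calibrated": [], "uncalibrated": []}
    for seed in seeds:
        for name, samples in (("uncalibrated", raw), ("calibrated", cal)):
            model = build_model(NetworkConfig.tiny(input_side=side,
                                                   seed=seed))
            cfg = TrainConfig(epochs=epochs, batch_size=4,
                              augment=_light_augment(), seed=seed)
            train(model, samples, cfg, train_idx, val_idx)
            per_seed[name].append(
                evaluate_samples(model, samples, test_idx)["wound"])
    return {
        "calibrated_mean_wound_iou": float(np.mean(per_seed["calibrated"])),
        "uncalibrated_mean_wound_iou":
            float(np.mean(per_seed["uncalibrated"])),
        "per_seed": {k: [float(v) for v in vs]
                     for k, vs in per_seed.items()},
        "seeds": list(seeds),
    }
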