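"""Multi-task U-Net for wound-area and tissue segmentation.

One shared encoder-decoder feeds two 1x1-convolution output branches: a
2-class wound/background head and a 4-class tissue head (background,
epithelial, granulation, necrotic).  Encoders are assembled from MBConv
inverted-residual blocks (1x1 expand -> 3x3 depthwise -> 1x1 squeeze) in
stage layouts patterned after EfficientNet-B2 and MobileNetV2; a
``tiny_test`` layout (3 resolution levels, <= 32 channels) exists for
CPU-scale experiments.  Decoder levels upsample 2x, concatenate the
encoder skip at the same resolution and fuse with a 3x3 convolution.

Training follows a fixed recipe: Adam (lr 1e-3, weight decay 1e-4), batch
size 4, pixel-wise weighted cross entropy summed over the two branches,
augmentation on the training fold only, and checkpointing of the
parameters with the lowest validation loss.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .augment import AugmentConfig, augment
from .errors import ConfigError

# stage layouts: (expand_ratio, channels, repeats, first_stride)
_STAGE_PLANS = {
    "mobilenet_v2_style": {
        "stem": (32, 2),
        "stages": [(1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2),
                   (6, 64, 4, 2), (6, 96, 3, 1), (6, 160, 3, 2),
                   (6, 320, 1, 1)],
        "decoder": [256, 128, 64, 32, 16],
    },
    "efficientnet_b2_style": {
        "stem": (32, 2),
        "stages": [(1, 16, 2, 1), (6, 24, 3, 2), (6, 48, 3, 2),
                   (6, 88, 4, 2), (6, 120, 4, 1), (6, 208, 5, 2),
                   (6, 352, 2, 1)],
        "decoder": [256, 128, 64, 32, 16],
    },
    "tiny_test": {
        "stem": (8, 1),
        "stages": [(2, 16, 1, 2), (2, 32, 1, 2)],
        "decoder": [16, 8],
    },
}


@dataclass(frozen=True)
class NetworkConfig:
    encoder_kind: str = "efficientnet_b2_style"
    wound_branch_classes: int = 2
    tissue_branch_classes: int = 4
    input_side: int = 1024
    seed: int = 0

    def __post_init__(self):
        if self.encoder_kind not in _STAGE_PLANS:
            raise ConfigError(f"unknown encoder kind {self.encoder_kind!r}")
        factor = self.downsample_factor
        if self.input_side % factor:
            raise ConfigError(
                f"input side {self.input_side} not divisible by the "
                f"encoder downsampling factor {factor}")

    @property
    def plan(self) -> dict:
        return _STAGE_PLANS[self.encoder_kind]

    @property
    def downsample_factor(self) -> int:
        f = self.plan["stem"][1]
        for _, _, _, s in self.plan["stages"]:
            f *= s if s == 2 else 1
        return f

    @classmethod
    def tiny(cls, input_side: int = 128, seed: int = 0) -> "NetworkConfig":
        return cls(encoder_kind="tiny_test", input_side=input_side, seed=seed)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 4
    epochs: int = 100
    class_weights_wound: tuple | None = None    # None -> inverse frequency
    class_weights_tissue: tuple | None = None
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0 or self.weight_decay < 0 \
                or self.batch_size < 1 or self.epochs < 1:
            raise ConfigError("rates and counts must be positive")
        if self.augment.crop is not None and self.augment.resize_to is not \
                None and self.augment.crop > self.augment.resize_to:
            raise ConfigError("crop must not exceed the resize side")


@dataclass
class Prediction:
    wound_mask: np.ndarray        # bool (H, W)
    tissue_labels: np.ndarray     # uint8 (H, W), codes 0..3
    wound_probs: np.ndarray       # (2, H, W)
    tissue_probs: np.ndarray      # (4, H, W)

    @property
    def tissue_labels_in_wound(self) -> np.ndarray:
        """Tissue labels with predictions outside the wound branch's mask
        suppressed (the 'consistent' fused view)."""
        return np.where(self.wound_mask, self.tissue_labels, 0
                        ).astype(np.uint8)


class _MBConv(nn.Layer):
    """Inverted residual: 1x1 expand -> 3x3 depthwise -> 1x1 squeeze,
    with an identity shortcut when shape allows."""

    def __init__(self, cin, cout, expand, stride, rng):
        mid = cin * expand
        ops = []
        if expand != 1:
            ops += [nn.Conv2d(cin, mid, 1, bias=False, rng=rng),
                    nn.BatchNorm2d(mid), nn.ReLU6()]
        ops += [nn.DepthwiseConv2d(mid, 3, stride=stride, rng=rng),
                nn.BatchNorm2d(mid), nn.ReLU6(),
                nn.Conv2d(mid, cout, 1, bias=False, rng=rng),
                nn.BatchNorm2d(cout)]
        self.body = nn.Sequential(*ops)
        self.residual = stride == 1 and cin == cout

    def params(self):
        return self.body.params()

    def set_training(self, flag):
        self.training = flag
        self.body.set_training(flag)

    def forward(self, x):
        y = self.body.forward(x)
        return y + x if self.residual else y

    def backward(self, gout):
        gx = self.body.backward(gout)
        return gx + gout if self.residual else gx


def _conv_bn_relu(cin, cout, k, stride, rng):
    return nn.Sequential(nn.Conv2d(cin, cout, k, stride=stride, bias=False,
                                   rng=rng),
                         nn.BatchNorm2d(cout), nn.ReLU6())


class SegmentationModel:
    """Shared encoder-decoder with wound and tissue output branches."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        plan = cfg.plan
        stem_ch, stem_stride = plan["stem"]
        self.stem_stride = stem_stride

        # encoder as resolution levels: level k keeps one spatial scale;
        # a stride-2 block opens the next level
        levels: list[list] = [[_conv_bn_relu(3, stem_ch, 3, stem_stride,
                                             rng)]]
        ch = stem_ch
        for expand, cout, repeats, stride in plan["stages"]:
            for r in range(repeats):
                s = stride if r == 0 else 1
                block = _MBConv(ch, cout, expand, s, rng)
                if s == 2:
                    levels.append([block])
                else:
                    levels[-1].append(block)
                ch = cout
        self.enc_levels = [nn.Sequential(*lv) for lv in levels]
        self.level_channels = []
        c = stem_ch
        for lv in levels:
            c = self._out_channels(lv, c)
            self.level_channels.append(c)

        dec_plan = plan["decoder"]
        n_up = len(self.enc_levels) - 1 + (1 if stem_stride == 2 else 0)
        if len(dec_plan) != n_up:
            raise ConfigError("decoder plan length mismatch")
        self.decoder = []
        dch = self.level_channels[-1]
        for i, dcout in enumerate(dec_plan):
            skip_idx = len(self.enc_levels) - 2 - i
            skip_ch = self.level_channels[skip_idx] if skip_idx >= 0 else 0
            self.decoder.append({
                "up": nn.UpsampleNearest2x(),
                "fuse": _conv_bn_relu(dch + skip_ch, dcout, 3, 1, rng),
                "skip_idx": skip_idx,
            })
            dch = dcout
        self.head_wound = nn.Conv2d(dch, cfg.wound_branch_classes, 1,
                                    rng=rng)
        self.head_tissue = nn.Conv2d(dch, cfg.tissue_branch_classes, 1,
                                     rng=rng)
        self.training = True

    @staticmethod
    def _out_channels(level_ops, cin):
        c = cin
        for op in level_ops:
            if isinstance(op, _MBConv):
                c = op.body.layers[-1].gamma.value.shape[0]
            else:  # conv-bn-relu Sequential
                c = op.layers[0].w.value.shape[0]
        return c

    # -- plumbing -----------------------------------------------------------

    def params(self) -> list[nn.Param]:
        ps = []
        for lv in self.enc_levels:
            ps += lv.params()
        for d in self.decoder:
            ps += d["fuse"].params()
        ps += self.head_wound.params() + self.head_tissue.params()
        return ps

    def set_training(self, flag: bool):
        self.training = flag
        for lv in self.enc_levels:
            lv.set_training(flag)
        for d in self.decoder:
            d["fuse"].set_training(flag)

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """x: (N, 3, H, W) float in [0, 1] -> (wound logits, tissue logits),
        both at full input resolution."""
        feats = []
        h = x
        for lv in self.enc_levels:
            h = lv.forward(h)
            feats.append(h)
        d = feats[-1]
        self._skip_cache = feats
        for dec in self.decoder:
            d = dec["up"].forward(d)
            if dec["skip_idx"] >= 0:
                skip = feats[dec["skip_idx"]]
                d = np.concatenate([d, skip], axis=1)
            dec["n_up_channels"] = d.shape[1] - (
                feats[dec["skip_idx"]].shape[1] if dec["skip_idx"] >= 0
                else 0)
            d = dec["fuse"].forward(d)
        return self.head_wound.forward(d), self.head_tissue.forward(d)

    def backward(self, g_wound: np.ndarray, g_tissue: np.ndarray):
        g = self.head_wound.backward(g_wound) \
            + self.head_tissue.backward(g_tissue)
        skip_grads = [None] * len(self.enc_levels)
        for dec in reversed(self.decoder):
            g = dec["fuse"].backward(g)
            if dec["skip_idx"] >= 0:
                ncut = dec["n_up_channels"]
                g_skip = g[:, ncut:]
                g = g[:, :ncut]
                si = dec["skip_idx"]
                skip_grads[si] = g_skip if skip_grads[si] is None \
                    else skip_grads[si] + g_skip
            g = dec["up"].backward(g)
        # bottom feature is both decoder input and last encoder output
        g_enc = g
        for i in reversed(range(len(self.enc_levels))):
            if i < len(self.enc_levels) - 1 and skip_grads[i] is not None:
                g_enc = g_enc + skip_grads[i]
            g_enc = self.enc_levels[i].backward(g_enc)
        return g_enc


    # -- persistence --------------------------------------------------------

    def _all_layers(self):
        def walk(layer):
            if isinstance(layer, nn.Sequential):
                for sub in layer.layers:
                    yield from walk(sub)
            elif isinstance(layer, _MBConv):
                yield from walk(layer.body)
            else:
                yield layer
        for lv in self.enc_levels:
            yield from walk(lv)
        for d in self.decoder:
            yield from walk(d["fuse"])
        yield self.head_wound
        yield self.head_tissue

    def state_arrays(self) -> list[np.ndarray]:
        """Parameters plus batch-norm running statistics, in walk order."""
        out = [p.value for p in self.params()]
        for layer in self._all_layers():
            if isinstance(layer, nn.BatchNorm2d):
                out += [layer.running_mean, layer.running_var]
        return out

    def load_state_arrays(self, arrays: list[np.ndarray]):
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ConfigError("checkpoint does not match this architecture")
        for dst, src in zip(own, arrays):
            dst[...] = src


def build_model(cfg: NetworkConfig) -> SegmentationModel:
    """Construct the two-branch U-Net described by ``cfg``."""
    return SegmentationModel(cfg)


def save_checkpoint(path, model: SegmentationModel, extra: dict | None = None):
    """Write weights + running stats + a config echo to an ``.npz`` file."""
    import json
    meta = {"network_config": {
        "encoder_kind": model.cfg.encoder_kind,
        "wound_branch_classes": model.cfg.wound_branch_classes,
        "tissue_branch_classes": model.cfg.tissue_branch_classes,
        "input_side": model.cfg.input_side,
        "seed": model.cfg.seed,
    }, "extra": extra or {}}
    arrays = {f"a{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[SegmentationModel, dict]:
    """Rebuild a model (and its config echo) from ``save_checkpoint``."""
    import json
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        arrays = [data[k] for k in sorted(data.files) if k.startswith("a")]
    cfg = NetworkConfig(**meta["network_config"])
    model = build_model(cfg)
    model.load_state_arrays(arrays)
    model.set_training(False)
    return model, meta


def weighted_ce_loss(wound_logits, tissue_logits, wound_labels,
                     tissue_labels, wound_weights, tissue_weights):
    """Total loss = wound-branch CE + tissue-branch CE (each a pixel mean
    of ``-w[class] log p[class]``).  Returns (loss, grad_wound, grad_tissue).
    """
    lw, gw = nn.weighted_cross_entropy(wound_logits, wound_labels,
                                       wound_weights)
    lt, gt = nn.weighted_cross_entropy(tissue_logits, tissue_labels,
                                       tissue_weights)
    return lw + lt, gw, gt


def inverse_frequency_weights(labels: np.ndarray, n_classes: int,
                              clip: tuple[float, float] = (0.25, 8.0)
                              ) -> np.ndarray:
    """Per-class weights inversely proportional to pixel frequency on the
    training fold, normalised to mean 1 and clipped for stability."""
    counts = np.bincount(np.asarray(labels).ravel(),
                         minlength=n_classes).astype(float)
    counts = np.maximum(counts, 1.0)
    w = counts.sum() / (n_classes * counts)
    w = w / w.mean()
    return np.clip(w, *clip)


def _to_input(image: np.ndarray) -> np.ndarray:
    """HWC uint8 -> CHW float in [0, 1]."""
    return np.ascontiguousarray(
        np.asarray(image, dtype=np.float64).transpose(2, 0, 1) / 255.0)


@dataclass
class TrainResult:
    model: SegmentationModel
    history: pd.DataFrame       # epoch, train_loss, val_loss, is_best
    best_epoch: int
    wound_weights: np.ndarray
    tissue_weights: np.ndarray


def train(model: SegmentationModel, samples: list, cfg: TrainConfig,
          train_idx, val_idx) -> TrainResult:
    """Train on ``samples[i] = (image HWC uint8, wound mask, tissue labels)``.

    ``train_idx`` / ``val_idx`` index disjoint sample subsets (callers
    supply subject-grouped splits).  Deterministic for a fixed
    ``cfg.seed``; the returned model carries the parameters of the epoch
    with the lowest validation loss.
    """
    train_idx = list(train_idx)
    val_idx = list(val_idx)
    if not train_idx or not val_idx:
        raise ValueError("empty train or validation split")
    if set(train_idx) & set(val_idx):
        raise ValueError("train and validation splits overlap")
    rng = np.random.default_rng(cfg.seed)

    if cfg.class_weights_wound is not None:
        w_wound = np.asarray(cfg.class_weights_wound, dtype=float)
    else:
        w_wound = inverse_frequency_weights(
            np.concatenate([np.asarray(samples[i][1]).astype(int).ravel()
                            for i in train_idx]), 2)
    if cfg.class_weights_tissue is not None:
        w_tissue = np.asarray(cfg.class_weights_tissue, dtype=float)
    else:
        w_tissue = inverse_frequency_weights(
            np.concatenate([np.asarray(samples[i][2]).astype(int).ravel()
                            for i in train_idx]), 4)

    opt = nn.Adam(model.params(), lr=cfg.learning_rate,
                  weight_decay=cfg.weight_decay)

    def batch_arrays(idx, augment_rng=None):
        xs, ws, ts = [], [], []
        for i in idx:
            img, wm, tl = samples[i]
            if augment_rng is not None:
                img, masks = augment(img, {"wound": wm, "tissue": tl},
                                     cfg.augment, augment_rng)
                wm, tl = masks["wound"], masks["tissue"]
            xs.append(_to_input(img))
            ws.append(np.asarray(wm).astype(int))
            ts.append(np.asarray(tl).astype(int))
        return np.stack(xs), np.stack(ws), np.stack(ts)

    def validation_loss():
        model.set_training(False)
        total, npx = 0.0, 0
        for i in val_idx:
            x, wl, tl = batch_arrays([i])
            lw, lt_ = model.forward(x)
            loss, _, _ = weighted_ce_loss(lw, lt_, wl, tl, w_wound,
                                          w_tissue)
            total += loss * wl.size
            npx += wl.size
        model.set_training(True)
        return total / npx

    history = []
    best_loss = np.inf
    best_state = nn.get_state(model.params())
    best_epoch = -1
    order = np.array(train_idx)
    for epoch in range(cfg.epochs):
        rng.shuffle(order)
        epoch_loss, nb = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x, wl, tl = batch_arrays(idx, augment_rng=rng)
            opt.zero_grad()
            logits_w, logits_t = model.forward(x)
            loss, gw, gt = weighted_ce_loss(logits_w, logits_t, wl, tl,
                                            w_wound, w_tissue)
            model.backward(gw, gt)
            opt.step()
            epoch_loss += loss
            nb += 1
        val_loss = validation_loss()
        is_best = val_loss < best_loss
        if is_best:
            best_loss = val_loss
            best_state = nn.get_state(model.params())
            best_epoch = epoch
        history.append({"epoch": epoch, "train_loss": epoch_loss / nb,
                        "val_loss": val_loss, "is_best": is_best})
    nn.set_state(model.params(), best_state)
    model.set_training(False)
    return TrainResult(model=model, history=pd.DataFrame(history),
                       best_epoch=best_epoch, wound_weights=w_wound,
                       tissue_weights=w_tissue)


def predict(model: SegmentationModel, image: np.ndarray,
            calibration=None) -> Prediction:
    """Segment one image; a supplied CalibrationResult is applied first.

    Ties at the argmax go to the lowest class index (numpy convention).
    """
    from .calibration import apply_color_transform
    image = np.asarray(image)
    if calibration is not None:
        image = apply_color_transform(image, calibration.transform)
    model.set_training(False)
    x = _to_input(image)[None]
    logits_w, logits_t = model.forward(x)
    pw = nn.softmax(logits_w, axis=1)[0]
    pt = nn.softmax(logits_t, axis=1)[0]
    return Prediction(
        wound_mask=pw.argmax(axis=0).astype(bool),
        tissue_labels=pt.argmax(axis=0).astype(np.uint8),
        wound_probs=pw,
        tissue_probs=pt,
    )
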