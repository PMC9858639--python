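"""Training-time augmentation applied jointly to an image and its masks.

Geometric transforms (crop, flips, grid distortion) are applied identically
to the image and every mask; photometric transforms (brightness, contrast,
Gaussian noise) touch the image only.  Masks stay integer-valued: geometric
warps resample them with nearest-neighbour interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi


@dataclass
class AugmentConfig:
    crop: int | None = 1024         # random-crop side, None disables
    hflip: bool = True
    vflip: bool = True
    grid_distortion: bool = True
    grid_cells: int = 4
    grid_magnitude: float = 0.25    # node shift, fraction of a cell
    brightness: float = 0.15        # max |additive shift| as fraction of 255
    contrast: float = 0.15          # max |log-ish contrast factor delta|
    gaussian_noise: float = 6.0     # noise sigma on the 0..255 scale
    resize_to: int | None = 1280    # pre-training center resize/crop side

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(crop=None, hflip=False, vflip=False,
                   grid_distortion=False, brightness=0.0, contrast=0.0,
                   gaussian_noise=0.0, resize_to=None)


def center_resize_crop(image: np.ndarray, masks: dict, side: int):
    """Scale the shorter side to ``side`` then take the central square crop,
    preserving aspect ratio (the pre-training normalisation convention)."""
    h, w = image.shape[:2]
    scale = side / min(h, w)
    if abs(scale - 1) > 1e-9:
        zoom = (scale, scale, 1)
        image = ndi.zoom(image.astype(float), zoom, order=1)
        masks = {k: ndi.zoom(m, (scale, scale), order=0) for k, m in
                 masks.items()}
    h, w = image.shape[:2]
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    image = image[r0:r0 + side, c0:c0 + side]
    masks = {k: m[r0:r0 + side, c0:c0 + side] for k, m in masks.items()}
    return image, masks


def _grid_distort(image, masks, cells, magnitude, rng):
    h, w = image.shape[:2]
    nodes_y = rng.uniform(-magnitude, magnitude, (cells + 1, cells + 1))
    nodes_x = rng.uniform(-magnitude, magnitude, (cells + 1, cells + 1))
    nodes_y *= h / cells
    nodes_x *= w / cells
    nodes_y[[0, -1], :] = 0.0   # pin the border so the frame is preserved
    nodes_x[:, [0, -1]] = 0.0
    zy = ndi.zoom(nodes_y, (h / (cells + 1), w / (cells + 1)), order=1)
    zx = ndi.zoom(nodes_x, (h / (cells + 1), w / (cells + 1)), order=1)
    zy = zy[:h, :w]
    zx = zx[:h, :w]
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    coords = np.stack([yy + zy, xx + zx])
    out = np.stack([ndi.map_coordinates(image[..., c].astype(float), coords,
                                        order=1, mode="reflect")
                    for c in range(image.shape[2])], axis=-1)
    masks = {k: ndi.map_coordinates(m, coords, order=0, mode="reflect")
             for k, m in masks.items()}
    return out, masks


def augment(image: np.ndarray, masks: dict, cfg: AugmentConfig,
            rng: np.random.Generator | None = None):
    """Apply one random augmentation draw to ``(image, masks)``.

    ``masks`` maps names to integer 2-D arrays aligned with ``image``.
    With every toggle off this is the identity.  Raises if the image is
    smaller than the requested crop.
    """
    rng = rng or np.random.default_rng(0)
    image = np.asarray(image)
    out = image.astype(float)
    masks = {k: np.asarray(m) for k, m in masks.items()}

    if cfg.crop is not None:
        h, w = out.shape[:2]
        if h < cfg.crop or w < cfg.crop:
            raise ValueError(
                f"image {h}x{w} smaller than crop {cfg.crop}")
        r0 = rng.integers(0, h - cfg.crop + 1)
        c0 = rng.integers(0, w - cfg.crop + 1)
        out = out[r0:r0 + cfg.crop, c0:c0 + cfg.crop]
        masks = {k: m[r0:r0 + cfg.crop, c0:c0 + cfg.crop]
                 for k, m in masks.items()}
    if cfg.hflip and rng.random() < 0.5:
        out = out[:, ::-1]
        masks = {k: m[:, ::-1] for k, m in masks.items()}
    if cfg.vflip and rng.random() < 0.5:
        out = out[::-1]
        masks = {k: m[::-1] for k, m in masks.items()}
    if cfg.grid_distortion and rng.random() < 0.5:
        out, masks = _grid_distort(out, masks, cfg.grid_cells,
                                   cfg.grid_magnitude, rng)
    if cfg.brightness > 0 and rng.random() < 0.5:
        out = out + rng.uniform(-cfg.brightness, cfg.brightness) * 255.0
    if cfg.contrast > 0 and rng.random() < 0.5:
        factor = 1.0 + rng.uniform(-cfg.contrast, cfg.contrast)
        out = (out - out.mean()) * factor + out.mean()
    if cfg.gaussian_noise > 0 and rng.random() < 0.5:
        out = out + rng.normal(0, cfg.gaussian_noise, out.shape)
    out = np.clip(out, 0, 255)
    masks = {k: np.ascontiguousarray(m) for k, m in masks.items()}
    return np.ascontiguousarray(out), masks
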