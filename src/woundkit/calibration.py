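"""Automatic color and metric calibration from the chart in a photograph.

The pipeline is fully unsupervised: detect the four corner fiducials,
estimate the chart-plane homography from their 16 corners, sample the 24
patch colors, fit the least-squares (Moore-Penrose) linear color transform
against the reference palette, apply it to the frame, and read the metric
scale off the projected marker geometry.

All color fitting happens in device 8-bit RGB as captured — no gamma
linearisation — and the transform is a pure 3x3 matrix acting on RGB row
vectors (an affine 4x3 variant is available via ``intercept=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from . import fiducial
from .chart import ChartSpec, reference_palette
from .errors import (ChartNotFoundError, IllConditionedFitError,
                     SamplingError, WoundkitError)

#: fraction of the patch side covered by the central sampling window
PATCH_WINDOW_FRAC = 0.4


@dataclass
class MarkerDetections:
    """Decoded chart markers found in one image."""

    markers: list[fiducial.DetectedMarker]
    image_shape: tuple[int, int]

    @property
    def ids(self) -> set[int]:
        return {m.marker_id for m in self.markers}

    def by_id(self, marker_id: int) -> fiducial.DetectedMarker:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)


@dataclass
class ColorTransform:
    """Linear map from observed RGB row vectors to reference RGB.

    ``matrix`` is 3x3 (or 4x3 when fitted with an intercept, acting on
    ``[r, g, b, 1]``).  ``fit_residual`` is the RMS error over the 24
    patches after mapping.
    """

    matrix: np.ndarray
    fit_residual: float
    source_colors: np.ndarray
    target_colors: np.ndarray
    color_space_tag: str = "device-RGB-8bit"

    @property
    def has_intercept(self) -> bool:
        return self.matrix.shape[0] == 4

    def map_colors(self, colors: np.ndarray) -> np.ndarray:
        colors = np.asarray(colors, dtype=float)
        if self.has_intercept:
            aug = np.hstack([colors, np.ones((len(colors), 1))])
            return aug @ self.matrix
        return colors @ self.matrix

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "fit_residual": float(self.fit_residual),
            "source_colors": self.source_colors.tolist(),
            "target_colors": self.target_colors.tolist(),
            "color_space_tag": self.color_space_tag,
        }


@dataclass
class CalibrationResult:
    """Everything calibration recovers from one photograph."""

    transform: ColorTransform
    mm_per_px: float
    homography: np.ndarray  # 3x3, chart mm coords -> image px (x, y)
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "transform": self.transform.to_dict(),
            "mm_per_px": float(self.mm_per_px),
            "homography": self.homography.tolist(),
            "diagnostics": self.diagnostics,
        }


def _to_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(float)
    return image.astype(float) @ np.array([0.299, 0.587, 0.114])


def detect_markers(image: np.ndarray, spec: ChartSpec) -> MarkerDetections:
    """Find all decodable chart markers; IDs outside the spec are ignored.

    An empty result is valid (no error for chartless images).
    """
    gray = _to_gray(image)
    markers = [m for m in fiducial.detect(gray)
               if m.marker_id in spec.marker_ids]
    return MarkerDetections(markers=markers, image_shape=gray.shape)


def normalize_orientation(dets: MarkerDetections, spec: ChartSpec
                          ) -> np.ndarray:
    """Homography H mapping chart mm coordinates to image pixels.

    Estimated from all 16 marker corners with known physical positions;
    orientation is fixed by the ID -> corner assignment in the spec.
    Raises :class:`ChartNotFoundError` unless all four markers are present.
    """
    missing = set(spec.marker_ids) - dets.ids
    if missing:
        raise ChartNotFoundError(missing, dets.ids)
    src, dst = [], []
    for corner in range(4):
        marker_id = spec.marker_ids[corner]
        src.append(spec.marker_corners_mm(corner))
        dst.append(dets.by_id(marker_id).corners)
    tf = fiducial.projective_from_points(np.vstack(src), np.vstack(dst))
    if tf is None:
        raise ChartNotFoundError(set(), dets.ids)
    return np.asarray(tf.params)


def _project(h: np.ndarray, pts_mm: np.ndarray) -> np.ndarray:
    pts_mm = np.atleast_2d(pts_mm)
    aug = np.hstack([pts_mm, np.ones((len(pts_mm), 1))])
    proj = aug @ h.T
    return proj[:, :2] / proj[:, 2:3]


def sample_patch_colors(image: np.ndarray, homography: np.ndarray,
                        spec: ChartSpec,
                        window_frac: float = PATCH_WINDOW_FRAC) -> np.ndarray:
    """Mean RGB over the central window of each patch, row-major order.

    The window covers ``window_frac`` of the patch side, projected through
    the homography; raises :class:`SamplingError` naming the first patch
    whose window leaves the image.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    half = 0.5 * window_frac * spec.patch_side_mm
    colors = np.empty((24, 3))
    for idx in range(24):
        cx, cy = spec.patch_center_mm(idx)
        n = 7  # 7x7 sample lattice across the window
        gx, gy = np.meshgrid(np.linspace(cx - half, cx + half, n),
                             np.linspace(cy - half, cy + half, n))
        pts_px = _project(homography, np.stack([gx.ravel(), gy.ravel()], 1))
        if (pts_px[:, 0].min() < 0 or pts_px[:, 0].max() > w
                or pts_px[:, 1].min() < 0 or pts_px[:, 1].max() > h):
            raise SamplingError(idx)
        coords = np.stack([pts_px[:, 1] - 0.5, pts_px[:, 0] - 0.5])
        for ch in range(3):
            vals = ndi.map_coordinates(image[..., ch].astype(float), coords,
                                       order=1, mode="nearest")
            colors[idx, ch] = vals.mean()
    return colors


def fit_color_transform(source: np.ndarray, target: np.ndarray,
                        intercept: bool = False) -> ColorTransform:
    """Least-squares linear color map via the Moore-Penrose pseudo-inverse.

    ``matrix = pinv(source) @ target``; with ``intercept=True`` the source
    is augmented with a constant column (affine variant).
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.shape[1] != 3:
        raise ValueError("source and target must both be (n, 3)")
    if not (np.isfinite(source).all() and np.isfinite(target).all()):
        raise ValueError("colors must be finite")
    design = source
    if intercept:
        design = np.hstack([source, np.ones((len(source), 1))])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise IllConditionedFitError(
            "source colors are rank deficient; cannot fit a color transform")
    matrix = np.linalg.pinv(design) @ target
    residual = float(np.sqrt(np.mean((design @ matrix - target) ** 2)))
    return ColorTransform(matrix=matrix, fit_residual=residual,
                          source_colors=source, target_colors=target)


def apply_color_transform(image: np.ndarray, transform: ColorTransform
                          ) -> np.ndarray:
    """Map every pixel through the transform, clipping to [0, 255]."""
    image = np.asarray(image)
    flat = image.reshape(-1, 3).astype(float)
    mapped = transform.map_colors(flat)
    out = np.clip(np.rint(mapped), 0, 255).astype(np.uint8)
    return out.reshape(image.shape)


def estimate_scale(homography: np.ndarray, spec: ChartSpec) -> float:
    """Millimetres per pixel in the chart plane.

    Projects each marker's ideal corners through the homography and averages
    ``marker_side_mm / projected side px`` over all 16 marker sides.
    """
    if abs(np.linalg.det(homography)) < 1e-12:
        raise WoundkitError("degenerate homography; cannot estimate scale")
    ratios = []
    for corner in range(4):
        corners_px = _project(homography, spec.marker_corners_mm(corner))
        sides = np.linalg.norm(np.roll(corners_px, -1, 0) - corners_px, axis=1)
        if sides.min() <= 0:
            raise WoundkitError("degenerate marker projection")
        ratios.extend(spec.marker_side_mm / sides)
    return float(np.mean(ratios))


def calibrate(image: np.ndarray, spec: ChartSpec | None = None,
              intercept: bool = False
              ) -> tuple[np.ndarray, CalibrationResult]:
    """Full automatic calibration of a photograph containing the chart.

    Returns the color-corrected image and a :class:`CalibrationResult` with
    the fitted transform, the metric scale and detection diagnostics.
    Raises :class:`ChartNotFoundError` when fewer than four markers decode.
    """
    spec = spec or ChartSpec()
    dets = detect_markers(image, spec)
    homography = normalize_orientation(dets, spec)
    source = sample_patch_colors(image, homography, spec)
    target = reference_palette().colors.astype(float)
    transform = fit_color_transform(source, target, intercept=intercept)
    corrected = apply_color_transform(image, transform)
    mm_per_px = estimate_scale(homography, spec)
    result = CalibrationResult(
        transform=transform,
        mm_per_px=mm_per_px,
        homography=homography,
        diagnostics={
            "markers_found": sorted(dets.ids),
            "patch_window_frac": PATCH_WINDOW_FRAC,
            "image_shape": list(dets.image_shape),
        },
    )
    return corrected, result
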