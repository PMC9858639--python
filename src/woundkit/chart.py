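"""Calibration-chart model: physical geometry, reference colors, rendering.

The chart is a 75 x 35 mm card carrying four square fiducial markers
(12.7 mm) at its corners and a Macbeth / ColorChecker-Classic arrangement of
24 color patches (6.35 mm each) in a 6 x 4 grid centred between the marker
columns.  The physical layout is expressed in millimetres with the origin at
the chart's top-left corner, x to the right and y downward; rasterisation
samples each pixel at its centre ``((c + 0.5) / px_per_mm,
(r + 0.5) / px_per_mm)`` so that ground-truth coordinates are exact and
scale linearly with resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ResolutionError
from .fiducial import DICTIONARY_NAME, MODULES, marker_pattern

#: ColorChecker-Classic sRGB reference values, row-major from the top-left
#: marker: natural tones, then chromatic rows, then the neutral ramp.
COLORCHECKER_SRGB = np.array([
    (115, 82, 68), (194, 150, 130), (98, 122, 157), (87, 108, 67),
    (133, 128, 177), (103, 189, 170),
    (214, 126, 44), (80, 91, 166), (193, 90, 99), (94, 60, 108),
    (157, 188, 64), (224, 163, 46),
    (56, 61, 150), (70, 148, 73), (175, 54, 60), (231, 199, 31),
    (187, 86, 149), (8, 133, 161),
    (243, 243, 242), (200, 200, 200), (160, 160, 160), (122, 122, 121),
    (85, 85, 85), (52, 52, 52),
], dtype=np.uint8)


@dataclass(frozen=True)
class ReferencePalette:
    """The 24 reference patch colors in fixed row-major chart order."""

    colors: np.ndarray
    color_space_tag: str = "sRGB-8bit"

    def __post_init__(self):
        colors = np.asarray(self.colors)
        if colors.shape != (24, 3):
            raise ValueError("palette must hold exactly 24 RGB triplets")
        if colors.min() < 0 or colors.max() > 255:
            raise ValueError("palette channels must lie in [0, 255]")
        object.__setattr__(self, "colors", colors.astype(np.uint8))


def reference_palette() -> ReferencePalette:
    """Canonical ColorChecker-Classic sRGB palette (pure function)."""
    return ReferencePalette(colors=COLORCHECKER_SRGB.copy())


@dataclass(frozen=True)
class ChartSpec:
    """Physical geometry and identity of the printed calibration chart.

    ``marker_ids`` maps corners in the order (TL, TR, BR, BL).  The patch
    grid is centred in the rectangle spanned horizontally by the inner
    marker edges and vertically by the chart; the derived margins are
    recorded in :class:`ChartGroundTruth` when rendering.
    """

    chart_width_mm: float = 75.0
    chart_height_mm: float = 35.0
    marker_side_mm: float = 12.7
    patch_side_mm: float = 6.35
    grid_rows: int = 4
    grid_cols: int = 6
    marker_ids: tuple[int, int, int, int] = (0, 1, 2, 3)
    marker_dictionary_name: str = DICTIONARY_NAME
    edge_margin_mm: float = 1.0
    patch_gap_mm: float = 1.0

    def __post_init__(self):
        for name in ("chart_width_mm", "chart_height_mm", "marker_side_mm",
                     "patch_side_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.grid_rows * self.grid_cols != 24:
            raise ValueError("patch grid must hold 24 patches")
        if len(set(self.marker_ids)) != 4:
            raise ValueError("marker_ids must be 4 distinct ids")
        if self.grid_cols * self.patch_side_mm > self.chart_width_mm:
            raise ValueError("patch grid wider than the chart")
        if self.grid_rows * self.patch_side_mm > self.chart_height_mm:
            raise ValueError("patch grid taller than the chart")

    # -- derived geometry (all in mm, chart frame) --------------------------

    def marker_origin_mm(self, corner: int) -> tuple[float, float]:
        """Top-left of the marker at corner index 0..3 = (TL, TR, BR, BL)."""
        m, s = self.edge_margin_mm, self.marker_side_mm
        w, h = self.chart_width_mm, self.chart_height_mm
        return [(m, m), (w - m - s, m), (w - m - s, h - m - s),
                (m, h - m - s)][corner]

    def marker_corners_mm(self, corner: int) -> np.ndarray:
        """(4, 2) marker corner coordinates, canonical TL, TR, BR, BL order."""
        ox, oy = self.marker_origin_mm(corner)
        s = self.marker_side_mm
        return np.array([(ox, oy), (ox + s, oy), (ox + s, oy + s),
                         (ox, oy + s)], dtype=float)

    def grid_extent_mm(self) -> tuple[float, float]:
        gw = self.grid_cols * self.patch_side_mm \
            + (self.grid_cols - 1) * self.patch_gap_mm
        gh = self.grid_rows * self.patch_side_mm \
            + (self.grid_rows - 1) * self.patch_gap_mm
        return gw, gh

    def grid_origin_mm(self) -> tuple[float, float]:
        """Top-left of the patch grid: centred between the marker columns
        horizontally and on the chart vertically."""
        inner_x0 = self.edge_margin_mm + self.marker_side_mm
        inner_x1 = self.chart_width_mm - self.edge_margin_mm - self.marker_side_mm
        gw, gh = self.grid_extent_mm()
        ox = inner_x0 + 0.5 * (inner_x1 - inner_x0 - gw)
        oy = 0.5 * (self.chart_height_mm - gh)
        return ox, oy

    def patch_origin_mm(self, index: int) -> tuple[float, float]:
        """Top-left of patch ``index`` (row-major, 0..23)."""
        row, col = divmod(index, self.grid_cols)
        ox, oy = self.grid_origin_mm()
        pitch = self.patch_side_mm + self.patch_gap_mm
        return ox + col * pitch, oy + row * pitch

    def patch_center_mm(self, index: int) -> tuple[float, float]:
        x, y = self.patch_origin_mm(index)
        return x + self.patch_side_mm / 2, y + self.patch_side_mm / 2

    def patch_centers_mm(self) -> np.ndarray:
        return np.array([self.patch_center_mm(i) for i in range(24)])

    def to_dict(self) -> dict:
        return {
            "chart_width_mm": self.chart_width_mm,
            "chart_height_mm": self.chart_height_mm,
            "marker_side_mm": self.marker_side_mm,
            "patch_side_mm": self.patch_side_mm,
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "marker_ids": list(self.marker_ids),
            "marker_dictionary_name": self.marker_dictionary_name,
            "edge_margin_mm": self.edge_margin_mm,
            "patch_gap_mm": self.patch_gap_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChartSpec":
        d = dict(d)
        d["marker_ids"] = tuple(d["marker_ids"])
        return cls(**d)


@dataclass
class ChartGroundTruth:
    """Exact pixel geometry of a rendered chart.

    Coordinates follow the package convention (pixel centre of ``[r, c]`` at
    ``(c + 0.5, r + 0.5)``), so every value here is simply the mm position
    multiplied by ``px_per_mm``.
    """

    px_per_mm: float
    image_shape: tuple[int, int]          # (height, width) in px
    marker_corners_px: dict[int, np.ndarray]  # id -> (4, 2), canonical order
    patch_centers_px: np.ndarray          # (24, 2)
    margins_mm: dict[str, float]
    spec: ChartSpec

    def to_json(self) -> str:
        return json.dumps({
            "px_per_mm": self.px_per_mm,
            "image_shape": list(self.image_shape),
            "marker_corners_px": {str(k): v.tolist()
                                  for k, v in self.marker_corners_px.items()},
            "patch_centers_px": self.patch_centers_px.tolist(),
            "margins_mm": self.margins_mm,
            "spec": self.spec.to_dict(),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ChartGroundTruth":
        d = json.loads(text)
        return cls(
            px_per_mm=d["px_per_mm"],
            image_shape=tuple(d["image_shape"]),
            marker_corners_px={int(k): np.array(v)
                               for k, v in d["marker_corners_px"].items()},
            patch_centers_px=np.array(d["patch_centers_px"]),
            margins_mm=d["margins_mm"],
            spec=ChartSpec.from_dict(d["spec"]),
        )


MIN_PX_PER_MM = 2.0
_MIN_MODULE_PX = 2.0  # a marker module must span at least this many pixels


def render_chart(spec: ChartSpec, px_per_mm: float
                 ) -> tuple[np.ndarray, ChartGroundTruth]:
    """Rasterise the chart at ``px_per_mm`` and return exact ground truth.

    Raises :class:`ResolutionError` when markers would be undecodable.
    """
    if px_per_mm < MIN_PX_PER_MM:
        raise ResolutionError(
            f"px_per_mm={px_per_mm} below minimum {MIN_PX_PER_MM}")
    module_px = spec.marker_side_mm * px_per_mm / MODULES
    if module_px < _MIN_MODULE_PX:
        raise ResolutionError(
            f"marker modules would span {module_px:.2f} px; "
            f"at least {_MIN_MODULE_PX} px needed to decode")
    height = round(spec.chart_height_mm * px_per_mm)
    width = round(spec.chart_width_mm * px_per_mm)
    img = np.full((height, width, 3), 255, dtype=np.uint8)

    # mm coordinates of every pixel centre
    xs = (np.arange(width) + 0.5) / px_per_mm
    ys = (np.arange(height) + 0.5) / px_per_mm

    palette = reference_palette().colors
    for idx in range(24):
        ox, oy = spec.patch_origin_mm(idx)
        s = spec.patch_side_mm
        cmask = (xs >= ox) & (xs < ox + s)
        rmask = (ys >= oy) & (ys < oy + s)
        img[np.ix_(rmask, cmask)] = palette[idx]

    for corner in range(4):
        marker_id = spec.marker_ids[corner]
        pattern = marker_pattern(marker_id)
        ox, oy = spec.marker_origin_mm(corner)
        s = spec.marker_side_mm
        cidx = np.nonzero((xs >= ox) & (xs < ox + s))[0]
        ridx = np.nonzero((ys >= oy) & (ys < oy + s))[0]
        u = np.minimum((xs[cidx] - ox) / s * MODULES, MODULES - 1e-9).astype(int)
        v = np.minimum((ys[ridx] - oy) / s * MODULES, MODULES - 1e-9).astype(int)
        cells = pattern[np.ix_(v, u)]
        img[np.ix_(ridx, cidx)] = np.where(cells[..., None] > 0, 255, 0)

    gx, gy = spec.grid_origin_mm()
    inner_x0 = spec.edge_margin_mm + spec.marker_side_mm
    truth = ChartGroundTruth(
        px_per_mm=px_per_mm,
        image_shape=(height, width),
        marker_corners_px={spec.marker_ids[c]:
                           spec.marker_corners_mm(c) * px_per_mm
                           for c in range(4)},
        patch_centers_px=spec.patch_centers_mm() * px_per_mm,
        margins_mm={
            "grid_left_of_inner_rect": gx - inner_x0,
            "grid_top_of_chart": gy,
            "marker_edge_margin": spec.edge_margin_mm,
            "patch_gap": spec.patch_gap_mm,
        },
        spec=spec,
    )
    return img, truth
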