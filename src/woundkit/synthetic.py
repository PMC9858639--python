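"""Synthetic wound scenes with exact ground truth.

The generator emulates the structure of clinical smartphone wound
photographs: a skin-toned background, a closed wound whose boundary is a
low-order Fourier perturbation of an ellipse, a tissue partition of the
wound bed (epithelial rim at the margin, granulation interior, small rare
necrotic patches), the calibration chart composited frontally at a known
scale, and a global invertible color cast plus sensor noise applied to the
whole frame.  Ground truth (masks, per-class pixel counts, scale, cast) is
retained from before the cast so every downstream module can be tested
without clinical data.

Class codes in ``tissue_labels``: 0 background, 1 epithelial, 2 granulation,
3 necrotic.  Tissue classes are mutually exclusive and live inside the
wound mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .chart import ChartSpec, reference_palette, render_chart
from .errors import PlacementError

CLASS_NAMES = {0: "background", 1: "epithelial", 2: "granulation",
               3: "necrotic"}

#: class-characteristic RGB means and spreads: granulation beefy red,
#: epithelial deep pink, necrotic dark yellow-brown eschar/slough mix
TISSUE_COLOR_MODELS = {
    1: ((226, 130, 148), 8.0),
    2: ((178, 48, 52), 10.0),
    3: ((97, 74, 42), 12.0),
}
SKIN_COLOR_DEFAULT = (198, 152, 124)

#: characteristic area of one necrotic patch, mm^2 (keeps necrosis rare and
#: small, mirroring the clinical class imbalance)
NECROTIC_PATCH_MM2 = 40.0


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene; a fixed seed fixes the scene."""

    image_shape: tuple[int, int] = (256, 256)   # (rows, cols)
    px_per_mm: float = 2.0
    skin_color: tuple[int, int, int] = SKIN_COLOR_DEFAULT
    skin_noise_sigma: float = 6.0
    wound_center_px: tuple[float, float] | None = None  # (row, col)
    wound_radius_mm: float = 20.0
    wound_aspect: float = 0.8
    boundary_roughness: float = 0.06
    #: fractions of the wound area per class (epithelial, granulation,
    #: necrotic); must sum to <= 1, the remainder stays unlabelled wound bed
    tissue_weights: tuple[float, float, float] = (0.25, 0.65, 0.10)
    cast: tuple | None = None          # 3x3 nested tuple; None = identity
    noise_sigma: float = 3.0
    include_chart: bool = True
    chart_origin_px: tuple[int, int] = (8, 8)   # (row, col)
    seed: int = 0

    def __post_init__(self):
        w = self.tissue_weights
        if min(w) < 0 or sum(w) > 1 + 1e-9:
            raise ValueError("tissue weights must be >= 0 and sum to <= 1")
        if self.cast is not None:
            m = np.asarray(self.cast, dtype=float)
            if m.shape != (3, 3) or abs(np.linalg.det(m)) < 1e-9:
                raise ValueError("cast must be an invertible 3x3 matrix")

    @property
    def cast_matrix(self) -> np.ndarray:
        if self.cast is None:
            return np.eye(3)
        return np.asarray(self.cast, dtype=float)


@dataclass
class SceneTruth:
    """Exact pre-cast ground truth for one scene."""

    params: SceneParams
    class_pixel_counts: dict[int, int]
    wound_pixel_count: int
    mm_per_px: float
    cast: np.ndarray
    chart_bbox_px: tuple[int, int, int, int] | None  # (r0, c0, r1, c1)


@dataclass
class WoundScene:
    image: np.ndarray          # uint8 (H, W, 3), cast + noise applied
    wound_mask: np.ndarray     # bool (H, W)
    tissue_labels: np.ndarray  # uint8 (H, W), codes 0..3
    truth: SceneTruth
    image_clean: np.ndarray | None = None  # pre-cast frame, for diagnostics


def random_cast(rng: np.random.Generator, strength: float = 0.15
                ) -> np.ndarray:
    """Random invertible cast that keeps the reference palette in gamut.

    Models white-balance/exposure shifts: perturbs the identity, then pulls
    back toward it until no palette color clips, so the cast remains
    information-preserving (a clipped cast is not invertible in effect).
    """
    pal = reference_palette().colors.astype(float)
    m = np.eye(3) + rng.normal(0.0, strength, (3, 3))
    for _ in range(60):
        mapped = pal @ m.T
        if mapped.min() >= 2 and mapped.max() <= 253 \
                and abs(np.linalg.det(m)) > 0.2:
            return m
        m = np.eye(3) + 0.85 * (m - np.eye(3))
    return np.eye(3)


def _wound_mask(params: SceneParams, rng: np.random.Generator,
                radius_mm: float | None = None,
                fourier: np.ndarray | None = None) -> np.ndarray:
    h, w = params.image_shape
    if params.wound_center_px is None:
        if params.include_chart:
            # default layout: chart strip on top, wound centred below it
            chart_rows = 35.0 * params.px_per_mm + params.chart_origin_px[0]
            cy = chart_rows + 0.55 * (h - chart_rows)
        else:
            cy = h / 2
        cx = w / 2
    else:
        cy, cx = params.wound_center_px
    radius_px = (radius_mm or params.wound_radius_mm) * params.px_per_mm
    if fourier is None:
        orders = np.arange(2, 6)
        amps = rng.normal(0, params.boundary_roughness / np.sqrt(orders))
        phases = rng.uniform(0, 2 * np.pi, len(orders))
        fourier = np.stack([orders, amps, phases])
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx + 0.5 - cx
    dy = (yy + 0.5 - cy) / params.wound_aspect
    theta = np.arctan2(dy, dx)
    rho = np.hypot(dx, dy)
    boundary = radius_px * (1 + sum(
        a * np.cos(k * theta + p) for k, a, p in fourier.T))
    return rho < boundary


def _partition_tissue(wound: np.ndarray, params: SceneParams,
                      rng: np.random.Generator) -> np.ndarray:
    """Exact-count tissue partition: epithelial rim by distance-to-edge
    quantile, necrotic as compact blobs around few seeds, granulation
    filling (up to its weight) the rest."""
    labels = np.zeros(wound.shape, dtype=np.uint8)
    coords = np.argwhere(wound)
    area = len(coords)
    if area == 0:
        return labels
    w_e, w_g, w_n = params.tissue_weights
    n_e = int(round(w_e * area))
    n_n = int(round(w_n * area))
    n_g = min(int(round(w_g * area)), area - n_e - n_n)

    dist = ndi.distance_transform_edt(wound)
    dvals = dist[wound]
    order = np.argsort(dvals, kind="stable")
    rim_idx = coords[order[:n_e]]
    labels[rim_idx[:, 0], rim_idx[:, 1]] = 1

    interior = coords[order[n_e:]]
    if n_n > 0 and len(interior) > 0:
        patch_px = max(1.0, NECROTIC_PATCH_MM2 * params.px_per_mm ** 2)
        k = max(1, int(np.ceil(n_n / patch_px)))
        seeds = interior[rng.choice(len(interior), size=min(k, len(interior)),
                                    replace=False)]
        d2 = ((interior[:, None, :] - seeds[None, :, :]) ** 2).sum(-1).min(1)
        take = np.argsort(d2, kind="stable")[:n_n]
        nec = interior[take]
        labels[nec[:, 0], nec[:, 1]] = 3
        keep = np.ones(len(interior), dtype=bool)
        keep[take] = False
        interior = interior[keep]
    if n_g >= len(interior):
        gran = interior
    else:
        # fill from a random side so the unlabelled remainder is contiguous
        anchor = interior[rng.integers(len(interior))]
        d2 = ((interior - anchor) ** 2).sum(1)
        gran = interior[np.argsort(d2, kind="stable")[:n_g]]
    labels[gran[:, 0], gran[:, 1]] = 2
    return labels


def _paint(shape, labels, params, rng) -> np.ndarray:
    h, w = shape
    img = np.empty((h, w, 3), dtype=float)
    base = np.asarray(params.skin_color, dtype=float)
    img[:] = base
    # smooth mottling plus fine grain for skin texture
    field_ = ndi.gaussian_filter(rng.normal(0, 1, (h, w, 3)), (4, 4, 0))
    img += field_ * params.skin_noise_sigma * 4.0
    for cls, (mean, sigma) in TISSUE_COLOR_MODELS.items():
        mask = labels == cls
        if not mask.any():
            continue
        img[mask] = np.asarray(mean, dtype=float)
        img[mask] += rng.normal(0, sigma, (int(mask.sum()), 3))
    img[labels == 0] += rng.normal(0, params.skin_noise_sigma / 2,
                                   ((labels == 0).sum(), 3))
    return np.clip(img, 0, 255)


def generate_scene(params: SceneParams, spec: ChartSpec | None = None,
                   *, _radius_mm: float | None = None,
                   _fourier: np.ndarray | None = None,
                   keep_clean: bool = False) -> WoundScene:
    """Generate one wound scene; byte-identical for a fixed seed."""
    spec = spec or ChartSpec()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape

    wound = _wound_mask(params, rng, radius_mm=_radius_mm, fourier=_fourier)
    labels = _partition_tissue(wound, params, rng)

    chart_bbox = None
    chart_img = None
    if params.include_chart:
        chart_img, _ = render_chart(spec, params.px_per_mm)
        ch, cw = chart_img.shape[:2]
        r0, c0 = params.chart_origin_px
        if r0 < 0 or c0 < 0 or r0 + ch > h or c0 + cw > w:
            raise PlacementError(
                f"chart ({ch}x{cw} px) does not fit in the "
                f"{h}x{w} px frame at origin {params.chart_origin_px}")
        chart_bbox = (r0, c0, r0 + ch, c0 + cw)
        pad = 2
        if wound[max(0, r0 - pad):r0 + ch + pad,
                 max(0, c0 - pad):c0 + cw + pad].any():
            raise PlacementError("wound overlaps the calibration chart")

    clean = _paint((h, w), labels, params, rng)
    if chart_bbox is not None:
        r0, c0, r1, c1 = chart_bbox
        clean[r0:r1, c0:c1] = chart_img

    cast = params.cast_matrix
    frame = clean.reshape(-1, 3) @ cast.T
    frame = frame.reshape(h, w, 3)
    if params.noise_sigma > 0:
        frame = frame + rng.normal(0, params.noise_sigma, frame.shape)
    image = np.clip(np.rint(frame), 0, 255).astype(np.uint8)

    counts = {c: int((labels == c).sum()) for c in (1, 2, 3)}
    counts[0] = int(labels.size - sum(counts.values()))
    truth = SceneTruth(
        params=params,
        class_pixel_counts=counts,
        wound_pixel_count=int(wound.sum()),
        mm_per_px=1.0 / params.px_per_mm,
        cast=cast,
        chart_bbox_px=chart_bbox,
    )
    return WoundScene(
        image=image, wound_mask=wound, tissue_labels=labels, truth=truth,
        image_clean=np.clip(np.rint(clean), 0, 255).astype(np.uint8)
        if keep_clean else None,
    )


@dataclass
class CohortEntry:
    subject_id: str
    visit: int
    scene: WoundScene


def distribute_visits(n_subjects: int, n_images: int) -> list[int]:
    """Spread ``n_images`` over subjects, at least one visit each."""
    if n_images < n_subjects:
        raise ValueError("need at least one image per subject")
    base = [1] * n_subjects
    for i in range(n_images - n_subjects):
        base[i % n_subjects] += 1
    return base


def generate_cohort(n_subjects: int, visits_per_subject,
                    base_params: SceneParams | None = None,
                    spec: ChartSpec | None = None,
                    seed: int = 0) -> list[CohortEntry]:
    """Longitudinal cohort with per-subject strictly shrinking wounds.

    ``visits_per_subject`` is an int (same for every subject) or a per-
    subject list.  Across visits the wound radius contracts by a fixed
    per-subject factor, necrosis recedes and epithelialisation advances,
    giving monotone ground-truth trends for longitudinal tests.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if isinstance(visits_per_subject, int):
        visits = [visits_per_subject] * n_subjects
    else:
        visits = list(visits_per_subject)
        if len(visits) != n_subjects:
            raise ValueError("one visit count per subject required")
    base_params = base_params or SceneParams()
    spec = spec or ChartSpec()
    master = np.random.SeedSequence(seed)
    subject_seqs = master.spawn(n_subjects)
    out = []
    for s, (n_vis, seq) in enumerate(zip(visits, subject_seqs)):
        srng = np.random.default_rng(seq)
        radius0 = srng.uniform(16.0, 24.0)
        shrink = srng.uniform(0.88, 0.92)   # per-visit radius factor
        orders = np.arange(2, 6)
        fourier = np.stack([
            orders,
            srng.normal(0, base_params.boundary_roughness / np.sqrt(orders)),
            srng.uniform(0, 2 * np.pi, len(orders)),
        ])
        w_e0, w_g0, w_n0 = base_params.tissue_weights
        for v in range(n_vis):
            frac = v / max(1, n_vis - 1) if n_vis > 1 else 0.0
            w_n = w_n0 * (1 - 0.8 * frac)      # necrosis debrided over time
            w_e = min(0.9, w_e0 * (1 + 1.2 * frac))  # epithelium advances
            w_g = max(0.0, min(w_g0, 1 - w_n - w_e))
            scene_seed = int(srng.integers(0, 2 ** 31 - 1))
            params = replace(base_params, seed=scene_seed,
                             tissue_weights=(w_e, w_g, w_n))
            scene = generate_scene(
                params, spec, _radius_mm=radius0 * shrink ** v,
                _fourier=fourier)
            out.append(CohortEntry(subject_id=f"S{s:02d}", visit=v,
                                   scene=scene))
    return out
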