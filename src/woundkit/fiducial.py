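"""Square binary fiducial markers: rendering patterns and detection.

The markers follow the ArUco construction: a one-module black border
surrounding an inner 4x4 binary matrix that encodes the marker identity.
Detection proceeds in the classical two stages — candidate quadrilateral
extraction from a thresholded image, then projective decoding of the inner
bit matrix with rotation disambiguation.

Coordinate convention used throughout the package: a point ``(x, y)`` is in
continuous image coordinates where the centre of pixel ``[r, c]`` sits at
``(c + 0.5, r + 0.5)``.  All corner arrays are ``(4, 2)`` float ``(x, y)``
rows ordered TL, TR, BR, BL *in the marker's own canonical orientation*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_local, threshold_otsu
from skimage.transform import ProjectiveTransform

GRID = 4          # inner bit matrix is GRID x GRID
MODULES = GRID + 2  # plus a one-module border on each side

# Inner 4x4 bit patterns (row-major, 1 = white module).  Chosen so that any
# two patterns differ in >= 6 bits under every relative rotation and no
# pattern is within 6 bits of its own rotations, making identity and
# orientation decoding unambiguous with a margin for sampling noise.
MARKER_BITS = {
    0: 0xE07F,
    1: 0x14CA,
    2: 0x1F97,
    3: 0x350D,
}

DICTIONARY_NAME = "woundkit_4x4_4"


def marker_bit_matrix(marker_id: int) -> np.ndarray:
    """Inner 4x4 binary matrix for ``marker_id`` (1 = white)."""
    bits = MARKER_BITS[marker_id]
    flat = [(bits >> (15 - i)) & 1 for i in range(16)]
    return np.array(flat, dtype=np.uint8).reshape(GRID, GRID)


def marker_pattern(marker_id: int) -> np.ndarray:
    """Full 6x6 module pattern including the black border (1 = white)."""
    pat = np.zeros((MODULES, MODULES), dtype=np.uint8)
    pat[1:-1, 1:-1] = marker_bit_matrix(marker_id)
    return pat


@dataclass
class DetectedMarker:
    """One decoded marker with canonically ordered sub-pixel corners."""

    marker_id: int
    corners: np.ndarray  # (4, 2) float (x, y): canonical TL, TR, BR, BL

    @property
    def center(self) -> np.ndarray:
        return self.corners.mean(axis=0)

    def side_lengths(self) -> np.ndarray:
        """Lengths of the four sides in pixels (TL-TR, TR-BR, BR-BL, BL-TL)."""
        rolled = np.roll(self.corners, -1, axis=0)
        return np.linalg.norm(rolled - self.corners, axis=1)


# ---------------------------------------------------------------------------
# candidate extraction
# ---------------------------------------------------------------------------

def _order_clockwise(pts: np.ndarray) -> np.ndarray:
    """Order 4 points clockwise (image y grows downward) from the centroid."""
    c = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
    return pts[np.argsort(ang)]


def _quad_from_contour(contour_xy: np.ndarray):
    """Reduce a closed contour to 4 vertices via Douglas-Peucker, escalating
    the tolerance until exactly four remain.

    The polygon approximation pins the path endpoints, so the contour is
    first rolled to start at the point farthest from the centroid — a true
    corner for any convex quad — instead of an arbitrary mid-edge point.
    """
    center = contour_xy.mean(axis=0)
    start = int(np.argmax(((contour_xy - center) ** 2).sum(axis=1)))
    contour_xy = np.roll(contour_xy, -start, axis=0)
    closed = np.vstack([contour_xy, contour_xy[:1]])
    per = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
    for frac in (0.01, 0.02, 0.03, 0.05, 0.08, 0.12):
        approx = measure.approximate_polygon(closed[:, ::-1], tolerance=frac * per)
        approx = approx[:, ::-1]
        if np.allclose(approx[0], approx[-1]):
            approx = approx[:-1]
        if len(approx) == 4:
            return approx
    return None


def _refine_corners(contour_xy: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """Refine quad corners by fitting a line to each contour edge (excluding
    points near the corners) and intersecting adjacent lines."""
    n = len(contour_xy)
    # index of the contour point closest to each approximate corner
    idx = [int(np.argmin(np.linalg.norm(contour_xy - q, axis=1))) for q in quad]
    lines = []
    for k in range(4):
        i0, i1 = idx[k], idx[(k + 1) % 4]
        fwd = (i1 - i0) % n
        bwd = (i0 - i1) % n
        if fwd <= bwd:  # walk whichever contour direction gives the short arc
            seg = contour_xy[np.arange(i0, i0 + fwd + 1) % n]
        else:
            seg = contour_xy[np.arange(i1, i1 + bwd + 1) % n]
        if len(seg) < 6:
            lines.append(None)
            continue
        trim = max(1, len(seg) // 6)  # drop points near rounded corners
        seg = seg[trim:-trim]
        centroid = seg.mean(axis=0)
        d = seg - centroid
        # total least squares direction = principal eigenvector
        _, _, vt = np.linalg.svd(d, full_matrices=False)
        direction = vt[0]
        normal = np.array([-direction[1], direction[0]])
        lines.append((normal, normal @ centroid))  # n.x = c
    refined = quad.copy()
    for k in range(4):
        la, lb = lines[k - 1], lines[k]
        if la is None or lb is None:
            continue
        A = np.vstack([la[0], lb[0]])
        b = np.array([la[1], lb[1]])
        det = np.linalg.det(A)
        if abs(det) < 1e-9:
            continue
        p = np.linalg.solve(A, b)
        if np.linalg.norm(p - quad[k]) < 5.0:  # guard against bad fits
            refined[k] = p
    return refined


def _candidate_regions(gray: np.ndarray, min_side: float):
    """Connected dark regions that could be markers, via a global Otsu cut
    with a local-threshold fallback."""
    candidates = []
    masks = []
    if gray.max() > gray.min():
        thr = threshold_otsu(gray)
        masks.append(gray < thr)
    h, w = gray.shape
    block = max(15, (min(h, w) // 8) | 1)
    try:
        masks.append(gray < threshold_local(gray, block_size=block, offset=10))
    except Exception:
        pass
    seen_centroids = []
    for dark in masks:
        filled = ndi.binary_fill_holes(dark)
        labels, n = ndi.label(filled)
        objects = ndi.find_objects(labels)
        for lab, sl in enumerate(objects, start=1):
            if sl is None:
                continue
            hh = sl[0].stop - sl[0].start
            ww = sl[1].stop - sl[1].start
            if hh < min_side or ww < min_side:
                continue
            if max(hh, ww) > 4 * min(hh, ww):
                continue
            area = np.count_nonzero(labels[sl] == lab)
            if area < 0.5 * hh * ww:  # squares are mostly filled
                continue
            cy = sl[0].start + hh / 2
            cx = sl[1].start + ww / 2
            if any((cx - px) ** 2 + (cy - py) ** 2 < min_side ** 2
                   for px, py in seen_centroids):
                continue
            seen_centroids.append((cx, cy))
            candidates.append((sl, labels[sl] == lab))
    return candidates


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _bilinear(gray: np.ndarray, pts_xy: np.ndarray) -> np.ndarray:
    coords = np.stack([pts_xy[:, 1] - 0.5, pts_xy[:, 0] - 0.5])
    return ndi.map_coordinates(gray, coords, order=1, mode="nearest")


def projective_from_points(src: np.ndarray, dst: np.ndarray):
    """Least-squares projective transform src -> dst, or None on failure.

    Wraps the scikit-image estimator across its API change.
    """
    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(src, dst)
        return tf if tf else None
    tf = ProjectiveTransform()
    return tf if tf.estimate(src, dst) else None


def _sample_modules(gray: np.ndarray, corners: np.ndarray) -> np.ndarray:
    """Mean intensity of each of the 6x6 modules, sampled through the
    projective map defined by the quad corners."""
    src = np.array([[0, 0], [MODULES, 0], [MODULES, MODULES], [0, MODULES]],
                   dtype=float)
    tf = projective_from_points(src, corners)
    if tf is None:
        return None
    offsets = np.array([(du, dv) for du in (-0.18, 0.0, 0.18)
                        for dv in (-0.18, 0.0, 0.18)])
    means = np.empty((MODULES, MODULES))
    centers = np.array([[(j + 0.5, i + 0.5) for j in range(MODULES)]
                        for i in range(MODULES)], dtype=float).reshape(-1, 2)
    all_pts = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    vals = _bilinear(gray, tf(all_pts)).reshape(-1, len(offsets)).mean(axis=1)
    means[:, :] = vals.reshape(MODULES, MODULES)
    return means


def _decode(means: np.ndarray):
    """Match the sampled module intensities against the dictionary.

    Returns ``(marker_id, rotation)`` where ``rotation`` is the number of
    90-degree counter-clockwise turns that bring the observed grid into the
    canonical orientation, or ``None`` when no pattern matches.
    """
    lo, hi = means.min(), means.max()
    if hi - lo < 20:  # not a binary pattern
        return None
    thr = 0.5 * (lo + hi)
    cells = (means > thr).astype(np.uint8)
    border = np.concatenate([cells[0, :], cells[-1, :], cells[1:-1, 0],
                             cells[1:-1, -1]])
    if border.sum() > 2:  # border must be (almost all) black
        return None
    inner = cells[1:-1, 1:-1]
    for marker_id, bits in MARKER_BITS.items():
        target = marker_bit_matrix(marker_id)
        for k in range(4):
            if np.array_equal(np.rot90(inner, k), target):
                return marker_id, k
    return None


def detect(gray: np.ndarray, min_side: float = 10.0) -> list[DetectedMarker]:
    """Detect and decode all dictionary markers in a grayscale image.

    Parameters
    ----------
    gray : 2-D float or uint8 array, intensities on the 0-255 scale.
    min_side : smallest marker side, in pixels, worth considering.

    Returns a list of :class:`DetectedMarker`; an empty list is a valid
    result for an image without markers.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ValueError("detect() expects a single-channel image")
    found: dict[int, DetectedMarker] = {}
    for sl, region in _candidate_regions(gray, min_side):
        pad = 3
        r0 = max(0, sl[0].start - pad)
        r1 = min(gray.shape[0], sl[0].stop + pad)
        c0 = max(0, sl[1].start - pad)
        c1 = min(gray.shape[1], sl[1].stop + pad)
        window = gray[r0:r1, c0:c1]
        placed = np.zeros(window.shape, dtype=bool)
        placed[sl[0].start - r0:sl[0].stop - r0,
               sl[1].start - c0:sl[1].stop - c0] = region
        region_vals = window[placed]
        outside = ~placed
        # border ink level vs. surrounding background level: the contour is
        # traced at their midpoint so hard edges land half a pixel out
        dark = np.percentile(region_vals, 20)
        light = np.median(window[outside])
        level = 0.5 * (dark + light)
        if not (window.min() < level < window.max()):
            continue
        contours = measure.find_contours(window, level=level)
        if not contours:
            continue
        contour = max(contours, key=len)
        contour_xy = np.stack([contour[:, 1] + 0.5 + c0,
                               contour[:, 0] + 0.5 + r0], axis=1)
        quad = _quad_from_contour(contour_xy)
        if quad is None:
            continue
        quad = _order_clockwise(quad)
        quad = _refine_corners(contour_xy, quad)
        quad = _order_clockwise(quad)
        means = _sample_modules(gray, quad)
        if means is None:
            continue
        decoded = _decode(means)
        if decoded is None:
            continue
        marker_id, rot = decoded
        canonical = np.roll(quad, -rot, axis=0)
        if marker_id not in found:
            found[marker_id] = DetectedMarker(marker_id, canonical)
    return [found[k] for k in sorted(found)]
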