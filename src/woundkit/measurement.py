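"""Metric wound measurement and longitudinal per-visit tissue-area series.

Masks are converted to physical areas with ``pixels * mm_per_px**2`` using
the scale recovered by calibration; areas are planar (chart-plane)
approximations with no curvature correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AREA_CLASSES = ("wound", "epithelial", "granulation", "necrotic")


def mask_area_mm2(mask: np.ndarray, mm_per_px: float) -> float:
    """Physical area of a binary mask: pixel count times mm_per_px squared."""
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    mask = np.asarray(mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary")
        mask = mask.astype(bool)
    return float(np.count_nonzero(mask)) * mm_per_px ** 2


@dataclass
class VisitRecord:
    """Per-visit measured areas for one subject."""

    subject_id: str
    visit: int
    areas_mm2: dict[str, float]    # keys from AREA_CLASSES
    mm_per_px: float
    source: str = ""

    def __post_init__(self):
        for cls, area in self.areas_mm2.items():
            if area < 0:
                raise ValueError(f"negative area for {cls}")


def record_from_masks(subject_id: str, visit: int, wound_mask: np.ndarray,
                      tissue_labels: np.ndarray, mm_per_px: float,
                      source: str = "") -> VisitRecord:
    """Measure all class areas from a wound mask and tissue label map."""
    areas = {"wound": mask_area_mm2(np.asarray(wound_mask).astype(bool),
                                    mm_per_px)}
    for cls, code in (("epithelial", 1), ("granulation", 2),
                      ("necrotic", 3)):
        areas[cls] = mask_area_mm2(np.asarray(tissue_labels) == code,
                                   mm_per_px)
    return VisitRecord(subject_id=subject_id, visit=visit, areas_mm2=areas,
                       mm_per_px=mm_per_px, source=source)


def longitudinal_series(records: list[VisitRecord]) -> pd.DataFrame:
    """Ordered per-visit area table with first differences and trend flags.

    All records must share one subject; duplicate visit indices are an
    error.  Columns: per class the area, its visit-to-visit delta, and a
    subject-level trend flag (``decreasing`` / ``increasing`` / ``mixed``).
    """
    if not records:
        raise ValueError("no records")
    subjects = {r.subject_id for r in records}
    if len(subjects) != 1:
        raise ValueError(f"records span multiple subjects: {sorted(subjects)}")
    visits = [r.visit for r in records]
    if len(set(visits)) != len(visits):
        raise ValueError("duplicate visit index")
    ordered = sorted(records, key=lambda r: r.visit)
    rows = []
    for r in ordered:
        row = {"subject_id": r.subject_id, "visit": r.visit,
               "mm_per_px": r.mm_per_px, "source": r.source}
        for cls in AREA_CLASSES:
            row[f"{cls}_mm2"] = r.areas_mm2.get(cls, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    for cls in AREA_CLASSES:
        delta = df[f"{cls}_mm2"].diff()
        df[f"{cls}_delta_mm2"] = delta
        d = delta.dropna()
        if len(d) == 0:
            trend = "single-visit"
        elif (d < 0).all():
            trend = "decreasing"
        elif (d > 0).all():
            trend = "increasing"
        else:
            trend = "mixed"
        df[f"{cls}_trend"] = trend
    return df


def plot_series(df: pd.DataFrame, path) -> None:
    """Write a per-class area-vs-visit panel figure (PNG/PDF by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(8, 6), sharex=True)
    for ax, cls in zip(axes.ravel(), AREA_CLASSES):
        ax.plot(df["visit"], df[f"{cls}_mm2"], marker="o")
        ax.set_title(cls)
        ax.set_xlabel("visit")
        ax.set_ylabel("area (mm$^2$)")
    fig.suptitle(f"subject {df['subject_id'].iloc[0]}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
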