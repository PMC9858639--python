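"""File-format plumbing: PNG images, PNG label maps, JSON sidecars, CSV.

Label maps are single-channel 8-bit PNGs with codes {0, 1, 2, 3} =
{background, epithelial, granulation, necrotic}; wound masks are separate
binary PNGs (0/255), mirroring the network's two output branches.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image


def read_image(path) -> np.ndarray:
    """8-bit RGB image as an (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_label_map(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def write_label_map(path, labels: np.ndarray) -> None:
    arr = np.asarray(labels)
    if arr.max(initial=0) > 255:
        raise ValueError("label codes must fit in 8 bits")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


def read_mask(path) -> np.ndarray:
    return read_label_map(path) > 127


def write_mask(path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(np.asarray(mask, dtype=bool), 255, 0)
                    .astype(np.uint8), mode="L").save(path)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def save_scene(directory, stem: str, scene) -> dict:
    """Write a WoundScene as image + label map + wound mask + truth JSON.

    Returns the relative paths written (used by cohort manifests).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": f"{stem}.png",
        "tissue": f"{stem}_tissue.png",
        "wound": f"{stem}_wound.png",
        "truth": f"{stem}_truth.json",
    }
    write_image(directory / paths["image"], scene.image)
    write_label_map(directory / paths["tissue"], scene.tissue_labels)
    write_mask(directory / paths["wound"], scene.wound_mask)
    t = scene.truth
    write_json(directory / paths["truth"], {
        "class_pixel_counts": {str(k): v
                               for k, v in t.class_pixel_counts.items()},
        "wound_pixel_count": t.wound_pixel_count,
        "mm_per_px": t.mm_per_px,
        "cast": t.cast,
        "chart_bbox_px": t.chart_bbox_px,
        "seed": t.params.seed,
        "px_per_mm": t.params.px_per_mm,
        "tissue_weights": list(t.params.tissue_weights),
    })
    return paths


def save_cohort(directory, cohort) -> Path:
    """Write every scene of a cohort plus a manifest CSV
    (subject_id, visit, image, wound, tissue, truth)."""
    directory = Path(directory)
    rows = []
    for entry in cohort:
        stem = f"{entry.subject_id}_v{entry.visit}"
        paths = save_scene(directory, stem, entry.scene)
        rows.append({"subject_id": entry.subject_id, "visit": entry.visit,
                     **paths})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort_samples(manifest_path):
    """Read a cohort manifest back into (samples, subject_ids, table).

    ``samples[i] = (image, wound_mask, tissue_labels)`` aligned with
    ``subject_ids[i]``.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    samples, subjects = [], []
    for _, row in df.iterrows():
        samples.append((read_image(base / row["image"]),
                        read_mask(base / row["wound"]),
                        read_label_map(base / row["tissue"])))
        subjects.append(row["subject_id"])
    return samples, subjects, df
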