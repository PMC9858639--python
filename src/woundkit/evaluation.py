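"""Segmentation metrics, subject-grouped nested CV, inter-rater agreement.

Metrics follow the standard per-class confusion-count definitions: pixel
accuracy ``(TP+TN)/N`` and intersection over union ``TP/(TP+FP+FN)``.  The
0/0 IoU case (class absent from both prediction and truth) returns 1.0 and
is flagged, so images that correctly contain no necrosis are not penalised;
summaries excluding such images are also reported.

Cross-validation is nested and grouped: subjects are partitioned across
outer folds (test role) and, within each outer fold, across inner folds
(validation role); every image follows its subject.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

CLASS_ORDER = ("wound", "epithelial", "granulation", "necrotic")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary per-class pixel confusion counts for one image."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally TP/TN/FP/FN between two binary masks of identical shape."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def pixel_accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / all pixels."""
    if c.total == 0:
        raise ValueError("pixel accuracy undefined on an empty image")
    return (c.tp + c.tn) / c.total


def iou(c: ConfusionCounts, empty_value: float = 1.0) -> float:
    """TP / (TP + FP + FN); the 0/0 case returns ``empty_value`` (default
    1.0: correctly predicting an absent class counts as perfect overlap)."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return empty_value
    return c.tp / denom


def mask_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    c = confusion_counts(pred, truth)
    return {
        "iou": iou(c),
        "pixel_accuracy": pixel_accuracy(c),
        "both_empty": c.tp + c.fp + c.fn == 0,
    }


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Subject-grouped nested CV plan.

    ``outer_folds[i]`` is ``(trainval_subjects, test_subjects)``;
    ``inner_folds[i][j]`` is ``(train_subjects, val_subjects)`` partitioning
    ``trainval_subjects`` of outer fold ``i``.
    """

    outer_folds: list[tuple[list, list]]
    inner_folds: list[list[tuple[list, list]]]
    n_outer: int
    n_inner: int
    seed: int

    def test_fold_of(self, subject) -> int:
        for i, (_, test) in enumerate(self.outer_folds):
            if subject in test:
                return i
        raise KeyError(subject)

    def to_json(self) -> str:
        return json.dumps({
            "n_outer": self.n_outer,
            "n_inner": self.n_inner,
            "seed": self.seed,
            "outer_folds": [[list(a), list(b)] for a, b in self.outer_folds],
            "inner_folds": [[[list(a), list(b)] for a, b in folds]
                            for folds in self.inner_folds],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FoldPlan":
        d = json.loads(text)
        return cls(
            outer_folds=[(a, b) for a, b in d["outer_folds"]],
            inner_folds=[[(a, b) for a, b in folds]
                         for folds in d["inner_folds"]],
            n_outer=d["n_outer"], n_inner=d["n_inner"], seed=d["seed"],
        )


def nested_cv_split(subject_ids, outer: int = 10, inner: int = 9,
                    seed: int = 0) -> FoldPlan:
    """Build a grouped nested CV plan from per-image subject ids.

    Subjects (not images) are split, so all images of a subject share every
    fold role.  Outer folds partition the subjects into ``outer`` nearly
    equal test sets; within each outer fold the remaining subjects are
    partitioned into ``inner`` validation sets.  Deterministic in ``seed``.
    """
    subjects = sorted(set(subject_ids))
    if len(subjects) < outer:
        raise ValueError(
            f"{len(subjects)} subjects cannot fill {outer} outer folds")
    subjects = np.array(subjects, dtype=object)
    outer_kf = KFold(n_splits=outer, shuffle=True, random_state=seed)
    outer_folds, inner_all = [], []
    for k, (trainval_idx, test_idx) in enumerate(outer_kf.split(subjects)):
        trainval = subjects[trainval_idx]
        test = subjects[test_idx]
        if len(trainval) < inner:
            raise ValueError(
                f"outer fold {k}: {len(trainval)} subjects cannot fill "
                f"{inner} inner folds")
        inner_kf = KFold(n_splits=inner, shuffle=True,
                         random_state=seed + 1 + k)
        inner_folds = [(list(trainval[a]), list(trainval[b]))
                       for a, b in inner_kf.split(trainval)]
        outer_folds.append((list(trainval), list(test)))
        inner_all.append(inner_folds)
    return FoldPlan(outer_folds=outer_folds, inner_folds=inner_all,
                    n_outer=outer, n_inner=inner, seed=seed)


# ---------------------------------------------------------------------------
# inter-rater agreement
# ---------------------------------------------------------------------------

def inter_rater_agreement(annotations: dict, classes=CLASS_ORDER
                          ) -> pd.DataFrame:
    """Pairwise IoU agreement between raters.

    ``annotations[rater][image_id][class_name]`` is a binary mask.  For
    every unordered rater pair and class the per-image IoU is computed,
    then summarised as mean and SD across images; the overall per-class
    figure is the unweighted mean over pairs.  Images missing from either
    rater are excluded with a warning and counted.
    """
    raters = sorted(annotations)
    if len(raters) < 2:
        raise ValueError("need at least two raters")
    rows = []
    for i, ra in enumerate(raters):
        for rb in raters[i + 1:]:
            shared = sorted(set(annotations[ra]) & set(annotations[rb]))
            missing = (set(annotations[ra]) | set(annotations[rb])) \
                - set(shared)
            if missing:
                warnings.warn(
                    f"pair ({ra}, {rb}): {len(missing)} image(s) lack an "
                    f"annotation from one rater and were excluded")
            for cls in classes:
                vals = [iou(confusion_counts(annotations[ra][img][cls],
                                             annotations[rb][img][cls]))
                        for img in shared]
                rows.append({
                    "rater_a": ra, "rater_b": rb, "class": cls,
                    "mean_iou": float(np.mean(vals)) if vals else np.nan,
                    "sd_iou": float(np.std(vals, ddof=0)) if vals else np.nan,
                    "n_images": len(vals),
                    "n_excluded": len(missing),
                })
    df = pd.DataFrame(rows)
    overall = (df.groupby("class", sort=False)["mean_iou"].mean()
               .rename("overall_mean_iou"))
    return df.merge(overall, on="class")


# ---------------------------------------------------------------------------
# run-level evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-class mean and SD of IoU and pixel accuracy over images."""

    per_image: pd.DataFrame           # image_id, class, iou, pixel_accuracy
    summary: pd.DataFrame             # class-level mean/sd, two variants
    fold_summary: pd.DataFrame | None = None

    def to_csv(self, path):
        self.summary.to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps({
            "summary": self.summary.to_dict(orient="records"),
            "per_image": self.per_image.to_dict(orient="records"),
        }, indent=2)


def _masks_of(entry: dict, cls: str) -> np.ndarray:
    if cls == "wound":
        return np.asarray(entry["wound"]).astype(bool)
    code = {"epithelial": 1, "granulation": 2, "necrotic": 3}[cls]
    return np.asarray(entry["tissue"]) == code


def evaluate_run(predictions: dict, truths: dict,
                 plan: FoldPlan | None = None,
                 image_subjects: dict | None = None) -> EvalReport:
    """Aggregate metrics over a full (nested CV) run.

    ``predictions[image_id]`` and ``truths[image_id]`` are dicts with a
    binary ``"wound"`` mask and an integer ``"tissue"`` label map.  Raises
    when any truth image lacks a prediction.  When a plan and an
    ``image_subjects`` map are given, a per-outer-fold breakdown is added.
    """
    missing = sorted(set(truths) - set(predictions))
    if missing:
        raise ValueError(f"missing predictions for images: {missing}")
    rows = []
    for image_id in sorted(truths):
        for cls in CLASS_ORDER:
            m = mask_metrics(_masks_of(predictions[image_id], cls),
                             _masks_of(truths[image_id], cls))
            rows.append({"image_id": image_id, "class": cls, **m})
    per_image = pd.DataFrame(rows)
    summaries = []
    for cls in CLASS_ORDER:
        sub = per_image[per_image["class"] == cls]
        present = sub[~sub["both_empty"]]
        summaries.append({
            "class": cls,
            "mean_iou": sub["iou"].mean(),
            "sd_iou": sub["iou"].std(ddof=0),
            "mean_pixel_accuracy": sub["pixel_accuracy"].mean(),
            "sd_pixel_accuracy": sub["pixel_accuracy"].std(ddof=0),
            "mean_iou_present_only": present["iou"].mean()
            if len(present) else np.nan,
            "n_images": len(sub),
            "n_both_empty": int(sub["both_empty"].sum()),
        })
    fold_summary = None
    if plan is not None and image_subjects is not None:
        per_image = per_image.assign(
            fold=[plan.test_fold_of(image_subjects[i])
                  for i in per_image["image_id"]])
        fold_summary = (per_image.groupby(["fold", "class"], sort=False)
                        [["iou", "pixel_accuracy"]].mean().reset_index())
    return EvalReport(per_image=per_image, summary=pd.DataFrame(summaries),
                      fold_summary=fold_summary)
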