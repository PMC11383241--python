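"""Object-detection evaluation: IoU matching, AP/mAP, confusion matrix.

A detector proposes ``(box, label, score)`` triples; ground truth is the set
of annotated floral count units.  A proposal is a true positive when it
overlaps an annotation sufficiently (IoU above the threshold, 0.5 by
convention), carries the correct label, and — for the confusion matrix —
scores above the confidence threshold.  When several proposals overlap one
annotation, the one with the highest IoU is the true positive and the
duplicates are false positives; matching is therefore greedy by descending
IoU.

Per-class average precision is the all-point-interpolated area under the
precision-recall curve built by ranking that class's detections by
confidence; mAP is the unweighted mean over classes present in the ground
truth.  The confusion matrix is built with label-agnostic matching (so that
species-for-species mistakes land in off-diagonal cells) and augmented with
a background row (spurious detections) and column (missed annotations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .voc import Annotation, Box

__all__ = [
    "BACKGROUND",
    "Detection",
    "EvalConfig",
    "Match",
    "MatchSet",
    "EvalResult",
    "iou",
    "match_class",
    "pr_curve",
    "average_precision",
    "mean_ap",
    "confusion_matrix",
    "percent_correct",
    "early_stop",
    "evaluate",
    "read_detections_csv",
    "write_detections_csv",
]

#: Label of the catch-all row/column in the confusion matrix.
BACKGROUND = "_background_"


@dataclass(frozen=True)
class Detection:
    """A predicted box with class label and confidence score in [0, 1]."""

    box: Box
    label: str
    score: float
    image_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0,1], got {self.score}")


@dataclass(frozen=True)
class EvalConfig:
    iou_threshold: float = 0.5
    score_threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("iou_threshold", "score_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")


@dataclass(frozen=True)
class Match:
    detection: Detection
    annotation: Optional[Annotation]
    iou: float
    flag: str  # "TP" | "FP"


@dataclass
class MatchSet:
    matches: list[Match]
    missed: list[Annotation]

    @property
    def n_tp(self) -> int:
        return sum(1 for m in self.matches if m.flag == "TP")

    @property
    def n_fp(self) -> int:
        return sum(1 for m in self.matches if m.flag == "FP")


def iou(b1: Box, b2: Box) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    inter = b1.intersection_area(b2)
    if inter == 0:
        return 0.0
    return inter / (b1.area + b2.area - inter)


def match_class(
    dets: Sequence[Detection],
    gts: Sequence[Annotation],
    iou_thr: float = 0.5,
    label_aware: bool = True,
) -> MatchSet:
    """Greedy one-to-one matching by descending IoU.

    Candidate pairs have IoU strictly above ``iou_thr`` (and equal labels
    when ``label_aware``); pairs are accepted in order of decreasing IoU
    over still-unused detections and annotations.  Accepted detections are
    TPs, the rest FPs; unmatched annotations are misses.  Ties in IoU break
    on (detection index, annotation index) for determinism.
    """
    pairs = []
    for i, d in enumerate(dets):
        for j, g in enumerate(gts):
            if label_aware and d.label != g.species_label:
                continue
            v = iou(d.box, g.box)
            if v > iou_thr:
                pairs.append((-v, i, j))
    pairs.sort()
    used_d: set[int] = set()
    used_g: set[int] = set()
    matched: dict[int, tuple[int, float]] = {}
    for neg_v, i, j in pairs:
        if i in used_d or j in used_g:
            continue
        used_d.add(i)
        used_g.add(j)
        matched[i] = (j, -neg_v)
    matches = []
    for i, d in enumerate(dets):
        if i in matched:
            j, v = matched[i]
            matches.append(Match(d, gts[j], v, "TP"))
        else:
            matches.append(Match(d, None, 0.0, "FP"))
    missed = [g for j, g in enumerate(gts) if j not in used_g]
    return MatchSet(matches=matches, missed=missed)


def pr_curve(
    dets_by_image: Mapping[str, Sequence[Detection]],
    gts_by_image: Mapping[str, Sequence[Annotation]],
    cls: str,
    iou_thr: float = 0.5,
) -> list[tuple[float, float]]:
    """Precision-recall pairs for one class, rank-accumulated over all images.

    Detections of the class are matched per image (label-aware, greedy by
    IoU), pooled, ranked by descending confidence, and cumulated:
    ``recall = TP/n_gt``, ``precision = TP/(TP+FP)`` at each rank.
    """
    n_gt = sum(
        sum(1 for g in gts if g.species_label == cls)
        for gts in gts_by_image.values()
    )
    if n_gt == 0:
        raise ValueError(f"class {cls!r} absent from ground truth")
    flagged: list[tuple[float, bool]] = []
    for img_id, dets in dets_by_image.items():
        dets_c = [d for d in dets if d.label == cls]
        gts_c = [
            g
            for g in gts_by_image.get(img_id, ())
            if g.species_label == cls
        ]
        ms = match_class(dets_c, gts_c, iou_thr, label_aware=True)
        flagged.extend((m.detection.score, m.flag == "TP") for m in ms.matches)
    flagged.sort(key=lambda t: -t[0])
    curve = []
    tp = fp = 0
    for _, is_tp in flagged:
        if is_tp:
            tp += 1
        else:
            fp += 1
        curve.append((tp / n_gt, tp / (tp + fp)))
    return curve


def average_precision(
    curve: Sequence[tuple[float, float]], interpolation: str = "all"
) -> float:
    """Area under the precision-recall curve.

    ``all`` (default): all-point interpolation,
    ``AP = sum_i (r_i - r_{i-1}) * max_{j>=i} p_j`` with r_0 = 0.
    ``11point``: mean of interpolated precision at recalls 0, 0.1, ..., 1.
    """
    if not curve:
        return 0.0
    recalls = np.asarray([r for r, _ in curve], dtype=float)
    precisions = np.asarray([p for _, p in curve], dtype=float)
    # precision as a downward-sloping function of recall
    ceiling = np.maximum.accumulate(precisions[::-1])[::-1]
    if interpolation == "all":
        prev = np.concatenate(([0.0], recalls[:-1]))
        return float(np.sum((recalls - prev) * ceiling))
    if interpolation == "11point":
        pts = []
        for r in np.linspace(0, 1, 11):
            mask = recalls >= r - 1e-12
            pts.append(float(ceiling[mask][0]) if mask.any() else 0.0)
        return float(np.mean(pts))
    raise ValueError(f"unknown interpolation {interpolation!r}")


def mean_ap(per_class_ap: Mapping[str, float]) -> float:
    """Unweighted mean of per-class AP values."""
    if not per_class_ap:
        raise ValueError("mean_ap of an empty class set is undefined")
    return float(np.mean(list(per_class_ap.values())))


def confusion_matrix(
    dets_by_image: Mapping[str, Sequence[Detection]],
    gts_by_image: Mapping[str, Sequence[Annotation]],
    cfg: EvalConfig = EvalConfig(),
    class_list: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Background-augmented confusion matrix.

    Rows hold actual annotations, columns hold predicted labels.  Detections
    below the confidence threshold are discarded; the surviving ones are
    matched label-agnostically per image so that label mistakes produce
    off-diagonal counts.  Unmatched annotations go to the background column
    (misses); unmatched detections to the background row (spurious hits).
    Every non-background row sums to that species' ground-truth count.
    """
    if class_list is None:
        classes = sorted(
            {g.species_label for gts in gts_by_image.values() for g in gts}
            | {
                d.label
                for dets in dets_by_image.values()
                for d in dets
                if d.score > cfg.score_threshold
            }
        )
    else:
        classes = list(class_list)
    labels = classes + [BACKGROUND]
    idx = {c: k for k, c in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)), dtype=int)
    for img_id in sorted(set(dets_by_image) | set(gts_by_image)):
        dets = [
            d
            for d in dets_by_image.get(img_id, ())
            if d.score > cfg.score_threshold
        ]
        gts = list(gts_by_image.get(img_id, ()))
        ms = match_class(dets, gts, cfg.iou_threshold, label_aware=False)
        for m in ms.matches:
            if m.flag == "TP":
                mat[idx[m.annotation.species_label], idx[m.detection.label]] += 1
            else:
                mat[idx[BACKGROUND], idx[m.detection.label]] += 1
        for g in ms.missed:
            mat[idx[g.species_label], idx[BACKGROUND]] += 1
    return pd.DataFrame(mat, index=labels, columns=labels)


def percent_correct(confusion: pd.DataFrame) -> float:
    """Percent of ground-truth annotations predicted with the correct label.

    ``100 * diagonal_sum / ground_truth_total`` over non-background classes;
    the background row (spurious detections) is excluded from the
    denominator.  Chance level for K equiprobable classes is 100/K.
    """
    classes = [c for c in confusion.index if c != BACKGROUND]
    total = int(confusion.loc[classes].to_numpy().sum())
    if total == 0:
        raise ValueError("percent_correct undefined with zero ground truth")
    diag = sum(int(confusion.loc[c, c]) for c in classes)
    return 100.0 * diag / total


def early_stop(map_history: Sequence[float], window: int = 5) -> bool:
    """Stop when the latest epoch metric drops below the mean of the
    preceding ``window`` epochs; never stops with insufficient history."""
    if len(map_history) <= window:
        return False
    recent = map_history[-window - 1 : -1]
    return map_history[-1] < sum(recent) / window


@dataclass
class EvalResult:
    per_class_ap: dict[str, float]
    map: float
    confusion: pd.DataFrame
    percent_correct: Optional[float]
    config: EvalConfig = field(default_factory=EvalConfig)

    def to_dict(self) -> dict:
        return {
            "mAP": self.map,
            "per_class_AP": dict(self.per_class_ap),
            "percent_correct": self.percent_correct,
            "iou_threshold": self.config.iou_threshold,
            "score_threshold": self.config.score_threshold,
        }


def evaluate(
    dets_by_image: Mapping[str, Sequence[Detection]],
    gts_by_image: Mapping[str, Sequence[Annotation]],
    cfg: EvalConfig = EvalConfig(),
    class_list: Optional[Sequence[str]] = None,
) -> EvalResult:
    """Full evaluation: per-class AP, mAP, confusion matrix, percent correct.

    AP uses all detections regardless of score (the PR curve sweeps the
    confidence axis); the confusion matrix applies the score threshold.
    Classes absent from the ground truth are excluded from mAP.
    """
    gt_classes = sorted(
        {g.species_label for gts in gts_by_image.values() for g in gts}
    )
    per_class_ap = {
        c: average_precision(
            pr_curve(dets_by_image, gts_by_image, c, cfg.iou_threshold)
        )
        for c in gt_classes
    }
    confusion = confusion_matrix(dets_by_image, gts_by_image, cfg, class_list)
    try:
        pc = percent_correct(confusion)
    except ValueError:
        pc = None
    return EvalResult(
        per_class_ap=per_class_ap,
        map=mean_ap(per_class_ap) if per_class_ap else float("nan"),
        confusion=confusion,
        percent_correct=pc,
        config=cfg,
    )


_DET_COLUMNS = ["image_id", "label", "score", "xmin", "ymin", "xmax", "ymax"]


def write_detections_csv(dets_by_image: Mapping[str, Sequence[Detection]], path) -> Path:
    rows = [
        {
            "image_id": img_id,
            "label": d.label,
            "score": d.score,
            "xmin": d.box.xmin,
            "ymin": d.box.ymin,
            "xmax": d.box.xmax,
            "ymax": d.box.ymax,
        }
        for img_id, dets in dets_by_image.items()
        for d in dets
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=_DET_COLUMNS).to_csv(path, index=False)
    return path


def read_detections_csv(path) -> dict[str, list[Detection]]:
    df = pd.read_csv(path)
    missing = [c for c in _DET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict[str, list[Detection]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.image_id), []).append(
            Detection(
                box=Box(int(row.xmin), int(row.ymin), int(row.xmax), int(row.ymax)),
                label=str(row.label),
                score=float(row.score),
                image_id=str(row.image_id),
            )
        )
    return out
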