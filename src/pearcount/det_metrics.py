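"""Pascal-VOC-style detection evaluation.

IoU, confidence-thresholded TP/FP/FN matching, the derived ratio metrics
(precision, recall, F1, false-negative and false-positive rates), mean IoU
over true positives, and 11-point interpolated average precision.

Matching follows the VOC convention: detections are visited in descending
confidence (ties broken by frame, then left, then top coordinate); each
detection claims the highest-IoU still-unclaimed ground-truth box, and the
claim stands only when IoU meets the threshold.  Detections below the
confidence threshold are suppressed before matching: they are neither TP nor
FP, and a ground-truth box they would have covered counts as FN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .io import BBox, DetectionStream, GroundTruthScene

__all__ = [
    "EvalConfig",
    "DetEvalReport",
    "iou",
    "evaluate_detections",
    "average_precision_11pt",
    "write_det_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalConfig:
    """TP rule: IoU ≥ iou_threshold among detections with confidence ≥ confidence_threshold."""

    iou_threshold: float = 0.5
    confidence_threshold: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.iou_threshold <= 1.0):
            raise ValidationError(f"iou_threshold must lie in (0, 1], got {self.iou_threshold}")
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValidationError(
                f"confidence_threshold must lie in [0, 1], got {self.confidence_threshold}"
            )


@dataclass(frozen=True)
class DetEvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    fnr: float
    fpr: float
    avg_iou: float
    ap: float

    @staticmethod
    def from_counts(tp: int, fp: int, fn: int, avg_iou: float = 0.0, ap: float = 0.0) -> "DetEvalReport":
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        return DetEvalReport(
            tp=tp,
            fp=fp,
            fn=fn,
            precision=precision,
            recall=recall,
            f1=f1,
            fnr=1.0 - recall,
            fpr=1.0 - precision,
            avg_iou=avg_iou,
            ap=ap,
        )


def iou(a: BBox, b: BBox) -> float:
    """Intersection area over union area; 0 for disjoint boxes."""
    ix = min(a.right, b.right) - max(a.x, b.x)
    iy = min(a.bottom, b.bottom) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area() + b.area() - inter)


def _match_frame(
    dets: Sequence, gt_boxes: dict[int, BBox], iou_threshold: float
) -> tuple[list[tuple[float, bool]], list[float], set[int]]:
    """Greedy VOC matching of one frame's detections against its GT boxes.

    Returns (per-detection (confidence, is_tp) labels in the visiting order,
    IoUs of the TP matches, set of claimed ground-truth ids).
    """
    labels: list[tuple[float, bool]] = []
    tp_ious: list[float] = []
    claimed: set[int] = set()
    for det in dets:
        best_oid, best_iou = None, 0.0
        for oid, gbox in gt_boxes.items():
            if oid in claimed:
                continue
            ov = iou(det.box, gbox)
            if ov > best_iou:
                best_oid, best_iou = oid, ov
        if best_oid is not None and best_iou >= iou_threshold:
            claimed.add(best_oid)
            labels.append((det.confidence, True))
            tp_ious.append(best_iou)
        else:
            labels.append((det.confidence, False))
    return labels, tp_ious, claimed


def evaluate_detections(
    dets: DetectionStream, gt: GroundTruthScene, cfg: EvalConfig | None = None
) -> DetEvalReport:
    """Score a detection stream against ground truth on matched frames.

    Every visible ground-truth (object, frame) box is one ground-truth
    instance.  Suppressed (below confidence threshold) detections contribute
    to FN through their unclaimed box, never to FP.
    """
    cfg = cfg or EvalConfig()
    if gt.n_frames > 0:
        bad = [f for f in dets if f < 0 or f >= gt.n_frames]
        if bad:
            raise ValidationError(
                f"detections reference frames {sorted(bad)[:5]} outside the "
                f"ground-truth range [0, {gt.n_frames})"
            )

    n_gt = gt.total_boxes()
    labels: list[tuple[float, bool]] = []
    tp_ious: list[float] = []
    tp = 0
    frames = sorted(set(dets) | {f for t in gt.objects.values() for f in t})
    for frame in frames:
        frame_dets = [
            d
            for d in dets.get(frame, [])
            if d.confidence >= cfg.confidence_threshold
        ]
        frame_dets.sort(key=lambda d: (-d.confidence, d.frame, d.box.x, d.box.y))
        frame_labels, frame_ious, claimed = _match_frame(
            frame_dets, gt.boxes_at(frame), cfg.iou_threshold
        )
        labels.extend(frame_labels)
        tp_ious.extend(frame_ious)
        tp += len(claimed)

    fp = sum(1 for _, is_tp in labels if not is_tp)
    fn = n_gt - tp
    avg_iou = sum(tp_ious) / len(tp_ious) if tp_ious else 0.0
    ap = average_precision_11pt(labels, n_gt)
    return DetEvalReport.from_counts(tp, fp, fn, avg_iou=avg_iou, ap=ap)


def average_precision_11pt(labels: Iterable[tuple[float, bool]], n_gt: int) -> float:
    """11-point interpolated AP.

    ``labels`` are (confidence, is_tp) pairs as produced by the matching
    sweep; they are ranked by descending confidence here.  AP is the mean over
    recall levels r ∈ {0, 0.1, ..., 1.0} of the maximum precision at recall
    ≥ r (0 when no ranked point reaches r).
    """
    if n_gt < 0:
        raise ValidationError(f"n_gt must be non-negative, got {n_gt}")
    ranked = sorted(labels, key=lambda t: -t[0])
    if n_gt == 0:
        if ranked:
            logger.warning("AP requested with detections but zero ground-truth boxes; returning 0")
        return 0.0
    if not ranked:
        return 0.0
    precisions: list[float] = []
    recalls: list[float] = []
    tp = 0
    for rank, (_, is_tp) in enumerate(ranked, start=1):
        tp += int(is_tp)
        precisions.append(tp / rank)
        recalls.append(tp / n_gt)
    total = 0.0
    for i in range(11):
        r = i / 10.0
        attained = [p for p, rc in zip(precisions, recalls) if rc >= r - 1e-12]
        total += max(attained) if attained else 0.0
    return total / 11.0


def write_det_report(reports: dict[str, DetEvalReport], path: str | Path) -> None:
    """Flat CSV, one row per run; ratio columns as percentages (2 decimals)."""
    rows = []
    for name, r in reports.items():
        rows.append(
            {
                "run": name,
                "TP": r.tp,
                "FP": r.fp,
                "FN": r.fn,
                "P": round(100 * r.precision, 2),
                "FPR": round(100 * r.fpr, 2),
                "R": round(100 * r.recall, 2),
                "FNR": round(100 * r.fnr, 2),
                "F1": round(100 * r.f1, 2),
                "avg_iou": round(100 * r.avg_iou, 2),
                "AP": round(100 * r.ap, 2),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
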