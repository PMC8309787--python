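"""Scoring a count record against ground truth.

Counting is evaluated at the object level: each counted track id is matched
to at most one ground-truth object by mean IoU over their co-visible frames
(greedy, descending overlap, admissible above a threshold).  Matched ids are
counting true positives, surplus ids false positives, unclaimed objects false
negatives.  The summary metrics are the CLEAR-MOT-flavoured set

    R_count = TP/(TP+FN)          FN_rate = 1 − R_count
    P_count = TP/(TP+FP)          FP_rate (two conventions, below)
    F1_count = 2·P·R/(P+R)
    MOTA = 1 − (FN + FP + mismatches)/total_gt

with mismatches defaulting to 0 — appropriate for static objects passing a
moving camera, where identity swaps between stationary fruits are not a
counting error mode.

FP_rate conventions: the complement convention (1 − P_count) mirrors the
detection-side FPR; the ``total_gt`` convention (FP/total_gt) is the one
under which MOTA = 1 − FN_rate − FP_rate holds exactly, and is the default.

A missed-object breakdown classifies each counting FN of a line-crossing
counter into why the line never saw it: never detected at all, detected only
beyond the line, first detected within a narrow band around the line, or
detected elsewhere (a tracking rather than detection failure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .counting import CountRecord
from .det_metrics import iou
from .errors import ConsistencyError, ValidationError
from .io import DetectionStream, GroundTruthScene

__all__ = [
    "CountEvalReport",
    "CountMatch",
    "match_counts_to_gt",
    "counting_metrics",
    "counting_metrics_from_rates",
    "fn_breakdown",
    "write_count_report",
    "BREAKDOWN_CATEGORIES",
]

logger = logging.getLogger(__name__)

BREAKDOWN_CATEGORIES = (
    "never_detected",
    "detected_only_after_line",
    "detected_near_line",
    "detected_other",
)


@dataclass(frozen=True)
class CountEvalReport:
    tp: int
    fp: int
    fn: int
    mismatches: int
    total_gt: int
    r_count: float
    fn_rate: float
    p_count: float
    fp_rate: float
    f1_count: float
    mota: float


@dataclass(frozen=True)
class CountMatch:
    """Per-id labels from matching counted ids to ground-truth objects."""

    tp: int
    fp: int
    fn: int
    id_labels: dict[int, str]  # counted id -> "tp" | "fp"
    fn_objects: tuple[int, ...]  # unclaimed ground-truth object ids
    assignment: dict[int, int]  # counted id -> object id, for the TPs


def _mean_covisible_iou(track, traj: dict) -> float:
    frames = set(track.history) & set(traj)
    if not frames:
        return 0.0
    return sum(iou(track.history[f][0], traj[f]) for f in frames) / len(frames)


def match_counts_to_gt(
    record: CountRecord,
    tracks,
    gt: GroundTruthScene,
    min_track_iou: float = 0.3,
) -> CountMatch:
    """Greedily assign counted ids to distinct ground-truth objects.

    Overlap is the mean IoU over co-visible frames; pairs below
    ``min_track_iou`` are inadmissible.  Assigned ids are TP, surplus counted
    ids FP, unclaimed objects FN.
    """
    by_id = {t.id: t for t in tracks}
    missing = [i for i in record.counted_ids if i not in by_id]
    if missing:
        raise ConsistencyError(f"counted ids absent from the track set: {missing}")

    pairs = []
    for cid in record.counted_ids:
        for oid, traj in gt.objects.items():
            ov = _mean_covisible_iou(by_id[cid], traj)
            if ov >= min_track_iou:
                pairs.append((ov, cid, oid))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    assignment: dict[int, int] = {}
    claimed: set[int] = set()
    for ov, cid, oid in pairs:
        if cid in assignment or oid in claimed:
            continue
        assignment[cid] = oid
        claimed.add(oid)

    id_labels = {cid: ("tp" if cid in assignment else "fp") for cid in record.counted_ids}
    fn_objects = tuple(sorted(set(gt.objects) - claimed))
    return CountMatch(
        tp=len(assignment),
        fp=len(record.counted_ids) - len(assignment),
        fn=len(fn_objects),
        id_labels=id_labels,
        fn_objects=fn_objects,
        assignment=assignment,
    )


def counting_metrics(
    tp: int,
    fp: int,
    fn: int,
    mismatches: int = 0,
    total_gt: int | None = None,
    fp_rate_convention: str = "total_gt",
) -> CountEvalReport:
    """Populate the counting metric suite from integer counts."""
    if min(tp, fp, fn, mismatches) < 0:
        raise ValidationError("counts must be non-negative")
    if total_gt is None:
        total_gt = tp + fn
    if total_gt == 0:
        raise ValidationError("total_gt must be positive")
    if tp + fn != total_gt:
        raise ValidationError(f"TP + FN = {tp + fn} must equal total_gt = {total_gt}")
    if fp_rate_convention not in ("total_gt", "complement"):
        raise ValidationError(f"unknown fp_rate_convention {fp_rate_convention!r}")

    r = tp / (tp + fn)
    if tp + fp > 0:
        p = tp / (tp + fp)
    else:
        logger.warning("P_count undefined with TP + FP = 0; reporting 0")
        p = 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    fp_rate = fp / total_gt if fp_rate_convention == "total_gt" else 1.0 - p
    mota = 1.0 - (fn + fp + mismatches) / total_gt
    return CountEvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        mismatches=mismatches,
        total_gt=total_gt,
        r_count=r,
        fn_rate=1.0 - r,
        p_count=p,
        fp_rate=fp_rate,
        f1_count=f1,
        mota=mota,
    )


def counting_metrics_from_rates(
    p_count: float,
    r_count: float,
    fp_rate: float,
    mismatches: int = 0,
) -> CountEvalReport:
    """Derive the identity metrics from printed percentage rates.

    Inputs are percentages (e.g. P = 87.04).  F1 follows from P and R alone;
    MOTA follows from the FN and FP rates under the total-count denominator:
    MOTA = 1 − FN_rate − FP_rate − mismatches/total (mismatches given as a
    rate of 0 here).  Integer counts are not recoverable from rounded rates
    and are reported as -1.
    """
    for name, v in (("p_count", p_count), ("r_count", r_count), ("fp_rate", fp_rate)):
        if not (0.0 <= v <= 100.0):
            raise ValidationError(f"{name} must be a percentage in [0, 100], got {v}")
    p = p_count / 100.0
    r = r_count / 100.0
    fpr = fp_rate / 100.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    fn_rate = 1.0 - r
    mota = 1.0 - fn_rate - fpr - (mismatches if mismatches else 0)
    return CountEvalReport(
        tp=-1,
        fp=-1,
        fn=-1,
        mismatches=mismatches,
        total_gt=-1,
        r_count=r,
        fn_rate=fn_rate,
        p_count=p,
        fp_rate=fpr,
        f1_count=f1,
        mota=mota,
    )


def fn_breakdown(
    fn_objects,
    tracks,
    detections: DetectionStream,
    line_y: float,
    frame_height: float,
    band_fraction: float = 0.05,
    iou_threshold: float = 0.5,
) -> dict[str, int]:
    """Classify each missed object of a line-crossing counter.

    A detection is associated with an object when it overlaps the object's
    ground-truth box at IoU ≥ ``iou_threshold`` on that frame.  Categories
    (mutually exclusive, exhaustive, in precedence order):

    * ``never_detected`` — no associated detection on any frame;
    * ``detected_only_after_line`` — every associated detection sits beyond
      the line (downstream of the flow);
    * ``detected_near_line`` — the first associated detection falls within
      ±``band_fraction`` of the frame height around the line;
    * ``detected_other`` — detected upstream early enough, so the miss is a
      tracking failure rather than a detection failure.
    """
    counts = {c: 0 for c in BREAKDOWN_CATEGORIES}
    band = band_fraction * frame_height
    for oid, traj in fn_objects.items():
        assoc: list[tuple[int, float]] = []  # (frame, centroid y)
        for frame, gbox in traj.items():
            for det in detections.get(frame, []):
                if iou(det.box, gbox) >= iou_threshold:
                    assoc.append((frame, det.box.centroid()[1]))
        if not assoc:
            counts["never_detected"] += 1
            continue
        assoc.sort()
        first_cy = assoc[0][1]
        if all(cy > line_y for _, cy in assoc):
            counts["detected_only_after_line"] += 1
        elif abs(first_cy - line_y) <= band:
            counts["detected_near_line"] += 1
        else:
            counts["detected_other"] += 1
    return counts


def write_count_report(reports: dict[str, CountEvalReport], path: str | Path) -> None:
    """CSV with one metric per row and one column per counting method (percentages)."""
    rows = ["MOTA", "FN rate", "FP rate", "Precision_count", "Recall_count", "F1_count"]
    attrs = ["mota", "fn_rate", "fp_rate", "p_count", "r_count", "f1_count"]
    data = {"metric": rows}
    for method, rep in reports.items():
        data[method] = [round(100 * getattr(rep, a), 2) for a in attrs]
    pd.DataFrame(data).to_csv(path, index=False)
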