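"""Training-methodology utilities.

These helpers support the detector-training side of a counting study without
running any network training themselves:

* a multi-step learning-rate schedule with linear warmup,
* a four-way 70:10:10:10 stratified dataset split for studies whose training
  images (high-resolution camera) and deployment images (mobile phone) come
  from different distributions,
* anchor-box computation by k-means clustering under the 1 − IoU distance,
* a staged error-gap report that reads the four split APs as a bias /
  overfitting / data-mismatch / validation-overfitting diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "LRSchedule",
    "lr_at",
    "SplitItem",
    "SplitSpec",
    "split_dataset",
    "kmeans_anchors",
    "GapReport",
    "error_gap_report",
]


# ---------------------------------------------------------------------------
# learning-rate schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LRSchedule:
    """Linear warmup to ``lr0`` over ``warmup_iters``, then multi-step decay.

    After warmup the rate is piecewise constant: each iteration index in
    ``steps`` multiplies the rate by ``d`` from the *following* iteration on
    (the recurrence LR_{n+1} = d · LR_n when n is a step).
    """

    lr0: float = 0.001
    warmup_iters: int = 1000
    steps: tuple[int, ...] = (4800, 5400)
    d: float = 0.1
    max_iter: int = 6000

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValidationError(f"lr0 must be positive, got {self.lr0}")
        if not (0.0 < self.d < 1.0):
            raise ValidationError(f"decay rate d must lie in (0, 1), got {self.d}")
        steps = tuple(self.steps)
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValidationError(f"steps must be strictly increasing, got {steps}")
        if steps and steps[0] <= self.warmup_iters:
            raise ValidationError("all steps must come after the warmup")
        object.__setattr__(self, "steps", steps)


def lr_at(schedule: LRSchedule, n: int) -> float:
    """Learning rate at iteration ``n``.

    Linear ramp lr0 · n / warmup_iters for n < warmup_iters (reaching lr0
    exactly at the warmup boundary), then lr0 · d^(number of steps < n).
    """
    if not (0 <= n <= schedule.max_iter):
        raise ValidationError(f"iteration {n} outside [0, {schedule.max_iter}]")
    if n < schedule.warmup_iters:
        return schedule.lr0 * n / schedule.warmup_iters
    n_drops = sum(1 for s in schedule.steps if s < n)
    return schedule.lr0 * schedule.d**n_drops


# ---------------------------------------------------------------------------
# stratified four-way split
# ---------------------------------------------------------------------------

PARTITIONS = ("train", "train_val", "val", "test")


@dataclass(frozen=True)
class SplitItem:
    """One dataset image: its name, capture source, and augmentation group.

    ``group`` ties augmented derivatives to their original image so that they
    never straddle partitions; it defaults to the item's own name.
    """

    name: str
    source: str  # "high_res" or "phone"
    group: str | None = None

    def __post_init__(self) -> None:
        if self.source not in ("high_res", "phone"):
            raise ValidationError(f"unknown source {self.source!r} for item {self.name!r}")
        if self.group is None:
            object.__setattr__(self, "group", self.name)


@dataclass(frozen=True)
class SplitSpec:
    """70:10:10:10 split; high-res items fill train/train-val, phone items val/test."""

    ratios: tuple[float, float, float, float] = (0.70, 0.10, 0.10, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValidationError(f"ratios must sum to 1, got {self.ratios}")


def largest_remainder_sizes(n: int, ratios: Sequence[float]) -> list[int]:
    """Integer partition sizes by the largest-remainder rule (ties by position)."""
    quotas = [n * r for r in ratios]
    sizes = [int(q) for q in quotas]
    leftover = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in order[:leftover]:
        sizes[i] += 1
    return sizes


def split_dataset(items: Sequence[SplitItem], spec: SplitSpec | None = None) -> dict[str, list[SplitItem]]:
    """Partition items into train / train-val / val / test.

    Target sizes come from largest-remainder rounding of the ratios over the
    full set.  Groups (augmentation families) are shuffled by seed within
    each source and placed whole: high-res groups fill train up to its target
    and overflow into train-val; phone groups fill val up to its target and
    overflow into test (so sizes are exact whenever each source covers its
    two partitions).  Too few phone items for the val+test targets is an
    error — phone items are never backfilled from high-res or vice versa.
    """
    spec = spec or SplitSpec()
    sizes = dict(zip(PARTITIONS, largest_remainder_sizes(len(items), spec.ratios)))

    groups: dict[str, list[SplitItem]] = {}
    for item in items:
        groups.setdefault(item.group, []).append(item)
    for key, members in groups.items():
        if len({m.source for m in members}) > 1:
            raise ValidationError(f"group {key!r} mixes capture sources")

    by_source = {"high_res": [], "phone": []}
    for key in groups:
        by_source[groups[key][0].source].append(key)
    n_phone = sum(len(groups[k]) for k in by_source["phone"])
    if n_phone < sizes["val"] + sizes["test"]:
        raise ValidationError(
            f"phone-source shortfall: {n_phone} phone items cannot fill "
            f"val+test = {sizes['val'] + sizes['test']}; refusing to backfill from high-res"
        )

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    out: dict[str, list[SplitItem]] = {p: [] for p in PARTITIONS}
    for source, (first, second) in (
        ("high_res", ("train", "train_val")),
        ("phone", ("val", "test")),
    ):
        keys = sorted(by_source[source])
        rng.shuffle(keys)
        for key in keys:
            members = groups[key]
            if len(out[first]) + len(members) <= sizes[first]:
                out[first].extend(members)
            else:
                out[second].extend(members)
    return out


# ---------------------------------------------------------------------------
# anchor boxes
# ---------------------------------------------------------------------------

def _anchor_iou(dims_a: np.ndarray, dims_b: np.ndarray) -> np.ndarray:
    """IoU of (w, h) boxes anchored at a common corner; broadcasts (n,2)×(k,2)."""
    wa, ha = dims_a[:, None, 0], dims_a[:, None, 1]
    wb, hb = dims_b[None, :, 0], dims_b[None, :, 1]
    inter = np.minimum(wa, wb) * np.minimum(ha, hb)
    return inter / (wa * ha + wb * hb - inter)


def kmeans_anchors(
    box_dims: Sequence[tuple[float, float]], k: int, seed: int = 0, max_iter: int = 300
) -> np.ndarray:
    """Cluster (w, h) pairs under the 1 − IoU distance; anchors sorted by area.

    Centers are medoids (the member minimizing its cluster's total distance),
    which guarantees the mean cost never increases across iterations.
    Initialization is seeded k-means++.  Iterates to an assignment fixpoint or
    ``max_iter`` rounds.
    """
    dims = np.asarray(box_dims, dtype=float)
    if dims.ndim != 2 or dims.shape[1] != 2 or np.any(dims <= 0):
        raise ValidationError("box_dims must be positive (w, h) pairs")
    n = len(dims)
    if k <= 0 or k > n:
        raise ValidationError(f"k must lie in [1, {n}], got {k}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    # k-means++ under d = 1 - IoU
    centers = [dims[rng.integers(n)]]
    while len(centers) < k:
        d = 1.0 - _anchor_iou(dims, np.asarray(centers)).max(axis=1)
        total = d.sum()
        if total <= 0:
            centers.append(dims[rng.integers(n)])
            continue
        centers.append(dims[rng.choice(n, p=d / total)])
    centers = np.asarray(centers)

    assign = np.full(n, -1)
    for _ in range(max_iter):
        new_assign = np.argmax(_anchor_iou(dims, centers), axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(k):
            members = dims[assign == c]
            if len(members) == 0:
                far = np.argmin(_anchor_iou(dims, centers).max(axis=1))
                centers[c] = dims[far]
                continue
            pairwise = 1.0 - _anchor_iou(members, members)
            centers[c] = members[np.argmin(pairwise.sum(axis=1))]
    order = np.argsort(centers[:, 0] * centers[:, 1])
    return centers[order]


def anchor_cost(box_dims: Sequence[tuple[float, float]], anchors: np.ndarray) -> float:
    """Mean 1 − IoU of each box against its best anchor."""
    dims = np.asarray(box_dims, dtype=float)
    return float(np.mean(1.0 - _anchor_iou(dims, np.asarray(anchors)).max(axis=1)))


# ---------------------------------------------------------------------------
# staged error-gap report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GapReport:
    """Pairwise AP gaps across the four splits and per-stage verdicts.

    Stages: A — bias against a target AP (skipped without a target);
    B — train vs train-val (overfitting); C — train-val vs val (data
    mismatch between capture sources); D — val vs test (validation
    overfitting).  A stage is ``ok`` when the downstream AP drops by no more
    than the tolerance — higher downstream AP is always favorable.
    """

    ap_train: float | None
    ap_train_val: float
    ap_val: float
    ap_test: float
    tolerance: float
    gaps: dict[str, float | None] = field(default_factory=dict)
    verdicts: dict[str, str] = field(default_factory=dict)


def error_gap_report(
    ap_train: float | None,
    ap_train_val: float,
    ap_val: float,
    ap_test: float,
    tolerance: float = 2.0,
    target_ap: float | None = None,
) -> GapReport:
    """Diagnose the four-way split APs (percentages in [0, 100])."""
    for name, v in (
        ("ap_train", ap_train),
        ("ap_train_val", ap_train_val),
        ("ap_val", ap_val),
        ("ap_test", ap_test),
    ):
        if v is not None and not (0.0 <= v <= 100.0):
            raise ValidationError(f"{name} must be a percentage in [0, 100], got {v}")

    gaps: dict[str, float | None] = {}
    verdicts: dict[str, str] = {}

    if target_ap is not None and ap_train is not None:
        gaps["A"] = target_ap - ap_train
        verdicts["A"] = "ok" if gaps["A"] <= tolerance else "high_bias"
    else:
        gaps["A"] = None
        verdicts["A"] = "ok"

    for stage, upstream, downstream, bad in (
        ("B", ap_train, ap_train_val, "overfit"),
        ("C", ap_train_val, ap_val, "data_mismatch"),
        ("D", ap_val, ap_test, "val_overfit"),
    ):
        if upstream is None:
            gaps[stage] = None
            verdicts[stage] = "ok"
            continue
        gap = upstream - downstream
        gaps[stage] = gap
        verdicts[stage] = "ok" if gap <= tolerance else bad

    return GapReport(
        ap_train=ap_train,
        ap_train_val=ap_train_val,
        ap_val=ap_val,
        ap_test=ap_test,
        tolerance=tolerance,
        gaps=gaps,
        verdicts=verdicts,
    )
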