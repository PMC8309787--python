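"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library code paths they check: assignment
by exhaustive enumeration over injections, detection matching by
maximum-cardinality search, visibility by direct interval arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
import pytest

from pearcount.io import BBox, Detection, GroundTruthScene


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_assignment(cost: np.ndarray, sentinel: float) -> tuple[int, float]:
    """(max feasible cardinality, min total cost at that cardinality) by enumeration."""
    m, n = cost.shape
    for k in range(min(m, n), -1, -1):
        best = None
        for rsub in combinations(range(m), k):
            for csub in permutations(range(n), k):
                if all(cost[r, c] < sentinel for r, c in zip(rsub, csub)):
                    tot = float(sum(cost[r, c] for r, c in zip(rsub, csub)))
                    if best is None or tot < best:
                        best = tot
        if best is not None:
            return k, best
    return 0, 0.0


def brute_force_max_matching(feasible: np.ndarray) -> int:
    """Maximum-cardinality matching size in a small bipartite feasibility matrix."""
    m, n = feasible.shape
    for k in range(min(m, n), 0, -1):
        for rsub in combinations(range(m), k):
            for csub in permutations(range(n), k):
                if all(feasible[r, c] for r, c in zip(rsub, csub)):
                    return k
    return 0


def rasterized_iou(a: BBox, b: BBox, grid: int = 60) -> float:
    """IoU by counting covered integer grid cells (integer-coordinate boxes only)."""
    canvas_a = np.zeros((grid, grid), dtype=bool)
    canvas_b = np.zeros((grid, grid), dtype=bool)
    canvas_a[int(a.y) : int(a.bottom), int(a.x) : int(a.right)] = True
    canvas_b[int(b.y) : int(b.bottom), int(b.x) : int(b.right)] = True
    inter = np.sum(canvas_a & canvas_b)
    union = np.sum(canvas_a | canvas_b)
    return inter / union if union else 0.0


def random_detection_instance(rng: np.random.Generator):
    """A detector-like single-frame instance: jittered GT copies plus spurious boxes."""
    n_gt = int(rng.integers(1, 4))
    gt_boxes = {}
    for oid in range(1, n_gt + 1):
        w, h = rng.uniform(10, 30, size=2)
        x = rng.uniform(0, 100 - w)
        y = rng.uniform(0, 100 - h)
        gt_boxes[oid] = BBox(x, y, w, h)
    dets = []
    for box in gt_boxes.values():
        if rng.random() < 0.8:
            dx, dy = rng.normal(0, 2.0, size=2)
            s = float(np.exp(rng.normal(0, 0.05)))
            dets.append(
                Detection(
                    0,
                    BBox(
                        min(max(box.x + dx, 0.0), 95.0),
                        min(max(box.y + dy, 0.0), 95.0),
                        box.w * s,
                        box.h * s,
                    ),
                    confidence=float(rng.uniform(0.5, 1.0)),
                )
            )
    for _ in range(rng.poisson(0.7)):
        w, h = rng.uniform(8, 25, size=2)
        dets.append(
            Detection(
                0,
                BBox(rng.uniform(0, 100 - w), rng.uniform(0, 100 - h), w, h),
                confidence=float(rng.uniform(0.1, 0.9)),
            )
        )
    dets = dets[:5]
    scene = GroundTruthScene(frame_size=(130.0, 130.0), objects={o: {0: b} for o, b in gt_boxes.items()}, n_frames=1)
    return scene, {0: dets} if dets else {}


# ---------------------------------------------------------------------------
# lightweight track stand-in for the counting modules
# ---------------------------------------------------------------------------

@dataclass
class FakeTrack:
    """Minimal track-shaped object for counting/eval tests."""

    id: int
    history: dict[int, tuple[BBox, bool]] = field(default_factory=dict)
    was_confirmed: bool = True


def path_track(tid: int, ys, x: float = 10.0, size: float = 10.0, detected=None) -> FakeTrack:
    """A track whose centroid visits the given y coordinates on frames 0,1,2,..."""
    hist = {}
    for f, y in enumerate(ys):
        had = True if detected is None else bool(detected[f])
        hist[f] = (BBox(x - size / 2, y - size / 2, size, size), had)
    return FakeTrack(id=tid, history=hist)


@pytest.fixture
def small_scene_cfg():
    from pearcount.simulator import SceneConfig

    return SceneConfig(
        n_fruits=8,
        frame_size=(240.0, 320.0),
        camera_speed=10.0,
        fruit_size_range=(24.0, 40.0),
        strip_length=600.0,
        seed=3,
    )
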