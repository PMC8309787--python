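"""Reading and writing detection streams and ground-truth trajectories.

Two plain-text dialects are supported:

* the MOT-challenge comma-separated layout
  (``frame,id,bb_left,bb_top,bb_width,bb_height,conf,...`` for detections,
  ``frame,id,bb_left,bb_top,bb_width,bb_height,flag,...`` for ground truth);
* per-frame YOLO/Darknet annotation files with normalized
  ``class cx cy w h [conf]`` lines plus a caller-supplied frame size.

One internal coordinate convention is used everywhere: pixels, origin at the
top-left corner, x rightward, y downward, boxes stored as
(left, top, width, height).  MOT frame indices are 1-based on disk and
0-based in memory.  YOLO class ids are ignored — the toolkit tracks a single
object class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ParseError, ValidationError

__all__ = [
    "BBox",
    "Detection",
    "DetectionStream",
    "GroundTruthScene",
    "read_detections",
    "write_detections",
    "read_ground_truth",
    "write_ground_truth",
    "read_embeddings",
    "write_embeddings",
    "attach_embeddings",
    "read_tracks",
]


def _fmt(v: float) -> str:
    """Canonical number formatting: integers without a decimal point."""
    if float(v) == int(v):
        return str(int(v))
    return format(float(v), ".6g")


@dataclass(frozen=True)
class BBox:
    """Axis-aligned pixel box: left edge, top edge, width, height."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValidationError(f"box dimensions must be positive, got w={self.w}, h={self.h}")

    @property
    def right(self) -> float:
        return self.x + self.w

    @property
    def bottom(self) -> float:
        return self.y + self.h

    def centroid(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def area(self) -> float:
        return self.w * self.h

    def clipped(self, frame_w: float, frame_h: float) -> "BBox | None":
        """Intersect with the viewport [0, frame_w] × [0, frame_h].

        Returns None when the box has no positive overlap with the frame.
        """
        x0 = max(self.x, 0.0)
        y0 = max(self.y, 0.0)
        x1 = min(self.right, frame_w)
        y1 = min(self.bottom, frame_h)
        if x1 - x0 <= 0 or y1 - y0 <= 0:
            return None
        return BBox(x0, y0, x1 - x0, y1 - y0)

    def to_cxcyah(self) -> np.ndarray:
        """(center x, center y, aspect = w/h, height) measurement vector."""
        cx, cy = self.centroid()
        return np.array([cx, cy, self.w / self.h, self.h], dtype=float)

    @staticmethod
    def from_cxcyah(vec: Sequence[float]) -> "BBox":
        cx, cy, a, h = float(vec[0]), float(vec[1]), float(vec[2]), float(vec[3])
        w = a * h
        return BBox(cx - w / 2.0, cy - h / 2.0, w, h)


@dataclass(frozen=True)
class Detection:
    """One detector output: frame index, box, confidence, optional embedding."""

    frame: int
    box: BBox
    confidence: float
    embedding: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValidationError(f"frame index must be non-negative, got {self.frame}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(f"confidence must lie in [0, 1], got {self.confidence}")
        if self.embedding is not None:
            emb = np.asarray(self.embedding, dtype=float)
            norm = float(np.linalg.norm(emb))
            if abs(norm - 1.0) > 1e-6:
                raise ValidationError(f"embedding must be unit-norm, got ||e|| = {norm}")
            object.__setattr__(self, "embedding", emb)


#: Detections grouped by 0-based frame index; each frame's list is ordered by
#: descending confidence, ties broken by (left, top).
DetectionStream = dict[int, list[Detection]]


def _sort_frame(dets: list[Detection]) -> list[Detection]:
    return sorted(dets, key=lambda d: (-d.confidence, d.box.x, d.box.y))


def group_by_frame(dets: Iterable[Detection]) -> DetectionStream:
    stream: DetectionStream = {}
    for det in dets:
        stream.setdefault(det.frame, []).append(det)
    return {f: _sort_frame(stream[f]) for f in sorted(stream)}


@dataclass
class GroundTruthScene:
    """Per-object per-frame ground-truth boxes over their visible frames."""

    frame_size: tuple[float, float]
    objects: dict[int, dict[int, BBox]] = field(default_factory=dict)
    n_frames: int = 0

    def __post_init__(self) -> None:
        w, h = self.frame_size
        for oid, traj in self.objects.items():
            if not traj:
                raise ValidationError(f"object {oid} has an empty visible frame set")
            for f, box in traj.items():
                if box.x < -1e-9 or box.y < -1e-9 or box.right > w + 1e-9 or box.bottom > h + 1e-9:
                    raise ValidationError(
                        f"object {oid} frame {f}: box {box} outside frame {self.frame_size}"
                    )

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def total_boxes(self) -> int:
        return sum(len(t) for t in self.objects.values())

    def boxes_at(self, frame: int) -> dict[int, BBox]:
        return {oid: traj[frame] for oid, traj in self.objects.items() if frame in traj}


# ---------------------------------------------------------------------------
# detection streams
# ---------------------------------------------------------------------------

def _parse_mot_det_line(line: str, lineno: int) -> Detection:
    parts = line.split(",")
    if len(parts) < 7:
        raise ParseError(f"line {lineno}: expected at least 7 comma-separated fields: {line!r}")
    try:
        frame = int(float(parts[0]))
        x, y, w, h = (float(p) for p in parts[2:6])
        conf = float(parts[6])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}: {line!r}") from None
    if frame < 1:
        raise ParseError(f"line {lineno}: MOT frames are 1-based, got {frame}")
    try:
        return Detection(frame=frame - 1, box=BBox(x, y, w, h), confidence=conf)
    except ValidationError as exc:
        raise ValidationError(f"line {lineno}: {exc}") from None


def _parse_yolo_line(line: str, lineno: int, frame: int, fw: float, fh: float) -> Detection:
    parts = line.split()
    if len(parts) not in (5, 6):
        raise ParseError(f"line {lineno}: expected 'class cx cy w h [conf]': {line!r}")
    try:
        cx, cy, w, h = (float(p) for p in parts[1:5])
        conf = float(parts[5]) if len(parts) == 6 else 1.0
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}: {line!r}") from None
    box = BBox((cx - w / 2.0) * fw, (cy - h / 2.0) * fh, w * fw, h * fh)
    try:
        return Detection(frame=frame, box=box, confidence=conf)
    except ValidationError as exc:
        raise ValidationError(f"line {lineno}: {exc}") from None


def read_detections(
    path: str | Path,
    dialect: str = "mot-det",
    frame_size: tuple[float, float] | None = None,
) -> DetectionStream:
    """Read a detection stream, grouped by 0-based frame index.

    ``mot-det`` reads a single comma-separated file (frames re-based from the
    1-based on-disk convention).  ``yolo-dir`` reads a directory of per-frame
    annotation files in lexicographic order; the frame index is taken from the
    digits in the file stem when present, else from the enumeration order, and
    ``frame_size`` is required to denormalize the coordinates.
    """
    path = Path(path)
    dets: list[Detection] = []
    if dialect == "mot-det":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line:
                    continue
                dets.append(_parse_mot_det_line(line, lineno))
    elif dialect == "yolo-dir":
        if frame_size is None:
            raise ConfigurationError("yolo-dir dialect requires frame_size=(width, height)")
        fw, fh = frame_size
        files = sorted(p for p in path.iterdir() if p.suffix == ".txt")
        for idx, fp in enumerate(files):
            stem_digits = "".join(c for c in fp.stem if c.isdigit())
            frame = int(stem_digits) if stem_digits else idx
            with open(fp) as fhandle:
                for lineno, raw in enumerate(fhandle, start=1):
                    line = raw.strip()
                    if not line:
                        continue
                    dets.append(_parse_yolo_line(line, lineno, frame, fw, fh))
    else:
        raise ConfigurationError(f"unknown detection dialect {dialect!r}")
    return group_by_frame(dets)


def write_detections(stream: DetectionStream, path: str | Path) -> None:
    """Write a stream in the MOT det dialect (1-based frames, id = -1)."""
    lines = []
    for frame in sorted(stream):
        for det in _sort_frame(stream[frame]):
            b = det.box
            lines.append(
                f"{frame + 1},-1,{_fmt(b.x)},{_fmt(b.y)},{_fmt(b.w)},{_fmt(b.h)},"
                f"{_fmt(det.confidence)},-1,-1,-1"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def read_ground_truth(
    path: str | Path,
    dialect: str = "mot-gt",
    frame_size: tuple[float, float] | None = None,
) -> GroundTruthScene:
    """Read a MOT gt file into a :class:`GroundTruthScene`.

    Lines with a zero visibility flag are treated as not visible.  When
    ``frame_size`` is omitted it is inferred from the box extents.
    """
    if dialect != "mot-gt":
        raise ConfigurationError(f"unknown ground-truth dialect {dialect!r}")
    objects: dict[int, dict[int, BBox]] = {}
    n_frames = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 7:
                raise ParseError(f"line {lineno}: expected at least 7 fields: {line!r}")
            try:
                frame = int(float(parts[0]))
                oid = int(float(parts[1]))
                x, y, w, h = (float(p) for p in parts[2:6])
                flag = float(parts[6])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}: {line!r}") from None
            if frame < 1:
                raise ParseError(f"line {lineno}: MOT frames are 1-based, got {frame}")
            n_frames = max(n_frames, frame)
            if flag == 0:
                continue
            traj = objects.setdefault(oid, {})
            if frame - 1 in traj:
                raise ValidationError(f"line {lineno}: duplicate (frame={frame}, id={oid}) pair")
            traj[frame - 1] = BBox(x, y, w, h)
    objects = {oid: traj for oid, traj in objects.items() if traj}
    if frame_size is None:
        fw = max((b.right for t in objects.values() for b in t.values()), default=0.0)
        fh = max((b.bottom for t in objects.values() for b in t.values()), default=0.0)
        frame_size = (math.ceil(fw), math.ceil(fh))
    # serialized coordinates are rounded, which can push a border box a hair
    # outside the frame; re-clipping restores the scene invariant
    objects = {
        oid: {f: b.clipped(frame_size[0], frame_size[1]) for f, b in traj.items()}
        for oid, traj in objects.items()
    }
    objects = {
        oid: {f: b for f, b in traj.items() if b is not None} for oid, traj in objects.items()
    }
    objects = {oid: traj for oid, traj in objects.items() if traj}
    return GroundTruthScene(frame_size=frame_size, objects=objects, n_frames=n_frames)


def write_ground_truth(scene: GroundTruthScene, path: str | Path) -> None:
    lines = []
    for frame in range(scene.n_frames):
        for oid in sorted(scene.objects):
            box = scene.objects[oid].get(frame)
            if box is None:
                continue
            lines.append(
                f"{frame + 1},{oid},{_fmt(box.x)},{_fmt(box.y)},{_fmt(box.w)},{_fmt(box.h)},1,-1,-1"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# embeddings sidecar and track files
# ---------------------------------------------------------------------------

def write_embeddings(stream: DetectionStream, path: str | Path) -> None:
    """Write per-detection appearance vectors as CSV: frame, det_index, v0.."""
    lines = []
    for frame in sorted(stream):
        for idx, det in enumerate(stream[frame]):
            if det.embedding is None:
                continue
            vec = ",".join(format(v, ".8g") for v in det.embedding)
            lines.append(f"{frame + 1},{idx},{vec}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_embeddings(path: str | Path) -> dict[tuple[int, int], np.ndarray]:
    """Read an embeddings sidecar into {(frame, det_index): unit vector}."""
    table: dict[tuple[int, int], np.ndarray] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: expected frame, det_index, vector: {line!r}")
            try:
                frame = int(parts[0]) - 1
                idx = int(parts[1])
                vec = np.array([float(p) for p in parts[2:]], dtype=float)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            norm = float(np.linalg.norm(vec))
            if norm > 0:
                vec = vec / norm
            table[(frame, idx)] = vec
    return table


def attach_embeddings(
    stream: DetectionStream, table: Mapping[tuple[int, int], np.ndarray]
) -> DetectionStream:
    """Return a copy of the stream with sidecar embeddings attached by index."""
    out: DetectionStream = {}
    for frame, dets in stream.items():
        row = []
        for idx, det in enumerate(dets):
            emb = table.get((frame, idx))
            if emb is not None:
                det = Detection(det.frame, det.box, det.confidence, emb)
            row.append(det)
        out[frame] = row
    return out


@dataclass
class TrackView:
    """A track as reconstructed from a MOT result file.

    Only confirmed tracks are written to disk, so ``was_confirmed`` is True;
    the confidence column stores the had-detection flag (1 observed,
    0 predicted-only).
    """

    id: int
    history: dict[int, tuple[BBox, bool]]
    was_confirmed: bool = True

    @property
    def first_frame(self) -> int:
        return min(self.history)

    @property
    def last_frame(self) -> int:
        return max(self.history)


def read_tracks(path: str | Path) -> list[TrackView]:
    """Read a MOT result file written by :func:`pearcount.tracker.write_tracks`."""
    views: dict[int, TrackView] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 7:
                raise ParseError(f"line {lineno}: expected at least 7 fields: {line!r}")
            frame = int(float(parts[0])) - 1
            tid = int(float(parts[1]))
            x, y, w, h = (float(p) for p in parts[2:6])
            flag = float(parts[6]) > 0
            views.setdefault(tid, TrackView(id=tid, history={})).history[frame] = (
                BBox(x, y, w, h),
                flag,
            )
    return [views[tid] for tid in sorted(views)]
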