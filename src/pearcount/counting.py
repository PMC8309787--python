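"""Counting strategies over finished tracks.

Three ways to turn a set of tracks into a fruit count:

* **unique_id** — the number of distinct track identifiers (optionally only
  ever-confirmed ones).  Sensitive (nothing detected is missed) but
  vulnerable to spurious or fragmented tracks.
* **roi_line** — a track is counted the first time its centroid crosses a
  horizontal region-of-interest line placed at a configurable fraction of the
  frame height.  Restrictive (spurious short tracks rarely cross) but misses
  objects first picked up beyond the line.
* **unique_id_lifespan** — unique-ID counting restricted to tracks whose
  detection coverage over their observed lifespan reaches a threshold,
  filtering out flicker-born fragments.

Crossing is evaluated on consecutive history frames, including coast
(predicted-only) frames: the tracker's bridging role during detection
dropouts is deliberately kept.  A centroid landing exactly on the line counts
as crossed on the next off-line frame.  Each id is counted at most once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = [
    "CounterConfig",
    "CountRecord",
    "count_unique_ids",
    "count_roi_line",
    "count_lifespan_filtered",
]


@dataclass(frozen=True)
class CounterConfig:
    roi_fraction: float = 0.5
    direction: str = "any"
    lifespan_fraction: float = 0.8
    count_only_confirmed: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.roi_fraction < 1.0):
            raise ValidationError(f"roi_fraction must lie in (0, 1), got {self.roi_fraction}")
        if not (0.0 <= self.lifespan_fraction <= 1.0):
            raise ValidationError(
                f"lifespan_fraction must lie in [0, 1], got {self.lifespan_fraction}"
            )
        if self.direction not in ("any", "downward", "upward"):
            raise ValidationError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class CountRecord:
    """Which ids a strategy counted; for roi_line, at which frame each crossed."""

    method: str
    counted_ids: tuple[int, ...]
    crossing_frame: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return len(self.counted_ids)

    def __post_init__(self) -> None:
        if len(set(self.counted_ids)) != len(self.counted_ids):
            raise ValidationError("counted_ids must be unique")
        if self.method == "roi_line" and set(self.crossing_frame) != set(self.counted_ids):
            raise ValidationError("crossing_frame must be defined exactly for counted_ids")


def _eligible(tracks, cfg: CounterConfig):
    if cfg.count_only_confirmed:
        return [t for t in tracks if getattr(t, "was_confirmed", False)]
    return list(tracks)


def count_unique_ids(tracks, cfg: CounterConfig | None = None) -> CountRecord:
    """Count every qualifying track identifier exactly once."""
    cfg = cfg or CounterConfig()
    ids = tuple(sorted(t.id for t in _eligible(tracks, cfg)))
    return CountRecord(method="unique_id", counted_ids=ids)


def _first_crossing(track, line_y: float, direction: str) -> int | None:
    frames = sorted(track.history)
    prev_sign = 0  # sign of the last off-line centroid
    for f in frames:
        box, _ = track.history[f]
        cy = box.centroid()[1]
        s = cy - line_y
        sign = 0 if s == 0 else (1 if s > 0 else -1)
        if sign == 0:
            continue  # exactly on the line: resolved at the next off-line frame
        if prev_sign != 0 and sign != prev_sign:
            if direction == "any" or (direction == "downward" and sign > 0) or (
                direction == "upward" and sign < 0
            ):
                return f
        prev_sign = sign
    return None


def count_roi_line(tracks, frame_height: float, cfg: CounterConfig | None = None) -> CountRecord:
    """Count tracks whose centroid crosses the line y = roi_fraction × frame height."""
    cfg = cfg or CounterConfig()
    if frame_height <= 0:
        raise ValidationError(f"frame_height must be positive, got {frame_height}")
    line_y = cfg.roi_fraction * frame_height
    counted: list[int] = []
    crossing: dict[int, int] = {}
    for track in _eligible(tracks, cfg):
        f = _first_crossing(track, line_y, cfg.direction)
        if f is not None:
            counted.append(track.id)
            crossing[track.id] = f
    counted.sort()
    return CountRecord(method="roi_line", counted_ids=tuple(counted), crossing_frame=crossing)


def track_coverage(track) -> float:
    """Fraction of frames with a supporting detection over the observed lifespan.

    The lifespan runs from the first frame to the last *detected* frame;
    coast frames the tracker appended while waiting out its deletion timer
    carry no information about the object and are not part of the span.
    """
    detected = [f for f, (_, had) in track.history.items() if had]
    span = max(detected) - min(track.history) + 1
    return len(detected) / span


def count_lifespan_filtered(tracks, cfg: CounterConfig | None = None) -> CountRecord:
    """Unique-ID counting restricted to tracks with coverage ≥ lifespan_fraction."""
    cfg = cfg or CounterConfig()
    ids = tuple(
        sorted(
            t.id
            for t in _eligible(tracks, cfg)
            if track_coverage(t) >= cfg.lifespan_fraction
        )
    )
    return CountRecord(method="unique_id_lifespan", counted_ids=ids)
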