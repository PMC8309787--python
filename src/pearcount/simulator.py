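"""Synthetic orchard-pass generator.

The generator emulates a camera carried along a fruit-tree row filming from
below: the fruits are static in the world and the camera motion renders as a
constant vertical image flow, so every fruit enters at the top edge, drifts
down the frame at ``camera_speed`` pixels per frame, crosses any horizontal
counting line, and exits at the bottom.  Geometry only — no rendering.

A separate corruption model turns the ideal ground-truth detections into a
realistic detector output:

* **flicker** — each true fruit-frame detection is dropped independently with
  probability ``p_miss``;
* **occlusion** — with probability ``occlusion_rate`` a fruit is occluded by
  foliage at the start of its pass and emerges only after a sampled number of
  frames (this is what makes "first seen beyond the counting line" possible);
* **localization jitter** — Gaussian noise on the box center and log-size;
* **false positives** — a Poisson number of spurious boxes per frame at
  uniform positions;
* **confidence noise** — clipped Gaussian confidences, with separate models
  for true and spurious detections;
* **appearance embeddings** — a fixed random unit vector per fruit, observed
  through additive Gaussian noise and renormalization; spurious detections
  get fresh random vectors.

All randomness flows from explicit seeds through independent child generators
per corruption channel, so changing one rate (say ``p_miss``) leaves every
other channel's draws untouched — paired-seed experiments stay paired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .io import (
    BBox,
    Detection,
    DetectionStream,
    GroundTruthScene,
    write_detections,
    write_embeddings,
    write_ground_truth,
)

__all__ = [
    "SceneConfig",
    "CorruptionConfig",
    "generate_scene",
    "corrupt_detections",
    "write_scene",
]


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one orchard pass.

    Defaults emulate a portrait 1080 × 1920 phone video of a tree row:
    50 fruits of 60–140 px spread over a strip long enough for a pass of
    about 960 frames (32 s at 30 FPS) at 20 px/frame image flow.
    """

    n_fruits: int = 50
    frame_size: tuple[float, float] = (1080.0, 1920.0)
    camera_speed: float = 20.0
    fruit_size_range: tuple[float, float] = (60.0, 140.0)
    strip_length: float = 17280.0
    min_visibility: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fruits < 0:
            raise ValidationError(f"n_fruits must be non-negative, got {self.n_fruits}")
        if self.camera_speed <= 0:
            raise ValidationError(f"camera_speed must be positive, got {self.camera_speed}")
        lo, hi = self.fruit_size_range
        if lo <= 0 or hi < lo:
            raise ValidationError(f"invalid fruit_size_range {self.fruit_size_range}")
        if hi >= min(self.frame_size):
            raise ValidationError("fruits must be smaller than the frame")
        if self.strip_length < hi:
            raise ValidationError("strip_length must accommodate at least one fruit")
        if not (0.0 <= self.min_visibility <= 1.0):
            raise ValidationError(f"min_visibility must lie in [0, 1], got {self.min_visibility}")


@dataclass(frozen=True)
class CorruptionConfig:
    """Detector-failure model; rates per fruit-frame or per frame as noted."""

    p_miss: float = 0.1
    occlusion_rate: float = 0.35
    occlusion_duration: tuple[int, int] = (20, 70)
    jitter_sigma: float = 2.0
    fp_rate: float = 0.2
    confidence_true: tuple[float, float] = (0.85, 0.08)
    confidence_false: tuple[float, float] = (0.40, 0.15)
    embedding_dim: int = 16
    embedding_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("p_miss", self.p_miss), ("occlusion_rate", self.occlusion_rate)):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.fp_rate < 0 or self.jitter_sigma < 0 or self.embedding_noise < 0:
            raise ValidationError("rates and noise scales must be non-negative")
        lo, hi = self.occlusion_duration
        if lo < 0 or hi < lo:
            raise ValidationError(f"invalid occlusion_duration {self.occlusion_duration}")
        if self.embedding_dim < 1:
            raise ValidationError("embedding_dim must be positive")


def n_pass_frames(cfg: SceneConfig) -> int:
    """Frames for the camera to sweep the whole strip past the viewport."""
    return math.ceil((cfg.strip_length + cfg.frame_size[1]) / cfg.camera_speed)


def generate_scene(cfg: SceneConfig) -> tuple[GroundTruthScene, DetectionStream]:
    """Place fruits in the strip and project them through the moving viewport.

    Returns the ground-truth scene and the ideal detection stream.  A fruit
    is visible on a frame while its box has positive overlap with the
    viewport; stored boxes are clipped to the frame.  The ideal detector
    reports the clipped box with confidence 1 and no embedding, but only
    once at least ``min_visibility`` of the fruit's area is inside the frame
    — a detector does not fire on a thin sliver at the border.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    fw, fh = cfg.frame_size
    lo, hi = cfg.fruit_size_range
    n_frames = n_pass_frames(cfg) if cfg.n_fruits > 0 else 0

    heights = rng.uniform(lo, hi, size=cfg.n_fruits)
    widths = heights * rng.uniform(0.8, 1.05, size=cfg.n_fruits)  # pears: roughly square
    widths = np.minimum(widths, fw - 1e-6)
    xs = rng.uniform(0.0, fw - widths)
    ys = rng.uniform(0.0, cfg.strip_length - heights)

    objects: dict[int, dict[int, BBox]] = {}
    stream: DetectionStream = {}
    for i in range(cfg.n_fruits):
        oid = i + 1
        traj: dict[int, BBox] = {}
        # image y of the box top: y_world - strip_length + f * speed
        f_lo = (cfg.strip_length - ys[i] - heights[i]) / cfg.camera_speed
        f_hi = (cfg.strip_length - ys[i] + fh) / cfg.camera_speed
        for f in range(max(0, math.floor(f_lo)), min(n_frames, math.ceil(f_hi) + 1)):
            y_img = ys[i] - cfg.strip_length + f * cfg.camera_speed
            box = BBox(xs[i], y_img, widths[i], heights[i]).clipped(fw, fh)
            if box is None:
                continue
            traj[f] = box
            if box.area() >= cfg.min_visibility * widths[i] * heights[i]:
                stream.setdefault(f, []).append(
                    Detection(frame=f, box=box, confidence=1.0)
                )
        if traj:
            objects[oid] = traj
    scene = GroundTruthScene(frame_size=cfg.frame_size, objects=objects, n_frames=n_frames)
    stream = {f: stream[f] for f in sorted(stream)}
    return scene, stream


def _unit_vector(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def corrupt_detections(
    ideal: DetectionStream,
    scene: GroundTruthScene,
    cfg: CorruptionConfig,
    scene_cfg: SceneConfig | None = None,
) -> DetectionStream:
    """Apply the detector-failure model to an ideal stream.

    ``scene_cfg`` supplies the size range for spurious boxes; when omitted it
    is inferred from the ground-truth box sizes.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_flicker, rng_occ, rng_jitter, rng_fp, rng_conf, rng_emb = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    fw, fh = scene.frame_size
    if scene_cfg is not None:
        size_lo, size_hi = scene_cfg.fruit_size_range
    else:
        all_h = [b.h for t in scene.objects.values() for b in t.values()]
        size_lo, size_hi = (min(all_h), max(all_h)) if all_h else (20.0, 40.0)

    oids = sorted(scene.objects)
    embeddings = {oid: _unit_vector(rng_emb, cfg.embedding_dim) for oid in oids}

    # corruption applies to what the ideal detector reported, not to every
    # ground-truth box (sub-visibility border slivers carry no detection)
    reported = {
        (f, round(d.box.x, 6), round(d.box.y, 6), round(d.box.w, 6), round(d.box.h, 6))
        for f, dets in ideal.items()
        for d in dets
    }

    # entry-anchored occlusion episodes, one Bernoulli draw per fruit
    occluded_until: dict[int, int] = {}
    for oid in oids:
        occurs = rng_occ.random() < cfg.occlusion_rate
        dur = int(rng_occ.integers(cfg.occlusion_duration[0], cfg.occlusion_duration[1] + 1))
        if occurs:
            occluded_until[oid] = min(scene.objects[oid]) + dur

    out: DetectionStream = {}

    def emit(frame: int, det: Detection) -> None:
        out.setdefault(frame, []).append(det)

    for oid in oids:
        emb = embeddings[oid]
        for frame in sorted(scene.objects[oid]):
            gbox = scene.objects[oid][frame]
            dropped = rng_flicker.random() < cfg.p_miss  # always consume the draw
            key = (frame, round(gbox.x, 6), round(gbox.y, 6), round(gbox.w, 6), round(gbox.h, 6))
            if key not in reported:
                continue
            if frame < occluded_until.get(oid, -1):
                continue
            if dropped:
                continue
            dx, dy = rng_jitter.normal(0.0, cfg.jitter_sigma, size=2)
            ls = rng_jitter.normal(0.0, cfg.jitter_sigma / max(gbox.h, 1.0), size=2)
            w = max(gbox.w * math.exp(ls[0]), 1.0)
            h = max(gbox.h * math.exp(ls[1]), 1.0)
            cx, cy = gbox.centroid()
            box = BBox(cx + dx - w / 2.0, cy + dy - h / 2.0, w, h).clipped(fw, fh)
            if box is None:
                continue
            conf = float(np.clip(rng_conf.normal(*cfg.confidence_true), 0.0, 1.0))
            noisy = emb + cfg.embedding_noise * rng_emb.standard_normal(cfg.embedding_dim)
            noisy = noisy / np.linalg.norm(noisy)
            emit(frame, Detection(frame=frame, box=box, confidence=conf, embedding=noisy))

    for frame in range(scene.n_frames):
        for _ in range(rng_fp.poisson(cfg.fp_rate)):
            h = rng_fp.uniform(size_lo, size_hi)
            w = h * rng_fp.uniform(0.8, 1.05)
            x = rng_fp.uniform(0.0, max(fw - w, 1e-6))
            y = rng_fp.uniform(0.0, max(fh - h, 1e-6))
            conf = float(np.clip(rng_conf.normal(*cfg.confidence_false), 0.0, 1.0))
            emit(
                frame,
                Detection(
                    frame=frame,
                    box=BBox(x, y, w, h),
                    confidence=conf,
                    embedding=_unit_vector(rng_fp, cfg.embedding_dim),
                ),
            )

    return {
        f: sorted(out[f], key=lambda d: (-d.confidence, d.box.x, d.box.y)) for f in sorted(out)
    }


def write_scene(
    out_dir: str | Path,
    scene: GroundTruthScene,
    stream: DetectionStream,
    scene_cfg: SceneConfig | None = None,
    corruption_cfg: CorruptionConfig | None = None,
) -> dict[str, str]:
    """Emit det.txt / gt.txt / embeddings.csv plus a YAML scene manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "detections": str(out_dir / "det.txt"),
        "ground_truth": str(out_dir / "gt.txt"),
        "embeddings": str(out_dir / "embeddings.csv"),
        "manifest": str(out_dir / "scene.yaml"),
    }
    write_detections(stream, paths["detections"])
    write_ground_truth(scene, paths["ground_truth"])
    write_embeddings(stream, paths["embeddings"])
    manifest = {
        "frame_size": [float(scene.frame_size[0]), float(scene.frame_size[1])],
        "n_frames": scene.n_frames,
        "n_objects": scene.n_objects,
    }
    if scene_cfg is not None:
        manifest["scene"] = {
            "n_fruits": scene_cfg.n_fruits,
            "camera_speed": scene_cfg.camera_speed,
            "fruit_size_range": list(scene_cfg.fruit_size_range),
            "strip_length": scene_cfg.strip_length,
            "seed": scene_cfg.seed,
        }
    if corruption_cfg is not None:
        manifest["corruption"] = {
            "p_miss": corruption_cfg.p_miss,
            "occlusion_rate": corruption_cfg.occlusion_rate,
            "occlusion_duration": list(corruption_cfg.occlusion_duration),
            "jitter_sigma": corruption_cfg.jitter_sigma,
            "fp_rate": corruption_cfg.fp_rate,
            "embedding_dim": corruption_cfg.embedding_dim,
            "embedding_noise": corruption_cfg.embedding_noise,
            "seed": corruption_cfg.seed,
        }
    Path(paths["manifest"]).write_text(yaml.safe_dump(manifest, sort_keys=True))
    return paths
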