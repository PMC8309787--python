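"""Online multi-object tracking by detection.

The tracker follows the SORT family design: a constant-velocity Kalman filter
per track on the (center x, center y, aspect ratio, height) box
parameterization, gated data association solved by the Hungarian algorithm,
and a tentative → confirmed → deleted lifecycle.  Association cost can be
motion overlap (1 − IoU), appearance (cosine distance against a bounded
gallery of past embeddings), or a convex combination of the two; candidate
pairs are gated by the squared Mahalanobis distance of the measurement under
the predicted state (chi-square quantile, 4 degrees of freedom).  Confirmed
tracks are matched first, in ascending time since their last update (the
matching cascade); everything left over is matched by IoU.

The tracker is strictly online: the state after frame t depends only on
frames ≤ t, and identifiers are never reused within a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import scipy.linalg
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2

from .det_metrics import iou
from .errors import ConfigurationError, NumericalError, SequencingError, ValidationError
from .io import BBox, Detection, DetectionStream, _fmt

__all__ = [
    "TrackerConfig",
    "TrackStatus",
    "Track",
    "KalmanFilter",
    "INFEASIBLE",
    "init_track",
    "predict",
    "hungarian_assign",
    "associate",
    "step",
    "run_tracker",
    "write_tracks",
]

#: Sentinel cost marking a forbidden (gated-out) track–detection pair.
INFEASIBLE = 1e5


@dataclass(frozen=True)
class TrackerConfig:
    """Tunable tracker constants.

    ``n_init`` consecutive hits confirm a tentative track; a track missed for
    more than ``max_age`` frames is deleted.  ``gate_quantile`` sets the
    chi-square gate (4 degrees of freedom) on the Mahalanobis distance.
    ``cost_mode`` selects the association cost; ``combined`` degrades to pure
    IoU when detections carry no embeddings.  The filter noise scales with the
    object height through the two std weights.
    """

    n_init: int = 3
    max_age: int = 30
    gate_quantile: float = 0.95
    cost_mode: str = "combined"
    appearance_weight: float = 0.5
    gallery_size: int = 100
    max_iou_cost: float = 0.85
    std_weight_position: float = 1.0 / 20
    std_weight_velocity: float = 1.0 / 160

    def __post_init__(self) -> None:
        if self.n_init < 1 or self.max_age < 1 or self.gallery_size < 1:
            raise ValidationError("n_init, max_age and gallery_size must be positive")
        if not (0.0 < self.gate_quantile < 1.0):
            raise ValidationError(f"gate_quantile must lie in (0, 1), got {self.gate_quantile}")
        if self.cost_mode not in ("iou", "appearance", "combined"):
            raise ConfigurationError(f"unknown cost_mode {self.cost_mode!r}")
        if not (0.0 <= self.appearance_weight <= 1.0):
            raise ValidationError(
                f"appearance_weight must lie in [0, 1], got {self.appearance_weight}"
            )

    @property
    def gate_threshold(self) -> float:
        return float(chi2.ppf(self.gate_quantile, df=4))


class TrackStatus(Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


class KalmanFilter:
    """Constant-velocity filter on the 8-vector (cx, cy, a, h, vcx, vcy, va, vh).

    Process and measurement noise scale with the tracked object's height,
    except for the (dimensionless) aspect ratio which uses small fixed
    standard deviations.
    """

    def __init__(self, std_weight_position: float = 1.0 / 20, std_weight_velocity: float = 1.0 / 160):
        self._wp = std_weight_position
        self._wv = std_weight_velocity
        self._F = np.eye(8)
        for i in range(4):
            self._F[i, 4 + i] = 1.0  # dt = 1 frame
        self._H = np.eye(4, 8)

    def initiate(self, measurement: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mean = np.zeros(8)
        mean[:4] = measurement
        h = measurement[3]
        # the initial aspect is uncertain: the first measurement of an object
        # entering the frame is often border-clipped, so its w/h says little
        # about the true shape; a generous prior lets later updates correct it
        std = np.array(
            [
                2 * self._wp * h,
                2 * self._wp * h,
                5e-1,
                2 * self._wp * h,
                10 * self._wv * h,
                10 * self._wv * h,
                1e-5,
                10 * self._wv * h,
            ]
        )
        return mean, np.diag(std**2)

    def predict(self, mean: np.ndarray, cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = mean[3]
        std = np.array(
            [
                self._wp * h,
                self._wp * h,
                1e-2,
                self._wp * h,
                self._wv * h,
                self._wv * h,
                1e-5,
                self._wv * h,
            ]
        )
        q = np.diag(std**2)
        mean = self._F @ mean
        cov = self._F @ cov @ self._F.T + q
        return self._clamp(mean), cov

    @staticmethod
    def _clamp(mean: np.ndarray) -> np.ndarray:
        # aspect and height must stay positive; extrapolation from heavily
        # clipped boxes at the frame border can otherwise drive them negative
        mean[2] = max(mean[2], 1e-3)
        mean[3] = max(mean[3], 1.0)
        return mean

    def project(self, mean: np.ndarray, cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = mean[3]
        std = np.array([self._wp * h, self._wp * h, 1e-1, self._wp * h])
        r = np.diag(std**2)
        return self._H @ mean, self._H @ cov @ self._H.T + r

    def update(
        self, mean: np.ndarray, cov: np.ndarray, measurement: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        proj_mean, proj_cov = self.project(mean, cov)
        try:
            chol = scipy.linalg.cho_factor(proj_cov, lower=True, check_finite=False)
        except scipy.linalg.LinAlgError as exc:
            raise NumericalError(f"innovation covariance not positive-definite: {exc}") from None
        gain = scipy.linalg.cho_solve(chol, (cov @ self._H.T).T, check_finite=False).T
        innovation = measurement - proj_mean
        new_mean = self._clamp(mean + gain @ innovation)
        new_cov = cov - gain @ proj_cov @ gain.T
        return new_mean, new_cov

    def gating_distance(
        self, mean: np.ndarray, cov: np.ndarray, measurements: np.ndarray
    ) -> np.ndarray:
        """Squared Mahalanobis distance of each (cx, cy, a, h) measurement."""
        proj_mean, proj_cov = self.project(mean, cov)
        try:
            chol = scipy.linalg.cholesky(proj_cov, lower=True, check_finite=False)
        except scipy.linalg.LinAlgError as exc:
            raise NumericalError(f"projected covariance not positive-definite: {exc}") from None
        d = measurements - proj_mean
        z = scipy.linalg.solve_triangular(chol, d.T, lower=True, check_finite=False)
        return np.sum(z * z, axis=0)


@dataclass
class Track:
    """One tracked object and its per-frame box history.

    ``history`` maps frame → (box, had_detection); it is contiguous from
    ``first_frame`` to the last recorded frame, with coast (predicted-only)
    frames flagged False.
    """

    id: int
    mean: np.ndarray
    cov: np.ndarray
    status: TrackStatus
    hits: int
    time_since_update: int
    first_frame: int
    last_frame: int
    history: dict[int, tuple[BBox, bool]]
    gallery: list[np.ndarray] = field(default_factory=list)
    was_confirmed: bool = False

    def predicted_box(self) -> BBox:
        return BBox.from_cxcyah(self.mean[:4])

    @property
    def is_active(self) -> bool:
        return self.status is not TrackStatus.DELETED

    def n_detected(self) -> int:
        return sum(1 for _, had in self.history.values() if had)

    def last_detected_frame(self) -> int:
        return max(f for f, (_, had) in self.history.items() if had)


_KF_CACHE: dict[tuple[float, float], KalmanFilter] = {}


def _kf(cfg: TrackerConfig) -> KalmanFilter:
    key = (cfg.std_weight_position, cfg.std_weight_velocity)
    if key not in _KF_CACHE:
        _KF_CACHE[key] = KalmanFilter(*key)
    return _KF_CACHE[key]


def init_track(det: Detection, frame: int, next_id: int, cfg: TrackerConfig | None = None) -> Track:
    """Start a tentative track from an unmatched detection."""
    cfg = cfg or TrackerConfig()
    mean, cov = _kf(cfg).initiate(det.box.to_cxcyah())
    gallery = [det.embedding] if det.embedding is not None else []
    return Track(
        id=next_id,
        mean=mean,
        cov=cov,
        status=TrackStatus.TENTATIVE,
        hits=1,
        time_since_update=0,
        first_frame=frame,
        last_frame=frame,
        history={frame: (det.box, True)},
        gallery=gallery,
    )


def predict(track: Track, cfg: TrackerConfig | None = None) -> Track:
    """Advance the track one frame under the constant-velocity model."""
    if track.status is TrackStatus.DELETED:
        raise ValidationError(f"track {track.id} is deleted and cannot be predicted")
    cfg = cfg or TrackerConfig()
    track.mean, track.cov = _kf(cfg).predict(track.mean, track.cov)
    try:
        np.linalg.cholesky(track.cov + 1e-12 * np.eye(8))
    except np.linalg.LinAlgError:
        raise NumericalError(f"track {track.id}: covariance lost positive-definiteness") from None
    track.time_since_update += 1
    return track


def hungarian_assign(
    cost: np.ndarray, infeasible_cost: float = INFEASIBLE
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-cost assignment that never uses forbidden pairs.

    Pairs with cost ≥ ``infeasible_cost`` are forbidden.  Among all
    assignments of maximum feasible cardinality the returned one has minimum
    total cost (forbidden pairs are priced high enough to be used only when
    unavoidable, then dropped from the result).
    """
    cost = np.atleast_2d(np.asarray(cost, dtype=float))
    if cost.size == 0:
        m, n = cost.shape if cost.ndim == 2 else (0, 0)
        return [], list(range(m)), list(range(n))
    m, n = cost.shape
    forbidden = cost >= infeasible_cost
    big = max(1.0, float(np.abs(cost[~forbidden]).sum()) if (~forbidden).any() else 1.0) * 1e3
    priced = np.where(forbidden, big, cost)
    rows, cols = linear_sum_assignment(priced)
    matches = [(int(r), int(c)) for r, c in zip(rows, cols) if not forbidden[r, c]]
    matched_rows = {r for r, _ in matches}
    matched_cols = {c for _, c in matches}
    unmatched_rows = [r for r in range(m) if r not in matched_rows]
    unmatched_cols = [c for c in range(n) if c not in matched_cols]
    return sorted(matches), unmatched_rows, unmatched_cols


def _iou_cost(tracks: list[Track], dets: list[Detection]) -> np.ndarray:
    cost = np.ones((len(tracks), len(dets)))
    for i, trk in enumerate(tracks):
        pbox = trk.predicted_box()
        for j, det in enumerate(dets):
            cost[i, j] = 1.0 - iou(pbox, det.box)
    return cost


def _appearance_cost(tracks: list[Track], dets: list[Detection]) -> np.ndarray:
    cost = np.ones((len(tracks), len(dets)))
    for i, trk in enumerate(tracks):
        if not trk.gallery:
            continue
        gal = np.stack(trk.gallery)
        for j, det in enumerate(dets):
            if det.embedding is None:
                continue
            cost[i, j] = 1.0 - float(np.max(gal @ det.embedding))
    return cost


def _gated_cost(
    tracks: list[Track], dets: list[Detection], cfg: TrackerConfig, mode: str
) -> np.ndarray:
    """Association cost with Mahalanobis (and IoU, in iou mode) gating applied."""
    if not tracks or not dets:
        return np.zeros((len(tracks), len(dets)))
    have_emb = all(d.embedding is not None for d in dets) and all(t.gallery for t in tracks)
    if mode == "appearance" and not any(d.embedding is not None for d in dets):
        raise ConfigurationError("appearance cost mode requires detection embeddings")
    if mode == "combined" and not have_emb:
        mode = "iou"  # graceful SORT fallback
    iou_gate_mask = None
    if mode == "iou":
        cost = _iou_cost(tracks, dets)
        iou_gate_mask = cost > cfg.max_iou_cost
    elif mode == "appearance":
        cost = _appearance_cost(tracks, dets)
    else:
        lam = cfg.appearance_weight
        cost = lam * _appearance_cost(tracks, dets) + (1.0 - lam) * _iou_cost(tracks, dets)

    measurements = np.stack([d.box.to_cxcyah() for d in dets])
    gate = cfg.gate_threshold
    kf = _kf(cfg)
    for i, trk in enumerate(tracks):
        gd = kf.gating_distance(trk.mean, trk.cov, measurements)
        cost[i, gd > gate] = INFEASIBLE
    if iou_gate_mask is not None:
        cost[iou_gate_mask] = INFEASIBLE
    return cost


def associate(
    tracks: list[Track], detections: list[Detection], cfg: TrackerConfig | None = None
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Match predicted tracks to one frame's detections.

    Stage 1 (matching cascade): confirmed tracks in ascending
    time_since_update, with the configured cost mode and Mahalanobis gate.
    Stage 2: every remaining track against the remaining detections by IoU,
    gated at ``max_iou_cost``.  Returns index pairs into the input lists plus
    the unmatched indices on both sides.
    """
    cfg = cfg or TrackerConfig()
    matches: list[tuple[int, int]] = []
    unmatched_dets = list(range(len(detections)))

    confirmed = [i for i, t in enumerate(tracks) if t.status is TrackStatus.CONFIRMED]
    unmatched_tracks = set(range(len(tracks)))
    for age in sorted({tracks[i].time_since_update for i in confirmed}):
        level = [i for i in confirmed if tracks[i].time_since_update == age]
        if not level or not unmatched_dets:
            continue
        cost = _gated_cost(
            [tracks[i] for i in level], [detections[j] for j in unmatched_dets], cfg, cfg.cost_mode
        )
        lvl_matches, _, _ = hungarian_assign(cost)
        for r, c in lvl_matches:
            matches.append((level[r], unmatched_dets[c]))
            unmatched_tracks.discard(level[r])
        matched_cols = {c for _, c in lvl_matches}
        unmatched_dets = [j for k, j in enumerate(unmatched_dets) if k not in matched_cols]

    remaining = sorted(i for i in unmatched_tracks)
    if remaining and unmatched_dets:
        sub_tracks = [tracks[i] for i in remaining]
        sub_dets = [detections[j] for j in unmatched_dets]
        cost = _iou_cost(sub_tracks, sub_dets)
        cost[cost > cfg.max_iou_cost] = INFEASIBLE
        iou_matches, _, _ = hungarian_assign(cost)
        for r, c in iou_matches:
            matches.append((remaining[r], unmatched_dets[c]))
            unmatched_tracks.discard(remaining[r])
        matched_cols = {c for _, c in iou_matches}
        unmatched_dets = [j for k, j in enumerate(unmatched_dets) if k not in matched_cols]

    return sorted(matches), sorted(unmatched_tracks), unmatched_dets


def _update_track(track: Track, det: Detection, frame: int, cfg: TrackerConfig) -> None:
    track.mean, track.cov = _kf(cfg).update(track.mean, track.cov, det.box.to_cxcyah())
    track.hits += 1
    track.time_since_update = 0
    track.history[frame] = (BBox.from_cxcyah(track.mean[:4]), True)
    track.last_frame = frame
    if det.embedding is not None:
        track.gallery.append(det.embedding)
        if len(track.gallery) > cfg.gallery_size:
            del track.gallery[: len(track.gallery) - cfg.gallery_size]
    if track.status is TrackStatus.TENTATIVE and track.hits >= cfg.n_init:
        track.status = TrackStatus.CONFIRMED
        track.was_confirmed = True


def step(
    tracks: list[Track],
    detections: list[Detection],
    frame: int,
    cfg: TrackerConfig | None = None,
) -> list[Track]:
    """Advance the tracker by one frame.

    Predicts every active track, associates, Kalman-updates the matched ones,
    spawns tentative tracks from unmatched detections, and applies the
    lifecycle rules (tentative missed once → deleted; missed for more than
    ``max_age`` frames → deleted).  Deleted tracks stay in the list so that
    identifiers are never reused.
    """
    cfg = cfg or TrackerConfig()
    active = [t for t in tracks if t.is_active]
    for t in active:
        if t.last_frame >= frame:
            raise SequencingError(
                f"frame {frame} presented after track {t.id} already saw frame {t.last_frame}"
            )
        predict(t, cfg)

    matches, unmatched_tracks, unmatched_dets = associate(active, detections, cfg)

    for ti, dj in matches:
        _update_track(active[ti], detections[dj], frame, cfg)

    for ti in unmatched_tracks:
        trk = active[ti]
        if trk.status is TrackStatus.TENTATIVE:
            trk.status = TrackStatus.DELETED
        elif trk.time_since_update > cfg.max_age:
            trk.status = TrackStatus.DELETED
        else:
            trk.history[frame] = (trk.predicted_box(), False)
            trk.last_frame = frame

    next_id = max((t.id for t in tracks), default=0) + 1
    for dj in unmatched_dets:
        tracks.append(init_track(detections[dj], frame, next_id, cfg))
        next_id += 1
    return tracks


def run_tracker(stream: DetectionStream, cfg: TrackerConfig | None = None) -> list[Track]:
    """Track a grouped-by-frame detection stream from frame 0 to its last frame.

    Deterministic given the stream and configuration; frames with no
    detections still advance (predict) every live track.
    """
    cfg = cfg or TrackerConfig()
    tracks: list[Track] = []
    if not stream:
        return tracks
    last = max(stream)
    for frame in range(last + 1):
        step(tracks, stream.get(frame, []), frame, cfg)
    return tracks


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    """Write confirmed tracks in the MOT result dialect (1-based frames).

    The confidence column carries the had-detection flag: 1 for observed
    frames, 0 for coast (predicted-only) frames.
    """
    lines = []
    frames = sorted({f for t in tracks if t.was_confirmed for f in t.history})
    by_frame: dict[int, list[tuple[int, BBox, bool]]] = {f: [] for f in frames}
    for t in tracks:
        if not t.was_confirmed:
            continue
        for f, (box, had) in t.history.items():
            by_frame[f].append((t.id, box, had))
    for f in frames:
        for tid, box, had in sorted(by_frame[f]):
            lines.append(
                f"{f + 1},{tid},{_fmt(box.x)},{_fmt(box.y)},{_fmt(box.w)},{_fmt(box.h)},"
                f"{1 if had else 0},-1,-1,-1"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
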