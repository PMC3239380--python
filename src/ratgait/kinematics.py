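"""Animal position, velocity and trial acceptability from video frames.

The arena videos contain a single animal over a static background.  Each
frame is background-subtracted and thresholded; the centroid of the
largest foreground component gives the animal's position, a calibration
(affine pixel -> cm mapping fit to grid correspondences) converts pixels
to geometric coordinates, and velocity follows by central differences
with a short moving-average smoother.

A trial is accepted only if (a) each hind limb shows at least two
complete gait cycles and (b) the smoothed speed stays within 15% of the
trial mean.  Footfall events themselves are digitized by hand upstream;
this module consumes event tables, it does not detect footfalls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .spatiotemporal import HIND_LIMBS, segment_strides, MalformedEventsError

__all__ = [
    "Calibration",
    "TrialKinematics",
    "track_centroid",
    "calibrate",
    "compute_kinematics",
    "accept_trial",
]

#: Maximum allowed relative speed excursion about the trial mean.
VELOCITY_TOLERANCE = 0.15
#: Minimum complete strides per hind limb ("two complete gait cycles").
MIN_STRIDES = 2
SMOOTH_WINDOW = 5
MAX_INTERP_GAP = 2  # consecutive missing centroids interpolated for velocity


@dataclass(frozen=True)
class Calibration:
    """Affine pixel -> cm mapping with its RMS fit residual."""

    matrix: np.ndarray  # 2x2
    offset: np.ndarray  # 2
    residual_cm: float

    def to_cm(self, xy_px: np.ndarray) -> np.ndarray:
        return np.asarray(xy_px, float) @ self.matrix.T + self.offset

    def to_px(self, xy_cm: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.matrix)
        return (np.asarray(xy_cm, float) - self.offset) @ inv.T


@dataclass
class TrialKinematics:
    """Centroid track and derived velocity for one arena pass."""

    times_s: np.ndarray
    centroid_xy_cm: np.ndarray  # (n, 2), NaN where the centroid was missing
    velocity_cm_s: np.ndarray  # smoothed per-frame speed
    mean_velocity_cm_s: float
    direction: np.ndarray  # unit planar vector
    accepted: bool = True
    reasons: list[str] = field(default_factory=list)


def track_centroid(
    frames: np.ndarray,
    background: np.ndarray,
    intensity_threshold: float,
    min_area_px: int = 5,
) -> np.ndarray:
    """Per-frame pixel centroid of the largest foreground component.

    Foreground is ``|frame - background| > intensity_threshold``.  Frames
    whose largest component is smaller than ``min_area_px`` are flagged
    missing (NaN row), never silently interpolated.  Coordinates are
    0-based (x, y) with pixel centers at integers.
    """
    frames = np.asarray(frames, float)
    background = np.asarray(background, float)
    if frames.ndim != 3 or frames.shape[1:] != background.shape:
        raise ValueError("frames and background dimensions do not match")
    out = np.full((frames.shape[0], 2), np.nan)
    any_found = False
    for i, frame in enumerate(frames):
        fg = np.abs(frame - background) > intensity_threshold
        labels, n = ndimage.label(fg)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        best = int(np.argmax(sizes)) + 1
        if sizes[best - 1] < min_area_px:
            continue
        cy, cx = ndimage.center_of_mass(labels == best)
        out[i] = (cx, cy)
        any_found = True
    if not any_found:
        raise ValueError("no frame contains a foreground component (all-empty stack)")
    return out


def calibrate(pixel_xy: np.ndarray, cm_xy: np.ndarray) -> Calibration:
    """Least-squares affine fit of grid correspondences (pixel -> cm).

    Needs at least three non-collinear point pairs; reports the RMS
    residual of the fit in cm.
    """
    px = np.atleast_2d(np.asarray(pixel_xy, float))
    cm = np.atleast_2d(np.asarray(cm_xy, float))
    if px.shape != cm.shape or px.shape[0] < 3:
        raise ValueError("need >=3 matching point pairs")
    design = np.column_stack([px, np.ones(len(px))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("calibration points are collinear")
    coef, *_ = np.linalg.lstsq(design, cm, rcond=None)
    matrix = coef[:2].T
    offset = coef[2]
    resid = cm - design @ coef
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return Calibration(matrix=matrix, offset=offset, residual_cm=rms)


def _interpolate_short_gaps(xy: np.ndarray, max_gap: int) -> tuple[np.ndarray, bool]:
    """Linearly fill runs of <=max_gap missing rows; flag longer runs."""
    xy = xy.copy()
    missing = np.isnan(xy[:, 0])
    if not missing.any():
        return xy, True
    if missing[0] or missing[-1]:
        return xy, False
    idx = np.flatnonzero(missing)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in runs:
        if len(run) > max_gap:
            return xy, False
        a, b = run[0] - 1, run[-1] + 1
        for j, i in enumerate(run, start=1):
            xy[i] = xy[a] + (xy[b] - xy[a]) * j / (b - a)
    return xy, True


def compute_kinematics(
    centroid_xy_cm: np.ndarray, fps: float = 200.0
) -> TrialKinematics:
    """Velocity series from a (possibly gappy) centroid track.

    Central differences on position, then a 5-frame moving average on
    speed.  Up to two consecutive missing frames are linearly interpolated
    for the velocity computation only; longer gaps invalidate the trial.
    """
    xy = np.asarray(centroid_xy_cm, float)
    if xy.ndim != 2 or xy.shape[0] < 3:
        raise ValueError("need >=3 centroid samples")
    times = np.arange(len(xy)) / fps
    filled, ok = _interpolate_short_gaps(xy, MAX_INTERP_GAP)
    if not ok:
        return TrialKinematics(
            times_s=times,
            centroid_xy_cm=xy,
            velocity_cm_s=np.full(len(xy), np.nan),
            mean_velocity_cm_s=float("nan"),
            direction=np.array([np.nan, np.nan]),
            accepted=False,
            reasons=["missing_centroids"],
        )
    vel_xy = np.gradient(filled, 1.0 / fps, axis=0)  # central differences
    speed = np.linalg.norm(vel_xy, axis=1)
    kernel = np.ones(SMOOTH_WINDOW) / SMOOTH_WINDOW
    pad = SMOOTH_WINDOW // 2
    padded = np.pad(speed, pad, mode="edge")
    smooth = np.convolve(padded, kernel, mode="valid")
    net = filled[-1] - filled[0]
    norm = np.linalg.norm(net)
    direction = net / norm if norm > 0 else np.array([1.0, 0.0])
    return TrialKinematics(
        times_s=times,
        centroid_xy_cm=xy,
        velocity_cm_s=smooth,
        mean_velocity_cm_s=float(smooth.mean()),
        direction=direction,
    )


def accept_trial(kin: TrialKinematics, events: pd.DataFrame) -> TrialKinematics:
    """Apply the trial acceptance rules; returns the annotated kinematics.

    Accepted iff each hind limb shows >= 2 complete strides and the
    smoothed speed never deviates more than 15% from the trial mean.
    Reason codes: ``cycles``, ``velocity``, ``missing_centroids``,
    ``malformed_events``.
    """
    if len(events) == 0:
        raise ValueError("empty event table")
    reasons = list(kin.reasons)
    try:
        strides = segment_strides(events)
        if any(len(strides[l]) < MIN_STRIDES for l in HIND_LIMBS):
            reasons.append("cycles")
    except MalformedEventsError:
        reasons.append("malformed_events")
    if np.isfinite(kin.mean_velocity_cm_s) and kin.mean_velocity_cm_s > 0:
        dev = np.max(np.abs(kin.velocity_cm_s - kin.mean_velocity_cm_s))
        if dev / kin.mean_velocity_cm_s >= VELOCITY_TOLERANCE:
            reasons.append("velocity")
    kin.accepted = len(reasons) == 0
    kin.reasons = reasons
    return kin
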