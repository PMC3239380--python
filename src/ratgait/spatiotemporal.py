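"""Stride-level geometric and temporal gait descriptors.

A trial is a single pass of the animal through the arena.  The raw material
is a table of footfall events (foot-strike / toe-off per hind limb, with
time and planar position).  From consecutive ipsilateral foot-strikes and
the enclosed toe-off we form strides and compute:

* duty factor (percentage stance time): 100 x stance time / stride time;
* gait symmetry: phase of the right foot-strike within the left-left
  stride interval (0.5 = perfectly alternating gait);
* stride length: distance between consecutive ipsilateral strike positions
  projected on the direction of travel;
* step width: perpendicular distance between contralateral strikes;
* stance-time imbalance: contralateral minus affected trial-mean duty
  factor, in percentage points (positive = the affected limb is favored).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HIND_LIMBS = ("LH", "RH")
#: Limb ipsilateral to the operated (right L5) side; configurable per call.
DEFAULT_AFFECTED = "RH"

__all__ = [
    "Stride",
    "MalformedEventsError",
    "segment_strides",
    "duty_factor",
    "gait_symmetry",
    "stride_length",
    "step_width",
    "stance_imbalance",
    "travel_direction",
    "trial_metrics",
]


class MalformedEventsError(ValueError):
    """Raised when a limb's event sequence cannot be segmented into strides."""


@dataclass(frozen=True)
class Stride:
    """One stride: strike -> toe-off -> next strike of the same limb."""

    limb: str
    strike_time_s: float
    toe_off_time_s: float
    next_strike_time_s: float
    strike_xy_cm: tuple[float, float]
    next_strike_xy_cm: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.strike_time_s < self.toe_off_time_s < self.next_strike_time_s):
            raise MalformedEventsError(
                f"{self.limb}: require strike < toe-off < next strike, got "
                f"{self.strike_time_s} / {self.toe_off_time_s} / {self.next_strike_time_s}"
            )

    @property
    def stance_time_s(self) -> float:
        return self.toe_off_time_s - self.strike_time_s

    @property
    def stride_time_s(self) -> float:
        return self.next_strike_time_s - self.strike_time_s


def segment_strides(
    events: pd.DataFrame, limbs: Sequence[str] = HIND_LIMBS
) -> dict[str, list[Stride]]:
    """Segment a footfall event table into strides per hind limb.

    Parameters
    ----------
    events
        Columns ``limb`` (LH/RH), ``event`` (strike/off), ``time_s``,
        ``x_cm``, ``y_cm``; one row per digitized event.
    limbs
        Limbs to segment (default both hind limbs).

    Returns
    -------
    dict mapping limb -> list of :class:`Stride` (n_strikes - 1 per limb
    when the sequence is well formed).

    Raises
    ------
    MalformedEventsError
        If a limb's sequence does not alternate strike/off (double strikes,
        double toe-offs) or the table is empty.
    """
    if len(events) == 0:
        raise MalformedEventsError("empty event table")
    limb_col = events["limb"].to_numpy()
    kind_col = events["event"].to_numpy()
    txy = events[["time_s", "x_cm", "y_cm"]].to_numpy(float)
    out: dict[str, list[Stride]] = {}
    for limb in limbs:
        mask = limb_col == limb
        kinds = kind_col[mask]
        sub = txy[mask]
        order = np.argsort(sub[:, 0], kind="stable")
        kinds, sub = kinds[order], sub[order]
        # drop a leading toe-off (animal entered the view mid-stance)
        start = 1 if len(kinds) and kinds[0] == "off" else 0
        kinds = kinds[start:]
        sub = sub[start:]
        expected = np.where(np.arange(len(kinds)) % 2 == 0, "strike", "off")
        if not np.array_equal(kinds, expected):
            bad = int(np.argmax(kinds != expected))
            raise MalformedEventsError(
                f"{limb}: non-alternating event sequence at row {bad} "
                f"(got {kinds[bad]!r}, expected {expected[bad]!r})"
            )
        t = sub[:, 0]
        xy = sub[:, 1:]
        strides: list[Stride] = []
        # strikes at even indices, toe-offs at odd
        for i in range(0, len(t) - 2, 2):
            strides.append(
                Stride(
                    limb=limb,
                    strike_time_s=t[i],
                    toe_off_time_s=t[i + 1],
                    next_strike_time_s=t[i + 2],
                    strike_xy_cm=(xy[i, 0], xy[i, 1]),
                    next_strike_xy_cm=(xy[i + 2, 0], xy[i + 2, 1]),
                )
            )
        out[limb] = strides
    return out


def duty_factor(stride: Stride) -> float:
    """Percentage stance time of one stride: 100 x stance / stride time."""
    if stride.stride_time_s <= 0:
        raise ValueError("zero or negative stride duration")
    return 100.0 * stride.stance_time_s / stride.stride_time_s


def gait_symmetry(
    left_strikes: Sequence[float], right_strikes: Sequence[float]
) -> np.ndarray:
    """Per-interval gait symmetry values.

    For each consecutive pair of left foot-strikes (tL1, tL2) the symmetry
    is (tR - tL1) / (tL2 - tL1) with tR the first right strike in the
    half-open interval (tL1, tL2]; a right strike coincident with tL1
    belongs to the previous interval and yields 0.0 there.  Intervals that
    contain no right strike are skipped with a warning.
    """
    tl = np.sort(np.asarray(left_strikes, float))
    tr = np.sort(np.asarray(right_strikes, float))
    if len(tl) < 2:
        raise ValueError("need at least two left foot-strikes")
    vals = []
    for t1, t2 in zip(tl[:-1], tl[1:]):
        inside = tr[(tr > t1) & (tr <= t2)]
        if len(inside) == 0:
            # boundary case: right strike exactly at t1 counts as phase 0
            if np.any(tr == t1):
                vals.append(0.0)
                continue
            warnings.warn(
                f"no right foot-strike in left-left interval ({t1:g}, {t2:g}]; skipped",
                stacklevel=2,
            )
            continue
        vals.append((inside[0] - t1) / (t2 - t1))
    return np.asarray(vals, float)


def travel_direction(xy: np.ndarray) -> np.ndarray:
    """Unit direction of travel: principal axis of a planar track.

    The sign is chosen along the net displacement so that 'forward' is
    consistent between trials regardless of which way the animal crossed.
    """
    xy = np.asarray(xy, float)
    if xy.ndim != 2 or xy.shape[0] < 2:
        raise ValueError("need >=2 planar points")
    centered = xy - xy.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    net = xy[-1] - xy[0]
    if net @ d < 0:
        d = -d
    return d / np.linalg.norm(d)


def stride_length(stride: Stride, direction: np.ndarray | None = None) -> float:
    """Stride length in cm.

    Distance between consecutive ipsilateral strike positions, projected on
    the direction of travel when one is supplied (suppresses lateral sway);
    Euclidean otherwise.
    """
    delta = np.asarray(stride.next_strike_xy_cm, float) - np.asarray(
        stride.strike_xy_cm, float
    )
    if direction is None:
        return float(np.linalg.norm(delta))
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return float(abs(delta @ d))


def step_width(
    left_xy: Sequence[float], right_xy: Sequence[float], direction: np.ndarray
) -> float:
    """Perpendicular distance between contralateral strike positions (cm)."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    delta = np.asarray(left_xy, float) - np.asarray(right_xy, float)
    perp = delta - (delta @ d) * d
    return float(np.linalg.norm(perp))


def stance_imbalance(
    duty_by_limb: Mapping[str, float | Iterable[float]],
    affected: str = DEFAULT_AFFECTED,
) -> float:
    """Stance-time imbalance in percentage points: contralateral - affected.

    Positive values mean the affected limb spends relatively less time in
    stance, i.e. is favored.  Trial-mean duty factors (or per-stride arrays,
    which are averaged) are expected for both hind limbs.
    """
    contra = "LH" if affected == "RH" else "RH"
    missing = [l for l in (affected, contra) if l not in duty_by_limb]
    if missing:
        raise ValueError(f"missing duty factor for limb(s): {missing}")
    a = float(np.mean(np.asarray(duty_by_limb[affected], float)))
    c = float(np.mean(np.asarray(duty_by_limb[contra], float)))
    return c - a


def trial_metrics(
    events: pd.DataFrame,
    affected: str = DEFAULT_AFFECTED,
    direction: np.ndarray | None = None,
) -> dict[str, float]:
    """All spatiotemporal descriptors for one trial.

    Returns a flat record with per-limb mean duty factors, mean symmetry,
    imbalance (pp), mean stride length (cm), mean step width (cm), stride
    counts, and the trial mean velocity estimated from strike positions.
    Direction of travel defaults to the principal axis of the strike
    positions when no centroid-track direction is given.
    """
    strides = segment_strides(events)
    limb_col = events["limb"].to_numpy()
    kind_col = events["event"].to_numpy()
    cols = events[["time_s", "x_cm", "y_cm"]].to_numpy(float)
    strikes = {}
    for limb in HIND_LIMBS:
        sub = cols[(limb_col == limb) & (kind_col == "strike")]
        strikes[limb] = sub[np.argsort(sub[:, 0], kind="stable")]
    if direction is None:
        # principal axis of the per-limb mean-centered strike positions:
        # immune to the lateral offset between the two limbs' tracks
        lh, rh = strikes["LH"][:, 1:], strikes["RH"][:, 1:]
        centered = np.vstack([lh - lh.mean(axis=0), rh - rh.mean(axis=0)])
        direction = travel_direction(centered)
        net = np.vstack([lh, rh])
        order = np.argsort(np.r_[strikes["LH"][:, 0], strikes["RH"][:, 0]])
        if (net[order][-1] - net[order][0]) @ direction < 0:
            direction = -direction

    duty = {
        limb: np.array([duty_factor(s) for s in strides[limb]])
        for limb in HIND_LIMBS
    }
    sym = gait_symmetry(strikes["LH"][:, 0], strikes["RH"][:, 0])

    lengths = [
        stride_length(s, direction) for limb in HIND_LIMBS for s in strides[limb]
    ]
    # step width: pair each left strike with the nearest-in-time right strike
    widths = []
    for t, x, y in strikes["LH"]:
        j = int(np.argmin(np.abs(strikes["RH"][:, 0] - t)))
        widths.append(step_width((x, y), strikes["RH"][j, 1:], direction))

    # velocity from projected strike displacement over the trial span
    pts = np.vstack([strikes["LH"], strikes["RH"]])
    order = np.argsort(pts[:, 0])
    t_all, proj = pts[order, 0], pts[order, 1:] @ direction
    velocity = (proj[-1] - proj[0]) / (t_all[-1] - t_all[0])

    contra = "LH" if affected == "RH" else "RH"
    return {
        "velocity_cm_s": float(velocity),
        "duty_affected_pct": float(duty[affected].mean()),
        "duty_contra_pct": float(duty[contra].mean()),
        "symmetry": float(sym.mean()),
        "imbalance_pp": stance_imbalance(duty, affected=affected),
        "stride_length_cm": float(np.mean(lengths)),
        "step_width_cm": float(np.mean(widths)),
        "n_strides_affected": int(len(strides[affected])),
        "n_strides_contra": int(len(strides[contra])),
    }
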