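"""Ground-reaction-force processing.

Force-plate traces (tri-axial, 200 Hz) for single hind-foot contacts are
low-pass filtered, the stance window is located on the vertical channel,
and each contact is generalized into ten descriptors:

===========  ====================================================
Max Fz       peak vertical force (mN)
Iz           vertical impulse, trapezoidal integral over stance (mN s)
Max F-x      peak braking force (mN, <= 0)
Max Fx       peak propulsive force (mN)
I-x          braking impulse (mN s, <= 0)
Ix           propulsive impulse (mN s)
t-x          braking time, % of stance with Fx < 0
Max Fy 1st   peak mediolateral force over the first half of stance
Max Fy 2nd   peak mediolateral force over the second half of stance
Iy           mediolateral impulse (mN s)
===========  ====================================================

Sign conventions: +Fx is propulsive in the direction of travel (-Fx is
braking), +Fy is directed toward the animal's midline for both limbs, and
+Fz is vertical, upward on the plate.  Statistics downstream are run on
body-weight-normalized values; raw mN are kept for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

GRAVITY_MN_PER_G = 9.80665  # weight in mN of a 1 g mass

__all__ = [
    "ForceTrace",
    "ForceMetrics",
    "lowpass_filter",
    "detect_stance",
    "extract_force_metrics",
    "ensemble_average",
    "body_weight_mN",
]


def body_weight_mN(body_weight_g: float) -> float:
    """Body weight force in mN for a mass in grams."""
    return body_weight_g * GRAVITY_MN_PER_G


@dataclass
class ForceTrace:
    """Tri-axial force samples for one foot contact."""

    t_s: np.ndarray
    fx_mN: np.ndarray
    fy_mN: np.ndarray
    fz_mN: np.ndarray
    body_weight_g: float
    fs_hz: float = 200.0
    limb: str = "RH"
    group: str = ""
    animal_id: str = ""
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, float)
        self.fx_mN = np.asarray(self.fx_mN, float)
        self.fy_mN = np.asarray(self.fy_mN, float)
        self.fz_mN = np.asarray(self.fz_mN, float)
        n = len(self.t_s)
        if not (len(self.fx_mN) == len(self.fy_mN) == len(self.fz_mN) == n):
            raise ValueError("force channels and time base differ in length")
        if n >= 2:
            dt = np.diff(self.t_s)
            if not np.allclose(dt, 1.0 / self.fs_hz, rtol=1e-6, atol=1e-9):
                raise ValueError("non-uniform sampling or fs mismatch")


@dataclass(frozen=True)
class ForceMetrics:
    """The ten generalized descriptors for one contact (raw mN units)."""

    max_fz_mN: float
    iz_mN_s: float
    max_f_neg_x_mN: float  # <= 0
    max_fx_mN: float
    i_neg_x_mN_s: float  # <= 0
    ix_mN_s: float
    t_neg_x_pct: float
    max_fy_first_mN: float
    max_fy_second_mN: float
    iy_mN_s: float
    stance_s: float = float("nan")

    def normalized(self, body_weight_g: float) -> "ForceMetrics":
        """Same metrics with forces as fractions of body weight (times are kept)."""
        bw = body_weight_mN(body_weight_g)
        return replace(
            self,
            max_fz_mN=self.max_fz_mN / bw,
            iz_mN_s=self.iz_mN_s / bw,
            max_f_neg_x_mN=self.max_f_neg_x_mN / bw,
            max_fx_mN=self.max_fx_mN / bw,
            i_neg_x_mN_s=self.i_neg_x_mN_s / bw,
            ix_mN_s=self.ix_mN_s / bw,
            max_fy_first_mN=self.max_fy_first_mN / bw,
            max_fy_second_mN=self.max_fy_second_mN / bw,
            iy_mN_s=self.iy_mN_s / bw,
        )


def lowpass_filter(trace: ForceTrace, cutoff_hz: float = 25.0) -> ForceTrace:
    """Zero-phase low-pass filter (4th-order Butterworth, forward-backward).

    DC gain is exactly 1; applied independently to each axis.  Raises if the
    trace is shorter than the filtfilt warm-up length or if the cutoff is
    not below the Nyquist frequency.
    """
    if trace.fs_hz <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    b, a = signal.butter(4, cutoff_hz / (trace.fs_hz / 2.0))
    padlen = 3 * (max(len(b), len(a)) - 1)
    if len(trace.t_s) <= padlen:
        raise ValueError(
            f"trace of {len(trace.t_s)} samples shorter than filter warm-up ({padlen})"
        )
    out = replace(trace)
    out.fx_mN = signal.filtfilt(b, a, trace.fx_mN)
    out.fy_mN = signal.filtfilt(b, a, trace.fy_mN)
    out.fz_mN = signal.filtfilt(b, a, trace.fz_mN)
    return out


def detect_stance(
    fz_mN: np.ndarray,
    body_weight_g: float,
    threshold_fraction: float = 0.02,
    hysteresis_samples: int = 5,
) -> tuple[int, int]:
    """Locate the stance window [on, off) on the vertical channel.

    The window is the longest contiguous run of samples with
    ``fz > threshold_fraction x body weight``; sub-threshold gaps shorter
    than ``hysteresis_samples`` inside a contact are bridged so that noise
    chatter at the threshold does not split the stance.
    """
    fz = np.asarray(fz_mN, float)
    above = fz > threshold_fraction * body_weight_mN(body_weight_g)
    if not above.any():
        raise ValueError("no sample above the stance threshold")
    # bridge short gaps (hysteresis)
    filled = above.copy()
    starts = np.flatnonzero(np.diff(np.r_[0, above.astype(int)]) == 1)
    ends = np.flatnonzero(np.diff(np.r_[above.astype(int), 0]) == -1) + 1
    for gap_start, gap_end in zip(ends[:-1], starts[1:]):
        if gap_end - gap_start < hysteresis_samples:
            filled[gap_start:gap_end] = True
    starts = np.flatnonzero(np.diff(np.r_[0, filled.astype(int)]) == 1)
    ends = np.flatnonzero(np.diff(np.r_[filled.astype(int), 0]) == -1) + 1
    k = int(np.argmax(ends - starts))
    return int(starts[k]), int(ends[k])


def _signed_time_and_impulse(
    t: np.ndarray, f: np.ndarray
) -> tuple[float, float, float]:
    """(time with f<0, negative-part integral, positive-part integral).

    The negative-time measure interpolates zero crossings linearly between
    samples so that a lobe ending exactly at a sample contributes exactly
    its constructed duration.
    """
    neg_time = 0.0
    for i in range(len(t) - 1):
        f0, f1, dt = f[i], f[i + 1], t[i + 1] - t[i]
        if f0 < 0 and f1 < 0:
            neg_time += dt
        elif f0 < 0 <= f1:
            neg_time += dt * f0 / (f0 - f1)
        elif f1 < 0 <= f0:
            neg_time += dt * f1 / (f1 - f0)
        elif f0 == 0 and f1 == 0:
            pass
        elif f0 == 0 and f1 < 0:
            neg_time += dt
        elif f1 == 0 and f0 < 0:
            neg_time += dt
    i_neg = float(np.trapezoid(np.minimum(f, 0.0), t))
    i_pos = float(np.trapezoid(np.maximum(f, 0.0), t))
    return neg_time, i_neg, i_pos


def extract_force_metrics(
    trace: ForceTrace, stance: tuple[int, int] | None = None
) -> ForceMetrics:
    """Generalize one contact into the ten force descriptors.

    Peaks are extrema within the stance window; impulses are trapezoidal
    time-integrals (the negative-Fx portion for I-x, positive for Ix, full
    stance for Iz and Iy); t-x is the fraction of stance time with Fx < 0;
    the two Fy peaks are taken over the first and second halves of stance.
    """
    if stance is None:
        stance = detect_stance(trace.fz_mN, trace.body_weight_g)
    on, off = stance
    if off - on < 2:
        raise ValueError("empty or single-sample stance window")
    t = trace.t_s[on:off]
    fx, fy, fz = trace.fx_mN[on:off], trace.fy_mN[on:off], trace.fz_mN[on:off]
    stance_s = t[-1] - t[0]

    neg_time, i_neg_x, ix = _signed_time_and_impulse(t, fx)
    half = len(t) // 2
    return ForceMetrics(
        max_fz_mN=float(fz.max()),
        iz_mN_s=float(np.trapezoid(fz, t)),
        max_f_neg_x_mN=float(min(fx.min(), 0.0)),
        max_fx_mN=float(max(fx.max(), 0.0)),
        i_neg_x_mN_s=i_neg_x,
        ix_mN_s=ix,
        t_neg_x_pct=100.0 * neg_time / stance_s,
        max_fy_first_mN=float(fy[:half].max()),
        max_fy_second_mN=float(fy[half:].max()),
        iy_mN_s=float(np.trapezoid(fy, t)),
        stance_s=float(stance_s),
    )


def ensemble_average(
    traces: Sequence[ForceTrace],
    n_bins: int = 100,
    axis: str = "fz",
    ci: float = 0.95,
) -> pd.DataFrame:
    """Ensemble-average normalized force curves across animals.

    Each trace is normalized to body weight (force) and to percent stance
    time, resampled to ``n_bins`` points by linear interpolation.  Trials
    are first averaged within animal, then the mean and a t-based
    ``ci`` confidence interval are taken across animals.  Traces whose
    stance window cannot be detected are excluded with a warning.

    Returns a frame with columns ``pct_stance, mean, ci_low, ci_high, n_animals``.
    """
    import warnings

    if len(traces) < 2:
        raise ValueError("need >=2 traces for an ensemble")
    grid = np.linspace(0.0, 100.0, n_bins)
    per_animal: dict[str, list[np.ndarray]] = {}
    for tr in traces:
        try:
            on, off = detect_stance(tr.fz_mN, tr.body_weight_g)
        except ValueError as exc:
            warnings.warn(f"trace excluded from ensemble: {exc}", stacklevel=2)
            continue
        t = tr.t_s[on:off]
        pct = 100.0 * (t - t[0]) / (t[-1] - t[0])
        f = getattr(tr, f"{axis}_mN")[on:off] / body_weight_mN(tr.body_weight_g)
        per_animal.setdefault(tr.animal_id, []).append(np.interp(grid, pct, f))
    if len(per_animal) < 2:
        raise ValueError("need >=2 animals with valid stance windows")
    curves = np.array([np.mean(v, axis=0) for v in per_animal.values()])
    n = curves.shape[0]
    mean = curves.mean(axis=0)
    sem = curves.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + ci / 2.0, n - 1)
    return pd.DataFrame(
        {
            "pct_stance": grid,
            "mean": mean,
            "ci_low": mean - tcrit * sem,
            "ci_high": mean + tcrit * sem,
            "n_animals": n,
        }
    )
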