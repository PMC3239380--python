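"""Seeded synthetic data emulating the radiculopathy gait study.

Every downstream stage of the pipeline can be exercised against data with
known ground truth: footfall event tables with velocity-dependent stride
length and duty factor plus injected group effects (an affected-limb duty
deficit and a symmetry phase offset, as seen after nucleus-pulposus
placement on the L5 DRG), tri-axial stance force curves with the
loading / braking-propulsion / bimodal-mediolateral phase structure of
walking rats, noisy incapacitance-meter readings, and stochastic up-down
von Frey series from a latent 50% threshold.

Timing model: a trial's velocity v fixes stride length L(v) = a + b*v,
stride time T = L/v, and duty factor d(v) = c + e*v; the affected (right
hind) limb's duty factor is reduced by the injected deficit, and right
foot-strikes are placed at phase 0.5 + symmetry_offset of the left-left
interval.  Force curves are sine-lobe compositions, chosen for their
closed-form integrals (a piecewise half-sine of amplitude A over stance T
has vertical impulse 2AT/pi regardless of where the peak falls).

Reproducibility: one master seed spawns independent per-(kind, animal,
trial) child streams via ``numpy.random.SeedSequence(master, spawn_key=...)``,
so adding trials or animals never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .behavior import STANDARD_FILAMENTS_G, UpDownSeries
from .dynamics import ForceTrace, body_weight_mN

__all__ = [
    "GROUPS",
    "StudyDesign",
    "GaitNoise",
    "GaitEffect",
    "ForceShape",
    "default_effects",
    "generate_gait_events",
    "simulate_trial_events",
    "generate_centroid_frames",
    "generate_force_trace",
    "generate_updown_responses",
    "generate_weight_readings",
    "child_rng",
]

GROUPS = ("preoperative", "sham", "np_alone", "np_stnfrii")

# Stream labels keep the different data kinds statistically independent.
_STREAMS = {"gait": 0, "frames": 1, "force": 2, "updown": 3, "weight": 4}


def child_rng(master_seed: int, kind: str, *key: int) -> np.random.Generator:
    """Deterministic child generator for (kind, *key) under one master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STREAMS[kind], *key))
    return np.random.default_rng(ss)


@dataclass
class StudyDesign:
    """Animals x groups x trials layout with per-group target velocities."""

    n_per_group: int = 6
    groups: Sequence[str] = GROUPS
    trials_per_animal: int = 5
    #: Per-group trial-velocity means (cm/s); study-like walking speeds.
    velocity_mean_cm_s: Mapping[str, float] = field(
        default_factory=lambda: {
            "preoperative": 29.8,
            "sham": 34.9,
            "np_alone": 32.6,
            "np_stnfrii": 39.0,
        }
    )
    velocity_sd_cm_s: float = 3.0
    strides_per_limb: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.trials_per_animal < 1:
            raise ValueError("n_per_group and trials_per_animal must be >= 1")
        if self.strides_per_limb < 2:
            raise ValueError("need >=2 strides per limb for a valid trial")
        for g in self.groups:
            if g not in self.velocity_mean_cm_s:
                raise ValueError(f"no velocity mean configured for group {g!r}")
            if self.velocity_mean_cm_s[g] <= 0:
                raise ValueError("velocity means must be positive")


@dataclass
class GaitNoise:
    """Per-metric Gaussian noise scales applied stride-by-stride."""

    duty_pp: float = 0.0
    symmetry: float = 0.0
    stride_cm: float = 0.0
    step_width_cm: float = 0.0


@dataclass
class GaitEffect:
    """Group-level gait parameters, with optional injected pathology.

    Duty factor and stride length are linear in velocity; the affected
    (right hind) limb's duty factor is reduced by
    ``affected_duty_deficit_pct`` percentage points and its foot-strike
    phase shifted by ``symmetry_offset`` from the balanced value 0.5.
    """

    duty_factor_intercept_pct: float = 81.0
    duty_factor_slope_pct_per_cm_s: float = -0.3
    stride_length_intercept_cm: float = 9.0
    stride_length_slope_cm_per_cm_s: float = 0.15
    step_width_cm: float = 2.5
    affected_duty_deficit_pct: float = 0.0
    symmetry_offset: float = 0.0
    noise_sd: GaitNoise = field(default_factory=GaitNoise)

    def __post_init__(self) -> None:
        if not -0.5 < self.symmetry_offset < 0.5:
            raise ValueError("symmetry_offset must lie in (-0.5, 0.5)")

    def duty_pct(self, velocity: float, affected: bool = False) -> float:
        d = self.duty_factor_intercept_pct + self.duty_factor_slope_pct_per_cm_s * velocity
        return d - self.affected_duty_deficit_pct if affected else d

    def stride_length_cm(self, velocity: float) -> float:
        return (
            self.stride_length_intercept_cm
            + self.stride_length_slope_cm_per_cm_s * velocity
        )

    def validate_over(self, velocities: Sequence[float]) -> None:
        """Reject parameter sets whose duty factor leaves (0, 100) or whose
        stride length is non-positive anywhere over the velocity range."""
        for v in velocities:
            for affected in (False, True):
                d = self.duty_pct(v, affected)
                if not 0.0 < d < 100.0:
                    raise ValueError(
                        f"duty factor {d:.1f}% outside (0, 100) at {v:.1f} cm/s"
                    )
            if self.stride_length_cm(v) <= 0:
                raise ValueError(f"non-positive stride length at {v:.1f} cm/s")


def default_effects(
    deficit_pp: float = 5.0,
    symmetry_offset: float = 0.05,
    noisy: bool = True,
) -> dict[str, GaitEffect]:
    """Study-like per-group effects: pathology in the NP-alone group only."""
    noise = (
        GaitNoise(duty_pp=1.0, symmetry=0.02, stride_cm=0.3, step_width_cm=0.2)
        if noisy
        else GaitNoise()
    )
    eff = {g: GaitEffect(noise_sd=noise) for g in GROUPS}
    eff["np_alone"] = GaitEffect(
        affected_duty_deficit_pct=deficit_pp,
        symmetry_offset=symmetry_offset,
        noise_sd=noise,
    )
    return eff


def simulate_trial_events(
    rng: np.random.Generator,
    velocity_cm_s: float,
    effect: GaitEffect,
    n_strides: int = 4,
    affected: str = "RH",
) -> pd.DataFrame:
    """Footfall events for one arena pass at a given velocity.

    Left hind strikes fall at multiples of the stride time, right hind
    strikes at phase 0.5 + symmetry_offset of each left-left interval;
    toe-offs realize the (noisy) per-stride duty factors.  The animal
    travels along +x; left strikes sit at +step_width/2, right at
    -step_width/2.  With all noise zero the downstream metrics recover the
    injected parameters exactly, by construction.
    """
    if velocity_cm_s <= 0:
        raise ValueError("velocity must be positive")
    effect.validate_over([velocity_cm_s])
    v = velocity_cm_s
    L = effect.stride_length_cm(v)
    T = L / v
    ns = effect.noise_sd
    n_strikes = n_strides + 1

    rows: list[tuple] = []
    # symmetry noise enters as a per-trial phase offset of the whole right
    # strike train: a per-strike jitter would also perturb right stride
    # durations and bias the measured duty factor through the denominator
    phase = 0.5 + effect.symmetry_offset
    if ns.symmetry:
        phase = phase + rng.normal(0.0, ns.symmetry)
    for limb, is_affected, y0, t0 in (
        ("LH", affected == "LH", +effect.step_width_cm / 2.0, 0.0),
        ("RH", affected == "RH", -effect.step_width_cm / 2.0, phase * T),
    ):
        duty = effect.duty_pct(v, is_affected)
        strikes = t0 + np.arange(n_strikes) * T
        duties = duty + rng.normal(0.0, ns.duty_pp, n_strikes) if ns.duty_pp else np.full(n_strikes, duty)
        duties = np.clip(duties, 1.0, 99.0)
        offs = strikes + duties / 100.0 * T
        xs = v * strikes
        if ns.stride_cm:
            xs = xs + rng.normal(0.0, ns.stride_cm, n_strikes)
        ys = np.full(n_strikes, y0)
        if ns.step_width_cm:
            ys = ys + rng.normal(0.0, ns.step_width_cm / np.sqrt(2.0), n_strikes)
        for k in range(n_strikes):
            rows.append((limb, "strike", strikes[k], xs[k], ys[k]))
            if k < n_strikes - 1:  # last stance extends past the view
                rows.append((limb, "off", offs[k], v * offs[k], ys[k]))
    df = pd.DataFrame(rows, columns=["limb", "event", "time_s", "x_cm", "y_cm"])
    return df.sort_values("time_s", kind="stable").reset_index(drop=True)


def generate_gait_events(
    design: StudyDesign, effects: Mapping[str, GaitEffect]
) -> pd.DataFrame:
    """Footfall event table for the whole study design.

    One block of events per animal x trial, tagged with ``animal_id``,
    ``group`` and ``trial_id``.  Effects must be defined for every group
    and are validated over the +-4 sd velocity range before any trial is
    generated.  Deterministic under a fixed ``design.seed``.
    """
    for g in design.groups:
        if g not in effects:
            raise ValueError(f"no GaitEffect configured for group {g!r}")
        vm = design.velocity_mean_cm_s[g]
        lo = max(1.0, vm - 4 * design.velocity_sd_cm_s)
        effects[g].validate_over([lo, vm, vm + 4 * design.velocity_sd_cm_s])

    frames = []
    for gi, group in enumerate(design.groups):
        for a in range(design.n_per_group):
            animal = f"{group}_{a:02d}"
            for t in range(design.trials_per_animal):
                rng = child_rng(design.seed, "gait", gi, a, t)
                v = rng.normal(
                    design.velocity_mean_cm_s[group], design.velocity_sd_cm_s
                )
                v = float(np.clip(v, 5.0, 80.0))
                ev = simulate_trial_events(
                    rng, v, effects[group], n_strides=design.strides_per_limb
                )
                ev.insert(0, "trial_id", t)
                ev.insert(0, "group", group)
                ev.insert(0, "animal_id", animal)
                frames.append(ev)
    return pd.concat(frames, ignore_index=True)


def generate_centroid_frames(
    n_frames: int = 40,
    shape: tuple[int, int] = (120, 160),
    fps: float = 200.0,
    pixel_scale_cm_per_px: float = 0.1,
    start_cm: tuple[float, float] = (2.0, 6.0),
    velocity_cm_s: tuple[float, float] = (30.0, 0.0),
    ellipse_axes_cm: tuple[float, float] = (2.0, 1.0),
    body_intensity: float = 200.0,
    background_level: float = 30.0,
    background_noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Grayscale frame stack with a moving bright ellipse on a textured floor.

    Returns ``(frames, truth_xy_px)`` where ``frames`` has shape
    ``(n_frames, rows, cols)`` (float, 0-255 scale) and ``truth_xy_px`` the
    ground-truth centroid per frame in 0-based (x, y) pixel coordinates
    with pixel centers at integers.  The ellipse leaving the field of view
    is an error.
    """
    if fps <= 0 or pixel_scale_cm_per_px <= 0:
        raise ValueError("fps and pixel scale must be positive")
    if min(ellipse_axes_cm) <= 0:
        raise ValueError("ellipse axes must be positive")
    rows, cols = shape
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS["frames"],)))
    background = np.full(shape, background_level, float)
    if background_noise > 0:
        background = background + rng.normal(0.0, background_noise, shape)
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    a_px = ellipse_axes_cm[0] / pixel_scale_cm_per_px
    b_px = ellipse_axes_cm[1] / pixel_scale_cm_per_px

    frames = np.empty((n_frames, rows, cols), float)
    truth = np.empty((n_frames, 2), float)
    for i in range(n_frames):
        t = i / fps
        cx = (start_cm[0] + velocity_cm_s[0] * t) / pixel_scale_cm_per_px
        cy = (start_cm[1] + velocity_cm_s[1] * t) / pixel_scale_cm_per_px
        if not (a_px <= cx <= cols - 1 - a_px and b_px <= cy <= rows - 1 - b_px):
            raise ValueError(f"ellipse leaves the field of view at frame {i}")
        mask = ((xx - cx) / a_px) ** 2 + ((yy - cy) / b_px) ** 2 <= 1.0
        frame = background.copy()
        frame[mask] = body_intensity
        frames[i] = frame
        truth[i] = (cx, cy)
    return frames, truth


def generate_force_trace(
    shape: "ForceShape",
    stance_s: float,
    body_weight_g: float,
    fs_hz: float = 200.0,
    seed: int = 0,
    lead_s: float = 0.05,
    tail_s: float = 0.05,
    rng: np.random.Generator | None = None,
    **trace_meta,
) -> ForceTrace:
    """One synthetic tri-axial contact with zero-padded lead-in/out.

    Fz is a piecewise half-sine peaking at ``fz_peak_time_pct`` of stance
    with amplitude ``fz_peak_fraction_bw x body weight``; Fx is a negative
    (braking) sine lobe over the first ``braking_fraction`` of stance then
    a positive (propulsive) lobe; Fy is two positive humps centered in
    each stance half.  Additive white Gaussian noise on all channels.
    """
    n_st = int(round(stance_s * fs_hz))
    if n_st < 3:
        raise ValueError("stance shorter than 3 samples")
    shape.validate()
    n_lead = int(round(lead_s * fs_hz))
    n_tail = int(round(tail_s * fs_hz))
    n = n_lead + n_st + n_tail
    t = np.arange(n) / fs_hz
    # phase within stance in [0, 1]; outside stance forces are zero
    u = (t - n_lead / fs_hz) / ((n_st - 1) / fs_hz)
    in_st = (u >= 0) & (u <= 1)
    uu = np.where(in_st, np.clip(u, 0.0, 1.0), 0.0)

    fz = np.zeros(n)
    up = shape.fz_peak_time_pct / 100.0
    amp_z = shape.fz_peak_fraction_bw * body_weight_mN(body_weight_g)
    rise = in_st & (uu <= up)
    fall = in_st & (uu > up)
    fz[rise] = amp_z * np.sin(np.pi / 2.0 * uu[rise] / up)
    fz[fall] = amp_z * np.cos(np.pi / 2.0 * (uu[fall] - up) / (1.0 - up))

    fx = np.zeros(n)
    b = shape.braking_fraction
    brake = in_st & (uu < b)
    prop = in_st & (uu >= b)
    fx[brake] = -shape.fx_braking_amp_mN * np.sin(np.pi * uu[brake] / b)
    fx[prop] = shape.fx_propulsion_amp_mN * np.sin(np.pi * (uu[prop] - b) / (1.0 - b))

    fy = np.zeros(n)
    first = in_st & (uu < 0.5)
    second = in_st & (uu >= 0.5)
    fy[first] = shape.fy_peak1_amp_mN * np.sin(2.0 * np.pi * uu[first])
    fy[second] = -shape.fy_peak2_amp_mN * np.sin(2.0 * np.pi * uu[second])

    if shape.noise_sd_mN > 0:
        if rng is None:
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(_STREAMS["force"],))
            )
        fz = fz + rng.normal(0.0, shape.noise_sd_mN, n)
        fx = fx + rng.normal(0.0, shape.noise_sd_mN, n)
        fy = fy + rng.normal(0.0, shape.noise_sd_mN, n)

    return ForceTrace(
        t_s=t, fx_mN=fx, fy_mN=fy, fz_mN=fz,
        body_weight_g=body_weight_g, fs_hz=fs_hz, **trace_meta,
    )


@dataclass
class ForceShape:
    """Phenomenological stance force-curve parameters for one group/limb."""

    fz_peak_fraction_bw: float = 0.75
    fz_peak_time_pct: float = 30.0
    fx_braking_amp_mN: float = 150.0
    fx_propulsion_amp_mN: float = 250.0
    braking_fraction: float = 0.25
    fy_peak1_amp_mN: float = 280.0
    fy_peak2_amp_mN: float = 180.0
    noise_sd_mN: float = 0.0

    def validate(self) -> None:
        if not 0.0 < self.braking_fraction < 1.0:
            raise ValueError("braking_fraction must lie in (0, 1)")
        if not 0.0 < self.fz_peak_time_pct < 100.0:
            raise ValueError("fz_peak_time_pct must lie in (0, 100)")
        for name in (
            "fz_peak_fraction_bw", "fx_braking_amp_mN", "fx_propulsion_amp_mN",
            "fy_peak1_amp_mN", "fy_peak2_amp_mN", "noise_sd_mN",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def generate_updown_responses(
    true_threshold_gF: float,
    filament_set: Sequence[float] = STANDARD_FILAMENTS_G,
    seed: int = 0,
    steepness: float = 6.0,
    start_gF: float = 2.0,
    rng: np.random.Generator | None = None,
) -> UpDownSeries:
    """Simulate one up-down von Frey series from a latent 50% threshold.

    P(withdrawal) is logistic in log10(force) centered at the latent
    threshold with the given steepness (per log10 unit).  The staircase
    starts at the filament nearest ``start_gF``, steps down after a
    withdrawal and up otherwise, and terminates once six responses have
    accumulated counting from the response before the first reversal, or
    when it steps outside the filament set (boundary assignment).
    """
    fil = np.asarray(filament_set, float)
    if fil.size == 0:
        raise ValueError("empty filament set")
    if np.any(np.diff(fil) <= 0):
        raise ValueError("filament set must be strictly ascending")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(_STREAMS["updown"],))
        )
    log_thr = np.log10(true_threshold_gF)
    idx = int(np.argmin(np.abs(np.log10(fil) - np.log10(start_gF))))
    presentations: list[tuple[float, bool]] = []
    responses: list[bool] = []
    boundary: str | None = None
    while True:
        f = float(fil[idx])
        p = float(expit(steepness * (np.log10(f) - log_thr)))
        withdrawal = bool(rng.random() < p)
        presentations.append((f, withdrawal))
        responses.append(withdrawal)
        rev = next(
            (i for i in range(1, len(responses)) if responses[i] != responses[i - 1]),
            None,
        )
        if rev is not None and len(responses) - (rev - 1) >= 6:
            break
        idx = idx - 1 if withdrawal else idx + 1
        if idx < 0:
            boundary = "low"
            break
        if idx >= len(fil):
            boundary = "high"
            break
    return UpDownSeries(
        presentations=presentations,
        filament_set=tuple(fil),
        cutoff_gF=float(fil[-1]),
        boundary=boundary,
    )


def generate_weight_readings(
    true_right_fraction: float,
    noise_sd: float = 0.02,
    n_trials: int = 5,
    total_weight_g: float = 300.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """(n_trials, 2) incapacitance readings (left_g, right_g).

    The per-trial right fraction is ``true_right_fraction`` plus Gaussian
    noise, so the expected computed weight distribution equals the injected
    fraction.
    """
    if not 0.0 < true_right_fraction < 1.0:
        raise ValueError("true_right_fraction must lie in (0, 1)")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(_STREAMS["weight"],))
        )
    frac = true_right_fraction + (
        rng.normal(0.0, noise_sd, n_trials) if noise_sd > 0 else 0.0
    )
    frac = np.clip(frac, 1e-6, 1.0 - 1e-6)
    right = total_weight_g * frac
    left = total_weight_g - right
    return np.column_stack([left, right])
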