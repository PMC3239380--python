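"""Schema-validated run configuration.

A single JSON document drives a full reproducible run: the synthetic
study design, per-group injected gait effects, force-curve shapes,
behavioral ground truths, and every analysis parameter.  Unknown keys are
rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .simulate import GROUPS, GaitEffect, GaitNoise, ForceShape, StudyDesign

_DEFAULT_VELOCITIES = {
    "preoperative": 29.8,
    "sham": 34.9,
    "np_alone": 32.6,
    "np_stnfrii": 39.0,
}
# Group body masses (g) echoing the study's reported means.
_DEFAULT_MASSES = {
    "preoperative": 285.0,
    "sham": 348.0,
    "np_alone": 325.0,
    "np_stnfrii": 340.0,
}
_DEFAULT_THRESHOLDS = {
    "preoperative": {"affected": 15.0, "contra": 15.0},
    "sham": {"affected": 8.0, "contra": 10.0},
    "np_alone": {"affected": 3.8, "contra": 9.0},
    "np_stnfrii": {"affected": 7.8, "contra": 10.0},
}
_DEFAULT_WEIGHT_FRACTIONS = {
    "preoperative": 0.50,
    "sham": 0.50,
    "np_alone": 0.45,
    "np_stnfrii": 0.49,
}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignConfig(_Strict):
    n_per_group: int = 6
    groups: list[str] = Field(default_factory=lambda: list(GROUPS))
    trials_per_animal: int = 5
    velocity_mean_cm_s: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_VELOCITIES)
    )
    velocity_sd_cm_s: float = 3.0
    strides_per_limb: int = 4

    def to_design(self, seed: int) -> StudyDesign:
        return StudyDesign(
            n_per_group=self.n_per_group,
            groups=tuple(self.groups),
            trials_per_animal=self.trials_per_animal,
            velocity_mean_cm_s=self.velocity_mean_cm_s,
            velocity_sd_cm_s=self.velocity_sd_cm_s,
            strides_per_limb=self.strides_per_limb,
            seed=seed,
        )


class NoiseConfig(_Strict):
    duty_pp: float = 1.0
    symmetry: float = 0.02
    stride_cm: float = 0.3
    step_width_cm: float = 0.2


class EffectConfig(_Strict):
    duty_factor_intercept_pct: float = 81.0
    duty_factor_slope_pct_per_cm_s: float = -0.3
    stride_length_intercept_cm: float = 9.0
    stride_length_slope_cm_per_cm_s: float = 0.15
    step_width_cm: float = 2.5
    affected_duty_deficit_pct: float = 0.0
    symmetry_offset: float = 0.0
    noise_sd: NoiseConfig = Field(default_factory=NoiseConfig)

    def to_effect(self) -> GaitEffect:
        d = self.model_dump()
        noise = GaitNoise(**d.pop("noise_sd"))
        return GaitEffect(noise_sd=noise, **d)


class ForceConfig(_Strict):
    trials_per_limb: int = 4
    stance_mean_s: float = 0.30
    stance_sd_s: float = 0.03
    body_mass_g: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_MASSES))
    body_mass_sd_g: float = 10.0
    fz_peak_fraction_bw: float = 0.75
    #: Reduced vertical loading on the affected limb of NP-alone animals.
    fz_peak_fraction_bw_np_affected: float = 0.65
    fz_peak_time_pct: float = 30.0
    fx_braking_amp_mN: float = 150.0
    fx_propulsion_amp_mN: float = 250.0
    braking_fraction: float = 0.25
    fy_peak1_amp_mN: float = 280.0
    fy_peak2_amp_mN: float = 180.0
    noise_sd_mN: float = 20.0

    def to_shape(self, group: str, limb_is_affected: bool) -> ForceShape:
        frac = self.fz_peak_fraction_bw
        if group == "np_alone" and limb_is_affected:
            frac = self.fz_peak_fraction_bw_np_affected
        return ForceShape(
            fz_peak_fraction_bw=frac,
            fz_peak_time_pct=self.fz_peak_time_pct,
            fx_braking_amp_mN=self.fx_braking_amp_mN,
            fx_propulsion_amp_mN=self.fx_propulsion_amp_mN,
            braking_fraction=self.braking_fraction,
            fy_peak1_amp_mN=self.fy_peak1_amp_mN,
            fy_peak2_amp_mN=self.fy_peak2_amp_mN,
            noise_sd_mN=self.noise_sd_mN,
        )


class BehaviorConfig(_Strict):
    thresholds_gF: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {g: dict(v) for g, v in _DEFAULT_THRESHOLDS.items()}
    )
    psychometric_steepness: float = 6.0
    weight_fraction: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_WEIGHT_FRACTIONS)
    )
    weight_noise_sd: float = 0.02
    weight_trials: int = 5


class AnalysisConfig(_Strict):
    fps: float = 200.0
    cutoff_hz: float = 25.0
    n_bins: int = 100
    stance_threshold_fraction: float = 0.02
    alpha: float = 0.05
    #: Bonferroni family size for deviation tests; None = number of groups.
    family_size: int | None = None
    unit: Literal["animal", "trial"] = "animal"
    affected_limb: Literal["LH", "RH"] = "RH"


class RunConfig(_Strict):
    """Top-level configuration for a simulate-and-analyze run."""

    seed: int = 0
    design: DesignConfig = Field(default_factory=DesignConfig)
    effects: dict[str, EffectConfig] = Field(default_factory=dict)
    force: ForceConfig = Field(default_factory=ForceConfig)
    behavior: BehaviorConfig = Field(default_factory=BehaviorConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)

    @model_validator(mode="after")
    def _fill_effects(self) -> "RunConfig":
        for g in self.design.groups:
            self.effects.setdefault(g, EffectConfig())
            self.force.body_mass_g.setdefault(g, 300.0)
            self.behavior.weight_fraction.setdefault(g, 0.5)
            self.behavior.thresholds_gF.setdefault(
                g, {"affected": 15.0, "contra": 15.0}
            )
        return self

    @classmethod
    def study_like(cls, seed: int = 0, **overrides) -> "RunConfig":
        """Configuration mirroring the study conditions, with NP-alone-like
        pathology (5 pp duty deficit, +0.05 symmetry offset, 0.45 weight
        fraction, reduced affected-limb vertical loading)."""
        effects = {g: EffectConfig() for g in GROUPS}
        effects["np_alone"] = EffectConfig(
            affected_duty_deficit_pct=5.0, symmetry_offset=0.05
        )
        return cls(seed=seed, effects=effects, **overrides)
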