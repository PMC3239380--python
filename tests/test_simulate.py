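"""Synthetic-data generator: determinism, injected ground truth, fixtures."""

import numpy as np
import pytest

from ratgait.behavior import updown_threshold, weight_distribution
from ratgait.dynamics import extract_force_metrics
from ratgait.simulate import (
    ForceShape,
    GaitEffect,
    StudyDesign,
    default_effects,
    generate_centroid_frames,
    generate_force_trace,
    generate_gait_events,
    generate_updown_responses,
    generate_weight_readings,
    simulate_trial_events,
)
from ratgait.spatiotemporal import trial_metrics


class TestDeterminism:
    def test_same_seed_byte_identical_events(self):
        des = StudyDesign(n_per_group=2, trials_per_animal=2, seed=42)
        eff = default_effects()
        a = generate_gait_events(des, eff).to_csv(index=False)
        b = generate_gait_events(des, eff).to_csv(index=False)
        assert a == b

    def test_different_seed_differs(self):
        eff = default_effects()
        a = generate_gait_events(StudyDesign(n_per_group=2, trials_per_animal=2, seed=1), eff)
        b = generate_gait_events(StudyDesign(n_per_group=2, trials_per_animal=2, seed=2), eff)
        assert not a["time_s"].equals(b["time_s"])

    def test_adding_trials_preserves_earlier_ones(self):
        """Child-seed splitting: trial t is identical whether or not later
        trials exist."""
        eff = default_effects()
        small = generate_gait_events(
            StudyDesign(n_per_group=2, trials_per_animal=2, seed=7), eff
        )
        big = generate_gait_events(
            StudyDesign(n_per_group=2, trials_per_animal=4, seed=7), eff
        )
        small_t0 = small[small["trial_id"] == 0].reset_index(drop=True)
        big_t0 = big[big["trial_id"] == 0].reset_index(drop=True)
        assert small_t0.equals(big_t0)


class TestGaitEvents:
    def test_zero_effects_give_exact_midpoint_symmetry(self, balanced_events):
        assert trial_metrics(balanced_events)["symmetry"] == pytest.approx(0.5, abs=1e-12)

    def test_injected_deficit_exact_without_noise(self, np_like_effect):
        ev = simulate_trial_events(np.random.default_rng(0), 32.0, np_like_effect)
        assert trial_metrics(ev)["imbalance_pp"] == pytest.approx(5.0, abs=1e-9)

    def test_minimum_two_cycles_always_present(self):
        des = StudyDesign(n_per_group=1, trials_per_animal=1, seed=0)
        ev = generate_gait_events(des, default_effects())
        for _, trial in ev.groupby(["animal_id", "trial_id"]):
            rec = trial_metrics(trial)
            assert rec["n_strides_affected"] >= 2
            assert rec["n_strides_contra"] >= 2

    def test_out_of_range_duty_rejected(self):
        eff = GaitEffect(duty_factor_intercept_pct=101.0, duty_factor_slope_pct_per_cm_s=0.0)
        with pytest.raises(ValueError, match="duty factor"):
            simulate_trial_events(np.random.default_rng(0), 30.0, eff)

    def test_missing_group_effect_rejected(self):
        des = StudyDesign(n_per_group=1, trials_per_animal=1, seed=0)
        with pytest.raises(ValueError, match="no GaitEffect"):
            generate_gait_events(des, {"preoperative": GaitEffect()})

    def test_symmetry_offset_bounds(self):
        with pytest.raises(ValueError):
            GaitEffect(symmetry_offset=0.6)


class TestCentroidFrames:
    def test_static_ellipse_constant_truth(self):
        frames, truth = generate_centroid_frames(
            n_frames=5, velocity_cm_s=(0.0, 0.0), seed=0
        )
        assert np.allclose(truth, truth[0])

    def test_constant_velocity_finite_difference(self):
        fps, scale = 200.0, 0.1
        _, truth = generate_centroid_frames(
            n_frames=10, velocity_cm_s=(30.0, 0.0), fps=fps,
            pixel_scale_cm_per_px=scale, seed=0,
        )
        v = np.diff(truth[:, 0]) * fps * scale
        assert np.allclose(v, 30.0, atol=1e-9)

    def test_leaving_field_of_view_is_error(self):
        with pytest.raises(ValueError, match="field of view"):
            generate_centroid_frames(n_frames=400, velocity_cm_s=(50.0, 0.0))


class TestForceTrace:
    def test_halfsine_impulse_closed_form(self):
        """Piecewise half-sine of amplitude A over stance T integrates to 2AT/pi."""
        bw = 300.0
        for peak_pct in (30.0, 50.0, 70.0):
            shape = ForceShape(
                fz_peak_fraction_bw=0.8, fz_peak_time_pct=peak_pct, noise_sd_mN=0.0
            )
            tr = generate_force_trace(shape, 0.5, bw, lead_s=0.0, tail_s=0.0)
            A = 0.8 * bw * 9.80665
            T = tr.t_s[-1] - tr.t_s[0]
            iz = np.trapezoid(tr.fz_mN, tr.t_s)
            assert iz == pytest.approx(2 * A * T / np.pi, rel=1e-3)

    def test_braking_fraction_constructed_zero_crossing(self):
        shape = ForceShape(braking_fraction=0.3, noise_sd_mN=0.0)
        tr = generate_force_trace(shape, 0.505, 300.0, lead_s=0.0, tail_s=0.0)
        m = extract_force_metrics(tr, (0, len(tr.t_s)))
        assert m.t_neg_x_pct == pytest.approx(30.0, abs=1e-9)

    def test_zero_amplitudes_give_zero_descriptors(self):
        shape = ForceShape(
            fz_peak_fraction_bw=0.0, fx_braking_amp_mN=0.0, fx_propulsion_amp_mN=0.0,
            fy_peak1_amp_mN=0.0, fy_peak2_amp_mN=0.0, noise_sd_mN=0.0,
        )
        tr = generate_force_trace(shape, 0.3, 300.0, lead_s=0.0, tail_s=0.0)
        m = extract_force_metrics(tr, (0, len(tr.t_s)))
        for f in ("max_fz_mN", "iz_mN_s", "max_f_neg_x_mN", "max_fx_mN",
                  "i_neg_x_mN_s", "ix_mN_s", "max_fy_first_mN",
                  "max_fy_second_mN", "iy_mN_s"):
            assert getattr(m, f) == 0.0

    def test_short_stance_is_error(self):
        with pytest.raises(ValueError, match="3 samples"):
            generate_force_trace(ForceShape(), 0.005, 300.0)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            ForceShape(braking_fraction=1.5).validate()


class TestUpDown:
    def test_threshold_below_set_all_withdrawals(self):
        s = generate_updown_responses(0.01, steepness=1e6, seed=0)
        assert all(w for _, w in s.presentations)
        assert s.boundary == "low"
        assert updown_threshold(s) == pytest.approx(s.min_assignable_gF)

    def test_threshold_above_set_no_withdrawals(self):
        s = generate_updown_responses(100.0, steepness=1e6, seed=0)
        assert not any(w for _, w in s.presentations)
        assert s.boundary == "high"
        assert updown_threshold(s) == pytest.approx(15.0)

    def test_sequence_follows_updown_rule(self):
        s = generate_updown_responses(4.0, seed=3)
        fil = list(s.filament_set)
        for (f0, w0), (f1, _) in zip(s.presentations, s.presentations[1:]):
            i0 = fil.index(f0)
            assert fil.index(f1) == (i0 - 1 if w0 else i0 + 1)

    def test_monte_carlo_threshold_recovery(self):
        """Median estimate over many series lands near the latent 4 g."""
        rng = np.random.default_rng(2024)
        est = []
        for _ in range(500):
            s = generate_updown_responses(4.0, rng=rng)
            est.append(updown_threshold(s))
        med = np.median(est)
        assert abs(med - 4.0) / 4.0 < 0.25

    def test_empty_filament_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_updown_responses(4.0, filament_set=[], seed=0)


class TestWeightReadings:
    def test_exact_fraction_without_noise(self):
        r = generate_weight_readings(0.5, noise_sd=0.0, n_trials=5, seed=0)
        assert weight_distribution(r) == pytest.approx(50.0, abs=1e-12)
        r = generate_weight_readings(0.42, noise_sd=0.0, n_trials=5, seed=0)
        assert weight_distribution(r) == pytest.approx(42.0, abs=1e-12)

    def test_noisy_mean_unbiased_over_seeds(self):
        means = []
        rng = np.random.default_rng(99)
        for _ in range(200):
            r = generate_weight_readings(0.45, noise_sd=0.02, n_trials=5, rng=rng)
            means.append(weight_distribution(r))
        grand = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(grand - 45.0) < 3 * se + 1e-9

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            generate_weight_readings(1.2, seed=0)
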