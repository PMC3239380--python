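"""Ground-reaction-force descriptors for one synthetic foot contact.

Generates a tri-axial stance force curve (vertical loading peak at 30% of
stance, braking over the first 25%, bimodal mediolateral force), filters
it at 25 Hz, detects the stance window on the vertical channel and prints
the ten generalized descriptors in raw mN.
"""

from ratgait.dynamics import detect_stance, extract_force_metrics, lowpass_filter
from ratgait.simulate import ForceShape, generate_force_trace

shape = ForceShape(
    fz_peak_fraction_bw=0.75,  # peak vertical force as a fraction of body weight
    fz_peak_time_pct=30.0,     # end of the loading phase
    braking_fraction=0.25,     # fraction of stance with net braking
    noise_sd_mN=20.0,
)
trace = generate_force_trace(shape, stance_s=0.30, body_weight_g=300.0, seed=42)

filtered = lowpass_filter(trace, cutoff_hz=25.0)
stance = detect_stance(filtered.fz_mN, filtered.body_weight_g, threshold_fraction=0.02)
m = extract_force_metrics(filtered, stance)

print(f"stance duration      : {m.stance_s*1e3:.0f} ms")
print(f"Max Fz               : {m.max_fz_mN:7.0f} mN   (peak vertical force)")
print(f"Iz                   : {m.iz_mN_s:7.1f} mN*s (vertical impulse)")
print(f"Max F-x / Max Fx     : {m.max_f_neg_x_mN:6.0f} / {m.max_fx_mN:.0f} mN "
      f"(peak braking / propulsion)")
print(f"I-x / Ix             : {m.i_neg_x_mN_s:6.1f} / {m.ix_mN_s:.1f} mN*s")
print(f"t-x                  : {m.t_neg_x_pct:7.1f} %    (braking time, % stance)")
print(f"Max Fy 0-50 / 50-100 : {m.max_fy_first_mN:6.0f} / {m.max_fy_second_mN:.0f} mN")
print(f"Iy                   : {m.iy_mN_s:7.1f} mN*s")
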