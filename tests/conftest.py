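import numpy as np
import pandas as pd
import pytest

from ratgait.simulate import GaitEffect, GaitNoise, simulate_trial_events


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_events(left_strikes, left_offs, right_strikes, right_offs,
                left_xy=None, right_xy=None):
    """Hand-built event table; positions default to strikes along +x."""
    rows = []
    for limb, strikes, offs, xy in (
        ("LH", left_strikes, left_offs, left_xy),
        ("RH", right_strikes, right_offs, right_xy),
    ):
        merged = [(t, "strike") for t in strikes] + [(t, "off") for t in offs]
        merged.sort()
        for i, (t, kind) in enumerate(merged):
            if xy is None:
                x, y = 30.0 * t, (1.0 if limb == "LH" else -1.0)
            else:
                x, y = xy[i]
            rows.append((limb, kind, t, x, y))
    return pd.DataFrame(rows, columns=["limb", "event", "time_s", "x_cm", "y_cm"])


@pytest.fixture
def balanced_events():
    """Zero-noise, zero-effect trial: perfectly alternating symmetric gait."""
    rng = np.random.default_rng(0)
    return simulate_trial_events(rng, 30.0, GaitEffect(), n_strides=4)


@pytest.fixture
def np_like_effect():
    return GaitEffect(affected_duty_deficit_pct=5.0, symmetry_offset=0.05)


@pytest.fixture
def noisy_effect():
    return GaitEffect(
        affected_duty_deficit_pct=5.0,
        symmetry_offset=0.05,
        noise_sd=GaitNoise(duty_pp=1.0, symmetry=0.02, stride_cm=0.3, step_width_cm=0.2),
    )
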