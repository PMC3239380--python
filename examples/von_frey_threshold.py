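"""50% paw-withdrawal threshold from simulated up-down von Frey series.

One series is shown presentation by presentation (X = withdrawal, step to
the next smaller filament; O = no withdrawal, step up); the threshold is
then estimated from the terminal six-response pattern.  A small Monte
Carlo shows the estimator recovering a latent 4 g threshold.
"""

import numpy as np

from ratgait.behavior import updown_threshold
from ratgait.simulate import generate_updown_responses

series = generate_updown_responses(true_threshold_gF=4.0, seed=5)
marks = " ".join(f"{f:g}{'X' if w else 'O'}" for f, w in series.presentations)
print(f"presentations : {marks}")
print(f"estimated 50% withdrawal threshold : {updown_threshold(series):.2f} g "
      f"(latent 4.0 g)")

rng = np.random.default_rng(123)
estimates = [
    updown_threshold(generate_updown_responses(4.0, rng=rng)) for _ in range(500)
]
print(f"median over 500 series             : {np.median(estimates):.2f} g")
print(f"interquartile range                : "
      f"{np.percentile(estimates, 25):.2f} - {np.percentile(estimates, 75):.2f} g")
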