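# ratgait

Quantitative gait, ground-reaction-force and pain-behavior analysis for
rodent models of lumbar radiculopathy — the analysis chain used in
preclinical studies that ask whether a unilateral nerve-root injury (for
example autologous nucleus pulposus placed on the right L5 dorsal root
ganglion) produces measurable limb compensations, and whether a treatment
prevents them.

The package is written for experimenters and analysts working with
high-speed (200 fps) open-arena gait video, a single-foot force plate
(200 Hz), an incapacitance meter and von Frey filaments.  Because such
studies rarely ship raw recordings, `ratgait` includes a first-class
synthetic-data generator that emulates the statistical structure of the
experiment with known ground truth, so the entire pipeline is verifiable
end to end without any animal data.

## What it computes

**Spatiotemporal descriptors** (per trial, from digitized foot-strike and
toe-off events):

- *percentage stance time* (limb duty factor)
  `DF = 100 · (t_off − t_strike) / (t_strike′ − t_strike)`;
- *gait symmetry* — the phase of the right hind foot-strike within the
  left–left stride interval, `(t_R − t_L1)/(t_L2 − t_L1)`; 0.5 is perfect
  alternation;
- *stance-time imbalance* — contralateral minus affected mean duty factor
  (percentage points; positive = affected limb favored);
- *stride length* (projected on the direction of travel) and *step width*
  (perpendicular to it).

**Force descriptors** (per contact, after a zero-phase 25 Hz low-pass and
stance detection on the vertical channel): Max Fz, Iz, Max F₋ₓ, Max Fₓ,
I₋ₓ, Iₓ, t₋ₓ, Max F_y(0–50%), Max F_y(50–100%), I_y — peaks, trapezoidal
impulses and percentage braking time, reported in raw mN with statistics
on body-weight-normalized values; plus ensemble mean ± 95% CI curves on
normalized force/time axes.

**Behavior**: the 50% paw-withdrawal threshold from up-down von Frey
series, `10^(X_f + kδ)` g with k from a shipped pattern table, and static
weight distribution, `100 · right/(left+right)`.

**Statistics**: velocity-covariate ANCOVA (common slope) with
Student–Newman–Keuls step-down post-hoc on adjusted means; one-sample
"deviation" t-tests of each group against the definitions of balanced,
symmetric gait (imbalance 0, symmetry 0.5, weight 50%) with Bonferroni
correction; one-way and two-factor (group × limb, Type II) ANOVA.  The
animal is the experimental unit: trials are averaged within animal first.

## Worked example

```bash
python examples/balanced_gait_metrics.py
```

prints

```
symmetry of midway right strikes : 0.500   (0.5 = alternating)
velocity                         : 30.0 cm/s
duty factor affected/contra      : 70.0 / 70.0 %
stance-time imbalance            : 0.000 pp  (0 = balanced)
stride length / step width       : 13.5 / 2.5 cm
injured trial imbalance/symmetry : 5.00 pp / 0.550   (favoring the affected limb)
```

The first line is the definitional identity: when right hind strikes fall
exactly midway between left hind strikes the symmetry variable is 0.5.
The balanced synthetic trial recovers its configured duty factor (70%)
on both limbs, hence zero imbalance; injecting a 5 pp affected-limb duty
deficit and a +0.05 phase offset is recovered exactly by the analysis.

Other examples: `force_descriptors.py` (the ten GRF descriptors for one
contact), `von_frey_threshold.py` (up-down estimation and its Monte-Carlo
recovery), `track_and_accept.py` (centroid tracking, calibration, the
15%-velocity / two-gait-cycle acceptance rules), and
`simulate_and_analyze.py` (a full four-group study in which only the
NP-alone group is flagged for imbalance, asymmetry and weight shift).

A thin CLI mirrors the pipeline stages:

```bash
ratgait run --seed 1 --outdir study/     # simulate + analyze + report
ratgait report study/
```

## Layout

```
src/ratgait/
  simulate.py        seeded synthetic study generator (ground truth known)
  kinematics.py      centroid tracking, calibration, trial acceptance
  spatiotemporal.py  strides, duty factor, symmetry, lengths/widths
  dynamics.py        filtering, stance detection, GRF descriptors, ensembles
  behavior.py        up-down thresholds (Dixon k-table), weight bearing
  stats.py           ANCOVA, SNK, deviation tests, two-factor ANOVA
  pipeline.py        stage orchestration, CSV outputs, manifest
  config.py, cli.py  schema-validated config; thin click CLI
```

See `docs/methods.md` for the models, parameter choices and limitations.
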