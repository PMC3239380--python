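# Methods

## Scope and design

`ratgait` reimplements, as a tested library, the analysis chain of a
preclinical gait study of unilateral lumbar radiculopathy in the rat:
spatiotemporal gait descriptors from high-speed video footfall events,
ground-reaction-force (GRF) descriptors from single-foot force-plate
contacts, von Frey mechanical sensitivity and incapacitance-meter weight
bearing, and the inferential statistics tying them together.  Raw animal
recordings are not distributable, so the package pairs every analysis
stage with a seeded synthetic generator whose ground truth is known; the
tests demonstrate identities, oracle equivalences and parameter recovery
on those synthetic conditions.

The affected limb is the right hind (ipsilateral to the exposed right L5
DRG) throughout; it is a parameter everywhere it matters.

## Synthetic gait model

A trial is one straight arena pass at velocity v (cm/s).  Stride length
is linear in velocity, L(v) = a + b·v, so stride time is T = L/v, and
duty factor (percentage stance time) is linear and decreasing,
d(v) = c + e·v.  Defaults: a = 9 cm, b = 0.15 cm/(cm/s) (≈80% stride
length increase over 10–70 cm/s, matching the reported velocity
dependence), c = 81%, e = −0.3 %/(cm/s) (≈72% at the ~30 cm/s walking
speeds typical of a 3-month rat; stance times then fall in the 0.2–0.6 s
range).  Left hind strikes fall at multiples of T; right hind strikes at
phase 0.5 + s of each left–left interval; toe-offs realize the per-stride
duty.  Injected pathology: the affected limb's duty factor is reduced by
a deficit Δ (pp) and the phase shifted by s.  With all noise zero the
downstream metrics return Δ and 0.5 + s exactly, by construction — this
is the backbone of the recovery tests.

Group conditions mirror the study: four groups (preoperative, sham,
NP alone, NP + sTNFRII) × 6 animals × 5 trials; group velocity means
29.8 / 34.9 / 32.6 / 39.0 cm/s with 3 cm/s between-trial sd; NP-alone-like
pathology Δ = 5 pp, s = +0.05, right-limb weight fraction 0.45.

Noise model (per-metric Gaussian sds; defaults 1 pp duty, 0.02 symmetry,
0.3 cm stride position, 0.2 cm step width): duty noise is per stride;
symmetry noise is a **per-trial phase offset** of the whole right strike
train.  Per-strike phase jitter would also perturb right stride durations
and bias the measured duty factor upward through the stride-time
denominator (Jensen's inequality), making the generator's nominal deficit
unequal to the mean of what the measurement model returns; the per-trial
formulation keeps the injected parameters the exact means of the
recovered ones.

Not emulated: turning or stopping mid-pass, fore-limb events, velocity
drift within a trial, the step-width–velocity narrowing (step width is a
per-group constant), digitization error correlated across events, and
animal growth between time points.  Passing tests therefore certify the
pipeline's arithmetic and inference under idealized locomotion, not
robustness to every artifact of real video.

## Kinematics

Frames are background-subtracted and thresholded; the animal is the
largest foreground component and its centroid is tracked per frame
(frames below a minimum foreground area are flagged missing, never
silently filled).  Pixel→cm calibration is a least-squares affine fit to
grid correspondences (≥3 non-collinear pairs; RMS residual reported);
affine rather than projective because the ventral mirror view is planar
and orthogonal.  Velocity: central differences on the centroid positions
followed by a 5-frame moving average on speed; up to 2 consecutive
missing frames are linearly interpolated for velocity only, longer gaps
invalidate the trial.  Acceptance: ≥2 complete strides per hind limb and
smoothed speed within 15% of the trial mean (the instantaneous-vs-
per-stride ambiguity is resolved as smoothed instantaneous speed).
Footfall events are digitized upstream by hand; this package ingests
event tables and does not auto-detect footfalls.

## Spatiotemporal descriptors

Strides are consecutive ipsilateral strike pairs with the enclosed
toe-off; non-alternating sequences are rejected with the offending row.
Symmetry pairs each left–left interval (tL1, tL2] with the first right
strike strictly after tL1 (a right strike coincident with tL1 scores 0.0
in that interval); intervals without a right strike are skipped with a
warning.  Imbalance is contralateral − affected trial-mean duty factor,
signed so that favoring the affected limb is positive.  Direction of
travel is the principal axis of the centroid track when available,
otherwise of the per-limb mean-centered strike positions (centering
removes the lateral offset between the limb tracks, which would otherwise
tilt the axis); stride lengths are projections on this axis, step widths
perpendicular distances.  Symmetry is averaged within trial, then within
animal.

## Force processing

Sign conventions: +Fx propulsive, +Fy toward the midline for both limbs,
+Fz vertical.  The 25 Hz low-pass is a 4th-order Butterworth applied
forward–backward (zero phase, DC gain exactly 1).  Stance is the longest
run of Fz above 2% of body weight, with sub-threshold gaps shorter than
5 samples bridged (hysteresis); the original experiment verified contact
on video instead, so detection thresholds are configurable.  Descriptors:
peaks are extrema within stance; impulses trapezoidal integrals (the
negative part of Fx for I₋ₓ, positive for Iₓ); t₋ₓ is the total time with
Fx < 0 as a percentage of stance, measured with linear interpolation of
zero crossings (robust to sign chatter; a constructed braking lobe over
the first 30% of stance yields exactly 30.0%).  The two Fy peaks are
taken over the first and second halves of stance.  Statistics run on
body-weight-normalized values; raw mN are reported for comparability.

Synthetic force curves are sine-lobe compositions chosen for closed-form
integrals: a piecewise half-sine of amplitude A over stance T has
vertical impulse 2AT/π wherever the peak falls, giving an analytic oracle
for the trapezoidal integrator (agreement <0.1% at 200 Hz, stance
≥0.2 s).  These shapes reproduce the phase structure of rat walking
(loading to ~30% stance, braking→propulsion crossover, bimodal
mediolateral force) but are phenomenological; their magnitudes are not
claimed to reproduce any measured table.

Ensemble curves: each contact normalized to body weight and % stance,
resampled to 100 bins by linear interpolation; trials averaged within
animal, then mean and t-based 95% CI across animals (across-animal CIs
chosen over across-trial).

## Behavior

Up-down von Frey: withdrawal → next smaller filament, none → next
larger, starting near 2 g on the standard 0.4–15 g rat set; the series
terminates after six responses counted from the one before the first
reversal, or when it steps off the set.  The threshold is
10^(X_f + k·δ) g with X_f the log10 force of the final filament,
δ the set's mean log10 spacing (≈0.197), and k a constant determined by
the six-response O/X pattern.  The shipped k-table contains
maximum-likelihood estimates of the 50% point under a normal psychometric
function with spread equal to one log-step — the construction behind the
classical small-sample up-down tables; it is antisymmetric under O↔X and
is checked in the tests against an independently coded grid-search MLE.
Boundary series are assigned the cutoff (15 g) at the top and one
log-step below the smallest filament (≈0.25 g) at the bottom.  The
simulated response model is logistic in log10(force) (steepness 6 per
decade by default), the standard psychometric choice; with it, 500
simulated series at a latent 4 g threshold recover a median within 25%.

Weight distribution is the trial-mean of 100·right/(left+right) over
five 5-s incapacitance readings.

## Statistics

"GLM with a velocity covariate" is read as a Gaussian linear model with
identity link (ANCOVA), metric ~ group + velocity with a common slope (no
group×velocity interaction), fit by OLS; group means are adjusted to the
grand-mean velocity, and the residual MSE/df feed the post-hoc.  A
constant-velocity design is rejected with an informative error (the
covariate would be collinear with the group factor).

Student–Newman–Keuls: means sorted; a pair spanning p ordered means is
tested against the studentized-range quantile q(α, p, df) (computed
numerically via `scipy.stats.studentized_range` and validated against
classical critical values in the tests), standard error √(MSE/n_h) with
n_h the harmonic mean of the two group sizes; step-down with the
containment rule (pairs inside a non-significant range are not tested).
For k = 2 the procedure reduces algebraically to the pooled two-sample
t-test, which the tests verify to 1e-6.

Deviation tests: one-sample t of animal-level means against the
theoretical values for balanced, symmetric gait (imbalance 0, symmetry
0.5, weight 50%), Bonferroni-multiplied by the family size (default: the
number of groups tested).  Zero-variance degenerate cases are reported
explicitly (p = 1 at the theoretical value; otherwise p below the machine
floor, flagged).  Under a balanced-gait null simulated through the full
gait pipeline the empirical type-I error at α = 0.05 is within
0.05 ± 0.02 (1000 replicates).

Two-factor (group × limb) ANOVA uses Type II sums of squares for the
unbalanced trial counts typical of force-plate work, on animal-aggregated
body-weight-normalized metrics, with SNK over the group×limb cells.  The
animal-as-unit default avoids pseudo-replication; a trial-level mode is
available.  α = 0.05 throughout.

## Reproducibility and numerics

One master seed spawns per-(data-kind, animal, trial) child streams via
`numpy.random.SeedSequence(master, spawn_key=...)`, so adding animals or
trials never perturbs earlier draws, and identical configurations yield
byte-identical CSVs.  Simulation sizes in the test suite — 200 seeds for
study-scale recovery, 1000 replicates for type-I calibration, 500 series
for threshold recovery — were chosen to keep Monte-Carlo error well below
the tolerances they check while the full suite runs in a few minutes.
Degenerate inputs are errors, not NaNs: empty event tables, all-empty
frame stacks, zero-total weight trials, stances under 3 samples,
unterminated up-down series, empty ANOVA cells.  Ties in symmetry
pairing resolve to the half-open interval (tL1, tL2].

## Known limitations

- Synthetic force magnitudes are phenomenological; only their phase
  structure and integral identities are meaningful.
- The k-table derivation assumes a normal psychometric function with
  spread equal to one log-step; other assumed spreads shift k values
  slightly.
- No mixed-effects modeling; the animal-mean aggregation discards
  within-animal trial counts' unequal precision.
- No markerless pose estimation or automatic footfall detection; no
  fore-limb metrics; no center-of-pressure or plate calibration.
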