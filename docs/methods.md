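# Methods

## Coordinate conventions and units

All computation happens in a right-handed camera frame: x to the
participant's left as seen by the camera (image right), y down, z away
from the camera (depth). The participant faces the camera, so backward
motion is increasing z and vertical up is −y. Internally everything is in
meters and seconds; degrees appear only at reporting boundaries. A missing
keypoint is all-NaN coordinates with confidence 0.

2D inputs (pixel keypoints plus per-pixel depth) are lifted to 3D with the
pinhole model x = (u − cx)·d/fx, y = (v − cy)·d/fy, z = d. Non-positive or
non-finite depth marks the keypoint missing rather than raising.

## Preprocessing

Sensor timestamps may jitter, and IIR filter design assumes uniform
sampling, so trajectories are first resampled onto a uniform grid at the
nominal rate (30 Hz) by per-coordinate linear interpolation. Missing runs
of at most `max_gap_interp` frames (default 5) are bridged; longer gaps
stay missing, and a required landmark (shoulders, hips, ankles,
bilaterally) with a longer gap makes the trial unusable.

Smoothing is a 4th-order Butterworth low-pass at 7 Hz applied
forward–backward (`scipy.signal.filtfilt`, reflective padding of 3× the
filter order). Zero-phase filtering is essential here: a causal filter's
group delay (tens of milliseconds at 30 Hz) would bias every latency
metric. The price is that the effective magnitude response is the square
of the single-pass response — at the 7 Hz cutoff the amplitude ratio is
1/2 rather than 1/√2, which the tests assert explicitly.

Derivatives are central differences (`np.gradient`; one-sided at the
ends). Acceleration is the iterated gradient, i.e. an effective 5-point
second-difference stencil: its noise variance is 4× lower than the 3-point
Laplacian, at the cost of a sinc² amplitude factor (≈ 6 % attenuation at
the filtered pull-pulse bandwidth at 30 Hz). Consequences worth knowing:

- a 3 m/s² Gaussian acceleration pulse (σ = 60 ms) is reported at ≈ 2.65
  m/s² after filtering (−4 %) and differentiation (−6 %);
- central differences attenuate band content by 1 − sin(ω·dt)/(ω·dt): at
  30 Hz this is 0.7 % at 1 Hz but 15 % at 4.6 Hz. Velocity-based metrics
  here involve much slower content (step speed profiles span ~0.3–0.5 s),
  where the factor is negligible.

Bilateral landmarks are combined as the arithmetic midpoint *before*
differentiation (linear operations commute; the midpoint halves
uncorrelated per-keypoint noise variance).

## Event detection

**Pull onset.** The detection series is the Euclidean norm of the
shoulder-midpoint acceleration. The threshold is baseline mean +
3 × baseline SD over the first 1 s of quiet stance (a tiny relative
epsilon keeps a zero-variance noise-free baseline from producing a zero
threshold that numerical filter ripple would cross). The crossing is the
start of the first post-baseline excursion that (a) holds at least two
consecutive samples above threshold and (b) reaches
max(0.5 × peak, min(mean + 2·(thr − mean), 0.7 × peak)), where peak is the
post-baseline maximum of the series excluding the trailing filter-edge
zone. The debounce (a) rejects isolated noise spikes; the gate (b) rejects
sustained noise excursions while still accepting a weak but dominant
pulse, and prevents locking onto later response-related peaks (trunk
deceleration, body braking) that can exceed a soft pull. Onset is then the
last local minimum — a sample not larger than either neighbour, earliest
sample of a plateau — strictly before the crossing, falling back to the
crossing when no minimum exists after the baseline. Pull magnitude is the
maximum of the series within 1 s after onset (`pull_peak_window`); an
unbounded search would pick up step- and recovery-related accelerations.

**Steps.** Per foot, maximal intervals of resultant ankle speed above
0.7 m/s, with endpoints linearly interpolated between samples (sub-frame
precision, matching a dense-scan oracle within a frame). Intervals
separated by a sub-threshold gap shorter than 67 ms (2 frames) are merged;
intervals shorter than 100 ms are discarded — raw threshold crossings on
noisy 30 Hz speed traces otherwise produce spurious micro-intervals.
Intervals starting before pull onset are discarded (anticipatory movement
is outside the clinical scheme). Step length is the horizontal (x–z)
displacement of the ankle between the interpolated crossings: ground
displacement, so vertical foot lift does not inflate it, but the
sub-threshold tails of the swing are — by construction — excluded (for a
minimum-jerk swing with peak 1.5 m/s they carry ≈ 15 % of the total
displacement; detector and synthetic ground truth share this convention).
The primary step velocity is the peak resultant speed within the step
(robust to the exact crossing endpoints); the mean speed is exported as a
secondary field.

**Trunk angle.** The trunk vector runs from the hip midpoint to the
shoulder midpoint; the baseline vector is its mean over the quiet-stance
window. The primary angle is the signed angle between the projections of
the two vectors onto the sagittal (y–z) plane, negative for backward lean;
a pure lateral lean reads 0. The unsigned full 3D angle is exported as a
secondary series. The retropulsion angle is the post-onset minimum of the
sagittal series.

**Recovery.** The earliest time at or after the retropulsion maximum that
is also at or after the end of the last detected step and at which
|angle| ≤ (1 − 0.75)·|max|. Reported as a latency from pull onset (the
same reference as the first-step latency); absent if no such time exists
within the recording.

`analyze_trial` composes validation → resampling → smoothing → midpoints
and derivatives → the four detectors, and is a pure function of the
trajectory and the configuration. All constants live in `AnalysisConfig`;
there are no hidden thresholds.

## Agreement statistics

Given n subjects measured by k = 2 methods or raters:

- Bland–Altman: bias = mean(a − b), RPC = 1.96 × SD(a − b) (ddof = 1).
- Method validity: single-measure two-way absolute-agreement ICC
  (McGraw–Wong A,1; equivalently Shrout–Fleiss 2,1),
  (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E)). The two-way
  *consistency* single-measure form (3,1) is exposed alongside for
  comparison, because the two labels are often conflated in the applied
  literature; outputs are named `icc_a1_two_way` to be unambiguous.
- Reliability: one-way random single-measure ICC(1,1),
  (MS_B − MS_W)/(MS_B + (k−1)·MS_W), and SEM = SD_pooled·√(1 − ICC) with
  SD_pooled the sample SD over all cells — the standard definition.
- ICC bands: poor < 0.5, moderate 0.5–0.75, good 0.75–0.9, excellent
  > 0.9; values exactly on a boundary take the lower band (an arbitrary,
  documented tie rule).
- Group comparisons: Welch's t-test (group variances are not assumed
  equal) and Pearson chi-squared without continuity correction (a warning
  recommends an exact test when expected counts fall below 5). Pearson or
  Spearman correlation for numeric vs ordinal pairings. p-values are
  reported unadjusted; Benjamini–Hochberg is available to users but not
  applied by default.
- The all-cells-equal matrix makes every ICC a 0/0 ratio; it returns NaN
  with a warning rather than a fabricated value. Report tables drop
  subjects with a missing value listwise per metric.

Both ICC estimators are verified in the tests against an explicit
sums-of-squares enumeration and against pingouin's implementation.

## Synthetic trial generator

The generator is a kinematic template, not a physics simulation: each
response component is authored directly so that every derived metric has a
closed-form or numerically exact ground truth.

A static skeleton is scaled to subject height H with fixed proportions
(fractions of H; heights above floor / half-widths): shoulder 0.818/0.115,
hip 0.530/0.095, knee 0.285/0.100, ankle 0.039/0.100, elbow 0.630/0.130,
wrist 0.490/0.140, nose 0.935/0, eyes 0.945/0.033, ears 0.930/0.070.
Exact values are cosmetic: the detectors use only relative geometry. Face
and arm keypoints move rigidly with the trunk to keep files
schema-complete. The camera sits 1 m above the floor, 2 m in front.

Motion components:

1. **Perturbation.** A whole-body backward translation whose acceleration
   is a biphasic pulse: a Gaussian push A·exp(−(t−t₀−2σ)²/2σ²) (defaults
   A = 3 m/s², σ = 60 ms) followed by an impulse-balanced braking Gaussian
   (4× wider, A/4, centered 0.8 s later), so the body comes to rest
   displaced A·σ·√(2π)·0.8 ≈ 0.2·A/3 m backward. Velocity and displacement
   have closed forms (Gaussian CDF antiderivatives). Translating the whole
   body — not just the upper body — keeps the trunk vector, and with it
   the retropulsion-angle ground truth, exactly equal to the authored tilt
   profile; a one-sided pulse applied above the hips would instead leave a
   permanent upper-body drift that swamps the trunk angle.
2. **Trunk tilt.** Rotation of all above-hip keypoints about the mid-hip
   in the sagittal plane: a C² minimum-jerk ramp to `max_tilt` (negative =
   backward) over `tilt_rise`, starting `tilt_delay` = 0.15 s after the
   pull (the trunk lags the shoulder impulse), then — if the trial
   recovers — the critically damped return (1 + x)e^(−x), x = (t−t_peak)/τ,
   which is exponential-family decay with zero initial slope. Smoothness
   matters: profiles with angular velocity or acceleration jumps (e.g. a
   raised-cosine ramp, whose angular acceleration is maximal at its very
   first instant) inject spurious spikes into the shoulder acceleration
   that no muscle-driven motion produces. Non-recovering trials plateau at
   `max_tilt`.
3. **Steps.** Per commanded step, the ankle translates backward along a
   minimum-jerk displacement of length L and duration T (speed
   30·(L/T)(τ²−2τ³+τ⁴), peak 1.875·L/T), with a vertical lift bell of
   0.1·L and the same-side knee following at half amplitude. The hip does
   not follow, keeping the mid-hip — and the trunk-angle ground truth —
   exact. Same-foot steps may not overlap in time.
4. **Noise.** i.i.d. Gaussian, SD 2 mm per coordinate per frame, no
   temporal correlation — the worst case for differentiation; the 7 Hz
   filter is the mitigation under test.

Ground truth: onset = t₀ (the push pulse's support start, μ − 2σ);
peak_acc = A (the translation component; the *measured* magnitude also
contains trunk-response acceleration, as it does in real recordings); step
boundaries = 0.7 m/s crossings of the noiseless resultant ankle velocity
(translation + step + lift), found on a 1 kHz grid and refined by
bisection to 1e-6 s, with lengths and peak speeds from the same noiseless
profile; maximum tilt = `max_tilt` at t_peak; recovery = the later of the
closed-form tilt-return crossing of 25 % (t_peak + 2.693·τ for the
critically damped return) and the last true step end. A commanded step
whose noiseless profile does not produce exactly one crossing interval
(too slow, or merged with a neighbour) is a parameter error, not a silent
mislabel.

Cohort profiles are phenomenological and calibrated to the group contrasts
reported for this test in clinical cohorts: healthy — pull A ≈ N(3.0, 0.5),
1–2 long fast steps (first length ≈ 0.32 m, peak speed ≈ 1.5 m/s), tilt
≈ −10.5°, recovery latency ≈ 1.7–1.9 s; slight impairment — softer pulls
(A ≈ 2.4), 3–5 shorter slower steps (≈ 0.24 m, ≈ 1.05 m/s), larger tilt
(≈ −14°), slower recovery; moderate impairment — 4–6 short steps, tilt
≈ −18°, no unaided recovery. Patient tilt rises are slower (0.65–0.70 s vs
0.55 s), consistent with bradykinesia. Step peak speeds are drawn directly
(floor 0.9 m/s) and durations derived as T = 1.875·L/v̂: a step is a
threshold-crossing event by definition, so ground-truth steps must cross
the 0.7 m/s threshold with margin; genuinely near-threshold steps — which
real patients do produce — are thereby excluded from the simulation by
construction (see Limitations).

## What the synthetic tests do and do not show

Passing parameter recovery on these cohorts shows the pipeline correctly
implements its own definitions under uniform sampling, complete skeletons
and white Gaussian noise. Real RGB-D pose data differ in ways the
generator deliberately omits: temporally correlated and occasionally
non-Gaussian tracking error (depth edge artifacts, limb swaps),
occlusion-driven missing runs, examiner hands touching the shoulders,
soft-tissue and clothing motion, and steps that hover near the velocity
threshold. Results on real recordings therefore need their own validation
against a reference measurement system — which is exactly what the
agreement-statistics half of the package is for.

Measured detector resolution at the simulated conditions (30 Hz, 10 s,
2 mm noise, 100 mixed-profile trials): step count exact in ~100 % of
trials; first-step length within 0.9 % (median); retropulsion angle within
0.16° (median); recovery latency within 1.2 frames (median). Pull-onset
localization is the noise-limited quantity: 2 mm position noise propagates
through the 7 Hz zero-phase filter and double differentiation to an
acceleration-norm noise floor of ≈ 0.3 m/s² (shoulder midpoint), so at the
pulse foot the per-frame signal increment is comparable to the noise and
the last-local-minimum rule carries an irreducible jitter of ±1–2 frames
(≈ 45 % of trials within one frame of truth; median |error| ≈ 1.1 frames).
First-step latency, being referenced to onset, inherits this jitter
(median |error| ≈ 1.05 frames vs ≈ 0.25 frames for the step crossing
itself). Sample-exact onset recovery at this noise level would require
either a higher frame rate, lower-noise keypoints, or a matched-filter
style estimator in place of the local-minimum rule.

## Numerical choices and degenerate inputs

- Filter edge handling: reflective padding, 3× filter order; the final
  3×order samples are additionally excluded from the onset peak search
  (filtfilt edge transients).
- Local-minimum ties: plateaus count, earliest plateau sample chosen.
- A noise-free constant baseline gets a relative-epsilon threshold so that
  numerical ripple cannot cross it; a noise-free quiet-stance trial
  therefore reports "no pull detected". On *noisy* quiet-stance data the
  3 SD rule can fire on noise — the method presumes the recording contains
  a pull, as it does in the clinical protocol.
- ICC of an all-equal matrix: NaN + warning. SEM requires ICC ≤ 1.
  Correlations and t-tests refuse zero-variance input.
- Seeds: every stochastic component (trial noise, cohort draws) is driven
  by an explicit integer seed; identical seeds give bit-identical output.

## Known limitations

- Step lengths are crossing-bounded ground displacements, systematically
  ~15 % smaller than the full swing amplitude; comparisons across systems
  are unaffected as long as both use the same convention.
- The measured pull magnitude is the peak of the *total* shoulder
  acceleration and over-reads the commanded pulse when the trunk response
  is vigorous relative to the pull.
- No automated clinical grade is assigned (grading in the source protocol
  is a clinician's judgement); the package exports quantitative features
  and booleans only. No center-of-mass or base-of-support stability
  computation.
- UMAP or other embeddings of the feature set are out of scope; users can
  feed the flat results table to any embedding library directly.
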