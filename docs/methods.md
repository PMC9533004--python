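# Methods

This note documents the models, conventions, numerical choices and design
decisions behind `whipkin`, and what the synthetic-data validation does and
does not establish.

## Coordinate frame and angle convention

The lab frame is right-handed with `x` pointing horizontally from the
participant toward the target, `z` vertical up and `y` to the
participant's left; the target direction defaults to `+x`. All azimuths
(whip, hand-handle) are angles of a horizontal projection measured from
"straight backward" (pointing away from the target): 0° = backward,
positive toward the participant's right, range (−180°, 180°]. Under this
convention a whip trailing almost directly behind the thrower reads near
0°, and one trailing behind-right reads positive. Marker files do not
record their frame; recordings exported in another convention must be
rotated before analysis.

## Filtering and differentiation

Positions are low-pass filtered with a linear-phase FIR filter designed by
Kaiser windowing: passband/stopband edges 1 Hz below/above the cutoff,
≥60 dB stopband attenuation, ≤0.1 dB passband ripple (the ripple is read
in dB). The minimum order from the Kaiser estimate is verified against the
realized frequency response and increased until both band specs hold; at
500 Hz with a 2 Hz transition this yields ~900 taps. Zero lag is realized
by a single pass of the (odd-length, symmetric) kernel with exact
group-delay compensation — equivalent to forward-backward filtering for a
linear-phase FIR but with unit (not squared) passband gain — using
antisymmetric reflection padding of one filter length at span edges.
Cutoffs: 20 Hz for hand and target markers, 40 Hz for whip and handle
markers. Cutoff selection by residual analysis is out of scope; the values
are taken as given.

Gaps of ≤50 frames (0.1 s) are bridged by linear interpolation before
filtering; longer gaps split the filtered spans and leave the affected
frames masked. Derivatives use second-order central differences with
one-sided stencils at span boundaries; masked frames stay undefined in the
derivatives.

## Segmentation

The whip-to-target distance series is the exact continuous minimum
distance between the polyline through `w1`–`w3` and the segment
`t1`–`t2`, computed per frame by closed-form segment-segment distance
(equivalent to the limit of dense resampling of both chains). Events are
its local minima with a 0.3 s refractory period, ≥0.1 m prominence and a
0.6 m ceiling; the refractory period suppresses double detections from
target oscillation and the ceiling rejects backswing passes.

Discrete trial starts search a 1.0 s window before the lift frame for the
last upward 0.5 m/s hand-speed crossing; a lift without a crossing flags
the trial excluded. Ties at equal extrema are always broken toward the
earliest frame, making segmentation deterministic.

On marker naming: `w1` is the tip and `w1`–`w3` are treated as the distal
(tip-side) markers everywhere — for lift detection, event detection and
the error metric alike. Source conventions for this task have used
"distal" both ways; this package does not attempt to reconcile that and
states its own convention explicitly.

## Per-trial metrics

- **Error** — minimum whip-to-target distance over the *throw interval*
  (throw onset → minimum distance). Over the full trial interval the
  rhythmic error would degenerate: a rhythmic trial starts at the previous
  minimum-distance event, where the distance still equals the previous
  trial's error. The full-trial variant is exported as `error_trial`.
- **Hit** — the target-spring free end `t1` is band-passed at 1–8 Hz
  (around the spring's free frequency); a hit is an oscillation envelope
  in the 0.8 s after trial end exceeding the pre-trial baseline by 5 mm.
  Both band and threshold are configuration parameters, calibrated on
  synthetic target oscillations.
- **Extension** — |w1 − h1| in metres at peak hand speed (the `w1`–`w10`
  chord over the 1.6 m arclength is exported as `extension_ratio`).
- **Whip azimuth** — total-least-squares (SVD) line through `w1`…`w10`
  and `h1`, oriented handle → tip, projected to the horizontal plane.
- **Hand azimuth** — orientation of the hand-handle body's long axis,
  from the proximal cluster (`h2` and the hand markers) toward the
  midpoint of `w10` and `h1`.
- **Peak speeds** — maxima of the hand and `w2` tangential speeds over the
  trial (`w1` is too noisy to differentiate reliably on real recordings).
- **Rhythmicity** — CoV (sample SD over mean, n−1) of start-to-start
  inter-trial intervals within a block.

Landmark-instant geometry (extension, azimuths) is estimated from a short
symmetric frame window around the peak-hand-speed frame rather than a
single frame: ±5 frames (10 ms) for chain quantities, ±15 frames for the
short (~0.25 m, few-marker) hand-handle axis. A symmetric window is
unbiased to first order because the chain rotates at a locally constant
rate around the peak, and it suppresses marker noise that a single frame
cannot: with a two-point axis, a single frame of even 5 mm noise could not
resolve 1°. The windows double as the fallback for gapped frames. Known
cost: window averaging shrinks the measured extension by ~1–2 mm at
nominal rotation rates.

Summaries use median/IQR for error and extension (skewed) and mean/SD for
the other metrics. Skewed metrics are modelled untransformed, so slopes
stay on the raw scale.

## Speed profiles

Per-trial speed segments are linearly resampled onto a fixed 500-point
grid on [−1, 0] with the minimum-distance landmark at the last sample;
averaging across trials (per participant, style and marker) uses the
sample SD. A fixed grid is equivalent to normalizing to the mean duration
up to an axis relabelling and makes cross-trial averaging trivial. Whip
profiles span the throw interval, hand profiles the full trial. Spans
shorter than 10 frames and profile-excluded trials are skipped.

## Mixed models

Gaussian LMMs are fitted with `statsmodels` `MixedLM` (REML for final
estimates, ML for likelihood-ratio comparisons; lbfgs with bfgs/powell
fallbacks, and a reduced random structure — recorded in the selection
trace — when the full one is singular). Wald statistics use a t reference
with between-participant degrees of freedom (n_participants − 2) as a
coarse small-sample correction; the choice is recorded in the result
metadata. In simulation this brings 95 % CI coverage of the planted
fixed effects to the nominal rate at the study's scale of 16 participants.
The binomial-logit GLMM for hit/miss uses the Laplace (posterior-mode)
approximation with participant intercept and style-slope variance
components; its posterior-mode SDs are reported (the variational
alternative understates them severely). Forward likelihood-ratio selection
adds `S`, `B`, `S:B` in order at α = 0.05, considering the interaction
only once both main effects are retained, and records every comparison.
Under a correctly specified null the interaction is retained at ≈5 %; note
that testing a fixed term while omitting genuinely present random slopes
is conservative in this design.

The error-correlation model replaces the block term with a covariate `X`
(random slopes on style and `X`); per-style slopes `βX` (discrete) and
`βX + βSX` (rhythmic) are derived rows with SEs from the fixed-effect
covariance. A single participant drops the model to OLS with a logged
trace entry. With one observation per cell and a balanced design the LMM
fixed effects coincide with OLS, which the tests verify against the
closed form; the Gaussian LMM is also cross-checked against an
independent lme4 fit.

## Synthetic scenes

The generator is *kinematic*: it scripts chain configurations that satisfy
the marker-spacing constraint exactly (adjacent whip markers keep their
arclengths to <1e-6 m before noise), rather than simulating whip dynamics.
Controlled ground truth, not physical fidelity, is the goal.

- **Hand**: Gaussian velocity bumps give a two-peak tangential-speed
  profile with the second (throw) peak higher — defaults 6.1 m/s
  (discrete) and 4.5 m/s (rhythmic); in the discrete style a solved return
  bump brings the hand back exactly, and lift/lower ramps take it between
  rest (0.25 m) and throw (1.35 m) heights.
- **Whip**: each chain segment follows a shared azimuth-angle schedule
  delayed by 20 ms per segment. Around the peak-hand-speed instant the
  schedule is linear in time, so the chain forms a circular-arc-like shape
  whose per-segment increment is solved (Brent) from the planted extension
  and whose orientation is solved from the planted azimuth via the
  rotation-equivariance of the SVD line fit — both plants are therefore
  exact at the nominal peak instant. The handle carries a separately
  solved angle offset realizing the planted hand azimuth. Afterwards each
  segment unfolds toward the target in its own burst: burst durations
  taper toward the tip and scale with segment length (floored so marker
  trajectories stay band-limited below the 40 Hz whip filter), the base
  duration being calibrated once per parameter set so the tip (`w2`) peak
  speed matches `tip_gain ×` the hand peak. This yields a strictly
  proximal-to-distal ordering of per-marker speed peaks.
- **Errors and hits**: the target is first placed so the nominal throw
  grazes it; each trial's planted error is then realized by the thrower
  standing farther from the target (a radial fall-short miss), solved by
  inverting the measured offset→distance map. Radial misses keep the
  minimum-distance event sharp because the tip still sweeps past the
  target transversally at full speed. In the discrete style the
  repositioning happens during the rest before the throw; in the rhythmic
  style it is absorbed into the backswing of the cycle (a wider backswing
  bump whose area is adjusted per cycle), so no extra movement phase
  exists and hand-speed landmarks are untouched. Trials with planted
  contact add a damped 3.5 Hz, 5 cm oscillation to `t1` (0.3× on `t2`)
  from the event frame.
- **Timing**: start-to-start intervals are drawn log-normally and then
  standardized so the realized sample CoV equals the planted value
  exactly. In the rhythmic style trial intervals mix adjacent cycle
  durations (events fall at a per-trial fraction of each cycle), so cycle
  durations are solved backwards from the planted interval sequence;
  warping a cycle changes speeds but not the spatial path.
- **Imperfections**: isotropic Gaussian noise (default 0.3 mm, typical of
  optical capture with soft markers) and scheduled gaps are applied last.

Ground truth is recorded from the noise-free twin of each scene: planted
quantities (extension, azimuth at the nominal peak, per-trial errors,
interval CoV, trial counts, contacts) are inputs; emergent quantities
(realized tip speeds, per-marker peak frames, per-trial hand azimuth) are
measured on the noiseless data.

What passing the closed loop does **not** show about real recordings: the
generator has no out-of-plane whip motion during the throw, no reflected
travelling waves, no marker-swap or ghost-marker artefacts, no drift or
non-Gaussian noise, constant per-trial kinematics apart from timing and
stance, and misses only in the radial direction. Pipeline accuracy on real
data is bounded by these simplifications.

Two documented measurement couplings surface even in the synthetic closed
loop and are properties of the definitions, not bugs: the whip azimuth
rotates ~0.5–0.9°/frame around the speed peak, so a ±2-frame landmark
error moves the measured azimuth by up to ~1.5°; and after a contact the
ringing target perturbs the next rhythmic trial's distance series by a few
millimetres.

## Problem sizes and tolerances

Test and reproduction runs use blocks of 8–15 discrete throws and 40 s
rhythmic blocks (~30 cycles) at the full 500 Hz rate, 100 random scenes
for the geometry oracle (0.1 mm dense sampling, 1e-4 m agreement), 40
noisy configurations for orientation recovery (5 mm noise, 1°/1 cm), and
100–200 simulated cohorts at the study scale (16 participants, 33 trials
per block, 2 styles × 5 blocks) for CI-coverage and likelihood-ratio
calibration. Landmark recovery is verified to ±2 frames; in practice the
synthetic blocks recover all landmarks within ±1 frame at default noise.

## Known limitations

- The rhythmic cycle caps the base unfolding time so every segment
  settles within the 1.2 s period; the realized rhythmic tip speed
  therefore runs ~5–8 % above its calibration target.
- The whip filter's band edge slightly reshapes the fastest part of the
  tip path; the noise-free closed-loop error is recovered to ~0.5–1 mm,
  not machine precision.
- Exclusion rules are exercised by injected gap schedules; the generator
  does not model the physical occlusion processes that cause gaps in real
  capture volumes.
- C3D reading requires the optional `ezc3d` dependency and is untested in
  this repository's suite; the wide-TSV dialect is the reference format.
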