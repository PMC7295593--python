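# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data tests do and do not show
about real recordings.

## Coordinate and sign conventions

One convention is used everywhere and asserted by the test suite: pixel
origin top-left with u rightward and v downward; 0-based frame indices;
times in seconds, positions in metres (millimetres only in reports); the
world z-axis points **down**, so flight height relative to the landing
point is h = −z and a bee below the target has negative h. Touchdown
defines t = 0 and the spatial origin; approach time is negative. Body
pitch β = arcsin(Δh/|body|) with Δh the height of the head above the
abdomen tip, so a head-up posture has positive β in [−90°, 90°]. Approach
speed U_P = −d(d_E)/dt is positive when closing in on the target.

## Stereo geometry

Cameras are plain 11-parameter DLT mappings without lens-distortion terms,
calibrated by linear least squares on ≥6 non-coplanar control points
(rank < 11 of the design matrix raises a degenerate-calibration error).
Triangulation stacks both cameras' two equations into a 4×3 least-squares
system per frame; it is exact for noise-free input. Frames with a system
condition number above 1e8 are flagged unreliable rather than
reconstructed — this separates genuinely degenerate stereo (identical or
near-parallel views) from noisy-but-usable frames. With the default
synthetic rig (orthogonal top/side cameras 1 m from a 0.5 m volume,
≈0.39 mm px⁻¹) and 0.5 px pixel noise, the median 3D error is ≈0.26 mm.

## Trajectory smoothing

Raw 3D tracks are smoothed per axis with a forward Kalman filter plus a
backward Rauch–Tung–Striebel pass under a constant-acceleration state
model (state [position, velocity, acceleration]). The noise configuration
is the study's: process-noise covariance diag(1, 0.1, 0.01) on the three
states, measurement noise 1 (identity scale), zero cross-covariance. The
scalar settings carry no published units or structure; they are read as
the diagonal in track units and exposed entirely through `SmootherSpec`.
Because filtering behaviour depends only on the Q/R ratios, the unit
question (m vs mm) does not change the output.

Two consequences of these ratios matter and are documented rather than
hidden. First, position smoothing is mild (the assumed per-frame process
noise exceeds the assumed measurement noise), so per-frame positions stay
close to the raw triangulation. Second, the per-frame data information
about the velocity state is very small, so the initial state prior decays
slowly: a "large" initial covariance of 1e3 still biases velocity
estimates by several percent hundreds of frames into a track. The default
initial covariance is therefore 1e6 (effectively diffuse, first observed
position with zero velocity/acceleration as the mean), which restores the
properties the smoother should have — interior velocity within 5% on
constant-velocity tracks, time-reversal symmetry, and velocity that
integrates back to displacement within 2%. The implementation is verified
against an exact batch MAP solution of the same linear-Gaussian model
(sparse normal equations), which it reproduces to 1e-12.

Head and abdomen-tip tracks are smoothed independently; only the
abdomen's position is used (for body pitch). Gaps must be handled
upstream; non-finite samples are rejected with the frame index.

## Kinematics

The remaining-path series d(I) sums per-frame displacement magnitudes
|ΔX(i)| between frame I and touchdown, with ΔX(i) the central-difference
displacement |X(i+1) − X(i−1)|/2 at interior frames and one-sided
differences at the track ends (the endpoint scheme keeps the series the
same length as the track; it is exposed in code and its ≤1% effect on τ
near touchdown is the tolerance used in tests). The empty sum makes
d = 0 at touchdown, and τ = d/d_E is left undefined (NaN) where d_E = 0.
On straight approaches τ = 1 to within the endpoint tolerance; on a
sampled semicircle the start-frame τ is π/2 to 0.1%.

## Synthetic landing generator

The generator encodes the observed landing behaviour as a minimal
controllable model. A signed along-track speed profile v(t) cruises at
0.12 m s⁻¹, decelerates over the last ~0.5 s to a 0.06 m s⁻¹ final
approach, and carries one Gaussian-shaped hover dip per requested hover
time (default one hover 1 s before touchdown, width 0.06 s) during which
the speed briefly crosses slightly below zero — emulating the hovering
wobble that makes real approach speeds oscillate around zero and giving
the pooled speed histogram its negative tail. The flight direction
oscillates in heading with amplitude `tortuosity_gain` (radians, default
0.45 at 2.5 Hz) and descends at slope 0.15, so the bee approaches from
slightly below (negative mean height, as observed). Position is the
backward time-integral of v·direction from touchdown, so every path ends
exactly at the origin; the abdomen tip sits one body length (14 mm)
behind the head at the per-landing pitch (default 40°). Gaussian-shaped
dips avoid velocity discontinuities that the smoother would distort
unpredictably.

Ground-truth annotations come from the realised noise-free kinematics:
the leg-extension frame is the final inward crossing of the 9 mm
leg-extension distance, and the ground-truth TL start applies the same
threshold rule as the segmentation stage to the noise-free series. The
closure tests therefore measure exactly the error introduced by camera
projection, pixel noise, triangulation and smoothing.

Study designs emulate the recorded cohort: 44 white and 61 red–blue
landings over 8 days. Positive metrics (durations, distances, tortuosity,
speed) take multiplicative condition effects — log-scale additive — with
the red–blue/white ratios of the reported group means (e.g. LE duration
0.19 → 0.24 s, ratio ≈1.263); height and pitch, which may be negative,
take additive effects. Day intercepts are drawn once per day and shared
by all landings of that day. The variance components are not published;
day_sd = 0.10 and residual_sd = 0.40 (log scale) were fixed once so that
the simulated LE-duration F statistic is of the observed order (≈7) at
the cohort sizes, and are not tuned thereafter. Part-of-day labels are
generated but carry no effect, matching the finding that only day
explained appreciable variation.

What the generator does **not** emulate: wingbeat dynamics and body
oscillation at wingbeat frequency, tracking dropouts and manual
re-digitisation error, correlated (non-Gaussian) pixel noise, lens
distortion, repeated flights by the same individual, or any coupling
between flight kinematics and the statistical effect sizes (the metric
table and the scene set are separate realisations of the same design).
Passing closure tests therefore shows the pipeline recovers its own
model's ground truth under realistic noise, not that real tracking error
behaves like the simulation.

Lamp spectra: the white lamp is a smooth broad curve over 400–700 nm
(phosphor-LED-like), the red–blue lamp two narrow Gaussians at 455 and
660 nm (σ = 8 nm) scaled so the white:red–blue photon-radiance ratio is
the measured 1.35 of the study conditions. The bundled achromatic
sensitivity curve is a **synthetic stand-in** — a Gaussian peaking at
540 nm with 100 nm FWHM, the qualitative shape of a green-receptor
sensitivity — because the measured curve exists only in figure form. The
resulting achromatic input ratio (≈11.8 with the default shapes) is an
emergent property of these synthetic curves and is deliberately not
calibrated; analyses of real lamps should supply measured spectra and a
digitised sensitivity curve as two-column CSVs.

## Phase segmentation

The hover-speed threshold is derived from the pooled approach-speed
histogram of all landings: Freedman–Diaconis binning (recorded in the
model object; the fitted-curve crossing is insensitive to reasonable bin
widths), a nonlinear least-squares fit of a sum of five Gaussian
components (the usual reading of a "fifth-order Gaussian model"), and the
threshold at the first speed right of the fitted curve's global mode
where the curve returns to its fitted frequency at U_P = 0. Component
means are initialised at sample quantiles with amplitudes read off the
histogram; non-convergence raises a diagnostic error, and a crossing at
(numerically) zero speed raises a no-threshold error. On a two-mode
mixture with known density and 100k samples the fitted threshold is
within a fraction of a percent of the closed-form crossing.

TL detection takes |U_P| ("absolute speed towards the platform", so
hovering wobble of either sign counts) below the threshold at the
earliest frame that also satisfies the two plausibility criteria — total
speed < 0.4 m s⁻¹ and d_E < 0.15 m. The criteria gate the candidate frame
itself, not the whole subsequent approach; this is one of two defensible
readings and is isolated in `detect_tl_start` for sensitivity analysis.

Exclusion rules: a failed landing drops both phases; a landing whose
hover is never detected drops TL only — classified `recording_too_short`
when the bee does get slow and close within the recording (its first
hover then predates the fixed 5 s camera buffer), `no_hover_found`
otherwise; an annotated leg extension earlier than the detected TL start
drops TL but keeps LE. On a constructed 105-landing batch with 7
truncated recordings, 1 LE-before-TL and 1 failed landing, the analysis
cohort is 96 TL and 104 LE.

## Statistics

Each metric/phase is modelled as f(value) ~ condition + (1 | day), fitted
by REML (statsmodels MixedLM behind the module surface). The transform f
is the first of identity, log, log log whose model residuals pass
Shapiro–Wilk at α = 0.05 (log requires positive values; log log values
> 1; if none passes, the applicable transform with the largest p is used
and recorded). The condition effect is tested with F = (b/se)² on 1 and
n − n_days − 1 degrees of freedom — the within-group convention of
nlme-style conditional F-tests, which gives 87 denominator df for 96
landings over 8 days and 95 for 104. Group means and their Wald 95% CIs
are computed on the transformed scale and mapped back by the inverse
transform of the point estimates and interval endpoints; no smearing
correction is applied, matching plain back-transformation of model
predictions. Single-day data fall back to a fixed-intercept OLS fit with
a warning; degenerate (constant) responses are rejected.

Calibration, measured by simulation at the cohort sizes: type-I error of
the condition test on null designs stays within binomial bounds of 0.05,
and the true LE-duration multiplier falls inside the back-transformed 95%
CI in ≈93% of replicates.

## Problem sizes and determinism

The test suite and the acceptance script use 50 full-pipeline closure
landings, 1000-point triangulation Monte Carlo, a 100k-sample threshold
mixture, 200 null and 100 effect replicates for the statistics stage, and
a 105-landing exclusion batch — sizes at which every quantity is stable
to well within its tolerance while the whole suite runs in about a
minute. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds reproduce identical scenes,
tables and pipeline outputs byte-for-byte.

## Known limitations

- Raw-video landmark tracking is out of scope: the pipeline starts from
  2D pixel tracks and manual leg-extension/touchdown annotations.
- The smoother assumes gap-free tracks; recordings with dropouts must be
  split upstream.
- `recording_too_short` vs `no_hover_found` classification is a heuristic
  (see above); with real data the distinction may need the annotator's
  judgement, and the annotation schema accepts a failed-landing flag but
  no override for the hover reason codes.
- Back-transformed means are medians under the log-normal reading;
  comparing them to arithmetic sample means conflates the two when the
  residual variance is large.
- The MAT-container reader auto-detects mm vs m from magnitudes and maps
  variable names through a configurable schema; containers with unusual
  layouts may need a custom schema map.
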