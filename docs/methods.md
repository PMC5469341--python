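# Methods

This note documents the models, defaults and design choices behind
`imudex`, in the order the pipeline runs.

## Data model and units

A recording is a set of synchronously sampled 9-DOF streams at
`fs = 100` Hz: accelerometer in m/s², gyroscope in deg/s, magnetometer
in µT (optional, all-or-nothing per sensor). Conversion from raw sensor
counts is out of scope. Timestamps are seconds from recording start;
all intervals are half-open `[t_ini, t_end)`; integration endpoints are
inclusive of a sample landing exactly on the boundary. Accelerations
are raw specific force (gravity included), which is why the
gravity-compensated magnitude subtracts `g` (default 9.80665 m/s²,
configurable).

## Offset calibration

`calibrate_offsets` is defined operationally over a rest window of at
least 0.5 s: gyro channels get the window mean subtracted per axis;
accelerometer vectors are rescaled by one factor so the window mean of
|a| equals g. The operation is idempotent. The full pipeline
(`compute_metrics`) applies the gyro part only: the accel scale factor
is estimated with relative error ≈ σ_a/(g·√n), and on an unbiased
accelerometer that estimation error — which the speed integrator turns
into linear drift — exceeds any bias it removes. The rescale stays
available for sensors with genuine scale error.

## Activity segmentation (Duration)

The comparator runs on the modulus of the analytic signal (Hilbert
envelope) of a **single signed gyro axis** (z of the back-of-hand
sensor by default). A signed axis oscillates around zero during
activity, so its envelope localizes sharply; the non-negative magnitude
Sω carries a large DC component whose envelope decays only like 1/d
past the activity edges, which we measured to smear onsets/offsets by
1–3 s and split exercises — `segmentation_signal(stream, axis=None)`
restores magnitude-based segmentation for comparison. Threshold
15 deg/s; ON runs ≤ `min_event_s` (1.0 s) removed first, then OFF holes
≤ `hole_fill_s` (1.0 s) filled — this order matters on pathological
inputs and matches the description of the procedure. The hole-fill
length is a configurable default, not a reported value. Detected
intervals from the reference sensor are applied to all sensors: the
sensors share the hand's schedule.

## Movement counting (Movements)

Within an exercise: Hilbert envelope of Sω → zero-phase Hann smoothing
(`smooth_window_ms` = 200 ms; window length rounded to an odd number of
samples so peaks are not delayed; reflection padding) → local maxima.
Artifact rejection discards maxima below `peak_min_height`
(default 10 deg/s, well under the ~100 deg/s scale of voluntary
movement peaks) **both in absolute height and in prominence** — the
prominence condition is what rejects sub-deg/s noise ripples riding on
sustained supra-threshold activity, which are not movement changes.
Maxima closer than `peak_merge_gap_ms` (default 300 ms, beyond the
smoother's support) are merged keeping the tallest: a burst of nearby
peaks is one motion performed with varying speed. Movements = retained
peak count; the epochs between consecutive peaks (padded to the
exercise boundaries) tile the exercise exactly and feed the kinematic
integrator. Movement economy = reference count / trainee count.

## Path metrics (Dispθ, Disp)

**Dispθ** is the trapezoidal area under Sω over the exercise after
detrending. The default detrend subtracts the rest-period mean of Sω
(the sensor's noise-plus-bias floor while the hand is still) and clamps
at zero; a plain linear detrend is retained as an option but would
annihilate constant rotation and produce negative angular speeds on a
non-negative magnitude.

**Disp** integrates dVa/dt = Sa with fixed-step 4th-order Runge-Kutta
at the sample period, movement by movement, each movement starting from
the previous one's final speed and Va = 0 at exercise onset. With Sa
interpolated linearly at half-steps, RK4 on this pure quadrature
reduces exactly to the trapezoid rule — the cumulative-trapezoid oracle
in the tests therefore agrees to machine precision, and the RK4 form is
kept for fidelity to the stated procedure. After integration a
**zero-velocity anchor** subtracts the piecewise-linear interpolant
through Va's values at movement boundaries: movements start and end
with the hand (near) still, so any residual speed there is integration
drift. Without this step, white accelerometer noise of σ_a integrates
to a random walk of scale σ_a·√(t/fs) whose |·|-integral is unbounded
in time; no pure integrator meets a few-percent path tolerance over a
one-minute exercise. The anchor is a config flag (`va_zero_anchor`,
default on); the raw chained integrator is unchanged underneath.
Disp = trapezoidal area of |Va| — the absolute value makes it a path
length rather than a (zero) net displacement. The magnitude-minus-g
form of Sa is kept verbatim even though it only approximates
gravity-free acceleration during rotation; it is the method's own
approximation, and Disp is invariant to sign flips of accel axes.

## Sensor redundancy and fusion

Pairwise redundancy: Pearson r between two sensors' Sω, one value per
movement epoch, summarized by mean and sample sd; zero-variance epochs
are skipped and counted. Orientation fusion is a gradient-descent
quaternion complementary filter (gyro propagation corrected toward the
gravity/field directions, gain β = 0.1 rad/s; β = 0 is open-loop gyro
integration), initialized from the first accel/mag sample; Euler
convention is intrinsic Z-Y-X in degrees — the source method names
neither the filter nor the convention, so the claims tested are
property-level (high correlation of SFω with Sω), not filter-exact.
SFω uses central differences of unwrapped angles (one-sided at the
endpoints); the fusion comparison maximizes Pearson r over integer
sample lags within ±500 ms because the filter delays its output
slightly.

## Assessment layer

Features are z-scored per variable with the sample (n−1) sd, so
Euclidean distance equals the standardized Euclidean distance. Ward
clustering uses the Ward.D2 criterion (merge cost = increase in total
within-cluster sum of squares); an exhaustive-cost oracle on small
instances guards against variant drift. With k = 2 the cluster with
lower mean Duration is labelled Type 1 (higher skill). A split whose
mean silhouette falls below 0.3 is flagged unstable: homogeneous
cohorts split at random land near 0.25, genuinely separated groups
above 0.35. Kruskal-Wallis uses mid-ranks, the tie-correction factor
1 − ΣT/(N³−N), and the upper chi-square tail with k−1 df; the printed
p-values of the study match the *unadjusted* values (verified by direct
rank arithmetic: the pegboard-duration case has H = 9.6 exactly), so
Bonferroni-adjusted values are reported alongside rather than instead.
Table reproduction rounds half away from zero to 2 decimals (4 for
p-values), after stripping float representation noise below 1e-10 —
one printed cell (a group mean of 22.675) requires exactly this
convention. One printed T_Ratio cell (2.91 where the printed inputs
give 2.9193) was evidently computed from unrounded timings; the
consistency check asserts agreement within one unit of the printed
decimal there.

## Synthetic recordings

The generator emulates a glove session, not hand biomechanics. A
session is rest (8 s) alternating with exercises; per exercise, `m`
movements are planted as raised-cosine angular-speed pulses (peak
~110 ± 15 deg/s; width ≈ 0.85 of the movement spacing; centers evenly
spaced with ±4% jitter) on top of a sustained 30 deg/s activity plateau
with 0.2 s ramps — the hand is never still mid-exercise, and the
plateau keeps the activity envelope above the 15 deg/s comparator
threshold between movement peaks. The plateau is inset 0.16 s from the
scheduled edges, matching the edge spread of an envelope-threshold
detector, so the planted interval is what such a detector genuinely
sees as activity. Each movement rotates about its own axis (dominant z
component) and reverses direction at its speed peak ("reach, then
return"), which bounds the simulated orientation (pitch stays well away
from gimbal lock) and makes single-axis gyro traces oscillate around
zero as real ones do. Acceleration is planted as one biphasic sine per
movement epoch, directed along the instantaneous gravity direction, so
each movement's speed returns to ~0 at its boundaries; translation
starts/ends ~0.6 s inside the activity window. Gravity and a fixed
Earth field (22, 0, −42) µT are rotated into the sensor frame with the
orientation obtained by integrating the planted angular velocity, so
gravity compensation and fusion are exercised consistently.

Noise defaults are consumer-MEMS datasheet orders of magnitude: gyro
0.5 deg/s rms per axis, accel 0.01 m/s² (~1 mg) rms per axis, mag
0.3 µT; gyro bias is zero by default and settable per axis. Finger
sensors (ids > 1) additionally carry smooth independent rotation
(15 deg/s, 0.5 s correlation, gated by the activity envelope), which
reproduces the observed redundancy regime: pairwise per-movement r in
the 0.9–0.95 range at default, thumb-index slightly lowest, decreasing
monotonically as finger motion grows. Ground truth uses closed forms:
angular path = Σ AᵢTᵢ/2 + plateau area; spatial path = Σ AₖLₖ²/(2π).
The skill presets (skilled/average/novice) differ in schedule, movement
count (25 vs 38 vs 51 on the pegboard exercise), pulse amplitude and
acceleration scale, ordered strictly in every planted metric.

What passing recovery tests shows — and what it does not: the simulator
shares the pipeline's structural assumptions (movements bounded by
speed peaks, near-zero velocity at boundaries, activity above the
comparator threshold throughout an exercise). Recovery therefore
validates the implementation and its noise robustness, not the method's
adequacy for hands that pause mid-exercise, drift-heavy uncalibrated
sensors, or motions where |a| − g is a poor acceleration proxy.

## Problem sizes

The default verification runs use 20 simulated recordings per skill
preset (≈110 s of 4-sensor data each at 100 Hz) for parameter recovery,
a 6-vs-8 cohort for tier classification, ≤6-point instances for the
exhaustive Ward oracle, and the full enumeration of all C(14,6) = 3003
group assignments as the exact reference for the Kruskal-Wallis
chi-square approximation.

## Known limitations

- Sa discards the direction of acceleration; Disp is a magnitude-level
  proxy for path length, not a trajectory integral.
- The zero-velocity anchor assumes movements end near rest; continuous
  gliding motion would be partially absorbed as "drift".
- The fusion filter is a generic complementary filter; no hard/soft-iron
  magnetometer calibration is modelled (synthetic fields are clean).
- Segmentation endpoints inherit the envelope's ~0.1–0.2 s edge spread;
  durations are accurate to about two tenths of a second, not to one
  sample.
- The packaged study tables make the assessment layer reproducible, but
  sensor-level values from the original study (raw recordings withheld)
  are emulated only qualitatively by the simulator.
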