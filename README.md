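# imudex

Manual-dexterity metrics and skill assessment from multi-sensor IMU
glove recordings.

Sensorized gloves are used to assess fine motor skills (FMS) of surgical
trainees on pegboard-style exercises: a hub samples up to eight 9-DOF
inertial sensors (tri-axial accelerometer, gyroscope and magnetometer) at
100 Hz while the subject performs a sequence of exercises separated by
rest periods. `imudex` implements the signal-processing and statistics
chain that turns those recordings into four dexterity metrics per
exercise and a classification of subjects by skill level, together with a
parametric simulator that generates recordings with planted ground truth.

## The method

All processing runs on magnitude signals. With gyro rates
(&omega;x, &omega;y, &omega;z) in deg/s and accelerations (ax, ay, az) in
m/s², the pipeline computes

- **S&omega; = &radic;(&omega;x² + &omega;y² + &omega;z²)** — angular
  speed magnitude; its peaks mark transitions between voluntary
  movements.
- **Sa = &radic;(ax² + ay² + az²) &minus; g** — acceleration magnitude
  with the gravitational magnitude removed (an orientation-free
  approximation to the motion acceleration).

and derives, per exercise:

- **Duration** (s): activity intervals are detected by comparing the
  Hilbert envelope of a gyro signal against a 15 deg/s threshold;
  supra-threshold runs of &le; 1 s are discarded and sub-threshold holes
  of &le; 1 s filled.
- **Movements** (count): local maxima of the smoothed (200 ms Hann)
  envelope of S&omega;, after discarding maxima that are too small to be
  voluntary motion and merging near-coincident maxima; also reported as
  *movement economy*, the ratio of an expert's count to the trainee's.
- **Disp&theta;** (deg): trapezoidal area under the detrended S&omega;
  over the exercise — total angular path.
- **Disp** (m): the speed magnitude Va solves dVa/dt = Sa by fixed-step
  4th-order Runge-Kutta, integrated movement-by-movement with chained
  initial conditions (Va = 0 at exercise onset) and a zero-velocity
  anchor at movement boundaries; Disp = &int;|Va| dt — total spatial
  path.

The assessment layer standardizes the per-subject metric table
(z-scores, i.e. standardized Euclidean distance), clusters it with
Ward's minimum-variance linkage, labels the cluster with lower mean
Duration as *Dexterity Type 1* (higher FMS), and validates the split per
variable with the tie-corrected Kruskal-Wallis rank test, Bonferroni
correction across variables. Two auxiliary analyses probe sensor
redundancy: per-movement Pearson correlation of S&omega; between sensor
pairs, and a comparison of S&omega; with SF&omega;, the angular-speed
magnitude reconstructed from finite differences of absolute orientation
angles estimated by a gradient-descent quaternion complementary filter
(accel + gyro + mag).

The per-volunteer tables of the validation study (video-review metrics
and the four dexterity metrics for 14 subjects) ship with the package as
CSV fixtures, so the entire assessment layer is reproducible end to end.

## Worked example

```python
from imudex import PipelineConfig, compute_metrics, generate_recording, preset

rec, truth = generate_recording(preset("skilled", seed=42))
for r in compute_metrics(rec, PipelineConfig()):
    if r.sensor == 1:
        print(f"exercise {r.exercise}: duration={r.duration:.2f} s, "
              f"movements={r.movements}, disp={r.disp:.3f} m, "
              f"disp_theta={r.disp_theta:.1f} deg")
```

```
exercise 1: duration=27.92 s, movements=19, disp=1.452 m, disp_theta=2001.2 deg
exercise 2: duration=13.92 s, movements=10, disp=0.655 m, disp_theta=992.3 deg
exercise 3: duration=34.96 s, movements=25, disp=1.965 m, disp_theta=2464.7 deg
```

The simulated "skilled" subject planted 28/14/35 s exercises with
19/10/25 movements and spatial paths of 1.456/0.661/1.966 m — the
pipeline recovers all of them (durations within 0.1 s, counts exactly,
paths within 1%). The third exercise is the pegboard test; 25 movements
is the economical reference (12 pieces transported plus the transitions).

Assessing the packaged study cohort:

```python
from imudex.datasets import exercise_features
from imudex.stats import DexterityAssessment

res = DexterityAssessment(exercise_features(3, 1), k=2).fit(bonferroni_m=4)
print(res.summary())
```

```
Dexterity assessment: 14 subjects, k=2

Type 1: {1, 4, 5, 9, 12, 13}
Type 2: {2, 3, 6, 7, 8, 10, 11, 14}

Group summary (mean (sd)):
  Type 1 (n=6): duration=45.87 (6.08), movements=31.67 (3.88), disp=2.24 (0.27), disp_theta=1099.17 (321.51)
  Type 2 (n=8): duration=73.70 (15.05), movements=53.38 (10.41), disp=3.31 (0.95), disp_theta=1732.75 (440.78)

Kruskal-Wallis (tie-corrected, chi-square approximation):
  duration: H=9.6000, p=0.0019, Bonferroni p=0.0078
  movements: H=8.8752, p=0.0029, Bonferroni p=0.0116
  disp: H=6.6667, p=0.0098, Bonferroni p=0.0393
  disp_theta: H=6.6667, p=0.0098, Bonferroni p=0.0393
```

Subjects 1, 4, 5, 9, 12 and 13 form the high-dexterity group; all four
metrics separate the groups at the 1% level before correction.

The same chain is scriptable from the shell via the `imudex` binary
(`simulate`, `segment`, `movements`, `metrics`, `redundancy`, `cluster`,
`kw`, `reproduce` subcommands); `imudex reproduce --tables 2,9,10`
recomputes the study's printed assessment tables from the packaged
fixtures and diffs every cell.

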