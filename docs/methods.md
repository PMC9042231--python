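# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic-data generators do and do not
emulate.

## Data model and conventions

Pose data enter as per-frame pixel coordinates plus a tracking likelihood
for three body parts (nose, body centre, tail base), in image coordinates
(origin top-left, y down). A single calibration factor `px_per_cm` maps
them into the arena frame; every downstream quantity is in cm, s, or cm/s.
Frame times are `frame_index / frame_rate`; the frame rate is a required
user input (default 30 Hz) because tracker CSVs do not carry it.

Points with likelihood below 0.9 are treated as missing. Interior gaps of
at most 5 consecutive frames are linearly interpolated; longer gaps stay
missing and are excluded from metric windows (occupancy denominators use
valid time only). This is an automated stand-in for the manual removal of
tracking errors that is customary when scoring such assays by hand; both
the threshold and the gap length are parameters.

## Kinematics

Speed is computed from the body centre only — nose jitter inflates
speed — using centered finite differences over two frame intervals
(one-sided at the series endpoints), then a centered moving average
(default 5 frames, odd, 1 disables smoothing). Frames with a missing
centre have no speed (NaN) before and after smoothing. Speed is invariant
under rigid motions of the coordinate frame by construction.

Head direction is the unsigned angle in [0°, 180°] between the
centre→nose vector and the centre→target vector; it is undefined (NaN)
when the nose coincides with the centre or the centre sits on the target.

Zone occupancy assigns each frame by a point-in-region test on the body
centre; boundaries count as inside, and a centre exactly on a chamber
partition goes to the first-listed zone (a deterministic tie-break).
Per-zone durations plus missing time always sum to the session duration.

## Escape scoring

A trial window runs from stimulus onset for the stimulus duration
(default 9 s, the ultrasound stimulus length). Arrival is the first frame
the centre is inside the shelter region.

- *Accuracy* = 100 − 10·(d/D) with d the centre-to-shelter distance (to
  the shelter center by default; a boundary option exists) at
  min(arrival, stimulus end). Arrived trials are scored d = 0. The formula
  is not clamped below zero by default, preserving its printed form; a
  clamp flag exists. If the evaluation frame is missing, the nearest valid
  frame within ±0.5 s is used, else the score is undefined.
- *Linearity* is path length over the onset→shelter chord, for arrived
  trials only. Because arrival is detected at the shelter *boundary*, the
  sampled path is closed to the shelter center before measuring; without
  this, a perfectly straight escape would score below 100% by exactly the
  shelter radius over the chord. With it, linearity ≥ 100 always, with
  equality iff the samples are collinear with the shelter.
- *Latency* uses orientation < 45°, speed > 2 cm/s, sustained 0.2 s.
  These criteria operationalize "turned its head and started to move";
  they are parameters, not measured constants.
- *Time to max speed* is measured from the detected movement onset to the
  first frame attaining the window maximum (ties break to the first).
- *Freezing* defaults: speed < 2 cm/s sustained ≥ 1 s. Only a verbal
  definition exists for freezing, so both values are exposed and echoed in
  outputs. *Running* is > 30 cm/s (0.3 m/s) with bouts merged across gaps
  ≤ 0.2 s. Bouts are half-open [start, end).
- *Escape runs* out of an odor-paired chamber: a chamber exit whose peak
  speed within ±0.5 s of the crossing exceeds 1.5× the session's mean
  ambulation speed (mean over frames moving faster than 2 cm/s). The
  printed criterion "greater than 50% of the average ambulation speed" is
  read as *50% greater than* the average, since the literal reading is
  satisfied by almost any movement; the factor is a parameter.

Speed/head-angle profiles normalize each arrived trial's shelter distance
by its onset distance, bin frames into 20 equal bins on [0, 1], and report
per-bin mean ± sd across trials; trials starting at zero distance are
excluded.

## Place aversion

Aversion index = (t_stim − t_nonstim)/t_total; preference index uses the
larger-occupancy side; CPA = post − pre. Binned curves use 5-min bins
(a 20-min test gives 4 bins); the session index equals the valid-time-
weighted mean of the bin indices exactly, which the tests assert as a
conservation law. Distance travelled sums centre displacements of the
smoothed path over valid frames.

## Epochs and restraint

Epoch metrics mask frames strictly to [start, end) and pool epochs by
label with frame-weighted means. The light-induced speed change is
(ON − OFF)/(ON + OFF), defined as 0 when both means are zero.

The struggle index is the *fraction* of binary movement samples per 10-s
bin rather than the per-bin sum: the fraction is sample-rate independent,
and the sum is recoverable as fraction × samples. The grand mean weighted
by per-bin counts equals the overall movement fraction exactly. A bin with
no samples indicates a sensor coverage gap and is an error.

## c-Fos counting

Segmentation is a global Otsu threshold (or a numeric cutoff), hole
filling, 8-connected labeling, and a minimum-area filter (20 px²), which
stands in for the visual size confirmation used in manual counting.
Circularity is 4π·area/perimeter², accepting objects > 0.6 as cells.

The perimeter comes from the marching-squares contour of the object at the
0.5 level, with the contour vertices smoothed by a 5-point circular moving
average before measuring. A raw pixel-edge perimeter — or even the raw
marching-squares polygon, which staircases along diagonal boundaries —
overestimates the perimeter of a rasterized disc by 9–27% and would push
small round cells below the 0.6 rule; with smoothing, a radius-10 disc
scores ≈ 1.00 and a 30×3 bar ≈ 0.28. The estimator choice is a declared
parameter of the method, since circularity values are only comparable
under a fixed estimator. An optional Gaussian background subtraction is
available in place of vendor deconvolution preprocessing.

## Synthetic data

The generators emulate the assay conditions the analyses were designed
for; all randomness flows from a single integer seed through numpy's
PCG64 generator, so outputs are bit-for-bit reproducible.

- *Goal-directed escape*: the agent sits still facing away, completes its
  turn to the shelter bearing within the commanded onset delay, then runs
  a straight path whose speed follows a raised cosine from a 5 cm/s floor
  to `v_max` (default 60 cm/s), peaking at the path midpoint. The raised
  cosine is a modeling choice matching the qualitative description of
  shelter-directed flight (peak speed mid-path), not a measured profile.
  The nose is placed 1.5 cm ahead of the centre along the heading, the
  tail base 2 cm behind; positional jitter is Gaussian (default 0.1 cm).
- *Disorganized escape*: heading = shelter bearing + AR(1) noise
  (coefficient 0.9 per frame at 30 Hz; stationary sd 50° per unit of the
  `disorganization` parameter d, clipped at ±80° so radial progress stays
  positive and arrival is guaranteed given enough time), with speed
  collapsing as `v_max / (1 + 14 d)` — slow, meandering flights. The
  steep speed collapse encodes the observation that without a shelter
  memory flights are *slow* as well as tortuous, and it makes the
  generator's design properties hold with wide margins: mean linearity is
  strictly increasing and mean 9-s accuracy strictly decreasing across
  d ∈ {0, 0.5, 1, 2, 4}, and arrival within 9 s is rare for d ≥ 0.5 at
  the default 72-cm start distance. At d = 0 the generator recovers
  goal-directed statistics (straight, fast, accuracy 100).
- *Two-chamber occupancy*: a two-state continuous-time Markov chain with
  baseline leave rate 0.05 s⁻¹ (mean stay 20 s) and stimulated-chamber
  leave rate scaled by (1 + a) for avoidance strength a, giving the
  closed-form expected aversion index −a/(2 + a). Conditioning pairs plant
  a CPA shift δ by solving for the post-session avoidance whose expected
  index is the pre index plus δ.
- *Restraint*: i.i.d. Bernoulli movement samples at 10 Hz.
- *c-Fos images*: circular Gaussian-profile cells (radius 6 px) and
  capsule-shaped bars (30 × 4.5 px, aspect > 3) placed without overlap on
  a noisy background.

What the generators do *not* emulate: gait and body articulation, wall
following and thigmotaxis, tracking identity swaps, non-stationary chamber
preferences, out-of-focus or overlapping nuclei. Passing tests therefore
demonstrate that the estimators recover known ground truth under the
stated model, not that they are robust to every artifact of real video.

## Problem sizes and numerical choices

Simulated cohorts use 30 seeds per condition (50 for conditioning
recovery), 20-min two-chamber sessions at 30 Hz, 30-min restraint traces
at 10 Hz, and 256×256 ROI images; these sizes keep the full test suite and
the acceptance script to a few seconds while leaving the statistical
margins of the assertions wide. Comparisons against brute-force oracles
use 1e-9 absolute tolerance; analytic oracles (semicircle linearity,
rectangle circularity) use 0.5% relative tolerance to absorb raster and
sampling error. Ties in maxima break to the first frame; interval
boundaries are half-open; region boundaries count as inside.

## Known limitations

Single-animal, 2-D tracking only; jump/rearing/grooming scoring is out of
scope (no kinematic definition exists for them here); inferential
statistics are left to standard tools. The accuracy formula is reported
unclamped, so trials evaluated far from the shelter can score below 0%.
Freezing, latency and escape-run criteria are operationalizations of
verbal definitions and should be reported alongside results; the output
tables echo them for that reason.
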