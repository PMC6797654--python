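# Methods

## Scope and model

`nystcal` automates eye-tracker calibration in the presence of infantile
nystagmus (IN).  The core idea: foveation periods — the low-velocity part
of each nystagmus cycle when the fovea is on target — can be found on a
completely *uncalibrated* signal by a relative criterion (the slowest
fixed fraction of each cycle's slow phase), and their median position per
calibration target gives the point of regard (POR) from which a raw-units
→ degrees polynomial map is fitted.  No fixed velocity threshold and no
position window are used before calibration, so the criterion adapts to
each individual's waveform and intensity.

## Pipeline and parameters

All constants live in `PipelineConfig`; defaults reproduce the standard
five-point calibration protocol.

| parameter | default | meaning |
|---|---|---|
| `max_gap_ms` | 25 | longest tracking gap filled by cubic splines |
| `blink_pad_ms` | 75 | invalidated on either side of remaining gaps |
| `sg_window_samples_1khz` | 21 | Savitzky–Golay window at 1000 Hz (scaled with rate, forced odd), order 3 |
| `saccade_k` | 6 | quick-phase criterion: speed > median + k·MAD |
| `saccade_merge_ms` / `min_saccade_ms` | 10 / 10 | run merging / minimum duration |
| `foveation_fraction` | 0.10 | window length as a fraction of slow-phase duration per cycle |
| `min_foveation_ms` | 7 | windows shorter than this are disregarded |
| `skip_initial_ms` | 300 | settling time excluded at each target |
| `capture_threshold` | 0.85 | advisory data-quality floor (warning, not a gate) |
| `classic_velocity_thresh_deg_s` | 4 | post-calibration classic criterion |
| `classic_position_window_deg` | 0.5 | optional classic position band |

Recordings below 200 Hz are rejected: quick-phase dynamics are not
resolvable below that rate.

**Filtering.**  The Savitzky–Golay parameterization is a package design
choice: order 3, 21 samples at 1000 Hz, applied independently to each maximal valid segment
(no values are synthesized across gaps, so blink edges cannot leak into
the velocity estimate).  Segments shorter than the window pass through
unsmoothed with speed masked.  Spline gap-filling uses not-a-knot cubic
splines on up to ten valid samples per flank, which reproduces polynomials
up to cubic exactly.

**Detection speed.**  The two raw axes have different unknown gains, so by
default detection runs on the absolute speed of the primary axis (the one
with the larger position SD; IN is primarily horizontal).  A config option
(`speed_mode="magnitude"`) instead combines MAD-rescaled per-axis speeds
into a 2-D magnitude.

**Cycle splitting.**  Cycles are delimited by peaks of the primary-axis
position.  The peak criteria are deliberately scale-free: minimum peak
separation of half the dominant period (from the autocorrelation maximum
searched over 0.5–10 Hz) and minimum prominence of 0.2 × the position IQR.
Polarity is chosen automatically: the sign (peaks vs troughs) whose peaks
sit on slower samples is used, which places cycle boundaries on the
foveating side of the waveform; the post-peak extension rule then catches
boundary-straddling foveations.  Boundary samples belong to the cycle they
open (half-open `[peak_i, peak_{i+1})`).

**Quick phases.**  The detector is built around one hard requirement: it
must work without a precalibrated signal, i.e. on arbitrary units.
A sample is a candidate when speed > median + 6·MAD (invariant under any
positive rescaling of raw units).  Candidate runs within 10 ms of each
other merge only if speed stays above the median across the gap (a dip
below median means two separate events — this also keeps noise blips in
the fast tail of an accelerating slow phase from dragging the onset
backwards).  Runs shorter than 10 ms are discarded; survivors grow outward
to the nearest local speed minimum, stopping once speed falls below the
median.  On simulated jerk sessions, detected onsets/offsets agree with
ground truth to within ~3 ms.

**Foveation search.**  Every candidate start position advances one sample
at a time ("each possible window", taken literally; implemented with
cumulative sums, verified against a plain-loop exhaustive search).  A
window must consist solely of slow-labelled valid samples — hence lie
within a single slow run; a window straddling a quick phase would average
saccadic speed into a supposed foveation.  Windows may end up to one
window-length past the cycle's closing peak; samples claimed beyond the
boundary become unavailable to the next cycle, so no sample is assigned to
two foveations.  Ties in mean speed go to the earliest window.  Even
sample counts take the mean of the two central order statistics, per
coordinate.

**Calibration.**  Default model: per-axis linear with a cross-talk term
(3 coefficients per axis), fitted by ordinary least squares.  This is
exact for any affine raw map including rotation of the calibration field,
and is solvable from a five-point grid with two degrees of freedom to
spare; a full quadratic (6 terms) is enabled only with ≥ 6 targets.
Screen coordinates are centered, rightward/upward positive.  Drift
correction composes a pure translation with the model so the
foveation-based POR of a single-target recording maps exactly to that
target; gains and cross-talk are untouched.

## The simulator

The generator emulates the study protocol: monocular 1000 Hz recordings,
five targets at ±5° H / ±3° V shown 10 s each, the first 300 ms at each
target excluded.  Jerk cycles use an accelerating exponential slow phase
`x(t) = x_f + s·A·(e^{t/τ} − 1)/(e^{T_s/τ} − 1)` (τ = T_s/2 by default —
accelerating slow phases are the defining diagnostic feature) with a 30 ms
minimum-jerk quick phase back to target, so saccade detection sees a
realistic finite-velocity signal rather than an instantaneous reset; the
extended-foveation variant prepends a stationary plateau (60 ms default);
pendular waveforms are pure sines.  White Gaussian noise (0.05°-equivalent
SD by default) is added in degrees before the unknown raw transform
(per-axis gain and offset plus field rotation, defaults 30 and 25
units/deg, offsets 150/−90, 3°).  One blink per target (100–200 ms,
uniformly placed) inserts an invalid run with 20 ms, 3° position spikes on
both edges to exercise the 75 ms trimming.  Ground truth carries the
noiseless gaze, cycle boundaries, quick-phase intervals, the transform,
and per-cycle true foveations found by exhaustive search on the true
speed.

What it deliberately does not model: waveform-type changes with gaze
angle, periodic alternating nystagmus, pseudocycloid/pseudojerk forms,
torsion, pupil-size artifacts, tracker nonlinearity, or head motion.
Hypermetric (overshooting) quick phases exist as an option but are
excluded from the default studies.  Passing tests therefore demonstrate
correctness of the algorithmic contract and robustness to noise, blinks
and unknown affine/rotated raw frames — not clinical performance on real
recordings.

## Validation studies

The suite and `scripts/acceptance.py` recompute everything from scratch;
no empirical number is stored.  Study sizes exercise the full default
parameter grid:

* **Exhaustive-search agreement** — on ~150 cycles spanning A ∈ {2, 4, 8}°
  × f ∈ {2, 3, 5} Hz, the selected window must equal the brute-force
  minimal-mean-speed window in every cycle.
* **Calibration exactness** — noiseless rotated affine maps (0°, 5°, 10°)
  on the five-point grid; residuals are at machine precision (~1e−15°,
  asserted < 1e−6°).
* **POR recovery** — 50 seeded jerk sessions cycling the grid: median POR
  error ≈ 3.5% of amplitude (asserted < 5%), and the foveation-based
  method beats the nonselective whole-trace median in every session
  (asserted ≥ 80%).
* **Amplitude dependence** — sweeping A = 1–6° at f = 3 Hz, 20 seeds per
  amplitude: the nonselective error grows ≈ 0.28°/° of amplitude while
  the algorithmic slope is ≈ 0.015°/° (asserted positive vs < one third
  of the nonselective slope).
* **Pendular both-sides property** — on a sine session, foveations land on
  both the peak-side and trough-side extrema (the POR then falls on
  whichever side is selected most often; no stronger claim is possible
  from eye movements alone).
* **Sample-exactness** — the 25 ms gap bound, 75 ms pads, 300 ms skip,
  10% window length and 7 ms floor are asserted to the sample on
  constructed fixtures.
* **Classic closed form** — fixed-threshold foveation durations on a
  calibrated sine match `(2/2πf)·asin(v_th/2πfA)` to well under 2 ms.

## Numerical choices and degenerate inputs

* Window length rounds to the nearest whole sample (minimum 1); the 7 ms
  floor is applied to the rounded duration.
* Constant signals: no dominant frequency → empty cycle set; zero speed →
  no quick phases; downstream stages return empty results rather than
  erroring, except POR computation, which fails loudly naming the target.
* Rank-deficient calibration designs (identical PORs, collinear targets)
  raise instead of returning a garbage fit.
* Gaps at the very start/end of a recording cannot be spline-filled and
  stay invalid; blink pads are clipped at the boundaries.
* `trim_blinks` tags the samples it invalidates so re-application dilates
  only genuine tracker gaps (idempotence).
* All randomness is confined to the simulator and fully seeded; the
  pipeline itself is deterministic, so identical inputs and configuration
  give byte-identical outputs.

## Known limitations

* The quick-phase detector and cycle-splitting parameterization are this
  package's own designs; other implementations of the same contracts
  (unit-freeness, scale invariance) may differ at the sample level.
* Foveation identification is by definition "the slowest window": in
  waveforms where the true retinal foveation is ambiguous (e.g.
  pseudocycloid with hypermetric quick phases), the method returns the
  slowest window, which may disagree with an expert's marking.
* The percent-of-amplitude normalization uses the median per-cycle
  peak-to-trough amplitude; POR errors are Euclidean 2-D distances.
* Only monocular recordings, delimited-text and minimal EyeLink-ASC
  sample input are supported; binary vendor formats are out of scope.
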