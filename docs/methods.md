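# Methods

`limbkine` quantifies the two repetitive lower-limb items of the motor
examination of the MDS-UPDRS (part III): toe tapping (TT, item 3.7) and leg
agility (LA, item 3.8). The measurement model is a dual-IMU setup at 100 Hz:
a foot-mounted sensor providing the sagittal-plane foot angle (pitch,
degrees; negative = toes elevated) for TT, and an ankle-mounted sensor
providing vertical acceleration (m/s²) for LA. Signals are analysed raw —
no filtering, resampling or interpolation — because the sensor-fusion
orientation stream is already smooth and complete.

## Movement-cycle segmentation

Both tasks are segmented into cycles delimited by consecutive ground
contacts:

* **TT** — a contact (T_start / T_end) is a local maximum of pitch above
  `TH_TT = -3°`; a candidate cycle between two contacts is retained only if
  the pitch minimum in between (A_up, toes up) falls below `TH_TTup = -5°`.
* **LA** — a contact is a local maximum of vertical acceleration above
  `TH_LA = 20 m/s²`; no A_up is defined on this signal.

Numerical choices the threshold rules leave open:

* *Local maximum* means strictly greater than both neighbours; a plateau of
  equal samples resolves deterministically to its first sample. Endpoint
  samples are never maxima.
* Peaks closer than `min_peak_separation = 0.15 s` (a ≈ 6.7 Hz ceiling,
  far above observed tapping rates < 4.5 Hz) are debounced, keeping the
  higher peak; ties keep the earlier one. Cycles shorter than
  `min_cycle_duration = 0.15 s` are discarded.
* An incomplete trailing movement (a contact without a following contact)
  is discarded: a cycle needs both boundaries.
* Sub-threshold pauses mid-trial simply produce longer cycles.

Each cycle is labelled with the 5-s interval of its start,
`interval = floor(t_start / 5) + 1` (a start exactly on a boundary belongs
to the later interval); starts at or beyond 20 s get label 0 and are
excluded from interval-wise analyses. The same convention is used by the
generator, so ground-truth and detected labels agree exactly.

## Per-cycle parameters

For a cycle of duration `T` (contact to contact):

* frequency `f = 1/T`; the trial frequency is the median of cycle
  frequencies (consistent with 28 taps / 10 s ↔ 2.8 Hz);
* angle `A` = pitch at the starting contact minus pitch at A_up
  (peak-to-peak excursion, degrees; TT only);
* dimensionless jerk `DLJ = (T^5 / A^2) · ∫ (d³θ/dt³)² dt` over the cycle,
  and `LDLJ = ln(DLJ)` (TT only). High values mean irregular movement. The
  third derivative is taken on the raw pitch by three passes of central
  finite differences (fourth-order interior stencil, lower-order at the
  trial edges); the integral is trapezoidal. A cycle spanning fewer than 8
  samples yields a missing value, not zero. A pure raised-cosine cycle has
  the closed form `DLJ = (2π)^6 / 8 ≈ 7691.1` for every amplitude and
  period, which the implementation reproduces to well under 1% at 100 Hz
  and which sits at the scale of the observed healthy-cohort median
  (~7·10³);
* maximum vertical acceleration over the cycle (LA only);
* IAV, the integral of the magnitude of the free acceleration vector:
  `∫ ‖a(t) − a_static‖ dt`, with `a_static` the channel-wise median over
  the quiet window before the first contact (default mode
  `subtract_static`; `raw_norm` integrates the raw magnitude instead).
  Gravity subtraction puts the values on the ~6 (m/s²)·s scale of the
  reference table rather than the ~140 scale of raw-norm variants.

Per-trial aggregation uses the cycles starting in the analysis window
(first 10 s by default): the tap count, the median of each parameter, and a
variability index `100·(max − min)/median` per parameter. The median was
chosen as the variability denominator for robustness and consistency with
every other trial statistic; the max–min spread itself is fixed by the
definition of the index.

## Cohort statistics

Trial medians are pooled across all trials and participants, separately for
the dominant and non-dominant leg, into median, IQR (Q3 − Q1, type-7
linear-interpolation quantiles) and `%IQR = 100·IQR/median`, classified as
small (< 30%), moderate (30–59%), high (60–119%) or very high (≥ 120%).
Dominance differences are tested per parameter with a two-sided Wilcoxon
signed-rank test paired at the participant level (each participant's median
over their dominant-leg trials vs non-dominant-leg trials; trial-level
pairing is available as an option). Zero differences are dropped, ties are
midranked, and the null distribution is enumerated exactly (a convolution
over doubled midranks) up to 25 usable pairs, switching to a tie-corrected
normal approximation with continuity correction above. The exact
enumeration is implemented here because the scipy exact mode declines tied
data; scipy serves as an independent cross-check on tie-free inputs. No
multiple-testing correction is applied across parameters.

## Interval models

The amplitude decrement of toe tapping is modelled on per-(trial, interval)
medians over four consecutive non-overlapping 5-s intervals:

    angle ~ 1 + time,  random: (1 + time + dominance | participant),  REML

with `time` the interval index 1..4 (continuous) and dominance coded 0/1
(non-dominant reference; the balanced design makes the time slope invariant
to the coding). An analogous model is fitted for frequency. Responses are
interval medians rather than per-cycle values so that n reflects
trial-intervals, not taps. Fitting uses statsmodels' MixedLM; when the full
correlated random-effects structure fails to converge, a simplification
ladder is walked — (1) full, (2) uncorrelated random effects,
(3) drop the dominance random slope, (4) random intercept only — and the
rung used is recorded in the results. Exactly deterministic data (zero
residual variance), which breaks any REML optimizer, falls through to a
pooled OLS with all variance components reported as zero and the fit
flagged singular. A fit is flagged singular whenever the smallest
random-effect covariance eigenvalue is below 1e-6 of the largest.

Diagnostics export (values only, no plotting): Brown–Forsythe/Levene test
of residual variance across leg dominance (median-centred by default,
mean-centred via flag), variance inflation factors of the fixed-effect
columns (balanced dominance against linear time gives exactly 1), and
residual/fitted/normal-Q-Q value tables.

The per-cycle frequency–angle relationship over the full 20 s is summarised
by OLS of angle on frequency with R² classified as negligible (< 0.10),
weak (0.10–0.15), moderate (0.16–0.48), strong (0.49–0.79) or very strong
(≥ 0.80). For simple regression R² is orientation-invariant, so regressing
angle on frequency is a reporting choice only.

## Synthetic cohort generator

The study recordings are not redistributable, so the generator reproduces
the statistical structure the analysis assumes, with exact ground-truth
event tables for oracle testing. Defaults are the study conditions:
23 participants × 5 trials × 2 legs × 2 tasks, 20-s trials at 100 Hz.

**TT.** Pitch is a concatenation of raised-cosine dips,
`θ(t') = −A(1−cos(2πt'/P))/2`, zero (neutral) at contacts. A cycle starting
in interval `i` has mean amplitude `17.41° − 0.83°·i` and mean rate
`2.75 Hz − 0.02 Hz·i`, plus participant-level offsets and per-cycle
log-free jitter (CV 0.05 on both period and amplitude, truncated at ±3 SD).
Each trial adds a linear pitch drift with rate drawn from
N(−0.01, 0.11²) °/s — the observed gyroscopic drift statistics — and white
measurement noise. The white-noise SD defaults to 0.01°: the pitch channel
is the output of an onboard Kalman sensor-fusion filter and is smooth
sample-to-sample, and because jerk triple-differentiates the raw signal,
the noise floor is what anchors the DLJ scale; 0.01° keeps the synthetic
cohort median DLJ at the observed ~7–10·10³ (0.1°+ of white noise would
inflate it by an order of magnitude, contradicting the reference table).
The first contact occurs `start_offset = 0.03 s` into the trial behind a
quiet lead-in with a shallow entry dip, so the first contact is an interior
local maximum; the movement stops mid-dip after the last full cycle. Only
cycles whose closing contact rounds to an interior sample of the grid are
emitted, which is what makes noiseless ground truth and detection agree to
≤ 1 sample everywhere.

**LA.** Vertical acceleration is gravity baseline (9.81 m/s²) + a smooth
raised-cosine swing dip per cycle (3 m/s², the leg lift) + a narrow
Gaussian impact pulse at each contact. Contacts are spaced 1/2.6 Hz apart
(CV 0.05). `impact_peak` (default 123 m/s²) is the *total* peak
acceleration at contact, matching the reference LA_Acc scale directly; the
pulse width default of 0.02 s was set together with it so that the
per-cycle IAV lands at the reference ~6.1 (m/s²)·s. White accelerometer
noise SD is 0.5 m/s².

**Cohort.** Participant-level random effects are drawn once per participant
and shared across their trials: angle intercept SD 2.5°, angle slope SD
0.3°/interval, dominance offset SD 0.5°, frequency SD 0.25 Hz, LA impact SD
12 m/s². These between-participant SDs are not published; they are sized so
that (a) mixed-model recovery is feasible at n = 23 and (b) pooled trial
dispersion is in the range of the reference table (e.g. frequency IQR
≈ 0.5 Hz). The split between within-trial noise and between-participant
variance is a modelling choice the published aggregates do not pin down. A
configurable fixed dominance effect (default 0, matching the reported null
result) is added for the dominant leg on top of the participant's random
dominance offset. Dominant legs are right with probability 19/23. Reseeding
reproduces byte-identical files.

**What the generator does not emulate:** hesitations, freezing and other
PD-impaired movement profiles; fatigue or learning trends beyond the linear
interval model; non-linear or non-stationary drift; magnetometer effects;
footwear damping differences. Passing tests therefore demonstrate that the
pipeline recovers the assumed statistical structure from signals shaped
like healthy-cohort data — not that it is robust to pathological movement,
which the thresholds would need re-tuning for.

## Degenerate inputs and edge rules

* Recordings must be uniformly sampled to 1 µs tolerance with complete
  channels; durations outside 10–25 s are invalid, outside 19–21 s warned.
* Re-zeroing (`rezero_pitch`, software analogue of the pre-trial
  orientation reset) subtracts the median pitch of the first 0.5 s; it is
  idempotent and optional — generator output is already zero-referenced, so
  it is off by default in the pipeline.
* An empty analysis window yields a trial with 0 taps and missing features,
  not an error; an empty cohort group is dropped from the summary with a
  warning; all-zero Wilcoxon differences leave the test undefined (NaN p).
* Extreme drift draws (|rate| ≳ 0.15 °/s) can pull late contact peaks below
  `TH_TT` and drop late cycles — the same failure mode the hardware
  orientation reset exists to prevent; robust medians keep the cohort
  statistics stable under the default drift model.

## Problem sizes in the validation suite

The validation suite and the reproduction script use the full default
cohort (460 trials) for cohort medians, 20 regenerated cohorts for
mixed-model recovery, 50 single trials per task for tap counts, and 100
noiseless trials per task for the segmentation oracle. The type-I-error
calibration of the dominance test uses 120 replicates of a reduced
null cohort (12 participants × 3 trials × 10-s trials, toe tapping only);
test size is insensitive to these dimensions and the binomial acceptance
band accounts for the replicate count.

## Known limitations

* Cycle boundaries are grid-quantized (±half a sample), which propagates
  to per-cycle frequency (~±0.07 Hz at 2.6 Hz) and, through `T^5`, to
  per-cycle DLJ (up to ~±10%); medians over ~28 cycles absorb this.
* The exact supplementary formulas behind the published DLJ, IAV and
  variability values are not available; the implementations are constrained
  by the closed-form raised-cosine oracle and by consistency with the
  printed reference table, which bound but do not uniquely fix them.
* The reported R² (0.15/0.19), Levene p (0.356) and IQR magnitudes depend
  on the real cohort's variance structure and are matched only
  qualitatively (band classification) by the synthetic cohort.
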