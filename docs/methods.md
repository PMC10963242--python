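# Methods

## Scope and model

`ppg2bp` estimates SBP, MAP and DBP (mmHg) from single 2.1-s, 1-kHz
fingertip PPG segments. The estimation model is feature-based: one best
beat per segment is reduced to a 48-slot vector of morphological,
derivative-based, spectral and demographic features, a per-target subset
is selected, and a nonlinear regressor maps features to pressure. MAP is
defined throughout as (2·DBP + SBP)/3. The package assumes segments are
short, roughly stationary, and contain at least three systolic peaks;
arrhythmia and ectopic-beat handling are out of scope, as is any
pulse-transit-time or calibration-based approach.

## Quality screening

The SQI is the population (biased) third standardized moment of the
segment's amplitude distribution; this estimator form is pinned by a
brute-force moment oracle in the tests and is switchable to the
bias-corrected form. The screening threshold defaults to 0.0 — clean PPG
pulses are right-skewed, while flat lines (flagged separately with a
`zero-variance` reason), inverted probe artifacts and blunt notch-less
waveforms skew at or below zero. The threshold that produced the original
study's 218-of-657 kept segments was never published; 0.0 is a calibrated
stand-in, exposed as a parameter everywhere screening is invoked, and the
657 → 218 re-enactment in the tests constructs its quality mix by design
rather than claiming to reproduce the original cut-off.

## Preprocessing

Min-max normalization to [0, 1] precedes filtering; the order
matters only for documentation since both are linear. Four low-pass
families are provided; the 7th-order Butterworth is the default and is
applied forward-backward (zero phase) so fiducial *times* are unshifted —
an error of a few milliseconds in t1 or t2 is a feature error of several
percent. The cutoff defaults to 12 Hz: the acquisition hardware the data
format derives from band-passed at 0.5–12 Hz, making 12 Hz the defensible
ceiling. The moving-average window is sized to put the boxcar's first
spectral null at the cutoff; the FIR path uses an odd-length symmetric
windowed-sinc kernel; the DWT path (db4) soft-thresholds the detail
levels whose bands lie above the cutoff with the universal threshold.
Baseline drift below the passband is *not* removed: normalization and
per-cycle analysis absorb slow drift, which is a documented limitation
rather than an accident. Records are normalized per-record, not
per-cycle.

## Cycle detection and selection

Systolic peaks are prominence-gated local maxima (prominence ≥ 0.1 on the
normalized scale, separation ≥ fs·60/180 samples, i.e. a 180-bpm
ceiling). Cycles run valley-to-valley: an onset is the minimum between
consecutive systolic peaks, so a complete cycle needs an in-record valley
on both sides and a 2.1-s segment yields one or two complete cycles at
resting rates. The best cycle is the one with the largest systolic
amplitude *above its own onset value* (robust to residual drift); ties go
to the earliest beat.

## Features

The 48 slots split 21 (PPG waveform) + 8 (first derivative) + 11 (second
derivative) + 6 (FFT) + age + gender (female = 0, male = 1). Conventions
that the loose symbols of the field leave open, fixed here:

* Landmark amplitudes x (systolic), z (notch), y (diastolic) are measured
  above the cycle-onset baseline; times from the cycle onset.
* The notch is the most prominent local minimum in
  (t1, t1 + 0.6·(tpi − t1)); the window keeps end-of-cycle troughs out of
  reach. Fallback: the maximum of the smoothed second derivative in the
  same window. The diastolic peak is the first local maximum after the
  notch whose prominence exceeds 2% of the cycle range (the gate keeps
  residual filter ripple from masquerading as the diastolic wave);
  fallback: the strongest inflection after the notch. A cycle whose
  fallback chain produces a "diastolic" point *below* the notch has no
  real notch and is rejected with a distinct error, mirroring the
  screening observation that unfit waveforms lack dicrotic notches.
* `ta1/tb1/te1/tl1` and `ta2/tb2` are absolute times from cycle onset;
  the named slot 23 ("elapsed time between a1 and b1") is tb1 − ta1 while
  the ratio slot 27 uses the absolute valley time. l1 is the last
  downward zero-crossing of the first derivative (the cycle-closing
  landmark, interpolated between samples); l2 is the cycle start.
* The second derivative is smoothed with an 11-sample moving average
  before landmark detection *and* amplitude read-out (double
  differentiation amplifies noise); the window is configurable.
* Slot 14 is the inflection-point area ratio A3/(A1+A2) as canonically
  defined; because parts of the selection literature label slot 14
  "A2/A1", that simple ratio is emitted as an auxiliary named feature so
  rankings can be mapped either way. Slot 15 implements the formula
  (A2+A3)/A1, not its prose gloss.
* Slot 16 ("systolic peak rising slope") is t1/x exactly as tabulated;
  the physically sensible x/t1 is available behind
  `slope_convention="physical"`.
* Slot 17's denominator (tpi − t3) is guarded: cycles with the diastolic
  peak within 5 ms of the cycle end are rejected rather than emitting
  near-infinite values.
* The width w is the full width at half the (baseline-corrected) systolic
  amplitude with sub-sample linear interpolation at both crossings; areas
  A1/A2/A3 are trapezoidal integrals of the baseline-corrected cycle
  split at t1 and t2.
* Spectral features come from the *full* segment (a single 0.8-s cycle
  cannot resolve harmonic structure at ~0.5-Hz spacing): magnitude FFT of
  the mean-removed record at the next power-of-two length, no window.
  The fundamental is the largest prominent local maximum in 0.5–12 Hz;
  the 2nd/3rd components are the next prominent local maxima above it in
  ascending frequency, with a prominence floor of 5% of the fundamental
  so zero-padding ripple is not counted. Peak-bin magnitudes carry
  rectangular-window scalloping error of up to ~10% for off-grid
  frequencies; the frequencies themselves are accurate to one bin.

## Feature selection

**CFS.** For every unordered instance pair, the response difference
Ey = y_i − y_j is paired with the signed feature-space distance
EX = sign(Ey)·sqrt(mean_k (X_ik − X_jk)²) over the candidate subset
(features standardized first — the slots mix seconds, ratios and
magnitudes, and raw distances would be unit-dominated). The fitness is
the Pearson correlation of EX with Ey; selection is greedy forward
search, stopping at a configured size or when the improvement falls below
1e-4, with ties broken toward the lower canonical index. Note that the
sign coupling gives even an *independent* feature a positive null
baseline (≈ 0.63 at n = 200, verified against a literal pairwise
enumeration); the search relies on the gap above that baseline, not on
the absolute value.

**ReliefF.** Weights start at zero and accumulate
(diff(R, M) − diff(R, H))/m over m sampled target instances R (default
m = n), with H/M the nearest hit/miss by Euclidean distance over all
[0, 1]-scaled features and k = 1 neighbor by default, matching the
single-neighbor update rule. Blood pressure is continuous, so "same
response" is defined by quantiles of the response-difference distribution
(hits ≤ 10th percentile, misses ≥ 90th); the per-feature diff is the
range-normalized absolute difference (a 0/1 equality diff at tolerance
1e-9 is available, and a regression-style mode that signs each neighbor's
contribution by its response difference sits behind `mode="rrelieff"`).
Default subset sizes are the published ones: CFS 15/16/16 and ReliefF
15/16/15 for SBP/MAP/DBP.

## Regression and validation

Estimator internals are delegated to scikit-learn, configured with the
published hyperparameters: SVR(RBF, C=100, ε=0.1);
RandomForestRegressor(150 trees, absolute-error criterion, depth ≤ 13);
DecisionTreeRegressor(absolute-error, min leaf 17, depth ≤ 12, min split
5); KNeighborsRegressor(K=51, leaf size 45, Euclidean) with K clamped to
n_train − 1 (with a warning) on small cohorts. Splitting is by subject:
a deterministic seed-driven shuffle puts 20% of subjects in the test set
and deals the rest into 10 CV folds; every segment of a subject stays on
one side. Features are standardized *inside* each training fold (fit on
train, applied to validation/test) since the RBF kernel and Euclidean
neighbors are scale-sensitive and global scaling would leak. An optional
hyperparameter grid is scored by mean CV MAE over the folds; the final
model refits on all training rows. Each segment is one instance;
held-out predictions can be reported per segment (default) or averaged
per subject.

## Evaluation

Errors are BP_actual − BP_estimate; ME is their mean and STD their
n−1-denominator standard deviation about ME; R² is computed about the
mean of the actual values and reported as NaN when they are constant.
AAMI passes iff |ME| ≤ 5 mmHg, STD ≤ 8 mmHg and ≥ 85 subjects, all
boundaries inclusive. BHS grades by the cumulative percentage of absolute
errors within 5/10/15 mmHg against A = (60, 85, 95), B = (50, 75, 90),
C = (40, 65, 85), inclusive; below C is "D". Bland-Altman uses
differences estimate − reference with limits md ± 1.96·sd and reports the
fraction of points inside.

## The synthetic generator

Each beat is the sum of three Gaussian bumps (systolic, notch shoulder,
diastolic). The six free parameters (three amplitudes, three centers) are
solved with a root finder so the rendered waveform has the configured
*value and zero slope* at each landmark: the systolic/diastolic peaks are
true local maxima at (t1, x) and (t3, y) and the notch a true local
minimum at (t2, z). Default widths (σ = 0.09/0.06/0.14 of the pulse
interval) were chosen so this topology holds across the whole morphology
range the cohort map produces; the wide diastolic decay also makes the
inter-beat valley V-shaped, so "minimum between peaks" is a
well-conditioned onset definition under noise. Beats tile at
60/heart-rate seconds with one virtual beat rendered before and after the
record, making the segment a window into a continuous train; ground truth
lists only complete valley-to-valley beats, with landmark positions
refined to the rendered waveform's actual extrema (neighboring-bump tails
shift them by ≲ 1 ms from their nominal spots).

Cohorts emulate the study population: age 57 ± 15 years, ~48% male,
SBP ~ N(127, 20) clipped to [80, 174] mmHg (partially age-driven),
DBP ~ N(71, 11) clipped to [42, 104], pulse pressure ≥ 20 mmHg. Beat
morphology is a deterministic monotone map of the subject's latent BP —
heart rate and the augmentation ratio y/x rise with SBP, the systolic
time fraction falls with it; notch depth z/x rises and notch timing falls
with DBP — plus small per-segment jitter modeling beat-to-beat
variability (the original subjects' variability is unpublished; this
model is our own). The heart-rate floor of 68 bpm guarantees at least
three systolic peaks, hence one complete cycle, in every 2.1-s segment.
Reference labels add N(0, 3 mmHg) measurement noise to the latent BP, so
a perfect estimator's test MAE floor is ≈ 2.4 mmHg. Default record noise
is mild baseline drift (0.05 units at 0.25 Hz), 50-Hz mains pickup (0.02)
and white noise (sd 0.01) on a unit-amplitude pulse. Unfit segments are
injected by inverting the waveform about its mean — a probe-contact
artifact that exactly negates the skewness.

What the generator does *not* emulate: respiratory amplitude modulation,
heart-rate variability within a segment, motion artifacts, pathological
morphologies, and any physiologic coupling beyond the documented
monotone map. Passing recovery tests therefore demonstrates that the
chain is self-consistent and noise-robust under these conditions, not
that the published real-data accuracy transfers; reproducing real-data
result tables requires the public dataset and is supported only as an
integration path (`ppg2bp extract --data <dir>`).

## Numerical choices and degenerate inputs

One pipeline seed fans out (via a seeded generator) to cohort synthesis,
splitting, selection and model randomness; identical seeds give
bit-identical artifacts. Constant segments are unfit with a distinct
reason rather than an exception; constant features carry zero ReliefF
weight exactly; zero-variance pairwise distances make the CFS fitness a
defined 0 with a warning; undefined feature ratios raise an error naming
the slot; records whose landmark chain fails are logged and excluded
rather than aborting the cohort. Problem sizes in the test suite (100
records for landmark recovery, 100 seeded runs for planted-feature
recovery, 150 subjects x 20 seeds for the end-to-end checks, 440
subjects in the acceptance script so the AAMI subject criterion is
decidable) were chosen as the smallest scales at which the corresponding
statistics are stable.

## Known limitations

* The skewness threshold is a stand-in, not the original study's cut-off.
* Drift below the passband is absorbed, not removed; extreme drift can
  still distort the best-cycle choice.
* Slot 16 is implemented as printed (t1/x) although the physical rising
  slope is x/t1; the switch is documented above.
* ReliefF's 0/1-style diff on a discrete feature (gender) inflates its
  weight relative to continuous features; this is inherent to the method.
* Single-beat features: no template averaging, so beat-to-beat jitter
  propagates directly into the feature vector.
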