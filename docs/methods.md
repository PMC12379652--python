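# Methods

This note documents the models, operational definitions, numerical choices
and limitations behind `cardiomag`.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

A recording is a samples x channels matrix in picotesla from a planar
rectangular sensor array (default 8 x 8, 4 cm pitch, 500 Hz).  Processing
follows the standard MCG chain:

1. **Band-pass filtering** 0.3-100 Hz, zero-phase forward-backward
   Butterworth (order 4 per direction), after linear detrending.  The
   0.3 Hz pole rings over seconds, so `filtfilt` padding is extended to
   ~3/f_low (and to the full signal length for single beats); the default
   padding would leak edge transients into the analysis window.
2. **Beat detection** on the instantaneous cross-channel RMS of the
   1 Hz-high-passed signal: adaptive threshold at 40% of the trace's 98th
   percentile with a 200 ms refractory period.  The QRS-to-T amplitude
   ratio of the generator (~5:1 in RMS) keeps T waves safely below this
   threshold.
3. **Averaging** registers beats on the detected R peak over a
   [-300 ms, +600 ms] window; the window end is clipped to the median RR
   interval minus 120 ms so the next QRS never enters the representative
   beat.  Out-of-bounds beats are dropped with a warning.
4. **Isoline correction**: band-pass filtering removes each channel's time
   average, which offsets the diastolic baseline by the beat's net
   time-integral.  Each channel is re-referenced to its mean over the
   pre-QRS window (beat start to 120 ms before the R peak) — the isoline
   at the beginning of the QRS complex.

## Segmentation

All fiducials are located on the RMS reference R(t) (0-based sample
indices, closed intervals).  Because sensor noise adds to R(t) in
quadrature, the noise floor (10th percentile of the smoothed trace) is
removed as `sqrt(max(R^2 - floor^2, 0))` before thresholding.

- `qrs_beg`, `qrs_end`: interpolated crossings of 5% of the QRS peak on
  either side of the dominant lobe (fraction configurable).
- `t_max`: R(t) argmax within 80-400 ms after `qrs_end`, on a ~60 ms
  Savitzky-Golay-smoothed trace (the T lobe is low-amplitude and broad).
- `t_beg`: steepest upstroke (Savitzky-Golay derivative) of the lobe that
  rises into `t_max`, searched after the last local minimum of R before
  the T peak.  The restriction matters for diseased beats, where an ST
  injury-current bump would otherwise masquerade as the T upstroke.
- `t_end`: interpolated return of R below 5% of the T peak after `t_max`.

Flat traces, monotone ramps and beats without a T lobe raise a
segmentation error rather than returning nonsense indices.

Against the generator's ground truth (the same operational definitions
evaluated on the noiseless beat), the segmenter recovers all five
fiducials within +/-2 samples on >= 95% of 200 seeded beats at default
noise; this is asserted by the test suite.

## Field maps and indices

The monopolarity index of a snapshot is the normalized absolute sum
`M = |sum B_n| / sum |B_n|`; an all-zero snapshot carries no imbalance
evidence and is defined as M = 0 (logged).  A `mean_square` variant
(`(1/N) sum B_n^2`) exists behind a switch for completeness; it is
unbounded and never the default.  Inside the MIG layer the same variant
choice applies, resolving the ambiguity between the two published forms in
favour of the bounded one.

Maps are interpolated with a bicubic spline on the regular lattice,
refined 4x, so pole localisation precision is a quarter of the sensor
spacing.  Pole positions live in interpolated-map space; distances are
reported in millimetres.  The pole axis is treated as undirected (angles
folded to 180 degrees) because extrema labelling can swap between frames;
the maximum pairwise folded angle difference is therefore bounded by 90
degrees.

## Dipole inversion

The forward model is a point current dipole `Q = (qx, qy, 0)` at depth
`d` below the array (default 60 mm), field `B = mu0/4pi (Q x r)/|r|^3`,
measured in one Cartesian component.  The default component is the normal
(`z`) one: that is what produces the classic balanced two-pole map of a
tangential cardiac dipole, and what the package's own dipolarity logic
assumes.  (The reference instrument is described as measuring tangential
fields; the component is configurable, and none of the derived indices
depend on the convention because they are scale- and pattern-normalized.)

Inversion is linear least squares for the moment on a coarse candidate
position grid (default 5 x 5 over the array hull, fixed depth), keeping
the best-residual candidate.  Kernels and pseudo-inverses are precomputed
per (grid, depth) and the fit is vectorised over time samples.  The fitted
magnitude is exactly linear in the data; position is quantised to the
candidate grid, which is sufficient for the trajectory-closure (VMCG) and
moment-dynamics parameters but is not a source-localisation method.
Moment-slope parameters are exported in units of 1/3 uA*m/s so cohort
tables sit at a readable magnitude; the scale is a units convention, not a
fit.

## Scores

Raw parameters are z-scored against a healthy reference distribution
shipped as package data (`data/score_reference.yaml`, frozen from a
50-subject healthy synthetic calibration cohort, rest and stress pooled).
A component scores points when |z| strictly exceeds graded cut-offs
(1.96, 2.58, 3.29); values exactly at a cut-off score nothing.  Default
allocation: ST-T analysis 3 (one point per component: moment dynamics,
pole distance, angle dynamics), T-dispersion 3, VMCG 2, PLP 2 — summing to
10 per phase.  VMCG and PLP are enhancers: they enter the total only if a
main parameter has at least one point.  A total of >= 2 is pathologic.
Real-device deployments must substitute their own calibration constants;
the shipped ones encode the synthetic world.

T-dispersion is a composite: 10 x (IQR / median of per-channel |B_n| at
`t_max`, clipped to [0, 3]) plus the standard deviation of per-channel
T-peak latencies in ms / 10.  Latencies are measured only on channels
whose T-peak amplitude reaches 25% of the strongest channel: channels at
the dipolar field null have noise-dominated argmax positions, not
latencies.  Both weights and the floor are arguments.

## MIG layer

`I(t) = R(t)(1 - M(t))` and `J(t) = R(t)M(t)` by pointwise product — the
interpretation consistent with "index x RMS" parameter naming and with
segment-wise averaging; conservation `I + J = R` holds to 1e-12 and is
property-tested.  A full-discrete-convolution variant (cropped to input
length) is selectable.  Calcium Release Velocity applies the same
convex-slope operator as Current Moment Increase to I(t) on
[`qrs_end`, `t_max`]; a sample is locally convex when the second
difference is >= 0, and the result is 0 when no convex sample has positive
slope.  The name is a physiological label for the putative intracellular
calcium flux component; no ionic current is literally measured.

## Statistics and classification

- Mann-Whitney U: exact enumeration p when n1 + n2 <= 12 without ties,
  otherwise the tie-corrected normal approximation (scipy).
- Benjamini-Hochberg step-up via statsmodels.
- Stepwise LDA: forward selection on the Wilks'-lambda partial
  F-to-enter; the entry level (default 0.05) is Bonferroni-corrected for
  the number of candidates at each step, so the null probability of
  selecting anything stays near the entry level regardless of how many
  features are screened (without this, screening ~30 features would admit
  a noise feature in roughly half of null cohorts).  Empty selection is a
  valid flagged outcome.  The discriminant itself is a two-class
  pooled-covariance LDA with equal priors and a ridge of 1e-8 x trace
  (plus an absolute floor) so that a discrete score that separates the
  classes perfectly — zero within-class variance — still yields a finite,
  correctly oriented rule.  Decision threshold: posterior 0.5.
- LOOCV refits the discriminant for each held-out subject.  Feature
  selection is frozen by default (the common, optimistic reporting
  protocol); `reselect` re-runs selection per fold.
- AUC by pairwise concordance with half credit for ties
  (trapezoid/scikit-learn), CI by stratified bootstrap (2000 resamples,
  default seed 20250825).
- Box's M through pingouin, guarded by explicit sample-size and
  singularity checks.

## Synthetic generator

Each beat is synthesised in field space from the Biot-Savart forward
model:

- **QRS**: a strong dipole (3 uA*m) at the array centre whose orientation
  sweeps 180 degrees across a 15 ms-sigma Gaussian envelope — a rotating
  depolarisation front.
- **T wave**: a slower dipole (sigma 42 ms at RR 0.857 s, scaling with
  sqrt(RR)) with fixed orientation, placed off-centre (+3.5, -2.5 cm):
  the truncated map of an off-centre source has the moderate monopolarity
  (~0.18) that healthy repolarization maps actually show, rather than a
  perfectly balanced pattern.  Per-channel latency jitter ~ N(0,
  `t_peak_jitter_ms`) models repolarization dispersion.
- **Injury current**: a spatially diffuse single-sign Gaussian patch
  (sigma = 3 sensor spacings) active over the ST segment (plateau phase),
  energy-matched to the dipolar T wave over ST-T so that
  `injury_current_fraction` is exactly its share of ST-T field energy.
  Monopolarity of ST-T maps is monotone in this fraction (tested).
- **Sensor noise**: additive white Gaussian, default 0.15 pT per sample
  and channel.
- **Cohort structure**: per-subject heart rates ~ N(phase mean, 10 bpm);
  per-subject seeds derive deterministically from (master seed, subject
  index, phase) so any subject regenerates in isolation; recordings tile
  the subject's beat at fixed RR.

Phenotype defaults (`data/phenotypes.yaml`) encode the healthy-vs-CAD
contrasts: CAD-like subjects have reduced T amplitude (x0.58), injury
fraction 0.38, 7 ms latency jitter, and a blunted stress heart rate
(85 vs 103 bpm) with no stress T-amplitude gain.  Healthy subjects carry
no injury current — that is what makes it an injury current.  Magnitudes
were chosen once so that cohort means of heart rate, moment dynamics and
calcium release velocity land in the range reported for real cohorts;
they were not adjusted afterwards.

**What a green test does and does not establish.**  The generator omits
torso volume-conductor effects, respiration and movement artefacts,
arrhythmic beats, RR variability within a recording, and any coupling
between parameters beyond the phenotype dials.  Effect sizes are strong
by construction, so perfect LOOCV separation on synthetic cohorts says
the pipeline preserves the information the generator put in — it is a
scaled-down analogue of, not a substitute for, clinical performance
figures, which require patient data this package does not ship.

## Degenerate inputs and tie-breaks

All-zero snapshots: M = 0 with a warning.  Constant maps: poles flagged
degenerate with a first-index tie-break.  Thresholds use strict
inequalities (values at threshold score 0).  Empty segments, single-class
folds, singular covariances and sub-minimum windows raise errors rather
than degrade silently.  A failed subject in cohort extraction is recorded
in a failures table and the run continues.
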