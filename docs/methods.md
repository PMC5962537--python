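# Methods

## Overview

`wristml` classifies free-living human behaviour from wrist-worn tri-axial
accelerometer data.  The recording is cut into non-overlapping 30-second
epochs; each epoch is summarised by 126 time- and frequency-domain features;
a balanced random forest votes on one of six behaviour classes per epoch
(sleep, sit/stand, walking, vehicle, mixed activity, bicycling); a discrete
hidden Markov model re-decodes the predicted sequence using empirically
estimated transition and emission distributions; and an eleven-class twin
of the same machinery converts marginal state probabilities into a
metabolic-equivalent (MET) energy-expenditure estimate per epoch.

Because no annotated free-living dataset ships with the package, every
stage is validated on synthetic cohorts whose generating process is known,
by parameter recovery and by oracle comparison.

## Signal preparation

Input streams are linearly interpolated onto a uniform 100 Hz grid spanning
the original time range.  Calibration is a six-parameter sphere fit: means
of stationary 10-s blocks (per-axis SD < 13 mg) should lie on the unit
gravity sphere, so per-axis gain and offset are chosen by least squares to
minimise `sum_i (||g * m_i + o|| - 1)^2`.  The fit is attempted only when
at least 10 sufficiently distinct stationary orientations exist (pairwise
distance >= 0.05 g); otherwise, or when the RMS residual is >= 0.01 g, the
recording is passed through unchanged and flagged, which later fails the
quality check.  This is a deliberate simplification of full device
calibration (no temperature term, no time drift).

Movement magnitude uses ENMO: `max(0, ||a|| - 1)` per sample, in g.  ENMO
is the only gravity/noise-removal transform applied; no additional
band-pass filter is used.  Trailing partial windows are dropped (and
logged) rather than padded, because the feature contract requires exactly
3000 samples; epoch intervals are half-open `[start, start + 30 s)`.

## The 126 epoch features

Ten groups (A-J, enumerated in `wristml.features`): ENMO moments (12); ENMO
FFT magnitudes at 1-15 Hz (15); per-axis mean/range/SD (9); per-axis FFT
magnitudes at 1-15 Hz (45); cross-axis covariance and correlation (6);
roll/pitch/yaw mean/SD/range (9); ENMO spectral summaries — dominant and
second-dominant frequency and power, total power, spectral entropy (6);
per-axis dominant frequency and power (6); ENMO band power in fifteen
1-Hz bands (15); per-axis total power (3).

Conventions, chosen once and fixed: the window mean is subtracted before
the FFT, no taper, magnitude `|DFT|/n`, "magnitude at f Hz" is the bin
nearest f (resolution 1/30 Hz); power is squared one-sided magnitude;
dominant-frequency search excludes the DC bin and an all-zero spectrum
reports 0; spectral entropy is in nats; "mean power deviation" is the mean
squared deviation of ENMO from its epoch mean and "mean amplitude
deviation" the mean absolute deviation; roll = atan2(y, z), pitch =
atan2(-x, sqrt(y^2+z^2)), yaw = atan2(y, x) (yaw is not identifiable from
gravity alone; the convention is declared for completeness).  Degenerate
statistics (CV at zero mean, skew/kurtosis/correlation of a constant
series) are defined as 0 so trees never see non-finite values.  Epochs
containing non-finite samples yield an all-zero vector flagged invalid.

Internally the element-wise arithmetic runs in float32 for speed; numpy's
pairwise reductions keep means and variances accurate to well below any
tolerance used here, and the returned matrix is float64.

## Balanced random forest

With `n_rare` the size of the rarest class in the training labels, each
tree receives a balanced bootstrap — `n_rare` rows drawn with replacement
from every class — and a random subspace of `floor(sqrt(F)) = 11` features
drawn without replacement.  The subspace is fixed per tree, not resampled
per node (a per-node variant is the more common random-forest construction;
the per-tree reading is implemented deliberately and the config exposes
`features_per_tree`).  Trees are CART (Gini impurity, best-split threshold
search at midpoints, grown to purity unless `min_leaf` intervenes); the
CART growth itself is delegated to scikit-learn, after which each tree is
converted to plain arrays and all prediction uses the package's own
vectorised traversal, so in-memory and deserialised models share one code
path bit for bit.

A tree votes one-hot; forest probabilities are votes normalised by the
tree count; the predicted class is the argmax with lowest-index
tie-breaking.

Out-of-bag (OOB) estimation: for every training row, votes are aggregated
over only the trees whose bag excludes that row; the row-normalised matrix
of (true class, OOB-predicted class) counts estimates p(predicted | true)
without a held-out set.  Rows with no OOB tree are excluded with a
warning; a class losing all rows raises (grow more trees).  OOB
aggregation is hard-label (row-level argmax) because the HMM observes
discrete predicted classes.

## Hidden Markov time smoothing

Hidden state = true behaviour, observation = forest prediction, both on
the 30-s epoch grid.  Transitions are bigram counts within training label
sequences, row-normalised; counts never cross subject or wear-bout
boundaries, and a state with no outgoing counts gets a one-hot
self-transition.  Structural zeros ("forbidden transitions") are preserved
exactly — no decoded path may use them.  The emission matrix is the OOB
confusion matrix; its zeros, being finite-sample artefacts rather than
structural, are floored at 1e-6 and rows renormalised so no single
observation can make a whole sequence impossible.  The initial
distribution, unspecified by the method's description, is the empirical
class prevalence of the training labels.

Viterbi decoding runs in log space with explicit -inf for zero
probabilities and lowest-index tie-breaking at every backtrack step.
Forward-backward marginals use scaled recursions; the backward pass is
renormalised by its own sum each step (any per-step scalar cancels in the
per-epoch renormalised marginals), which prevents overflow for states with
negligible forward mass.  Decoding is per contiguous wear bout; sequences
never span non-wear gaps.  Both programmes are verified against exhaustive
path enumeration on hundreds of random small models.

## MET prediction

The eleven MET-relevant labels (bicycling, gym, sitstand+activity,
sitstand+lowactivity, sitting, sleep, sports, standing, vehicle, walking,
walking+activity) get a second forest + HMM trained by the identical
machinery.  A class's representative MET is the arithmetic mean of the
distinct (activity, MET) pairs that built it (a duration-weighted mean over
training records is available by flag; the unweighted mean is the
default).  Epoch MET = sum_k (marginal probability of state k) x (MET of
class k) — a convex combination, so every epoch lies between the scheme's
extremes — and MET-hours/day = sum over the day of epoch MET x 30/3600.
No MET compendium table ships with the package; MET values are inputs
(simulator parameters, or user annotations).

## Non-wear and quality control

An epoch is stationary when every axis SD < 13 mg; maximal runs of >= 120
consecutive stationary epochs (60 min) are non-wear.  The 13 mg threshold
is a declared convention (configurable).  Non-worn stretches of per-epoch
quantities are imputed with the mean of the same 30-s time-of-day slot on
the other days' worn epochs; with no donor the epoch stays missing and is
flagged.  Inclusion requires: wear >= 72 h (inclusive), worn data in every
hour of the 24-h cycle (local clock, no timezone arithmetic), mean vector
magnitude (mean ENMO over worn epochs) <= 100 mg, successful calibration,
and a clipped-sample fraction <= 0.01 (clipped: any axis |a| >= 7.96 g,
just inside the device's +/-8 g range).

## Evaluation

Leave-one-subject-out: for each held-out subject, forest, OOB emissions,
transitions and MET scheme are estimated on the remaining subjects only.
Scoring is at the 30-s epoch level: Cohen's kappa (with the convention
that two constant, equal raters score 1 with a warning) before (raw forest
argmax) and after (Viterbi) smoothing; row-normalised confusion
percentages; daily MET-hours RMSE and Pearson r against the generator's
truth.  Minute-level confusion aggregates the two epochs of each minute by
majority vote with first-epoch tie-break (a declared convention).
Bland-Altman daily limits use the sample SD (ddof = 1) of differences and
bias +/- 1.96 SD; Cohen's d uses the size-pooled SD.

## The synthetic cohort generator

Behaviour labels follow a first-order Markov chain at epoch resolution.
The default chain has realistic dwell times (sleep bouts of hours, vehicle
bouts of ~15 min), structural zeros (e.g. sleep never jumps directly to
walking, vehicle or bicycling), and a stationary distribution in which
bicycling is rare (~4%) — the class imbalance the balanced forest exists
for.

Per class, the signal model is: a gravity orientation, an optional
sinusoid oscillating *along* that orientation (so the ENMO fundamental
sits at the profile's frequency), and white noise.  On top, per-epoch
jitters make the classes overlap the way free-living data do: small-angle
orientation wobble, lognormal amplitude jitter, Gaussian frequency jitter,
and a rest probability — the chance that an epoch of the class is
motionless.  Vehicle shares sit/stand's posture and is at rest 45% of the
time (a stopped car is just sitting), which makes that pair irreducibly
confusable at the epoch level; this is deliberate, because a perfectly
separable cohort would make the smoothing stage vacuous.  These defaults
were fixed at design time to produce a raw-forest kappa around 0.9 with a
visible smoothing gain, and are not adjusted thereafter.

Each epoch also draws a fine activity from the class's mixture — the fine
labels are exactly the eleven MET classes, with compendium-style MET
values as generator parameters — giving a per-epoch ground-truth MET.
Non-wear episodes (Poisson per day, 75-180 min) freeze the signal at a
random orientation, exactly constant, so the stationarity rule must fire.
Subject i of a cohort uses derived seed `seed + i`; all outputs are
bit-reproducible for a fixed seed.

What the generator does **not** emulate: biomechanics (gait harmonics,
device ringing), device-specific noise spectra, temperature drift, diurnal
structure in the chain (no time-of-day dependence), or annotation noise in
the labels.  Passing tests therefore demonstrate the correctness and the
statistical behaviour of the machinery under its own assumptions, not
field performance on any real cohort.

## Problem sizes and numerical choices

The reference evaluation cohort is 12 subjects x 24 h (34,560 epochs,
104 M samples); the smoothing-direction check runs ten replicate cohorts
of 12 subjects x 6 h each, chosen so the full suite completes in minutes
on a single CPU.  Forests in the end-to-end runs use 30-50 trees — tree
count has little effect beyond saturation here, as the monotone-ensemble
test confirms.  Stochastic-matrix rows are validated to 1e-9; HMM oracle
agreement to 1e-10; emission flooring at 1e-6; Viterbi ties break to the
lowest class index; the transition-recovery tolerance (L-inf 0.05 at 1e5
epochs) reflects binomial error in the rarest row.

## Known limitations

- The 126-feature list is a declared canonical enumeration of the printed
  feature families; other realisations of the same families exist.
- Calibration is a stationary-sphere fit only; recordings from devices
  with temperature-dependent bias will calibrate imperfectly yet may pass
  QC.
- Emissions are discrete (hard-label); vote-fraction (soft) emissions are
  out of scope, as are Baum-Welch re-estimation and higher-order chains.
- The generator's Markov chain is time-homogeneous, so time-of-day
  behaviour profiles on synthetic cohorts are flat; the profile machinery
  is exercised for its contracts, not for realism.
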