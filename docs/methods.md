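# Methods

## Signal model

Scalp EEG is modeled as an instantaneous linear mixture `x(t) = A s(t) + n(t)`
of cortical sources through a mixing matrix **A**, with additive sensor
noise.  A spatial filter is a row vector **w** with `w x(t)` estimating one
source; the corresponding scalp pattern is the column of the (generalized)
inverse of the filter matrix.  All processing operates on 32-channel
recordings sampled at 256 Hz and band-passed 2–30 Hz.  Each 8-s trial
contributes two analysis windows: rest `[0, 2)` s (blank screen before the
cue) and imagery `[2.5, 4.5)` s, half-open sample ranges obtained by
rounding `seconds × fs`.  Per-state training matrices concatenate the
corresponding window of every trial.

Band-pass filtering uses a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`): zero phase, so ERD latencies are not shifted; the
magnitude response is applied twice.

## Decomposition

The state training matrix is centered, reduced to 15 principal components
(thin SVD; rank-deficient inputs reduce further with a warning), and
unmixed by ICA after symmetric whitening.  Two engines satisfy the same
separation contract — on linear mixtures of independent non-Gaussian
sources, `unmixing @ mixing` must be a permutation of a diagonal matrix —
and the contract, not the algorithm, is what the package guarantees and
tests.  The default engine is FastICA; extended infomax (via mne) is
available through `engine="extended-infomax"`.  FastICA was made the
default because it reaches the same recovery quality on session-length
simulated EEG (best-match pattern correlations ≥ 0.99 for both) at roughly
two orders of magnitude less compute, which keeps a full-session
decomposition interactive on a laptop.

Composition back to channel space: `filters = unmixing @ pca_basis`,
`patterns = pinv(filters)`.  ICA's sign/scale indeterminacy is fixed by
convention: every pattern column is unit-norm with its largest-magnitude
electrode positive.  The reciprocal scale moves into the filter row, so a
component's time course carries the physical microvolt-at-scalp amplitude
of its source.  This matters for the zero-training classifier: hemispheric
power asymmetries must survive the decomposition, and a unit-variance
output convention would silently normalize them away.  Training channel
means are stored and subtracted when filters are applied to new data.

## Motor-component identification

Each component's scalp pattern receives an equivalent-dipole fit in a
single-sphere head model.  The forward model is the exact
spherical-harmonic series for a current dipole in a homogeneous conducting
sphere with insulating exterior (radius 1, conductivity 1), truncated at
order 60 — the series converges geometrically in dipole eccentricity, so
truncation error is below 1e-4 for eccentricities ≤ 0.9; the central-dipole
closed form `V = 3 (m·r̂)/(4π)` anchors the implementation.  Fitting runs a
vectorized coarse search over a 0.1-radius interior grid (the moment is a
closed-form least-squares solve at each node) followed by Nelder–Mead
refinement confined to radius 0.95.  Residual variance
`rv = ‖pattern − fit‖²/‖pattern‖²` gates candidates at 20 %: genuinely
dipolar (brain-like) patterns fit at rv ≪ 1 %, spatially white patterns
almost never pass.

Survivors are scored per hemisphere on three criteria: distance of the
fitted dipole to the template dipole (head-radius units; reported also on a
mm scale using a nominal 87.5 mm head radius), Pearson correlation between
the sign-normalized pattern and the template pattern, and the mu power
ratio — mean Welch PSD over `[10, 15)` Hz divided by `[15, 20)` Hz (1-s
windows, 50 % overlap; the half-open band convention is a package choice).
Criterion values become 1-based ordinal ranks (rank 1 = most motor-like;
ties go to the earlier component), combined as `f = 3·I_dist + 1·I_corr +
2·I_ratio`.  The smallest f wins each hemisphere.  Two degenerate cases are
resolved by package convention: equal f is broken by the smaller distance
rank (the heaviest-weighted criterion) and then by component order — in a
minimal simulated scene with only four gate-survivors, the alpha confound
(which always wins the power-ratio rank) can otherwise tie a true motor
component; and if one component wins both hemispheres it keeps the side
with the smaller f while the other side takes its runner-up.

Templates are group means of motor dipoles and sign-normalized patterns,
built leave-one-out so a subject's own data never enters its template; for
single simulated subjects a canonical template (radial dipoles at 0.7
radius under C3/C4) stands in.

## Features and classification

All three feature families reduce an imagery segment to two accumulated
band powers.  Band power is a plain rectangular-window FFT with Parseval
normalization (one-sided per-bin powers summing to the mean squared
amplitude; band edges 8–30 Hz inclusive on bin centres), so a unit
sinusoid at a bin-aligned frequency reads exactly 0.5.  Features are linear
power by default; a log option exists but is off, since the compared
methods are defined on accumulated power.

* monopolar: C3 and C4 channels directly;
* ICA: the two selected motor filters — from the rest state, the imagery
  state, or another session; the caller's choice of filter source *is* the
  translation being studied;
* CSP: trace-normalized per-trial covariances averaged per class, composite
  whitening, eigendecomposition of the whitened class-1 covariance, and the
  two back-projected extreme-eigenvalue filters (exactly two, to match the
  two-component ICA feature set).

Classification is two-class Fisher discriminant analysis, `w ∝ S_w⁻¹(m₁−m₂)`
with the bias at the midpoint of the projected class means and a ridge of
`1e-8·trace` if the scatter is singular.  Accuracy is estimated by
stratified 10-fold cross-validation repeated 10 times with per-repetition
reshuffling from a seed.  CSP filters are retrained inside every training
fold; ICA filters are trained once per state on the full session — for the
imagery state this reproduces the (unsupervised) overlap between ICA
training data and test folds that is inherent to the design; a strict
no-leakage variant simply means training ICA on the rest state, which never
sees imagery samples (an assertion enforces the disjointness).

The zero-training rule classifies a trial as left-hand iff
`P_L/μ_L ≥ P_R/μ_R`, where μ are the components' mean resting band powers
(ties → left, logged; a probability-zero event on real data).  Dividing by
the resting baseline cancels hemispheric amplitude asymmetry, which
otherwise drives the unweighted sign rule toward one class.

Descriptive analyses: Welch PSD (1-s windows, 50 % overlap) and ERSP maps
(250-ms windows, 87.5 % overlap, trial-averaged, `10·log₁₀` relative to the
mean rest-window power per frequency).  The window parameters are package
choices sized to resolve 2-s analysis windows.

## Synthetic sessions

The simulator generates the study conditions with known ground truth.  The
default scene is the minimal cast that makes motor identification
nontrivial: left and right motor sources (mu 10–12 Hz at full amplitude
plus beta 20–22 Hz at half amplitude, 6 µV scale) at 0.7 radius under
C3/C4; a posterior alpha generator (9–11 Hz, 25 µV, unmodulated) placed
deep (0.4 radius) and left-lateralized toward P3 — posterior alpha in real
recordings is strong, widespread and asymmetric, and it is exactly this
asymmetric leakage into C3/C4 that degrades monopolar features, since a
perfectly symmetric confound would be cancelled by the two-feature
discriminant; a frontal 2–5 Hz artifact (4 µV); and 1 µV white sensor
noise.  Sources are mixed through the single-sphere forward model with
unit-norm columns and amplitudes carried by the source envelopes.

Source carriers are band-pass-filtered Gaussian noise multiplied by a slow
log-normal burst modulation (circular Gaussian smoothing of white noise,
~0.5 s timescale, exponentiated at strength 0.6, normalized to unit mean
square).  The burstiness is essential, not cosmetic: a band-limited
Gaussian process is still Gaussian and therefore unidentifiable for ICA;
the waxing-and-waning of real cortical rhythms is what makes them
super-Gaussian (the simulated rhythms have excess kurtosis well above 1) —
with it, the pattern-recovery correlations exceed 0.99.

Task modulation is a deterministic per-trial envelope: amplitude 1 outside
the imagery window and `1 + erd_depth` inside, with 0.25-s linear ramps.
Defaults follow the asymmetry of real ERD/ERS: contralateral −0.5,
ipsilateral +0.15, so an imagery window loses 75 % of its contralateral
band power.  Trials are back-to-back (8 s each), classes balanced and
shuffled from the seed; everything is reproducible bit-for-bit from
(config, seed).

What the simulator does *not* emulate: volume conduction through realistic
skull/scalp layers, eye-blink morphology, non-stationary electrode drift
within a session, inter-subject spectral variability, or multiple motor
generators per hemisphere.  Passing tests therefore demonstrate the
pipeline's correctness and its behaviour under the modeled physics, not
performance on any particular real cohort.  Session-to-session transfer is
modeled by re-mixing the same sources through a misaligned montage for the
second session — a rigid rotation of the whole cap (a re-seated cap shifts
coherently; independent per-electrode noise largely averages out inside a
broad spatial filter and barely degrades transfer) plus a 1-degree
per-electrode wobble — while the analysis assumes the nominal cap.

## Problem sizes and numerical choices

Simulated evaluations use 100 trials per class (50 in the shared test
fixture; 24 for the byte-stability check), a 10-subject cohort for the
rest-vs-task comparison, and a 9-subject cohort plus 10 label permutations
for the null checks — a single subject's cross-validated accuracy at
chance carries about 4 points of sampling noise from the heavy-tailed
band-power features, so chance-level claims are asserted on cohort means.
Bulk runs use 3 cross-validation repetitions, single-subject examinations
10.  Seeds are fixed throughout;
every randomized routine takes an explicit seed.  Degenerate inputs have
defined behaviour: rank-deficient PCA reduces order with a warning,
identical CSP class covariances yield all-0.5 eigenvalues with a warning,
zero neighbor-band power yields an infinite power ratio (logged), all-zero
patterns and all-rejected component sets are hard errors.

## Known limitations

* The equivalent-dipole machinery shares its forward model with the
  simulator; dipole-recovery tests therefore validate the fitting
  procedure, not head-model adequacy for real anatomy.
* Only two motor components (one per hemisphere) are selected even when
  more exist; multi-component feature combination is out of scope.
* The canonical template assumes hand-area sources under C3/C4; cohorts
  with atypical generators need leave-one-out templates from their own
  fits.
* EDF/BDF reading covers the common monopolar continuous-recording layout;
  annotations channels and variable per-channel rates are not interpreted.
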