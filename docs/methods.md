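# Methods

This note documents the models and procedures `mrcperd` implements, the
defaults and why they hold, the synthetic-data generator's assumptions,
and the numerical choices a maintainer would want to know.

## Study design emulated

Two sessions per subject — motor execution (ME) and motor imagery (MI)
— under an S1–S2 paradigm: a warning stimulus at t = 0 s and an
imperative movement cue at t = 2 s in every trial. Six right-upper-limb
movements (elbow flexion, elbow extension, supination, pronation, hand
open, hand close) are recorded 60 times each per session, in 10 blocks
with equal per-block counts and randomized order, and pooled pairwise
into three movement classes of 120 trials. Defaults: 15 subjects,
61 EEG + 3 EOG channels (5/10-system labels, positions from the MNE
10-05 template head), one accelerometer channel, 512 Hz.

The *desk profile* (`desk_profile()`: 8 subjects, 16 channels covering
the vertex, the frontal row and both ERD ROIs, 256 Hz) is the
scaled-down variant the test suite and the acceptance script run; it
keeps the full trial design (120 trials/class) while a whole cohort
processes in a few minutes on one CPU. Those are the problem sizes
quoted by the tests; the full-rate defaults are used for structural
checks only.

## Synthetic signal model

Sessions are sums of interpretable sources, each projected through a
fixed scalp topography. All topographies are zero-mean across EEG
channels (the average-reference forward convention), so the mandatory
common-average re-reference leaves every source contribution unchanged
— without this, a configured source amplitude would be unrecoverable
by construction.

**MRCP.** A slow negativity peaking 50 ms before each trial's true
movement onset: a 1.5 s half-cosine ramp to the negative peak and a
1 s half-cosine return, *projected onto the 0.3–3 Hz analysis band*
(40 repeated applications of the 4th-order zero-phase Butterworth
band-pass, renormalised to unit negative peak each pass). The
projection makes the analysis filter essentially idempotent on the
template: without it the filter attenuates the raw ramp by ~8% per
pass and the configured amplitude could never be read back to within
half a microvolt. Topography: mean-subtracted gaussian centred on Cz,
vertex weight 1, so with all stochastic terms off the generated peak
at Cz equals the configured amplitude exactly. Defaults (ME):
−8 / −6.5 / −5 µV for flexion-extension / pronation-supination /
hand open-close — a few-µV late CNV negativity, ordered as motor
tasks typically order.

**Mu and beta rhythms.** Band-confined Gaussian noise (8th-order
zero-phase filter on a band inset 10% from each edge — mu source
8.5–12.5 Hz inside the 8–13 Hz analysis band, beta 15.6–28.4 inside
14–30 Hz), baseline RMS 4 µV at its ROI, amplitude multiplied by
√(1 − g(t)·d) so *power* is suppressed by exactly the configured
depth d where g = 1. The inset matters: Butterworth skirts of one
rhythm otherwise leak into the other band's analysis filter and, since
the two rhythms carry different suppression depths, bias each other's
recovered depth by several points. The suppression profile g is a
trapezoid per trial: linear decline from 0.9 s before onset, full
depth held over onset ± 0.3 s, linear recovery complete 2 s (ME) or
1 s (MI) after onset — the post-onset ME/MI divergence seen in real
data. The plateau is wide enough that the 200 ms feature window plus
the 250 ms power smoothing reads only the plateau, and the decline
starts late enough that smoothing cannot bleed suppression into the
−1.5…−1 s reference window; both are required for the measured
ERD-min to equal −100·d without systematic deficit. Topographies:
wide (σ = 0.1 m) mean-subtracted gaussian lobes centred on each
band's ROI centroid, normalised so the smallest-|weight| ROI channel
is 1 — wide enough that the lobe keeps one sign across its ROI (a
narrower lobe puts the zero-mean crossing ring inside the ROI and the
normalisation explodes). Default depths (ME): mu 0.45/0.45/0.40,
beta 0.40/0.40/0.35 per class.

**Condition contrast.** MI amplitudes and depths are 0.6 × ME
throughout — an intermediate effect size that preserves the
qualitative ME > MI ordering and keeps the paired contrast detectable
at 8 subjects against narrowband power-estimation noise (per-cell
ERD-min estimates carry ~4–5 percentage points of sampling SD at 120
trials; see *Limitations*).

**Onsets.** ME onsets are S2 + delay, delay ~ N(0.5 s, 0.1 s) per
trial, truncated at 50 ms. MI has no observable movement; its internal
(imagined) onsets are modelled as *locked to the subject's habitual
latency* — the class-wise mean of that subject's ME delays — because
the analysis can only ever align MI trials at the imputed class mean,
and a generator that jitters MI onsets trial-by-trial makes the
configured amplitudes unrecoverable in principle. The accelerometer
carries a 50 ms raised-cosine step (amplitude 1, noise SD 0.05) at the
true onset in ME and no step in MI.

**Blinks and noise.** Biphasic low-frequency blink transients at
Poisson times (10/min), frontal-dominant zero-mean topography (peak
0.8 × 120 µV on the scalp), mirrored into the EOG channels with gains
1/0.85/0.7 of 120 µV; independent white sensor noise (SD 2 µV) on
EEG and EOG.

**Randomness.** One root seed; every session draws from an independent
`SeedSequence(entropy=seed, spawn_key=(subject, condition))`
substream, and subject-level amplitude factors (lognormal, fractional
SD 0.2, shared between a subject's two sessions) from a separate
stream — regenerating a subset of subjects never changes the others.
Monte Carlo chains likewise use one CRC-keyed substream per
(subject, condition, class).

What the generator does **not** emulate: volume-conduction forward
modelling, 1/f background spectra, eye movements other than blinks,
muscle artifacts, fatigue drift across blocks, or inter-session
baseline shifts. Passing tests therefore demonstrate that the
*pipeline* is correct and internally calibrated, not that it is robust
to every artifact class in real recordings.

## Preprocessing

Order follows the recorded chain: broadband 0.3–100 Hz band-pass
(clipped to 0.45·fs for low-rate profiles) → SOBI on the continuous
EEG+EOG → ocular-component removal → epoching → rejection → common
average reference. All offline filters are zero-phase (forward–
backward Butterworth; doubled effective order) so MRCP peak latency is
not shifted; a causal option exists.

**SOBI.** Whitening from the zero-lag covariance eigendecomposition
(reduced to effective rank if singular), then Jacobi-style joint
diagonalization of the symmetrized lagged covariances at lags
1…0.2·fs samples (≈0–200 ms), with rotation tolerance 1e-6 on the
Givens sine and a 100-sweep cap. The summed squared off-diagonal
criterion is non-increasing by construction and is stored per sweep.

**Ocular flagging.** A component is ocular iff its relative spectral
power below 5 Hz exceeds 0.55 AND (max |corr| with an EOG channel
> 0.7 OR the frontal concentration of its mixing column > 0.55).
"Frontal" is an absolute anatomical cut (y ≥ 0.045 m on the template
head — the Fp/AF/F rows), not a percentile: a percentile definition
mislabels central channels as frontal on posterior-heavy montages and
then removes the vertex MRCP component. Thresholds are configurable
and recorded on the model; without EOG channels the frequency +
topography pair alone decides (logged).

**Rejection.** Per trial × EEG channel: peak-to-peak amplitude and
excess kurtosis; each metric's threshold is the *median* of the pooled
trial×channel values + k·SD (k = 5) — the robust centre keeps the
threshold itself unpolluted by the outliers being hunted. A trial is
dropped when more than 25% of EEG channels are flagged; surviving
flagged channels are excluded from the common average and from that
trial's contribution to averages (never interpolated). Applied per
subject and movement class.

## Features

MRCP and ERD are computed from band-filtered *continuous* data epoched
at the (detected or imputed) movement onset, common-average
referenced. The MRCP peak search is clipped so the 200 ms averaging
window always fits inside the epoch; "peak" means the most negative
sample (an |amplitude| option exists). ERD power is smoothed with a
250 ms moving average before normalisation (squared 512 Hz samples
are too noisy to plot or window raw); smoothing is linear, so it
commutes with trial averaging, and the analytic-identity tests set it
to 0. The percent-change normalisation makes ERD invariant under any
global gain, and the reference window normalises itself to 0 by
construction.

## Monte Carlo trial reduction

A chain is one random permutation of a cell's retained trials: the
size-s subset is its first s elements, which is exactly the
"remove 10 at random, repeatedly" construction and turns subset
averages into prefix sums — the whole analysis is vectorised over
realizations (the 200 ms windows around the MRCP search region and
the two scalar window-means per ERD channel are the only per-trial
state). Features are recomputed from subset *averages*, never from
per-trial features. The reference is the full retained set (sizes are
clipped when rejection leaves fewer than 110 trials; clipping is the
honest option when the nominal 120 is not available). Percent
differences use 100·|v − v_ref|/|v_ref|, sign-safe for the
negative-valued features. Default 1000 realizations; the tests and the
acceptance script run 100 (the between-subject medians are stable to
well under a point at 100).

## Statistics

Paired t: t = mean(d)/(SD(d)/√n), df = n−1, two-sided p from the t
distribution (scipy's vetted CDF); zero-variance differences are
flagged degenerate. Monte Carlo profiles report the arithmetic mean p
across realizations *and* the fraction with p ≤ 0.05, because a mean
of p-values is descriptive, not itself a calibrated test.

The 3-way rmANOVA parameterises every effect by Kronecker products of
orthonormal Helmert contrasts; each effect is tested against its own
subject-by-effect error term, and Greenhouse–Geisser
ε = (Σλ)²/(df·Σλ²) (bounded to [1/df, 1]) rescales both degrees of
freedom. Because the MRCP peak (µV) and the ERD minima (%) live on
different scales, each feature is z-scored across all its values
before entering the ANOVA by default (raw-values option provided);
without standardisation the Feature factor mostly measures units.
Note the textbook claim "the GG-corrected p is never smaller" holds
for F ≥ 1; for F < 1 shrinking both df can lower p — the
implementation simply applies the definition.

Per-electrode paired t-tests are reported uncorrected; scalp-level
multiple-comparison correction is out of scope.

## Numerical choices and degenerate inputs

- Epoch windows are half-open [start, end) in samples; all times are
  seconds with each trial's S1 at its event-table time.
- Trials whose window exceeds the recording are dropped, not padded.
- EDF round trips are exact to one 16-bit quantization step per
  channel; the internal HDF5 container is bit-exact (float64).
- Zero-phase high-pass transients decay over seconds; steady-state
  filter properties are asserted on the interior of long test signals.
- Degenerate inputs raise: empty trial subsets, all-flagged component
  sets, all-excluded CAR, zero reference-window power, fewer than 3
  surviving trials, missing ANOVA cells.

## Limitations

- ERD-min at 120 trials carries ~4–5 percentage points of sampling SD
  per subject × class × band (narrowband power in sub-second windows
  has few degrees of freedom). Cohort-level recovery (means over
  8 subjects and 3 classes) is accurate to ~1–2 points; single-cell
  values are not, and real studies face the same floor.
- The measured MRCP feature is a windowed mean of a band-limited
  average and reads ~3% below the point amplitude of the injected
  template; at the default amplitudes this is ≤ 0.4 µV.
- MI alignment rests on the imputed class-mean latency; any real
  trial-to-trial variability of imagined timing (which the generator
  deliberately omits) would smear MI averages beyond what these tests
  measure.
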