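# Methods

This note documents the models, defaults, and numerical choices behind
`periflick`, and what the synthetic-data validation does and does not
establish.

## The paradigm being modelled

Two large panels flicker at 13 Hz (left) and 15 Hz (right) behind a
visual detection task.  Each 9 s trial has three 3 s phases: central
fixation, a directional cue (gaze/attention shifts to one side), and a
target requiring a speeded response.  Flicker contrast — the amplitude
modulation depth, i.e. the ON/OFF gray-level difference as a fraction of
the background-to-white range — is varied across three conditions:
control (70% of maximal depth), periliminal (at the individually
measured visibility threshold), and subliminal (one staircase step
below).  The analysis asks whether the attended side can be read out
from the EEG tag responses, single trial by single trial.

## Flicker model

The ON gray level is `floor(g0 + (g_max − g0)·m)` with g₀ = 130 and
g_max = 255; the floor (rather than round) reproduces the convention of
reporting 217 for m = 0.70, where exact arithmetic gives 217.5.  Frame
schedules sample the ideal 50%-duty square wave at frame midpoints
(k + 0.5)/refresh; at 120 Hz this gives exact 4-ON/4-OFF cycles for
15 Hz and an alternating 5/4-frame pattern for 13 Hz whose ON fraction
still converges to ½.  How a real presentation system schedules 13 Hz on
a 120 Hz grid is not standardised; midpoint sampling was chosen as the
least-biased deterministic rule.  The measured background luminance
(124 cd/m²) is carried as metadata only — no gray→luminance model is
fitted because the monitor gamma is unknown.

## Staircase protocol and simulated observers

Blocks present four stimuli in random order: the two flickers at the
current depth and two static catch stimuli.  An error is a missed
flicker or a response to a static stimulus.  The descending phase steps
−0.001 (0.1% of maximal depth) from 0.05 until a block has more than two
errors; the ascending phase steps +0.0002 until both flickers in a block
are detected.  All visited depths therefore lie on the lattice
{0.05 − 0.001·i + 0.0002·j}.

Simulated observers respond via a logistic psychometric function
`P(detect) = g + (1 − g − λ)/(1 + e^{−β(d − t)})` with threshold t,
slope β, lapse rate λ, and guess rate g; g is also the false-alarm
probability on static stimuli.  Two consequences are worth noting:

- With g = 0 a four-trial block can contain at most two errors, so the
  ">2 errors" descent rule can never fire.  The default observer has
  g = 0.1; the protocol presumes observers who sometimes respond in the
  absence of a detectable flicker, which matches real psychophysics.
- Even with g > 0 the per-block stop probability below threshold is
  bounded (≈0.3 at best), so low-threshold observers occasionally reach
  zero depth without triggering the rule.  The implementation then emits
  a `ProtocolFailureWarning` and starts the ascending phase from zero,
  which still converges on the threshold from below.

Whether static-stimulus false alarms count toward the descending stop
rule is ambiguous in the protocol description; they are counted here,
since the rule is otherwise unreachable (see above).  The ascending stop
considers only the two flicker trials.  With steep observers
(β = 2×10⁴) the recovered periliminal depth has median error ≤ 0.002
over thresholds in [0.005, 0.04] (validated over 500 simulated runs).

## Synthetic sessions

`SimConfig` defaults define the study conditions: 32 channels (10-20
labels with a parieto-occipital row) at 500 Hz; 30 trials per condition
(90 total) in condition blocks with balanced, randomly ordered sides;
3+3+3 s phases and a 1 s inter-trial gap.

**Sources.** Each tag is a sinusoid at f plus a 0.3-weighted second
harmonic (the analysis characterises only f and 2f, so no full
square-wave response is synthesised), mixed through a Gaussian spatial
topography (σ = 4.5 cm) centred 2.5 cm left/right of Oz.  During
fixation both sources run at the baseline amplitude; from cue onset the
attended source ramps linearly over 0.5 s to `attention_ratio` × baseline
and stays there through the target phase.  The 0.5 s default reflects
the observed latency of the SSVEP attention response.

**Background.** Independent per-channel 1/f noise (exponent 1.0,
RMS 10 µV) plus occipital alpha (8–12 Hz narrowband noise, 4 µV RMS at
the topography peak) multiplied by 0.7 during cue/target — emulating
alpha suppression when gaze leaves fixation.

**Condition gains.** Baseline source amplitude is
`ssvep_gain × response_gain(condition)` with ssvep_gain = 1.2 µV and
explicit per-condition gains 1.0 / 0.45 / 0.12 (control / periliminal /
subliminal).  A compressive power law of physical contrast
(`contrast_response`, default γ = 0.5) is available, but cannot separate
periliminal (depth 0.02) from subliminal (0.0198): near-threshold vision
is far steeper than any power law of contrast, so the defaults encode
that steepness directly.  The absolute values were calibrated once so
that condition-wise decoding of the default session lands near — not
at — ceiling for control and near chance for subliminal (observed means
over five seeds: ≈99 / 83 / 57%), keeping recovery tests informative.
No published per-condition amplitudes exist to calibrate against.

**What the generator does not emulate:** eye movements and EOG/EMG
artifacts, volume-conduction head models (mixing is a direct Gaussian
topography), non-stationary noise, inter-subject variability, or
behavioural responses.  Passing tests therefore demonstrate that the
*analysis* is correct under the stated statistical structure, not that
the structure exhausts real EEG.  In particular ICA-based component
pruning is skipped by default on synthetic data (there are no artifacts
to remove); the pruning *rule* is tested on constructed mixtures.

## Preprocessing

Fixed order: band-pass filter → bad-channel detection → spherical
interpolation → average reference → (optional component pruning) →
epoching.  The FIR is a 1651-tap Hamming-windowed sinc whose
half-amplitude (−6 dB) points sit at 0.5 and 40.5 Hz (passband 1–40 Hz),
applied once, centred, so the net phase is zero; an odd tap count gives
an integer group delay (the quoted order 1651 is taken as the tap
count).  Bad channels are those whose mean log₁₀ Welch PSD (2 s
segments, 50% overlap, 1–40 Hz) deviates more than 3 robust SDs
(1.4826·MAD) from the cross-channel median — the robust variant is used
because the plain SD is itself inflated by the outlying channel at small
channel counts; the band and log scaling are conventional choices.
Spherical-spline interpolation is delegated to MNE's EEG implementation.
The effective data rank (channels − interpolated − 1 for average
reference) is tracked and exposed for downstream decompositions.
Component pruning removes components whose externally supplied
classifier confidence exceeds 0.70 (strictly) for any artifact class;
the classifier itself (e.g. an IClabel-style network) is out of scope.

## RESS

For target frequency f, trials are narrowband filtered by frequency-
domain multiplication with a Gaussian (FWHM 1 Hz — amplitude response,
zero phase) at f and at f ± 1 Hz.  Channel covariances over the 0–6 s
post-cue window are averaged over trials into S (target) and R (mean of
the two neighbours).  The filter solves S w = λ R̃ w with
R̃ = (1 − γ)R + γ·mean(eig(R))·I, γ = 0.01: shrinkage is required
because average-referenced (rank-deficient) covariances make the pencil
singular.  The top eigenvector, unit-normalised with its sign fixed so
the topography S·w is positive at the posterior midline channel, is the
spatial filter; λ > 1 indicates genuine target-band excess.  Filters are
fitted per condition and per frequency (6 per session), pooling left-
and right-cue trials.

**SNR.** No closed-form SNR definition accompanies the RESS literature's
figures; the neighbour-bin convention is used: power at each FFT bin
divided by mean power in bins 0.5–2 Hz away on both sides (skip and span
configurable), ≈1 for featureless noise.  Time courses use a sliding
2 s window stepped by 0.1 s — 2 s is the minimum at FWHM = 1 Hz
spectral resolution, and the window centre is the timestamp.

**Attention normalisation.** Because the filter maximises power at its
own frequency, raw component SNR overfits.  The nontarget component
(filter at the other tag frequency) serves as a within-trial control,
either by subtracting its time series before SNR computation
(`mode="signal"`, the default, following the methods-text reading) or by
subtracting SNR traces (`mode="snr"`, following the figure-caption
reading).  Both are provided; the intent is genuinely ambiguous.  Note
that per-side indices carry a real 13-vs-15 Hz asymmetry (the 1/f
background makes 15 Hz SNR slightly higher), so the symmetry-based
fixation-phase null holds for the pooled left/right average.

## Decoding and chance calibration

Features are the RMS amplitudes of the two narrowband RESS components
over the 3 s cue window ("amplitude" is unspecified in the source
analysis; RMS is the natural scale-preserving choice).  The classifier
is a pooled-covariance linear discriminant with empirical priors,
scored by seeded stratified 5-fold cross-validation.  The default
engine is an internal vectorised implementation verified
prediction-for-prediction against scikit-learn's
`LinearDiscriminantAnalysis` (the estimator API is ~500× slower, which
matters for the permutation loops); `engine="sklearn"` switches to the
library.  Significance is calibrated per dataset by 200 full label
permutations (class counts preserved, folds re-drawn per permutation):
the empirical 95th/99th percentiles (linear interpolation) are the
α = .05/.01 boundaries, and the observed accuracy must exceed them
*strictly* — ties are non-significant.  For 30-trial two-feature
datasets these boundaries fall near 68% and 72%, far above the naive
50%; the type-I error of the resulting test is 5% ± 2% (validated over
500 null datasets).  The fixation-vs-task SNR threshold is the
root-node split of a depth-2, ≤2-feature decision tree fitted on pooled
single-trial SNR values; a threshold whose tree cannot beat 60%
resubstitution accuracy is flagged uninformative.

## Pipeline, seeds, problem sizes

`run_pipeline` derives per-stage seeds from one master seed via
`SeedSequence`, so reports are byte-identical across runs and stages can
be re-run in isolation.  Validation suites use deliberately sized
simulations: threshold recovery over 500 observers, type-I error over
500 null datasets (200 permutations each), chance-boundary pooling over
200 datasets, attention-ratio ladders over 20-trial single-condition
sessions (10 seeds per rung), and condition-ordering over three full
90-trial sessions — sizes chosen to make the statistical assertions
stable while keeping the whole suite to a few minutes.

## Known limitations

- The generator's condition gains are a calibration, not a measurement;
  absolute µV values should not be compared with recorded data.
- The bad-channel rule keys on broadband spectral power only; it can
  flag channels at the extremes of a strong spatial power gradient
  (e.g. a frontal channel in a heavily occipital montage) and will miss
  transient artifacts.
- `mode="signal"` normalisation can leave residual nontarget power when
  the two filters are far from orthogonal.
- Permutation boundaries are reported per dataset; pooling across
  datasets (as the acceptance script does for its summary percentiles)
  assumes exchangeable nulls across datasets of identical design.
- EDF writing is not implemented (reading is); BrainVision is the
  round-trip format.
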