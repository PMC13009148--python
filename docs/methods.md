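# Methods

## The analysis in brief

The pipeline classifies subjects, not segments. Each subject's ten-channel
resting-state EEG is harmonized to 250 Hz, band-passed 0.5–45 Hz, average
referenced and cut into non-overlapping 2-s segments (10 × 500 samples). A
convolutional network emits a probability per segment; a subject is labelled
positive when at least 50 % of their segments are (ties count as positive,
which only matters for even segment counts). Held-out test subjects never
contribute segments to training or validation. Two tasks share the
machinery: MDD vs HC (diagnosis) and responder vs non-responder to SSRI
treatment (prediction). Grad-CAM maps explain the fitted model in channel ×
frequency terms, ten classical learners on spectral/connectivity features
provide a baseline, and a number-needed-to-treat model converts classifier
accuracy into treatment-allocation outcomes.

## Synthetic cohort model

Clinical EEG of this kind is access-restricted, so the package generates
cohorts with the statistical structure the analysis assumes. Per subject,
the signal (microvolts) is the sum of:

- **1/f^γ background**: Gaussian noise with power ∝ f^(−γ), γ = 1 by
  default, 10 µV RMS per channel — the broadband scale-free floor of scalp
  EEG.
- **Alpha rhythm**: narrowband Gaussian noise centred on `alpha_freq`
  (default 10 Hz, ~1 Hz bandwidth), multiplied by a positive envelope with
  ~2 s coherence time (smoothed Gaussian process, mean 1, SD ≈ 0.5) and an
  envelope-mean amplitude of 10 µV on every channel. A stochastic carrier is
  used deliberately: real alpha phase drifts, and a fixed per-subject phase
  would hand the classifier a spurious subject-identity cue that no real
  cohort provides.
- **Class effects**: the alpha amplitude is multiplied by `diag_amp_ratio`
  on F7, F4, F3, P3 for MDD subjects and by `resp_amp_ratio` on F3, F7, F4
  for responders. Ratios of 1 give a null cohort. These channel sets mirror
  the interpretability findings the pipeline is meant to recover, and are
  config-overridable.
- **Ocular transients**: biphasic 100–400 ms pulses at `blink_rate`
  (default 6/min — eyes-closed rates are low), 60 µV at F7 with a frontal,
  laterally asymmetric decay so the F7−F8 bipolar surrogate sees them.
- **EMG bursts**: 30–100 Hz band-limited noise bursts (default 2/min,
  15 µV RMS), lateral-frontal dominant; the 45 Hz low-pass is what removes
  them, so they exercise that stage.

Site heterogeneity enters through the six default site profiles (sampling
rates 250/512/1000 Hz, durations 72–906 s, group sizes summing to 146 HC /
203 MDD with 103 responders). The 512 Hz sites force non-integer resampling
ratios through the pipeline. Responder counts per site are stored as exact
fractions of included patients (e.g. 55/111 ≈ 49.5 % at the largest site),
so cohort totals are reproduced exactly.

What the generator does **not** model: inter-subject amplitude variability,
vigilance drift, posterior alpha dominance, realistic MDD
electrophysiology, sex effects, comorbidity. Passing tests therefore show
that the pipeline recovers a planted, parameterized effect under realistic
noise and multi-site heterogeneity — not that the effect exists in real
patients.

## Preprocessing choices

Stage order is fixed: channel intersection → 100 Hz FIR anti-alias low-pass
and polyphase resampling to 250 Hz → zero-phase 4th-order Butterworth
band-pass 0.5–45 Hz (sensitivity variant 30 Hz) → optional eye correction →
common average reference → 2-s segmentation → optional ±100 µV rejection →
train-set z-normalization. Zero-phase IIR filtering and polyphase rational
resampling are standard EEG practice and give testable attenuation
contracts (≥20 dB at DC/60 Hz, <1 dB at 10 Hz). Eye correction is simple
least-squares regression of a surrogate EOG (the F7−F8 derivation
low-passed at 5 Hz) out of every channel; the eye-event counter thresholds
the same surrogate at 3 robust SDs (MAD-based) with a 500 ms refractory
window. Both cleaning steps are **off** by default: the with/without
comparison favours the plain pipeline, and they remain available as the
"extensive preprocessing" variant. Rejection applies after average
referencing (the values as modelled). Segmentation is non-overlapping — the
per-subject segment counts of the cohort profile (36 from 72 s, 450 from
900 s) force it.

## Network and training

The classifier is six blocks of [Conv2D, 200 filters, 'same' padding,
ReLU] → max-pool (1,2) → dropout, kernels (2,2) in blocks 1–3 and (1,2) in
blocks 4–6 (a monotone reading of "from (2,2) to (1,2)"), dropout 0.3
except 0.5 after block 6, then flatten → dense(64) → sigmoid. Pooling never
touches the channel axis, so per-channel relevance stays meaningful.
Max-pooling and dense sizes are not pinned by the architecture description;
(1,2) pooling and 64 units are the defaults and sit in the search grid.
Training: class-weighted binary cross-entropy (weights proportional to 2:3
for HC:MDD, 17:20 for R:NR, normalized to mean 1), Adamax at 5·10⁻⁵, batch
64, early stopping on the weighted validation loss with patience 70 within
a 900-epoch budget, restoring best-validation weights. The engine is
vectorized NumPy (im2col convolutions over BLAS); gradients are verified
against numerical differentiation in the tests.

**Reduced-scale protocol.** The test suite trains an 8-filter, dense-32
variant on cohorts of 40 subjects/class × 100 segments (50 per subject used
for training) with learning rate 5·10⁻⁴ and ≤50 epochs. The learning rate
matters: at ≥3·10⁻³ the network becomes overconfident within an epoch or
two, validation *loss* rises while validation accuracy still improves, and
loss-based early stopping restores a stale model whose segment threshold is
badly calibrated for the majority vote. At 5·10⁻⁴ the validation loss
declines to a converged minimum, matching the qualitative behaviour the
full-scale protocol relies on.

Validation subjects are drawn as whole subjects (leakage guard) alternating
between classes until ~5 % of remaining segments are covered; the
stratification guarantees both classes are represented even in small
cohorts.

## Grad-CAM in channel × frequency space

Per segment, each conv layer contributes a rectified, gradient-weighted
activation sum toward the predicted class; layer maps are upsampled to
10 × 500 (linear along time; the channel axis is categorical) and averaged,
then min-max normalized. Two deliberate deviations from the textbook
image formulation:

- **Elementwise gradient weighting** (default). The classic formulation
  pools gradients over space into per-filter weights, which presumes a
  global-average-pooling head. This network flattens into a dense layer, so
  spatial pooling of gradients discards exactly the localization being
  sought; elementwise weighting (ReLU(Σ_k G_k ⊙ A_k)) preserves it. On
  planted single-channel fixtures the pooled variant localizes ~30–50 % of
  segments, the elementwise variant 100 %. The pooled variant remains
  available (`GradCamConfig(pooled_weights=True)`).
- **Receptive-field re-centring.** Bottom-padded 'same' convolutions shift
  each (2,·)-kernel layer's map half a row toward lower indices; each
  layer's relevance is spread uniformly over its receptive-field extent
  along the channel axis before averaging.

Marked spans are contiguous runs above τ = 0.3 (minimum 32 samples =
128 ms, the shortest window resolving an 8 Hz cycle fragment on the
zero-padded 512-point grid). Span spectra are computed on raw microvolt
segments (detrended, Hann-tapered, zero-padded), span-length-weighted and
averaged per channel, so units remain physical (µV²/Hz). Which class's
gradient to target defaults to each segment's predicted class; layer
weights default to the unweighted mean over all six layers.

## Conventional baseline

Per subject: 5 band powers (Delta 0.5–4, Theta 4–8, Alpha 8–12, Beta 12–20,
Gamma 20–45 Hz) × 10 channels from the segment-averaged periodogram, the
alpha peak frequency (flat-window fallback: 10 Hz, flagged; ties → lower
frequency), and 6 lobe-pair connectivity values (frontal {F7,F3,F4,F8},
central {C3,C4}, parietal {P3,P4}, occipital {O1,O2}) — 57 variables in
total. "Lagged linear connectivity" is implemented as the lagged-coherence
family, Im(Sxy)²/(SxxSyy − Re(Sxy)²) band-averaged over 0.5–45 Hz, which
excludes instantaneous (volume-conduction-like) dependence by construction;
this is one member of the family such measures come from, chosen because it
is well defined, bounded and testable. Ten learners (logistic
regression, Gaussian naïve Bayes, decision tree, random forest, gradient
boosting, LightGBM, XGBoost, k-NN, SVM, AdaBoost) run at library defaults
with fixed seeds under leave-one-subject-out cross-validation, with
within-fold standardization.

## Clinical decision model

All arithmetic is exact (`fractions.Fraction`). From a confusion matrix,
predicted responders receive the SSRI and respond at the matrix PPV;
predicted non-responders receive the SNRI alternative (50 % response), so
response rate = (TP + 0.5·(TN+FN))/N, improvement = response rate − 0.5,
NNT = 1/improvement (undefined, not infinite, when improvement ≤ 0), and
nPPV = PPV / baseline response rate. The parametric variant on a balanced
cohort reduces to response rate = 1/2 + a/4 and NNT = 4/a for accuracy a.
Scenario tables of this kind sometimes mix rows that no single generating
matrix produces (e.g. an nPPV row equal to accuracy/0.6 rather than
PPV/baseline); the package computes every quantity from its own definition and additionally emits the accuracy/0.6
sequence as an explicitly labelled "as printed" row. NNT is reported to two
decimals, kept exact internally.

## Numerical and degenerate-input conventions

- All randomness flows from named integer seeds (NumPy `default_rng` /
  `SeedSequence`); identical configuration + seed reproduces identical
  outputs bit-for-bit, including cohort signals.
- Zero-variance training segments, empty prediction sets, single-class AUC
  input, and flat EOG surrogates raise or warn explicitly rather than
  propagating NaNs.
- Majority-vote ties resolve to the positive class; alpha-peak ties to the
  lower frequency; importance-ranking ties to canonical channel order.
- Welch's t-test with both groups degenerate returns t = 0 (equal means)
  or ±∞ (separated means) rather than erroring on indicator data.

## Known limitations

- The NumPy engine targets CPU-scale experiments; the full 200-filter
  network on the full cohort is supported but slow — the package's own
  experiments use the reduced protocol above, and the test suite scales
  problem sizes accordingly.
- The synthetic effect is a single planted amplitude ratio; real-cohort
  accuracies cannot be, and are not, reproduced.
- EDF export writes 16-bit, one-second records and truncates a trailing
  partial second.

Per-segment overlays target each segment's predicted class (explaining that
decision); the aggregated channel-importance topography targets the positive
class throughout, because averaging maps with opposing targets mixes
evidence for the two classes — under an average reference, "evidence for
HC" concentrates on the complementary channel set and would cancel the
topography of interest.
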