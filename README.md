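# eegmark

EEG biomarkers for major depression: a tested, reusable pipeline for
(a) discriminating patients with major depressive disorder (MDD) from
healthy controls (HC) and (b) predicting response to SSRI antidepressants,
from ten-channel resting-state eyes-closed EEG.

The package is aimed at computational-psychiatry researchers who want to
study this class of model — a convolutional network on channels × time
EEG segments with subject-wise evaluation — without access to restricted
clinical recordings: a synthetic multi-site cohort generator with a planted,
parameterized alpha-band (8–12 Hz) effect stands in for the clinical data,
so every stage is runnable and testable end to end.

## What it implements

- **Synthetic cohorts** (`eegmark.synthetic`): six recording sites with
  heterogeneous sampling rates (250/512/1000 Hz), durations (72–906 s) and
  group sizes (146 HC / 203 MDD, 103 responders). Signals are 1/f Gaussian
  background + amplitude-modulated narrowband alpha (class effects as
  amplitude ratios at frontal/parietal channels) + ocular transients + EMG
  bursts. EDF export, MNE-based import.
- **Harmonization** (`eegmark.preprocess`): intersection to the 10 shared
  channels (F7, F4, P3, O1, F3, C4, F8, O2, P4, C3), 100 Hz anti-alias
  low-pass then polyphase resampling to 250 Hz, zero-phase 0.5–45 Hz
  band-pass (30 Hz variant), optional EOG-regression eye correction and
  ±100 µV min-max segment rejection, common average reference,
  non-overlapping 2-s segmentation, train-set z-normalization.
- **Classifier** (`eegmark.cnn`, engine in `eegmark.nn`): six conv blocks
  (200 filters, kernels (2,2)→(1,2), max-pool (1,2) along time, dropout
  0.3/0.5), dense head, single sigmoid output on (10, 500, 1) inputs.
  Class-weighted cross-entropy (2:3 HC:MDD, 17:20 R:NR), Adamax at 5·10⁻⁵,
  early stopping on validation loss (patience 70, max 900 epochs), seeded
  random hyperparameter search. Implemented in vectorized NumPy.
- **Subject-wise evaluation** (`eegmark.evaluation`): leakage-safe splits
  (balanced held-out test subjects, 20/20 diagnosis and 10/10 response;
  ~5% whole-subject validation), the ≥50 % segment-vote rule, confusion
  matrices, sensitivity/specificity, rank-based AUC, repeated folds,
  assessment-week Welch t-test.
- **Interpretation** (`eegmark.gradcam`): Grad-CAM relevance maps averaged
  over conv layers, binarized at τ = 0.3 into marked spans, span-wise
  Fourier spectra per channel, channel-importance topography.
- **Classical baselines** (`eegmark.baselines`): band powers (Delta–Gamma ×
  10 channels), alpha peak frequency, 6 lobe-pair lagged linear
  connectivity values; ten standard learners with leave-one-subject-out
  cross-validation.
- **Clinical decision model** (`eegmark.decision`): biomarker-guided
  treatment allocation — response rate, improvement over the 50 % baseline,
  number needed to treat (NNT), PPV/NPV and normalized PPV — in exact
  rational arithmetic.

## Worked example

```python
from fractions import Fraction
from eegmark.decision import DecisionScenario, allocation_from_matrix
from eegmark.evaluation import ConfusionMatrix

scenario = DecisionScenario(matrix=ConfusionMatrix(tp=9, fp=1, tn=7, fn=3))
out = allocation_from_matrix(scenario)
print(f"response rate {float(out.response_rate):.0%}, "
      f"improvement {float(out.improvement):.0%}, NNT {float(out.nnt):g}")
```

prints

```
response rate 70%, improvement 20%, NNT 5
```

With a response-prediction marker of 80 % accuracy (9 true responders and 7
true non-responders among 20 patients), predicted responders receive the
SSRI (9 respond), predicted non-responders switch to an SNRI with a 50 %
response rate (5 of 10 respond): 14/20 = 70 % respond overall, 20
percentage points above the unguided 50 % baseline, i.e. one extra
responder per NNT = 5 patients allocated by the marker.

A small end-to-end experiment (generate → preprocess → train → evaluate →
explain → baselines → decision table):

```bash
eegmark run --out runs/demo --seed 7
```

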