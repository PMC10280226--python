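# Methods

## The screening model

The pipeline treats COPD screening as binary classification of 2-second
PPG epochs. The modeling assumptions are: (i) the diagnostic signal, if
present, is carried by short-time time-domain statistics of the denoised
pulse waveform and of its LF/MF/HF sub-frequency components; (ii) epochs
are exchangeable classification units — subject identity is bookkept but,
under the epoch-random protocol, deliberately ignored; (iii) the positive
class (COPD) and negative class (healthy) are each homogeneous enough for
class-conditional means and variances to drive feature ranking.

Assumption (ii) is the scientifically loaded one. Epochs from one subject
share that subject's traits (heart rate, pulse amplitude, sensor coupling),
so a random epoch split places near-duplicates of every test epoch in the
training half and any model with memory (kNN especially) can classify by
recognizing the *subject* rather than the disease. The package therefore
implements both the epoch-random 50/50 split and leave-one-subject-out
(LOSO); the acceptance suite asserts the ordering (epoch-random ≥ LOSO)
rather than pretending the optimistic protocol is unbiased.

## Filtering

All filters are Chebyshev type-II in second-order-section form, applied
forward–backward (`sosfiltfilt`) for zero phase; the effective stopband
attenuation is therefore twice the design's 40 dB.

A design subtlety: for a Chebyshev-II filter the design frequencies are
*stopband* edges, while the band definitions (0.1–20, 0.04–0.15,
0.09–0.15, 0.15–6 Hz) are passbands. Using the band edges directly as
design frequencies puts them at the −40 dB point and, for the very narrow
LF band, leaves almost no passband at all (measured gain 0.14 at the
0.1 Hz band center). The implementation therefore places the stopband
edges a transition ratio (default 2×) outward of the stated passband on
each side, clamped below Nyquist. With order 4 this yields in-band gain
within a fraction of a percent of unity for every band, ≥ 80 dB zero-phase
rejection beyond the stopband edges, and a numerically stable SOS cascade
even for the LF band at f_s = 100 Hz (impulse-response tail ~1e−16). Order
and ratio are configurable per `FilterSpec`.

The moving-average smoother (5 samples, centered, edge-replicated) has the
usual periodic-sinc response; at f_s = 100 Hz its gain at 10 Hz is 0.647.
In-band tones near the upper passband edge of the denoiser are therefore
attenuated by the smoother even though the bandpass passes them within 5%;
the tests assert the composite response against this product rather than
against unity. Filtering runs on the full record *before* epoching, so
sub-0.5 Hz bands are meaningful despite 2-s epochs.

## Features

The 25 descriptors follow fixed printed conventions rather than textbook
ones, because reproducing the method requires the exact formulas:

* kurtosis and skewness use an (n−1)·Sᵏ denominator (not bias-corrected
  moment ratios);
* Hjorth mobility is the variance ratio S₁²/S² — *not* its square root —
  and complexity is √((S₂²/S₁²)² − (S₁²/S²)²) with the radicand clamped
  at 0; derivatives are plain first differences without f_s scaling;
* "mean absolute deviation" is about the mean; the 10th central moment
  uses 1/n; the trimmed means cut round(n·p/200) samples per tail; the
  "singular value" of an epoch vector is its 2-norm; quantiles use Hazen
  plotting positions (i − 0.5)/n.

Bandpassed signals are near zero-mean, which makes three features fragile:
the coefficient of variation (divide by x̄ ≈ 0) is computed as printed and
any non-finite cell is sanitized to 0 and flagged before ranking or
classification; geometric and harmonic means are taken over |x| with a
1e−12 floor so they stay finite and monotone in signal magnitude. Exactly
constant epochs are flagged `DegenerateEpoch` semantics-wise (scalar API
raises; the matrix path sanitizes and records the flag mask).

Every feature is verified against an independently written pure-Python
loop transcription to 1e−9 relative on random epochs, plus scale- and
shift-homogeneity property tests.

## Selection

Features are ranked by the Fisher criterion on class-conditional sample
means/variances (ddof = 1); constant features score 0. The reported
association level R is the absolute point-biserial correlation with the
0/1 label, banded at 0.2/0.4/0.7/0.9. Ranking defaults to training rows
only (no test leakage) but can be run on all rows to reproduce a
whole-dataset association table. Subset sizes use ceil(0.05·level·pool),
which guarantees ≥ 1 feature for 25-feature pools and strict nesting; ties
break by column order for determinism.

## Classification

The three base learners and the tuner are scikit-learn; the method-specific
logic (feature pools, level subsets, vote fusion, split protocols) is the
package's own. Hyperparameters minimize mean 5-fold stratified CV
misclassification over: k ∈ {3,5,7} × {euclidean, manhattan, minkowski
p=3} for kNN; C ∈ {1,10,100} × γ ∈ {scale, 0.01, 0.1} (RBF) for the SVM;
50/100/200 bagged trees (random forest) for the ensemble. Features are
z-scored with training statistics inside every model; zero-variance
training columns are dropped with a warning.

Score conventions: kNN and the forest report vote fractions; the SVM
reports a logistic squash of its decision margin — monotone, hence
AUC-equivalent to the margin, in [0,1], and consistent with the 0.5
threshold. The hybrid's hard label is the 2-of-3 majority; since majority
votes carry no ranking information, its AUC uses the mean member score (a
convention, stated wherever reported).

## Evaluation

Sensitivity, specificity, accuracy (percent — deliberately a mixed scale
matching the reporting format), precision/F1, Cohen's kappa computed from
the confusion counts via p_o and p_e (cross-checked against scikit-learn's
independent implementation in a property test over random matrices), and
Mann-Whitney AUC with 0.5 tie credit. Kappa is labeled with the
conventional agreement bands (0.81–1.00 very good … < 0 very poor). Under
LOSO, per-fold test sets contain one subject (one class), so criteria are
computed on predictions pooled over folds.

## The synthetic cohort generator

No public dataset matches the clinical cohort, so `ppgcopd.synth`
generates one: per subject, a two-Gaussian beat (systolic bump at 0.30 T,
width 0.10 T; dicrotic bump 0.4·a1 at 0.65 T, width 0.12 T) repeated at
the subject's beat period with 3% white cycle jitter, amplitude-modulated
by respiration (±20%), plus 0.05 Hz baseline wander (0.3·a1) and white
instrument noise. Subject traits: heart rate ~ N(75, 8) bpm truncated to
[50, 110], respiratory rate ~ U(0.2, 0.35) Hz, pulse amplitude
a1 ~ LogNormal(0, 0.15), demographics matched to the reference cohort
(age 53.5 ± 8.8 yr, weight 102.4 ± 7.8 kg, height 172.9 ± 6.4 cm, 12/14
male). The class effect δ scales COPD pulse amplitude by (1 − 0.15 δ),
cycle jitter by (1 + 0.5 δ) and noise by (1 + 0.5 δ). Records are fully
determined by (seed, subject index, class).

Two generator choices deserve justification:

* **Instrument noise is absolute** (sd `noise_sd = 0.7` in units of the
  nominal pulse amplitude), not proportional to the subject's perfusion:
  photodetector and electronics noise does not track pulse strength. This
  matters for protocol hygiene — noise scaled by a1 would stamp each
  subject's amplitude trait onto the noise floor itself, making subjects
  identifiable from pure noise statistics.
* **Within-subject variability is white** by default: beat-to-beat
  log-normal amplitude variation (sd 0.15) and per-cycle period jitter.
  Slow AR(1) heart-rate and perfusion drifts are implemented
  (`hr_drift_sd`, `amp_drift_sd`) but default to 0: under an epoch-random
  split, slow drift *adds* leakage (a test epoch's temporal neighbors sit
  in the training half with nearly identical drift state), which is an
  interesting protocol pathology to demonstrate but a poor default for a
  null-calibrated generator.

These magnitudes were calibrated so that the generator satisfies its two
defining contracts simultaneously: at δ = 0 the end-to-end epoch-split
hybrid accuracy sits at chance (within [45, 55]% with |κ| ≤ 0.1 in at
least 4 of 5 seeds — i.e., residual subject-trait leakage is below the
measurement floor), while at δ = 3 the same pipeline reaches ≥ 90%
accuracy. Spec-level physiology (heart-rate and respiratory distributions,
wander, modulation depth, jitter, the δ scalings) was held fixed during
calibration.

What the generator does **not** emulate: real pulse morphology (anacrotic
limb asymmetry, notch position variation), motion and perfusion artifacts,
arrhythmia, SpO2 coupling, or any validated COPD waveform physiology. The
class effect is a synthetic construction. Passing tests therefore certify
the *pipeline* — formulas, filters, protocol handling, determinism — and
the recoverability of a known planted effect; they say nothing about
clinical discriminability of real COPD from real PPG.

## Problem sizes and numerics

Test and acceptance runs use desk-scale cohorts chosen to exercise every
code path with comfortable statistics: the reference condition is 20
subjects × 300 s at f_s = 100 Hz (3,000 epochs, ~10⁵× smaller than a
clinical sleep-lab archive would be); LOSO contrasts use 10 subjects ×
120 s. EDF round trips are exact in f_s (integral record durations) and
within range/2¹⁵ in amplitude (16-bit quantization over a symmetric
physical range rounded up to two significant digits). All randomness flows
from a single seed fanned out by fixed per-stage offsets; identical
config + seed reproduces byte-identical CSV/JSON artifacts.

## Known limitations

* The 50/50 epoch protocol's optimism is documented and measurable, not
  corrected; LOSO is provided as the honest alternative.
* The hybrid's mean-score AUC is a convention; majority votes have no
  intrinsic ranking.
* LF (0.04–0.15 Hz) and MF (0.09–0.15 Hz) overlap by definition; both are
  kept as defined, so their feature blocks are strongly correlated.
* The SVM grid is compact (9 points) for tractability; widen
  `classify.DEFAULT_GRIDS` for serious tuning studies.
* EDF support is the minimal single-channel subset the pipeline needs,
  not a general EDF(+) implementation.
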