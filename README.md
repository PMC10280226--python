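# ppgcopd

Screening for chronic obstructive pulmonary disease (COPD) from a single
photoplethysmography (PPG) channel. COPD is normally diagnosed by
spirometry (FEV1/FVC < 0.70), which is hospital-bound and hard on children,
the disabled and severely ill patients. The pulse-oximeter PPG waveform is
trivially easy to record, and its shape and sub-frequency content carry
cardiorespiratory information, so a classifier over short PPG windows is an
attractive pre-screening instrument. This package implements, tests and
evaluates such a screening pipeline for signal-processing and biomedical-ML
researchers.

## Method

For each subject's raw PPG record x(t) sampled at f_s:

1. **Denoise** — zero-phase Chebyshev type-II bandpass (0.1–20 Hz,
   order 4, 40 dB stopband) followed by a centered 5-sample moving average.
2. **Sub-band decomposition** — the clean signal is split into LF
   (0.04–0.15 Hz), MF (0.09–0.15 Hz) and HF (0.15–6 Hz) components with the
   same zero-phase filter family, giving four aligned signals
   (PPG, LF, MF, HF).
3. **Epoching** — all four signals are cut into non-overlapping T = 2 s
   epochs; the epoch is the classification unit.
4. **Features** — 25 time-domain descriptors per epoch per band
   (kurtosis, skewness, IQR, coefficient of variation, geometric/harmonic
   means, Hjorth activity S², mobility S₁²/S², complexity
   √((S₂²/S₁²)² − (S₁²/S²)²), extrema, median, mean absolute deviation,
   10th central moment, mean, curve length (1/n)Σ|Δxᵢ|, energy, RMS,
   standard error, SD, shape factor, vector 2-norm, 25%/50% trimmed means,
   Teager energy (1/n)Σ(xᵢ₋₁² − xᵢxᵢ₋₂)) → 100 features per epoch,
   optionally + age/weight/height.
5. **Selection** — features ranked by the Fisher score
   F_j = (μ_j1 − μ_j0)² / (s²_j1 + s²_j0), with the association level
   R_j = |point-biserial correlation| reported alongside; ten nested
   levels keep the top 5%, 10%, …, 50%.
6. **Classification** — kNN (k ∈ {3,5,7}; euclidean, manhattan,
   minkowski-3), RBF-SVM and bagged decision trees, each tuned by
   grid search minimizing 5-fold stratified CV misclassification on
   z-scored training features; a **hybrid** model takes the majority vote
   of the three hard labels.
7. **Evaluation** — sensitivity, specificity, accuracy (%), Cohen's
   kappa with agreement bands, F-measure (F1) and AUC, from the
   COPD-positive confusion matrix.

Two split protocols are built in: the epoch-random 50/50 split (epochs of
every subject appear on both sides — optimistic, because subject traits
leak) and leave-one-subject-out (subject-disjoint, the honest estimate).
Both are exposed precisely so the gap is measurable.

The clinical recordings the method was designed around are not publicly
deposited, so the package ships a seeded synthetic cohort generator
(`ppgcopd.synth`) producing quasi-periodic two-bump pulse waveforms with
respiratory modulation, baseline wander, instrument noise and a
controllable COPD-vs-healthy effect δ (weaker, more irregular, noisier
pulses). See `docs/methods.md` for what it does and does not emulate.

## Worked example

```python
import ppgcopd as pc

cfg = pc.RunConfig(
    synth=pc.CohortSpec(n_copd=5, n_healthy=5, duration_s=120.0,
                        effect_size=3.0),
    pools=("PPG",), levels="all-features", seed=42)
bundle = pc.run(cfg)
print(bundle["table"].to_string(index=False))
```

prints (600 two-second epochs, epoch-random 50/50 split):

```
pool level         model  Sensitivity  Specificity  Accuracy    Kappa  F-measure      AUC
 PPG   all           knn     0.993333     0.986667 99.000000 0.980000   0.990033 0.993289
 PPG   all           svm     1.000000     0.986667 99.333333 0.986667   0.993377 1.000000
 PPG   all ensemble_tree     0.993333     0.993333 99.333333 0.986667   0.993333 0.999956
 PPG   all        hybrid     1.000000     0.986667 99.333333 0.986667   0.993377 0.999956
```

Each row is one model's test-half performance using all 25 PPG-band
features: at a strong synthetic class effect (δ = 3) every model separates
the classes almost perfectly, and the hybrid matches its best members.
Accuracy is on the percent scale; the other criteria are proportions. With
`effect_size=0.0` the same pipeline stays at chance (≈ 50%), and with
`split_mode="leave_one_subject_out"` you get the subject-disjoint estimate.

The same stages are scriptable from the shell:

```sh
ppgcopd simulate --out cohort/ --n-copd 5 --n-healthy 5 --duration-s 120 --seed 1
ppgcopd features --manifest cohort/manifest.csv --out features.csv
ppgcopd rank     --features features.csv --pool ALL --out ranking.csv
ppgcopd train    --features features.csv --pool ALL --level 5 --out predictions.csv
ppgcopd evaluate --predictions predictions.csv --out report.csv
```

## Layout

| module | contents |
| --- | --- |
| `ppgcopd.records` | `PpgRecord`/`Cohort`, CSV + EDF I/O, manifests |
| `ppgcopd.preprocess` | denoising, LF/MF/HF decomposition, epoching, periodogram |
| `ppgcopd.features` | the 25 descriptors, feature-matrix assembly |
| `ppgcopd.selection` | Fisher ranking, R interpretation, selection levels |
| `ppgcopd.classify` | splits, tuned kNN/SVM/bagged trees, hybrid vote |
| `ppgcopd.evaluate` | confusion matrix, six criteria, kappa bands, tables |
| `ppgcopd.synth` | seeded synthetic PPG cohort generator |
| `ppgcopd.pipeline` / `ppgcopd.cli` | end-to-end orchestration, YAML config, CLI |
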