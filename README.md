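# ftir-recur

A chemometric analysis pipeline for detecting **non-muscle-invasive
bladder cancer (NMIBC) recurrence from urine ATR-FTIR spectra**. NMIBC
follow-up relies on repeated cystoscopy; a spectroscopic liquid-biopsy
readout of urine is a candidate non-invasive alternative. The analytical
challenge is not the classifier itself but everything around it:
replicate spectra of one urine sample are near-duplicates that leak
across naive train/test splits, acquisition batches drift, the classes
are imbalanced, and the preprocessing (derivative order, window,
normalization band, wavenumber range, binning) changes model performance
as much as the model family does.

`ftir-recur` packages that whole workflow for researchers working with
biofluid mid-IR fingerprinting:

- **Spectra I/O and domain types** — wide/long CSV and JCAMP-DX readers,
  metadata sidecars, strict grid/replicate/label invariants.
- **Preprocessing grid** — Savitzky–Golay derivatives (polyorder 3,
  windows 5–13, trimmed edges), band-maximum (amide 1500–1700 /
  urea 1400–1500 cm⁻¹) and vector normalization, range extraction
  (500–4000, 700–900, 700–1800, 2800–3000 cm⁻¹), channel binning —
  720 variants, 25,200 runs across 35 declared model families.
- **Technical-variability QC** — PCA by batch, within-replicate /
  across-patient / across-batch Euclidean distance distributions,
  Wilcoxon rank-sum tests.
- **Outlier removal** — a pcout-style robust principal-component
  detector (kurtosis-weighted location + scatter outlyingness,
  translated biweight weights) applied once before splitting.
- **Leakage-safe resampling** — patient-grouped 70:30 split, stratified
  group k-fold, and hand-rolled SMOTE applied strictly inside training
  folds.
- **Model search** — scikit-learn backends behind caret-style names
  (`rf`, `RRF`, `ranger`, `cforest`, `gbm`, `svmPoly`, `mlp`,
  `LogitBoost`, `gaussprRadial`), tuned by grouped CV with AUROC
  (Mann–Whitney rank form) as the objective; dual-criterion selection
  (CV ROC > 0.8 and test F1 > 0.5) and multi-seed revalidation.
- **Importance profiling** — permutation importance (AUROC drop,
  out-of-bag for forests) and per-wavenumber univariate ROC, aligned to
  bin centers so spikes can be read off against band assignments
  (e.g. lipid CH₂ asymmetric stretching near 2912 cm⁻¹).
- **Synthetic cohorts** — a generator reproducing the study's data
  structure (41 NMIBC-free + 21 recurrence patients, triplicate
  spectra, 7 batches, a QC sample in every batch, 4 cm⁻¹ grid,
  urea/amide/lipid band structure, class effects on the 2912 and
  2980 cm⁻¹ bands) so the full pipeline is testable without any
  clinical data.

## Worked example

```python
from ftir_recur import (CohortConfig, PreprocessConfig, generate_cohort,
                        grouped_split, stratified_group_kfold, run_search,
                        profile_cohort, locate_peaks)
from ftir_recur.models import _labeled_patients

cohort, truth = generate_cohort(CohortConfig(seed=7))   # 193 spectra

patients = _labeled_patients(cohort)
split = grouped_split(patients, ratio=0.7, seed=7)      # 44 train / 18 test
folds = stratified_group_kfold(
    [(p, l) for p, l in patients if p in set(split.train_patients)],
    k=3, repeats=1, seed=7)

config = PreprocessConfig(range="ch_stretch", sg_derivative=1,
                          sg_window=13, bin_size=1, normalization="urea")
record = run_search(cohort, [("rf", config)], split, folds, seed=7)[0]
print(f"CV ROC:       {record.cv_roc:.3f}")
print(f"test AUROC:   {record.test_auroc:.3f}")
print(f"test F1:      {record.test_f1:.3f}")
print(f"sensitivity:  {record.sensitivity:.2f}")
print(f"specificity:  {record.specificity:.2f}")

profile = profile_cohort(cohort, PreprocessConfig(range="ch_stretch"), seed=7)
for w, h in locate_peaks(profile, 2):
    print(f"importance peak at {w:.0f} cm^-1 (height {h:.2f})")
```

Output:

```
CV ROC:       0.989
test AUROC:   0.983
test F1:      0.872
sensitivity:  0.94
specificity:  0.89
importance peak at 2980 cm^-1 (height 1.00)
importance peak at 2912 cm^-1 (height 0.21)
```

The forest, trained with SMOTE-balanced patient-grouped folds on the
first-derivative, urea-normalized C–H stretching region, separates the
synthetic recurrence class almost perfectly (the generator plants a 1.3×
amplitude effect on the 2912 and 2980 cm⁻¹ lipid bands), and the
permutation-importance profile localizes exactly those two bands.

The same workflow is scriptable from the shell:

```bash
ftir-recur simulate --seed 7 --out-spectra s.csv --out-meta m.csv --out-truth t.csv
ftir-recur qc --spectra s.csv --meta m.csv --out qc.json
ftir-recur run-all --config pipeline.yaml     # full search -> run directory
```

## Layout

```
src/ftir_recur/
  spectra.py     # domain types, CSV/JCAMP-DX I/O, label collapsing
  preprocess.py  # SG derivatives, normalizations, binning, pipeline
  qc.py          # PCA, distance groups, Wilcoxon rank-sum
  outliers.py    # pcout-style robust outlier detection
  resampling.py  # grouped split, group k-fold, SMOTE
  models.py      # registry, metrics, grid search, selection, revalidation
  importance.py  # permutation importance, univariate ROC, peaks
  synthetic.py   # cohort generator + truth checks
  pipeline.py    # end-to-end driver with manifest
  cli.py         # `ftir-recur` subcommands
```

See `docs/methods.md` for the statistical model, parameter defaults, and
the design decisions behind the transform order, leakage guards, and
importance evaluation.
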