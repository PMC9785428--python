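# Methods

`ftir-recur` implements a chemometric classification workflow for urine
ATR-FTIR spectra: given per-measurement absorbance traces with patient,
replicate, batch and cystoscopy-label metadata, it searches a
preprocessing × model grid for a classifier of NMIBC recurrence, guards
the search against the leakage modes this data structure invites, and
profiles which wavenumbers carry the decision. Because clinical spectra
of this kind are rarely public, the package ships a synthetic cohort
generator with the same statistical structure, so every stage is
testable end to end.

## Data model

A spectrum is absorbance over a strictly ascending wavenumber grid
(cm⁻¹); a cohort (`SpectraSet`) shares one grid. Files arriving with
descending grids (the common FTIR export convention) are reversed on
read. Spectra on mismatched grids are rejected, never silently
interpolated — an explicit `regrid` utility exists for deliberate
resampling. Each spectrum carries `(patient_id, replicate_index,
batch_id)` (unique within a set), a QC flag, and a label in
`{free, recurrence, unknown}`. QC spectra are always unlabeled and never
enter training. The four raw cystoscopy outcomes (free, hyperplasia,
inflammation, recurrence) collapse to the binary response with
recurrence as the positive class.

## Preprocessing grid

One grid point is `(range, sg_derivative, sg_window, bin_size,
normalization)`:

| axis | values | notes |
|---|---|---|
| range | full 500–4000, bacterial 700–900, fingerprint 700–1800, C–H stretch 2800–3000 cm⁻¹ | closed intervals |
| SG derivative | 0, 1, 2 | polynomial order fixed at 3 |
| SG window | 5, 7, 9, 13 channels | trimmed edges, see below |
| bin size | 1, 2, 3, 5, 10 channels | block means |
| normalization | none, amide (1500–1700), urea (1400–1500) | band maximum; vector norm available |

That is 720 preprocessing variants; across the 35 declared model
families the full product is 25,200 runs.

Transform order is derivative → normalization → range extraction →
binning, and it is fixed: the amide and urea reference bands lie outside
three of the four analysis ranges, so band scaling must act before the
range is cut, and it acts on the derivative signal because that is the
representation the classifier sees. After a derivative the band divisor
is `max |·|` in-band, keeping the operator defined for signed spectra.
Savitzky–Golay filtering trims `(window−1)/2` channels per edge instead
of extrapolating; because the filter runs on the full acquired grid, the
interior analysis ranges are unaffected. Binning drops a trailing
partial bin so all features have equal width. A rubberband (lower convex
hull) baseline is available but off by default, matching workflows where
spectra arrive already baseline-corrected.

## Technical-variability QC

Before modeling, the cohort is examined for batch structure: PCA on
column-centered (unscaled — spectra share units) vector-normalized
spectra, and the distribution of pairwise Euclidean distances split into
three exclusive groups: same patient (within-replicate), different
patients in one batch, different patients across batches. Wilcoxon
rank-sum tests (midranks; exact enumeration for combined n ≤ 10 without
ties, otherwise normal approximation with tie and continuity
corrections) compare the groups. In a healthy cohort, within-replicate
distances are stochastically smallest and across-batch distances are not
systematically inflated relative to across-patient ones. The three-group
partition is one documented reading of replicate/patient/batch
variability; batch-effect *correction* is deliberately out of scope.

## Outlier detection

Multivariate outliers are flagged once, before splitting, on a single
exploratory representation (full range, no derivative, vector norm), and
the flags are reused across the whole grid search. The detector follows
the principal-component scheme of Filzmoser, Maronna & Werner (2008):
median/MAD column scaling; PCs covering ≥ 99 % variance; rescaled scores;
location outlyingness from kurtosis-weighted robust distances and
scatter outlyingness from unweighted ones; translated-biweight weights;
final weight the scaled product of the two, flagged below 0.25. One
constant is recalibrated: the location-phase biweight reaches zero at
`median + 6·MAD` rather than the published `median + 2.5·MAD`. At the
published value the detector flags roughly 10 % of perfectly clean
Gaussian data at cutoff 0.25 (a known liberality of the scheme); at 6.0
the measured clean-data flag rate is ~4 % while contaminants shifted by
≥ 5 robust SDs are still flagged essentially always. The published
constant remains available via `location_translation=2.5`.

## Resampling and class imbalance

All assignments are made at the patient level and inherited by spectra:
a 70:30 class-stratified patient split (per class,
`floor(n·ratio + 0.5)` patients to training, seeded shuffle) and a
stratified group k-fold (patients shuffled within class, dealt
round-robin; fold class counts differ by ≤ 1 patient). Replicates of a
patient therefore never straddle a boundary.

SMOTE handles the 41:21 imbalance: each synthetic minority row is
`x + g·(x_nn − x)` with `x_nn` one of the k = 5 nearest minority
neighbors and `g ~ U(0,1)` — an exact convex combination of two real
rows. Balancing happens only inside training folds (and on the training
split for the final refit), never on validation folds or the test set;
oversampling before splitting would put interpolates of validation
points into training. Minority rows are raised to parity with the
majority. The CV driver exposes an audit hook that records, per fold,
how many synthetic rows were trained on and exactly which real rows were
scored, so the leakage invariants are tested rather than assumed.

## Model search and selection

The registry maps caret-style family names to scikit-learn backends with
small tuning grids: `rf`/`RRF` random forests (the `RRF` grid includes
mtry = 2), `ranger` extremely-randomized trees, `cforest` a forest with
per-tree subsampling, `gbm` gradient boosting, `svmPoly` a scaled
polynomial-kernel SVM, `mlp` a single-hidden-layer network,
`LogitBoost` stump boosting, `gaussprRadial` an RBF Gaussian-process
classifier. Thirty-five family names are declared so the full search
cardinality is well-defined; the nine above have fitted backends, and
the registry is an ordinary dict open to extension. Regularized-
feature-entry forests are out of scope; `RRF` denotes the forest with
small-mtry tuning.

Per grid point: preprocess, tune by grouped CV maximizing mean
validation AUROC (SMOTE inside each training fold; single-class
validation folds are skipped), refit the best tuning on the full
training split, and score the held-out test spectra (spectrum-level by
default; patient-level aggregation averages replicate probabilities).
AUROC is computed by the Mann–Whitney rank formula (ties count ½);
threshold metrics call probabilities ≥ 0.5 positive and define F1 = 0
when precision + recall = 0. Backend failures become failed records,
not crashes.

Selection applies the dual criterion CV ROC > 0.8 **and** test F1 > 0.5:
the first screens out configurations that merely got lucky on the test
split (high test scores with near-chance CV performance), the second
screens out overfit ones. `revalidate` then repeats the whole
split/tune/test cycle across fresh seeds (default 10) to measure
robustness to the partition itself.

## Importance profiling

`permutation_importance` is model-agnostic: the mean drop in AUROC over
repeated random permutations of one feature column, negatives clipped,
max-normalized. Evaluation rows are out-of-bag when the model is a
bootstrap forest fitted on exactly the rows provided (per-tree OOB
predictions; a feature no tree uses gets importance exactly 0),
otherwise a held-out split. A univariate profile scores each wavenumber
bin alone, folded to `max(a, 1−a)` so direction does not matter.

Two failure modes shape the cohort-level default (`profile_cohort`).
Row-level OOB evaluation on replicate data leaks patient identity: a
tree trained on one replicate scores its out-of-bag sibling, so any
patient-specific channel acquires spurious importance. Held-out
evaluation avoids that but saturates when the test AUROC is 1.0 — no
single-channel permutation registers a drop. `profile_cohort` therefore
averages replicates per patient (making the forests' row bootstrap a
patient bootstrap: OOB rows belong to unseen patients and OOB AUROC
stays informative) and averages importance over three independently
seeded forests to damp forest-sampling noise. Peaks are local maxima of
the importance vector ranked by height, reported at bin centers.

## Synthetic cohorts

The generator emulates the assumed data structure, not urine physics:
Gaussian bands (urea ~1460 cm⁻¹ dominant; amide I/II inside their
normalization windows; fingerprint bands; the C–H quartet at
2850/2912/2960/2980 cm⁻¹; a broad O–H/N–H envelope) on a 500–4000 cm⁻¹
grid at 4 cm⁻¹. Defaults are the study conditions: 41 free + 21
recurrence patients, 3 replicates each, 7 acquisition batches, one QC
sample re-measured in every batch (193 spectra). Per patient, band
amplitudes get multipliers ~N(1, 0.08); recurrence patients additionally
multiply the 2912 and 2980 cm⁻¹ band amplitudes by 1.3. Replicate noise
is N(0, 0.02) per band — an order below patient variation, which is what
makes the replicate < patient distance ordering testable. Batches add a
smooth offset (SD 0.01) and gain (SD 2 %); each measurement gets a random
quadratic baseline (coefficient SD 0.005) and white channel noise
(SD 0.003). All draws flow from one seed; a truth table records the
latent effects and `truth_check` verifies the distance ordering and
band-integral signs before anything downstream is trusted.

What the generator does **not** emulate: Lorentzian/Voigt line shapes,
ATR penetration-depth dispersion, water-vapor artifacts, correlated
metabolite panels, or realistic between-lab variation. Passing tests
therefore demonstrate that the *pipeline machinery* is correct and
leakage-free under the assumed structure — not that any particular
clinical performance level is attainable.

## Verification problem sizes

The test suite runs everything at desk scale: the null calibration
(class effects removed; selected-model test AUROC must average into
[0.4, 0.6]) uses 20 seeded cohorts with a single forest configuration
and 3-fold CV; the signal-recovery check uses 10 seeded cohorts, a
4-range mini-grid, and requires the top two importance peaks within 3
channels (12 cm⁻¹) of the planted bands in ≥ 9/10 seeds plus selection
concentrating on the 2800–3000 cm⁻¹ range; outlier recovery uses 50
contaminated and 20 clean draws. `scripts/acceptance.py` recomputes the
same quantities from scratch at one seed.

## Known limitations

- The 35-name registry fits only 9 backends; the remaining names exist
  for search-cardinality purposes and produce failed records if run.
- pcout here is a from-description reimplementation; edge behavior may
  differ from the R original (one constant deliberately recalibrated,
  above).
- Exact Wilcoxon enumeration is limited to combined n ≤ 10 without ties.
- JCAMP-DX support covers the `(X++(Y..Y))` fixed-grid form only.
- CV repeats default to 3 in the pipeline config (1 in the desk-scale
  tests); the number of repeats used in any given study is rarely
  reported, and results are insensitive to it here.
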