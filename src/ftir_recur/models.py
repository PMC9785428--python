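"""Model registry, evaluation metrics, grid search, and revalidation.

The search space is the Cartesian product of preprocessing
configurations and classifier families. For each grid point the
classifier is tuned by patient-grouped cross-validation with mean AUROC
as the objective (SMOTE balancing inside training folds only), refit on
the full training split, and evaluated on the held-out test split with
recurrence as the positive class.

Model families are scikit-learn backends keyed by their caret-style
names. Thirty-five names are declared (fixing the grid cardinality of
the full search); nine ship with fitted backends — the families whose
selection behavior the analysis actually examines. The registry is a
plain dict and open for extension.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from scipy.stats import rankdata

from .preprocess import FeatureMatrix, PreprocessConfig, apply_pipeline
from .resampling import (
    FoldPlan,
    SplitPlan,
    balance_training_fold,
    grouped_split,
    stratified_group_kfold,
)

__all__ = [
    "ModelFamily",
    "SearchRecord",
    "SelectionCriteria",
    "CARET_MODEL_NAMES",
    "default_model_registry",
    "auroc",
    "roc_points",
    "binary_metrics",
    "enumerate_grid",
    "run_search",
    "records_to_frame",
    "select_models",
    "revalidate",
]

POSITIVE_LABEL = "recurrence"

#: The full declared model-name list (35 names). Families without a
#: registered backend still count toward grid cardinality but cannot be
#: fitted.
CARET_MODEL_NAMES = [
    "rf", "ranger", "cforest", "RRF", "gbm", "svmPoly", "mlp",
    "LogitBoost", "gaussprRadial",
    "glmnet", "pls", "knn", "nb", "lda", "qda", "svmRadial", "svmLinear",
    "nnet", "avNNet", "xgbTree", "xgbLinear", "C5.0", "rpart", "treebag",
    "bagEarth", "earth", "pam", "sda", "hdda", "glm", "bayesglm", "plr",
    "spls", "wsrf", "parRF",
]
assert len(CARET_MODEL_NAMES) == 35 and len(set(CARET_MODEL_NAMES)) == 35


@dataclass
class ModelFamily:
    """A named classifier constructor plus its tuning grid."""

    name: str
    factory: object  # callable(seed, **hyperparams) -> unfitted estimator
    tuning_grid: dict = field(default_factory=dict)

    def candidates(self):
        """Yield hyperparameter dicts from the grid (deterministic order)."""
        if not self.tuning_grid:
            yield {}
            return
        keys = sorted(self.tuning_grid)
        for combo in itertools.product(*(self.tuning_grid[k] for k in keys)):
            yield dict(zip(keys, combo))

    def build(self, seed: int, **hyperparams):
        return self.factory(seed, **hyperparams)


def default_model_registry(n_estimators: int = 100) -> dict:
    """The nine fitted model families.

    "RRF" maps to a random forest whose tuning grid includes mtry=2
    (the regularized-feature-entry internals are out of scope);
    "ranger" to an extremely-randomized forest; "cforest" to a forest
    with per-tree subsampling; "LogitBoost" to stump-based adaptive
    boosting.
    """
    def forest(seed, **kw):
        return RandomForestClassifier(n_estimators=n_estimators, random_state=seed, **kw)

    def extra(seed, **kw):
        return ExtraTreesClassifier(n_estimators=n_estimators, random_state=seed, **kw)

    def subsampled_forest(seed, **kw):
        return RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, max_samples=0.632, **kw
        )

    def gbm(seed, **kw):
        return GradientBoostingClassifier(random_state=seed, **kw)

    def svm_poly(seed, **kw):
        return make_pipeline(
            StandardScaler(), SVC(kernel="poly", probability=True, random_state=seed, **kw)
        )

    def mlp(seed, **kw):
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(random_state=seed, max_iter=2000, **kw),
        )

    def logit_boost(seed, **kw):
        return AdaBoostClassifier(random_state=seed, **kw)

    def gauss_rbf(seed, **kw):
        return make_pipeline(
            StandardScaler(),
            GaussianProcessClassifier(kernel=1.0 * RBF(1.0), random_state=seed, **kw),
        )

    return {
        "rf": ModelFamily("rf", forest, {"max_features": ["sqrt", 2]}),
        "ranger": ModelFamily("ranger", extra, {"max_features": ["sqrt"]}),
        "cforest": ModelFamily("cforest", subsampled_forest, {"max_features": ["sqrt"]}),
        "RRF": ModelFamily("RRF", forest, {"max_features": [2, "sqrt"]}),
        "gbm": ModelFamily("gbm", gbm, {"max_depth": [2], "n_estimators": [100]}),
        "svmPoly": ModelFamily("svmPoly", svm_poly, {"svc__degree": [2], "svc__C": [1.0]}),
        "mlp": ModelFamily("mlp", mlp, {"mlpclassifier__hidden_layer_sizes": [(5,)]}),
        "LogitBoost": ModelFamily("LogitBoost", logit_boost, {"n_estimators": [50]}),
        "gaussprRadial": ModelFamily("gaussprRadial", gauss_rbf, {}),
    }


# ---------------------------------------------------------------------------
# metrics


def _binarize(labels, pos_label=None):
    y = np.asarray(labels)
    if y.dtype == bool:
        return y
    if pos_label is None:
        pos_label = POSITIVE_LABEL if y.dtype.kind in "UO" else 1
    return y == pos_label


def auroc(scores, labels, pos_label=None) -> float:
    """AUROC via the Mann–Whitney rank formula.

    Equals P(score_pos > score_neg) + 0.5 P(tie); midranks handle ties.
    """
    scores = np.asarray(scores, float)
    y = _binarize(labels, pos_label)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUROC")
    ranks = rankdata(scores)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores, labels, pos_label=None):
    """(fpr, tpr, thresholds) of the ROC curve, for plotting."""
    y = _binarize(labels, pos_label)
    return _sk_roc_curve(y, np.asarray(scores, float))


def binary_metrics(probabilities, labels, threshold: float = 0.5,
                   pos_label=None) -> dict:
    """Accuracy, F1, sensitivity, specificity and the confusion table.

    Recurrence is the positive class; probabilities exactly at the
    threshold are called positive. F1 is defined as 0 when precision
    and recall are both 0.
    """
    p = np.asarray(probabilities, float)
    if len(p) == 0:
        raise ValueError("empty input")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y = _binarize(labels, pos_label)
    pred = p >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    accuracy = (tp + tn) / len(y)
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity > 0 else 0.0)
    return {
        "accuracy": accuracy,
        "f1": f1,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }


# ---------------------------------------------------------------------------
# search


@dataclass
class SelectionCriteria:
    """Dual-criterion filter: CV ROC above threshold AND test F1 above
    threshold — screens out both overfit and underfit grid points."""

    min_cv_roc: float = 0.8
    min_test_f1: float = 0.5

    def __post_init__(self):
        for v in (self.min_cv_roc, self.min_test_f1):
            if not 0.0 < v < 1.0:
                raise ValueError("selection thresholds must lie in (0, 1)")

    def passes(self, record) -> bool:
        return (np.isfinite(record.cv_roc) and np.isfinite(record.test_f1)
                and record.cv_roc > self.min_cv_roc
                and record.test_f1 > self.min_test_f1)


@dataclass
class SearchRecord:
    model: str
    config: PreprocessConfig
    cv_roc: float = float("nan")
    test_accuracy: float = float("nan")
    test_f1: float = float("nan")
    test_auroc: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    confusion: dict = field(default_factory=dict)
    seed: int = 0
    best_params: dict = field(default_factory=dict)
    error: str = ""

    @property
    def failed(self) -> bool:
        return bool(self.error)


def enumerate_grid(config_space: dict, model_names) -> list:
    """Full Cartesian product of models × preprocessing configurations.

    Deterministic order: model, then range, derivative, normalization,
    window, bin.
    """
    if not config_space or not model_names:
        raise ValueError("empty search space")
    grid = []
    for model in model_names:
        for rng_name in config_space["range"]:
            for deriv in config_space["sg_derivative"]:
                for norm in config_space["normalization"]:
                    for window in config_space["sg_window"]:
                        for bin_size in config_space["bin_size"]:
                            grid.append(
                                (
                                    model,
                                    PreprocessConfig(
                                        range=rng_name,
                                        sg_derivative=deriv,
                                        sg_window=window,
                                        bin_size=bin_size,
                                        normalization=norm,
                                    ),
                                )
                            )
    return grid


def _labeled_patients(spectra_set):
    """Unique (patient_id, label) pairs over labeled, non-QC spectra."""
    seen = {}
    for s in spectra_set:
        if s.meta.is_qc or s.meta.label == "unknown":
            continue
        seen[s.meta.patient_id] = s.meta.label
    return sorted(seen.items())


def _rows_by_patients(meta, patients):
    pat = set(patients)
    return np.array([i for i, p in enumerate(meta["patient_id"]) if p in pat], int)


def _predict_proba_pos(estimator, X):
    proba = estimator.predict_proba(X)
    classes = list(estimator.classes_)
    return proba[:, classes.index(True)]


def _cross_validate(family, features, meta, y, folds: FoldPlan,
                    train_patients, seed: int, leak_audit=None):
    """Mean CV AUROC per tuning candidate; returns (best_params, best_roc)."""
    train_set = set(train_patients)
    fold_rows = []
    for rep in range(folds.repeats):
        for fidx, fold_patients in folds.folds(rep):
            val_pat = [p for p in fold_patients if p in train_set]
            fit_pat = [p for p in train_set if folds.assignments[rep].get(p) != fidx]
            val_rows = _rows_by_patients(meta, val_pat)
            fit_rows = _rows_by_patients(meta, fit_pat)
            if len(val_rows) == 0 or len(np.unique(y[val_rows])) < 2:
                continue  # single-class validation fold: no AUROC
            fold_rows.append((rep, fidx, fit_rows, val_rows))
    if not fold_rows:
        raise ValueError("no usable CV folds (every fold single-class)")
    best_params, best_roc = None, -np.inf
    for params in family.candidates():
        rocs = []
        for rep, fidx, fit_rows, val_rows in fold_rows:
            fold_seed = (seed * 10007 + rep * 101 + fidx) % (2**31 - 1)
            Xb, yb, synth = balance_training_fold(
                features.values[fit_rows], y[fit_rows], seed=fold_seed
            )
            est = family.build(fold_seed, **params)
            est.fit(Xb, yb)
            scores = _predict_proba_pos(est, features.values[val_rows])
            if leak_audit is not None:
                leak_audit.append(
                    {"repeat": rep, "fold": fidx,
                     "n_val": len(val_rows),
                     "n_train_real": int((~synth).sum()),
                     "n_train_synthetic": int(synth.sum()),
                     "val_rows": val_rows.tolist()}
                )
            rocs.append(auroc(scores, y[val_rows]))
        mean_roc = float(np.mean(rocs))
        if mean_roc > best_roc:
            best_roc, best_params = mean_roc, params
    return best_params, best_roc


def _evaluate_grid_point(family, config, spectra_set, split, folds, seed,
                         aggregate_patient=False, leak_audit=None):
    features = apply_pipeline(spectra_set, config)
    meta = spectra_set.without_qc().meta_frame()
    meta = meta.set_index("sample_id").loc[features.sample_ids].reset_index()
    y = _binarize(meta["label"].to_numpy())
    labeled = meta["label"].to_numpy() != "unknown"
    if not labeled.all():
        keep = np.flatnonzero(labeled)
        features_values = features.values[keep]
        meta = meta.iloc[keep].reset_index(drop=True)
        y = y[keep]
    else:
        features_values = features.values
    # re-wrap so downstream indexing stays aligned
    features = FeatureMatrix(features_values, features.feature_wavenumbers,
                             list(meta["sample_id"]), config)

    best_params, cv_roc = _cross_validate(
        family, features, meta, y, folds, split.train_patients, seed,
        leak_audit=leak_audit,
    )
    train_rows = _rows_by_patients(meta, split.train_patients)
    test_rows = _rows_by_patients(meta, split.test_patients)
    Xb, yb, _ = balance_training_fold(
        features.values[train_rows], y[train_rows], seed=seed
    )
    est = family.build(seed, **best_params)
    est.fit(Xb, yb)
    scores = _predict_proba_pos(est, features.values[test_rows])
    y_test = y[test_rows]
    if aggregate_patient:
        test_pat = meta["patient_id"].to_numpy()[test_rows]
        agg_scores, agg_y = [], []
        for p in sorted(set(test_pat)):
            m = test_pat == p
            agg_scores.append(scores[m].mean())
            agg_y.append(y_test[m][0])
        scores = np.array(agg_scores)
        y_test = np.array(agg_y)
    m = binary_metrics(scores, y_test)
    return SearchRecord(
        model=family.name,
        config=config,
        cv_roc=cv_roc,
        test_accuracy=m["accuracy"],
        test_f1=m["f1"],
        test_auroc=auroc(scores, y_test),
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        confusion=m["confusion"],
        seed=seed,
        best_params=best_params,
    ), est, features


def run_search(spectra_set, grid, split: SplitPlan, folds: FoldPlan,
               criteria: SelectionCriteria | None = None, seed: int = 0,
               registry: dict | None = None, aggregate_patient: bool = False,
               leak_audit=None) -> list:
    """Evaluate every (model, PreprocessConfig) grid point.

    Per point: preprocess, tune by grouped CV maximizing mean AUROC
    (SMOTE inside training folds), refit on the training split, score
    the held-out test split. Backend failures become failed records,
    not crashes.
    """
    if not grid:
        raise ValueError("empty grid")
    registry = registry if registry is not None else default_model_registry()
    records = []
    for model_name, config in grid:
        if model_name not in registry:
            records.append(SearchRecord(model=model_name, config=config, seed=seed,
                                        error=f"no backend registered for {model_name!r}"))
            continue
        family = registry[model_name]
        try:
            record, _, _ = _evaluate_grid_point(
                family, config, spectra_set, split, folds, seed,
                aggregate_patient=aggregate_patient, leak_audit=leak_audit,
            )
        except Exception as exc:  # failed fits are recorded, not raised
            record = SearchRecord(model=model_name, config=config, seed=seed,
                                  error=f"{type(exc).__name__}: {exc}")
        records.append(record)
    return records


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        c = r.confusion or {}
        rows.append(
            {
                "model": r.model,
                "range": r.config.range,
                "sg_derivative": r.config.sg_derivative,
                "sg_window": r.config.sg_window,
                "bin_size": r.config.bin_size,
                "normalization": r.config.normalization,
                "cv_roc": r.cv_roc,
                "test_accuracy": r.test_accuracy,
                "test_f1": r.test_f1,
                "test_auroc": r.test_auroc,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "tp": c.get("tp"), "fp": c.get("fp"),
                "fn": c.get("fn"), "tn": c.get("tn"),
                "seed": r.seed,
                "error": r.error,
            }
        )
    return pd.DataFrame(rows)


def select_models(records, criteria: SelectionCriteria | None = None) -> dict:
    """Count passing configurations per model, sorted descending."""
    if not records:
        raise ValueError("no records")
    criteria = criteria or SelectionCriteria()
    counts = {}
    for r in records:
        if not r.failed and criteria.passes(r):
            counts[r.model] = counts.get(r.model, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def revalidate(model_name: str, config: PreprocessConfig, spectra_set,
               n_repeats: int = 10, seeds=None, ratio: float = 0.7,
               k: int = 10, cv_repeats: int = 1,
               registry: dict | None = None) -> pd.DataFrame:
    """Robustness against dataset splitting: repeat split + train + test.

    A fresh patient-grouped 70:30 split is drawn per seed; the model is
    tuned and refit each time, and accuracy / F1 / AUROC on the new test
    split are recorded.
    """
    if seeds is None:
        seeds = list(range(n_repeats))
    registry = registry if registry is not None else default_model_registry()
    patients = _labeled_patients(spectra_set)
    out = []
    for s in seeds:
        split = grouped_split(patients, ratio=ratio, seed=s)
        train_lab = [(p, l) for p, l in patients if p in set(split.train_patients)]
        folds = stratified_group_kfold(train_lab, k=k, repeats=cv_repeats, seed=s)
        rec = run_search(spectra_set, [(model_name, config)], split, folds,
                         seed=s, registry=registry)[0]
        out.append({"seed": s, "accuracy": rec.test_accuracy, "f1": rec.test_f1,
                    "auroc": rec.test_auroc, "error": rec.error})
    return pd.DataFrame(out)
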