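"""Per-wavenumber variable importance and univariate ROC profiling.

Importance is model-agnostic permutation importance: the mean drop in
AUROC when one feature column is shuffled. For bagged forests the
evaluation uses out-of-bag rows (each row scored only by trees that did
not see it in their bootstrap sample); for any other backend a held-out
evaluation split is used. Alongside it, a univariate ROC profile scores
each wavenumber bin on its own, folded to max(a, 1-a) so the direction
of the class difference does not matter.

Both vectors are aligned to the feature matrix's bin-center wavenumbers,
so they can be plotted under the spectra they explain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema

from .models import auroc, _predict_proba_pos, _binarize
from .preprocess import FeatureMatrix

__all__ = [
    "ImportanceProfile",
    "permutation_importance",
    "univariate_roc_profile",
    "locate_peaks",
    "build_profile",
    "profile_cohort",
]


@dataclass
class ImportanceProfile:
    feature_wavenumbers: np.ndarray
    importance: np.ndarray       # permutation importance, max-normalized
    univariate_roc: np.ndarray   # folded per-feature AUROC

    def __post_init__(self):
        n = len(self.feature_wavenumbers)
        if len(self.importance) != n or len(self.univariate_roc) != n:
            raise ValueError("profile vectors must align with wavenumbers")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavenumber": self.feature_wavenumbers,
                "importance": self.importance,
                "univariate_roc": self.univariate_roc,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _oob_masks(forest, n_samples):
    """Per-tree boolean OOB masks for a fitted bootstrap forest, or None."""
    if not getattr(forest, "bootstrap", False) or not hasattr(forest, "estimators_"):
        return None
    n_fit = getattr(forest, "_n_samples", None)
    if n_fit is not None and n_fit != n_samples:
        # rows are not the ones the forest was trained on: no valid OOB
        return None
    try:
        from sklearn.ensemble._forest import (
            _generate_unsampled_indices,
            _get_n_samples_bootstrap,
        )
    except ImportError:
        return None
    import inspect

    def _call(fn, *args):
        # the sample_weight argument appeared in newer sklearn versions
        if "sample_weight" in inspect.signature(fn).parameters:
            return fn(*args, None)
        return fn(*args)

    try:
        n_boot = _call(_get_n_samples_bootstrap, n_samples, forest.max_samples)
        masks = []
        for tree in forest.estimators_:
            mask = np.zeros(n_samples, dtype=bool)
            idx = _call(_generate_unsampled_indices, tree.random_state,
                        n_samples, n_boot)
            mask[idx] = True
            masks.append(mask)
    except TypeError:
        return None
    return masks


def _oob_scores(forest, X, masks):
    """Mean positive-class probability per row over trees holding it OOB."""
    pos_col = list(forest.classes_).index(True)
    total = np.zeros(X.shape[0])
    count = np.zeros(X.shape[0])
    for tree, mask in zip(forest.estimators_, masks):
        if not mask.any():
            continue
        proba = tree.predict_proba(X[mask])
        total[mask] += proba[:, pos_col]
        count[mask] += 1
    seen = count > 0
    scores = np.full(X.shape[0], np.nan)
    scores[seen] = total[seen] / count[seen]
    return scores, seen


def _tree_pos_proba(tree, X, pos_col):
    return tree.predict_proba(X)[:, pos_col]


def _oob_permutation_importance(forest, X, y, masks, n_permutations, rng):
    """OOB permutation importance, re-predicting only affected trees.

    A permuted feature changes a tree's predictions only if the tree
    splits on it, so unaffected trees keep their cached OOB
    contributions — which also makes the importance of a feature unused
    by every tree exactly zero.
    """
    n = X.shape[0]
    pos_col = list(forest.classes_).index(True)
    tree_preds = []
    count = np.zeros(n)
    total = np.zeros(n)
    for tree, mask in zip(forest.estimators_, masks):
        pred = np.zeros(n)
        if mask.any():
            pred[mask] = _tree_pos_proba(tree, X[mask], pos_col)
            count[mask] += 1
            total[mask] += pred[mask]
        tree_preds.append(pred)
    seen = count > 0
    baseline = auroc(total[seen] / count[seen], y[seen])

    trees_using = {}
    for t, tree in enumerate(forest.estimators_):
        for j in np.unique(tree.tree_.feature):
            if j >= 0:
                trees_using.setdefault(int(j), []).append(t)

    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        affected = trees_using.get(j, [])
        if not affected:
            continue  # importance exactly 0
        acc = 0.0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            Xp = X.copy()
            Xp[:, j] = X[perm, j]
            new_total = total.copy()
            for t in affected:
                mask = masks[t]
                if not mask.any():
                    continue
                new_pred = _tree_pos_proba(forest.estimators_[t], Xp[mask], pos_col)
                new_total[mask] += new_pred - tree_preds[t][mask]
            acc += baseline - auroc(new_total[seen] / count[seen], y[seen])
        drops[j] = acc / n_permutations
    return drops


def permutation_importance(fitted_model, features: FeatureMatrix | np.ndarray,
                           labels, n_permutations: int = 10,
                           seed: int = 0) -> np.ndarray:
    """Mean AUROC drop per permuted feature column, negatives clipped.

    If ``fitted_model`` is a bootstrap forest fit on exactly these rows,
    the baseline and permuted AUROCs are computed from out-of-bag
    predictions; otherwise ``features``/``labels`` are treated as a
    held-out evaluation split and scored with ``predict_proba``.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = _binarize(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation rows must contain both classes")
    rng = np.random.default_rng(seed)

    masks = _oob_masks(fitted_model, X.shape[0])
    if masks is not None:
        drops = _oob_permutation_importance(fitted_model, X, y, masks,
                                            n_permutations, rng)
        return np.clip(drops, 0.0, None)

    if hasattr(fitted_model, "estimators_") and hasattr(fitted_model, "classes_"):
        # forest probabilities are the mean over trees, so the
        # affected-trees shortcut applies on held-out rows too
        masks = [np.ones(X.shape[0], bool)] * len(fitted_model.estimators_)
        drops = _oob_permutation_importance(fitted_model, X, y, masks,
                                            n_permutations, rng)
        return np.clip(drops, 0.0, None)

    baseline = auroc(_predict_proba_pos(fitted_model, X), y)
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        acc = 0.0
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            acc += baseline - auroc(_predict_proba_pos(fitted_model, Xp), y)
        drops[j] = acc / n_permutations
    return np.clip(drops, 0.0, None)


def univariate_roc_profile(features: FeatureMatrix | np.ndarray, labels) -> np.ndarray:
    """Per-feature AUROC of the raw values, folded to max(a, 1-a)."""
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = _binarize(labels)
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        a = auroc(X[:, j], y)
        out[j] = max(a, 1.0 - a)
    return out


def build_profile(fitted_model, features: FeatureMatrix, labels,
                  n_permutations: int = 10, seed: int = 0) -> ImportanceProfile:
    """Importance (max-normalized) + univariate ROC, wavenumber-aligned."""
    imp = permutation_importance(fitted_model, features, labels,
                                 n_permutations=n_permutations, seed=seed)
    peak = imp.max()
    if peak > 0:
        imp = imp / peak
    return ImportanceProfile(
        feature_wavenumbers=np.asarray(features.feature_wavenumbers, float),
        importance=imp,
        univariate_roc=univariate_roc_profile(features, labels),
    )


def profile_cohort(spectra_set, config, n_models: int = 3,
                   n_permutations: int = 10, seed: int = 0,
                   patient_average: bool = True,
                   model_factory=None) -> ImportanceProfile:
    """Wavenumber importance profile for a whole labeled cohort.

    Replicate spectra are averaged per patient so that the forests'
    row-level bootstrap is a patient-level bootstrap: out-of-bag rows
    then belong to patients a tree has never seen, which removes
    replicate identity leakage and keeps OOB AUROC away from
    saturation. Importance is averaged over ``n_models`` independently
    seeded forests to damp forest-sampling noise.
    """
    from .preprocess import apply_pipeline
    from sklearn.ensemble import RandomForestClassifier

    features = apply_pipeline(spectra_set, config)
    meta = spectra_set.without_qc().meta_frame().set_index("sample_id")
    meta = meta.loc[features.sample_ids]
    labeled = meta["label"].to_numpy() != "unknown"
    X = features.values[labeled]
    pids = meta["patient_id"].to_numpy()[labeled]
    labels = meta["label"].to_numpy()[labeled]
    if patient_average:
        patients = sorted(set(pids))
        X = np.vstack([X[pids == p].mean(axis=0) for p in patients])
        labels = np.array([labels[pids == p][0] for p in patients])
        ids = patients
    else:
        ids = list(meta.index[labeled])
    fm = FeatureMatrix(X, features.feature_wavenumbers, ids, config)
    y = _binarize(labels)
    if model_factory is None:
        def model_factory(s):
            return RandomForestClassifier(n_estimators=300, random_state=s)
    imps = []
    for k in range(n_models):
        sub_seed = (seed * 1000 + k) % (2**31 - 1)
        est = model_factory(sub_seed)
        est.fit(fm.values, y)
        imps.append(permutation_importance(est, fm, y,
                                           n_permutations=n_permutations,
                                           seed=sub_seed))
    imp = np.mean(imps, axis=0)
    peak = imp.max()
    if peak > 0:
        imp = imp / peak
    return ImportanceProfile(
        feature_wavenumbers=np.asarray(fm.feature_wavenumbers, float),
        importance=imp,
        univariate_roc=univariate_roc_profile(fm, y),
    )


def locate_peaks(profile: ImportanceProfile, top_n: int = 2) -> list:
    """Local maxima of the importance vector, ranked by height.

    Returns up to ``top_n`` ``(wavenumber, importance)`` pairs. A flat
    profile has no peaks. Plateau maxima report their first channel;
    boundary channels count as peaks when they exceed their neighbor.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    v = profile.importance
    if len(v) == 0 or np.allclose(v, v[0]):
        return []
    idx = list(argrelextrema(v, np.greater_equal, order=1)[0])
    # drop plateau repeats, keep strict-or-boundary maxima only
    peaks = []
    for i in idx:
        left = v[i - 1] if i > 0 else -np.inf
        right = v[i + 1] if i < len(v) - 1 else -np.inf
        if v[i] > left or v[i] > right:
            if not peaks or i != peaks[-1] + 1 or v[i] != v[peaks[-1]]:
                peaks.append(i)
    peaks.sort(key=lambda i: -v[i])
    return [(float(profile.feature_wavenumbers[i]), float(v[i]))
            for i in peaks[:top_n]]


def plot_profile(raw_set, processed: FeatureMatrix, profile: ImportanceProfile,
                 labels, path=None):
    """Four stacked panels: raw spectra, processed spectra, importance,
    univariate ROC — all on a shared wavenumber axis."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = _binarize(labels)
    fig, axes = plt.subplots(4, 1, figsize=(8, 10), sharex=True)
    lo, hi = profile.feature_wavenumbers[0], profile.feature_wavenumbers[-1]
    for s in raw_set:
        if s.meta.is_qc:
            continue
        mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
        color = "firebrick" if s.meta.label == "recurrence" else "steelblue"
        axes[0].plot(s.wavenumbers[mask], s.absorbance[mask], color=color,
                     alpha=0.25, lw=0.5)
    axes[0].set_ylabel("raw absorbance")
    for i in range(processed.n_samples):
        color = "firebrick" if y[i] else "steelblue"
        axes[1].plot(processed.feature_wavenumbers, processed.values[i],
                     color=color, alpha=0.25, lw=0.5)
    axes[1].set_ylabel("processed")
    axes[2].plot(profile.feature_wavenumbers, profile.importance, color="black")
    axes[2].set_ylabel("importance")
    axes[3].plot(profile.feature_wavenumbers, profile.univariate_roc, color="black")
    axes[3].set_ylabel("univariate ROC")
    axes[3].set_xlabel("wavenumber (cm$^{-1}$)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
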