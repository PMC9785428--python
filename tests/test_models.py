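"""Metrics, grid enumeration, selection, and the search driver."""

import itertools

import numpy as np
import pytest

from ftir_recur.models import (
    CARET_MODEL_NAMES,
    SearchRecord,
    SelectionCriteria,
    auroc,
    binary_metrics,
    default_model_registry,
    enumerate_grid,
    records_to_frame,
    revalidate,
    run_search,
    select_models,
)
from ftir_recur.preprocess import PreprocessConfig, default_config_space
from ftir_recur.models import _labeled_patients
from ftir_recur.resampling import grouped_split, stratified_group_kfold


def pair_counting_auroc(scores, y):
    """Exhaustive oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, y) if l]
    neg = [s for s, l in zip(scores, y) if not l]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], pos_label=1) == 1.0

    def test_handworked_example(self):
        # pairs: .8>.5, .8>.1, .3<.5, .3>.1 -> 3/4
        assert auroc([0.8, 0.3, 0.5, 0.1], [1, 1, 0, 0], pos_label=1) == 0.75

    def test_all_ties_half(self):
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0], pos_label=1) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1], pos_label=1)

    def test_matches_pair_counting_oracle_randomized(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(2, 21)
            y = np.zeros(n, dtype=int)
            y[: rng.integers(1, n)] = 1
            rng.shuffle(y)
            if y.all() or not y.any():
                continue
            scores = rng.choice([0.1, 0.25, 0.5, 0.75, 0.9], size=n)
            assert auroc(scores, y, pos_label=1) == pytest.approx(
                pair_counting_auroc(scores, y), abs=1e-12
            )


class TestBinaryMetrics:
    def test_confusion_arithmetic(self):
        # TP=3 FP=1 FN=1 TN=5
        probs = [0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.2, 0.3, 0.4, 0.45]
        y = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        m = binary_metrics(probs, y, pos_label=1)
        assert m["confusion"] == {"tp": 3, "fp": 1, "fn": 1, "tn": 5}
        assert m["precision"] == pytest.approx(0.75)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_perfect_probabilities(self):
        m = binary_metrics([1.0, 1.0, 0.0], [1, 1, 0], pos_label=1)
        assert m["accuracy"] == 1.0 and m["f1"] == 1.0

    def test_degenerate_f1_zero(self):
        m = binary_metrics([0.1, 0.2, 0.3], [1, 1, 0], pos_label=1)
        assert m["f1"] == 0.0

    def test_threshold_ties_go_positive(self):
        m = binary_metrics([0.5], [1], pos_label=1)
        assert m["confusion"]["tp"] == 1

    def test_metrics_consistent_with_confusion(self):
        rng = np.random.default_rng(3)
        probs = rng.uniform(size=50)
        y = rng.integers(0, 2, 50)
        m = binary_metrics(probs, y, pos_label=1)
        c = m["confusion"]
        assert m["accuracy"] == (c["tp"] + c["tn"]) / 50
        assert m["sensitivity"] == pytest.approx(c["tp"] / (c["tp"] + c["fn"]))
        assert m["specificity"] == pytest.approx(c["tn"] / (c["tn"] + c["fp"]))


class TestGridEnumeration:
    def test_full_study_grid_cardinality(self):
        grid = enumerate_grid(default_config_space(), CARET_MODEL_NAMES)
        assert len(grid) == 25_200  # 720 preprocessing variants x 35 models

    def test_singletons(self):
        space = {"range": ["full"], "sg_derivative": [0],
                 "normalization": ["none"], "sg_window": [9], "bin_size": [1]}
        assert len(enumerate_grid(space, ["rf"])) == 1
        space["bin_size"] = [1, 2]
        assert len(enumerate_grid(space, ["rf", "gbm"])) == 4

    def test_deterministic_order(self):
        a = enumerate_grid(default_config_space(), ["rf", "gbm"])
        b = enumerate_grid(default_config_space(), ["rf", "gbm"])
        assert a == b
        assert a[0][0] == "rf" and a[-1][0] == "gbm"


class TestSelection:
    def _rec(self, model, cv, f1):
        return SearchRecord(model=model, config=PreprocessConfig(),
                            cv_roc=cv, test_f1=f1)

    def test_empty_when_none_pass(self):
        assert select_models([self._rec("rf", 0.5, 0.4)]) == {}

    def test_counts_by_model(self):
        recs = [self._rec("rf", 0.9, 0.7)] * 3 + [self._rec("gbm", 0.85, 0.6)]
        assert select_models(recs) == {"rf": 3, "gbm": 1}

    def test_overfit_high_f1_low_cv_excluded(self):
        # high test F1 cannot rescue a poor CV ROC: the dual criterion
        # screens out lucky-test-set configurations
        rec = self._rec("gaussprRadial", 0.46, 0.86)
        assert select_models([rec, self._rec("rf", 0.82, 0.71)]) == {"rf": 1}

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            SelectionCriteria(min_cv_roc=1.2)


@pytest.fixture(scope="module")
def small_search(small_cohort):
    cohort, _ = small_cohort
    pats = _labeled_patients(cohort)
    split = grouped_split(pats, 0.7, seed=7)
    train = [(p, l) for p, l in pats if p in set(split.train_patients)]
    folds = stratified_group_kfold(train, k=3, repeats=1, seed=7)
    return cohort, split, folds


class TestRunSearch:
    def test_strong_effect_mini_grid_high_auroc(self, small_search):
        cohort, split, folds = small_search
        grid = [
            ("rf", PreprocessConfig(range="ch_stretch")),
            ("gbm", PreprocessConfig(range="ch_stretch", bin_size=2)),
        ]
        records = run_search(cohort, grid, split, folds, seed=7)
        assert all(not r.failed for r in records)
        assert all(r.test_auroc > 0.8 for r in records)

    def test_determinism(self, small_search):
        cohort, split, folds = small_search
        grid = [("rf", PreprocessConfig(range="ch_stretch"))]
        r1 = run_search(cohort, grid, split, folds, seed=3)[0]
        r2 = run_search(cohort, grid, split, folds, seed=3)[0]
        assert (r1.cv_roc, r1.test_auroc, r1.confusion) == \
            (r2.cv_roc, r2.test_auroc, r2.confusion)

    def test_unregistered_model_is_failed_record(self, small_search):
        cohort, split, folds = small_search
        records = run_search(cohort, [("pls", PreprocessConfig())],
                             split, folds)
        assert records[0].failed and "pls" in records[0].error

    def test_validation_rows_are_real_spectra(self, small_search):
        # SMOTE must never leak synthetic rows into validation scoring
        cohort, split, folds = small_search
        audit = []
        run_search(cohort, [("rf", PreprocessConfig(range="ch_stretch"))],
                   split, folds, seed=1, leak_audit=audit)
        n_rows = len(cohort.without_qc())
        assert audit
        for entry in audit:
            assert entry["n_train_synthetic"] >= 0
            assert all(0 <= r < n_rows for r in entry["val_rows"])
            # validation fold count equals the real spectra of its patients
            assert entry["n_val"] <= n_rows

    def test_records_frame_columns(self, small_search):
        cohort, split, folds = small_search
        records = run_search(cohort, [("rf", PreprocessConfig(range="ch_stretch"))],
                             split, folds)
        df = records_to_frame(records)
        for col in ("model", "range", "cv_roc", "test_f1", "tp", "fn", "seed"):
            assert col in df.columns


def test_revalidate_distribution(small_cohort):
    cohort, _ = small_cohort
    df = revalidate("rf", PreprocessConfig(range="ch_stretch"), cohort,
                    n_repeats=3, k=3)
    assert len(df) == 3
    assert (df["error"] == "").all()
    assert df["auroc"].median() > 0.7
    df2 = revalidate("rf", PreprocessConfig(range="ch_stretch"), cohort,
                     n_repeats=3, k=3)
    np.testing.assert_array_equal(df["auroc"], df2["auroc"])


def test_registry_names_declared():
    registry = default_model_registry()
    assert set(registry) <= set(CARET_MODEL_NAMES)
    assert len(CARET_MODEL_NAMES) == 35
    for family in registry.values():
        assert list(family.candidates())  # at least one tuning candidate
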