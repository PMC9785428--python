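"""Patient-grouped splitting, stratified group k-fold, and SMOTE.

Replicate spectra of one urine sample must never straddle a train/test
boundary or a CV fold — otherwise near-duplicate spectra leak across the
boundary and inflate every performance estimate. All assignments here
are therefore made at the *patient* level and inherited by spectra.

SMOTE oversampling is applied only inside training folds, never to
validation folds or the held-out test set: oversampling before the split
would place synthetic interpolates of validation points into training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "SplitPlan",
    "FoldPlan",
    "grouped_split",
    "stratified_group_kfold",
    "smote",
    "balance_training_fold",
]


@dataclass
class SplitPlan:
    train_patients: list
    test_patients: list
    ratio: float
    seed: int

    def __post_init__(self):
        overlap = set(self.train_patients) & set(self.test_patients)
        if overlap:
            raise ValueError(f"patients in both train and test: {sorted(overlap)[:5]}")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "train_patients": list(self.train_patients),
                "test_patients": list(self.test_patients),
                "ratio": self.ratio,
                "seed": self.seed,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(d["train_patients"], d["test_patients"], d["ratio"], d["seed"])


@dataclass
class FoldPlan:
    k: int
    repeats: int
    assignments: list = field(default_factory=list)  # per repeat: {patient: fold}
    seed: int = 0

    def folds(self, repeat: int):
        """Yield (fold_index, patients_in_fold) for one repeat."""
        mapping = self.assignments[repeat]
        for f in range(self.k):
            yield f, [p for p, fi in mapping.items() if fi == f]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"k": self.k, "repeats": self.repeats, "seed": self.seed,
             "assignments": self.assignments},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _by_class(patients):
    classes = {}
    for pid, label in patients:
        classes.setdefault(label, []).append(pid)
    return classes


def grouped_split(patients, ratio: float = 0.7, seed: int = 0) -> SplitPlan:
    """Class-stratified random split of *patients* (not spectra).

    ``patients`` is a list of ``(patient_id, label)`` pairs. Per class,
    ``floor(n*ratio + 0.5)`` patients go to training (nearest rounding,
    ties up); membership comes from a seeded shuffle, so the plan is
    deterministic for a fixed seed.
    """
    classes = _by_class(patients)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for label in sorted(classes):
        pids = sorted(classes[label])
        if len(pids) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 patients")
        n_train = int(np.floor(len(pids) * ratio + 0.5))
        order = rng.permutation(len(pids))
        train.extend(pids[i] for i in order[:n_train])
        test.extend(pids[i] for i in order[n_train:])
    return SplitPlan(sorted(train), sorted(test), ratio, seed)


def stratified_group_kfold(patients, k: int = 10, repeats: int = 3,
                           seed: int = 0) -> FoldPlan:
    """Deal patients round-robin to k folds, shuffled within class.

    Fold class counts differ by at most one patient per class. Folds may
    lack a class entirely when k exceeds a class size (a warning is the
    caller's concern; CV simply skips single-class validation folds).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    classes = _by_class(patients)
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(repeats):
        mapping = {}
        offset = 0
        for label in sorted(classes):
            pids = sorted(classes[label])
            order = rng.permutation(len(pids))
            for i, idx in enumerate(order):
                # offset staggers classes so fold sizes stay balanced
                mapping[pids[idx]] = (i + offset) % k
            offset = (offset + len(pids)) % k
        assignments.append(mapping)
    return FoldPlan(k=k, repeats=repeats, assignments=assignments, seed=seed)


def smote(minority_rows, n_synthetic: int, k_neighbors: int = 5,
          seed: int = 0) -> np.ndarray:
    """Synthetic minority oversampling.

    Each synthetic row is ``x + g * (x_nn - x)`` with ``x`` a uniformly
    chosen minority row, ``x_nn`` one of its ``k_neighbors`` nearest
    minority neighbors (Euclidean), and ``g ~ Uniform(0, 1)`` — i.e. a
    convex combination of two real minority rows.
    """
    X = np.asarray(minority_rows, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("SMOTE needs at least 2 minority rows")
    if n_synthetic < 0:
        raise ValueError("n_synthetic must be >= 0")
    if n_synthetic == 0:
        return np.empty((0, X.shape[1]))
    k = min(k_neighbors, X.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, indices = nn.kneighbors(X)  # first neighbor is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, X.shape[0], size=n_synthetic)
    pick = rng.integers(1, k + 1, size=n_synthetic)
    g = rng.uniform(0.0, 1.0, size=n_synthetic)
    x = X[base]
    x_nn = X[indices[base, pick]]
    return x + g[:, None] * (x_nn - x)


def balance_training_fold(rows, labels, seed: int = 0, k_neighbors: int = 5):
    """Oversample the minority class to parity with the majority.

    Returns ``(rows, labels, is_synthetic)``; synthetic rows are
    appended after the real ones. Must only ever be applied to the
    training side of a fold.
    """
    X = np.asarray(rows, float)
    y = np.asarray(labels)
    values, counts = np.unique(y, return_counts=True)
    if len(values) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(values)}")
    n_needed = int(abs(counts[0] - counts[1]))
    if n_needed == 0:
        return X, y, np.zeros(len(y), dtype=bool)
    minority = values[np.argmin(counts)]
    synth = smote(X[y == minority], n_needed, k_neighbors=k_neighbors, seed=seed)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    flag = np.concatenate([np.zeros(len(y), bool), np.ones(n_needed, bool)])
    return X_out, y_out, flag
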