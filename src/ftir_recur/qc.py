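"""Technical-variability and batch-effect assessment.

Three views of a cohort before any modeling: a PCA colored by batch, the
distribution of pairwise Euclidean distances split into within-replicate
/ across-patient / across-batch groups, and Wilcoxon rank-sum tests
between those groups. If replicate noise is smaller than between-patient
variation and batches do not dominate, within-replicate distances should
be stochastically smaller than across-patient distances, and across-batch
distances should not be systematically inflated.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.stats import rankdata, norm
from sklearn.decomposition import PCA

from .spectra import SpectraSet
from .preprocess import FeatureMatrix, vector_normalize

__all__ = [
    "PcaResult",
    "DistanceGroups",
    "pca",
    "pairwise_distance_groups",
    "wilcoxon_rank_sum",
    "qc_report",
]


@dataclass
class PcaResult:
    scores: np.ndarray                    # samples x components
    explained_variance_ratio: np.ndarray  # per retained component
    component_loadings: np.ndarray        # components x features
    mean: np.ndarray                      # column means removed before projection

    def reconstruct(self) -> np.ndarray:
        """Inverse-transform the retained components (adds the mean back)."""
        return self.scores @ self.component_loadings + self.mean


@dataclass
class DistanceGroups:
    within_replicate: np.ndarray
    across_patient: np.ndarray
    across_batch: np.ndarray

    def as_dict(self):
        return {
            "within_replicate": self.within_replicate,
            "across_patient": self.across_patient,
            "across_batch": self.across_batch,
        }


def pca(matrix: FeatureMatrix | np.ndarray, n_components: int) -> PcaResult:
    """PCA on column-mean-centered (unscaled) features.

    Spectra share units, so columns are centered but not standardized;
    standardizing would inflate noise channels.
    """
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, features)="
            f"{min(n - 1, p)}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return PcaResult(
        scores=scores,
        explained_variance_ratio=model.explained_variance_ratio_,
        component_loadings=model.components_,
        mean=model.mean_,
    )


def pairwise_distance_groups(spectra_set: SpectraSet, include_qc: bool = False,
                             representation: str = "vector") -> DistanceGroups:
    """Partition all pairwise Euclidean distances into three groups.

    * ``within_replicate`` — both spectra from the same patient;
    * ``across_patient``  — different patients, same acquisition batch;
    * ``across_batch``    — different patients, different batches.

    Every eligible pair lands in exactly one group. Distances are
    computed on vector-normalized full-range spectra by default
    (``representation='raw'`` skips normalization).
    """
    spectra = [s for s in spectra_set if include_qc or not s.meta.is_qc]
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    if representation == "vector":
        rows = np.vstack([vector_normalize(s).absorbance for s in spectra])
    elif representation == "raw":
        rows = np.vstack([s.absorbance for s in spectra])
    else:
        raise ValueError(f"unknown representation {representation!r}")
    within, across_p, across_b = [], [], []
    for i, j in itertools.combinations(range(len(spectra)), 2):
        d = float(np.linalg.norm(rows[i] - rows[j]))
        mi, mj = spectra[i].meta, spectra[j].meta
        if mi.patient_id == mj.patient_id:
            within.append(d)
        elif mi.batch_id == mj.batch_id:
            across_p.append(d)
        else:
            across_b.append(d)
    return DistanceGroups(np.array(within), np.array(across_p), np.array(across_b))


def wilcoxon_rank_sum(x, y) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test with midranks.

    Exact p by enumeration of rank assignments when n_x + n_y <= 10 and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections. Returns the rank-sum statistic of ``x`` and
    the two-sided p-value.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        ranks = rankdata(pooled)
        return {"statistic": float(ranks[:nx].sum()), "p_two_sided": 1.0}
    ranks = rankdata(pooled)  # midranks for ties
    w = float(ranks[:nx].sum())
    u = w - nx * (nx + 1) / 2.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if nx + ny <= 10 and not has_ties:
        # enumerate all C(nx+ny, nx) assignments of ranks to group x
        all_ranks = np.arange(1, nx + ny + 1)
        total = comb(nx + ny, nx)
        count_le = count_ge = 0
        for combo in itertools.combinations(all_ranks, nx):
            s = sum(combo)
            if s <= w:
                count_le += 1
            if s >= w:
                count_ge += 1
        p = min(1.0, 2.0 * min(count_le, count_ge) / total)
        return {"statistic": w, "p_two_sided": p}
    n = nx + ny
    mean_u = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_u = nx * ny / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return {"statistic": w, "p_two_sided": 1.0}
    z = (abs(u - mean_u) - 0.5) / np.sqrt(var_u)  # continuity correction
    p = min(1.0, 2.0 * norm.sf(max(z, 0.0)))
    return {"statistic": w, "p_two_sided": float(p)}


def qc_report(spectra_set: SpectraSet, n_components: int = 10,
              path=None) -> dict:
    """Variance-explained, per-group distance quartiles, and rank-sum
    p-values between all group pairs; optionally written as JSON."""
    non_qc = spectra_set.without_qc()
    rows = np.vstack([vector_normalize(s).absorbance for s in non_qc])
    k = min(n_components, rows.shape[0] - 1, rows.shape[1])
    pca_res = pca(rows, k)
    groups = pairwise_distance_groups(spectra_set)
    gd = groups.as_dict()
    report = {
        "n_spectra": len(non_qc),
        "explained_variance_ratio": [float(v) for v in pca_res.explained_variance_ratio],
        "distance_quartiles": {
            name: [float(q) for q in np.percentile(vals, [25, 50, 75])] if len(vals) else []
            for name, vals in gd.items()
        },
        "rank_sum": {},
    }
    for (na, a), (nb, b) in itertools.combinations(gd.items(), 2):
        if len(a) and len(b):
            res = wilcoxon_rank_sum(a, b)
            report["rank_sum"][f"{na}_vs_{nb}"] = {
                "statistic": res["statistic"],
                "p_two_sided": res["p_two_sided"],
            }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report
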