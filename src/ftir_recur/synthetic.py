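"""Synthetic urine ATR-FTIR cohort generator.

Generates cohorts with the statistical structure the pipeline assumes:
Gaussian absorption bands (urea dominant, amide I/II, fingerprint and
C–H stretching bands) on a 4 cm^-1 grid, patient-level band-amplitude
variation, smaller replicate noise, smooth per-batch offset/gain
effects, a random quadratic baseline drift, white channel noise, and a
QC sample re-measured in every batch. A class effect multiplies the
amplitudes of selected bands (by default the lipid C–H bands near 2912
and 2980 cm^-1) for recurrence patients.

Every draw is governed by a single seed, so a config is reproducible
bit-for-bit. The accompanying truth table records the latent effects so
tests can verify the generator before trusting anything downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumMeta, SpectraSet
from .qc import pairwise_distance_groups

__all__ = [
    "BandModel",
    "CohortConfig",
    "default_band_library",
    "generate_cohort",
    "truth_check",
]


@dataclass(frozen=True)
class BandModel:
    """One Gaussian absorption band."""

    center: float          # cm^-1
    width: float           # Gaussian sigma, cm^-1
    amplitude: float       # absorbance units
    class_effect: float = 1.0  # amplitude multiplier for recurrence

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")
        if self.class_effect <= 0:
            raise ValueError("class_effect must be > 0")

    def shape(self, wavenumbers: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((wavenumbers - self.center) / self.width) ** 2)


def default_band_library() -> list:
    """Urine-like band set.

    Urea (~1460 cm^-1) is the dominant solute band; amide I/II sit in
    their normalization windows; a handful of fingerprint bands and the
    C–H stretching quartet complete the profile. Only the lipid CH2
    asymmetric-stretch band near 2912 cm^-1 and the CH3 band near
    2980 cm^-1 carry a class effect by default.
    """
    return [
        BandModel(1000.0, 35.0, 0.20),   # carbohydrate / phosphate fingerprint
        BandModel(1160.0, 25.0, 0.15),
        BandModel(1240.0, 30.0, 0.18),
        BandModel(1460.0, 30.0, 1.00),   # urea: library maximum
        BandModel(1550.0, 25.0, 0.40),   # amide II
        BandModel(1650.0, 28.0, 0.65),   # amide I
        BandModel(780.0, 20.0, 0.10),    # bacterial fingerprint region
        BandModel(860.0, 18.0, 0.08),
        BandModel(2850.0, 12.0, 0.10),   # CH2 symmetric stretch
        BandModel(2912.0, 10.0, 0.15, class_effect=1.3),  # CH2 asym stretch
        BandModel(2960.0, 9.0, 0.08),    # CH3 asym stretch
        BandModel(2980.0, 8.0, 0.10, class_effect=1.3),   # CH3 stretch
        BandModel(3300.0, 120.0, 0.45),  # O-H / N-H stretch envelope
    ]


@dataclass
class CohortConfig:
    """Study-condition defaults: 41 NMIBC-free + 21 recurrence patients,
    3 replicate spectra each, 7 acquisition batches, one QC sample in
    every batch, 500–4000 cm^-1 grid at 4 cm^-1 spacing."""

    n_free: int = 41
    n_recur: int = 21
    replicates_per_patient: int = 3
    n_batches: int = 7
    include_qc: bool = True
    grid_lo: float = 500.0
    grid_hi: float = 4000.0
    grid_step: float = 4.0
    bands: list = field(default_factory=default_band_library)
    sigma_patient: float = 0.08     # between-patient band-amplitude SD
    sigma_replicate: float = 0.02   # within-patient (replicate) SD
    batch_offset_sd: float = 0.01
    batch_gain_sd: float = 0.02
    baseline_coeffs_sd: float = 0.005
    channel_noise_sd: float = 0.003
    seed: int = 0

    def __post_init__(self):
        if self.n_free < 2 or self.n_recur < 2:
            raise ValueError("need at least 2 patients per class")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        for name in ("sigma_patient", "sigma_replicate", "batch_offset_sd",
                     "batch_gain_sd", "baseline_coeffs_sd", "channel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_hi - self.grid_lo) / self.grid_step)) + 1
        return self.grid_lo + self.grid_step * np.arange(n)

    def null(self) -> "CohortConfig":
        """Copy with every class effect removed (label-blind cohort)."""
        return replace(
            self,
            bands=[replace(b, class_effect=1.0) for b in self.bands],
        )


def _compose(grid, bands, multipliers, gain, offset, baseline):
    total = np.zeros_like(grid)
    for band, m in zip(bands, multipliers):
        total += band.amplitude * m * band.shape(grid)
    return gain * total + offset + baseline


def generate_cohort(config: CohortConfig):
    """Simulate a cohort; returns ``(SpectraSet, truth_table)``.

    The truth table has one row per spectrum recording its latent
    per-band multipliers, batch gain/offset, and label; the generating
    config rides along in ``truth.attrs['config']``.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    bands = list(config.bands)
    n_bands = len(bands)
    class_mult = np.array([b.class_effect for b in bands])
    x = (grid - grid.mean()) / (grid.max() - grid.min()) * 2.0  # in [-1, 1]

    batch_offsets = rng.normal(0.0, config.batch_offset_sd, config.n_batches)
    batch_gains = rng.normal(1.0, config.batch_gain_sd, config.n_batches)
    batch_ids = [f"batch{b + 1}" for b in range(config.n_batches)]

    labels = ["free"] * config.n_free + ["recurrence"] * config.n_recur
    patient_ids = [f"P{str(i + 1).zfill(3)}" for i in range(len(labels))]
    # patients dealt to batches in shuffled order, all replicates together
    batch_of_patient = rng.permutation(
        [i % config.n_batches for i in range(len(labels))]
    )

    spectra, truth_rows = [], []

    def make_measurement(pid, rep_idx, batch, label, is_qc, patient_mult):
        rep_noise = rng.normal(0.0, config.sigma_replicate, n_bands)
        coeffs = rng.normal(0.0, config.baseline_coeffs_sd, 3)
        baseline = coeffs[0] + coeffs[1] * x + coeffs[2] * x**2
        channel_noise = (
            rng.normal(0.0, config.channel_noise_sd, len(grid))
            if config.channel_noise_sd > 0 else 0.0
        )
        mult = patient_mult + rep_noise
        values = _compose(grid, bands, mult, batch_gains[batch],
                          batch_offsets[batch], baseline) + channel_noise
        sid = f"{pid}_r{rep_idx}_{batch_ids[batch]}"
        meta = SpectrumMeta(sample_id=sid, patient_id=pid,
                            replicate_index=rep_idx, batch_id=batch_ids[batch],
                            is_qc=is_qc, label=label)
        spectra.append(Spectrum(grid, values, meta))
        row = {"sample_id": sid, "patient_id": pid, "label": label,
               "batch_id": batch_ids[batch], "is_qc": is_qc,
               "batch_gain": batch_gains[batch],
               "batch_offset": batch_offsets[batch]}
        for band, m in zip(bands, mult):
            row[f"band_{band.center:.0f}"] = m * band.amplitude
        truth_rows.append(row)

    for i, (pid, label) in enumerate(zip(patient_ids, labels)):
        patient_mult = rng.normal(1.0, config.sigma_patient, n_bands)
        if label == "recurrence":
            patient_mult = patient_mult * class_mult
        batch = int(batch_of_patient[i])
        for rep in range(1, config.replicates_per_patient + 1):
            make_measurement(pid, rep, batch, label, False, patient_mult)

    if config.include_qc:
        qc_mult = rng.normal(1.0, config.sigma_patient, n_bands)
        for b in range(config.n_batches):
            make_measurement("QC", b + 1, b, "unknown", True, qc_mult)

    cohort = SpectraSet(spectra)
    cohort.log(
        f"simulated cohort: {config.n_free} free + {config.n_recur} recurrence "
        f"patients x {config.replicates_per_patient} replicates, "
        f"{config.n_batches} batches, seed={config.seed}"
    )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["config"] = config
    return cohort, truth


def truth_check(cohort: SpectraSet, truth: pd.DataFrame,
                config: CohortConfig | None = None) -> dict:
    """Verify the generated cohort against its latent truth.

    Checks (1) that within-replicate distances are smaller than
    across-patient distances whenever sigma_replicate < sigma_patient,
    and (2) that mean band integrals of class-effect bands differ
    between classes with the configured sign.
    """
    if config is None:
        config = truth.attrs.get("config")
    if config is None:
        raise ValueError("CohortConfig required (pass explicitly or via truth.attrs)")
    set_ids = set(cohort.sample_ids)
    truth_ids = set(truth["sample_id"])
    if set_ids != truth_ids:
        raise ValueError("cohort and truth table ids do not match")

    groups = pairwise_distance_groups(cohort)
    med_within = float(np.median(groups.within_replicate))
    med_across = float(np.median(groups.across_patient))
    ordering_expected = config.sigma_replicate < config.sigma_patient
    ordering_holds = med_within < med_across

    band_results = {}
    grid = cohort.wavenumbers
    meta = cohort.meta_frame()
    matrix = cohort.to_matrix()
    rec_rows = ((meta["label"] == "recurrence") & ~meta["is_qc"]).to_numpy()
    free_rows = ((meta["label"] == "free") & ~meta["is_qc"]).to_numpy()
    for band in config.bands:
        if band.class_effect == 1.0:
            continue
        mask = np.abs(grid - band.center) <= 2.0 * band.width
        integrals = matrix[:, mask].sum(axis=1) * config.grid_step
        diff = float(integrals[rec_rows].mean() - integrals[free_rows].mean())
        expected_sign = 1.0 if band.class_effect > 1.0 else -1.0
        band_results[f"{band.center:.0f}"] = {
            "mean_recurrence_minus_free": diff,
            "sign_matches": bool(np.sign(diff) == expected_sign),
        }

    return {
        "median_within_replicate": med_within,
        "median_across_patient": med_across,
        "replicate_lt_patient_expected": ordering_expected,
        "replicate_lt_patient_holds": ordering_holds,
        "class_bands": band_results,
        "ok": (ordering_holds or not ordering_expected)
        and all(v["sign_matches"] for v in band_results.values()),
    }
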