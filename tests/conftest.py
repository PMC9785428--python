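import numpy as np
import pytest

from ftir_recur import CohortConfig, generate_cohort
from ftir_recur.spectra import Spectrum, SpectrumMeta, SpectraSet


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-condition cohort (62 patients, 193 spectra)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort for fast model-level tests."""
    cfg = CohortConfig(n_free=12, n_recur=8, replicates_per_patient=2,
                       n_batches=3, seed=5)
    return generate_cohort(cfg)


def make_spectrum(wavenumbers, absorbance, sample_id="s1", patient_id="p1",
                  replicate_index=1, batch_id="b1", is_qc=False, label="unknown"):
    return Spectrum(
        np.asarray(wavenumbers, float),
        np.asarray(absorbance, float),
        SpectrumMeta(sample_id=sample_id, patient_id=patient_id,
                     replicate_index=replicate_index, batch_id=batch_id,
                     is_qc=is_qc, label=label),
    )


@pytest.fixture
def spectrum_factory():
    return make_spectrum


@pytest.fixture
def tiny_set():
    grid = np.arange(500.0, 4001.0, 4.0)
    rng = np.random.default_rng(0)
    spectra = [
        make_spectrum(grid, rng.uniform(0.1, 1.0, len(grid)),
                      sample_id=f"s{i}", patient_id=f"p{i % 2}",
                      replicate_index=i // 2 + 1, label="free")
        for i in range(4)
    ]
    return SpectraSet(spectra)
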