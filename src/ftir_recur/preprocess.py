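"""Spectral preprocessing operators and their composition.

The preprocessing search space has five axes: wavenumber range,
Savitzky–Golay derivative order, SG window size, bin size, and
normalization band. One point of that space is a
:class:`PreprocessConfig`; :func:`apply_pipeline` turns a
:class:`~ftir_recur.spectra.SpectraSet` into the
:class:`FeatureMatrix` consumed by model training.

Transform order is fixed and documented: SG derivative (on the full
acquired grid) -> normalization (band maximum or vector norm, computed
on the full-range transformed spectrum) -> range extraction -> binning.
The amide (1500–1700 cm^-1) and urea (1400–1500 cm^-1) reference bands
lie outside three of the four analysis ranges, so normalization must
happen before extraction; the derivative comes first so band scaling
acts on the analyzed signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Spectrum, SpectraSet, IntegrityError

__all__ = [
    "RANGE_BOUNDS",
    "NORMALIZATION_BANDS",
    "PreprocessConfig",
    "FeatureMatrix",
    "savitzky_golay",
    "normalize_band",
    "vector_normalize",
    "bin_channels",
    "extract_range",
    "rubberband_baseline",
    "apply_pipeline",
    "default_config_space",
]

#: Named analysis ranges (cm^-1): full spectrum, bacterial fingerprint,
#: extended fingerprint, and hydrocarbon C–H stretching region.
RANGE_BOUNDS = {
    "full": (500.0, 4000.0),
    "bacterial": (700.0, 900.0),
    "fingerprint": (700.0, 1800.0),
    "ch_stretch": (2800.0, 3000.0),
}

#: Reference bands for band-maximum normalization.
NORMALIZATION_BANDS = {
    "amide": (1500.0, 1700.0),
    "urea": (1400.0, 1500.0),
}


@dataclass(frozen=True)
class PreprocessConfig:
    """One point of the preprocessing grid."""

    range: str = "full"
    sg_derivative: int = 0
    sg_window: int = 9
    bin_size: int = 1
    normalization: str = "none"
    sg_polyorder: int = 3

    def __post_init__(self):
        if self.range not in RANGE_BOUNDS:
            raise ValueError(f"unknown range {self.range!r}; expected {sorted(RANGE_BOUNDS)}")
        if self.normalization not in ("none", "vector", *NORMALIZATION_BANDS):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.sg_derivative not in (0, 1, 2):
            raise ValueError("sg_derivative must be 0, 1 or 2")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**{k: d[k] for k in
                      ("range", "sg_derivative", "sg_window", "bin_size", "normalization")
                      if k in d})


@dataclass
class FeatureMatrix:
    """Samples × features matrix with bin-center wavenumbers."""

    values: np.ndarray
    feature_wavenumbers: np.ndarray
    sample_ids: list
    config: PreprocessConfig = field(default_factory=PreprocessConfig)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.feature_wavenumbers = np.asarray(self.feature_wavenumbers, dtype=float)
        if self.values.ndim != 2:
            raise IntegrityError("feature values must be 2-D")
        if self.values.shape[1] != len(self.feature_wavenumbers):
            raise IntegrityError("feature_wavenumbers/value column mismatch")
        if self.values.shape[0] != len(self.sample_ids):
            raise IntegrityError("sample_ids/value row mismatch")
        if len(self.feature_wavenumbers) > 1 and np.any(
            np.diff(self.feature_wavenumbers) <= 0
        ):
            raise IntegrityError("feature_wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise IntegrityError("non-finite feature values")

    @property
    def n_samples(self):
        return self.values.shape[0]

    @property
    def n_features(self):
        return self.values.shape[1]

    def rows_for(self, sample_ids) -> np.ndarray:
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        return np.array([index[s] for s in sample_ids], dtype=int)


def _check_uniform(grid: np.ndarray) -> float:
    spacing = np.diff(grid)
    if len(spacing) == 0:
        raise ValueError("need at least two channels")
    mean = spacing.mean()
    if np.max(np.abs(spacing - mean)) > 1e-6 * abs(mean):
        raise ValueError("Savitzky–Golay requires a uniform wavenumber grid")
    return float(mean)


def savitzky_golay(absorbance, window: int, polyorder: int, deriv: int,
                   spacing: float = 1.0) -> np.ndarray:
    """SG derivative filter, edges trimmed.

    Fits a degree-``polyorder`` polynomial by least squares in each
    sliding ``window`` and evaluates its ``deriv``-th derivative at the
    window center. Only interior points are returned: the output is
    shorter than the input by ``window - 1``. The derivative accounts
    for the physical channel ``spacing`` (units absorbance·cm^deriv).
    """
    y = np.asarray(absorbance, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    if deriv > polyorder:
        raise ValueError("deriv must be <= polyorder")
    if window > len(y):
        raise ValueError(f"window {window} larger than spectrum ({len(y)} channels)")
    filtered = savgol_filter(y, window_length=window, polyorder=polyorder,
                             deriv=deriv, delta=spacing)
    half = (window - 1) // 2
    return filtered[half:len(y) - half]


def normalize_band(spectrum: Spectrum, band_lo: float, band_hi: float) -> Spectrum:
    """Divide by the maximum |absorbance| within [band_lo, band_hi].

    Uses the absolute maximum so the operator stays well-defined for
    signed derivative spectra. Idempotent.
    """
    mask = (spectrum.wavenumbers >= band_lo) & (spectrum.wavenumbers <= band_hi)
    if not np.any(mask):
        raise ValueError(
            f"band [{band_lo}, {band_hi}] does not intersect the grid "
            f"({spectrum.meta.sample_id!r})"
        )
    divisor = np.max(np.abs(spectrum.absorbance[mask]))
    if divisor < 1e-12:
        raise ValueError(
            f"degenerate (flat) normalization band for {spectrum.meta.sample_id!r}"
        )
    return spectrum.with_values(spectrum.wavenumbers, spectrum.absorbance / divisor)


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale to unit Euclidean norm."""
    norm = np.linalg.norm(spectrum.absorbance)
    if norm < 1e-12:
        raise ValueError(f"all-zero spectrum {spectrum.meta.sample_id!r}")
    return spectrum.with_values(spectrum.wavenumbers, spectrum.absorbance / norm)


def bin_channels(spectrum: Spectrum, bin_size: int) -> Spectrum:
    """Average consecutive blocks of ``bin_size`` channels.

    Bin centers are the mean wavenumber of each block; a trailing
    partial block is dropped so all features have equal width.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n = len(spectrum.wavenumbers)
    if bin_size > n:
        raise ValueError(f"bin_size {bin_size} exceeds channel count {n}")
    if bin_size == 1:
        return spectrum
    m = n // bin_size
    w = spectrum.wavenumbers[: m * bin_size].reshape(m, bin_size).mean(axis=1)
    a = spectrum.absorbance[: m * bin_size].reshape(m, bin_size).mean(axis=1)
    return spectrum.with_values(w, a)


def extract_range(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep channels with lo <= wavenumber <= hi (closed interval)."""
    if lo >= hi:
        raise ValueError(f"invalid range [{lo}, {hi}]")
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if not np.any(mask):
        raise ValueError(
            f"range [{lo}, {hi}] contains no channels ({spectrum.meta.sample_id!r})"
        )
    return spectrum.with_values(spectrum.wavenumbers[mask], spectrum.absorbance[mask])


def rubberband_baseline(spectrum: Spectrum) -> Spectrum:
    """Subtract the lower convex hull of (wavenumber, absorbance).

    A simple stand-in for vendor baseline correction; optional and off
    by default in the pipeline.
    """
    x, y = spectrum.wavenumbers, spectrum.absorbance
    if len(x) < 3:
        raise ValueError("rubberband baseline needs >= 3 channels")
    # Andrew's monotone chain, lower hull only.
    hull = []
    for i in range(len(x)):
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            if (x2 - x1) * (y[i] - y1) - (y2 - y1) * (x[i] - x1) <= 0:
                hull.pop()
            else:
                break
        hull.append((x[i], y[i]))
    hx = np.array([p[0] for p in hull])
    hy = np.array([p[1] for p in hull])
    baseline = np.interp(x, hx, hy)
    return spectrum.with_values(x, y - baseline)


def _preprocess_one(spectrum: Spectrum, config: PreprocessConfig) -> Spectrum:
    s = spectrum
    if config.sg_derivative > 0:
        spacing = _check_uniform(s.wavenumbers)
        half = (config.sg_window - 1) // 2
        values = savitzky_golay(
            s.absorbance, config.sg_window, config.sg_polyorder,
            config.sg_derivative, spacing,
        )
        s = s.with_values(s.wavenumbers[half:len(s.wavenumbers) - half], values)
    if config.normalization in NORMALIZATION_BANDS:
        lo, hi = NORMALIZATION_BANDS[config.normalization]
        s = normalize_band(s, lo, hi)
    elif config.normalization == "vector":
        s = vector_normalize(s)
    lo, hi = RANGE_BOUNDS[config.range]
    s = extract_range(s, lo, hi)
    s = bin_channels(s, config.bin_size)
    return s


def apply_pipeline(spectra_set: SpectraSet, config: PreprocessConfig,
                   include_qc: bool = False) -> FeatureMatrix:
    """Run the configured transform chain over a set.

    QC spectra are excluded by default (they carry no class label and
    never enter model training). Row order follows the input set.
    """
    source = spectra_set if include_qc else spectra_set.without_qc()
    if len(source) == 0:
        raise ValueError("empty SpectraSet")
    rows, ids = [], []
    grid = None
    for s in source:
        try:
            out = _preprocess_one(s, config)
        except ValueError as exc:
            raise ValueError(f"preprocessing failed for {s.meta.sample_id!r}: {exc}") from exc
        if grid is None:
            grid = out.wavenumbers
        rows.append(out.absorbance)
        ids.append(s.meta.sample_id)
    spectra_set.log(f"apply_pipeline({config.to_dict()}) -> {len(rows)}x{len(grid)}")
    return FeatureMatrix(np.vstack(rows), grid, ids, config)


def default_config_space() -> dict:
    """The full preprocessing grid: 4 ranges x 3 derivatives x 3
    normalizations x 4 windows x 5 bins = 720 configurations."""
    return {
        "range": ["full", "bacterial", "fingerprint", "ch_stretch"],
        "sg_derivative": [0, 1, 2],
        "normalization": ["none", "amide", "urea"],
        "sg_window": [5, 7, 9, 13],
        "bin_size": [1, 2, 3, 5, 10],
    }
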