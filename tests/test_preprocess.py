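"""Preprocessing operators against independent oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ftir_recur.preprocess import (
    PreprocessConfig,
    apply_pipeline,
    bin_channels,
    extract_range,
    normalize_band,
    rubberband_baseline,
    savitzky_golay,
    vector_normalize,
)
from ftir_recur.spectra import SpectraSet, Spectrum, SpectrumMeta


def _spec(grid, values):
    return Spectrum(np.asarray(grid, float), np.asarray(values, float),
                    SpectrumMeta("s", "p", 1, "b"))


def sg_oracle(y, window, polyorder, deriv, spacing):
    """Independent oracle: per-window least-squares polynomial fit,
    derivative evaluated at the window center."""
    half = (window - 1) // 2
    out = []
    for c in range(half, len(y) - half):
        x = (np.arange(-half, half + 1)) * spacing
        coeffs = np.polynomial.polynomial.polyfit(x, y[c - half:c + half + 1],
                                                  polyorder)
        p = np.polynomial.Polynomial(coeffs)
        out.append(p.deriv(deriv)(0.0) if deriv else p(0.0))
    return np.array(out)


class TestSavitzkyGolay:
    def test_constant_reproduced(self):
        y = np.full(20, 3.7)
        out = savitzky_golay(y, 7, 3, 0, 1.0)
        np.testing.assert_allclose(out, 3.7, atol=1e-12)
        assert len(out) == 20 - 6

    def test_quadratic_first_derivative_exact(self):
        x = np.arange(30.0)
        out = savitzky_golay(x**2, 5, 3, 1, 1.0)
        np.testing.assert_allclose(out, 2 * x[2:-2], atol=1e-9)

    @pytest.mark.parametrize("deriv", [0, 1, 2, 3])
    def test_cubic_polynomials_reproduced_to_machine_precision(self, deriv):
        # degree-3 LS fit reproduces any cubic exactly, hence all its
        # derivatives at interior points
        x = np.linspace(0, 10, 40)
        spacing = x[1] - x[0]
        poly = np.polynomial.Polynomial([1.0, -2.0, 0.5, 0.25])
        out = savitzky_golay(poly(x), 5, 3, deriv, spacing)
        expected = poly.deriv(deriv)(x[2:-2]) if deriv else poly(x[2:-2])
        np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_matches_sliding_least_squares_oracle(self):
        rng = np.random.default_rng(42)
        y = rng.normal(size=25)
        for deriv in (0, 1, 2):
            out = savitzky_golay(y, 7, 3, deriv, 0.5)
            np.testing.assert_allclose(
                out, sg_oracle(y, 7, 3, deriv, 0.5), atol=1e-8
            )

    def test_window_larger_than_spectrum(self):
        with pytest.raises(ValueError):
            savitzky_golay(np.ones(5), 7, 3, 0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            savitzky_golay(np.ones(20), 6, 3, 0)


class TestNormalization:
    def test_band_max_halves_everything(self, spectrum_factory):
        s = spectrum_factory([100.0, 200.0, 300.0], [0.5, 2.0, 1.0])
        out = normalize_band(s, 150, 250)
        np.testing.assert_allclose(out.absorbance, [0.25, 1.0, 0.5])

    def test_band_already_unit_unchanged(self, spectrum_factory):
        s = spectrum_factory([100.0, 200.0], [0.3, 1.0])
        out = normalize_band(s, 150, 250)
        np.testing.assert_allclose(out.absorbance, s.absorbance)

    def test_band_outside_grid_errors(self, spectrum_factory):
        s = spectrum_factory([100.0, 200.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            normalize_band(s, 500, 600)

    def test_degenerate_band_errors(self, spectrum_factory):
        s = spectrum_factory([100.0, 200.0, 300.0], [0.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="degenerate"):
            normalize_band(s, 50, 250)

    def test_signed_derivative_band_uses_absolute_max(self, spectrum_factory):
        s = spectrum_factory([1.0, 2.0, 3.0], [-4.0, 2.0, 1.0])
        out = normalize_band(s, 0.5, 2.5)
        assert np.max(np.abs(out.absorbance[:2])) == pytest.approx(1.0)

    def test_vector_norm_example(self, spectrum_factory):
        s = spectrum_factory([1.0, 2.0, 3.0], [1.0, 2.0, 2.0])
        np.testing.assert_allclose(
            vector_normalize(s).absorbance, [1 / 3, 2 / 3, 2 / 3]
        )

    @pytest.mark.parametrize("op", ["band", "vector"])
    def test_idempotence(self, op, spectrum_factory):
        rng = np.random.default_rng(1)
        s = spectrum_factory(np.arange(100.0, 200.0), rng.uniform(0.1, 2, 100))
        if op == "band":
            once = normalize_band(s, 120, 180)
            twice = normalize_band(once, 120, 180)
        else:
            once = vector_normalize(s)
            twice = vector_normalize(once)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-9)


class TestBinningAndRange:
    def test_binning_means(self, spectrum_factory):
        s = spectrum_factory([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        out = bin_channels(s, 2)
        np.testing.assert_allclose(out.absorbance, [1.5, 3.5])
        np.testing.assert_allclose(out.wavenumbers, [1.5, 3.5])

    def test_bin_one_identity(self, spectrum_factory):
        s = spectrum_factory([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert bin_channels(s, 1) is s

    def test_trailing_remainder_dropped(self, spectrum_factory):
        s = spectrum_factory(np.arange(7.0), np.arange(7.0))
        assert len(bin_channels(s, 3).absorbance) == 2

    def test_ch_stretch_extraction_channel_count(self, spectrum_factory):
        grid = np.arange(500.0, 4001.0, 4.0)
        s = spectrum_factory(grid, np.ones_like(grid))
        out = extract_range(s, 2800, 3000)
        assert len(out.wavenumbers) == 51  # 2800, 2804, ..., 3000
        assert out.wavenumbers[0] == 2800.0 and out.wavenumbers[-1] == 3000.0

    def test_whole_grid_extraction_identity(self, spectrum_factory):
        s = spectrum_factory([1.0, 2.0], [3.0, 4.0])
        out = extract_range(s, 0, 10)
        np.testing.assert_array_equal(out.absorbance, s.absorbance)

    def test_invalid_range(self, spectrum_factory):
        s = spectrum_factory([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError):
            extract_range(s, 5, 5)

    @given(st.integers(2, 5), st.integers(0, 3))
    @settings(max_examples=20, deadline=None)
    def test_bin_then_extract_commutes_on_aligned_grid(self, bin_size, block):
        # extraction boundaries aligned to bin boundaries
        grid = np.arange(0.0, 60.0)
        rng = np.random.default_rng(7)
        s = _spec(grid, rng.uniform(size=60))
        n_blocks = 60 // bin_size
        lo_block = min(block, n_blocks - 1)
        lo, hi = lo_block * bin_size, n_blocks * bin_size - 1
        a = bin_channels(extract_range(s, lo - 0.5, hi + 0.5), bin_size)
        b = extract_range(bin_channels(s, bin_size), lo - 0.5, hi + 0.5)
        np.testing.assert_allclose(a.absorbance, b.absorbance, atol=1e-12)


class TestRubberband:
    def test_straight_line_zeroed(self, spectrum_factory):
        x = np.arange(10.0)
        s = spectrum_factory(x, 2 * x + 1)
        np.testing.assert_allclose(rubberband_baseline(s).absorbance, 0, atol=1e-12)

    def test_gaussian_on_slope_recovered(self, spectrum_factory):
        x = np.linspace(0, 100, 201)
        peak = np.exp(-0.5 * ((x - 50) / 5) ** 2)
        s = spectrum_factory(x, peak + 0.01 * x + 0.3)
        out = rubberband_baseline(s)
        tails = out.absorbance[(x < 20) | (x > 80)]
        assert np.max(np.abs(tails)) < 1e-6 * out.absorbance.max()
        assert out.absorbance.max() == pytest.approx(1.0, rel=1e-3)

    def test_nonnegative_peak_with_zero_tails_unchanged(self, spectrum_factory):
        x = np.linspace(0, 10, 101)
        peak = np.exp(-0.5 * ((x - 5) / 0.5) ** 2)
        peak[x < 2] = 0.0
        peak[x > 8] = 0.0
        s = spectrum_factory(x, peak)
        np.testing.assert_allclose(rubberband_baseline(s).absorbance, peak,
                                   atol=1e-9)


class TestApplyPipeline:
    def test_identity_path_returns_raw(self, tiny_set):
        cfg = PreprocessConfig(range="full", sg_derivative=0, bin_size=1,
                               normalization="none")
        fm = apply_pipeline(tiny_set, cfg)
        np.testing.assert_allclose(fm.values, tiny_set.to_matrix())
        np.testing.assert_array_equal(fm.feature_wavenumbers, tiny_set.wavenumbers)

    def test_final_model_config_scales_before_extraction(self, tiny_set):
        # urea band (1400-1500) lies outside 2800-3000: normalization
        # must have happened before the range was cut
        cfg = PreprocessConfig(range="ch_stretch", sg_derivative=1,
                               sg_window=13, bin_size=1, normalization="urea")
        fm = apply_pipeline(tiny_set, cfg)
        assert fm.feature_wavenumbers.min() >= 2800
        assert fm.feature_wavenumbers.max() <= 3000
        # manually reproduce one row
        s = tiny_set.spectra[0]
        deriv = savitzky_golay(s.absorbance, 13, 3, 1, 4.0)
        w = s.wavenumbers[6:-6]
        band = (w >= 1400) & (w <= 1500)
        deriv = deriv / np.max(np.abs(deriv[band]))
        keep = (w >= 2800) & (w <= 3000)
        np.testing.assert_allclose(fm.values[0], deriv[keep], atol=1e-10)

    def test_identical_spectra_identical_rows(self, spectrum_factory):
        grid = np.arange(500.0, 4001.0, 4.0)
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.1, 1, len(grid))
        s1 = spectrum_factory(grid, vals, sample_id="a", patient_id="p1")
        s2 = spectrum_factory(grid, vals, sample_id="b", patient_id="p2")
        fm = apply_pipeline(SpectraSet([s1, s2]),
                            PreprocessConfig(range="fingerprint",
                                             sg_derivative=2, sg_window=9,
                                             bin_size=3, normalization="amide"))
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    def test_row_order_follows_input_order(self, tiny_set):
        cfg = PreprocessConfig(range="fingerprint", bin_size=2)
        fm = apply_pipeline(tiny_set, cfg)
        reversed_set = SpectraSet(list(tiny_set.spectra[::-1]))
        fm_rev = apply_pipeline(reversed_set, cfg)
        assert fm_rev.sample_ids == fm.sample_ids[::-1]
        np.testing.assert_allclose(fm_rev.values, fm.values[::-1])

    def test_qc_spectra_excluded(self, default_cohort):
        cohort, _ = default_cohort
        fm = apply_pipeline(cohort, PreprocessConfig(range="ch_stretch"))
        assert fm.n_samples == 186  # 62 patients x 3 replicates, no QC

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(sg_window=4)
        with pytest.raises(ValueError):
            PreprocessConfig(range="uv")
        with pytest.raises(ValueError):
            PreprocessConfig(sg_derivative=3)
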