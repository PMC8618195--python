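"""Baseline removal, CH₂ normalization and the three chemical markers."""

import math

import numpy as np
import pytest

from brams import (AnalysisConfig, Modality, NormalizationError, Spectrum,
                   band_first_moment, crystallinity_fwhm,
                   extract_raman_features, mineralization_ratio,
                   normalize_to_reference, peak_intensity, remove_baseline,
                   raman_axis)


def rspec(axis, intensity):
    return Spectrum(np.asarray(axis, float), np.asarray(intensity, float),
                    Modality.RAMAN)


class TestRemoveBaseline:
    def test_pure_polynomial_is_removed(self):
        axis = raman_axis()
        t = axis / 1000.0
        baseline = 5.0 + 2.0 * t - 0.4 * t ** 2 + 0.05 * t ** 3
        out = remove_baseline(rspec(axis, baseline), order=5)
        assert np.max(np.abs(out.intensity)) < 1e-6 * baseline.max()

    def test_peaks_on_zero_baseline_preserved(self, raman_spectrum_builder):
        s = raman_spectrum_builder([(1003, 10, 1.0), (1445, 16, 2.0)])
        out = remove_baseline(s)
        for center, height in ((1003, 1.0), (1445, 2.0)):
            got = peak_intensity(out, center, 8)
            assert got == pytest.approx(height, rel=0.02)

    def test_peaks_on_polynomial_recovered(self, raman_spectrum_builder):
        s = raman_spectrum_builder(
            [(1003, 10, 1.0), (1445, 16, 2.0), (2935, 20, 1.5)],
            baseline_coeffs=(3.0, -1.0, 0.12))
        out = remove_baseline(s)
        for center, height in ((1003, 1.0), (1445, 2.0), (2935, 1.5)):
            assert peak_intensity(out, center, 8) == pytest.approx(
                height, rel=0.05)

    def test_output_non_negative_and_axis_unchanged(self, raman_spectrum_builder):
        s = raman_spectrum_builder([(1445, 16, 1.0)], baseline_coeffs=(2.0,))
        out = remove_baseline(s)
        assert np.all(out.intensity >= 0)
        assert np.array_equal(out.axis, s.axis)

    def test_too_few_channels_rejected(self):
        s = rspec([800, 900, 1000], [1, 2, 1])
        with pytest.raises(ValueError):
            remove_baseline(s, order=5)


class TestNormalizeToReference:
    def test_divides_by_reference_window_maximum(self):
        axis = np.arange(800.0, 1800.0, 1.0)
        inten = np.ones_like(axis)
        inten[axis == 1445.0] = 5.0
        out = normalize_to_reference(rspec(axis, inten))
        assert peak_intensity(out, 1445, 10) == pytest.approx(1.0)
        assert out.intensity[0] == pytest.approx(0.2)

    def test_idempotent(self):
        axis = np.arange(800.0, 1800.0, 1.0)
        inten = np.exp(-((axis - 1445.0) ** 2) / 200.0)
        once = normalize_to_reference(rspec(axis, inten))
        twice = normalize_to_reference(once)
        assert np.allclose(once.intensity, twice.intensity)

    def test_zero_reference_flags_pixel(self):
        axis = np.arange(800.0, 1800.0, 1.0)
        inten = np.where(axis < 1200, 1.0, 0.0)
        with pytest.raises(NormalizationError):
            normalize_to_reference(rspec(axis, inten))


class TestPeakIntensity:
    def test_single_channel(self):
        assert peak_intensity(rspec([965.0], [3.0]), 965, 8) == 3.0

    def test_window_maximum_over_enumerated_channels(self):
        assert peak_intensity(rspec([964.0, 966.0], [2.0, 5.0]), 965, 8) == 5.0

    def test_symmetric_peak_apex(self, raman_spectrum_builder):
        s = raman_spectrum_builder([(965, 12, 4.0)])
        assert peak_intensity(s, 965, 8) == pytest.approx(4.0, rel=1e-3)

    def test_empty_window_is_error(self):
        from brams import EmptyBandError
        with pytest.raises(EmptyBandError):
            peak_intensity(rspec([800.0, 1800.0], [1.0, 1.0]), 965, 8)


class TestMineralizationRatio:
    def test_equal_peaks_give_unity(self, raman_spectrum_builder):
        s = raman_spectrum_builder([(860, 12, 1.0), (965, 12, 1.0)])
        assert mineralization_ratio(s) == pytest.approx(1.0, rel=1e-3)

    def test_two_to_one_amplitudes(self, raman_spectrum_builder):
        s = raman_spectrum_builder([(860, 12, 1.0), (965, 12, 2.0)])
        assert mineralization_ratio(s) == pytest.approx(2.0, rel=5e-3)

    def test_scale_invariance(self, raman_spectrum_builder):
        s = raman_spectrum_builder([(860, 12, 1.0), (965, 12, 1.7)])
        assert mineralization_ratio(s.scaled(2.0)) == pytest.approx(
            mineralization_ratio(s), rel=1e-12)

    def test_zero_proline_flags_missing(self):
        axis = raman_axis()
        inten = np.zeros_like(axis)
        inten[axis == 965.0] = 1.0  # no proline signal at all
        assert math.isnan(mineralization_ratio(rspec(axis, inten)))


class TestBandFirstMoment:
    def test_single_band(self, raman_spectrum_builder):
        s = raman_spectrum_builder([(2935, 20, 1.0)])
        assert band_first_moment(s, (2800, 3100)) == pytest.approx(2935, abs=2)

    def test_equal_area_bands_give_midpoint(self):
        axis = raman_axis()
        inten = np.zeros_like(axis)
        inten[axis == 2872.0] = 3.0
        inten[axis == 2935.0] = 3.0
        assert band_first_moment(rspec(axis, inten), (2800, 3100)) == \
            pytest.approx(2903.5)

    def test_moment_decreases_with_lipid_amplitude(self, raman_spectrum_builder):
        moments = []
        for lipid in (0.2, 0.5, 1.0, 2.0, 5.0):
            s = raman_spectrum_builder([(2872, 20, lipid), (2935, 20, 1.0)])
            moments.append(band_first_moment(s, (2800, 3100)))
        assert all(a > b for a, b in zip(moments, moments[1:]))
        assert 2800 < min(moments) and max(moments) < 3100

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(7)
        axis = raman_axis()
        for _ in range(50):
            inten = rng.uniform(0, 5, axis.size)
            lo, hi = 2800, 3100
            num = sum(i * a for a, i in zip(axis, inten) if lo <= a <= hi)
            den = sum(i for a, i in zip(axis, inten) if lo <= a <= hi)
            got = band_first_moment(rspec(axis, inten), (lo, hi))
            assert got == pytest.approx(num / den, rel=1e-12)


class TestCrystallinity:
    def test_recovers_lorentzian_fwhm(self, raman_spectrum_builder):
        s = raman_spectrum_builder([(965, 14, 2.0)])
        assert crystallinity_fwhm(s) == pytest.approx(14.0, rel=0.05)

    def test_flat_window_is_flagged(self):
        axis = raman_axis()
        assert math.isnan(crystallinity_fwhm(rspec(axis, np.zeros_like(axis))))


class TestExtractRamanFeatures:
    def test_lipid_only_spectrum(self, pipeline_config):
        from brams import PixelTruth, simulate_raman_spectrum
        t = PixelTruth(nu_soft=6.9, nu_hard=18.0, frac_soft=50,
                       raman_composition={"lipid": 1.0}, noise=0.0)
        f = extract_raman_features(simulate_raman_spectrum(t), pipeline_config)
        assert f.ch_moment == pytest.approx(2872, abs=5)

    def test_heme_shifts_moment_below_protein_value(self, pipeline_config):
        from brams import PixelTruth, simulate_raman_spectrum
        protein = PixelTruth(nu_soft=6.9, nu_hard=18.0, frac_soft=50,
                             raman_composition={"collagen": 1.0}, noise=0.0)
        hemic = PixelTruth(nu_soft=6.9, nu_hard=18.0, frac_soft=50,
                           raman_composition={"collagen": 1.0, "heme": 1.0},
                           noise=0.0)
        f_prot = extract_raman_features(simulate_raman_spectrum(protein),
                                        pipeline_config)
        f_heme = extract_raman_features(simulate_raman_spectrum(hemic),
                                        pipeline_config)
        assert f_heme.heme_moment < f_prot.heme_moment

    def test_mineral_free_spectrum(self, pipeline_config):
        from brams import PixelTruth, simulate_raman_spectrum
        t = PixelTruth(nu_soft=6.9, nu_hard=18.0, frac_soft=50,
                       raman_composition={"collagen": 1.0, "lipid": 0.3},
                       noise=0.0)
        f = extract_raman_features(simulate_raman_spectrum(t), pipeline_config)
        assert f.mineral_to_matrix == pytest.approx(0.0, abs=0.1)

    def test_markers_invariant_under_scale_and_baseline(
            self, raman_spectrum_builder, pipeline_config):
        bands = [(860, 12, 0.5), (965, 12, 1.0), (1445, 16, 2.0),
                 (1580, 16, 0.4), (1660, 20, 0.8), (2872, 20, 1.0),
                 (2935, 24, 1.5)]
        base = extract_raman_features(raman_spectrum_builder(bands),
                                      pipeline_config)
        perturbed = extract_raman_features(
            raman_spectrum_builder(bands, baseline_coeffs=(2.0, 0.5, -0.1)
                                   ).scaled(7.0),
            pipeline_config)
        assert perturbed.mineral_to_matrix == pytest.approx(
            base.mineral_to_matrix, rel=0.05)
        assert perturbed.ch_moment == pytest.approx(base.ch_moment, abs=2.0)
        assert perturbed.heme_moment == pytest.approx(base.heme_moment, abs=5.0)

    def test_failed_normalization_flags_all_markers(self, pipeline_config):
        axis = raman_axis()
        f = extract_raman_features(rspec(axis, np.zeros_like(axis)),
                                   pipeline_config)
        assert math.isnan(f.mineral_to_matrix)
        assert math.isnan(f.ch_moment)
        assert f.normalized is None
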