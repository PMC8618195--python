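"""Generators: determinism, construction guarantees and pipeline recovery."""

import numpy as np
import pytest

from brams import (AnalysisConfig, PhantomSpec, PixelTruth,
                   band_intensity, brillouin_axis, extract_brillouin_features,
                   generate_phantom, generate_study_fixture,
                   longitudinal_modulus, raman_template_truth,
                   simulate_brillouin_spectrum, simulate_raman_spectrum)


def truth(frac=40.0, noise=0.0, **kw):
    return PixelTruth(nu_soft=6.86, nu_hard=18.3, frac_soft=frac,
                      noise=noise, **kw)


class TestSimulateBrillouin:
    def test_soft_only_leaves_hard_band_at_background(self):
        s = simulate_brillouin_spectrum(truth(frac=100.0))
        hard = s.intensity[s.axis > 13.5]
        background = 0.01 * s.intensity.max()
        assert np.all(hard <= 2 * background)

    def test_band_area_ratio_matches_configured_fraction(self):
        s = simulate_brillouin_spectrum(truth(frac=30.0))
        off_band = (s.axis < 4) | (s.axis > 32)
        bg = float(np.median(s.intensity[off_band]))
        a_soft = band_intensity(s, (4, 13)) - bg * 9
        a_hard = band_intensity(s, (13, 32)) - bg * 19
        ratio = a_soft / (a_soft + a_hard)
        assert ratio == pytest.approx(0.30, abs=0.01)

    def test_same_seed_identical(self):
        a = simulate_brillouin_spectrum(truth(noise=50.0), seed=3)
        b = simulate_brillouin_spectrum(truth(noise=50.0), seed=3)
        assert np.array_equal(a.intensity, b.intensity)

    def test_peak_outside_axis_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_brillouin_spectrum(truth(), axis=np.arange(8.0, 35.0, 0.05))


class TestSimulateRaman:
    def test_lipid_only_ch_moment(self, config):
        from brams import band_first_moment

        t = truth(raman_composition={"lipid": 1.0})
        s = simulate_raman_spectrum(t)
        tt = raman_template_truth(t)
        # band truncation (2800 sits 72 cm⁻¹ below the line) shifts the
        # moment of a FWHM-24 Lorentzian up by ~4.6 cm⁻¹
        assert tt["ch_moment"] == pytest.approx(2872, abs=6)

    def test_all_zero_weights_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            simulate_raman_spectrum(truth(raman_composition={"lipid": 0.0}))

    def test_same_seed_identical(self):
        t = truth(noise=50.0)
        a = simulate_raman_spectrum(t, seed=4)
        b = simulate_raman_spectrum(t, seed=4)
        assert np.array_equal(a.intensity, b.intensity)


class TestGeneratePhantom:
    def test_cortical_region_structure(self):
        _, grid = generate_phantom(PhantomSpec("cortical", shape=(16, 16),
                                               seed=1))
        regions = [px.region for px in grid.flat]
        assert regions.count("vessel") >= 1
        assert regions.count("cortical_matrix") >= 100

    def test_trabecular_has_spicule_and_marrow(self):
        _, grid = generate_phantom(PhantomSpec("trabecular", shape=(16, 16),
                                               seed=2))
        regions = {px.region for px in grid.flat}
        assert "spicule" in regions
        assert regions & {"yellow_marrow", "red_marrow"}

    def test_same_seed_byte_identical(self):
        spec = PhantomSpec("cortical", shape=(6, 6), seed=9, noise=50.0)
        a, _ = generate_phantom(spec)
        b, _ = generate_phantom(spec)
        for sa, sb in zip(a.brillouin.flat, b.brillouin.flat):
            assert sa.intensity.tobytes() == sb.intensity.tobytes()
        for sa, sb in zip(a.raman.flat, b.raman.flat):
            assert sa.intensity.tobytes() == sb.intensity.tobytes()

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError, match="4, 4"):
            PhantomSpec("cortical", shape=(3, 8), seed=0)


@pytest.fixture(scope="module")
def noiseless_run():
    from brams import map_features
    cfg = AnalysisConfig(subtract_background=True)
    smap, grid = generate_phantom(
        PhantomSpec("cortical", shape=(8, 8), seed=21, noise=0.0), cfg)
    return map_features(smap, cfg), grid, cfg


class TestPipelineRecovery:
    def test_noiseless_brillouin_recovery(self, noiseless_run):
        fmap, grid, _ = noiseless_run
        for r in range(8):
            for c in range(8):
                px = grid[r, c]
                assert fmap["nu_soft"][r, c] == pytest.approx(px.nu_soft,
                                                              abs=0.05)
                assert fmap["nu_hard"][r, c] == pytest.approx(px.nu_hard,
                                                              abs=0.05)
                assert fmap["I_soft"][r, c] == pytest.approx(px.frac_soft,
                                                             abs=1.0)
                assert fmap["M_soft"][r, c] == pytest.approx(
                    longitudinal_modulus(px.nu_soft), rel=0.02)
                assert fmap["M_hard"][r, c] == pytest.approx(
                    longitudinal_modulus(px.nu_hard), rel=0.02)

    def test_noiseless_raman_recovery(self, noiseless_run):
        fmap, grid, cfg = noiseless_run
        for r in range(8):
            for c in range(8):
                tt = raman_template_truth(grid[r, c], cfg)
                assert fmap["ch_moment"][r, c] == pytest.approx(
                    tt["ch_moment"], abs=2.0)
                assert fmap["mineral_to_matrix"][r, c] == pytest.approx(
                    tt["mineral_to_matrix"], rel=0.05)

    def test_error_shrinks_as_noise_vanishes(self, pipeline_config):
        medians = []
        for snr in (10.0, 50.0, 0.0):
            errs = []
            for i in range(50):
                rng = np.random.default_rng(1000 + i)
                frac = float(rng.uniform(28, 40))
                t = PixelTruth(nu_soft=6.86, nu_hard=18.64, frac_soft=frac,
                               noise=snr)
                f = extract_brillouin_features(
                    simulate_brillouin_spectrum(t, seed=2000 + i),
                    pipeline_config)
                errs.append(abs(f.I_soft - frac))
            medians.append(float(np.median(errs)))
        assert medians[0] >= medians[1] >= medians[2]


@pytest.fixture(scope="module")
def study_rois():
    return generate_study_fixture(seed=3, shape=(5, 5), noise=0.0)


class TestStudyFixture:
    def test_six_named_rois(self, study_rois):
        assert set(study_rois) == {
            "frozen_cortical_diaphysis", "fixed_cortical_diaphysis",
            "frozen_trabecular_diaphysis", "fixed_trabecular_diaphysis",
            "frozen_cortical_epiphysis", "frozen_trabecular_epiphysis"}

    def test_fixation_contrast_directions(self, study_rois):
        def mean_truth(name, attr):
            _, grid = study_rois[name]
            return float(np.mean([getattr(px, attr) for px in grid.flat]))

        # fixation raises the soft-phase frequency and depletes its fraction
        for tissue in ("cortical", "trabecular"):
            frozen = mean_truth(f"frozen_{tissue}_diaphysis", "nu_soft")
            fixed = mean_truth(f"fixed_{tissue}_diaphysis", "nu_soft")
            assert fixed > frozen
            f_frac = mean_truth(f"frozen_{tissue}_diaphysis", "frac_soft")
            x_frac = mean_truth(f"fixed_{tissue}_diaphysis", "frac_soft")
            assert x_frac < 0.5 * f_frac

    def test_epiphyseal_trabecular_marrow_is_heme_enriched(self, study_rois):
        def mean_weight(name, comp):
            _, grid = study_rois[name]
            return float(np.mean([px.raman_composition[comp]
                                  for px in grid.flat]))

        assert mean_weight("frozen_trabecular_epiphysis", "heme") > \
            5 * mean_weight("frozen_trabecular_diaphysis", "heme")
        assert mean_weight("frozen_trabecular_diaphysis", "lipid") > \
            mean_weight("frozen_trabecular_epiphysis", "lipid")

    def test_same_seed_identical(self):
        a = generate_study_fixture(seed=4, shape=(4, 4), noise=50.0)
        b = generate_study_fixture(seed=4, shape=(4, 4), noise=50.0)
        for name in a:
            sa, sb = a[name][0], b[name][0]
            for x, y in zip(sa.raman.flat, sb.raman.flat):
                assert x.intensity.tobytes() == y.intensity.tobytes()
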