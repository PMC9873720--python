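"""Corrections and optical indices checked against closed forms and round trips."""

import numpy as np
import pytest

from wetdom import synthetic as syn
from wetdom.spectra import (
    EEM,
    AbsorbanceSpectrum,
    ScatterWidths,
    absorption_coefficient,
    blank_subtract,
    fluorescence_index,
    ife_correct,
    peak_ratio,
    pick_peaks,
    raman_area,
    raman_emission_wavelength,
    raman_normalize,
    remove_scatter,
    scatter_mask,
    slope_ratio,
    spectral_slope,
    suva254,
)


def make_eem(intensity=None, fill=1.0, **flags):
    ex = np.arange(230.0, 500.0 + 1e-9, 5.0)
    em = np.arange(250.0, 700.0 + 1e-9, 2.0)
    if intensity is None:
        intensity = np.full((em.size, ex.size), fill)
    return EEM(ex=ex, em=em, intensity=intensity, **flags)


def flat_spectrum(A=0.1, path=0.01):
    wl = np.arange(230.0, 800.0 + 1e-9, 1.0)
    return AbsorbanceSpectrum(wavelength=wl, absorbance=np.full(wl.size, A),
                              path_length=path)


class TestBlankSubtract:
    def test_sample_equal_blank_gives_zero(self):
        out = blank_subtract(make_eem(fill=2.5), make_eem(fill=2.5))
        assert np.all(out.intensity == 0.0)
        assert out.blank_corrected

    def test_zero_blank_leaves_sample(self):
        sample = make_eem(fill=3.0)
        out = blank_subtract(sample, make_eem(fill=0.0))
        np.testing.assert_array_equal(out.intensity, sample.intensity)

    def test_round_trip_recovers_signal(self):
        rng = np.random.default_rng(0)
        signal = make_eem(intensity=rng.uniform(0, 5, (226, 55)))
        blank = make_eem(intensity=rng.uniform(0, 0.2, (226, 55)))
        contaminated = make_eem(intensity=signal.intensity + blank.intensity)
        out = blank_subtract(contaminated, blank)
        np.testing.assert_allclose(out.intensity, signal.intensity, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        other = EEM(ex=np.arange(240.0, 500.0, 5.0),
                    em=np.arange(250.0, 700.0, 2.0),
                    intensity=np.zeros((225, 52)))
        with pytest.raises(ValueError, match="grid"):
            blank_subtract(make_eem(), other)

    def test_double_subtraction_refused(self):
        once = blank_subtract(make_eem(), make_eem(fill=0.0))
        with pytest.raises(ValueError, match="already"):
            blank_subtract(once, make_eem(fill=0.0))


class TestRamanNormalization:
    def test_constant_blank_area_is_window_width(self):
        assert raman_area(make_eem(fill=1.0)) == pytest.approx(57.0)

    def test_zero_blank_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            assert raman_area(make_eem(fill=0.0)) == 0.0

    def test_triangular_profile_matches_trapezoid(self):
        eem = make_eem(fill=0.0)
        j = np.argmin(np.abs(eem.ex - 350.0))
        # triangle peaking at em 400
        tri = np.maximum(0.0, 1.0 - np.abs(eem.em - 400.0) / 30.0)
        inten = eem.intensity.copy()
        inten[:, j] = tri
        eem = make_eem(intensity=inten)
        inner = eem.em[(eem.em > 371.0) & (eem.em < 428.0)]
        pts = np.concatenate([[371.0], inner, [428.0]])
        expected = np.trapezoid(np.interp(pts, eem.em, tri), pts)
        assert raman_area(eem) == pytest.approx(expected, rel=1e-12)

    def test_self_normalization_gives_unit_area(self):
        blank = make_eem(fill=2.0)
        area = raman_area(blank)
        normalized = raman_normalize(blank, area)
        assert raman_area(normalized) == pytest.approx(1.0)
        assert normalized.raman_normalized

    def test_linearity_and_identity(self):
        eem = make_eem(fill=4.0)
        assert np.all(raman_normalize(eem, 1.0).intensity == eem.intensity)
        half = raman_normalize(eem, 2.0).intensity
        quarter = raman_normalize(eem, 4.0).intensity
        np.testing.assert_allclose(half, 2 * quarter)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            raman_normalize(make_eem(), 0.0)


class TestIFECorrection:
    def test_zero_absorbance_is_identity(self):
        eem = make_eem(fill=1.5)
        out = ife_correct(eem, flat_spectrum(A=0.0))
        np.testing.assert_array_equal(out.intensity, eem.intensity)
        assert out.ife_corrected

    def test_flat_absorbance_0p301_doubles(self):
        out = ife_correct(make_eem(fill=1.0), flat_spectrum(A=0.301))
        np.testing.assert_allclose(out.intensity, 10 ** 0.301, rtol=1e-12)
        assert out.intensity[0, 0] == pytest.approx(2.0, rel=1e-3)

    def test_generator_round_trip(self, coarse_grids):
        ex, em = coarse_grids
        pristine = syn.gen_eem_dataset(syn.EEMScenario(
            n_samples=3, seed=2, ex_grid=ex, em_grid=em))
        attenuated = syn.gen_eem_dataset(syn.EEMScenario(
            n_samples=3, seed=2, ife=True, ex_grid=ex, em_grid=em))
        spec = attenuated.absorbance[0]
        for raw, clean in zip(attenuated.eems, pristine.eems):
            corrected = ife_correct(raw, spec)
            np.testing.assert_allclose(corrected.intensity, clean.intensity,
                                       rtol=1e-6)

    def test_high_absorbance_warns(self):
        with pytest.warns(UserWarning, match="unreliable"):
            ife_correct(make_eem(), flat_spectrum(A=1.0))

    def test_missing_coverage_rejected(self):
        wl = np.arange(300.0, 800.0, 1.0)
        spec = AbsorbanceSpectrum(wavelength=wl, absorbance=np.full(wl.size, 0.1))
        with pytest.raises(ValueError, match="cover"):
            ife_correct(make_eem(), spec)


class TestScatterRemoval:
    def test_zero_widths_remove_nothing(self):
        eem = make_eem(fill=1.0)
        out = remove_scatter(eem, ScatterWidths(0.0, 0.0, 0.0, 0.0))
        assert not np.isnan(out.intensity).any()
        assert out.scatter_removed

    def test_synthetic_ridge_fully_excised(self, coarse_grids):
        ex, em = coarse_grids
        st = syn.ScatterSettings(rayleigh2=False, raman=False,
                                 width_rayleigh1=4.0)
        ds = syn.gen_eem_dataset(syn.EEMScenario(
            n_samples=1, seed=0, scatter=st,
            scores=np.zeros((1, 5)), ex_grid=ex, em_grid=em))
        widths = ScatterWidths(rayleigh1=15.0, rayleigh2=0.0, raman1=0.0)
        out = remove_scatter(ds.eems[0], widths)
        # brute-force mask: every cell with meaningful ridge intensity
        ridge = ds.eems[0].intensity > 1e-3
        removed = np.isnan(out.intensity)
        assert np.all(removed[ridge])
        np.testing.assert_array_equal(
            removed, scatter_mask(ex, em, widths))

    def test_interpolation_restores_linear_profile(self):
        # interior band only: linear interpolation across the gap is exact
        ex = np.arange(280.0, 340.0 + 1e-9, 5.0)
        em = np.arange(250.0, 700.0 + 1e-9, 2.0)
        line = np.linspace(1, 10, em.size)
        eem = EEM(ex=ex, em=em,
                  intensity=np.tile(line[:, None], (1, ex.size)))
        out = remove_scatter(eem, ScatterWidths(10.0, 0.0, 0.0),
                             interpolate=True)
        np.testing.assert_allclose(out.intensity, eem.intensity, rtol=1e-12)


class TestAbsorbanceIndices:
    def test_absorption_coefficient_arithmetic(self):
        assert absorption_coefficient(flat_spectrum(A=0.1, path=0.01)) == \
            pytest.approx(np.log(10) * 0.1 / 0.01)
        assert absorption_coefficient(flat_spectrum(A=0.1)) == \
            pytest.approx(23.03, abs=0.01)
        assert absorption_coefficient(flat_spectrum(A=0.0)) == 0.0

    def test_interpolated_query(self):
        wl = np.array([250.0, 254.0, 255.0, 300.0])
        ab = np.array([0.5, 0.2, 0.4, 0.1])
        spec = AbsorbanceSpectrum(wavelength=wl, absorbance=ab)
        assert spec.value_at(254.5) == pytest.approx(0.3)

    def test_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="range"):
            absorption_coefficient(flat_spectrum(), wavelength=1000.0)

    def test_suva_arithmetic_and_linearity(self):
        spec = flat_spectrum(A=0.2, path=0.01)  # 20 per metre
        assert suva254(spec, 10.0) == pytest.approx(2.0)
        assert suva254(spec, 20.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            suva254(spec, 0.0)

    def test_effluent_like_suva(self):
        # back-solved: A254/m = 2.4 * 15.5 -> SUVA = 2.4 at DOC 15.5 mg/L
        spec = flat_spectrum(A=2.4 * 15.5 * 0.01, path=0.01)
        assert suva254(spec, 15.5) == pytest.approx(2.4)


class TestSpectralSlope:
    def test_noiseless_exact(self):
        spec, _ = syn.gen_absorbance(a_ref=10.0, slopes=0.018)
        assert spectral_slope(spec, (275.0, 295.0)) == \
            pytest.approx(0.018, abs=1e-8)

    def test_constant_spectrum_zero_slope(self):
        assert spectral_slope(flat_spectrum(A=0.3), (275.0, 295.0)) == 0.0

    def test_noisy_mean_recovery_within_2pct(self):
        rng = np.random.default_rng(14)
        est = []
        for _ in range(100):
            spec, _ = syn.gen_absorbance(a_ref=10.0, slopes=0.018)
            noisy = AbsorbanceSpectrum(
                wavelength=spec.wavelength,
                absorbance=spec.absorbance *
                (1 + 0.01 * rng.standard_normal(spec.wavelength.size)),
                path_length=spec.path_length)
            est.append(spectral_slope(noisy, (275.0, 295.0)))
        assert np.mean(est) == pytest.approx(0.018, rel=0.02)

    def test_slope_ratio(self):
        assert slope_ratio(0.012, 0.020) == pytest.approx(0.6)
        with pytest.raises(ValueError):
            slope_ratio(0.012, 0.0)


class TestFluorescenceIndices:
    def test_symmetric_eem_fi_is_one(self):
        assert fluorescence_index(make_eem(fill=2.0)) == pytest.approx(1.0)

    def test_fi_conventions_differ_on_sloped_emission(self):
        eem = make_eem(intensity=np.tile(
            np.linspace(1, 5, 226)[:, None], (1, 55)))
        assert fluorescence_index(eem, "corrected") != \
            fluorescence_index(eem, "legacy")
        with pytest.raises(ValueError):
            fluorescence_index(eem, "bogus")

    def test_component_at_t_coordinates_dominates(self):
        comp = syn.ComponentSpec("t_like", 275.0, 340.0, 12.0, 15.0)
        ex = np.arange(230.0, 500.0 + 1e-9, 5.0)
        em = np.arange(250.0, 700.0 + 1e-9, 2.0)
        ds = syn.gen_eem_dataset(syn.EEMScenario(
            components=[comp], n_samples=1, scores=np.array([[3.0]]),
            ex_grid=ex, em_grid=em))
        peaks = pick_peaks(ds.eems[0])
        assert peaks["T"] == pytest.approx(3.0, rel=1e-9)
        assert peaks["B"] < peaks["T"]

    def test_peak_a_matches_exhaustive_scan(self):
        rng = np.random.default_rng(8)
        eem = make_eem(intensity=rng.uniform(0, 1, (226, 55)))
        peaks = pick_peaks(eem)
        j = np.argmin(np.abs(eem.ex - 260.0))
        sel = (eem.em >= 380.0) & (eem.em <= 410.0)
        assert peaks["A"] == np.max(eem.intensity[sel, j])

    def test_zero_t_peak_flags_ratio(self):
        peaks = {"A": 1.0, "T": 0.0}
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(peak_ratio(peaks))

    def test_fully_missing_window_warns(self):
        intensity = np.full((226, 55), np.nan)
        eem = make_eem(intensity=intensity)
        with pytest.warns(UserWarning):
            peaks = pick_peaks(eem)
        assert all(np.isnan(v) for v in peaks.values())


class TestRamanWavelength:
    def test_water_raman_at_350_nm_excitation(self):
        # 3400 1/cm shift from 350 nm lands near 397 nm
        assert raman_emission_wavelength(350.0) == pytest.approx(397.3, abs=0.5)
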