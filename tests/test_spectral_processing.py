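"""Preprocessing chain, band features and the synthetic library."""

import numpy as np
import pytest

from marginscan import library as lib
from marginscan import spectral_processing as spp

from .oracles import gaussian_band_mean, savgol_center_coefficients


def _full_preprocess(s):
    return spp.normalize_auc(
        spp.subtract_baseline_modpoly(spp.smooth(s)))


class TestCalibration:
    def test_quadratic_recovered_exactly(self):
        px = np.array([10.0, 200.0, 500.0, 800.0, 1000.0])
        true = np.array([1e-4, 1.1, 350.0])
        cal = spp.calibrate_wavenumber(px, np.polyval(true, px), order=2)
        assert np.allclose(cal.coefficients, true, rtol=0, atol=1e-9)

    def test_identity_pairs_give_identity_map(self):
        px = np.arange(5.0)
        cal = spp.calibrate_wavenumber(px, px, order=1)
        assert np.allclose(cal(np.array([2.5, 7.0])), [2.5, 7.0])

    def test_noisy_fit_residual_matches_lstsq_oracle(self, rng):
        px = np.array([50.0, 230.0, 460.0, 710.0, 950.0])
        wn = np.polyval([2e-4, 0.9, 400.0], px) + rng.normal(0, 0.5, 5)
        cal = spp.calibrate_wavenumber(px, wn, order=2)
        A = np.vander(px, 3)
        coef, *_ = np.linalg.lstsq(A, wn, rcond=None)
        rms = float(np.sqrt(np.mean((wn - A @ coef) ** 2)))
        assert cal.residual_rms == pytest.approx(rms, abs=1e-10)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="underdetermined"):
            spp.calibrate_wavenumber([1.0, 2.0], [1.0, 2.0], order=2)


class TestResponseCorrection:
    def test_measured_equals_true_is_identity(self, axis, rng):
        y = rng.random(axis.size) + 0.5
        lamp = spp.Spectrum(axis, np.full(axis.size, 2.0))
        s = spp.Spectrum(axis, y)
        out = spp.correct_response(s, lamp, lamp)
        assert np.allclose(out.intensities, y)

    def test_doubled_response_halves_output(self, axis):
        s = spp.Spectrum(axis, np.full(axis.size, 4.0))
        measured = spp.Spectrum(axis, np.full(axis.size, 2.0))
        true = spp.Spectrum(axis, np.full(axis.size, 1.0))
        assert np.allclose(spp.correct_response(s, measured, true).intensities,
                           2.0)

    def test_round_trip_recovers_input(self, axis, rng):
        y = rng.random(axis.size) + 0.2
        response = 0.5 + (axis - axis[0]) / (axis[-1] - axis[0])  # ramp
        true = spp.Spectrum(axis, np.ones(axis.size))
        measured = spp.Spectrum(axis, 1.0 / response)
        distorted = spp.Spectrum(axis, y / response)
        out = spp.correct_response(distorted, measured, true)
        assert np.allclose(out.intensities, y, rtol=0, atol=1e-12)

    def test_zero_in_measured_lamp_rejected(self, axis):
        s = spp.Spectrum(axis, np.ones(axis.size))
        bad = spp.Spectrum(axis, np.zeros(axis.size))
        with pytest.raises(ValueError, match="positive"):
            spp.correct_response(s, bad, s)


class TestSmoothing:
    def test_polynomial_reproduced_exactly_in_interior(self, axis):
        t = (axis - axis.mean()) / 100.0
        y = 1.0 + 2.0 * t + 0.5 * t**2 - 0.1 * t**3
        out = spp.smooth(spp.Spectrum(axis, y), window=7, polyorder=3)
        assert np.allclose(out.intensities[3:-3], y[3:-3], atol=1e-10)

    def test_noise_variance_reduced(self, axis, rng):
        y = rng.normal(0.0, 1.0, axis.size)
        out = spp.smooth(spp.Spectrum(axis, y), window=7, polyorder=3)
        assert out.intensities.var() < y.var()

    def test_matches_convolution_coefficient_oracle(self, axis, rng):
        y = rng.random(axis.size)
        out = spp.smooth(spp.Spectrum(axis, y), window=9, polyorder=3)
        h = savgol_center_coefficients(9, 3)
        manual = np.convolve(y, h[::-1], mode="valid")
        assert np.allclose(out.intensities[4:-4], manual, atol=1e-10)

    def test_invalid_window_rejected(self, axis):
        s = spp.Spectrum(axis, np.ones(axis.size))
        with pytest.raises(ValueError):
            spp.smooth(s, window=6)
        with pytest.raises(ValueError):
            spp.smooth(s, window=3, polyorder=5)


class TestBaseline:
    def test_pure_polynomial_removed(self, axis):
        t = (axis - axis[0]) / (axis[-1] - axis[0])
        y = 3.0 - 2.0 * t + 1.5 * t**2 - 0.4 * t**3
        out = spp.subtract_baseline_modpoly(spp.Spectrum(axis, y), order=5)
        assert np.abs(out.intensities).max() < 1e-6 * np.abs(y).max()

    def test_peak_heights_recovered_within_5_percent(self, axis):
        t = (axis - axis[0]) / (axis[-1] - axis[0])
        baseline = 0.5 - 0.3 * t + 0.2 * t**3
        peaks = (0.20 * np.exp(-0.5 * ((axis - 1100) / 8) ** 2)
                 + 0.35 * np.exp(-0.5 * ((axis - 1450) / 10) ** 2))
        out = spp.subtract_baseline_modpoly(
            spp.Spectrum(axis, baseline + peaks), order=5)
        for center, height in ((1100, 0.20), (1450, 0.35)):
            got = out.intensities[np.argmin(np.abs(axis - center))]
            assert got == pytest.approx(height, rel=0.05)

    def test_all_zero_input_stays_zero(self, axis):
        out = spp.subtract_baseline_modpoly(
            spp.Spectrum(axis, np.zeros(axis.size)))
        assert np.allclose(out.intensities, 0.0)

    def test_invariant_to_added_polynomial(self, axis, rng):
        # adding any polynomial of degree <= order changes the output by
        # less than 5% of the peak height
        peaks = 0.30 * np.exp(-0.5 * ((axis - 1300) / 9) ** 2)
        noise = rng.normal(0, 1e-3, axis.size)
        t = (axis - axis[0]) / (axis[-1] - axis[0])
        poly = 1.0 + 0.8 * t - 0.5 * t**2 + 0.3 * t**4
        a = spp.subtract_baseline_modpoly(spp.Spectrum(axis, peaks + noise))
        b = spp.subtract_baseline_modpoly(
            spp.Spectrum(axis, peaks + noise + poly))
        assert np.abs(a.intensities - b.intensities).max() < 0.05 * 0.30

    def test_order_validation(self, axis):
        with pytest.raises(ValueError):
            spp.subtract_baseline_modpoly(
                spp.Spectrum(axis, np.ones(axis.size)), order=0)


class TestNormalization:
    def test_constant_over_span(self):
        axis = spp.default_axis(1000.0, 1100.0, 1.0)
        out = spp.normalize_auc(spp.Spectrum(axis, np.full(axis.size, 2.0)))
        assert np.allclose(out.intensities, 1.0 / 100.0)

    def test_idempotent(self, axis, rng):
        s = spp.normalize_auc(spp.Spectrum(axis, rng.random(axis.size) + 0.1))
        again = spp.normalize_auc(s)
        assert np.array_equal(again.intensities, s.intensities)

    def test_unit_area_by_independent_integration(self, axis, rng):
        out = spp.normalize_auc(spp.Spectrum(axis, rng.random(axis.size) + 0.1))
        assert np.trapezoid(out.intensities, axis) == pytest.approx(1.0,
                                                                    abs=1e-9)

    def test_zero_area_rejected(self, axis):
        with pytest.raises(ValueError, match="zero-area"):
            spp.normalize_auc(spp.Spectrum(axis, np.zeros(axis.size)))


class TestBandRatio:
    def test_identical_bands_give_one(self, axis):
        y = np.ones(axis.size)
        s = spp.Spectrum(axis, y)
        assert spp.band_ratio(s, 1265, 1304) == pytest.approx(1.0)

    def test_isolated_gaussians_with_known_amplitudes(self, axis):
        y = (3.0 * np.exp(-0.5 * ((axis - 1100) / 8) ** 2)
             + 1.5 * np.exp(-0.5 * ((axis - 1600) / 8) ** 2))
        s = spp.Spectrum(axis, y)
        ratio = spp.band_ratio(s, 1100, 1600, halfwidth=4.0)
        num = gaussian_band_mean(3.0, 1100, 8 * 2.3548, 1096, 1104)
        den = gaussian_band_mean(1.5, 1600, 8 * 2.3548, 1596, 1604)
        assert ratio == pytest.approx(num / den, abs=0.01)
        assert ratio == pytest.approx(2.0, abs=0.01)

    def test_band_outside_axis_rejected(self, axis):
        s = spp.Spectrum(axis, np.ones(axis.size))
        with pytest.raises(ValueError, match="outside"):
            spp.band_ratio(s, 500, 1304)


class TestSynthesize:
    def test_single_component_peaks_at_strongest_band(self, axis):
        s = spp.synthesize_spectrum(lib.component("polymer_film"),
                                    wavenumbers=axis)
        assert axis[np.argmax(s.intensities)] == pytest.approx(1614, abs=1)

    def test_mixture_linearity(self, axis):
        fa, fi = lib.component("fatty"), lib.component("fibroadenomatoid")
        mix = spp.synthesize_spectrum([fa, fi], fractions=[0.5, 0.5],
                                      wavenumbers=axis)
        expected = 0.5 * (fa.profile(axis) + fi.profile(axis))
        assert np.allclose(mix.intensities, expected, atol=1e-12)

    def test_seeded_determinism(self, axis):
        kw = dict(fractions=[1.0], noise_sigma=1e-3, seed=9, wavenumbers=axis)
        s1 = spp.synthesize_spectrum([lib.component("fatty")], **kw)
        s2 = spp.synthesize_spectrum([lib.component("fatty")], **kw)
        assert np.array_equal(s1.intensities, s2.intensities)

    def test_bad_fractions_rejected(self, axis):
        with pytest.raises(ValueError, match="sum to 1"):
            spp.synthesize_spectrum([lib.component("fatty")],
                                    fractions=[0.7], wavenumbers=axis)


class TestPipelineOrder:
    def test_smoothing_after_normalization_refused(self, axis, rng):
        s = spp.normalize_auc(spp.Spectrum(axis, rng.random(axis.size) + 0.1))
        with pytest.raises(ValueError, match="order violation"):
            spp.smooth(s)

    def test_response_correction_after_baseline_refused(self, axis, rng):
        s = spp.subtract_baseline_modpoly(
            spp.Spectrum(axis, rng.random(axis.size)))
        lamp = spp.Spectrum(axis, np.ones(axis.size))
        with pytest.raises(ValueError, match="order violation"):
            spp.correct_response(s, lamp, lamp)

    def test_stage_tags_accumulate_in_order(self, axis, rng):
        s = _full_preprocess(spp.Spectrum(axis, rng.random(axis.size) + 0.2))
        assert s.stages == ("raw", "smoothed", "baseline_subtracted",
                            "normalized")


@pytest.fixture(scope="module")
def prepped(axis):
    out = {}
    for i, name in enumerate(("fatty", "fibroadenomatoid")):
        s = spp.synthesize_spectrum(lib.component(name),
                                    baseline_coefficients=(0.05, -0.02),
                                    noise_sigma=1e-4, seed=100 + i,
                                    wavenumbers=axis)
        out[name] = _full_preprocess(s)
    return out


class TestTissueLibraryContrasts:
    """The class contrasts that drive margin discrimination must survive
    the full preprocessing chain."""

    def test_phenylalanine_band_detectable_only_in_fibroadenomatoid(self, prepped):
        fa, fi = prepped["fatty"], prepped["fibroadenomatoid"]
        assert spp.band_intensity(fi, 1006) > 3 * spp.band_intensity(fa, 1006)

    def test_fibroadenomatoid_has_higher_1265_to_1304(self, prepped):
        assert spp.band_ratio(prepped["fibroadenomatoid"], 1265, 1304) > \
            spp.band_ratio(prepped["fatty"], 1265, 1304)

    def test_fibroadenomatoid_has_lower_1445(self, prepped):
        assert spp.band_intensity(prepped["fibroadenomatoid"], 1445) < \
            spp.band_intensity(prepped["fatty"], 1445)

    def test_fatty_has_higher_1445_to_1265(self, prepped):
        assert spp.band_ratio(prepped["fatty"], 1445, 1265) > \
            spp.band_ratio(prepped["fibroadenomatoid"], 1445, 1265)

    def test_amide_i_band_broader_in_fibroadenomatoid(self, prepped):
        def fwhm_around(s, center, window=60.0):
            wn, y = s.wavenumbers, s.intensities
            sel = (wn > center - window) & (wn < center + window)
            yy = y[sel]
            half = yy.max() / 2.0
            above = np.flatnonzero(yy >= half)
            return wn[sel][above[-1]] - wn[sel][above[0]]

        assert fwhm_around(prepped["fibroadenomatoid"], 1657) > \
            fwhm_around(prepped["fatty"], 1657)


class TestSNR:
    def test_known_signal_and_noise_levels(self, axis, rng):
        y = np.zeros(axis.size)
        sel = (axis >= 1400) & (axis <= 1500)
        y[sel] = 2.0
        noise_sel = (axis >= 1750) & (axis <= 1800)
        y[noise_sel] = rng.normal(0.0, 0.1, noise_sel.sum())
        got = spp.snr(spp.Spectrum(axis, y))
        expected = 2.0 / np.std(y[noise_sel])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_noise_free_region_gives_infinite_snr(self, axis):
        s = spp.Spectrum(axis, np.where(axis < 1700, 1.0, 0.0))
        assert np.isinf(spp.snr(s))
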