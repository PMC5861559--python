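import numpy as np
import pytest
from scipy.special import erf

import phonescope as ps
from phonescope.errors import FitError, GeometryError
from phonescope.resolution import (LineProfile, MultiGaussianModel,
                                   differentiate, extract_profile,
                                   fit_multi_gaussian)
from phonescope.targets import FWHM_PER_SIGMA, gaussian_sigma_from_fwhm

from conftest import LENS_SCENES, render_element_4_2


def gaussian_esf_profile(sigma, spacing, center=0.0, half_span=None,
                         lo=0.1, hi=0.9):
    """Analytic Gaussian-blurred step edge sampled on a uniform grid."""
    half_span = 8 * sigma if half_span is None else half_span
    x = np.arange(-half_span, half_span + spacing / 2, spacing)
    esf = lo + (hi - lo) * 0.5 * (1 + erf((x - center) / (sigma * np.sqrt(2))))
    return LineProfile(positions=x - x[0], intensities=esf), x - x[0]


class TestExtractProfile:
    def test_horizontal_segment_equals_row(self):
        rng = np.random.default_rng(1)
        img = ps.RasterImage(rng.random((32, 48)), pixel_pitch=1.2)
        prof = extract_profile(img, (10, 5), (10, 40))
        np.testing.assert_allclose(prof.intensities,
                                   img.intensities[10, 5:41])
        assert prof.spacing == pytest.approx(1.2)

    def test_width_averaging_reduces_noise(self):
        rng = np.random.default_rng(2)
        img = ps.RasterImage(0.5 + 0.05 * rng.standard_normal((400, 400)),
                             pixel_pitch=1.0)
        sd1 = extract_profile(img, (200, 10), (200, 390)).intensities.std()
        sd5 = extract_profile(img, (200, 10), (200, 390),
                              width_px=5).intensities.std()
        assert sd5 == pytest.approx(sd1 / np.sqrt(5), rel=0.2)

    def test_out_of_bounds_rejected(self):
        img = ps.RasterImage(np.zeros((32, 32)), pixel_pitch=1.2)
        with pytest.raises(GeometryError):
            extract_profile(img, (10, -5), (10, 20))


class TestDifferentiate:
    def test_linear_ramp_constant_derivative(self):
        prof = LineProfile(np.arange(20.0), 3.0 * np.arange(20.0) + 1.0)
        d = differentiate(prof)
        np.testing.assert_allclose(d.intensities, 3.0)

    def test_ideal_step_localized(self):
        y = np.zeros(21)
        y[11:] = 1.0
        d = differentiate(LineProfile(np.arange(21.0), y))
        assert np.count_nonzero(d.intensities) == 2
        assert set(np.nonzero(d.intensities)[0]) == {10, 11}

    def test_too_short(self):
        with pytest.raises(ps.PhonescopeError):
            differentiate(LineProfile(np.array([0.0, 1.0]),
                                      np.array([0.0, 1.0])))

    def test_gaussian_edge_oracle(self):
        # derivative of a finely sampled Gaussian ESF is the Gaussian itself
        sigma = 1.63
        prof, x = gaussian_esf_profile(sigma, spacing=0.1)
        d = differentiate(prof)
        c = 8 * sigma  # edge center after the grid was shifted to start at 0
        oracle = 0.8 * np.exp(-(x - c) ** 2 / (2 * sigma**2)) \
            / (sigma * np.sqrt(2 * np.pi))
        resid = d.intensities[5:-5] - oracle[5:-5]
        nrmse = np.sqrt(np.mean(resid**2)) / np.sqrt(np.mean(oracle[5:-5]**2))
        assert nrmse < 0.02


class TestMultiGaussianFit:
    def test_single_gaussian_exact_recovery(self):
        x = np.arange(0.0, 60.0, 0.5)
        a, c, s = 0.7, 31.2, 2.4
        y = a * np.exp(-((x - c) / s) ** 2 / 2)
        (peak,) = fit_multi_gaussian(LineProfile(x, y), discrete=False)
        assert peak.amplitude == pytest.approx(a, rel=1e-6)
        assert peak.center == pytest.approx(c, rel=1e-6)
        assert peak.sigma == pytest.approx(s, rel=1e-6)
        assert peak.fwhm == pytest.approx(s * FWHM_PER_SIGMA, rel=1e-6)

    def test_two_opposite_peaks_with_noise(self):
        rng = np.random.default_rng(42)
        x = np.arange(0.0, 80.0, 0.5)
        s = 2.0
        y = (np.exp(-((x - 30.0) / s) ** 2 / 2)
             - np.exp(-((x - 38.0) / s) ** 2 / 2))  # separated by 4 sigma
        y += rng.normal(0, 1 / 50.0, len(x))  # SNR 50
        p1, p2 = fit_multi_gaussian(LineProfile(x, y), expected_peaks=2,
                                    discrete=False)
        assert p1.center == pytest.approx(30.0, abs=0.1 * s)
        assert p2.center == pytest.approx(38.0, abs=0.1 * s)
        assert p1.sigma == pytest.approx(s, rel=0.05)
        assert p2.sigma == pytest.approx(s, rel=0.05)
        assert p1.amplitude > 0 > p2.amplitude

    def test_six_alternating_peaks_on_rendered_element(self):
        img, roi = render_element_4_2(1.2, 3.2, seed=3)
        r0, c0, r1, c1 = roi
        row = (r0 + r1) / 2
        prof = extract_profile(img, (row, c0 - 25), (row, c1 + 25))
        peaks = fit_multi_gaussian(differentiate(prof), expected_peaks=6)
        assert len(peaks) == 6
        signs = [np.sign(p.amplitude) for p in peaks]
        assert signs == [-1, 1, -1, 1, -1, 1]

    def test_requesting_more_peaks_than_present(self):
        x = np.arange(0.0, 40.0, 0.5)
        y = np.exp(-((x - 20.0) / 2.0) ** 2 / 2)
        with pytest.raises(FitError, match="expected"):
            fit_multi_gaussian(LineProfile(x, y), expected_peaks=3)

    def test_flat_profile_has_no_peaks(self):
        x = np.arange(0.0, 40.0, 0.5)
        with pytest.raises(FitError):
            fit_multi_gaussian(LineProfile(x, np.zeros_like(x)))

    def test_result_summary_and_uncertainties(self):
        from conftest import SNR50_NOISE

        x = np.arange(0.0, 60.0, 0.5)
        y = 0.5 * np.exp(-((x - 30.0) / 2.0) ** 2 / 2)
        res = MultiGaussianModel(LineProfile(x, y),
                                 discrete=False).fit()
        text = res.summary()
        assert "peaks: 1" in text and "fwhm" in text
        (errs,) = res.peak_stderrs
        assert all(np.isfinite(errs))


class TestMeasureResolution:
    @pytest.mark.parametrize("name, M, fwhm",
                             [s for s in LENS_SCENES if s[0] == "CAY046"])
    def test_roundtrip_cay046(self, name, M, fwhm):
        img, roi = render_element_4_2(M, fwhm, seed=1)
        est = ps.measure_resolution(img, roi, magnification=M,
                                    expected_peaks=6)
        assert est.fwhm_mean == pytest.approx(fwhm, rel=0.05)
        assert est.n_edges == 6
        assert est.plane == "sample"

    def test_blurrier_scene_larger_estimate(self):
        est3 = ps.measure_resolution(*render_element_4_2(1.0, 3.0, seed=2),
                                     magnification=1.0, expected_peaks=6)
        est9 = ps.measure_resolution(*render_element_4_2(1.0, 9.0, seed=2),
                                     magnification=1.0, expected_peaks=6)
        assert est9.fwhm_mean > est3.fwhm_mean

    def test_invariance_to_scaling_and_inversion(self):
        img, roi = render_element_4_2(1.2, 3.2, seed=4)
        base = ps.measure_resolution(img, roi, magnification=1.2,
                                     expected_peaks=6).fwhm_mean
        scaled = ps.RasterImage(img.intensities * 0.37,
                                pixel_pitch=img.pixel_pitch)
        inverted = ps.RasterImage(img.intensities.max() - img.intensities,
                                  pixel_pitch=img.pixel_pitch)
        for variant in (scaled, inverted):
            est = ps.measure_resolution(variant, roi, magnification=1.2,
                                        expected_peaks=6)
            assert est.fwhm_mean == pytest.approx(base, rel=0.02)

    def test_plane_bookkeeping(self):
        img, roi = render_element_4_2(1.2, 3.2, seed=1)
        sample = ps.measure_resolution(img, roi, magnification=1.2,
                                       expected_peaks=6)
        sensor = ps.measure_resolution(img, roi, magnification=1.2,
                                       expected_peaks=6, plane="sensor")
        assert sensor.fwhm_mean == pytest.approx(sample.fwhm_mean * 1.2,
                                                 rel=1e-9)

    def test_sampling_fields_attached(self):
        img, roi = render_element_4_2(1.2, 3.2, seed=1)
        est = ps.measure_resolution(img, roi, magnification=1.2,
                                    expected_peaks=6)
        assert est.points_per_peak == pytest.approx(
            2 * est.fwhm_mean * 1.2 / 1.2, rel=1e-9)
        assert not est.adequate_sampling  # 6.4 points < 7


@pytest.fixture(scope="module")
def charts():
    out = {}
    for fwhm in (3.0, 9.0):
        scene = ps.SceneConfig(magnification=1.0, pixel_pitch=1.2,
                               psf_fwhm=fwhm, seed=3,
                               image_size=(760, 760))
        out[fwhm] = ps.render_usaf([4, 5, 6, 7], scene,
                                   orientations=("vertical",))
    return out


class TestSmallestResolvableElement:
    def test_finer_under_less_blur(self, charts):
        el3 = ps.smallest_resolvable_element(*charts[3.0])
        el9 = ps.smallest_resolvable_element(*charts[9.0])
        assert el3 is not None and el9 is not None
        assert el3.bar_width < el9.bar_width

    def test_unit_threshold_resolves_nothing(self, charts):
        assert ps.smallest_resolvable_element(
            *charts[9.0], modulation_threshold=1.0) is None

    def test_unblurred_chart_resolves_finest_rendered(self):
        scene = ps.SceneConfig(magnification=1.0, pixel_pitch=1.2,
                               psf_fwhm=0.0, image_size=(760, 760))
        img, emap = ps.render_usaf([4, 5], scene, orientations=("vertical",))
        el = ps.smallest_resolvable_element(img, emap)
        finest = min((ps.USAFElementSpec.from_indices(g, e)
                      for g, e, _ in emap), key=lambda s: s.bar_width)
        assert (el.group, el.element) == (finest.group, finest.element)


class TestFeatureContrast:
    def test_square_wave_full_contrast(self):
        x = np.arange(100.0)
        y = (x // 10 % 2).astype(float)
        prof = LineProfile(x, y)
        res = ps.feature_contrast(prof, (0, 99))
        assert res.modulation == pytest.approx(1.0)
        assert res.resolved

    def test_constant_profile_unresolved(self):
        prof = LineProfile(np.arange(50.0), np.full(50, 0.7))
        res = ps.feature_contrast(prof, (10, 40))
        assert res.modulation == 0.0
        assert not res.resolved

    def test_empty_window(self):
        prof = LineProfile(np.arange(50.0), np.full(50, 0.7))
        with pytest.raises(ps.PhonescopeError):
            ps.feature_contrast(prof, (200, 300))

    def test_filament_resolvability_transition(self):
        results = {}
        for fwhm in (3.0, 9.0):
            scene = ps.SceneConfig(magnification=1.0, pixel_pitch=1.2,
                                   psf_fwhm=fwhm, image_size=(120, 120))
            img = ps.add_filament_phantom(scene, filament_width=6.0,
                                          spacing=10.0)
            prof = extract_profile(img, (60, 5), (60, 114))
            mid = 0.5 * (prof.positions[0] + prof.positions[-1])
            results[fwhm] = ps.feature_contrast(prof, (mid - 6, mid + 6))
        assert results[3.0].resolved
        assert not results[9.0].resolved
        assert results[9.0].modulation < results[3.0].modulation


class TestLineProfileInvariants:
    def test_nonuniform_spacing_rejected(self):
        with pytest.raises(ValueError):
            LineProfile(np.array([0.0, 1.0, 2.5]), np.zeros(3))

    def test_decreasing_positions_rejected(self):
        with pytest.raises(ValueError):
            LineProfile(np.array([0.0, 2.0, 1.0]), np.zeros(3))

    def test_gaussian_peak_fwhm_relation(self):
        peak = ps.GaussianPeak(center=0.0, sigma=2.0, amplitude=1.0)
        assert peak.fwhm == pytest.approx(2.0 * FWHM_PER_SIGMA)
        with pytest.raises(ValueError):
            ps.GaussianPeak(center=0.0, sigma=0.0, amplitude=1.0)
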