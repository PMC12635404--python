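"""Spectrum synthesis, window integration and noise estimation."""

import numpy as np
import pytest

import hypermet as hm
from hypermet.spectra import DEFAULT_FREQ_MHZ, hz_to_ppm, ppm_to_hz


@pytest.fixture
def axis():
    return np.arange(190.0, 178.0, -0.005)


def singlet(center=183.5, window=(182.0, 185.0), amp=1.0, lw=2.0, name="s"):
    return hm.PeakDefinition(name, center, window, "singlet", linewidth_Hz=lw, amplitude=amp)


class TestSynthesize:
    def test_singlet_peak_height_and_area(self, axis):
        peak = singlet(amp=3.0)
        spec = hm.synthesize_spectrum([peak], axis, DEFAULT_FREQ_MHZ)
        assert spec.max() == pytest.approx(3.0, rel=1e-3)
        assert axis[np.argmax(spec)] == pytest.approx(183.5, abs=0.005)
        # Lorentzian area = amp * pi * (fwhm/2)
        fwhm_ppm = hz_to_ppm(2.0, DEFAULT_FREQ_MHZ)
        expected_area = 3.0 * np.pi * fwhm_ppm / 2.0
        got = hm.integrate_peak(spec, axis, (180.0, 187.0))
        assert got == pytest.approx(expected_area, rel=0.01)

    def test_lactate_doublet_splitting(self, axis):
        """55 Hz coupling splits the lactate line by 0.437 ppm at 125.77 MHz."""
        doublet = hm.PeakDefinition(
            "lactate_c1", 183.5, (182.0, 185.0), "doublet", J_Hz=55.0, linewidth_Hz=2.0
        )
        spec = hm.synthesize_spectrum([doublet], axis, DEFAULT_FREQ_MHZ)
        # two maxima, one on each side of the center
        left = axis[np.argmax(np.where(axis < 183.5, spec, -np.inf))]
        right = axis[np.argmax(np.where(axis > 183.5, spec, -np.inf))]
        sep_ppm = right - left
        assert sep_ppm == pytest.approx(55.0 / 125.77, abs=0.01)
        assert ppm_to_hz(sep_ppm, DEFAULT_FREQ_MHZ) == pytest.approx(55.0, abs=1.3)

    def test_linearity_of_rendering(self, axis):
        a = singlet(center=181.0, window=(180.0, 182.0), amp=2.0, name="a")
        b = singlet(center=186.0, window=(185.0, 187.0), amp=0.5, name="b")
        both = hm.synthesize_spectrum([a, b], axis, DEFAULT_FREQ_MHZ)
        separate = hm.synthesize_spectrum([a], axis, DEFAULT_FREQ_MHZ) + hm.synthesize_spectrum(
            [b], axis, DEFAULT_FREQ_MHZ
        )
        np.testing.assert_allclose(both, separate, rtol=1e-12)

    def test_doublet_conserves_area(self, axis):
        s = singlet(amp=2.0)
        d = hm.PeakDefinition(
            "d", 183.5, (182.0, 185.0), "doublet", J_Hz=55.0, linewidth_Hz=2.0, amplitude=2.0
        )
        area_s = hm.integrate_peak(hm.synthesize_spectrum([s], axis, DEFAULT_FREQ_MHZ), axis, (179.0, 189.0))
        area_d = hm.integrate_peak(hm.synthesize_spectrum([d], axis, DEFAULT_FREQ_MHZ), axis, (179.0, 189.0))
        assert area_d == pytest.approx(area_s, rel=0.01)

    def test_axis_must_cover_windows(self):
        small = np.arange(185.0, 184.0, -0.01)
        with pytest.raises(ValueError, match="does not cover"):
            hm.synthesize_spectrum([singlet()], small, DEFAULT_FREQ_MHZ)

    def test_hz_ppm_inverse(self):
        assert hz_to_ppm(ppm_to_hz(0.437, 125.77), 125.77) == pytest.approx(0.437, rel=1e-15)


class TestIntegratePeak:
    def test_zero_spectrum(self, axis):
        assert hm.integrate_peak(np.zeros_like(axis), axis, (182.0, 185.0)) == 0.0

    def test_rectangle_area(self):
        axis = np.arange(10.0, 0.0, -0.01)
        spec = np.where((axis >= 4.0) & (axis < 6.0), 2.5, 0.0)
        got = hm.integrate_peak(spec, axis, (3.0, 7.0))
        assert got == pytest.approx(2.5 * 2.0, abs=2.5 * 0.01)

    def test_linearity(self, axis):
        rng = np.random.default_rng(0)
        x = rng.normal(size=axis.size)
        y = rng.normal(size=axis.size)
        w = (182.0, 185.0)
        lhs = hm.integrate_peak(3.0 * x + 0.5 * y, axis, w)
        rhs = 3.0 * hm.integrate_peak(x, axis, w) + 0.5 * hm.integrate_peak(y, axis, w)
        assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-12)

    def test_baseline_subtraction_removes_offset_ramp(self, axis):
        spec = hm.synthesize_spectrum([singlet(amp=1.0)], axis, DEFAULT_FREQ_MHZ)
        ramp = 0.3 + 0.05 * (axis - axis.min())
        clean = hm.integrate_peak(spec, axis, (182.0, 185.0), baseline=True)
        ramped = hm.integrate_peak(spec + ramp, axis, (182.0, 185.0), baseline=True)
        assert ramped == pytest.approx(clean, rel=0.02)

    def test_empty_window_rejected(self, axis):
        with pytest.raises(ValueError):
            hm.integrate_peak(np.zeros_like(axis), axis, (50.0, 50.5))


class TestEstimateNoise:
    def test_gaussian_noise_recovered(self):
        axis = np.arange(200.0, 150.0, -0.01)
        rng = np.random.default_rng(42)
        sigma = 0.37
        spec = rng.normal(0.0, sigma, axis.size)
        est = hm.estimate_noise(spec, axis, (160.0, 162.0))
        assert est == pytest.approx(sigma, rel=0.15)

    def test_zero_vector_and_offset_invariance(self):
        axis = np.arange(10.0, 0.0, -0.05)
        assert hm.estimate_noise(np.zeros_like(axis), axis, (2.0, 8.0)) == 0.0
        rng = np.random.default_rng(1)
        spec = rng.normal(size=axis.size)
        base = hm.estimate_noise(spec, axis, (2.0, 8.0))
        assert hm.estimate_noise(spec + 100.0, axis, (2.0, 8.0)) == pytest.approx(base)

    def test_window_overlapping_peak_rejected(self, axis):
        with pytest.raises(ValueError, match="overlaps"):
            hm.estimate_noise(np.zeros_like(axis), axis, (184.0, 186.0), peaks=[singlet()])

    def test_too_few_points_rejected(self):
        axis = np.arange(10.0, 0.0, -0.5)
        with pytest.raises(ValueError, match="16 points"):
            hm.estimate_noise(np.zeros_like(axis), axis, (4.0, 6.0))


class TestSeriesToDynamic:
    def test_round_trip_from_known_series(self):
        """Spectra rendered from known traces reduce back proportionally."""
        import dataclasses

        sc = dataclasses.replace(
            hm.get_preset("day7"),
            render_spectra=True,
            noise_sd_frac=0.0,
            spectrum_noise_sd_frac=0.0,
        )
        series, spectra = hm.generate_dynamic(sc)
        sub = hm.DEFAULT_C13_PEAKS["glucose_anomeric"]
        prod = hm.DEFAULT_C13_PEAKS["lactate_c1"]
        reduced = hm.series_to_dynamic(spectra, sub, prod)
        for got, ref in (
            (reduced.substrate_signal, series.substrate_signal),
            (reduced.product_signal, series.product_signal),
        ):
            corr = np.corrcoef(got, ref)[0, 1]
            assert corr >= 0.999

    def test_single_scan(self):
        axis = np.arange(190.0, 178.0, -0.01)
        spec = hm.synthesize_spectrum([singlet()], axis, DEFAULT_FREQ_MHZ)
        ss = hm.SpectrumSeries(axis, spec[None, :], scan_times_s=[0.0])
        out = hm.series_to_dynamic(
            ss, singlet(center=183.5, window=(182.0, 184.0), name="sub"),
            singlet(center=186.0, window=(185.0, 187.0), name="prod"),
        )
        assert len(out) == 1

    def test_scan_order_passthrough(self):
        """No hidden smoothing: permuting scans permutes outputs identically."""
        axis = np.arange(190.0, 178.0, -0.02)
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(6, axis.size))
        sub = singlet(center=183.5, window=(182.0, 184.0), name="sub")
        prod = singlet(center=186.0, window=(185.0, 187.0), name="prod")
        base = hm.series_to_dynamic(hm.SpectrumSeries(axis, mat, scan_times_s=np.arange(6.0)), sub, prod)
        perm = np.array([3, 1, 5, 0, 2, 4])
        scrambled = hm.series_to_dynamic(
            hm.SpectrumSeries(axis, mat[perm], scan_times_s=np.arange(6.0)), sub, prod
        )
        np.testing.assert_array_equal(scrambled.substrate_signal, base.substrate_signal[perm])

    def test_overlapping_windows_warn_in_provenance(self):
        axis = np.arange(190.0, 178.0, -0.02)
        mat = np.zeros((3, axis.size))
        a = singlet(center=183.5, window=(182.0, 185.0), name="a")
        b = singlet(center=184.0, window=(183.0, 186.0), name="b")
        out = hm.series_to_dynamic(hm.SpectrumSeries(axis, mat, scan_times_s=np.arange(3.0)), a, b)
        assert any("overlap" in w for w in out.meta.get("warnings", []))


class TestSummedSNRGrowth:
    def test_snr_grows_like_sqrt_n(self):
        """Summing n identical-signal scans grows SNR by ~sqrt(n)."""
        axis = np.arange(190.0, 178.0, -0.005)
        peak = singlet(amp=1.0)
        rng = np.random.default_rng(11)
        n = 50
        mat = np.stack(
            [hm.synthesize_spectrum([peak], axis, DEFAULT_FREQ_MHZ, noise_sd=0.05, seed=rng) for _ in range(n)]
        )
        ss = hm.SpectrumSeries(axis, mat, scan_times_s=np.arange(float(n)))

        def snr(spec):
            height = spec[(axis >= 182.0) & (axis < 185.0)].max()
            return height / hm.estimate_noise(spec, axis, (187.0, 189.5), peaks=[peak])

        snr1 = np.mean([snr(mat[i]) for i in range(10)])
        snr_n = snr(ss.summed(n))
        assert snr_n / snr1 == pytest.approx(np.sqrt(n), rel=0.2)
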