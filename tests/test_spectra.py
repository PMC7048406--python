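"""Reflectance calibration, band resampling and NDVI conventions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import grassinvert as gi
from grassinvert.errors import BandCoverageError, CalibrationError, UndefinedNdviError

WL = np.arange(400.0, 1000.0, 2.3)


class TestCalibration:
    def test_target_equals_panel_gives_unit_reflectance(self):
        wl = np.array([500.0, 600.0, 700.0])
        panel = np.array([1000.0, 1100.0, 1200.0])
        dark = np.array([50.0, 60.0, 70.0])
        spec = gi.calibrate_reflectance(wl, panel, panel, dark, panel_reflectivity=1.0)
        np.testing.assert_allclose(spec.reflectance, 1.0)

    def test_target_equals_dark_gives_zero(self):
        wl = np.array([500.0, 600.0])
        spec = gi.calibrate_reflectance(wl, [50.0, 60.0], [1000.0, 1100.0], [50.0, 60.0])
        np.testing.assert_allclose(spec.reflectance, 0.0)

    def test_halfway_counts_give_half_reflectance(self):
        wl = np.array([500.0, 600.0])
        dark = np.array([50.0, 60.0])
        panel = np.array([1050.0, 1060.0])
        target = dark + 0.5 * (panel - dark)
        spec = gi.calibrate_reflectance(wl, target, panel, dark)
        np.testing.assert_allclose(spec.reflectance, 0.5)

    def test_panel_not_above_dark_names_channel(self):
        wl = np.array([500.0, 600.0])
        with pytest.raises(CalibrationError, match="channel 1"):
            gi.calibrate_reflectance(wl, [100.0, 100.0], [1000.0, 40.0], [50.0, 60.0])

    @given(gain=st.floats(min_value=0.1, max_value=100.0))
    def test_invariant_to_global_gain_on_all_counts(self, gain):
        wl = np.array([500.0, 600.0, 700.0])
        tgt, pan, drk = np.array([300.0, 400.0, 500.0]), np.array([900.0, 950.0, 1000.0]), np.array([20.0, 25.0, 30.0])
        base = gi.calibrate_reflectance(wl, tgt, pan, drk)
        scaled = gi.calibrate_reflectance(wl, gain * tgt, gain * pan, gain * drk)
        np.testing.assert_allclose(scaled.reflectance, base.reflectance, rtol=1e-12)

    def test_values_above_cap_are_clipped_with_warning(self, caplog):
        wl = np.array([500.0])
        with caplog.at_level("WARNING"):
            spec = gi.calibrate_reflectance(wl, [2000.0], [1000.0], [0.0])
        assert spec.reflectance[0] == pytest.approx(1.2)
        assert "clipped" in caplog.text


class TestResampleBand:
    def test_flat_spectrum_returns_its_level(self):
        spec = gi.Spectrum(WL, np.full(WL.size, 0.3))
        assert gi.resample_band(spec, gi.RED) == pytest.approx(0.3)
        assert gi.resample_band(spec, gi.NIR) == pytest.approx(0.3)

    def test_two_channel_window_mean(self):
        spec = gi.Spectrum(np.array([640.0, 660.0]), np.array([0.1, 0.3]))
        assert gi.resample_band(spec, gi.RED) == pytest.approx(0.2)

    def test_window_endpoints_inclusive(self):
        spec = gi.Spectrum(np.array([630.0, 680.0, 700.0]), np.array([0.1, 0.3, 0.9]))
        assert gi.resample_band(spec, gi.RED) == pytest.approx(0.2)

    def test_channels_outside_window_are_ignored(self):
        inside = gi.Spectrum(np.array([640.0, 660.0]), np.array([0.1, 0.3]))
        padded = gi.Spectrum(
            np.array([500.0, 640.0, 660.0, 900.0]), np.array([0.9, 0.1, 0.3, 0.8])
        )
        assert gi.resample_band(padded, gi.RED) == gi.resample_band(inside, gi.RED)

    def test_no_channel_in_window_raises(self):
        spec = gi.Spectrum(np.array([700.0, 750.0, 800.0]), np.array([0.2, 0.2, 0.2]))
        with pytest.raises(BandCoverageError):
            gi.resample_band(spec, gi.RED)

    def test_coarse_and_fine_grids_agree_on_smooth_spectrum(self):
        # dense-grid oracle: band mean of a smooth continuous spectrum
        f = lambda wl: 0.1 + 0.3 / (1.0 + np.exp(-(wl - 718.0) / 10.0))
        for band in (gi.RED, gi.NIR):
            coarse = np.arange(400.0, 1000.0, 2.3)
            fine = np.arange(400.0, 1000.0, 1.0)
            m_coarse = gi.resample_band(gi.Spectrum(coarse, f(coarse)), band)
            m_fine = gi.resample_band(gi.Spectrum(fine, f(fine)), band)
            assert m_coarse == pytest.approx(m_fine, abs=0.005)


class TestNdvi:
    def test_direct_arithmetic(self):
        assert gi.compute_ndvi(gi.BroadbandReflectance(red=0.05, nir=0.40)) == pytest.approx(
            0.35 / 0.45
        )

    def test_equal_bands_give_zero(self):
        assert gi.compute_ndvi(gi.BroadbandReflectance(red=0.2, nir=0.2)) == 0.0

    def test_zero_red_gives_one(self):
        assert gi.compute_ndvi(gi.BroadbandReflectance(red=0.0, nir=0.3)) == 1.0

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedNdviError):
            gi.compute_ndvi(gi.BroadbandReflectance(red=0.0, nir=0.0))

    @given(
        red=st.floats(min_value=0.0, max_value=1.2),
        nir=st.floats(min_value=0.0, max_value=1.2),
    )
    def test_bounded_in_unit_interval(self, red, nir):
        if red + nir == 0:
            return
        assert -1.0 <= gi.compute_ndvi(gi.BroadbandReflectance(red=red, nir=nir)) <= 1.0

    @given(
        red=st.floats(min_value=0.01, max_value=1.0),
        nir=st.floats(min_value=0.01, max_value=1.0),
        delta=st.floats(min_value=0.001, max_value=0.2),
    )
    def test_monotone_in_nir_antimonotone_in_red(self, red, nir, delta):
        base = gi.compute_ndvi(gi.BroadbandReflectance(red=red, nir=nir))
        assert gi.compute_ndvi(gi.BroadbandReflectance(red=red, nir=nir + delta)) > base
        assert gi.compute_ndvi(gi.BroadbandReflectance(red=red + delta, nir=nir)) < base


class TestQuadratAndPlotAggregation:
    def _spec(self, red_level, nir_level):
        wl = np.array([640.0, 660.0, 850.0, 870.0])
        return gi.Spectrum(wl, np.array([red_level, red_level, nir_level, nir_level]))

    def test_single_spectrum_matches_band_mean_ndvi(self):
        spec = self._spec(0.1, 0.5)
        assert gi.quadrat_ndvi([spec]) == pytest.approx(gi.spectrum_ndvi(spec))

    def test_duplicate_spectra_do_not_change_the_mean(self):
        spec = self._spec(0.1, 0.5)
        assert gi.quadrat_ndvi([spec, spec]) == pytest.approx(gi.quadrat_ndvi([spec]))

    def test_mean_of_ndvi_convention_not_ndvi_of_mean(self):
        # heterogeneous two-pixel quadrat: the two conventions differ
        s1, s2 = self._spec(0.05, 0.50), self._spec(0.30, 0.35)
        mean_of_ndvi = (gi.spectrum_ndvi(s1) + gi.spectrum_ndvi(s2)) / 2
        mean_spec = gi.Spectrum(s1.wavelengths, (s1.reflectance + s2.reflectance) / 2)
        ndvi_of_mean = gi.spectrum_ndvi(mean_spec)
        assert mean_of_ndvi != pytest.approx(ndvi_of_mean)
        assert gi.quadrat_ndvi([s1, s2]) == pytest.approx(mean_of_ndvi)

    def test_empty_quadrat_raises(self):
        with pytest.raises(ValueError):
            gi.quadrat_ndvi([])

    def test_plot_mean(self):
        assert gi.plot_mean_ndvi([0.4, 0.6]) == pytest.approx(0.5)
        assert gi.plot_mean_ndvi([0.37]) == pytest.approx(0.37)
        assert gi.plot_mean_ndvi([0.1, 0.5, 0.9]) == gi.plot_mean_ndvi([0.9, 0.1, 0.5])
        with pytest.raises(ValueError):
            gi.plot_mean_ndvi([])


def test_ndvi_table_matches_per_spectrum_computation(noiseless_campaign):
    table = gi.ndvi_table(noiseless_campaign.spectra)
    merged = table.merge(noiseless_campaign.quadrats, on="quadrat_id", suffixes=("", "_gen"))
    np.testing.assert_allclose(merged["soc_ndvi"], merged["soc_ndvi_gen"], rtol=1e-12)
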