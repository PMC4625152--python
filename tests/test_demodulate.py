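"""Harmonic demodulation: band extraction, the scatter metric and its
closed-form Gaussian behaviour, and the absorption channel."""

import numpy as np
import pytest

from sfhi import (
    AcquisitionSettings,
    GridSpec,
    HarmonicBand,
    NoGridError,
    FlatFieldError,
    Phantom,
    bands_for_pitch,
    estimate_grid_frequency,
    extract_harmonic,
    interior,
    reconstruct,
    scatter_to_sigma,
    simulate_acquisition,
    simulate_reference,
)


def _uniform_phantom(shape, sigma=0.0, optical_depth=0.0, k=0.05):
    return Phantom(
        np.full(shape, float(optical_depth)),
        np.full(shape, sigma**2 / k),
        scatter_coupling=k,
    )


class TestEstimateGridFrequency:
    @pytest.mark.parametrize("pitch", [8.0, 16.0])
    def test_recovers_configured_pitch_within_one_bin(self, noise_free, pitch):
        ref = simulate_reference(GridSpec(pitch_px=pitch), (256, 256), settings=noise_free)
        f_row, f_col = estimate_grid_frequency(ref)
        assert abs(f_row - 1 / pitch) <= 1 / 256
        assert abs(f_col - 1 / pitch) <= 1 / 256

    def test_uniform_image_raises_no_grid(self):
        with pytest.raises(NoGridError):
            estimate_grid_frequency(np.ones((128, 128)))


class TestExtractHarmonic:
    def test_pure_cosine_gives_constant_half_amplitude_envelope(self):
        n, pitch, amp = 128, 8.0, 3.0
        img = amp * np.cos(2 * np.pi * np.arange(n)[None, :] / pitch) * np.ones((n, 1))
        env = np.abs(extract_harmonic(img, bands_for_pitch(pitch)[(0, 1)]))
        np.testing.assert_allclose(env, amp / 2, rtol=1e-9)

    def test_dc_band_of_constant_image_is_identity(self):
        img = np.full((64, 64), 7.5)
        env = extract_harmonic(img, bands_for_pitch(8.0)[(0, 0)])
        np.testing.assert_allclose(np.abs(env), 7.5, rtol=1e-12)

    def test_empty_band_has_negligible_energy(self):
        # band-limited image: all energy at f = 1/64, none in the carrier band
        x = np.arange(128)
        img = 1.0 + 0.5 * np.cos(2 * np.pi * x[None, :] / 64.0) * np.ones((128, 1))
        env = np.abs(extract_harmonic(img, bands_for_pitch(8.0)[(0, 1)]))
        assert env.max() <= 1e-10 * np.abs(img).max()

    def test_window_beyond_nyquist_rejected(self):
        band = HarmonicBand((0, 1), (0.0, 0.49), 0.05)
        with pytest.raises(ValueError, match="Nyquist"):
            extract_harmonic(np.zeros((64, 64)), band)

    def test_band_centre_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            HarmonicBand((0, 2), (0.0, 0.6), 0.01)


class TestReconstruct:
    def test_reference_against_itself_is_null(self, grid8, reference256):
        rec = reconstruct(reference256, reference256)
        assert np.abs(rec.absorption).max() <= 1e-9
        assert np.abs(rec.scatter_h).max() <= 1e-9
        assert np.abs(rec.scatter_v).max() <= 1e-9

    def test_uniform_attenuation_recovered(self, grid8, noise_free, reference256):
        sample = simulate_acquisition(
            _uniform_phantom((256, 256), optical_depth=0.5), grid8, settings=noise_free
        )
        rec = reconstruct(sample, reference256)
        a = interior(rec.absorption, rec.margin_px)
        np.testing.assert_allclose(a, 0.5, rtol=1e-6)
        assert np.abs(interior(rec.scatter_h, rec.margin_px)).max() < 1e-6

    def test_uniform_blur_matches_closed_form(self, grid8, noise_free, reference256):
        sigma = 1.2
        sample = simulate_acquisition(
            _uniform_phantom((256, 256), sigma=sigma), grid8, settings=noise_free
        )
        rec = reconstruct(sample, reference256)
        expected = 2 * np.pi**2 * sigma**2 / 8.0**2  # = 0.444
        s_mean = interior(rec.scatter_h, rec.margin_px).mean()
        assert s_mean == pytest.approx(expected, rel=0.02)
        assert interior(rec.scatter_v, rec.margin_px).mean() == pytest.approx(expected, rel=0.02)

    def test_scatter_metric_linear_in_sigma_squared(self, grid8, noise_free, reference256):
        sigmas = np.array([0.3, 0.6, 0.9, 1.2, 1.5])
        means = []
        for s in sigmas:
            sample = simulate_acquisition(
                _uniform_phantom((256, 256), sigma=s), grid8, settings=noise_free
            )
            rec = reconstruct(sample, reference256)
            means.append(interior(rec.scatter_h, rec.margin_px).mean())
        x = sigmas**2
        y = np.array(means)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        r2 = 1 - resid.var() / y.var()
        assert r2 >= 0.999

    def test_pitch_taken_from_exposure_metadata(self, grid8, noise_free, reference256):
        sample = simulate_acquisition(_uniform_phantom((256, 256)), grid8, settings=noise_free)
        rec = reconstruct(sample, reference256)  # no explicit pitch
        assert rec.pitch_px == (8.0, 8.0)

    def test_auto_pitch_estimates_from_reference(self, noise_free, reference256):
        sample = np.asarray(reference256, dtype=float)
        rec = reconstruct(sample, np.asarray(reference256, float), auto_pitch=True)
        assert rec.pitch_px[0] == pytest.approx(8.0)

    def test_shape_mismatch_rejected(self, reference256):
        with pytest.raises(ValueError, match="shape"):
            reconstruct(np.ones((64, 64)), reference256)

    def test_zero_reference_raises_flat_field_error(self):
        with pytest.raises((FlatFieldError, NoGridError)):
            reconstruct(np.ones((64, 64)), np.zeros((64, 64)), pitch_px=8.0)

    def test_degenerate_grid_flagged(self, noise_free):
        # no wires -> no carrier -> reconstruction must refuse
        ref = simulate_reference(GridSpec(duty=0.0), (64, 64), settings=noise_free)
        with pytest.raises(NoGridError, match="first-harmonic"):
            reconstruct(ref, ref, pitch_px=8.0)

    def test_noisy_null_object_scatter_has_zero_mean(self, grid8):
        ref = simulate_reference(grid8, (256, 256), settings=AcquisitionSettings(1e5, 7, True))
        smp = simulate_reference(grid8, (256, 256), settings=AcquisitionSettings(1e5, 8, True))
        rec = reconstruct(smp.pixels, ref.pixels, pitch_px=8.0)
        s = interior(rec.scatter_h, rec.margin_px)
        se = s.std() / np.sqrt(s.size / 8.0**2)  # envelope pixels correlate over ~pitch
        assert abs(s.mean()) < 3 * max(se, 1e-4)


class TestScatterToSigma:
    def test_zero_maps_to_zero(self):
        assert scatter_to_sigma(0.0, 1 / 8) == 0.0

    def test_inverts_closed_form(self):
        S = 2 * np.pi**2 * 1.2**2 / 64
        assert scatter_to_sigma(S, 1 / 8) == pytest.approx(1.2, rel=1e-12)

    def test_negative_values_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            out = scatter_to_sigma(np.array([-0.1, 0.0, 0.444]), 1 / 8)
        assert out[0] == 0.0

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 1.5])
    def test_round_trip_recovery_with_noise(self, grid8, sigma):
        # simulate -> reconstruct -> invert at fluence 1e5
        acq = AcquisitionSettings(1e5, 11, True)
        ref = simulate_reference(grid8, (256, 256), settings=AcquisitionSettings(1e5, 12, True))
        sample = simulate_acquisition(_uniform_phantom((256, 256), sigma=sigma), grid8, settings=acq)
        rec = reconstruct(sample, ref)
        s_mean = interior(rec.scatter_h, rec.margin_px).mean()
        assert scatter_to_sigma(s_mean, 1 / 8) == pytest.approx(sigma, rel=0.05)


class TestRotationEquivariance:
    def test_rot90_swaps_scatter_channels(self, grid8, noise_free, reference256):
        yy, xx = np.mgrid[0:256, 0:256]
        gold = 26 * np.exp(-(((yy - 150) / 25.0) ** 2 + ((xx - 110) / 18.0) ** 2) / 2)
        od = 0.4 * np.exp(-(((yy - 120) / 60.0) ** 2 + ((xx - 128) / 50.0) ** 2) / 2)
        ph = Phantom(od, gold)
        rec = reconstruct(simulate_acquisition(ph, grid8, settings=noise_free), reference256)
        ph_rot = Phantom(np.rot90(od), np.rot90(gold))
        rec_rot = reconstruct(simulate_acquisition(ph_rot, grid8, settings=noise_free), reference256)
        m = rec.margin_px
        a = interior(rec_rot.scatter_h, m)
        b = interior(np.rot90(rec.scatter_v), m)
        rel_rms = np.sqrt(((a - b) ** 2).mean()) / np.sqrt((b**2).mean())
        assert rel_rms < 0.01
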