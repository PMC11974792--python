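"""Spectral fields, phase shaping, and two-photon spectra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from melsim.pulse_optics import (FrequencyGrid, PhaseProfile, SpectralBand,
                                 apply_band_mask, apply_phase,
                                 make_supercontinuum,
                                 snap_omega0_to_half_grid, temporal_profile,
                                 total_yield, two_photon_spectrum,
                                 wavelength_to_omega)


class TestSupercontinuum:
    @pytest.mark.parametrize("power,center,fwhm", [
        (20.0, 1030.0, 180.0), (5.0, 1000.0, 100.0), (31.7, 1080.0, 220.0),
    ])
    def test_power_integral_matches_request(self, grid, power, center, fwhm):
        # independent trapezoidal re-integration of |E|^2 over omega
        f = make_supercontinuum(center, fwhm, power_mw=power, grid=grid)
        integral = np.trapezoid(np.abs(f.amplitude) ** 2, grid.omega)
        assert integral == pytest.approx(power, rel=1e-9)

    def test_zero_power_is_zero_field(self, grid):
        f = make_supercontinuum(power_mw=0.0, grid=grid)
        assert np.all(f.amplitude == 0)

    def test_support_outside_grid_raises(self, grid):
        with pytest.raises(ValueError):
            make_supercontinuum(support=SpectralBand(700.0, 1160.0), grid=grid)

    def test_default_reference_power(self, default_field):
        assert default_field.power_mw() == pytest.approx(20.0, rel=1e-9)


class TestPhase:
    def test_zero_coefficients_identity(self, default_field):
        out = apply_phase(default_field, PhaseProfile(980.0, {}))
        assert np.array_equal(out.amplitude, default_field.amplitude)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(a2=st.floats(-2e4, 2e4), a3=st.floats(-5e4, 5e4),
           center=st.floats(920.0, 1150.0))
    def test_phase_only_leaves_magnitude(self, default_field, a2, a3, center):
        out = apply_phase(default_field, PhaseProfile(center, {2: a2, 3: a3}))
        mag0 = np.abs(default_field.amplitude)
        assert np.max(np.abs(np.abs(out.amplitude) - mag0)) < 1e-12 * mag0.max()

    def test_orders_below_two_rejected(self):
        with pytest.raises(ValueError):
            PhaseProfile(980.0, {1: 100.0})


class TestBandMask:
    def test_hard_edge_zeroes_outside(self, default_field):
        out = apply_band_mask(default_field, SpectralBand(1100.0, 1200.0), 0.0)
        lam = default_field.grid.lambda_nm
        assert np.all(out.amplitude[lam < 1100.0] == 0)

    def test_full_band_preserves_power(self, default_field):
        out = apply_band_mask(default_field, SpectralBand(900.0, 1200.0))
        assert abs(out.power_mw() - default_field.power_mw()) < 0.01 * default_field.power_mw()

    def test_complementary_hard_masks_partition_power(self, default_field):
        lo = apply_band_mask(default_field, SpectralBand(851.0, 1030.0), 0.0)
        hi = apply_band_mask(default_field, SpectralBand(1030.0, 1249.0), 0.0)
        # the shared sample at exactly 1030 nm is counted twice only if a grid
        # point lands on it; complementary windows cover each sample once
        lam = default_field.grid.lambda_nm
        assert not np.any(lam == 1030.0)
        total = lo.power_mw() + hi.power_mw()
        assert total == pytest.approx(default_field.power_mw(), rel=1e-9)

    def test_disjoint_band_returns_zero_with_warning(self, default_field, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="melsim.pulse_optics"):
            out = apply_band_mask(default_field, SpectralBand(700.0, 800.0))
        assert np.all(out.amplitude == 0)
        assert any("disjoint" in r.message for r in caplog.records)


class TestTwoPhotonSpectrum:
    def test_narrowband_doubles_frequency(self, grid):
        f = make_supercontinuum(980.0, 10.0, SpectralBand(940.0, 1020.0), grid=grid)
        tps = two_photon_spectrum(f)
        lam_peak = tps.lambda_eq_nm[np.argmax(tps.s)]
        assert lam_peak == pytest.approx(490.0, abs=1.0)

    def test_flat_phase_dominates_random_phases(self, default_field, rng):
        s_flat = two_photon_spectrum(default_field).s
        for _ in range(20):
            prof = PhaseProfile(float(rng.uniform(930, 1150)),
                                {2: float(rng.uniform(-2e4, 2e4)),
                                 3: float(rng.uniform(-5e4, 5e4)),
                                 4: float(rng.uniform(-5e5, 5e5))})
            s_phi = two_photon_spectrum(apply_phase(default_field, prof)).s
            assert np.all(s_phi <= s_flat * (1 + 1e-9) + 1e-12 * s_flat.max())

    @pytest.mark.parametrize("center_nm", [980.0, 1140.0])
    def test_tod_preserves_doubled_center(self, default_field, center_nm):
        # odd phase cancels pairwise: a3*W^3 + a3*(-W)^3 = 0 at 2*omega0
        tps_flat = two_photon_spectrum(default_field)
        shaped = apply_phase(default_field, PhaseProfile.tod(center_nm))
        tps_tod = two_photon_spectrum(shaped)
        w0 = snap_omega0_to_half_grid(default_field.grid,
                                      wavelength_to_omega(center_nm))
        k = int(round((2 * w0 - tps_tod.two_omega[0]) / default_field.grid.domega))
        rel = abs(tps_tod.s[k] - tps_flat.s[k]) / tps_flat.s[k]
        assert rel < 1e-3

    def test_fft_matches_direct_sum(self):
        grid = FrequencyGrid.default(n_points=1024)
        f = make_supercontinuum(grid=grid)
        shaped = apply_phase(f, PhaseProfile.tod(1000.0))
        s_fft = two_photon_spectrum(shaped, method="fft").s
        s_dir = two_photon_spectrum(shaped, method="direct").s
        assert np.max(np.abs(s_fft - s_dir)) < 1e-9 * s_dir.max()


class TestYield:
    def test_zero_field_zero_yield(self, grid):
        f = make_supercontinuum(power_mw=0.0, grid=grid)
        assert total_yield(two_photon_spectrum(f)) == 0.0

    def test_quartic_amplitude_scaling(self, default_field):
        y1 = total_yield(two_photon_spectrum(default_field))
        doubled = default_field.with_amplitude(default_field.amplitude * np.sqrt(2.0))
        y2 = total_yield(two_photon_spectrum(doubled))
        assert y2 == pytest.approx(4.0 * y1, rel=1e-9)

    def test_flat_phase_maximizes_yield(self, default_field, rng):
        y_flat = total_yield(two_photon_spectrum(default_field))
        for _ in range(10):
            prof = PhaseProfile(float(rng.uniform(930, 1150)),
                                {3: float(rng.uniform(-5e4, 5e4))})
            y = total_yield(two_photon_spectrum(apply_phase(default_field, prof)))
            assert y <= y_flat * (1 + 1e-9)


class TestTemporalProfile:
    def test_flat_phase_duration_near_transform_limit(self, default_field):
        tp = temporal_profile(default_field)
        assert 5.0 <= tp.fwhm_fs <= 30.0

    def test_gdd_broadens(self, default_field):
        tp0 = temporal_profile(default_field)
        chirped = apply_phase(default_field, PhaseProfile.gdd(1030.0, 10000.0))
        assert temporal_profile(chirped).fwhm_fs > tp0.fwhm_fs

    def test_parseval(self, default_field):
        tp = temporal_profile(default_field)
        dt = tp.t_fs[1] - tp.t_fs[0]
        energy_t = np.sum(tp.intensity) * dt
        energy_w = np.trapezoid(np.abs(default_field.amplitude) ** 2,
                                default_field.grid.omega)
        assert energy_t == pytest.approx(energy_w, rel=1e-6)
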