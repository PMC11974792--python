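"""Broadband ultrafast fields, spectral phase/amplitude shaping, and two-photon spectra.

The stimulation light is a near-infrared supercontinuum (roughly 900-1160 nm)
represented by its complex spectral amplitude ``E(omega)`` on a uniform angular
frequency grid.  Two-photon absorption is driven not by ``|E|^2`` but by the
*two-photon excitation spectrum*

    S(2 w_s) = | sum_W E(w_s + W) E(w_s - W) d_omega |^2,

the squared magnitude of the field's autoconvolution.  Because the sum is
coherent, spectral *phase* alone can reshape S without touching the spectral
envelope: a flat phase maximizes S everywhere (transform limit), while pure
third-order dispersion a3*(w - w0)^3, being odd about w0, cancels pairwise at
exactly 2*w0 and suppresses S away from it.  That asymmetry is the photoswitching
mechanism this package models: TOD centered at 980 nm concentrates S near an
equivalent single-photon wavelength of 490 nm (blue, opsin-activating) while TOD
centered at 1140 nm moves it to ~570 nm (yellow, deactivating).

Units: angular frequency in rad/fs, wavelength in nm, time in fs.  Field
amplitudes carry units of sqrt(mW * fs) so that the trapezoidal integral of
``|E(omega)|^2`` over the grid equals the average power in mW.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "C_NM_PER_FS",
    "FrequencyGrid",
    "SpectralField",
    "PhaseProfile",
    "SpectralBand",
    "TwoPhotonSpectrum",
    "TemporalProfile",
    "wavelength_to_omega",
    "omega_to_wavelength",
    "make_supercontinuum",
    "apply_phase",
    "apply_band_mask",
    "two_photon_spectrum",
    "total_yield",
    "temporal_profile",
]

logger = logging.getLogger(__name__)

#: speed of light in nm per fs
C_NM_PER_FS = 299.792458


def wavelength_to_omega(lambda_nm):
    """Angular frequency (rad/fs) of vacuum wavelength ``lambda_nm``."""
    return 2.0 * np.pi * C_NM_PER_FS / np.asarray(lambda_nm, dtype=float)


def omega_to_wavelength(omega):
    """Vacuum wavelength (nm) of angular frequency ``omega`` (rad/fs)."""
    return 2.0 * np.pi * C_NM_PER_FS / np.asarray(omega, dtype=float)


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform angular-frequency grid spanning at least 850-1250 nm."""

    omega: np.ndarray

    def __post_init__(self):
        om = np.asarray(self.omega, dtype=float)
        object.__setattr__(self, "omega", om)
        if om.ndim != 1 or om.size < 1024:
            raise ValueError("grid needs at least 1024 points")
        d = np.diff(om)
        if np.any(d <= 0):
            raise ValueError("grid must be strictly increasing")
        if (d.max() - d.min()) / d.mean() > 1e-9:
            raise ValueError("grid must be uniform")
        lo, hi = wavelength_to_omega(1250.0), wavelength_to_omega(850.0)
        if om[0] > lo or om[-1] < hi:
            raise ValueError("grid must cover 850-1250 nm")

    @classmethod
    def default(cls, lambda_min_nm: float = 850.0, lambda_max_nm: float = 1250.0,
                n_points: int = 2048) -> "FrequencyGrid":
        om = np.linspace(wavelength_to_omega(lambda_max_nm),
                         wavelength_to_omega(lambda_min_nm), n_points)
        return cls(om)

    @property
    def n_points(self) -> int:
        return self.omega.size

    @property
    def domega(self) -> float:
        return float(self.omega[1] - self.omega[0])

    @property
    def lambda_nm(self) -> np.ndarray:
        return omega_to_wavelength(self.omega)


@dataclass(frozen=True)
class SpectralField:
    """Complex spectral amplitude on a :class:`FrequencyGrid`.

    ``trapz(|amplitude|^2, omega)`` is the average power in mW.
    """

    grid: FrequencyGrid
    amplitude: np.ndarray
    rep_rate_mhz: float = 20.0
    label: str = ""

    def __post_init__(self):
        amp = np.asarray(self.amplitude, dtype=complex)
        object.__setattr__(self, "amplitude", amp)
        if amp.shape != self.grid.omega.shape:
            raise ValueError("amplitude shape must match grid")
        if not np.all(np.isfinite(amp.view(float))):
            raise ValueError("amplitude must be finite")

    def power_mw(self) -> float:
        """Average power by trapezoidal quadrature of the spectral density."""
        return float(np.trapezoid(np.abs(self.amplitude) ** 2, self.grid.omega))

    def with_amplitude(self, amplitude, label: str | None = None) -> "SpectralField":
        return replace(self, amplitude=np.asarray(amplitude, dtype=complex),
                       label=self.label if label is None else label)


@dataclass(frozen=True)
class PhaseProfile:
    """Polynomial spectral phase sum_n a_n (omega - omega0)^n, orders n >= 2.

    Piston and linear phase are excluded: they shift the pulse in time but leave
    every two-photon observable unchanged.
    """

    center_wavelength_nm: float
    coefficients: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.center_wavelength_nm <= 0:
            raise ValueError("center wavelength must be positive")
        for order in self.coefficients:
            if int(order) != order or order < 2:
                raise ValueError("phase orders must be integers >= 2")

    @property
    def omega0(self) -> float:
        return float(wavelength_to_omega(self.center_wavelength_nm))

    @classmethod
    def tod(cls, center_wavelength_nm: float, a3_fs3: float = 15000.0) -> "PhaseProfile":
        """Pure third-order dispersion a3*(omega - omega0)^3."""
        return cls(center_wavelength_nm, {3: a3_fs3})

    @classmethod
    def gdd(cls, center_wavelength_nm: float, a2_fs2: float) -> "PhaseProfile":
        """Pure group-delay dispersion a2*(omega - omega0)^2."""
        return cls(center_wavelength_nm, {2: a2_fs2})


@dataclass(frozen=True)
class SpectralBand:
    """Wavelength band [lambda_lo_nm, lambda_hi_nm]."""

    lambda_lo_nm: float
    lambda_hi_nm: float

    def __post_init__(self):
        if not self.lambda_lo_nm < self.lambda_hi_nm:
            raise ValueError("band must satisfy lambda_lo < lambda_hi")


@dataclass(frozen=True)
class TwoPhotonSpectrum:
    """Two-photon spectral density on the doubled-frequency axis.

    ``s`` is quartic in the field amplitude (arbitrary units); ``lambda_eq_nm``
    is the equivalent single-photon wavelength 2*pi*c/(2*omega), so a degenerate
    photon pair at wavelength L maps to L/2.
    """

    two_omega: np.ndarray
    s: np.ndarray

    @property
    def lambda_eq_nm(self) -> np.ndarray:
        return 2.0 * np.pi * C_NM_PER_FS / self.two_omega


@dataclass(frozen=True)
class TemporalProfile:
    """Intensity envelope of the pulse and its interpolated FWHM."""

    t_fs: np.ndarray
    intensity: np.ndarray
    fwhm_fs: float
    multi_lobe: bool = False


def make_supercontinuum(center_nm: float = 1030.0, fwhm_nm: float = 180.0,
                        support: SpectralBand = SpectralBand(900.0, 1160.0),
                        power_mw: float = 20.0, rep_rate_mhz: float = 20.0,
                        grid: FrequencyGrid | None = None,
                        label: str = "supercontinuum") -> SpectralField:
    """Gaussian-envelope supercontinuum truncated to ``support``, flat phase.

    The spectral *power* density is Gaussian in wavelength with the given center
    and FWHM, hard-truncated to the support band, then rescaled so that the
    trapezoidal power integral equals ``power_mw`` exactly.
    """
    if power_mw < 0:
        raise ValueError("power must be nonnegative")
    if grid is None:
        grid = FrequencyGrid.default()
    lam = grid.lambda_nm
    if support.lambda_lo_nm < lam.min() - 1e-9 or support.lambda_hi_nm > lam.max() + 1e-9:
        raise ValueError("support band outside grid coverage")
    dens = np.exp(-4.0 * math.log(2.0) * ((lam - center_nm) / fwhm_nm) ** 2)
    dens[(lam < support.lambda_lo_nm) | (lam > support.lambda_hi_nm)] = 0.0
    if power_mw == 0:
        amp = np.zeros_like(dens)
    else:
        integral = np.trapezoid(dens, grid.omega)
        amp = np.sqrt(dens * (power_mw / integral))
    return SpectralField(grid, amp.astype(complex), rep_rate_mhz, label)


def snap_omega0_to_half_grid(grid: FrequencyGrid, omega0: float) -> float:
    """Nearest point to ``omega0`` on the half-step grid of ``grid``.

    On the half-grid, 2*omega0 coincides exactly with a sample of the
    autoconvolution axis, so odd phase orders cancel pairwise at 2*omega0 to
    machine precision instead of to the discretization error.
    """
    half = grid.domega / 2.0
    return float(grid.omega[0] + round((omega0 - grid.omega[0]) / half) * half)


def apply_phase(fld: SpectralField, profile: PhaseProfile,
                snap_center: bool = True) -> SpectralField:
    """Multiply the field by exp(i * sum_n a_n (omega - omega0)^n).

    Phase-only: ``|E|`` is unchanged at every sample.  ``snap_center`` moves
    omega0 onto the half-grid (a shift below one grid step, < 0.1 nm) so the
    doubled center frequency is exactly representable on the two-photon axis.
    """
    omega0 = profile.omega0
    if snap_center:
        omega0 = snap_omega0_to_half_grid(fld.grid, omega0)
    delta = fld.grid.omega - omega0
    phase = np.zeros_like(delta)
    for order, a_n in profile.coefficients.items():
        phase += a_n * delta ** int(order)
    return fld.with_amplitude(fld.amplitude * np.exp(1j * phase))


def apply_band_mask(fld: SpectralField, band: SpectralBand,
                    edge_width_nm: float = 2.0) -> SpectralField:
    """Amplitude mask: raised-cosine window, 1 inside the band, 0 beyond the edge.

    ``edge_width_nm = 0`` gives a hard knife-edge.  A band disjoint from the
    grid returns an identically zero field (with a warning) rather than erroring,
    mirroring a knife-edge that blocks the whole spectrum.
    """
    if edge_width_nm < 0:
        raise ValueError("edge width must be nonnegative")
    lam = fld.grid.lambda_nm
    lo, hi = band.lambda_lo_nm, band.lambda_hi_nm
    if edge_width_nm == 0:
        w = ((lam >= lo) & (lam <= hi)).astype(float)
    else:
        w = np.zeros_like(lam)
        inside = (lam >= lo) & (lam <= hi)
        w[inside] = 1.0
        below = (lam < lo) & (lam > lo - edge_width_nm)
        w[below] = 0.5 * (1.0 + np.cos(np.pi * (lo - lam[below]) / edge_width_nm))
        above = (lam > hi) & (lam < hi + edge_width_nm)
        w[above] = 0.5 * (1.0 + np.cos(np.pi * (lam[above] - hi) / edge_width_nm))
    if not np.any(w > 0):
        logger.warning("band mask %s disjoint from grid coverage; returning zero field",
                       band)
    return fld.with_amplitude(fld.amplitude * w)


def _direct_autoconvolution(amplitude: np.ndarray, domega: float) -> np.ndarray:
    """O(N^2) autoconvolution by explicit pair summation (independent oracle)."""
    n = amplitude.size
    outer = np.outer(amplitude, amplitude)
    idx = (np.arange(n)[:, None] + np.arange(n)[None, :]).ravel()
    flat = outer.ravel()
    conv = (np.bincount(idx, weights=flat.real, minlength=2 * n - 1)
            + 1j * np.bincount(idx, weights=flat.imag, minlength=2 * n - 1))
    return conv * domega


def two_photon_spectrum(fld: SpectralField, method: str = "fft") -> TwoPhotonSpectrum:
    """Two-photon excitation spectrum |(E * E)(2 omega)|^2.

    ``method="fft"`` uses an FFT-based linear autoconvolution; ``method="direct"``
    sums all photon pairs explicitly.  Both enumerate the same pair set and agree
    to rounding error.
    """
    dw = fld.grid.domega
    if method == "fft":
        conv = fftconvolve(fld.amplitude, fld.amplitude) * dw
    elif method == "direct":
        conv = _direct_autoconvolution(fld.amplitude, dw)
    else:
        raise ValueError(f"unknown method {method!r}")
    two_omega = 2.0 * fld.grid.omega[0] + np.arange(conv.size) * dw
    return TwoPhotonSpectrum(two_omega, np.abs(conv) ** 2)


def total_yield(tps: TwoPhotonSpectrum) -> float:
    """Integrated two-photon spectral density (scalar absorption proxy).

    Scales as the fourth power of the field amplitude, i.e. quadratically in
    average power.
    """
    return float(np.trapezoid(tps.s, tps.two_omega))


def temporal_profile(fld: SpectralField) -> TemporalProfile:
    """Intensity envelope |e(t)|^2 of the pulse and its FWHM.

    The envelope is the inverse Fourier transform of E(omega), normalized so that
    ``sum(intensity) * dt`` equals the spectral power integral (Parseval).  The
    time axis is centered on the envelope peak and carries no absolute timing.
    If more than one lobe exceeds half maximum, the FWHM of the lobe containing
    the global peak is reported and ``multi_lobe`` is set.
    """
    n = fld.grid.n_points
    dw = fld.grid.domega
    dt = 2.0 * np.pi / (n * dw)
    envelope = np.fft.ifft(fld.amplitude) * n * dw / math.sqrt(2.0 * np.pi)
    intensity = np.abs(envelope) ** 2
    peak = int(np.argmax(intensity))
    intensity = np.roll(intensity, n // 2 - peak)
    t = (np.arange(n) - n // 2) * dt
    fwhm, multi = _fwhm(t, intensity)
    return TemporalProfile(t, intensity, fwhm, multi)


def _fwhm(t: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """FWHM by linear interpolation between half-maximum crossings."""
    top = y.max()
    if top <= 0:
        return float("nan"), False
    half = top / 2.0
    above = y >= half
    # count contiguous runs above half maximum
    rising = np.flatnonzero(np.diff(above.astype(int)) == 1).size + int(above[0])
    multi = rising > 1
    ipk = int(np.argmax(y))
    # walk outwards from the global peak to its own half crossings
    i = ipk
    while i > 0 and y[i - 1] >= half:
        i -= 1
    if i == 0:
        t_lo = t[0]
    else:
        f = (half - y[i - 1]) / (y[i] - y[i - 1])
        t_lo = t[i - 1] + f * (t[i] - t[i - 1])
    j = ipk
    while j < y.size - 1 and y[j + 1] >= half:
        j += 1
    if j == y.size - 1:
        t_hi = t[-1]
    else:
        f = (y[j] - half) / (y[j] - y[j + 1])
        t_hi = t[j] + f * (t[j + 1] - t[j])
    return float(t_hi - t_lo), bool(multi)
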