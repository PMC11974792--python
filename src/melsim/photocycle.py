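"""Tri-stable melanopsin photocycle driven by two-photon excitation.

Melanopsin interconverts among three retinal isomer states: the ground state
|R> (11-cis), the signaling-active |M> (all-trans), and the silent excited
|E> (7-cis).  Blue-equivalent light drives R->M and E->M; yellow-equivalent
light drives M->E; M and E relax thermally back to R with distinct rates.
In the two-photon regime the drive is the two-photon spectrum S(2w) from
:mod:`melsim.pulse_optics`, read on the equivalent single-photon wavelength
axis (a degenerate pair at 980 nm acts like a 490 nm photon).

Photo-rates are spectral overlaps of S with per-state action spectra,
normalized so the default flat-phase full-band field at the reference power
has unit overlap with a flat action spectrum.  Since S is quartic in the field
amplitude, every photo-rate scales as (average power)^2.

State occupancies evolve on the probability simplex under the linear ODE
dp/dt = Q p with piecewise-constant rates per illumination segment; the
integrator steps with exact matrix exponentials, so trajectories are exact for
piecewise-constant protocols at any sampling interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm, null_space

from .pulse_optics import (FrequencyGrid, SpectralField, TwoPhotonSpectrum,
                           make_supercontinuum, two_photon_spectrum)

__all__ = [
    "ActionSpectrum",
    "PhotocycleParams",
    "PhotocycleState",
    "RateSet",
    "Segment",
    "IlluminationProtocol",
    "Trajectory",
    "reference_normalization",
    "photo_rates",
    "rate_matrix",
    "simulate_photocycle",
    "steady_state",
]


@dataclass(frozen=True)
class ActionSpectrum:
    """Unit-peak Gaussian absorption band in equivalent single-photon wavelength."""

    peak_lambda_eq_nm: float
    fwhm_nm: float

    def __post_init__(self):
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm must be positive")

    def __call__(self, lambda_eq_nm) -> np.ndarray:
        lam = np.asarray(lambda_eq_nm, dtype=float)
        return np.exp(-4.0 * math.log(2.0)
                      * ((lam - self.peak_lambda_eq_nm) / self.fwhm_nm) ** 2)


@dataclass
class PhotocycleParams:
    """Action spectra, photo-rate gains, and thermal relaxation rates.

    ``sigma_R`` drives R->M (gain ``eta_RM``), ``sigma_E`` drives E->M
    (``eta_EM``), ``sigma_M`` drives M->E (``eta_ME``).  Gains are in 1/s per
    unit normalized spectral overlap at the reference power ``p_ref_mw``.
    ``z_ref`` caches the reference normalization integral; it is computed on
    first use if unset.
    """

    sigma_R: ActionSpectrum = ActionSpectrum(480.0, 90.0)
    sigma_E: ActionSpectrum = ActionSpectrum(460.0, 90.0)
    sigma_M: ActionSpectrum = ActionSpectrum(560.0, 90.0)
    eta_RM: float = 2.0
    eta_EM: float = 2.0
    eta_ME: float = 2.0
    k_MR: float = 0.25
    k_ER: float = 0.02
    p_ref_mw: float = 20.0
    z_ref: float | None = None

    def __post_init__(self):
        for name in ("eta_RM", "eta_EM", "eta_ME", "k_MR", "k_ER"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.p_ref_mw <= 0:
            raise ValueError("p_ref_mw must be positive")

    def ensure_z_ref(self, grid: FrequencyGrid | None = None) -> float:
        if self.z_ref is None:
            self.z_ref = reference_normalization(self.p_ref_mw, grid)
        return self.z_ref


@dataclass(frozen=True)
class PhotocycleState:
    """Point on the occupancy simplex (p_R, p_M, p_E)."""

    p_R: float
    p_M: float
    p_E: float

    def __post_init__(self):
        p = self.as_array()
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError("occupancies must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("occupancies must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_R, self.p_M, self.p_E], dtype=float)

    @classmethod
    def rest(cls) -> "PhotocycleState":
        """Dark-adapted state: everything in the ground state |R>."""
        return cls(1.0, 0.0, 0.0)

    @classmethod
    def from_array(cls, p) -> "PhotocycleState":
        p = np.asarray(p, dtype=float)
        return cls(float(p[0]), float(p[1]), float(p[2]))


@dataclass(frozen=True)
class RateSet:
    """Photo rates (k_RM, k_EM, k_ME) and thermal rates (k_MR, k_ER), all 1/s."""

    k_RM: float
    k_EM: float
    k_ME: float
    k_MR: float
    k_ER: float

    def __post_init__(self):
        for name in ("k_RM", "k_EM", "k_ME", "k_MR", "k_ER"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def scaled_photo(self, factor: float) -> "RateSet":
        """Photo rates multiplied by ``factor``; thermal rates untouched."""
        return replace(self, k_RM=self.k_RM * factor, k_EM=self.k_EM * factor,
                       k_ME=self.k_ME * factor)

    @classmethod
    def dark(cls, params: "PhotocycleParams") -> "RateSet":
        return cls(0.0, 0.0, 0.0, params.k_MR, params.k_ER)


@dataclass(frozen=True)
class Segment:
    """One illumination segment of a protocol.

    ``coverage_duty`` is the fraction of the segment during which the cell is
    actually under the beam (1.0 for a targeted spiral dwelling on the soma,
    the cell-area/field-area ratio for full-frame raster scanning).
    ``power_scale`` rescales the field's built-in power (rates go as its
    square); ``rate_scale`` multiplies photo rates directly (expression level).
    """

    t_start: float
    t_end: float
    field: SpectralField | None = None
    coverage_duty: float = 1.0
    power_scale: float = 1.0
    rate_scale: float = 1.0

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValueError("segment must have t_end > t_start")
        if not 0.0 <= self.coverage_duty <= 1.0:
            raise ValueError("coverage_duty must lie in [0, 1]")


@dataclass(frozen=True)
class IlluminationProtocol:
    """Ordered, non-overlapping illumination segments; gaps are darkness."""

    segments: tuple = ()

    def __post_init__(self):
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        for a, b in zip(segs, segs[1:]):
            if b.t_start < a.t_end - 1e-12:
                raise ValueError("protocol segments must be ordered and non-overlapping")

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_end if self.segments else 0.0


@dataclass(frozen=True)
class Trajectory:
    """Occupancy trajectory sampled at uniform times."""

    t: np.ndarray
    p: np.ndarray  # shape (T, 3), columns (p_R, p_M, p_E)

    @property
    def p_R(self) -> np.ndarray:
        return self.p[:, 0]

    @property
    def p_M(self) -> np.ndarray:
        return self.p[:, 1]

    @property
    def p_E(self) -> np.ndarray:
        return self.p[:, 2]


_Z_REF_CACHE: dict = {}


def reference_normalization(p_ref_mw: float = 20.0,
                            grid: FrequencyGrid | None = None) -> float:
    """Normalization integral Z_ref = int S_ref d(lambda_eq).

    S_ref is the two-photon spectrum of the default flat-phase full-band
    supercontinuum at the reference power, so by construction that field has
    unit overlap with a flat (identity) action spectrum.
    """
    key = (p_ref_mw, None if grid is None else (grid.n_points, grid.omega[0], grid.omega[-1]))
    if key not in _Z_REF_CACHE:
        fld = make_supercontinuum(power_mw=p_ref_mw, grid=grid)
        tps = two_photon_spectrum(fld)
        _Z_REF_CACHE[key] = _integral_dlambda(tps, np.ones_like(tps.s))
    return _Z_REF_CACHE[key]


def _integral_dlambda(tps: TwoPhotonSpectrum, weight: np.ndarray) -> float:
    """int S(lambda_eq) * weight d(lambda_eq), on the ascending wavelength axis."""
    lam = tps.lambda_eq_nm
    order = np.argsort(lam)
    return float(np.trapezoid((tps.s * weight)[order], lam[order]))


def photo_rates(tps: TwoPhotonSpectrum, params: PhotocycleParams,
                power_scale: float = 1.0,
                grid: FrequencyGrid | None = None) -> RateSet:
    """Photo-transition rates from spectral overlap with the action spectra.

    k_XY = eta_XY * int S(lambda_eq) sigma_X(lambda_eq) d(lambda_eq) / Z_ref.
    ``power_scale`` multiplies the field's average power, so rates pick up a
    factor power_scale**2 (S is quartic in amplitude).  Thermal rates are
    copied through unchanged.
    """
    z = params.ensure_z_ref(grid)
    lam = tps.lambda_eq_nm
    p2 = power_scale ** 2
    k_rm = params.eta_RM * _integral_dlambda(tps, params.sigma_R(lam)) / z * p2
    k_em = params.eta_EM * _integral_dlambda(tps, params.sigma_E(lam)) / z * p2
    k_me = params.eta_ME * _integral_dlambda(tps, params.sigma_M(lam)) / z * p2
    return RateSet(k_rm, k_em, k_me, params.k_MR, params.k_ER)


def rate_matrix(rates: RateSet) -> np.ndarray:
    """Generator Q of dp/dt = Q p, state order (R, M, E); columns sum to zero."""
    return np.array([
        [-rates.k_RM, rates.k_MR, rates.k_ER],
        [rates.k_RM, -(rates.k_ME + rates.k_MR), rates.k_EM],
        [0.0, rates.k_ME, -(rates.k_EM + rates.k_ER)],
    ])


def _segment_rates(seg: Segment, params: PhotocycleParams) -> RateSet:
    if seg.field is None:
        return RateSet.dark(params)
    tps = two_photon_spectrum(seg.field)
    rates = photo_rates(tps, params, power_scale=seg.power_scale, grid=seg.field.grid)
    return rates.scaled_photo(seg.coverage_duty * seg.rate_scale)


def simulate_photocycle(protocol: IlluminationProtocol, params: PhotocycleParams,
                        initial: PhotocycleState | None = None, dt: float = 0.05,
                        t_end: float | None = None) -> Trajectory:
    """Evolve the occupancies under a piecewise-constant illumination protocol.

    Exact matrix-exponential stepping: within each constant-rate interval the
    propagator expm(Q * tau) is applied, splitting steps at segment boundaries,
    so the sampled trajectory is exact regardless of ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if initial is None:
        initial = PhotocycleState.rest()
    if t_end is None:
        t_end = protocol.t_end
    n = int(round(t_end / dt)) + 1
    t = np.arange(n) * dt

    # breakpoints and generator per constant-rate interval
    edges = [0.0]
    gens = []
    cursor = 0.0
    dark_q = rate_matrix(RateSet.dark(params))
    for seg in protocol.segments:
        if seg.t_start > cursor + 1e-12:
            gens.append(dark_q)
            edges.append(seg.t_start)
        gens.append(rate_matrix(_segment_rates(seg, params)))
        edges.append(seg.t_end)
        cursor = seg.t_end
    gens.append(dark_q)  # darkness after the last segment
    edges.append(np.inf)

    prop_cache: dict = {}

    def propagate(p, q_idx, tau):
        if tau <= 1e-15:
            return p
        key = (q_idx, round(tau, 12))
        if key not in prop_cache:
            prop_cache[key] = expm(gens[q_idx] * tau)
        return prop_cache[key] @ p

    p = initial.as_array()
    out = np.empty((n, 3))
    out[0] = p
    q_idx = 0
    now = 0.0
    for k in range(1, n):
        target = t[k]
        while True:
            nxt = edges[q_idx + 1]
            if nxt >= target - 1e-12:
                p = propagate(p, q_idx, target - now)
                now = target
                break
            p = propagate(p, q_idx, nxt - now)
            now = nxt
            q_idx += 1
        out[k] = p
    return Trajectory(t, out)


def steady_state(rates: RateSet) -> PhotocycleState:
    """Stationary occupancies: normalized null space of the rate matrix.

    With all rates zero every distribution is stationary and no unique answer
    exists; that degenerate case raises ``ValueError``.
    """
    q = rate_matrix(rates)
    ns = null_space(q, rcond=1e-12)
    if ns.shape[1] != 1:
        raise ValueError("steady state is not unique (all rates zero?)")
    v = ns[:, 0]
    v = np.abs(v)
    v = v / v.sum()
    v = np.clip(v, 0.0, 1.0)
    v = v / v.sum()
    return PhotocycleState.from_array(v)
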