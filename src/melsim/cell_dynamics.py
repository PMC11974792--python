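"""Calcium and fluorescence dynamics downstream of the melanopsin photocycle.

The active-state occupancy p_M(t) drives a single calcium pool:

    dc/dt = k_drive * p_M * a  -  k_clear * c

For *sustained* cells (melanopsin-expressing HEK293T) the adaptation gate a is
identically 1, so a pulse of p_M produces a calcium transient whose rise is set
by the p_M decay and whose fall is set by clearance.  *Adapting* cells (ipRGCs)
close the gate with time constant ``tau_adapt`` while light is on — down to a
small residual floor ``adapt_floor``, so a persistent fraction of the response
survives — producing the brief peak followed by an exponential decay toward a
low plateau seen under sustained illumination; in darkness the gate reopens
with ``tau_recover``.

Fluorescence follows a linear indicator model F = f0 * (1 + gain_g * c); an
optional saturating variant c/(1 + c/Kd) is available behind ``hill_kd``.
Integration uses exponential-Euler steps, which are exact when p_M is piecewise
constant on the step grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CellKinetics", "CalciumTrace", "calcium_response", "fluorescence"]

#: gate threshold: p_M above this counts as "light on" for the adaptation gate
P_M_LIGHT_THRESHOLD = 0.01


@dataclass(frozen=True)
class CellKinetics:
    """Calcium/fluorescence kinetics of one cell.

    ``mode`` is ``"sustained"`` (gate pinned at 1; tau fields ignored) or
    ``"adapting"``.  ``beta_clear`` optionally makes clearance calcium-dependent,
    k_clear * (1 + beta * c); it defaults to 0 (plain linear clearance).
    """

    mode: str = "sustained"
    k_drive: float = 0.6          # 1/s, influx gain per unit p_M
    k_clear: float = 0.04         # 1/s, clearance
    tau_adapt: float = 3.2        # s, gate closing under light (adapting only)
    tau_recover: float = 20.0     # s, gate reopening in darkness
    adapt_floor: float = 0.0      # residual gate under sustained light
    gain_g: float = 1.0           # fluorescence per unit calcium
    f0: float = 1000.0            # baseline fluorescence, camera counts
    hill_kd: float | None = None  # indicator saturation constant; None = linear
    beta_clear: float = 0.0

    def __post_init__(self):
        if self.mode not in ("sustained", "adapting"):
            raise ValueError("mode must be 'sustained' or 'adapting'")
        for name in ("k_drive", "k_clear", "tau_adapt", "tau_recover", "gain_g", "f0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.adapt_floor < 1.0:
            raise ValueError("adapt_floor must lie in [0, 1)")


@dataclass(frozen=True)
class CalciumTrace:
    """Calcium proxy c(t) >= 0 and adaptation gate a(t) in [0, 1]."""

    t: np.ndarray
    c: np.ndarray
    a: np.ndarray


def calcium_response(p_m: np.ndarray, kinetics: CellKinetics, dt: float,
                     t: np.ndarray | None = None) -> CalciumTrace:
    """Integrate the calcium pool driven by a uniformly sampled p_M trajectory.

    Exponential-Euler stepping: within each step the drive k_drive * p_M * a is
    held at its start-of-step value and the linear clearance is integrated
    exactly, so the scheme is exact for piecewise-constant p_M (and beta = 0).
    Initial conditions c(0) = 0, a(0) = 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p_m = np.asarray(p_m, dtype=float)
    n = p_m.size
    if t is None:
        t = np.arange(n) * dt
    c = np.zeros(n)
    a = np.ones(n)
    adapting = kinetics.mode == "adapting"
    decay_adapt = math.exp(-dt / kinetics.tau_adapt) if adapting else 1.0
    decay_recover = math.exp(-dt / kinetics.tau_recover) if adapting else 1.0
    for k in range(1, n):
        gate = a[k - 1]
        drive = kinetics.k_drive * p_m[k - 1] * gate
        kc = kinetics.k_clear * (1.0 + kinetics.beta_clear * c[k - 1])
        decay_c = math.exp(-kc * dt)
        c[k] = c[k - 1] * decay_c + drive * (1.0 - decay_c) / kc
        if adapting:
            if p_m[k - 1] > P_M_LIGHT_THRESHOLD:
                floor = kinetics.adapt_floor
                a[k] = floor + (gate - floor) * decay_adapt
            else:
                a[k] = 1.0 - (1.0 - gate) * decay_recover
    return CalciumTrace(t, c, a)


def fluorescence(trace: CalciumTrace, kinetics: CellKinetics) -> np.ndarray:
    """Expected (noiseless) fluorescence F(t) = f0 * (1 + gain_g * signal(c))."""
    c = trace.c
    if kinetics.hill_kd is not None:
        signal = c / (1.0 + c / kinetics.hill_kd)
    else:
        signal = c
    return kinetics.f0 * (1.0 + kinetics.gain_g * signal)
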