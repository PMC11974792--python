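"""Structured configuration: shipped calibrated defaults and helpers to build
fields, photocycle parameters, and cell kinetics from a parameter file.

The parameter file is YAML; the shipped copy lives in ``melsim/data/`` and is
the output of the calibration routine in :mod:`melsim.calibrate`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import yaml

from .cell_dynamics import CellKinetics
from .photocycle import ActionSpectrum, PhotocycleParams
from .pulse_optics import (FrequencyGrid, PhaseProfile, SpectralBand, SpectralField,
                           apply_band_mask, apply_phase, make_supercontinuum)

__all__ = ["Defaults", "load_defaults", "save_params"]


@dataclass
class Defaults:
    """Typed view over a parameter file, with field/parameter builders."""

    raw: dict

    # -- optics -----------------------------------------------------------
    def grid(self) -> FrequencyGrid:
        g = self.raw["optics"]["grid"]
        return FrequencyGrid.default(g["lambda_min_nm"], g["lambda_max_nm"],
                                     g["n_points"])

    def support(self) -> SpectralBand:
        lo, hi = self.raw["optics"]["support_nm"]
        return SpectralBand(lo, hi)

    def field(self, power_mw: float = 20.0, grid: FrequencyGrid | None = None,
              label: str = "supercontinuum") -> SpectralField:
        o = self.raw["optics"]
        return make_supercontinuum(o["center_nm"], o["fwhm_nm"], self.support(),
                                   power_mw, o["rep_rate_mhz"],
                                   grid or self.grid(), label)

    def tod_field(self, center_nm: float, power_mw: float = 20.0,
                  grid: FrequencyGrid | None = None) -> SpectralField:
        """Full-envelope field with pure TOD centered at ``center_nm``."""
        base = self.field(power_mw, grid, label=f"tod_{center_nm:.0f}")
        profile = PhaseProfile.tod(center_nm, self.raw["optics"]["tod_a3_fs3"])
        return apply_phase(base, profile)

    def band_field(self, band: SpectralBand, power_mw: float = 20.0,
                   edge_width_nm: float = 2.0,
                   grid: FrequencyGrid | None = None) -> SpectralField:
        """Flat-phase field amplitude-masked to ``band``.

        Band requests wider than the supercontinuum support are effectively
        clipped to it, since the envelope is zero outside the support.
        """
        base = self.field(power_mw, grid,
                          label=f"band_{band.lambda_lo_nm:.0f}_{band.lambda_hi_nm:.0f}")
        return apply_band_mask(base, band, edge_width_nm)

    # -- photocycle -------------------------------------------------------
    def photocycle_params(self) -> PhotocycleParams:
        p = self.raw["photocycle"]
        spec = {k: ActionSpectrum(v["peak_nm"], v["fwhm_nm"])
                for k, v in p["action_spectra"].items()}
        return PhotocycleParams(
            sigma_R=spec["R"], sigma_E=spec["E"], sigma_M=spec["M"],
            eta_RM=p["eta_RM"], eta_EM=p["eta_EM"], eta_ME=p["eta_ME"],
            k_MR=p["k_MR"], k_ER=p["k_ER"], p_ref_mw=p["p_ref_mw"])

    # -- cells ------------------------------------------------------------
    def kinetics(self, which: str) -> CellKinetics:
        return CellKinetics(**self.raw["cells"][which])

    @property
    def iprgc_gain_sigma_log(self) -> float:
        return self.raw["cells"]["iprgc_gain_sigma_log"]

    @property
    def imaging(self) -> dict:
        return self.raw["imaging"]


def load_defaults(path: str | Path | None = None) -> Defaults:
    """Load a parameter file; with no path, the shipped calibrated defaults."""
    if path is None:
        ref = importlib.resources.files("melsim") / "data" / "default_params.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    return Defaults(yaml.safe_load(text))


def save_params(raw: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(raw, sort_keys=False))
    return path
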