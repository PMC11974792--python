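"""Calibration of the shipped default parameters.

The recordings being emulated report cell-level kinetics (rise/decay times and
peak amplitudes), never molecular rates, so the free model rates are fixed by a
two-stage routine against a shipped target-kinetics table:

* HEK reference condition (1 s spiral scan at 20 mW): biexponential decay time
  25 s, rise time 4 s, peak dF/F0 ~ 1.0 (amplitude-scale aid).
* Adapting-cell (ipRGC) raster condition at 50 mW: mean peak dF/F0 5.4 %,
  mean monoexponential decay time 3.2 s.

Stage A runs deterministic coordinate descent on a *noiseless fast path*
(photocycle -> calcium -> frame-sampled dF/F0, no rendering), after fixing the
shared photo-rate gain eta so the reference condition drives the active-state
occupancy to 0.6 at the end of the 1 s scan.  Stage B runs the full noisy
render-and-analyze pipeline and applies a few multiplicative correction passes,
absorbing the small biases the fast path cannot see (noise-driven peak bias,
fit-shape effects of sampling and epoch averaging).  The result is written as
the parameter file that every experiment runner loads.
"""

from __future__ import annotations

import copy
import math
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .cell_dynamics import calcium_response
from .config import Defaults, save_params
from .photocycle import IlluminationProtocol, Segment, simulate_photocycle
from .trace_analysis import Epoch, fit_biexponential, fit_monoexp_plateau

__all__ = ["CALIBRATION_TARGETS", "fast_reference_kinetics", "fast_iprgc_kinetics",
           "calibrate_defaults"]

#: shipped target-kinetics table (cell-level observables the defaults must hit)
CALIBRATION_TARGETS = {
    "hek_rise_s": 4.0,
    "hek_decay_s": 25.0,
    "hek_peak_dff": 1.0,
    "iprgc_peak_pct": 5.4,
    "iprgc_decay_s": 3.2,
}


def _frame_sample(t_fine, y_fine, frame_rate, t_end):
    t_frames = np.arange(0.0, t_end, 1.0 / frame_rate)
    return t_frames, np.interp(t_frames, t_fine, y_fine)


def fast_reference_kinetics(defaults: Defaults, duration_s: float = 1.0,
                            power_mw: float = 20.0, t_end: float = 50.0) -> dict:
    """Noiseless single-epoch kinetics at the HEK reference condition."""
    fld = defaults.field(power_mw=power_mw)
    params = defaults.photocycle_params()
    kin = defaults.kinetics("hek")
    protocol = IlluminationProtocol((Segment(0.0, duration_s, fld),))
    traj = simulate_photocycle(protocol, params, dt=0.05, t_end=t_end)
    ca = calcium_response(traj.p_M, kin, 0.05, t=traj.t)
    dff = kin.gain_g * ca.c
    t_f, y_f = _frame_sample(traj.t, dff, defaults.imaging["frame_rate"], t_end)
    fit = fit_biexponential(Epoch(t_f, y_f))
    return {"rise_s": fit.rise_time, "decay_s": fit.decay_time,
            "peak_dff": float(np.max(y_f)), "p_M_end_of_scan":
            float(np.interp(duration_s, traj.t, traj.p_M))}


def fast_iprgc_kinetics(defaults: Defaults, power_mw: float = 50.0,
                        t_end: float = 50.0, gain_mult: float | None = None) -> dict:
    """Noiseless adapting-cell kinetics under sustained raster illumination.

    ``gain_mult`` defaults to the mean of the lognormal cell-to-cell
    variability, exp(sigma_log^2 / 2), so the fast path tracks the population
    mean rather than the median cell.
    """
    fld = defaults.field(power_mw=power_mw)
    params = defaults.photocycle_params()
    kin = defaults.kinetics("iprgc")
    if gain_mult is None:
        gain_mult = math.exp(defaults.iprgc_gain_sigma_log ** 2 / 2.0)
    kin = replace(kin, k_drive=kin.k_drive * gain_mult)
    duty = defaults.imaging["raster_duty"]
    protocol = IlluminationProtocol((Segment(0.0, t_end, fld, coverage_duty=duty),))
    traj = simulate_photocycle(protocol, params, dt=0.05, t_end=t_end)
    ca = calcium_response(traj.p_M, kin, 0.05, t=traj.t)
    dff = kin.gain_g * ca.c
    t_f, y_f = _frame_sample(traj.t, dff, defaults.imaging["frame_rate"], t_end)
    fit = fit_monoexp_plateau(Epoch(t_f, y_f))
    return {"peak_pct": float(np.max(y_f) * 100.0), "decay_s": fit.decay_time,
            "plateau_a": fit.a}


def _fix_eta(raw: dict, target_p_m: float = 0.5) -> None:
    """Set the shared photo-rate gain so p_M(end of 1 s scan at 20 mW) = target.

    p_M at the end of the scan rises with the gain toward a branching-limited
    photoequilibrium just above 0.5 (M->E conversion caps it), so the target is
    sought on the rising branch; if it is out of reach the gain maximizing the
    end-of-scan occupancy is used instead.
    """

    def p_m_end(log_eta):
        work = copy.deepcopy(raw)
        for key in ("eta_RM", "eta_EM", "eta_ME"):
            work["photocycle"][key] = float(np.exp(log_eta))
        return fast_reference_kinetics(Defaults(work))["p_M_end_of_scan"] - target_p_m

    try:
        log_eta = optimize.brentq(p_m_end, math.log(0.05), math.log(5.0), xtol=1e-4)
    except ValueError:
        grid = np.linspace(math.log(0.05), math.log(20.0), 25)
        log_eta = grid[int(np.argmax([p_m_end(g) for g in grid]))]
    for key in ("eta_RM", "eta_EM", "eta_ME"):
        raw["photocycle"][key] = float(np.exp(log_eta))


def _descend(raw: dict, targets: dict, passes: int = 3) -> None:
    """Coordinate descent on the noiseless fast path."""

    def hek(work):
        return fast_reference_kinetics(Defaults(work))

    def iprgc(work):
        return fast_iprgc_kinetics(Defaults(work))

    def tune(path, bounds, objective):
        sect, key = path

        def loss(value):
            work = copy.deepcopy(raw)
            work[sect][key] = float(value)
            return objective(work)

        res = optimize.minimize_scalar(loss, bounds=bounds, method="bounded",
                                       options={"xatol": 1e-4})
        raw[sect][key] = float(res.x)

    for _ in range(passes):
        tune(("photocycle", "k_MR"), (0.05, 1.0),
             lambda w: (hek(w)["rise_s"] - targets["hek_rise_s"]) ** 2)

        # clearance of the sustained cells sets the slow decay
        def kc_loss(value):
            work = copy.deepcopy(raw)
            work["cells"]["hek"]["k_clear"] = float(value)
            return (hek(work)["decay_s"] - targets["hek_decay_s"]) ** 2

        res = optimize.minimize_scalar(kc_loss, bounds=(0.01, 0.2),
                                       method="bounded", options={"xatol": 1e-5})
        raw["cells"]["hek"]["k_clear"] = float(res.x)
        # dF/F0 is linear in the drive: exact one-step update
        peak = hek(raw)["peak_dff"]
        raw["cells"]["hek"]["k_drive"] *= targets["hek_peak_dff"] / peak

        def tau_loss(value):
            work = copy.deepcopy(raw)
            work["cells"]["iprgc"]["tau_adapt"] = float(value)
            return (iprgc(work)["decay_s"] - targets["iprgc_decay_s"]) ** 2

        res = optimize.minimize_scalar(tau_loss, bounds=(0.5, 10.0),
                                       method="bounded", options={"xatol": 1e-4})
        raw["cells"]["iprgc"]["tau_adapt"] = float(res.x)
        peak_pct = iprgc(raw)["peak_pct"]
        raw["cells"]["iprgc"]["k_drive"] = (raw["cells"]["iprgc"]["k_drive"]
                                            * targets["iprgc_peak_pct"] / peak_pct)


def _pipeline_correct(raw: dict, targets: dict, seed: int, passes: int = 2,
                      n_epochs: int = 13) -> pd.DataFrame:
    """Multiplicative correction against the full noisy pipeline."""
    from .experiments import ExperimentConfig, run_condition, run_iprgc
    import tempfile

    report = []
    for i in range(passes):
        with tempfile.TemporaryDirectory() as tmp:
            path = save_params(raw, Path(tmp) / "params.yaml")
            cond = run_condition(1.0, 20.0, seed, n_epochs, Defaults(copy.deepcopy(raw)))
            # the ipRGC summary fluctuates with the 34 per-cell gain draws;
            # average over a few seeds so one draw does not bias the correction
            iprs = [run_iprgc(ExperimentConfig(seed=seed + 101 * j,
                                               params_path=str(path),
                                               n_epochs=n_epochs))
                    for j in range(3)]
        row = {"pass": i, "rise_s": cond.fit.rise_time,
               "decay_s": cond.fit.decay_time,
               "peak_dff": cond.per_cell_peaks[0],
               "iprgc_peak_pct": float(np.mean([r.mean_peak_pct for r in iprs])),
               "iprgc_decay_s": float(np.mean([r.mean_decay_s for r in iprs]))}
        report.append(row)
        raw["photocycle"]["k_MR"] *= row["rise_s"] / targets["hek_rise_s"]
        raw["cells"]["hek"]["k_clear"] *= row["decay_s"] / targets["hek_decay_s"]
        raw["cells"]["hek"]["k_drive"] *= targets["hek_peak_dff"] / row["peak_dff"]
        raw["cells"]["iprgc"]["tau_adapt"] *= (targets["iprgc_decay_s"]
                                               / row["iprgc_decay_s"])
        raw["cells"]["iprgc"]["k_drive"] *= (targets["iprgc_peak_pct"]
                                             / row["iprgc_peak_pct"])
    return pd.DataFrame(report)


def calibrate_defaults(base: Defaults, out_path: str | Path, seed: int = 0,
                       targets: dict | None = None, descent_passes: int = 3,
                       pipeline_passes: int = 2,
                       n_epochs: int = 13) -> tuple:
    """Full calibration: returns (calibrated raw dict, report DataFrame).

    Deterministic given ``seed``.  If the starting parameters already satisfy
    the targets, the corrections are no-ops within the optimizer tolerance.
    """
    targets = targets or CALIBRATION_TARGETS
    raw = copy.deepcopy(base.raw)
    _fix_eta(raw)
    _descend(raw, targets, passes=descent_passes)
    report = pd.DataFrame()
    if pipeline_passes > 0:
        report = _pipeline_correct(raw, targets, seed, passes=pipeline_passes,
                                   n_epochs=n_epochs)
    save_params(raw, out_path)
    return raw, report
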