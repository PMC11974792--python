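"""Config-driven replications of the five stimulation paradigms.

Each runner builds a synthetic recording with :mod:`melsim.synthetic_imaging`,
pushes it through the quantification pipeline in :mod:`melsim.trace_analysis`,
and returns a summary table:

* ``run_duration_sweep`` — targeted spiral stimulation of one HEK-mode cell at
  fixed power, scan duration varied (20-1000 ms); epoch-averaged biexponential
  kinetics per duration.
* ``run_power_sweep`` — same paradigm, scan duration fixed at 1 s, average
  power varied (5-30 mW).
* ``run_band_comparison`` — raster illumination with the full supercontinuum
  versus knife-edge bands 900-1000 nm (activating) and 1100-1200 nm
  (deactivating, started from the photo-activated state).
* ``run_tod_sweep`` — identical spectral envelope, pure third-order dispersion
  centered at 980 / 1030 / 1140 nm; sustained response per phase profile.
* ``run_phase_switch`` — 30 s of one TOD profile then the other; post-switch
  transient per order.
* ``run_iprgc`` — a field of adapting-mode cells under sustained raster
  illumination at 50 mW; per-cell peak dF/F0, peak-normalized monoexponential
  decay, and an active-versus-inactive tail comparison.

All runners are deterministic given (config, seed); per-condition seeds are
derived from the base seed and the condition parameters, so a shared condition
(e.g. 1 s at 20 mW) yields the identical recording in either sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Defaults, load_defaults
from .photocycle import steady_state, photo_rates, two_photon_spectrum
from .pulse_optics import SpectralBand
from .synthetic_imaging import (AcquisitionConfig, CellSpec, Scene, StimEvent,
                                StimulusPlan, simulate_movie)
from .trace_analysis import (Epoch, ROISpec, average_epochs, compute_dff,
                             default_baseline_window, extract_trace,
                             fit_biexponential, fit_monoexp_plateau,
                             peak_amplitude, segment_epochs, tail_mean,
                             ttest_two_tailed)

__all__ = [
    "ExperimentConfig", "ConditionResult", "IprgcResult", "SwitchResult",
    "run_duration_sweep", "run_power_sweep", "run_condition",
    "run_band_comparison", "run_tod_sweep", "run_phase_switch", "run_iprgc",
]

DURATION_GRID_S = (0.02, 0.05, 0.1, 0.5, 1.0)
POWER_GRID_MW = (5.0, 10.0, 20.0, 30.0)
REFERENCE_DURATION_S = 1.0
REFERENCE_POWER_MW = 20.0
IPRGC_POWER_MW = 50.0
EPOCH_PRE_S = 5.0
EPOCH_POST_S = 50.0
INTER_STIM_INTERVAL_S = 60.0


@dataclass
class ExperimentConfig:
    """Shared knobs for the paradigm runners."""

    paradigm: str = "duration_sweep"
    seed: int = 0
    n_epochs: int = 13
    durations_s: tuple = DURATION_GRID_S
    powers_mw: tuple = POWER_GRID_MW
    n_active: int = 34
    n_inactive: int = 6
    out_dir: str | None = None
    params_path: str | None = None

    def defaults(self) -> Defaults:
        return load_defaults(self.params_path)


def _condition_seed(seed: int, duration_s: float, power_mw: float) -> int:
    return (seed * 1000003 + int(round(duration_s * 1e4)) * 1009
            + int(round(power_mw * 10)) * 7) % (2 ** 31)


def _hek_scene(defaults: Defaults) -> Scene:
    """3 OPN4+ cells and 1 OPN4- cell on a 128x128 frame (spiral paradigms)."""
    img = defaults.imaging
    kin = defaults.kinetics("hek")
    centers = [(32.0, 32.0), (32.0, 96.0), (96.0, 32.0), (96.0, 96.0)]
    cells = [CellSpec(center=c, radius=6.0, opn4_positive=(i < 3), kinetics=kin,
                      gfp_brightness=img["gfp_brightness"],
                      calbryte_baseline=img["hek_calbryte_baseline"])
             for i, c in enumerate(centers)]
    return Scene(tuple(cells), background=img["background"])


def _acq(defaults: Defaults, n_frames: int, shape=(128, 128), seed: int = 0,
         noise: bool = True) -> AcquisitionConfig:
    img = defaults.imaging
    return AcquisitionConfig(shape=shape, frame_rate=img["frame_rate"],
                             n_frames=n_frames, photon_gain=img["photon_gain"],
                             read_noise_sigma=img["read_noise_sigma"], seed=seed,
                             noise_enabled=noise)


@dataclass
class ConditionResult:
    """One spiral-stimulation condition, fully analyzed."""

    duration_s: float
    power_mw: float
    n_epochs: int
    fit: object                 # BiexpFit of the epoch-averaged transient
    avg_epoch: Epoch
    per_cell_peaks: dict        # cell id -> peak of its epoch-averaged dF/F0
    blank_noise_sd: float       # s.d. of a blank-ROI raw dF/F0 trace
    targeted_cell: int = 0

    def row(self) -> dict:
        return {"duration_s": self.duration_s, "power_mw": self.power_mw,
                "n_epochs": self.n_epochs,
                "peak_dff": peak_amplitude(self.avg_epoch),
                "rise_s": self.fit.rise_time, "decay_s": self.fit.decay_time,
                "rmse": self.fit.rmse}


def run_condition(duration_s: float, power_mw: float, seed: int,
                  n_epochs: int = 13, defaults: Defaults | None = None,
                  noise: bool = True) -> ConditionResult:
    """Targeted spiral stimulation of one HEK-mode cell; epoch-averaged kinetics.

    ``n_epochs`` stimulation events are delivered to cell 0 at a 60 s
    inter-stimulus interval; the epoch-averaged dF/F0 transient is fitted with
    the biexponential.  ``duration_s = 0`` is the no-stimulation control (one
    sham event time is still used for epoch alignment).
    """
    defaults = defaults or load_defaults()
    img = defaults.imaging
    fr = img["frame_rate"]
    t0 = 15.0
    total = t0 + (n_epochs - 1) * INTER_STIM_INTERVAL_S + EPOCH_POST_S + 5.0
    n_frames = int(np.ceil(total * fr))
    scene = _hek_scene(defaults)
    acq = _acq(defaults, n_frames, seed=_condition_seed(seed, duration_s, power_mw),
               noise=noise)
    event_times = [t0 + k * INTER_STIM_INTERVAL_S for k in range(n_epochs)]
    fields = {"full": defaults.field(power_mw=power_mw)}
    events = [StimEvent(t_on=te, duration=duration_s, power_mw=power_mw,
                        field_label="full", target=0)
              for te in event_times] if duration_s > 0 else []
    plan = StimulusPlan("targeted_spiral", tuple(events), fields)
    stack = simulate_movie(scene, acq, plan, defaults.photocycle_params())

    per_cell_peaks = {}
    avg0 = None
    for idx, cell in enumerate(scene.cells):
        t, raw = extract_trace(stack, ROISpec(cell.center))
        dff = compute_dff(raw, t, default_baseline_window(t, event_times[0]))
        epochs = segment_epochs(dff, event_times, EPOCH_PRE_S, EPOCH_POST_S)
        avg = average_epochs(epochs)
        per_cell_peaks[idx] = peak_amplitude(avg)
        if idx == 0:
            avg0 = avg
    t, blank = extract_trace(stack, ROISpec((64.0, 64.0)))
    blank_dff = compute_dff(blank, t, default_baseline_window(t, event_times[0]))
    fit = fit_biexponential(avg0)
    return ConditionResult(duration_s, power_mw, n_epochs, fit, avg0,
                           per_cell_peaks, float(np.std(blank_dff.dff)))


def run_duration_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Peak/rise/decay versus spiral scan duration at the reference power."""
    defaults = config.defaults()
    rows = [run_condition(d, REFERENCE_POWER_MW, config.seed, config.n_epochs,
                          defaults).row()
            for d in config.durations_s]
    return _maybe_write(pd.DataFrame(rows), config, "duration_sweep.csv")


def run_power_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Peak/rise/decay versus average power at the reference 1 s scan duration."""
    defaults = config.defaults()
    rows = [run_condition(REFERENCE_DURATION_S, p, config.seed, config.n_epochs,
                          defaults).row()
            for p in config.powers_mw]
    return _maybe_write(pd.DataFrame(rows), config, "power_sweep.csv")


# ---------------------------------------------------------------------------
# raster paradigms

def _raster_scene(defaults: Defaults, kin=None, n_pos: int = 3,
                  n_neg: int = 3) -> Scene:
    img = defaults.imaging
    kin = kin or defaults.kinetics("hek")
    centers = [(24.0 + 40.0 * (i // 3), 24.0 + 40.0 * (i % 3))
               for i in range(n_pos + n_neg)]
    cells = [CellSpec(center=c, radius=6.0, opn4_positive=(i < n_pos), kinetics=kin,
                      gfp_brightness=img["gfp_brightness"],
                      calbryte_baseline=img["hek_calbryte_baseline"])
             for i, c in enumerate(centers)]
    return Scene(tuple(cells), background=img["background"])


def _raster_run(defaults: Defaults, fld, seed: int, t_on: float = 10.0,
                t_off: float = 60.0, initial_states=None, power_mw=None,
                scene: Scene | None = None, shape=(128, 128)):
    """One raster recording: darkness until ``t_on``, then uniform illumination."""
    fr = defaults.imaging["frame_rate"]
    n_frames = int(np.ceil((t_off + 0.5) * fr))
    scene = scene or _raster_scene(defaults)
    acq = _acq(defaults, n_frames, shape=shape, seed=seed % (2 ** 31))
    power = fld.power_mw() if power_mw is None else power_mw
    plan = StimulusPlan("global_raster",
                        (StimEvent(t_on, t_off - t_on, power, "beam", None),),
                        {"beam": fld},
                        raster_duty=defaults.imaging["raster_duty"])
    stack = simulate_movie(scene, acq, plan, defaults.photocycle_params(),
                           initial_states=initial_states)
    return stack, scene, t_on


def _sustained_dff(stack, scene, t_on: float, settle_s: float = 5.0) -> dict:
    """Mean dF/F0 during illumination (after a settle window), per cell."""
    out = {}
    for idx, cell in enumerate(scene.cells):
        t, raw = extract_trace(stack, ROISpec(cell.center))
        dff = compute_dff(raw, t, default_baseline_window(t, t_on))
        out[idx] = float(np.mean(dff.dff[t >= t_on + settle_s]))
    return out


def run_band_comparison(config: ExperimentConfig) -> pd.DataFrame:
    """Sustained response under full-band vs activating vs deactivating bands.

    The 1100-1200 nm (deactivating) recording starts from the photoequilibrium
    reached under full-band raster illumination, matching a paradigm where
    deactivation is probed on already-activated cells.
    """
    defaults = config.defaults()
    bands = {"full_900_1200": SpectralBand(900.0, 1200.0),
             "act_900_1000": SpectralBand(900.0, 1000.0),
             "deact_1100_1200": SpectralBand(1100.0, 1200.0)}
    params = defaults.photocycle_params()
    duty = defaults.imaging["raster_duty"]

    # photoequilibrium under full-band raster drive, for the deactivation run
    full_field = defaults.band_field(bands["full_900_1200"], REFERENCE_POWER_MW)
    full_rates = photo_rates(two_photon_spectrum(full_field), params,
                             grid=full_field.grid).scaled_photo(duty)
    activated = steady_state(full_rates)

    rows = []
    for i, (name, band) in enumerate(bands.items()):
        fld = defaults.band_field(band, REFERENCE_POWER_MW)
        init = None
        if name == "deact_1100_1200":
            init = {idx: activated for idx in range(3)}
        stack, scene, t_on = _raster_run(defaults, fld, config.seed * 17 + i,
                                         initial_states=init)
        sus = _sustained_dff(stack, scene, t_on)
        opn4_pos = [sus[i] for i in range(3)]
        opn4_neg = [sus[i] for i in range(3, 6)]
        rows.append({"band": name, "power_in_band_mw": fld.power_mw(),
                     "sustained_dff": float(np.mean(opn4_pos)),
                     "sustained_dff_opn4neg": float(np.mean(opn4_neg))})
    return _maybe_write(pd.DataFrame(rows), config, "band_comparison.csv")


def run_tod_sweep(config: ExperimentConfig,
                  centers_nm=(980.0, 1030.0, 1140.0)) -> pd.DataFrame:
    """Sustained response for pure TOD centered at each wavelength.

    All three fields share the identical spectral envelope; only the phase
    differs (a3 fixed at the shipped value).
    """
    defaults = config.defaults()
    rows = []
    for i, center in enumerate(centers_nm):
        fld = defaults.tod_field(center, REFERENCE_POWER_MW)
        stack, scene, t_on = _raster_run(defaults, fld, config.seed * 29 + i)
        sus = _sustained_dff(stack, scene, t_on)
        rows.append({"tod_center_nm": center, "power_mw": fld.power_mw(),
                     "sustained_dff": float(np.mean([sus[i] for i in range(3)])),
                     "sustained_dff_opn4neg": float(np.mean([sus[i] for i in range(3, 6)]))})
    return _maybe_write(pd.DataFrame(rows), config, "tod_sweep.csv")


@dataclass
class SwitchResult:
    order: str
    trace_t: np.ndarray
    trace_dff: np.ndarray
    switch_s: float
    post_switch_peak: float     # max dF/F0 after the switch minus level at switch


def run_phase_switch(config: ExperimentConfig, switch_s: float = 30.0) -> list:
    """Dynamic photoswitching: one TOD profile for 30 s, then the other.

    Returns results for both orders (activation-first 980->1140 nm and
    deactivation-first 1140->980 nm).  The post-switch transient is the maximum
    dF/F0 after the switch relative to the level at the switch time.
    """
    defaults = config.defaults()
    fr = defaults.imaging["frame_rate"]
    t_on = 10.0
    t_end = t_on + 2 * switch_s + 5.0
    results = []
    for j, (first, second) in enumerate(((980.0, 1140.0), (1140.0, 980.0))):
        fld_a = defaults.tod_field(first, REFERENCE_POWER_MW)
        fld_b = defaults.tod_field(second, REFERENCE_POWER_MW)
        n_frames = int(np.ceil((t_end + 0.5) * fr))
        scene = _raster_scene(defaults)
        acq = _acq(defaults, n_frames, seed=(config.seed * 41 + j) % (2 ** 31))
        t_sw = t_on + switch_s
        plan = StimulusPlan("global_raster", (
            StimEvent(t_on, switch_s, fld_a.power_mw(), "a", None),
            StimEvent(t_sw, switch_s, fld_b.power_mw(), "b", None),
        ), {"a": fld_a, "b": fld_b}, raster_duty=defaults.imaging["raster_duty"])
        stack = simulate_movie(scene, acq, plan, defaults.photocycle_params())
        t, raw = extract_trace(stack, ROISpec(scene.cells[0].center))
        dff = compute_dff(raw, t, default_baseline_window(t, t_on))
        at_switch = float(dff.dff[np.searchsorted(t, t_sw)])
        post = float(np.max(dff.dff[t > t_sw]) - at_switch)
        results.append(SwitchResult(f"{first:.0f}_then_{second:.0f}", t, dff.dff,
                                    t_sw, post))
    if config.out_dir:
        pd.DataFrame([{"order": r.order, "post_switch_peak": r.post_switch_peak}
                      for r in results]).to_csv(
            Path(config.out_dir) / "phase_switch.csv", index=False)
    return results


@dataclass
class IprgcResult:
    summary: pd.DataFrame       # per-cell peak, decay, tail statistics
    mean_peak_pct: float        # mean over active cells of peak dF/F0, percent
    mean_decay_s: float         # mean monoexponential decay time, seconds
    t_stat: float
    p_value: float


def run_iprgc(config: ExperimentConfig) -> IprgcResult:
    """Adapting-mode cells under sustained raster illumination at 50 mW.

    Active (OPN4+) cells carry lognormal cell-to-cell variability on the
    calcium drive; inactive cells get no photocycle.  Per cell: peak dF/F0,
    peak-normalized monoexponential decay time, and the mean of the last ten
    frames; groups are compared with the pooled Student's t-test.
    """
    defaults = config.defaults()
    img = defaults.imaging
    kin = defaults.kinetics("iprgc")
    rng = np.random.default_rng((config.seed * 7919 + 13) % (2 ** 31))
    n_total = config.n_active + config.n_inactive
    cols = int(np.ceil(np.sqrt(n_total)))
    pitch = 36.0
    cells = []
    for i in range(n_total):
        r, c = divmod(i, cols)
        center = (20.0 + pitch * r, 20.0 + pitch * c)
        active = i < config.n_active
        mult = float(np.exp(rng.normal(0.0, defaults.iprgc_gain_sigma_log)))
        k = replace(kin, k_drive=kin.k_drive * mult) if active else kin
        cells.append(CellSpec(center=center, radius=6.0, opn4_positive=active,
                              kinetics=k, gfp_brightness=img["gfp_brightness"],
                              calbryte_baseline=img["iprgc_calbryte_baseline"]))
    scene = Scene(tuple(cells), background=img["background"])

    fld = defaults.field(power_mw=IPRGC_POWER_MW)
    stack, scene, t_on = _raster_run(defaults, fld, config.seed * 53 + 5,
                                     scene=scene, power_mw=IPRGC_POWER_MW,
                                     shape=(256, 256))
    rows = []
    for idx, cell in enumerate(scene.cells):
        t, raw = extract_trace(stack, ROISpec(cell.center))
        dff = compute_dff(raw, t, default_baseline_window(t, t_on))
        fit = fit_monoexp_plateau(dff)
        rows.append({"cell": idx, "active": cell.opn4_positive,
                     "peak_dff": peak_amplitude(dff),
                     "decay_s": fit.decay_time, "plateau_a": fit.a,
                     "tail_mean": tail_mean(dff), "degenerate": fit.degenerate})
    df = pd.DataFrame(rows)
    act = df[df.active]
    inact = df[~df.active]
    t_stat, p = ttest_two_tailed(act.tail_mean, inact.tail_mean)
    res = IprgcResult(df, float(act.peak_dff.mean() * 100.0),
                      float(act.decay_s.mean()), t_stat, p)
    _maybe_write(df, config, "iprgc.csv")
    return res


def _maybe_write(df: pd.DataFrame, config: ExperimentConfig, name: str) -> pd.DataFrame:
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / name, index=False)
    return df
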