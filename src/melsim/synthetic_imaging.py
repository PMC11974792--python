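"""Synthetic two-channel calcium-imaging movies with ground truth.

Renders the kind of recording the rest of the package analyzes: a static GFP
channel marking the OPN4-positive cells and a dynamic Calbryte-590 channel whose
per-cell brightness follows the modeled fluorescence F(t).  Cells are drawn as
cosine-tapered disks blended over a uniform background; shot noise is Poisson at
a configurable counts-per-photon gain, followed by Gaussian read noise, and
frames are clipped to the camera bit depth.  Every stack carries a ground-truth
sidecar (noiseless F(t), photocycle occupancies, calcium, and the stimulus event
table) so analysis results can be checked against what was actually simulated.

Stimulation paradigms:

* ``targeted_spiral`` — events dwell on a single target cell (coverage duty 1);
  only that cell's photocycle sees light.
* ``global_raster`` — the imaging beam itself stimulates; every OPN4+ cell is
  illuminated at a small coverage duty (beam dwell fraction per frame).

I/O: multi-page 16-bit TIFF with channels interleaved per frame (GFP page then
Calbryte page), plus a JSON metadata sidecar and a ground-truth CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cell_dynamics import CellKinetics, calcium_response, fluorescence
from .photocycle import (IlluminationProtocol, PhotocycleParams, PhotocycleState,
                         Segment, simulate_photocycle)
from .pulse_optics import SpectralField

__all__ = [
    "CellSpec", "Scene", "AcquisitionConfig", "StimEvent", "StimulusPlan",
    "GroundTruth", "MovieStack", "simulate_movie", "write_movie", "read_movie",
]

#: default beam dwell fraction for raster illumination (cell area / field area)
DEFAULT_RASTER_DUTY = 0.02


@dataclass(frozen=True)
class CellSpec:
    """One rendered cell: geometry, channels, and response kinetics."""

    center: tuple  # (row, col), pixels
    radius: float = 6.0
    opn4_positive: bool = True
    kinetics: CellKinetics = field(default_factory=CellKinetics)
    gfp_brightness: float = 800.0
    calbryte_baseline: float = 1000.0
    expression_scale: float = 1.0

    def __post_init__(self):
        if self.radius < 2.0:
            raise ValueError("cell radius must be at least 2 px")


@dataclass(frozen=True)
class Scene:
    cells: tuple
    background: float = 100.0

    def __post_init__(self):
        object.__setattr__(self, "cells", tuple(self.cells))


@dataclass(frozen=True)
class AcquisitionConfig:
    shape: tuple = (256, 256)
    frame_rate: float = 1.63
    n_frames: int = 100
    bit_depth: int = 16
    photon_gain: float = 1.0      # camera counts per detected photon
    read_noise_sigma: float = 10.0
    seed: int = 0
    noise_enabled: bool = True

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class StimEvent:
    """One stimulation event; ``target=None`` means all OPN4+ cells (raster)."""

    t_on: float
    duration: float
    power_mw: float
    field_label: str
    target: int | None = None

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("event duration must be positive")


@dataclass(frozen=True)
class StimulusPlan:
    paradigm: str  # "targeted_spiral" | "global_raster"
    events: tuple = ()
    fields: dict = field(default_factory=dict)  # label -> SpectralField
    raster_duty: float = DEFAULT_RASTER_DUTY

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        if self.paradigm not in ("targeted_spiral", "global_raster"):
            raise ValueError("paradigm must be 'targeted_spiral' or 'global_raster'")


@dataclass
class GroundTruth:
    """Per-cell noiseless traces aligned to frame times, plus the event table."""

    t: np.ndarray
    per_cell: dict  # cell index -> {"F","p_M","p_E","c"} arrays
    events: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, d in self.per_cell.items():
            rows.append(pd.DataFrame({
                "cell": cid, "frame": np.arange(self.t.size), "t": self.t,
                "F": d["F"], "p_M": d["p_M"], "p_E": d["p_E"], "c": d["c"],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class MovieStack:
    gfp: np.ndarray       # (T, H, W) uint16
    calbryte: np.ndarray  # (T, H, W) uint16
    acq: AcquisitionConfig
    ground_truth: GroundTruth | None = None

    @property
    def n_frames(self) -> int:
        return self.gfp.shape[0]


def _disk_profile(shape, center, radius, taper=1.5):
    """Cosine-tapered disk weight map and its bounding-box slices."""
    taper = min(taper, radius / 2.0)
    r0 = int(max(0, np.floor(center[0] - radius - 1)))
    r1 = int(min(shape[0], np.ceil(center[0] + radius + 2)))
    c0 = int(max(0, np.floor(center[1] - radius - 1)))
    c1 = int(min(shape[1], np.ceil(center[1] + radius + 2)))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = np.hypot(rr - center[0], cc - center[1])
    w = np.zeros(dist.shape)
    w[dist <= radius - taper] = 1.0
    edge = (dist > radius - taper) & (dist < radius)
    w[edge] = 0.5 * (1.0 + np.cos(np.pi * (dist[edge] - (radius - taper)) / taper))
    return w, (slice(r0, r1), slice(c0, c1))


def _cell_protocol(cell_idx: int, cell: CellSpec, plan: StimulusPlan,
                   acq: AcquisitionConfig) -> IlluminationProtocol:
    """Build the illumination protocol one cell experiences under the plan."""
    segs = []
    for ev in plan.events:
        hits = (ev.target == cell_idx) or (ev.target is None and cell.opn4_positive)
        if not hits or not cell.opn4_positive:
            continue
        fld = plan.fields[ev.field_label]
        duty = 1.0 if plan.paradigm == "targeted_spiral" else plan.raster_duty
        base_power = fld.power_mw()
        scale = 1.0 if base_power == 0 else ev.power_mw / base_power
        segs.append(Segment(ev.t_on, ev.t_on + ev.duration, fld,
                            coverage_duty=duty, power_scale=scale,
                            rate_scale=cell.expression_scale))
    segs.sort(key=lambda s: s.t_start)
    return IlluminationProtocol(tuple(segs))


def simulate_movie(scene: Scene, acq: AcquisitionConfig, plan: StimulusPlan,
                   params: PhotocycleParams,
                   initial_states: dict | None = None,
                   dt: float = 0.05) -> MovieStack:
    """Simulate the full loop: photocycle -> calcium -> fluorescence -> frames.

    ``initial_states`` optionally maps cell index to a :class:`PhotocycleState`
    (default: dark-adapted rest).  Deterministic for a fixed ``acq.seed``.
    """
    n_cells = len(scene.cells)
    for cell in scene.cells:
        if (cell.center[0] - cell.radius < 0 or cell.center[1] - cell.radius < 0
                or cell.center[0] + cell.radius > acq.shape[0] - 1
                or cell.center[1] + cell.radius > acq.shape[1] - 1):
            raise ValueError(f"cell at {cell.center} extends outside the frame")
    for ev in plan.events:
        if ev.target is not None and not 0 <= ev.target < n_cells:
            raise ValueError(f"unknown target cell id {ev.target}")
        if ev.t_on < 0 or ev.t_on + ev.duration > acq.duration + 1e-9:
            raise ValueError("stimulation event extends beyond the recording")
        if ev.field_label not in plan.fields:
            raise ValueError(f"unknown field label {ev.field_label!r}")

    t_frames = acq.frame_times
    per_cell = {}
    for idx, cell in enumerate(scene.cells):
        protocol = _cell_protocol(idx, cell, plan, acq)
        if protocol.segments:
            init = (initial_states or {}).get(idx)
            traj = simulate_photocycle(protocol, params, initial=init, dt=dt,
                                       t_end=acq.duration)
            kin = CellKinetics(**{**asdict(cell.kinetics), "f0": cell.calbryte_baseline})
            ca = calcium_response(traj.p_M, kin, dt, t=traj.t)
            f_full = fluorescence(ca, kin)
            per_cell[idx] = {
                "F": np.interp(t_frames, traj.t, f_full),
                "p_M": np.interp(t_frames, traj.t, traj.p_M),
                "p_E": np.interp(t_frames, traj.t, traj.p_E),
                "c": np.interp(t_frames, traj.t, ca.c),
            }
        else:
            flat = np.zeros(acq.n_frames)
            per_cell[idx] = {
                "F": np.full(acq.n_frames, cell.calbryte_baseline),
                "p_M": flat, "p_E": flat.copy(), "c": flat.copy(),
            }

    h, w = acq.shape
    gfp = np.full((acq.n_frames, h, w), scene.background, dtype=np.float64)
    cal = np.full((acq.n_frames, h, w), scene.background, dtype=np.float64)
    for idx, cell in enumerate(scene.cells):
        prof, box = _disk_profile(acq.shape, cell.center, cell.radius)
        if cell.opn4_positive:
            gfp[(slice(None),) + box] += prof * (cell.gfp_brightness - scene.background)
        f_t = per_cell[idx]["F"]
        cal[(slice(None),) + box] += prof[None, :, :] * (f_t[:, None, None]
                                                         - scene.background)

    if acq.noise_enabled:
        rng = np.random.default_rng(acq.seed)
        gfp = _apply_noise(gfp, acq, rng)
        cal = _apply_noise(cal, acq, rng)
    top = 2 ** acq.bit_depth - 1
    gfp = np.clip(np.rint(gfp), 0, top).astype(np.uint16)
    cal = np.clip(np.rint(cal), 0, top).astype(np.uint16)

    events = pd.DataFrame([{
        "target": -1 if ev.target is None else ev.target, "t_on": ev.t_on,
        "duration": ev.duration, "power_mw": ev.power_mw,
        "field_label": ev.field_label,
    } for ev in plan.events])
    gt = GroundTruth(t_frames, per_cell, events)
    return MovieStack(gfp, cal, acq, gt)


def _apply_noise(frames, acq, rng):
    photons = np.clip(frames, 0, None) / acq.photon_gain
    noisy = rng.poisson(photons).astype(np.float64) * acq.photon_gain
    noisy += rng.normal(0.0, acq.read_noise_sigma, size=frames.shape)
    return noisy


def write_movie(stack: MovieStack, path) -> Path:
    """Write an interleaved multi-page TIFF plus JSON and ground-truth CSV sidecars."""
    path = Path(path)
    pages = np.empty((2 * stack.n_frames,) + stack.gfp.shape[1:], dtype=np.uint16)
    pages[0::2] = stack.gfp
    pages[1::2] = stack.calbryte
    tifffile.imwrite(path, pages, photometric="minisblack")
    acq = asdict(stack.acq)
    acq["shape"] = list(stack.acq.shape)
    meta = {"acquisition": acq, "channel_order": ["gfp", "calbryte"],
            "n_frames": stack.n_frames}
    if stack.ground_truth is not None:
        meta["events"] = stack.ground_truth.events.to_dict(orient="records")
        stack.ground_truth.to_frame().to_csv(path.with_suffix(".ground_truth.csv"),
                                             index=False)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_movie(path) -> MovieStack:
    """Read a stack written by :func:`write_movie`; pixel data round-trips exactly."""
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] % 2:
        raise ValueError(
            f"malformed movie TIFF {path}: expected an even page count of "
            f"interleaved channel pages, got {pages.shape[0] if pages.ndim == 3 else 1}")
    meta = json.loads(path.with_suffix(".json").read_text())
    acq_d = dict(meta["acquisition"])
    acq_d["shape"] = tuple(acq_d["shape"])
    acq = AcquisitionConfig(**acq_d)
    gt = None
    gt_path = path.with_suffix(".ground_truth.csv")
    if gt_path.exists():
        df = pd.read_csv(gt_path)
        per_cell = {}
        t = None
        for cid, g in df.groupby("cell"):
            g = g.sort_values("frame")
            t = g["t"].to_numpy()
            per_cell[int(cid)] = {k: g[k].to_numpy() for k in ("F", "p_M", "p_E", "c")}
        events = pd.DataFrame(meta.get("events", []))
        gt = GroundTruth(t, per_cell, events)
    return MovieStack(pages[0::2], pages[1::2], acq, gt)
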