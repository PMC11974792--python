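"""Quantification of calcium-imaging traces.

The conventions implemented here mirror a standard calcium-transient pipeline
for melanopsin work: mean intensity inside a 5-pixel-diameter circular ROI per
frame; normalization dF/F0 = (F(t) - F0) / F0 against a pre-stimulus baseline;
stimulus-aligned epoch extraction and pointwise averaging; a biexponential
A (e^{-bt} - e^{-ct}) fitted to the averaged transient of sustained cells
(decay time 1/b, rise time 1/c with c >= b); a peak-normalized monoexponential
with plateau (1 - a) e^{-bt} + a fitted from the peak frame for adapting cells;
peak amplitude and tail-mean summaries; and a pooled-variance two-tailed
Student's t-test for group comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ROISpec", "DffTrace", "Epoch", "BiexpFit", "MonoexpFit",
    "roi_pixel_indices", "extract_trace", "compute_dff", "default_baseline_window",
    "segment_epochs", "average_epochs", "fit_biexponential", "fit_monoexp_plateau",
    "peak_amplitude", "tail_mean", "ttest_two_tailed",
]


@dataclass(frozen=True)
class ROISpec:
    """Circular region of interest; ``center`` is (row, col), 0-based pixels."""

    center: tuple
    diameter: float = 5.0

    def __post_init__(self):
        if self.diameter < 1:
            raise ValueError("diameter must be at least 1 px")


@dataclass(frozen=True)
class DffTrace:
    """Normalized fluorescence trace dF/F0 with its baseline bookkeeping."""

    t: np.ndarray
    dff: np.ndarray
    f0: float
    baseline_window: tuple  # (first_frame, last_frame_exclusive)


@dataclass(frozen=True)
class Epoch:
    """A stimulus-aligned excerpt; t = 0 at event onset."""

    t: np.ndarray
    dff: np.ndarray
    n_averaged: int = 1


@dataclass(frozen=True)
class BiexpFit:
    """Fit of A (e^{-bt} - e^{-ct}) with c >= b; times are reciprocals of rates."""

    A: float
    b: float
    c: float
    rmse: float
    converged: bool = True

    @property
    def decay_time(self) -> float:
        return 1.0 / self.b

    @property
    def rise_time(self) -> float:
        return 1.0 / self.c


@dataclass(frozen=True)
class MonoexpFit:
    """Fit of (1 - a) e^{-bt} + a to a peak-normalized trace."""

    a: float
    b: float
    rmse: float
    degenerate: bool = False
    converged: bool = True

    @property
    def decay_time(self) -> float:
        return 1.0 / self.b


def roi_pixel_indices(roi: ROISpec, shape) -> tuple:
    """Pixel (rows, cols) of the discrete disk of the given diameter.

    A pixel belongs when its center lies within (diameter - 1) / 2 of the ROI
    center — the discrete-disk convention under which an N-pixel-diameter
    region is exactly N pixels wide (diameter 5 at an integer center gives the
    classic 13-pixel disk).
    """
    r0, c0 = roi.center
    rad = (roi.diameter - 1.0) / 2.0
    rr = np.arange(int(np.floor(r0 - rad)), int(np.ceil(r0 + rad)) + 1)
    cc = np.arange(int(np.floor(c0 - rad)), int(np.ceil(c0 + rad)) + 1)
    rg, cg = np.meshgrid(rr, cc, indexing="ij")
    inside = np.hypot(rg - r0, cg - c0) <= rad
    rows, cols = rg[inside], cg[inside]
    if rows.size and (rows.min() < 0 or cols.min() < 0 or rows.max() >= shape[0]
                      or cols.max() >= shape[1]):
        raise ValueError("ROI extends outside the frame")
    return rows, cols


def extract_trace(stack, roi: ROISpec, channel: str = "calbryte"):
    """Per-frame mean over the circular ROI; returns (t, values).

    Frame times come from the stack's acquisition frame rate.
    """
    frames = getattr(stack, channel)
    rows, cols = roi_pixel_indices(roi, frames.shape[1:])
    values = frames[:, rows, cols].mean(axis=1)
    t = np.arange(frames.shape[0]) / stack.acq.frame_rate
    return t, values.astype(float)


def default_baseline_window(t: np.ndarray, first_event_t: float,
                            pre_gap_s: float = 2.0, min_frames: int = 5) -> tuple:
    """Frames from recording start until ``pre_gap_s`` before the first event."""
    n = int(np.searchsorted(t, first_event_t - pre_gap_s, side="right"))
    return (0, max(n, min_frames))


def compute_dff(values: np.ndarray, t: np.ndarray, baseline_window: tuple) -> DffTrace:
    """dF/F0 with F0 the mean of the baseline frames."""
    lo, hi = baseline_window
    f0 = float(np.mean(values[lo:hi]))
    if f0 <= 0:
        raise ValueError("baseline fluorescence must be positive")
    return DffTrace(np.asarray(t, float), (np.asarray(values, float) - f0) / f0,
                    f0, (lo, hi))


def segment_epochs(trace: DffTrace, event_times, pre_s: float = 5.0,
                   post_s: float = 50.0) -> list:
    """Stimulus-aligned epochs, t = 0 at each event onset.

    Epochs use a fixed frame count so they can be averaged pointwise.
    Overlapping windows warn but are kept.
    """
    event_times = np.sort(np.asarray(event_times, dtype=float))
    if event_times.size == 0:
        raise ValueError("need at least one event")
    dt = float(np.mean(np.diff(trace.t)))
    n_pre = int(round(pre_s / dt))
    n_post = int(round(post_s / dt))
    if event_times.size > 1 and np.any(np.diff(event_times) < pre_s + post_s):
        warnings.warn("epoch windows overlap; epochs kept", stacklevel=2)
    epochs = []
    for t_on in event_times:
        i_on = int(np.searchsorted(trace.t, t_on - 1e-9))
        lo, hi = i_on - n_pre, i_on + n_post
        if lo < 0 or hi > trace.t.size:
            raise ValueError("epoch window extends outside the recording")
        epochs.append(Epoch(trace.t[lo:hi] - t_on, trace.dff[lo:hi]))
    return epochs


def average_epochs(epochs) -> Epoch:
    """Pointwise mean of time-aligned epochs (truncated to the shortest)."""
    if not epochs:
        raise ValueError("no epochs to average")
    n = min(e.t.size for e in epochs)
    dff = np.mean([e.dff[:n] for e in epochs], axis=0)
    return Epoch(epochs[0].t[:n], dff, n_averaged=sum(e.n_averaged for e in epochs))


# multi-start grid for the biexponential: slow rate b x fast rate c, in 1/s
_B_STARTS = (0.01, 0.05, 0.2)
_C_STARTS = (0.2, 1.0, 5.0)
_RATE_BOUNDS = (1e-4, 100.0)


def fit_biexponential(epoch: Epoch) -> BiexpFit:
    """Nonlinear least squares of A (e^{-bt} - e^{-ct}) on the t >= 0 samples.

    Multi-start over a rate grid; the model is symmetric under (b <-> c,
    A <-> -A), so the result is relabeled to the c >= b, A > 0 branch.
    """
    keep = epoch.t >= -1e-9
    t, y = epoch.t[keep], epoch.dff[keep]
    if t.size < 10:
        raise ValueError("need at least 10 samples from stimulus onset")

    def model(tt, amp, b, c):
        return amp * (np.exp(-b * tt) - np.exp(-c * tt))

    best = None
    a0 = max(float(np.max(y)), 1e-6)
    for b0 in _B_STARTS:
        for c0 in _C_STARTS:
            try:
                popt, _ = optimize.curve_fit(
                    model, t, y, p0=(2.0 * a0, b0, c0),
                    bounds=([0.0, _RATE_BOUNDS[0], _RATE_BOUNDS[0]],
                            [np.inf, _RATE_BOUNDS[1], _RATE_BOUNDS[1]]),
                    maxfev=20000)
            except RuntimeError:
                continue
            sse = float(np.sum((model(t, *popt) - y) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
    if best is None:
        return BiexpFit(np.nan, np.nan, np.nan, np.inf, converged=False)
    sse, (amp, b, c) = best
    if b > c:
        b, c = c, b
        amp = abs(amp)
    return BiexpFit(float(amp), float(b), float(c),
                    float(np.sqrt(sse / t.size)))


def fit_monoexp_plateau(trace: DffTrace | Epoch) -> MonoexpFit:
    """Peak-normalized monoexponential-with-plateau fit.

    The trace is normalized to its maximum, t = 0 is placed at the peak frame,
    and (1 - a) e^{-bt} + a is fitted over the post-peak samples.  A flat trace
    is flagged degenerate (a -> 1, rate meaningless).
    """
    y_raw = np.asarray(trace.dff, dtype=float)
    t_raw = np.asarray(trace.t, dtype=float)
    top = float(np.max(y_raw))
    if top <= np.min(y_raw) + 1e-15:
        return MonoexpFit(1.0, np.nan, 0.0, degenerate=True)
    y = y_raw / top
    ipk = int(np.argmax(y))
    t = t_raw[ipk:] - t_raw[ipk]
    y = y[ipk:]
    if t.size < 4:
        return MonoexpFit(1.0, np.nan, np.inf, degenerate=True, converged=False)

    def model(tt, a, b):
        return (1.0 - a) * np.exp(-b * tt) + a

    best = None
    a0 = float(np.clip(y[-1], 0.0, 0.9))
    for b0 in (0.05, 0.3, 1.0, 3.0):
        try:
            popt, _ = optimize.curve_fit(
                model, t, y, p0=(a0, b0),
                bounds=([0.0, _RATE_BOUNDS[0]], [1.0, _RATE_BOUNDS[1]]),
                maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        return MonoexpFit(np.nan, np.nan, np.inf, converged=False)
    sse, (a, b) = best
    return MonoexpFit(float(a), float(b), float(np.sqrt(sse / t.size)))


def peak_amplitude(epoch: Epoch | DffTrace) -> float:
    """Maximum dF/F0 over the epoch."""
    return float(np.max(epoch.dff))


def tail_mean(trace: DffTrace | Epoch, k_frames: int = 10) -> float:
    """Mean dF/F0 over the final ``k_frames`` frames."""
    return float(np.mean(np.asarray(trace.dff)[-k_frames:]))


def ttest_two_tailed(group_a, group_b) -> tuple:
    """Pooled-variance two-tailed Student's t-test; returns (t, p).

    Degenerate zero-variance groups with equal means give (0, 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
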