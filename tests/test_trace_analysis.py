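"""ROI extraction, dF/F0, epoch handling, exponential fits, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from melsim.trace_analysis import (Epoch, ROISpec, average_epochs, compute_dff,
                                   default_baseline_window, fit_biexponential,
                                   fit_monoexp_plateau, peak_amplitude,
                                   roi_pixel_indices, segment_epochs, tail_mean,
                                   ttest_two_tailed)


class _FakeStack:
    def __init__(self, frames, frame_rate=1.63):
        self.calbryte = frames
        self.gfp = frames

        class Acq:
            pass

        self.acq = Acq()
        self.acq.frame_rate = frame_rate


class TestRoi:
    @pytest.mark.parametrize("diameter", range(1, 10))
    @pytest.mark.parametrize("center", [(20, 20), (20.5, 19.5)])
    def test_membership_matches_exhaustive_enumeration(self, diameter, center):
        rows, cols = roi_pixel_indices(ROISpec(center, diameter), (40, 40))
        got = set(zip(rows.tolist(), cols.tolist()))
        # discrete-disk rule: an N-px-diameter region spans N pixel centers
        expected = {(i, j) for i in range(40) for j in range(40)
                    if np.hypot(i - center[0], j - center[1]) <= (diameter - 1) / 2}
        assert got == expected

    def test_default_diameter_five_has_13_pixels(self):
        rows, _ = roi_pixel_indices(ROISpec((10, 10)), (30, 30))
        assert rows.size == 13

    def test_uniform_frames_give_constant_trace(self):
        from melsim.trace_analysis import extract_trace
        frames = np.full((7, 20, 20), 42.0)
        t, vals = extract_trace(_FakeStack(frames), ROISpec((10, 10)))
        assert np.all(vals == 42.0)
        assert t[1] - t[0] == pytest.approx(1 / 1.63)

    def test_roi_outside_frame_raises(self):
        with pytest.raises(ValueError):
            roi_pixel_indices(ROISpec((1, 1), 5), (40, 40))


class TestDff:
    def test_constant_trace_gives_zero(self):
        t = np.arange(20.0)
        dff = compute_dff(np.full(20, 100.0), t, (0, 10))
        assert np.all(dff.dff == 0)
        assert dff.f0 == 100.0

    def test_formula(self):
        t = np.arange(10.0)
        vals = np.full(10, 100.0)
        vals[7] = 110.0
        dff = compute_dff(vals, t, (0, 5))
        assert dff.dff[7] == pytest.approx(0.10)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(scale=st.floats(1e-3, 1e4))
    def test_invariant_to_positive_scaling(self, scale):
        t = np.arange(30.0)
        vals = 100.0 + 10.0 * np.sin(t / 3.0) + 50.0 * (t > 15)
        d1 = compute_dff(vals, t, (0, 10)).dff
        d2 = compute_dff(vals * scale, t, (0, 10)).dff
        assert np.allclose(d1, d2, atol=1e-12)

    def test_nonpositive_baseline_raises(self):
        with pytest.raises(ValueError):
            compute_dff(np.zeros(10), np.arange(10.0), (0, 5))

    def test_default_baseline_window_bounds(self):
        t = np.arange(0, 30, 0.5)
        lo, hi = default_baseline_window(t, 10.0)
        assert lo == 0 and t[hi - 1] <= 8.0
        # minimum of 5 frames even for early events
        assert default_baseline_window(t, 0.5)[1] == 5


class TestEpochs:
    def test_identical_epochs_average_to_themselves(self):
        t = np.arange(0, 200, 1.0)
        y = np.zeros_like(t)
        for t_on in (50.0, 120.0):
            y[int(t_on):int(t_on) + 10] = 1.0
        trace = compute_dff(100.0 * (1 + y), t, (0, 20))
        epochs = segment_epochs(trace, [50.0, 120.0], pre_s=5, post_s=40)
        avg = average_epochs(epochs)
        assert np.allclose(avg.dff, epochs[0].dff)
        assert avg.n_averaged == 2

    def test_opposite_epochs_cancel(self):
        e1 = Epoch(np.arange(10.0), np.ones(10))
        e2 = Epoch(np.arange(10.0), -np.ones(10))
        assert np.all(average_epochs([e1, e2]).dff == 0)

    def test_overlapping_windows_warn(self):
        t = np.arange(0, 100, 1.0)
        trace = compute_dff(np.full(100, 10.0), t, (0, 5))
        with pytest.warns(UserWarning):
            epochs = segment_epochs(trace, [30.0, 40.0], pre_s=5, post_s=30)
        assert len(epochs) == 2

    def test_averaging_52_epochs_reduces_noise_sqrt_n(self, rng):
        # central-limit check on a flat noisy segment
        n_epochs, n_samples, sigma = 52, 80, 0.05
        epochs = [Epoch(np.arange(n_samples, dtype=float),
                        rng.normal(0, sigma, n_samples))
                  for _ in range(n_epochs)]
        avg = average_epochs(epochs)
        assert np.std(avg.dff) == pytest.approx(sigma / np.sqrt(52), rel=0.3)


class TestBiexponential:
    def test_noiseless_recovery(self):
        t = np.arange(0, 60, 0.6)
        y = 1.0 * (np.exp(-0.04 * t) - np.exp(-0.25 * t))
        fit = fit_biexponential(Epoch(t, y))
        assert fit.A == pytest.approx(1.0, rel=1e-3)
        assert fit.b == pytest.approx(0.04, rel=1e-3)
        assert fit.c == pytest.approx(0.25, rel=1e-3)
        assert fit.decay_time == pytest.approx(25.0, rel=1e-3)
        assert fit.rise_time == pytest.approx(4.0, rel=1e-3)

    def test_time_rescaling_equivariance(self):
        t = np.arange(0, 60, 0.6)
        y = 0.8 * (np.exp(-0.05 * t) - np.exp(-0.5 * t))
        fit1 = fit_biexponential(Epoch(t, y))
        fit2 = fit_biexponential(Epoch(2 * t, y))
        assert fit2.b == pytest.approx(fit1.b / 2, rel=1e-3)
        assert fit2.c == pytest.approx(fit1.c / 2, rel=1e-3)

    def test_recovery_under_default_noise_averaged_epochs(self, rng):
        t = np.arange(0, 50, 1 / 1.63)
        clean = 1.0 * (np.exp(-0.04 * t) - np.exp(-0.25 * t))
        epochs = [Epoch(t, clean + rng.normal(0, 0.03, t.size))
                  for _ in range(20)]
        fit = fit_biexponential(average_epochs(epochs))
        assert fit.b == pytest.approx(0.04, rel=0.10)
        assert fit.c == pytest.approx(0.25, rel=0.10)

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            fit_biexponential(Epoch(np.arange(5.0), np.ones(5)))


class TestMonoexpPlateau:
    def test_noiseless_recovery(self):
        t = np.arange(0, 30, 0.6)
        y = 0.9 * np.exp(-0.3125 * t) + 0.1
        fit = fit_monoexp_plateau(Epoch(t, y))
        assert fit.a == pytest.approx(0.1, rel=1e-3)
        assert fit.b == pytest.approx(0.3125, rel=1e-3)
        assert fit.decay_time == pytest.approx(3.2, rel=1e-3)

    def test_fit_starts_at_peak_frame(self):
        # rising segment before the peak must not affect the decay estimate
        t = np.arange(0, 40, 0.5)
        rise = np.clip(t / 5.0, 0, 1)
        y = rise * (0.8 * np.exp(-0.4 * np.clip(t - 5.0, 0, None)) + 0.2)
        fit = fit_monoexp_plateau(Epoch(t, y))
        assert fit.b == pytest.approx(0.4, rel=0.02)

    def test_flat_trace_degenerate(self):
        fit = fit_monoexp_plateau(Epoch(np.arange(20.0), np.ones(20)))
        assert fit.degenerate
        assert fit.a == 1.0

    def test_recovery_under_noise_averaged(self, rng):
        t = np.arange(0, 30, 1 / 1.63)
        clean = 0.9 * np.exp(-0.3125 * t) + 0.1
        epochs = [Epoch(t, clean + rng.normal(0, 0.03, t.size)) for _ in range(20)]
        fit = fit_monoexp_plateau(average_epochs(epochs))
        assert fit.b == pytest.approx(0.3125, rel=0.10)


class TestSummariesAndStats:
    def test_peak_of_monotone_epoch_is_last_sample(self):
        e = Epoch(np.arange(10.0), np.linspace(0, 1, 10))
        assert peak_amplitude(e) == 1.0

    def test_tail_mean_of_constant(self):
        e = Epoch(np.arange(30.0), np.full(30, 0.05))
        for k in (3, 10, 25):
            assert tail_mean(e, k) == pytest.approx(0.05)

    def test_identical_groups(self):
        t, p = ttest_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_shifted_groups_significant(self):
        # textbook pooled-variance computation: sd = 1, diff = 10,
        # t = 10 / sqrt(2/3) = 12.247, df = 4
        t, p = ttest_two_tailed([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert abs(t) == pytest.approx(12.247, rel=1e-3)
        assert p < 0.01

    def test_small_groups_raise(self):
        with pytest.raises(ValueError):
            ttest_two_tailed([1.0], [1.0, 2.0])
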