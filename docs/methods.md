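# Methods

This note documents the models inside `melsim`, the choices that were genuinely
open, and what the synthetic recordings do and do not establish about real data.

## Spectral fields and two-photon excitation

The stimulation source is represented by a complex spectral amplitude E(ω) on a
uniform angular-frequency grid (2048 points spanning 850–1250 nm; ω = 2πc/λ
with c = 299.792458 nm/fs). Amplitudes carry units of √(mW·fs) so the
trapezoidal integral of |E|² over ω is the average power in mW. The default
envelope is a Gaussian in wavelength centered at the 1030 nm pump with 180 nm
FWHM, hard-truncated to the 900–1160 nm supercontinuum support and renormalized
to the requested power. The true photonic-crystal-fiber output shape is not
constrained by the recordings being emulated; the Gaussian is the simplest
smooth envelope spanning the printed band, and the ~12 fs transform-limited
duration it implies is checked only as an order-of-magnitude property.

Two-photon absorption is driven by S(2ω) = |(E ∗ E)(2ω)|², computed as an
FFT-based linear autoconvolution (2N−1 samples, spacing Δω); an O(N²)
direct pair sum is kept as an independent oracle and agrees to rounding error.
Key analytic facts used as tests: S is pointwise maximal for flat phase
(triangle inequality); odd phase orders cancel pairwise at exactly 2ω₀; the
integrated yield scales as the fourth power of amplitude (power squared).

**Center snapping.** `apply_phase` snaps ω₀ onto the half-grid by default
(a < 0.1 nm shift). Only then does 2ω₀ coincide with a sample of the
autoconvolution axis; at an off-grid ω₀ the nearest-sample pairs acquire a
residual odd phase 3a₃δ²ε (≈ 1 rad at the band edge for ε = Δω/2,
a₃ = 15,000 fs³) and the exact-invariance property at 2ω₀ is destroyed by
discretization alone.

Band masks mimic a physical knife edge at the pulse-shaper plane: a
raised-cosine window in wavelength with a 2 nm default edge (0 = hard edge).
Band requests wider than the support (e.g. 900–1200 nm) are effectively clipped
by the envelope rather than rejected.

## Photocycle

Occupancies p = (p_R, p_M, p_E) of the 11-cis ground, all-trans active, and
7-cis silent states evolve as dp/dt = Q·p with photo-rates

k_XY = η_XY · ∫ S(λ_eq) σ_X(λ_eq) dλ_eq / Z_ref,

where λ_eq = 2πc/(2ω) is the equivalent single-photon wavelength and Z_ref
normalizes the flat-phase full-band field at the 20 mW reference power to unit
overlap with a flat action spectrum. Raster illumination scales photo-rates by
a coverage duty (default 0.02 ≈ cell area / field area — the beam dwells on a
soma only a small fraction of each frame); targeted spiral scans use duty 1.
Because S is quartic in amplitude, all photo-rates scale as power².

Action spectra are unit-peak Gaussians in λ_eq: σ_R at 480 nm, σ_E at 460 nm,
σ_M at 560 nm, all 70 nm FWHM. Peaks follow the blue-activation /
yellow-deactivation assignment (degenerate pairs at 980/1140 nm act at
490/570 nm). The width is a deliberate compromise: wide enough to represent
melanopsin's broad per-state absorption, narrow enough that a TOD profile
centered at 980 nm out-drives one centered at 1030 nm. At ≥90 nm width the
1030-centered profile wins — its S(2ω₀) peak sits at the center of the
envelope and is ~1.5× larger, which broader action spectra can no longer
discriminate — and the monotone 980 > 1030 > 1140 ordering of sustained
responses collapses. These are calibration defaults, not measurements.

Thermal relaxations: k_MR ≈ 0.24 s⁻¹ (calibrated; sets the ~4 s calcium rise
via the post-stimulus decay of p_M) and k_ER = 0.02 s⁻¹ (the slow E → R
recovery; the recordings emulated here do not constrain it tightly). The
shared photo-gain η is fixed so the 1 s / 20 mW reference scan ends at
p_M = 0.5 — essentially the branching-limited photoequilibrium, since M → E
conversion caps p_M just above 0.49 at any gain.

Integration is exact: rates are piecewise-constant per illumination segment,
and the propagator e^{QΔt} is applied with steps split at segment boundaries,
so trajectories are independent of the sampling interval and conserve the
simplex to rounding error.

## Calcium and fluorescence

A single calcium pool per cell: dc/dt = k_drive·p_M·a − k_clear·c, integrated
with exponential-Euler steps (exact for piecewise-constant p_M). The gate a ≡ 1
in sustained mode (HEK293T-like overexpression), so a 1 s stimulus yields a
transient whose measured rise is governed by k_MR and decay by
k_clear ≈ 0.04 s⁻¹. In adapting mode (ipRGC-like) the gate closes under light
(p_M > 0.01) with τ_adapt ≈ 1.8 s toward a residual floor of 0.08 and reopens
in darkness with τ_recover = 20 s. The floor keeps a small persistent response
under sustained illumination — it is what the plateau term a of the
monoexponential fit estimates, and without it active and inactive cells would
be indistinguishable in their late-trace means. The model places adaptation
downstream of the photocycle; whether the real ipRGC decay reflects pigment
depletion or downstream adaptation is not resolved by the recordings emulated
here. Fluorescence is linear, F = f0(1 + g·c); an optional saturating variant
c/(1 + c/Kd) and a calcium-dependent clearance k_clear(1 + βc) exist behind
config flags but are off by default and excluded from all shipped results.

## Synthetic recordings

Cells are cosine-tapered disks (radius 6 px, 1.5 px taper) blended over a
100-count background on a 128×128 (targeted paradigms) or 256×256 (ipRGC
field) frame at 1.63 Hz. The GFP channel is static and marks OPN4⁺ cells only;
the calcium channel renders each cell's F(t). Noise is Poisson shot noise at
1 count/photon followed by Gaussian read noise (σ = 10 counts), clipped to
16 bits; everything is deterministic given the acquisition seed. Calcium-channel
baselines are 1000 counts for HEK-mode cells and 4000 for ipRGC-mode cells
(the retinal protocol bulk-loads 4× the indicator concentration), which gives
the ~5% ipRGC transients a workable single-cell SNR. Movies carry a
ground-truth sidecar (noiseless F, p_M, p_E, c per frame and the event table),
so every analysis step can be validated against what was simulated.

Not modeled: optical PSF and depth sectioning, motion, bleaching, stimulus
artifacts in the imaging channel, GFP photophysics, and any cell-segmentation
step (ROIs are supplied). Passing tests therefore demonstrate correctness of
the quantification pipeline and internal consistency of the model — not that
the model captures every feature of real microscope data.

## Quantification conventions

* ROI: discrete disk, pixel-center distance ≤ (d−1)/2 — a 5-pixel-diameter ROI
  is 5 pixels wide (13 pixels at an integer center).
* ΔF/F0 with F0 the mean from recording start to 2 s before the first event
  (≥ 5 frames).
* Epochs aligned at stimulus onset (5 s pre / 50 s post), averaged pointwise;
  fits are applied to the epoch average, matching the convention of fitting
  condition averages rather than individual noisy epochs.
* Biexponential A(e^{−bt} − e^{−ct}): multi-start least squares over
  b ∈ {0.01, 0.05, 0.2} × c ∈ {0.2, 1, 5} s⁻¹, bounds (10⁻⁴, 100) s⁻¹, A ≥ 0;
  the model is symmetric under (b ↔ c, A ↔ −A), so results are relabeled to
  c ≥ b (decay 1/b, rise 1/c).
* Monoexponential plateau (1 − a)e^{−bt} + a: trace normalized to its maximum
  and t = 0 placed at the peak frame (the convention adopted where the
  alternative — recording start — would mix the rise into the decay estimate);
  flat traces are flagged degenerate.
* Group comparison: pooled-variance two-tailed Student's t (not Welch).
* Specificity: per-cell peaks are read from epoch-averaged traces and compared
  to 3× the raw blank-ROI ΔF/F0 standard deviation. On raw single traces the
  maximum of ~1300 noise samples exceeds 3σ by order statistics alone, so the
  averaged-trace reading is the only well-posed one — and it matches the
  fits-on-averages convention above.

## Calibration

The emulated recordings report cell-level kinetics, never molecular rates, so
free parameters are fixed against a shipped target table — reference-condition
decay 25 s, rise 4 s, peak ΔF/F0 ≈ 1.0 (amplitude-scale aid), adapting-cell
mean peak 5.4 % and decay 3.2 s — in two stages:

* **Stage A** (noiseless fast path: photocycle → calcium → frame-sampled fit,
  no rendering): η solved first for the p_M = 0.5 saturation rule, then
  deterministic coordinate descent over k_MR, k_clear (HEK), k_drive (HEK,
  closed-form since ΔF/F is linear in drive), τ_adapt and k_drive (ipRGC, at
  the mean of the lognormal cell-to-cell gain variability, σ_log = 0.4).
* **Stage B**: two multiplicative correction passes against the full noisy
  render-and-analyze pipeline (the ipRGC summary averaged over three seeds so
  a single set of gain draws cannot bias the correction). This absorbs what
  the fast path cannot see: the upward bias of per-cell peak maxima under
  noise and fit-shape effects of sampling and epoch averaging.

The result is `src/melsim/data/default_params.yaml`, the file every runner
loads; `melsim calibrate` reproduces it. Re-running calibration from an
already-calibrated file is a no-op up to optimizer tolerance.

## Problem sizes of the shipped replications

Reference condition: 13 epochs at 60 s spacing on a 128×128 field (≈ 1350
frames); duration grid {20, 50, 100, 500, 1000} ms, power grid {5, 10, 20,
30} mW; band/TOD/switch paradigms: single 60–75 s raster recordings; ipRGC
paradigm: 34 active + 6 inactive cells, one 60 s recording at 256×256. These
sizes keep any single replication within tens of seconds on one CPU while
matching the epoch structure (n ≈ 52 transients from 4 cells) and cell count
(n = 34) of the emulated study.

## Known limitations

* The photocycle is classical and rate-based; coherent control enters only
  through S(2ω). No single-molecule stochasticity, no bleaching.
* Linear indicator by default; strong responses (peak ΔF/F0 ≈ 1) would
  saturate a real dye to some degree.
* The shortening of decay times with stronger irradiation seen in the emulated
  recordings has no mechanism here (the optional β-clearance term can produce
  the trend but ships disabled).
* ΔF/F0 is nonnegative in this model, so adapting cells end slightly *above*
  inactive cells in late-trace comparisons; real retinal recordings can show
  the opposite sign (e.g. baseline contamination by early response frames,
  bleaching), which the model does not attempt.
* Action spectra, noise levels, image geometry, and the E-state relaxation
  rate are design defaults constrained only loosely by the emulated study.
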