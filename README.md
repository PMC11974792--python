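# melsim

Closed-loop simulation and analysis of **two-photon activation, deactivation,
and coherent control of melanopsin-expressing cells**.

Melanopsin (OPN4), the photopigment of intrinsically photosensitive retinal
ganglion cells (ipRGCs), is tri-stable: blue light drives the ground state
|R⟩ (11-cis retinal) and the silent excited state |E⟩ (7-cis) to the
signaling-active state |M⟩ (all-trans), yellow light drives |M⟩ → |E⟩, and both
excited states relax thermally back to |R⟩. With a broadband near-infrared
femtosecond source, two-photon absorption reaches these transitions through the
**two-photon excitation spectrum**

S(2ω) = |∫ E(ω + Ω) E(ω − Ω) dΩ|²,

the squared autoconvolution of the complex spectral field E(ω). S is maximal
everywhere for a flat spectral phase (transform limit); pure third-order
dispersion (TOD) φ(ω) = a₃(ω − ω₀)³, being odd about ω₀, preserves S at exactly
2ω₀ while suppressing it elsewhere — so shifting the TOD center between 980 nm
(equivalent single-photon drive at 490 nm, activating) and 1140 nm (570 nm,
deactivating) photoswitches the pigment without touching the spectral envelope.

The package implements the whole loop a stimulation experiment closes:

1. **`pulse_optics`** — supercontinuum fields (900–1160 nm), phase profiles and
   knife-edge band masks, S(2ω), pulse durations;
2. **`photocycle`** — photo-rates from spectral overlap of S with per-state
   action spectra, exact matrix-exponential evolution of (p_R, p_M, p_E);
3. **`cell_dynamics`** — calcium `dc/dt = k_drive·p_M·a − k_clear·c` with a
   sustained (HEK293T-like) or adapting (ipRGC-like) gate `a`, and a linear
   indicator model for Calbryte-590 fluorescence;
4. **`synthetic_imaging`** — two-channel 16-bit TIFF movies (static GFP tag,
   dynamic calcium channel) at ~1.63 Hz with Poisson + read noise and a
   ground-truth sidecar;
5. **`trace_analysis`** — 5-pixel ROI traces, ΔF/F0, stimulus-aligned epoch
   averaging, biexponential fits A(e^{−bt} − e^{−ct}) (decay 1/b, rise 1/c),
   peak-normalized monoexponential-plateau fits (1 − a)e^{−bt} + a, and
   pooled-variance two-tailed Student's t-tests;
6. **`experiments`** — config-driven replications of the five stimulation
   paradigms (scan-duration sweep, power sweep, spectral bands, TOD tuning,
   dynamic phase switching, ipRGC adaptation) plus the calibration routine
   that fixes the shipped default parameters.

## Worked example

```python
import numpy as np
from melsim import load_defaults
from melsim.pulse_optics import total_yield, two_photon_spectrum
from melsim.experiments import run_condition

defaults = load_defaults()

# coherent control: same envelope, different cubic spectral phase
flat = defaults.field(power_mw=20.0)
for label, fld in [("flat phase", flat),
                   ("TOD @ 980 nm", defaults.tod_field(980.0, 20.0)),
                   ("TOD @ 1140 nm", defaults.tod_field(1140.0, 20.0))]:
    tps = two_photon_spectrum(fld)
    lam_peak = tps.lambda_eq_nm[np.argmax(tps.s)]
    print(f"{label:14s} yield={total_yield(tps):8.2f}  S peaks at {lam_peak:5.1f} nm")

# full closed-loop replication of the targeted-stimulation reference condition
res = run_condition(duration_s=1.0, power_mw=20.0, seed=1, n_epochs=13)
print(f"peak dF/F0 = {res.per_cell_peaks[0]:.2f}, "
      f"rise = {res.fit.rise_time:.1f} s, decay = {res.fit.decay_time:.1f} s")
```

prints

```
flat phase     yield=  127.72  S peaks at 506.8 nm
TOD @ 980 nm   yield=    2.66  S peaks at 490.0 nm
TOD @ 1140 nm  yield=    0.59  S peaks at 566.0 nm
peak dF/F0 = 1.01, rise = 4.0 s, decay = 24.9 s
```

The two TOD fields carry the identical spectral envelope and average power, yet
their two-photon drive concentrates at 490 nm versus 566 nm equivalent
wavelength — the blue/yellow distinction that flips melanopsin between its
active and silent states. The last line is the full simulate → render → analyze
loop: a single OPN4⁺ cell is spiral-scanned for 1 s at 20 mW thirteen times, the
noisy movie is re-analyzed with a 5-pixel ROI, and the biexponential fit of the
epoch-averaged ΔF/F0 transient recovers ~4 s rise and ~25 s decay kinetics
typical of melanopsin-driven calcium responses.

A command-line interface mirrors the library:

```
melsim simulate   --config scene.yaml --seed 1 --out out/
melsim analyze    --movie out/movie.tif --rois rois.csv --events events.csv --out analysis/
melsim experiment --paradigm tod --seed 1 --out results/
melsim calibrate  --out params.yaml
```

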