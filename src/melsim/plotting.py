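"""Small plotting helpers for spectra and traces (matplotlib Axes in, Axes out)."""

from __future__ import annotations

import numpy as np


def plot_two_photon_spectrum(tps, ax=None, label=None):
    """Two-photon spectral density against equivalent single-photon wavelength."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lam = tps.lambda_eq_nm
    order = np.argsort(lam)
    ax.plot(lam[order], tps.s[order], label=label)
    ax.set_xlabel("equivalent wavelength (nm)")
    ax.set_ylabel("S(2ω) (a.u.)")
    if label:
        ax.legend()
    return ax


def plot_dff(trace, ax=None, events=None, label=None):
    """dF/F0 trace with optional stimulation tick marks."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trace.t, trace.dff, label=label)
    if events is not None:
        for t_on in events:
            ax.axvline(t_on, color="k", lw=0.5, alpha=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ΔF/F0")
    if label:
        ax.legend()
    return ax
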