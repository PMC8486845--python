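"""Plotting helpers mirroring the figures of a break-junction campaign."""

from __future__ import annotations

import numpy as np

from .datatypes import Histogram2D, IVSweep


def plot_histogram2d(hist: Histogram2D, ax=None, cmap: str = "viridis"):
    """Render a 2D G-z histogram (displacement vs log10 conductance)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.pcolormesh(hist.z_edges, hist.logg_edges, hist.counts.T, cmap=cmap)
    ax.set_xlabel("displacement (nm)")
    ax.set_ylabel("log10 G / G0")
    return ax


def plot_iv_histogram2d(
    sweeps: list[IVSweep],
    v_bins: int = 110,
    logi_range: tuple[float, float] = (-13.0, -5.0),
    logi_bins: int = 80,
    ax=None,
    cmap: str = "viridis",
):
    """2D histogram of an I-V ensemble over (V, log10 |I|) bins."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    v = np.concatenate([s.bias for s in sweeps])
    i = np.concatenate([s.current for s in sweeps])
    keep = np.abs(i) > 0
    h, ve, ie = np.histogram2d(v[keep], np.log10(np.abs(i[keep])),
                               bins=(v_bins, logi_bins),
                               range=((v.min(), v.max()), logi_range))
    ax.pcolormesh(ve, ie, h.T, cmap=cmap)
    ax.set_xlabel("bias (V)")
    ax.set_ylabel("log10 |I| (A)")
    return ax
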