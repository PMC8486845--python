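"""Transition voltage spectroscopy.

Sweeps are first classified into high/low conductance states by their
low-bias conductance (two-means clustering in log space). For each sweep and
polarity, log10(|I|/V^2) is plotted against 1/|V| (the Fowler-Nordheim
representation) and the transition voltage V_trans is read off as the bias
at the interior minimum after moving-average smoothing. Polarities are
analysed separately and pooled by absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import FNSpectrum, IVSweep, TransitionVoltage
from .iv_models import single_level_current

__all__ = [
    "TVSConfig",
    "classify_iv",
    "fn_transform",
    "find_vtrans",
    "vtrans_ensemble",
    "vtrans_histogram",
    "tune_level_energy",
]


@dataclass
class TVSConfig:
    """Tunable knobs of the TVS stage."""

    window: tuple[float, float] = (0.05, 0.15)  # |V| range for classification
    fallback: str = "low"  # label when clustering collapses
    #: minimum separation of the two cluster centres (decades of conductance)
    #: below which the ensemble is treated as a single population
    min_separation_decades: float = 0.5
    v_min: float = 0.1  # V; excludes the 1/V singularity
    smooth_points: int = 5  # centred moving average before minimum-finding


def _low_bias_logg(sweep: IVSweep, cfg: TVSConfig) -> float:
    v, i = sweep.bias, sweep.current
    m = (np.abs(v) >= cfg.window[0]) & (np.abs(v) <= cfg.window[1])
    if not m.any():
        raise ValueError("no samples in the classification window")
    g = np.mean(np.abs(i[m] / v[m]))
    return float(np.log10(max(g, 1e-300)))


def _two_means_1d(x: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 1D two-means: centres initialized at min/max.
    Returns boolean mask of membership in the upper cluster."""
    c0, c1 = float(x.min()), float(x.max())
    if c0 == c1:
        return np.zeros(x.size, dtype=bool)
    for _ in range(max_iter):
        upper = np.abs(x - c1) < np.abs(x - c0)
        if not upper.any() or upper.all():
            break
        n0, n1 = float(x[~upper].mean()), float(x[upper].mean())
        if (n0, n1) == (c0, c1):
            break
        c0, c1 = n0, n1
    return upper


def classify_iv(
    ensemble: list[IVSweep], cfg: TVSConfig | None = None
) -> list[str]:
    """Label each sweep 'high' or 'low' by two-means clustering of the
    low-bias log-conductance. All-identical conductances collapse to a
    single cluster labelled ``cfg.fallback``."""
    cfg = cfg or TVSConfig()
    logg = np.array([_low_bias_logg(s, cfg) for s in ensemble])
    if np.allclose(logg, logg[0]):
        return [cfg.fallback] * len(ensemble)
    upper = _two_means_1d(logg)
    if not upper.any() or upper.all():
        return [cfg.fallback] * len(ensemble)
    separation = float(logg[upper].mean() - logg[~upper].mean())
    if separation < cfg.min_separation_decades:
        return [cfg.fallback] * len(ensemble)
    return ["high" if u else "low" for u in upper]


def fn_transform(
    sweep: IVSweep, polarity: str, cfg: TVSConfig | None = None
) -> FNSpectrum:
    """Fowler-Nordheim spectrum (1/|V|, log10(|I|/V^2)) for one polarity.

    Points with |V| < ``cfg.v_min`` or non-positive |I| are dropped; an
    empty result raises ValueError. Output is sorted by increasing 1/|V|.
    """
    if polarity not in ("pos", "neg"):
        raise ValueError(f"polarity must be 'pos' or 'neg', got {polarity!r}")
    cfg = cfg or TVSConfig()
    v, i = sweep.bias, sweep.current
    m = (v > 0) if polarity == "pos" else (v < 0)
    m &= np.abs(v) >= cfg.v_min
    m &= np.abs(i) > 0
    if not m.any():
        raise ValueError(f"sweep has no usable {polarity} branch")
    av = np.abs(v[m])
    fn = np.log10(np.abs(i[m]) / av**2)
    order = np.argsort(1.0 / av)
    return FNSpectrum((1.0 / av)[order], fn[order])


def find_vtrans(
    spectrum: FNSpectrum, cfg: TVSConfig | None = None
) -> float | None:
    """|V| at the interior minimum of the smoothed FN spectrum, or None when
    the minimum sits on the boundary of the scanned range."""
    cfg = cfg or TVSConfig()
    y = spectrum.fn_value
    k = max(1, cfg.smooth_points)
    if y.size < k + 2:
        raise ValueError("spectrum shorter than the smoothing window")
    if k > 1:
        ys = np.convolve(y, np.ones(k) / k, mode="valid")
        x = spectrum.inv_bias[(k - 1) // 2: (k - 1) // 2 + ys.size]
    else:
        ys, x = y, spectrum.inv_bias
    j = int(np.argmin(ys))
    if j == 0 or j == ys.size - 1:
        return None
    return float(1.0 / x[j])


def vtrans_ensemble(
    sweeps: list[IVSweep], cfg: TVSConfig | None = None
) -> list[TransitionVoltage]:
    """Per-sweep transition voltages for both polarities."""
    cfg = cfg or TVSConfig()
    out = []
    for s in sweeps:
        tv = TransitionVoltage()
        for pol in ("pos", "neg"):
            try:
                v = find_vtrans(fn_transform(s, pol, cfg), cfg)
            except ValueError:
                v = None
            if pol == "pos":
                tv.v_trans_pos = v
            else:
                tv.v_trans_neg = v
        out.append(tv)
    return out


def vtrans_histogram(
    values: list[TransitionVoltage],
    bins: int = 40,
    v_range: tuple[float, float] | None = None,
    pool_polarities: bool = True,
) -> dict:
    """Histogram + mean/sd over defined V_trans values, pooling polarities
    by absolute value by default."""
    pooled: list[float] = []
    for tv in values:
        if tv.v_trans_pos is not None:
            pooled.append(tv.v_trans_pos)
        if pool_polarities and tv.v_trans_neg is not None:
            pooled.append(tv.v_trans_neg)
    if not pooled:
        raise ValueError("no defined V_trans values")
    arr = np.asarray(pooled)
    if v_range is None and arr.max() - arr.min() < 1e-6:
        v_range = (float(arr.min()) - 0.05, float(arr.max()) + 0.05)
    counts, edges = np.histogram(arr, bins=bins, range=v_range)
    return {
        "counts": counts,
        "edges": edges,
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "n": int(arr.size),
    }


def tune_level_energy(
    target_vtrans: float,
    params,
    eps_range: tuple[float, float] = (0.05, 1.0),
    eps_step: float = 0.002,
) -> float:
    """Brute-force scan over the single-level energy eps0 (fixed coupling)
    so that the noise-free high-state sweep's FN minimum sits at
    ``target_vtrans``. Operates on the same sweep grid and extraction
    pipeline used for real data."""
    cfg = TVSConfig()
    v = np.linspace(params.sweep_min, params.sweep_max, params.n_points)
    best_eps, best_err = None, np.inf
    for eps in np.arange(*eps_range, eps_step):
        i = single_level_current(v, eps, params.coupling)
        sweep = IVSweep(v, i)
        try:
            vt = find_vtrans(fn_transform(sweep, "pos", cfg), cfg)
        except ValueError:
            continue
        if vt is None:
            continue
        err = abs(vt - target_vtrans)
        if err < best_err:
            best_eps, best_err = float(eps), err
    if best_eps is None:
        raise RuntimeError("no eps0 in the scan range yields an interior FN minimum")
    return best_eps
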