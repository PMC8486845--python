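"""Break-junction trace processing.

Implements the displacement-origin convention (z = 0 where conductance first
drops below 50 mG0), the per-trace-histogram plateau filter that removes
simple-exponential traces, 1D/2D conductance histograms with Gaussian peak
fitting, and two-segment tunnelling-decay-constant (beta1 / beta2)
extraction.

Plateau window location
-----------------------
The plateau judgement itself follows the per-trace histogram construction:
the trace's log10 G values (median-filtered for noise robustness) are binned
at 0.1 decades, and a plateau is declared when some bin's occupancy,
converted to displacement through the sampling step, reaches a minimum
plateau length. Two half-offset bin grids are evaluated so that a plateau
straddling a bin edge is not missed. For traces that pass, the fit window
[z_start, z_end] is refined from the histogram band by a local-slope
criterion, which makes the subsequent least-squares beta1 fit exact on
noise-free traces. beta2 is fitted from the first post-rupture sample (found
by a drop threshold on the smoothed trace) down to the noise floor; samples
clipped at the floor are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import medfilt

from .constants import LN10, ORIGIN_CONDUCTANCE_G0, beta_nm_inv_to_a_inv
from .datatypes import ConductanceTrace, DecayFit, Histogram2D, PeakEstimate, PlateauResult

__all__ = [
    "FilterConfig",
    "DecayFitConfig",
    "set_displacement_origin",
    "filter_plateau_traces",
    "histogram2d",
    "conductance_peak",
    "fit_decay_constants",
    "fit_single_decay",
    "PeakFitError",
]


class PeakFitError(RuntimeError):
    """Raised when the Gaussian peak fit is degenerate or fails."""


@dataclass
class FilterConfig:
    """Configuration of the per-trace-histogram plateau filter."""

    bin_decades: float = 0.1
    range_log10: tuple[float, float] = (-6.0, -1.0)
    min_plateau_nm: float = 0.05
    smooth_points: int = 11  # median filter width (odd); 1 disables


@dataclass
class DecayFitConfig:
    """Configuration of the two-segment decay-constant fit."""

    slope_span: int = 61  # samples per local-slope regression window
    slope_threshold_a_inv: float = 1.0  # plateau iff local |slope| below this
    edge_trim: int = 2  # samples dropped at each end of the slope run
    band_halfwidth_decades: float = 0.3  # coarse window around the band centre
    post_drop_decades: float = 0.45  # beta2 window starts this far below centre
    noise_floor_g0: float = 10 ** -6.5
    min_points: int = 5
    smooth_points: int = 11


def set_displacement_origin(trace: ConductanceTrace) -> ConductanceTrace:
    """Shift displacement so the first sample with G < 50 mG0 sits at z = 0.

    Samples before the crossing keep negative z. A trace that never drops
    below 50 mG0 is returned unshifted with ``meta['originated'] = False``
    and is excluded from downstream histogram/filter stages. Idempotent.
    """
    below = trace.conductance < ORIGIN_CONDUCTANCE_G0
    meta = dict(trace.meta)
    if not below.any():
        meta["originated"] = False
        return ConductanceTrace(trace.displacement.copy(), trace.conductance.copy(), meta)
    k = int(np.argmax(below))
    meta["originated"] = True
    return ConductanceTrace(trace.displacement - trace.displacement[k],
                            trace.conductance.copy(), meta)


def _best_bin_occupancy(log10g: np.ndarray, cfg: FilterConfig) -> tuple[int, float]:
    """Max per-bin sample count over two half-offset bin grids and the
    log10 G centre of that bin."""
    lo, hi = cfg.range_log10
    w = cfg.bin_decades
    best_count, best_center = 0, np.nan
    for offset in (0.0, 0.5 * w):
        edges = np.arange(lo + offset, hi + w, w)
        if edges.size < 2:
            continue
        counts, _ = np.histogram(log10g, bins=edges)
        j = int(np.argmax(counts))
        if counts[j] > best_count:
            best_count = int(counts[j])
            best_center = 0.5 * (edges[j] + edges[j + 1])
    return best_count, best_center


def _smoothed_log10g(trace: ConductanceTrace, smooth_points: int) -> np.ndarray:
    y = trace.log10_g
    if smooth_points > 1:
        k = smooth_points if smooth_points % 2 == 1 else smooth_points + 1
        if y.size > k:
            y = medfilt(y, kernel_size=k)
    return y


def _local_slopes(z: np.ndarray, y: np.ndarray, span: int) -> np.ndarray:
    """Sliding-window least-squares slope of y vs z (uniform spacing assumed);
    entries within span//2 of either end are NaN."""
    n = y.size
    out = np.full(n, np.nan)
    if n < span or span < 2:
        return out
    dz = (z[-1] - z[0]) / (n - 1) if n > 1 else 1.0
    j = np.arange(span) - (span - 1) / 2.0
    kern = j / (np.sum(j**2) * dz)
    valid = np.convolve(y, kern[::-1], mode="valid")
    h = (span - 1) // 2
    out[h:h + valid.size] = valid
    return out


def _plateau_window(
    trace: ConductanceTrace, band_center_log10: float, cfg: DecayFitConfig
) -> tuple[int, int] | None:
    """Refined [i0, i1] sample window of the plateau, or None."""
    z = trace.displacement
    ys = _smoothed_log10g(trace, cfg.smooth_points)
    in_band = np.abs(ys - band_center_log10) <= cfg.band_halfwidth_decades
    in_band &= trace.log10_g > np.log10(cfg.noise_floor_g0) + 0.3
    if not in_band.any():
        return None
    i0, i1 = _longest_true_run(in_band)
    # refine by local slope within the coarse run (with margin for the span)
    margin = cfg.slope_span
    a, b = max(0, i0 - margin), min(z.size, i1 + 1 + margin)
    slopes = _local_slopes(z[a:b], trace.log10_g[a:b], cfg.slope_span)
    flat = np.abs(slopes) * LN10 * 0.1 <= cfg.slope_threshold_a_inv  # -> A^-1
    flat &= ~np.isnan(slopes)
    if not flat.any():
        return None
    # a slope window that overlaps the fast segments exceeds the threshold,
    # so the run boundary already sits inside the plateau; a small trim
    # guards the residual boundary discretization
    j0, j1 = _longest_true_run(flat)
    j0, j1 = j0 + cfg.edge_trim, j1 - cfg.edge_trim
    if j1 - j0 + 1 < cfg.min_points:
        return None
    return a + j0, a + j1


def _longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    starts, ends = idx[::2], idx[1::2] - 1
    k = int(np.argmax(ends - starts))
    return int(starts[k]), int(ends[k])


def judge_plateau(
    trace: ConductanceTrace,
    cfg: FilterConfig | None = None,
    fit_cfg: DecayFitConfig | None = None,
) -> PlateauResult:
    """Per-trace plateau judgement from the trace's own log10 G histogram."""
    cfg = cfg or FilterConfig()
    fit_cfg = fit_cfg or DecayFitConfig()
    ys = _smoothed_log10g(trace, cfg.smooth_points)
    count, center_log10 = _best_bin_occupancy(ys, cfg)
    dz = float(np.median(np.diff(trace.displacement)))
    if count * dz < cfg.min_plateau_nm or not np.isfinite(center_log10):
        return PlateauResult(present=False)
    # presence is decided by the histogram occupancy alone; the fit window
    # is refined separately and degenerates (z_start == z_end) when the
    # plateau is too short to support a slope fit
    win = _plateau_window(trace, center_log10, fit_cfg)
    if win is None:
        in_band = np.abs(ys - center_log10) <= fit_cfg.band_halfwidth_decades
        zc = float(np.median(trace.displacement[in_band])) if in_band.any() else 0.0
        i0 = i1 = int(np.argmin(np.abs(trace.displacement - zc)))
    else:
        i0, i1 = win
    return PlateauResult(
        present=True,
        z_start=float(trace.displacement[i0]),
        z_end=float(trace.displacement[i1]),
        band_center=10.0 ** center_log10 * 1e3,
    )


def filter_plateau_traces(
    ensemble: list[ConductanceTrace],
    cfg: FilterConfig | None = None,
) -> tuple[list[ConductanceTrace], list[PlateauResult]]:
    """Remove simple-exponential traces; keep those with a plateau.

    Traces must be originated first (``meta['originated']``); un-originated
    traces are rejected outright. Returns the retained traces and the
    per-trace :class:`PlateauResult` report for the whole input ensemble.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    cfg = cfg or FilterConfig()
    retained, report = [], []
    for tr in ensemble:
        if not tr.meta.get("originated", False):
            report.append(PlateauResult(present=False))
            continue
        res = judge_plateau(tr, cfg)
        report.append(res)
        if res.present:
            retained.append(tr)
    return retained, report


def histogram2d(
    ensemble: list[ConductanceTrace],
    z_edges: np.ndarray,
    logg_edges: np.ndarray,
) -> Histogram2D:
    """Accumulate trace samples of originated traces into a 2D (z, log10 G)
    histogram; the total count equals the number of in-range samples."""
    z_edges = np.asarray(z_edges, dtype=float)
    logg_edges = np.asarray(logg_edges, dtype=float)
    counts = np.zeros((z_edges.size - 1, logg_edges.size - 1))
    for tr in ensemble:
        if not tr.meta.get("originated", True):
            continue
        h, _, _ = np.histogram2d(tr.displacement, tr.log10_g,
                                 bins=(z_edges, logg_edges))
        counts += h
    return Histogram2D(z_edges, logg_edges, counts)


def _gauss_offset(x, amp, mu, sigma, base):
    return base + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def conductance_peak(
    ensemble: list[ConductanceTrace],
    fit_range: tuple[float, float],
    n_bins: int = 60,
) -> PeakEstimate:
    """Gaussian fit of the 1D log10 G histogram over ``fit_range`` (log10
    G/G0). Returns the centre back-transformed to mG0 and the width in
    decades. A constant offset absorbs the tunnelling-decay background.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    lo, hi = fit_range
    samples = np.concatenate([tr.log10_g for tr in ensemble])
    samples = samples[(samples >= lo) & (samples <= hi)]
    if samples.size == 0:
        raise PeakFitError("no samples in fit range")
    counts, edges = np.histogram(samples, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    nz = np.flatnonzero(counts)
    if nz.size == 0:
        raise PeakFitError("degenerate histogram")
    if nz.size == 1:
        return PeakEstimate(center=10.0 ** centers[nz[0]] * 1e3,
                            sd_log10=0.0, amplitude=float(counts[nz[0]]))
    jmax = int(np.argmax(counts))
    p0 = [float(counts[jmax] - counts.min()), float(centers[jmax]), 0.1,
          float(counts.min())]
    try:
        popt, _ = curve_fit(
            _gauss_offset, centers, counts, p0=p0,
            bounds=([0.0, lo, 1e-4, 0.0], [np.inf, hi, hi - lo, np.inf]),
            maxfev=10_000)
    except RuntimeError as exc:  # pragma: no cover - pathological histograms
        raise PeakFitError(f"Gaussian fit failed: {exc}") from exc
    amp, mu, sigma, _ = popt
    return PeakEstimate(center=10.0 ** mu * 1e3, sd_log10=float(sigma),
                        amplitude=float(amp))


def _ols_slope_r2(z: np.ndarray, lng: np.ndarray) -> tuple[float, float]:
    A = np.vstack([z, np.ones_like(z)]).T
    coef, res, *_ = np.linalg.lstsq(A, lng, rcond=None)
    ss_tot = float(np.sum((lng - lng.mean()) ** 2))
    ss_res = float(res[0]) if res.size else float(np.sum((lng - A @ coef) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(coef[0]), r2


def fit_decay_constants(
    trace: ConductanceTrace,
    plateau: PlateauResult,
    cfg: DecayFitConfig | None = None,
) -> DecayFit:
    """Least-squares beta1 (within the plateau window) and beta2 (from the
    post-rupture sample down to the noise floor), both in A^-1."""
    if not plateau.present:
        raise ValueError("fit_decay_constants requires a present plateau")
    cfg = cfg or DecayFitConfig()
    z, g = trace.displacement, trace.conductance
    lng = np.log(g)

    w1 = (z >= plateau.z_start) & (z <= plateau.z_end)
    if w1.sum() < cfg.min_points:
        raise ValueError("too few samples in the plateau window")
    slope1, r2_1 = _ols_slope_r2(z[w1], lng[w1])

    ys = _smoothed_log10g(trace, cfg.smooth_points)
    center_log10 = np.log10(plateau.band_center * 1e-3)
    after = z > plateau.z_end
    dropped = ys < center_log10 - cfg.post_drop_decades
    cand = np.flatnonzero(after & dropped)
    if cand.size == 0:
        raise ValueError("no post-plateau decay segment found")
    start = int(cand[0]) + (cfg.smooth_points // 2 + 1)
    w2 = np.zeros_like(w1)
    w2[start:] = True
    w2 &= g > cfg.noise_floor_g0
    if w2.sum() < cfg.min_points:
        raise ValueError("too few samples in the post-plateau window")
    slope2, r2_2 = _ols_slope_r2(z[w2], lng[w2])

    return DecayFit(
        beta1=beta_nm_inv_to_a_inv(-slope1),
        beta2=beta_nm_inv_to_a_inv(-slope2),
        window1=(float(plateau.z_start), float(plateau.z_end)),
        window2=(float(z[start]), float(z[w2][-1]) if w2.any() else float("nan")),
        fit_quality=(r2_1, r2_2),
    )


def fit_single_decay(
    trace: ConductanceTrace, cfg: DecayFitConfig | None = None
) -> float:
    """Decay constant (A^-1) of a no-plateau trace, fitted over the full
    post-origin range down to the noise floor."""
    cfg = cfg or DecayFitConfig()
    z, g = trace.displacement, trace.conductance
    mask = (z >= 0) & (g > cfg.noise_floor_g0)
    if mask.sum() < cfg.min_points:
        raise ValueError("too few samples for a decay fit")
    slope, _ = _ols_slope_r2(z[mask], np.log(g[mask]))
    return beta_nm_inv_to_a_inv(-slope)
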