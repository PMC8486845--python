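"""Self-restoration statistics of consecutive-trace series.

For each trace in a consecutive series the dwell length -- the displacement
spent inside a conductance band bracketing the molecular plateau -- is
measured and compared against a formation threshold (0.060 nm for the
90-mer band 1.4-2.4 mG0, 0.028 nm for the 10-mer band 0.14-0.16 mG0). The
resulting boolean formation series is summarized by the formation
probability, the joint probability that adjacent traces both formed, their
ratio (1 under independence), a permutation p-value, and the longest
success run.
"""

from __future__ import annotations

import numpy as np

from .datatypes import ConductanceTrace, DwellConfig, DwellRecord, JointProbResult

__all__ = [
    "dwell_length",
    "dwell_records",
    "judge_formation",
    "restoration_stats",
    "max_consecutive_run",
    "time_axis",
    "DWELL_90MER",
    "DWELL_10MER",
    "DEFAULT_TRACE_PERIOD_S",
]

#: Dwell band and formation threshold presets.
DWELL_90MER = DwellConfig(band_low=1.4, band_high=2.4, threshold_nm=0.060)
DWELL_10MER = DwellConfig(band_low=0.14, band_high=0.16, threshold_nm=0.028)

#: Per-trace period: 30 nm pull at 31 nm/s plus the 0.3 s hybridization wait.
DEFAULT_TRACE_PERIOD_S = 30.0 / 31.0 + 0.3


def dwell_length(trace: ConductanceTrace, cfg: DwellConfig) -> float:
    """Displacement (nm) the trace spends inside [band_low, band_high] mG0.

    Each sample in the band contributes its preceding displacement
    increment; non-contiguous visits accumulate. Invariant under
    displacement-origin shifts.
    """
    g_mg0 = trace.conductance * 1e3
    in_band = (g_mg0 >= cfg.band_low) & (g_mg0 <= cfg.band_high)
    dz = np.diff(trace.displacement)
    return float(np.sum(dz[in_band[1:]]))


def dwell_records(
    ensemble: list[ConductanceTrace], cfg: DwellConfig
) -> list[DwellRecord]:
    """Dwell length and formation judgement for every trace, in order."""
    out = []
    for idx, tr in enumerate(ensemble):
        d = dwell_length(tr, cfg)
        out.append(DwellRecord(trace_index=idx, dwell=d,
                               formed=d >= cfg.threshold_nm))
    return out


def judge_formation(records: list[DwellRecord], cfg: DwellConfig) -> np.ndarray:
    """Boolean formation series: formed iff dwell >= threshold (inclusive)."""
    order = np.argsort([r.trace_index for r in records])
    dwells = np.array([r.dwell for r in records])[order]
    return dwells >= cfg.threshold_nm


def max_consecutive_run(series: np.ndarray) -> int:
    """Length of the longest all-true run."""
    best = cur = 0
    for s in np.asarray(series, dtype=bool):
        cur = cur + 1 if s else 0
        best = max(best, cur)
    return best


def restoration_stats(
    series: np.ndarray, n_perm: int = 999, seed: int = 0
) -> JointProbResult:
    """Joint-probability analysis of a boolean formation series.

    The statistic is the fraction of adjacent pairs with both traces formed;
    its null distribution under exchangeability comes from ``n_perm``
    permutations of the series (two-sided, add-one corrected). The
    independence ratio p_joint / p_form^2 is 1 for a memoryless series and
    above 1 for persistent junction formation; it is NaN when p_form = 0.
    """
    s = np.asarray(series, dtype=bool)
    if s.size < 2:
        raise ValueError("series must have length >= 2")
    p_form = float(s.mean())
    p_joint = float(np.mean(s[1:] & s[:-1]))
    ratio = p_joint / p_form**2 if p_form > 0 else float("nan")

    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    x = s.copy()
    for k in range(n_perm):
        rng.shuffle(x)
        perm_stats[k] = np.mean(x[1:] & x[:-1])
    ge = int(np.sum(perm_stats >= p_joint))
    le = int(np.sum(perm_stats <= p_joint))
    p_one = min(ge + 1, le + 1) / (n_perm + 1)
    p_value = min(1.0, 2.0 * p_one)

    return JointProbResult(
        p_form=p_form,
        p_joint_adjacent=p_joint,
        independence_ratio=ratio,
        p_value=p_value,
        max_run=max_consecutive_run(s),
    )


def time_axis(series: np.ndarray, trace_period_s: float = DEFAULT_TRACE_PERIOD_S):
    """Attach t = index * period to a formation (or dwell) series.

    Returns (times_s, series). The longest-run duration readout is
    ``max_consecutive_run(series) * trace_period_s``.
    """
    if trace_period_s <= 0:
        raise ValueError("trace_period_s must be positive")
    s = np.asarray(series)
    return np.arange(s.size) * trace_period_s, s
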