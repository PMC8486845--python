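"""Core record types shared by the trace, I-V and restoration pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class ConductanceTrace:
    """A single break-junction pull: conductance versus tip displacement.

    Parameters
    ----------
    displacement : ndarray
        Tip displacement in nm, non-decreasing.
    conductance : ndarray
        Conductance in G0 units, strictly positive.
    meta : dict
        Acquisition metadata (bias_mV, tip_velocity_nm_s, sample_rate_Hz, ...).
        ``meta['originated']`` is set by :func:`set_displacement_origin`.
    """

    displacement: np.ndarray
    conductance: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.conductance = np.asarray(self.conductance, dtype=float)
        if self.displacement.shape != self.conductance.shape:
            raise ValueError("displacement and conductance must have equal length")
        if self.displacement.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if np.any(np.diff(self.displacement) < 0):
            raise ValueError("displacement must be non-decreasing")
        if np.any(self.conductance <= 0):
            raise ValueError("conductance must be positive")

    def __len__(self) -> int:
        return int(self.displacement.size)

    @property
    def log10_g(self) -> np.ndarray:
        return np.log10(self.conductance)


@dataclass
class PlateauResult:
    """Outcome of the per-trace plateau judgement."""

    present: bool
    z_start: float = float("nan")
    z_end: float = float("nan")
    band_center: float = float("nan")  # mG0

    def __post_init__(self) -> None:
        if self.present and not (self.z_start <= self.z_end):
            raise ValueError("z_start must not exceed z_end for a present plateau")


@dataclass
class DecayFit:
    """Two-segment tunnelling decay constants of one trace (A^-1)."""

    beta1: float
    beta2: float
    window1: tuple[float, float]
    window2: tuple[float, float]
    fit_quality: tuple[float, float]  # R^2 per segment


@dataclass
class Histogram2D:
    """2D conductance-displacement histogram accumulated over an ensemble."""

    z_edges: np.ndarray
    logg_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.z_edges = np.asarray(self.z_edges, dtype=float)
        self.logg_edges = np.asarray(self.logg_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.z_edges) <= 0) or np.any(np.diff(self.logg_edges) <= 0):
            raise ValueError("histogram edges must be strictly increasing")
        if self.counts.shape != (self.z_edges.size - 1, self.logg_edges.size - 1):
            raise ValueError("counts shape inconsistent with edges")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class PeakEstimate:
    """Gaussian fit of a 1D log-conductance histogram."""

    center: float  # mG0
    sd_log10: float  # decades
    amplitude: float  # counts

    def __post_init__(self) -> None:
        if not self.center > 0:
            raise ValueError("peak center must be positive")


@dataclass
class IVSweep:
    """One bias sweep: current versus voltage."""

    bias: np.ndarray  # V
    current: np.ndarray  # A
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bias = np.asarray(self.bias, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.bias.shape != self.current.shape:
            raise ValueError("bias and current must have equal length")
        d = np.diff(self.bias)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("bias must be strictly monotone within a sweep")


@dataclass
class FNSpectrum:
    """Fowler-Nordheim transform of one polarity of a sweep."""

    inv_bias: np.ndarray  # 1/V
    fn_value: np.ndarray  # log10(|I| / V^2)

    def __post_init__(self) -> None:
        self.inv_bias = np.asarray(self.inv_bias, dtype=float)
        self.fn_value = np.asarray(self.fn_value, dtype=float)
        if self.inv_bias.shape != self.fn_value.shape:
            raise ValueError("inv_bias and fn_value must have equal length")


@dataclass
class TransitionVoltage:
    """Per-sweep transition voltages; None when the minimum is not interior."""

    v_trans_pos: float | None = None
    v_trans_neg: float | None = None


@dataclass
class DwellConfig:
    """Conductance band and formation threshold for dwell-length analysis."""

    band_low: float  # mG0
    band_high: float  # mG0
    threshold_nm: float

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError("require 0 < band_low < band_high")
        if not self.threshold_nm > 0:
            raise ValueError("threshold_nm must be positive")


@dataclass
class DwellRecord:
    """Dwell length of one trace inside the configured band."""

    trace_index: int
    dwell: float  # nm
    formed: bool

    def __post_init__(self) -> None:
        if self.dwell < 0:
            raise ValueError("dwell must be non-negative")


@dataclass
class JointProbResult:
    """Joint-probability statistics of a formation series."""

    p_form: float
    p_joint_adjacent: float
    independence_ratio: float  # p_joint / p_form^2; NaN when p_form == 0
    p_value: float
    max_run: int
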