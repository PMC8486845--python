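"""Seeded generators for every input of the analysis pipeline.

The module emulates the raw data of an STM break-junction campaign on a
DNA-zipper junction:

* two-segment exponentially decaying conductance-displacement (G-z) traces
  with a molecular plateau (:func:`gen_bj_trace`),
* bimodal current-voltage sweep ensembles -- a molecular high-conductance
  state described by a symmetric single-level (Lorentzian-transmission)
  model and a tunnelling low state with a linear-plus-cubic I-V
  (:func:`gen_iv_sweep`),
* consecutive-trace series with persistent or independent junction
  formation (:func:`gen_consecutive_series`),
* random DNA sequences standing in for the proprietary oligos
  (:func:`gen_sequence`).

Trace shape
-----------
A molecular trace is piecewise linear in (z, ln G): a fast pre-plateau decay
at ``beta2`` from ``start_conductance`` down to the plateau entry, a plateau
segment of drawn length L with slope ``-beta1`` geometrically centred on
``plateau_conductance``, an abrupt rupture drop (the junction breaks), and a
post-rupture tunnelling decay at ``beta2`` down to the noise floor.
Multiplicative noise is Gaussian in log10 G. The plateau centring makes the
displacement spent inside a symmetric conductance band equal to L up to
sampling discretization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import beta_a_inv_to_nm_inv
from .datatypes import ConductanceTrace, IVSweep
from .iv_models import single_level_current

__all__ = [
    "TraceGenParams",
    "IVGenParams",
    "SeriesGenParams",
    "gen_bj_trace",
    "gen_bj_ensemble",
    "gen_iv_sweep",
    "gen_iv_ensemble",
    "gen_consecutive_series",
    "draw_formation_series",
    "gen_sequence",
    "preset_trace",
    "preset_iv",
    "preset_series",
]

# Fraction by which conductance drops at the rupture that ends the plateau.
RUPTURE_DROP = 0.4
# Flat tail recorded at the noise floor after the decay bottoms out (nm).
TAIL_NM = 0.2


@dataclass
class TraceGenParams:
    """Parameters of the G-z trace generator (conductances in mG0 where noted)."""

    plateau_conductance: float = 1.9  # mG0
    plateau_length_mean: float = 0.15  # nm
    plateau_length_sd: float = 0.075  # nm
    beta1: float = 0.27  # A^-1, in-plateau decay
    beta2: float = 2.0  # A^-1, post-plateau decay
    beta_bare: float = 2.2  # A^-1, no-molecule decay
    start_conductance: float = 100.0  # mG0
    noise_sd_log10g: float = 0.1  # decades
    sample_rate: float = 20_000.0  # Hz
    tip_velocity: float = 31.0  # nm/s
    noise_floor: float = 10 ** -6.5  # G0
    plateau_probability: float = 0.8

    def __post_init__(self) -> None:
        for name in ("beta1", "beta2", "beta_bare", "sample_rate", "tip_velocity",
                     "plateau_length_mean", "plateau_length_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sample_rate <= 0 or self.tip_velocity <= 0:
            raise ValueError("sample_rate and tip_velocity must be positive")
        if not 0 <= self.plateau_probability <= 1:
            raise ValueError("plateau_probability must be in [0, 1]")
        if not (self.start_conductance * 1e-3 > self.plateau_conductance * 1e-3
                > self.noise_floor):
            raise ValueError("require start > plateau > noise floor (G0 units)")

    @property
    def dz(self) -> float:
        """Displacement step per sample, nm."""
        return self.tip_velocity / self.sample_rate


@dataclass
class IVGenParams:
    """Parameters of the I-V sweep generator."""

    level_energy: float = 0.35  # eV, single-level position
    coupling: float = 0.05  # eV, level broadening
    low_state_linear: float = 1.0e-10  # A/V
    low_state_cubic: float = 1.2e-10  # A/V^3
    sweep_min: float = -1.1  # V
    sweep_max: float = 1.1  # V
    n_points: int = 100  # 5 ms sweep sampled at 20 kHz
    high_state_fraction: float = 0.5
    noise_sd_logi: float = 0.05  # decades

    def __post_init__(self) -> None:
        if not (self.sweep_min < 0 < self.sweep_max):
            raise ValueError("sweep range must span 0")
        if self.coupling <= 0:
            raise ValueError("coupling must be positive")
        if not 0 <= self.high_state_fraction <= 1:
            raise ValueError("high_state_fraction must be in [0, 1]")
        if self.n_points < 4:
            raise ValueError("n_points too small")


@dataclass
class SeriesGenParams:
    """Parameters of the consecutive-trace series generator."""

    n_traces: int = 700
    mode: str = "persistent"  # persistent | independent | simulator-driven
    p_form: float = 0.8
    p_persist: float = 0.95
    dwell_given_formed_mean: float = 0.15  # nm
    dwell_given_formed_sd: float = 0.075  # nm
    dwell_given_unformed_mean: float = 0.0  # nm; 0 -> bare decay, no plateau
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_traces < 1:
            raise ValueError("n_traces must be >= 1")
        for name in ("p_form", "p_persist"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mode not in ("persistent", "independent", "simulator-driven"):
            raise ValueError(f"unknown mode: {self.mode!r}")


def preset_trace(name: str) -> TraceGenParams:
    """Trace-generator presets: ``'90mer'``, ``'10mer'`` or ``'bare'``."""
    if name == "90mer":
        return TraceGenParams()
    if name == "10mer":
        return TraceGenParams(plateau_conductance=0.15,
                              plateau_length_mean=0.07,
                              plateau_length_sd=0.035)
    if name == "bare":
        return TraceGenParams(plateau_probability=0.0)
    raise ValueError(f"unknown preset: {name!r}")


def preset_iv(name: str = "90mer") -> IVGenParams:
    """I-V generator preset with the level energy tuned so the high-state
    Fowler-Nordheim minimum sits at 0.4 V (computed lazily by :mod:`tvs`)."""
    if name != "90mer":
        raise ValueError(f"unknown preset: {name!r}")
    from .tvs import tune_level_energy

    p = IVGenParams()
    return replace(p, level_energy=tune_level_energy(0.4, p))


def preset_series(name: str) -> SeriesGenParams:
    """Series presets: persistent 90mer-like, independent 10mer-like."""
    if name == "90mer":
        return SeriesGenParams(mode="persistent", p_form=0.8, p_persist=0.95)
    if name == "10mer":
        return SeriesGenParams(mode="independent", p_form=0.3,
                               dwell_given_formed_mean=0.07,
                               dwell_given_formed_sd=0.035)
    raise ValueError(f"unknown preset: {name!r}")


def _lognormal_from_mean_sd(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from a log-normal parameterized by its arithmetic mean and sd."""
    if sd == 0:
        return mean
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def gen_bj_trace(
    params: TraceGenParams,
    with_plateau: bool = True,
    seed: int | np.random.Generator = 0,
    plateau_length: float | None = None,
) -> ConductanceTrace:
    """Generate one conductance-displacement trace.

    ``plateau_length`` overrides the drawn plateau length (nm); the drawn
    value is stored in ``meta['plateau_length_nm']`` for ground-truth tests.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dz = params.dz
    b1 = beta_a_inv_to_nm_inv(params.beta1)  # nm^-1, natural log
    b2 = beta_a_inv_to_nm_inv(params.beta2)
    bb = beta_a_inv_to_nm_inv(params.beta_bare)
    g_start = params.start_conductance * 1e-3  # G0
    g_floor = params.noise_floor
    meta = {
        "bias_mV": 20.0,
        "tip_velocity_nm_s": params.tip_velocity,
        "sample_rate_Hz": params.sample_rate,
        "with_plateau": bool(with_plateau),
    }

    if with_plateau:
        if plateau_length is None:
            plateau_length = _lognormal_from_mean_sd(
                rng, params.plateau_length_mean, params.plateau_length_sd)
        length = float(max(plateau_length, 0.0))
        gp = params.plateau_conductance * 1e-3  # G0, geometric plateau centre
        g_p_start = gp * math.exp(0.5 * b1 * length)
        g_p_end = gp * math.exp(-0.5 * b1 * length)
        z1 = math.log(g_start / g_p_start) / b2 if g_p_start < g_start else 0.0
        z2 = z1 + length
        g_after_drop = RUPTURE_DROP * g_p_end
        z3 = z2 + math.log(g_after_drop / g_floor) / b2
        z_total = z3 + TAIL_NM
        z = np.arange(0.0, z_total, dz)
        ln_g = np.empty_like(z)
        pre = z < z1
        mid = (z >= z1) & (z < z2)
        post = z >= z2
        ln_g[pre] = math.log(g_start) - b2 * z[pre]
        ln_g[mid] = math.log(g_p_start) - b1 * (z[mid] - z1)
        ln_g[post] = math.log(g_after_drop) - b2 * (z[post] - z2)
        meta["plateau_length_nm"] = length
    else:
        z3 = math.log(g_start / g_floor) / bb
        z = np.arange(0.0, z3 + TAIL_NM, dz)
        ln_g = math.log(g_start) - bb * z

    log10_g = ln_g / math.log(10.0)
    if params.noise_sd_log10g > 0:
        log10_g = log10_g + rng.normal(0.0, params.noise_sd_log10g, size=z.size)
    g = 10.0 ** log10_g
    np.clip(g, g_floor, g_start, out=g)
    return ConductanceTrace(z, g, meta)


def gen_bj_ensemble(
    params: TraceGenParams, n_traces: int, seed: int = 0
) -> list[ConductanceTrace]:
    """Generate an ensemble; each trace gets a plateau with probability
    ``params.plateau_probability`` (bare decay otherwise)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_traces):
        has_plateau = rng.random() < params.plateau_probability
        out.append(gen_bj_trace(params, with_plateau=has_plateau, seed=rng))
    return out


def gen_iv_sweep(
    state: str,
    params: IVGenParams,
    seed: int | np.random.Generator = 0,
    noise: bool = True,
) -> IVSweep:
    """Generate one I-V sweep in the ``'high'`` (molecular, single-level) or
    ``'low'`` (tunnelling, linear + cubic) state. I(0) = 0 exactly."""
    if state not in ("high", "low"):
        raise ValueError(f"unknown state: {state!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = np.linspace(params.sweep_min, params.sweep_max, params.n_points)
    if state == "high":
        i = single_level_current(v, params.level_energy, params.coupling)
    else:
        i = params.low_state_linear * v + params.low_state_cubic * v**3
    if noise and params.noise_sd_logi > 0:
        i = i * 10.0 ** rng.normal(0.0, params.noise_sd_logi, size=v.size)
    return IVSweep(v, i, {"state": state})


def gen_iv_ensemble(
    params: IVGenParams, n_sweeps: int, seed: int = 0
) -> tuple[list[IVSweep], list[str]]:
    """Generate a mixed high/low ensemble; returns sweeps and true labels."""
    rng = np.random.default_rng(seed)
    sweeps, labels = [], []
    for _ in range(n_sweeps):
        state = "high" if rng.random() < params.high_state_fraction else "low"
        sweeps.append(gen_iv_sweep(state, params, seed=rng))
        labels.append(state)
    return sweeps, labels


def draw_formation_series(params: SeriesGenParams) -> np.ndarray:
    """Draw the boolean junction-formation series.

    ``persistent``: two-state Markov chain with stationary probability
    ``p_form`` and self-transition P(formed -> formed) = ``p_persist``;
    ``independent``: i.i.d. Bernoulli(``p_form``).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_traces
    if params.mode == "independent":
        return rng.random(n) < params.p_form
    if params.mode != "persistent":
        raise ValueError("draw_formation_series supports persistent/independent modes")
    p, q = params.p_form, params.p_persist
    # stationary pi(formed) = p requires P(unformed -> formed) = p (1 - q) / (1 - p)
    if p >= 1.0:
        return np.ones(n, dtype=bool)
    p01 = p * (1.0 - q) / (1.0 - p)
    if p01 > 1.0:
        raise ValueError("p_persist too small for the requested p_form")
    states = np.empty(n, dtype=bool)
    u = rng.random(n)
    states[0] = u[0] < p
    for i in range(1, n):
        stay = q if states[i - 1] else 1.0 - p01
        states[i] = u[i] < stay if states[i - 1] else u[i] >= stay
    return states


def gen_consecutive_series(
    params: SeriesGenParams,
    trace_params: TraceGenParams | None = None,
) -> list[ConductanceTrace]:
    """Generate a consecutive-trace series with the configured formation
    dynamics. Formed traces carry a plateau with dwell drawn from the formed
    distribution; unformed traces decay bare (or carry a short plateau when
    ``dwell_given_unformed_mean`` > 0). True states are stored in
    ``meta['formed_truth']``."""
    if trace_params is None:
        trace_params = preset_trace("90mer")
    if params.mode == "simulator-driven":
        from .zipper_sim import gen_simulated_series

        return gen_simulated_series(params, trace_params)
    states = draw_formation_series(params)
    rng = np.random.default_rng([params.seed, 1])
    out = []
    for idx, formed in enumerate(states):
        if formed:
            length = _lognormal_from_mean_sd(
                rng, params.dwell_given_formed_mean, params.dwell_given_formed_sd)
            tr = gen_bj_trace(trace_params, with_plateau=True, seed=rng,
                              plateau_length=length)
        elif params.dwell_given_unformed_mean > 0:
            length = float(rng.exponential(params.dwell_given_unformed_mean))
            tr = gen_bj_trace(trace_params, with_plateau=True, seed=rng,
                              plateau_length=length)
        else:
            tr = gen_bj_trace(trace_params, with_plateau=False, seed=rng)
        tr.meta["trace_index"] = idx
        tr.meta["formed_truth"] = bool(formed)
        out.append(tr)
    return out


_BASES = np.array(list("ACGT"))


def gen_sequence(n_bp: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """Random DNA sequence of length ``n_bp`` with expected GC content
    ``gc_fraction``; deterministic for a fixed seed."""
    if n_bp < 2:
        raise ValueError("n_bp must be >= 2")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    return "".join(rng.choice(_BASES, size=n_bp, p=[p_at, p_gc, p_gc, p_at]))
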