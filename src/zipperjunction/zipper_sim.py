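"""Sequence-dependent 1D zipper model of a tethered DNA duplex under pulling.

The junction geometry mirrors the zipper configuration: both thiol linkers
sit at the same duplex end, so the pulled load path runs tip -> spring ->
unzipped single strand (n_open nucleotides) -> fork -> unzipped single
strand of the complementary strand -> spring -> surface. The state of the
duplex is reduced to the fork coordinate n_open (base pairs unzipped from
the tethered end); rupture of the junction proceeds by unzipping rather
than Au-S bond breaking.

Components
----------
* nearest-neighbour (NN) opening free energies from the embedded unified
  dinucleotide DH/DS parameter set (1 M NaCl reference; salt corrections
  deliberately omitted),
* freely-jointed-chain (FJC) elasticity of the released single strands
  (Langevin function; 0.63 nm contour and 1.5 nm Kuhn length per
  nucleotide by default),
* two Hookean springs of 8.5 N/m in series modelling the Au-S/Au-Au
  bridges,
* a Metropolis kinetic Monte Carlo chain over n_open with proposal moves
  +-1 at a fixed attempt rate, driven by a pull(30 nm)-hold-return (or
  release) protocol of the tip.

At fixed tip height the chain samples the exact Boltzmann distribution of
E(n) = sum of pair opening costs + mechanical free energy Phi(n, z); during
tip motion z advances on a fine grid (quasi-static discretization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KCAL_PER_MOL_TO_PN_NM, beta_a_inv_to_nm_inv, kt_pn_nm
from .datatypes import ConductanceTrace

__all__ = [
    "NN_DH_DS",
    "Duplex",
    "ZipperParams",
    "Protocol",
    "Trajectory",
    "nn_step_free_energies",
    "duplex_free_energy",
    "fjc_extension",
    "fjc_helmholtz_per_nt",
    "force_balance",
    "mechanical_free_energy",
    "fork_energies",
    "kmc_run",
    "sample_fork_occupancy",
    "unzip_force_plateau",
    "ConductanceMap",
    "junction_conductance",
    "trace_from_trajectory",
    "gen_simulated_series",
]

# Unified dinucleotide nearest-neighbour parameters (1 M NaCl):
# 5'->3' step -> (dH kcal/mol, dS cal/mol/K). Reverse-complement symmetric.
NN_DH_DS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

# Duplex initiation terms (per terminal pair): G*C and A*T ends.
NN_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}


def nn_step_free_energies(sequence: str, temperature: float = 300.0) -> np.ndarray:
    """Per-step pairing free energies (kcal/mol, positive = cost to open)
    of each dinucleotide step of the duplex at the given temperature.

    The total duplex stability (without initiation) equals the sum, and is
    invariant under reverse complementation.
    """
    seq = sequence.upper()
    if any(b not in "ACGT" for b in seq):
        raise ValueError(f"unknown characters in sequence: {sequence!r}")
    if len(seq) < 2:
        raise ValueError("need at least 2 bases")
    out = np.empty(len(seq) - 1)
    for i in range(len(seq) - 1):
        dh, ds = NN_DH_DS[seq[i:i + 2]]
        out[i] = -(dh - temperature * ds * 1e-3)
    return out


def duplex_free_energy(sequence: str, temperature: float = 300.0) -> float:
    """Total hybridization free energy (kcal/mol, negative = stable duplex),
    including the two terminal initiation terms."""
    steps = nn_step_free_energies(sequence, temperature)
    seq = sequence.upper()
    total = -float(steps.sum())
    for base in (seq[0], seq[-1]):
        dh, ds = NN_INIT[base]
        total += dh - temperature * ds * 1e-3
    return total


@dataclass
class Duplex:
    """A duplex identified by one strand (5'->3') and its per-step opening
    free energies at the working temperature."""

    sequence: str
    step_free_energies: np.ndarray  # kcal/mol, length n_bp - 1
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.step_free_energies = np.asarray(self.step_free_energies, dtype=float)
        if len(self.sequence) != self.step_free_energies.size + 1:
            raise ValueError("step_free_energies must have length n_bp - 1")
        if np.any(self.step_free_energies <= 0):
            raise ValueError("duplex must favour the closed state "
                             "(positive opening cost per step)")

    @classmethod
    def from_sequence(cls, sequence: str, temperature: float = 300.0) -> "Duplex":
        return cls(sequence, nn_step_free_energies(sequence, temperature), temperature)

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    def pair_opening_costs(self) -> np.ndarray:
        """Per-base-pair opening costs (kcal/mol, length n_bp): the NN step
        energies distributed half to each flanking pair, so the total
        equals the plain step sum and is reverse-complement invariant."""
        s = self.step_free_energies
        costs = np.zeros(self.n_bp)
        costs[:-1] += 0.5 * s
        costs[1:] += 0.5 * s
        return costs


@dataclass
class ZipperParams:
    """Mechanical and kinetic parameters of the zipper model."""

    k_spring: float = 8.5  # N/m per spring (Au-Au bond stiffness)
    temperature: float = 300.0  # K
    contour_per_nt: float = 0.63  # nm of ssDNA contour per nucleotide
    kuhn_length: float = 1.5  # nm
    attempt_rate: float = 1.0e6  # KMC attempt frequency, s^-1
    rupture_force: float = 1.5  # nN, Au-S/Au-Au breaking threshold
    duplex_rise: float = 0.34  # nm/bp, B-form rise (geometry bookkeeping)
    slack_nm: float = 2.0  # fixed duplex-end geometry offset
    #: flexible thiol-linker/terminal geometry in the load path, expressed as
    #: FJC nucleotide-equivalents (total over both strands); 0 gives the pure
    #: Hookean spring limit at n_open = 0
    linker_nt: int = 4

    def __post_init__(self) -> None:
        for name in ("k_spring", "temperature", "contour_per_nt", "kuhn_length",
                     "attempt_rate", "rupture_force", "duplex_rise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.linker_nt < 0:
            raise ValueError("linker_nt must be >= 0")

    @property
    def k_spring_pn_nm(self) -> float:
        return self.k_spring * 1000.0  # N/m -> pN/nm

    @property
    def kt(self) -> float:
        return kt_pn_nm(self.temperature)


@dataclass
class Protocol:
    """Tip schedule: pull at constant velocity, hold, then return or release."""

    pull_distance: float = 30.0  # nm
    pull_velocity: float = 31.0  # nm/s
    hold_time: float = 0.3  # s
    return_tip: bool = True  # move back to the start position
    release_after_pull: bool = False  # decouple the springs instead
    settle_time: float = 0.5  # s of free evolution after return/release

    def __post_init__(self) -> None:
        if self.pull_distance < 0:
            raise ValueError("pull_distance must be >= 0")
        if self.pull_velocity <= 0:
            raise ValueError("pull_velocity must be positive")
        if self.return_tip and self.release_after_pull:
            raise ValueError("choose either return_tip or release_after_pull")


@dataclass
class Trajectory:
    """Sampled time course of the junction state."""

    time: np.ndarray  # s
    z_tip: np.ndarray  # nm
    n_open: np.ndarray  # unzipped pairs counted from the tethered end
    #: tether force in pN, time-averaged over the sampling stride (the
    #: bandwidth-limited observable; microstate fluctuations are faster
    #: than any force probe)
    force: np.ndarray
    n_bp: int
    termination: str = "completed"  # completed | strand_separation | rupture
    pair_state: list[str] | None = None  # optional per-frame open/closed bits
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.n_open = np.asarray(self.n_open, dtype=int)
        if np.any((self.n_open < 0) | (self.n_open > self.n_bp)):
            raise ValueError("n_open out of [0, n_bp]")
        if np.any(np.asarray(self.force) < 0):
            raise ValueError("force must be non-negative")

    @property
    def n_duplex(self) -> np.ndarray:
        """Base pairs remaining in the duplex region per frame."""
        return self.n_bp - self.n_open

    def pair_state_at(self, frame: int) -> np.ndarray:
        """Boolean open/closed state per pair (True = open) at a frame,
        under the fork model (pairs open sequentially from the tether)."""
        k = int(self.n_open[frame])
        state = np.zeros(self.n_bp, dtype=bool)
        state[:k] = True
        return state


# ---------------------------------------------------------------------------
# polymer elasticity and force balance


def _langevin(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-4
    with np.errstate(over="ignore", invalid="ignore"):
        full = 1.0 / np.tanh(np.where(small, 1.0, u)) - 1.0 / np.where(small, 1.0, u)
    return np.where(small, u / 3.0 - u**3 / 45.0, full)


def fjc_extension(force_pn: float | np.ndarray, params: ZipperParams) -> np.ndarray:
    """FJC extension per nucleotide (nm) at the given force (pN): the
    Langevin function of f b / kT scaled by the contour per nucleotide.
    Strictly increasing in force; saturates at ``contour_per_nt``."""
    f = np.asarray(force_pn, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be >= 0")
    u = f * params.kuhn_length / params.kt
    return params.contour_per_nt * _langevin(u)


def _fjc_gibbs_per_nt(f: np.ndarray, params: ZipperParams) -> np.ndarray:
    """FJC Gibbs free energy per nucleotide at force f (pN nm):
    g(f) = -(c/b) kT ln(sinh u / u)."""
    f = np.asarray(f, dtype=float)
    u = f * params.kuhn_length / params.kt
    pref = params.contour_per_nt / params.kuhn_length * params.kt
    out = np.empty_like(u)
    small = u < 1e-4
    big = u > 30.0
    mid = ~small & ~big
    out[small] = u[small] ** 2 / 6.0
    out[mid] = np.log(np.sinh(u[mid]) / u[mid])
    out[big] = u[big] - math.log(2.0) - np.log(u[big])
    return -pref * out


def fjc_helmholtz_per_nt(f: np.ndarray, params: ZipperParams) -> np.ndarray:
    """FJC Helmholtz free energy per nucleotide (pN nm) at the extension
    reached under force f, via the Legendre transform f*x + g(f)."""
    f = np.asarray(f, dtype=float)
    return f * fjc_extension(f, params) + _fjc_gibbs_per_nt(f, params)


def _extension(f: np.ndarray, n_open: int, params: ZipperParams) -> np.ndarray:
    """Total reach beyond the slack at force f: springs in series plus the
    2 * n_open released nucleotides plus the flexible linker segment."""
    nt = 2.0 * n_open + params.linker_nt
    return 2.0 * f / params.k_spring_pn_nm + nt * fjc_extension(f, params)


def force_balance(n_open: int, z_tip: float, params: ZipperParams) -> float:
    """Equilibrium tether force (pN) at fixed fork position and tip height.

    Solves extension(f) = z_tip - slack by bracketed root finding; returns
    0 when the tip is within the slack. The returned force satisfies the
    extension equation to better than 1e-9 nm.
    """
    from scipy.optimize import brentq

    if not 0 <= n_open:
        raise ValueError("n_open must be >= 0")
    target = z_tip - params.slack_nm
    if target <= 0:
        return 0.0
    f_hi = params.k_spring_pn_nm / 2.0 * target + 1.0
    return float(brentq(lambda f: float(_extension(np.float64(f), n_open, params)) - target,
                        0.0, f_hi, xtol=1e-12, rtol=8.9e-16))


def _solve_force_grid(n_open: int, z_grid: np.ndarray, params: ZipperParams,
                      n_iter: int = 80) -> np.ndarray:
    """Vectorized bisection for the tether force on a z grid."""
    target = np.maximum(z_grid - params.slack_nm, 0.0)
    lo = np.zeros_like(target)
    hi = params.k_spring_pn_nm / 2.0 * target + 1.0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        under = _extension(mid, n_open, params) < target
        lo = np.where(under, mid, lo)
        hi = np.where(under, hi, mid)
    f = 0.5 * (lo + hi)
    return np.where(target <= 0.0, 0.0, f)


def mechanical_free_energy(
    n_open: int, z_tip: float, params: ZipperParams
) -> float:
    """Helmholtz free energy (pN nm) of springs + released ssDNA at fixed
    tip height, evaluated at the equilibrium force."""
    f = force_balance(n_open, z_tip, params)
    fa = np.float64(f)
    nt = 2.0 * n_open + params.linker_nt
    return float(fa**2 / params.k_spring_pn_nm
                 + nt * fjc_helmholtz_per_nt(fa, params))


def fork_energies(duplex: Duplex, params: ZipperParams, z_tip: float) -> np.ndarray:
    """Total free energy E(n) (pN nm) over all fork states n = 0..n_bp at a
    fixed tip height; the Boltzmann weights of exp(-E/kT) are the exact
    stationary law of the KMC chain at frozen protocol."""
    costs = duplex.pair_opening_costs() * KCAL_PER_MOL_TO_PN_NM
    cum = np.concatenate(([0.0], np.cumsum(costs)))
    phi = np.array([mechanical_free_energy(n, z_tip, params)
                    for n in range(duplex.n_bp + 1)])
    return cum + phi


def _phi_force_tables(
    n_bp: int, params: ZipperParams, z_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    nz = z_grid.size
    force = np.empty((n_bp + 1, nz))
    phi = np.empty((n_bp + 1, nz))
    for n in range(n_bp + 1):
        f = _solve_force_grid(n, z_grid, params)
        force[n] = f
        nt = 2.0 * n + params.linker_nt
        phi[n] = f**2 / params.k_spring_pn_nm + nt * fjc_helmholtz_per_nt(f, params)
    return force, phi


# ---------------------------------------------------------------------------
# kinetic Monte Carlo


def _acceptance(delta_e: np.ndarray, kt: float) -> np.ndarray:
    return np.exp(-np.maximum(delta_e, 0.0) / kt)


def kmc_run(
    duplex: Duplex,
    params: ZipperParams | None = None,
    protocol: Protocol | None = None,
    seed: int = 0,
    z_grid_step: float = 0.01,
    frame_stride: int = 2000,
    record_pair_state: bool = False,
) -> Trajectory:
    """Metropolis KMC of the fork coordinate under the tip protocol.

    Proposals are +-1 moves of n_open at ``params.attempt_rate``; acceptance
    exp(-dE/kT) with dE the pair opening cost minus the mechanical free
    energy released at fixed z_tip. Out-of-range proposals are rejected
    (reflecting boundary). The run terminates early on strand separation
    (n_open = n_bp under tension) or when the tether force exceeds the Au-S
    rupture threshold. Bit-reproducible for a fixed seed and stride.
    """
    params = params or ZipperParams()
    protocol = protocol or Protocol()
    rng = np.random.default_rng(seed)
    kt = params.kt
    n_bp = duplex.n_bp
    costs = duplex.pair_opening_costs() * KCAL_PER_MOL_TO_PN_NM
    dt = 1.0 / params.attempt_rate
    rupture_pn = params.rupture_force * 1000.0

    n_steps_z = max(1, int(round(protocol.pull_distance / z_grid_step)))
    z_grid = np.linspace(0.0, protocol.pull_distance, n_steps_z + 1)
    force_tab, phi_tab = _phi_force_tables(n_bp, params, z_grid)
    # per z-index move acceptances
    d_open = phi_tab[1:, :] - phi_tab[:-1, :] + costs[:, None]
    acc_open_tab = _acceptance(d_open, kt)
    acc_close_tab = _acceptance(-d_open, kt)
    acc_open_free = _acceptance(costs, kt)  # springs decoupled (release)

    attempts_per_z = max(1, int(round(
        params.attempt_rate * z_grid_step / protocol.pull_velocity)))

    # schedule: (kind, z-index sequence or duration)
    segments: list[tuple[str, object]] = [("pull", range(1, n_steps_z + 1))]
    if protocol.hold_time > 0:
        segments.append(("hold", protocol.hold_time))
    if protocol.return_tip:
        segments.append(("return", range(n_steps_z - 1, -1, -1)))
        if protocol.settle_time > 0:
            segments.append(("settle", protocol.settle_time))
    elif protocol.release_after_pull:
        segments.append(("release", protocol.settle_time or protocol.hold_time))

    n = 0
    t = 0.0
    j = 0  # current z index
    termination = "completed"
    times, zs, ns, forces = [0.0], [0.0], [0], [float(force_tab[0, 0])]
    states: list[str] | None = [] if record_pair_state else None
    if record_pair_state:
        states.append("0" * n_bp)

    def record(force_now: float) -> None:
        times.append(t)
        zs.append(float(z_grid[j]))
        ns.append(n)
        forces.append(force_now)
        if states is not None:
            states.append("1" * n + "0" * (n_bp - n))

    def run_chunk(m: int, released: bool) -> tuple[str | None, float]:
        """Advance m attempts at the current z index; returns a termination
        cause (or None) and the time-averaged tether force over the chunk."""
        nonlocal n, t
        if released:
            acc_open = acc_open_free.tolist()
            acc_close = [1.0] * n_bp
            ftab = [0.0] * (n_bp + 1)
            sep_tension = False
        else:
            acc_open = acc_open_tab[:, j].tolist()
            acc_close = acc_close_tab[:, j].tolist()
            ftab = force_tab[:, j].tolist()
            sep_tension = force_tab[n_bp, j] > 0.5
        u = rng.random((m, 2))
        nn = n
        fsum = 0.0
        for i in range(m):
            if u[i, 0] < 0.5:
                if nn < n_bp and u[i, 1] < acc_open[nn]:
                    nn += 1
                    if nn == n_bp and sep_tension:
                        n = nn
                        t += (i + 1) * dt
                        return "strand_separation", (fsum + ftab[nn]) / (i + 1)
            elif nn > 0 and u[i, 1] < acc_close[nn - 1]:
                nn -= 1
            fsum += ftab[nn]
        n = nn
        t += m * dt
        return None, fsum / m

    for kind, payload in segments:
        if termination != "completed":
            break
        if kind in ("pull", "return"):
            for jz in payload:  # type: ignore[union-attr]
                j = jz
                cause, f_now = run_chunk(attempts_per_z, released=False)
                record(f_now)
                if cause is not None:
                    termination = cause
                    break
                if f_now > rupture_pn:
                    termination = "rupture"
                    break
        else:  # hold / settle / release
            duration = float(payload)  # type: ignore[arg-type]
            total = int(round(duration * params.attempt_rate))
            released = kind == "release"
            done = 0
            while done < total:
                m = min(frame_stride, total - done)
                cause, f_now = run_chunk(m, released=released)
                done += m
                record(f_now)
                if cause is not None:
                    termination = cause
                    break
                if kind in ("settle", "release") and n == 0:
                    break
            if termination != "completed":
                break

    return Trajectory(
        time=np.asarray(times), z_tip=np.asarray(zs),
        n_open=np.asarray(ns, dtype=int), force=np.asarray(forces),
        n_bp=n_bp, termination=termination, pair_state=states,
        meta={"seed": seed, "z_grid_step": z_grid_step,
              "attempts_per_z": attempts_per_z},
    )


def sample_fork_occupancy(
    duplex: Duplex,
    params: ZipperParams,
    z_tip: float,
    n_steps: int,
    seed: int = 0,
    burn_in: int = 0,
) -> np.ndarray:
    """Occupancy counts of the fork coordinate from a frozen-protocol KMC
    run at fixed tip height (exact per-state energies, no z grid)."""
    rng = np.random.default_rng(seed)
    kt = params.kt
    n_bp = duplex.n_bp
    energies = fork_energies(duplex, params, z_tip)
    d_open = np.diff(energies)
    acc_open = _acceptance(d_open, kt).tolist()
    acc_close = _acceptance(-d_open, kt).tolist()
    counts = np.zeros(n_bp + 1, dtype=np.int64)
    n = int(np.argmin(energies))  # start at the modal state
    u = rng.random((n_steps + burn_in, 2))
    for i in range(n_steps + burn_in):
        if u[i, 0] < 0.5:
            if n < n_bp and u[i, 1] < acc_open[n]:
                n += 1
        elif n > 0 and u[i, 1] < acc_close[n - 1]:
            n -= 1
        if i >= burn_in:
            counts[n] += 1
    return counts


def unzip_force_plateau(trajectory: Trajectory) -> float:
    """Mean tether force (pN) over frames in which the fork advanced since
    the previous sampled frame -- the unzipping force plateau."""
    dn = np.diff(trajectory.n_open)
    opened = dn > 0
    if not opened.any():
        raise ValueError("trajectory contains no unzipping phase")
    return float(np.mean(trajectory.force[1:][opened]))


# ---------------------------------------------------------------------------
# coupling to the conductance pipeline


@dataclass
class ConductanceMap:
    """Mapping from junction state to conductance for simulator-driven
    trace generation: the plateau preset while the junction is intact,
    bare tunnelling decay from the origin level otherwise."""

    plateau_mg0: float = 1.9
    beta_bare: float = 2.2  # A^-1
    origin_mg0: float = 50.0
    noise_floor_g0: float = 10 ** -6.5


def junction_conductance(
    z_tip: float, n_open: int, n_bp: int, cfg: ConductanceMap | None = None,
    intact: bool | None = None,
) -> float:
    """Conductance (mG0) of one trajectory frame."""
    cfg = cfg or ConductanceMap()
    if intact is None:
        intact = n_open < n_bp
    if intact:
        return cfg.plateau_mg0
    b = beta_a_inv_to_nm_inv(cfg.beta_bare)
    g = cfg.origin_mg0 * math.exp(-b * max(z_tip, 0.0))
    return max(g, cfg.noise_floor_g0 * 1e3)


def trace_from_trajectory(
    trajectory: Trajectory, cfg: ConductanceMap | None = None
) -> ConductanceTrace:
    """Synthetic G-z trace of the pull phase of a trajectory."""
    cfg = cfg or ConductanceMap()
    zs = trajectory.z_tip
    pull_end = int(np.argmax(zs)) + 1
    z = zs[:pull_end]
    sep = trajectory.termination == "strand_separation"
    g = np.array([
        junction_conductance(z[i], int(trajectory.n_open[i]), trajectory.n_bp, cfg,
                             intact=not (sep and i == pull_end - 1))
        for i in range(pull_end)
    ]) * 1e-3
    # if the junction separated, continue the bare decay to the full pull
    if sep and z.size and z[-1] < zs.max():
        extra = np.arange(z[-1] + 0.01, zs.max(), 0.01)
        gx = np.array([junction_conductance(ze, trajectory.n_bp, trajectory.n_bp,
                                            cfg, intact=False) for ze in extra]) * 1e-3
        z = np.concatenate([z, extra])
        g = np.concatenate([g, gx])
    meta = {"originated": True, "simulated": True,
            "termination": trajectory.termination}
    return ConductanceTrace(z, np.maximum(g, cfg.noise_floor_g0), meta)


def gen_simulated_series(
    series_params,
    trace_params,
    duplex: Duplex | None = None,
    params: ZipperParams | None = None,
    protocol: Protocol | None = None,
) -> list[ConductanceTrace]:
    """Consecutive-trace series whose formation state is delegated to the
    zipper simulator: each cycle pulls the tethered duplex; a cycle ending
    in strand separation leaves the junction unformed until a new duplex
    hybridizes (probability ``p_form`` per approach)."""
    from .synthetic_data import gen_bj_trace

    if duplex is None:
        from .synthetic_data import gen_sequence

        duplex = Duplex.from_sequence(gen_sequence(90, 0.5, seed=series_params.seed))
    params = params or ZipperParams()
    protocol = protocol or Protocol()
    rng = np.random.default_rng(series_params.seed)
    out = []
    intact = True
    for idx in range(series_params.n_traces):
        if not intact and rng.random() < series_params.p_form:
            intact = True
        if intact:
            traj = kmc_run(duplex, params, protocol,
                           seed=int(rng.integers(2**31)))
            intact = traj.termination != "strand_separation"
            formed = True
        else:
            formed = False
        tr = gen_bj_trace(trace_params, with_plateau=formed, seed=rng)
        tr.meta["trace_index"] = idx
        tr.meta["formed_truth"] = formed
        out.append(tr)
    return out
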