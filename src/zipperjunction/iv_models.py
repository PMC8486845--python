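"""Closed-form I-V models for junction states.

The molecular (high-conductance) state uses the symmetric single-level
model: a Lorentzian transmission T(E) = Gamma^2 / ((E - eps0)^2 + Gamma^2)
integrated over the symmetric bias window,

    I(V) = (2e/h) * Gamma * [atan((eV/2 - eps0)/Gamma) + atan((eV/2 + eps0)/Gamma)]

which is odd in V and exhibits an interior Fowler-Nordheim minimum whose
position is tunable through eps0. The tunnelling (low) state is I = aV + bV^3.
"""

from __future__ import annotations

import numpy as np

from .constants import E_CHARGE, H_PLANCK


def single_level_current(
    bias_v: np.ndarray | float, level_energy_ev: float, coupling_ev: float
) -> np.ndarray:
    """Current (A) of the symmetric single-level model. Odd in V; I(0) = 0."""
    v = np.asarray(bias_v, dtype=float)
    eps0, gamma = level_energy_ev, coupling_ev
    integral_ev = gamma * (
        np.arctan((v / 2.0 - eps0) / gamma) + np.arctan((v / 2.0 + eps0) / gamma)
    )
    return (2.0 * E_CHARGE / H_PLANCK) * integral_ev * E_CHARGE


def cubic_current(
    bias_v: np.ndarray | float, a: float, b: float
) -> np.ndarray:
    """Tunnelling low-state current I = a V + b V^3 (A)."""
    v = np.asarray(bias_v, dtype=float)
    return a * v + b * v**3
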