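"""Membrane dynamics of the multi-compartment RGC model.

Five-conductance Hodgkin–Huxley-type formulation of retinal ganglion cell
excitability in the Fohlmeister–Miller tradition: fast sodium (m³h),
calcium (c³), delayed-rectifier potassium (n⁴), inactivating A-type
potassium (a³h_A), calcium-activated potassium, and leak.  Intracellular
calcium follows the Ca current with first-order decay and sets the K(Ca)
activation and the calcium reversal potential (Nernst).

All rate constants live in this module so that the kinetics can be
inspected, and replaced, in one place.  Rates are expressed at 22 °C; a
single Q10 factor scales them at other temperatures.  Sectional channel
densities are package defaults chosen to give a stable ~−65 mV resting
state, spike initiation in the high-density sodium band, and conduction
along the axon; the leak reversal is solved per compartment at
initialisation so the configured resting potential is an exact
equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["MembraneParams", "SECTION_DENSITIES", "gate_steady_states",
           "FARADAY"]

FARADAY = 96485.332          # C/mol
GAS_R = 8.31446              # J/(mol K)

# channel densities, mS/cm², by section
SECTION_DENSITIES = {
    #            gNa    gCa   gK    gA    gKCa
    "dendrite":  (40.0, 2.0, 12.0, 36.0, 0.05),
    "soma":      (80.0, 1.5, 18.0, 54.0, 0.065),
    "hillock":   (150.0, 1.5, 18.0, 54.0, 0.065),
    "sodium_band": (700.0, 1.5, 18.0, 54.0, 0.065),
    "axon":      (100.0, 0.0, 18.0, 0.0, 0.0),
}


@dataclass
class MembraneParams:
    """Biophysical constants of the cable model.

    Conductance densities in mS/cm², capacitance in µF/cm², axial
    resistivity in Ω·cm, potentials in mV, calcium concentrations in mM.
    """

    densities: dict[str, tuple[float, float, float, float, float]] = \
        field(default_factory=lambda: dict(SECTION_DENSITIES))
    g_leak: float = 0.05
    e_na: float = 35.0
    e_k: float = -75.0
    cm: float = 1.0
    axial_resistivity: float = 110.0
    v_rest: float = -65.0
    temperature_c: float = 22.0
    q10: float = 2.0
    ca_out: float = 1.8
    ca_rest: float = 1.0e-4
    ca_dissociation: float = 1.0e-3   # K(Ca) half-activation, mM
    ca_tau_ms: float = 1.5

    def __post_init__(self):
        for name, dens in self.densities.items():
            if any(g < 0 for g in dens):
                raise ValueError(f"negative conductance density for {name!r}")

    @property
    def rate_scale(self) -> float:
        """Q10 multiplier applied to all gate rate constants."""
        return self.q10 ** ((self.temperature_c - 22.0) / 10.0)

    @property
    def nernst_factor(self) -> float:
        """RT/2F in mV at the configured temperature (for E_Ca)."""
        t_k = self.temperature_c + 273.15
        return 1000.0 * GAS_R * t_k / (2.0 * FARADAY)


@njit(cache=True)
def _vtrap(x, y):
    # x / (exp(x/y) - 1), guarded at the removable singularity
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0)
    return x / (np.exp(x / y) - 1.0)


@njit(cache=True)
def gate_rates(v):
    """(α, β) for the six gates m, h, c, n, a, h_A at potential v (mV, 22 °C)."""
    am = 0.6 * _vtrap(-(v + 30.0), 10.0)
    bm = 20.0 * np.exp(-(v + 55.0) / 18.0)
    ah = 0.4 * np.exp(-(v + 50.0) / 20.0)
    bh = 6.0 / (1.0 + np.exp(-0.1 * (v + 20.0)))
    ac = 0.3 * _vtrap(-(v + 13.0), 10.0)
    bc = 10.0 * np.exp(-(v + 38.0) / 18.0)
    an = 0.02 * _vtrap(-(v + 40.0), 10.0)
    bn = 0.4 * np.exp(-(v + 50.0) / 80.0)
    aa = 0.006 * _vtrap(-(v + 90.0), 10.0)
    ba = 0.1 * np.exp(-(v + 30.0) / 10.0)
    aha = 0.04 * np.exp(-(v + 70.0) / 20.0)
    bha = 0.6 / (1.0 + np.exp(-0.1 * (v + 40.0)))
    return am, bm, ah, bh, ac, bc, an, bn, aa, ba, aha, bha


def gate_steady_states(v: float) -> np.ndarray:
    """Steady-state values of (m, h, c, n, a, h_A) at potential v."""
    r = gate_rates(v)
    return np.array([r[2 * i] / (r[2 * i] + r[2 * i + 1]) for i in range(6)])
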