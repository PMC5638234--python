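"""C3 Farquhar-von Caemmerer-Berry assimilation model.

Used to model net assimilation A when it was not measured (a requirement of
the partial-dependence surrogate) and as the carbon side of the coupled-leaf
simulator. Net assimilation is the minimum of the Rubisco-limited and
RuBP-regeneration-limited rates minus day respiration:

    Ac = Vcmax (Ci - Gamma*) / (Ci + Kc (1 + O/Ko))
    Aj = (J/4) (Ci - Gamma*) / (Ci + 2 Gamma*)
    A  = min(Ac, Aj) - Rd

with J the electron transport rate from a non-rectangular hyperbola in
absorbed light, and Arrhenius temperature scaling of Vcmax, Jmax, Rd,
Gamma*, Kc and Ko (activation energies after Bernacchi et al.; 25 C
reference). Defaults: Vcmax25 = 60, Jmax25 = 1.67 Vcmax25,
Rd25 = 0.015 Vcmax25, O = 210 mmol mol-1; all overridable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError
from .models import GAMMA_STAR_25

R_GAS = 8.314  # J mol-1 K-1
T_REF = 298.15  # K


@dataclass(frozen=True)
class FarquharParams:
    """Photosynthetic capacity and kinetic constants at 25 C.

    Units: Vcmax25, Jmax25, Rd25 in umol m-2 s-1; gamma_star25, Kc25 in
    umol mol-1; Ko25 and O in mmol mol-1; activation energies in J mol-1.
    ``theta_j`` is the curvature and ``quantum_yield`` the initial slope
    (mol e- per mol photon, absorptance included) of the light response.
    """

    Vcmax25: float = 60.0
    Jmax25: float = 100.2   # 1.67 * Vcmax25
    Rd25: float = 0.9       # 0.015 * Vcmax25
    gamma_star25: float = GAMMA_STAR_25
    Kc25: float = 404.9
    Ko25: float = 278.4
    O: float = 210.0
    theta_j: float = 0.7
    quantum_yield: float = 0.3
    Ea_Vcmax: float = 65330.0
    Ea_Jmax: float = 43540.0
    Ea_Rd: float = 46390.0
    Ea_gamma_star: float = 37830.0
    Ea_Kc: float = 79430.0
    Ea_Ko: float = 36380.0

    def __post_init__(self) -> None:
        for name in ("Vcmax25", "Jmax25", "Rd25", "gamma_star25",
                     "Kc25", "Ko25", "O"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")


def arrhenius(k25, Ea, Tleaf):
    """Scale a 25 C value to leaf temperature Tleaf (C)."""
    Tk = np.asarray(Tleaf, dtype=float) + 273.15
    return k25 * np.exp(Ea * (Tk - T_REF) / (R_GAS * T_REF * Tk))


def gamma_star_at(Tleaf, params: FarquharParams | None = None):
    """Gamma* (umol mol-1) at leaf temperature."""
    p = params or FarquharParams()
    return arrhenius(p.gamma_star25, p.Ea_gamma_star, Tleaf)


def electron_transport(PAR, Jmax, theta: float, quantum_yield: float):
    """Non-rectangular hyperbola light response of electron transport J."""
    aI = quantum_yield * np.asarray(PAR, dtype=float)
    disc = (aI + Jmax) ** 2 - 4.0 * theta * aI * Jmax
    return (aI + Jmax - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * theta)


def farquhar_a(Ci, Tleaf, PAR, params: FarquharParams | None = None):
    """Net assimilation A (umol m-2 s-1) at intercellular CO2 Ci.

    A = min(Ac, Aj) - Rd; returns -Rd at Ci = Gamma* or PAR = 0.
    """
    p = params or FarquharParams()
    Ci = np.asarray(Ci, dtype=float)
    if np.any(Ci <= 0):
        raise InvalidInputError("Ci must be > 0")
    if np.any(np.asarray(PAR) < 0):
        raise InvalidInputError("PAR must be >= 0")

    vcmax = arrhenius(p.Vcmax25, p.Ea_Vcmax, Tleaf)
    jmax = arrhenius(p.Jmax25, p.Ea_Jmax, Tleaf)
    rd = arrhenius(p.Rd25, p.Ea_Rd, Tleaf)
    gstar = arrhenius(p.gamma_star25, p.Ea_gamma_star, Tleaf)
    kc = arrhenius(p.Kc25, p.Ea_Kc, Tleaf)
    ko = arrhenius(p.Ko25, p.Ea_Ko, Tleaf)

    ac = vcmax * (Ci - gstar) / (Ci + kc * (1.0 + p.O / ko))
    j = electron_transport(PAR, jmax, p.theta_j, p.quantum_yield)
    aj = (j / 4.0) * (Ci - gstar) / (Ci + 2.0 * gstar)
    out = np.minimum(ac, aj) - rd
    return out if np.ndim(out) else float(out)
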