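"""Empirical stomatal conductance models and Weibull vulnerability curves.

Four models of water-vapor stomatal conductance gs (mol m-2 s-1) are
implemented, differing in how they represent atmospheric (VPD) versus
hydraulic (leaf water potential) limitation:

``M``
    Medlyn optimal-empirical model,
    gs = 1.6 (A/Cs) (1 + g1/sqrt(D)).
``BBL``
    Ball-Berry-Leuning (no residual-conductance g0 term),
    gs = alpha A / ((Cs - Gamma*) (1 + D/d1)).
``T``
    Tuzet variant: the VPD term of BBL is replaced by a sigmoidal
    (Weibull-form) dependence on leaf water potential,
    gs = alpha A exp(-(|psi|/c)^b) / (Cs - Gamma*).
``BBL.H``
    BBL combined with the Weibull hydraulic term,
    gs = alpha A exp(-(|psi|/c)^b) / ((Cs - Gamma*) (1 + D/d1)).

Water potentials are stored as psi <= 0 MPa and the Weibull is evaluated on
the magnitude |psi| with a positive scale ``c`` (avoids fractional powers of
negative numbers). The same survival-form Weibull,
S(psi) = exp(-(|psi|/c)^b), describes xylem vulnerability: percent loss of
conductivity PLC = 100 (1 - S).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .exceptions import InvalidInputError

#: CO2 compensation point Gamma* at 25 C, umol mol-1 (Arrhenius-scaled by
#: the Farquhar module; overridable per species).
GAMMA_STAR_25 = 42.75

#: Floor on VPD (kPa) inside the Medlyn model, guarding the 1/sqrt(D)
#: singularity; gas-exchange measurements below this are unreliable.
D_FLOOR = 0.05

MODEL_IDS = ("M", "BBL", "BBL.H", "T")

#: Free (fitted) parameters per model, in canonical order.
FREE_PARAMS = {
    "M": ("g1",),
    "BBL": ("alpha", "d1"),
    "T": ("alpha", "b", "c"),
    "BBL.H": ("alpha", "d1", "b", "c"),
}


def _check_cs_gamma(Cs, gamma_star) -> None:
    if np.any(np.asarray(Cs) <= gamma_star):
        raise InvalidInputError(
            f"Cs must exceed gamma_star={gamma_star}; model undefined otherwise"
        )


def medlyn_gs(A, Cs, D, g1, d_floor: float = D_FLOOR):
    """Medlyn et al. optimal-empirical model.

    gs = 1.6 (A/Cs) (1 + g1 / sqrt(D)), with D floored at ``d_floor`` kPa.

    Parameters are: A (umol m-2 s-1), Cs (umol mol-1), D (kPa),
    g1 (kPa^0.5). Returns gs in mol m-2 s-1 (the 1.6 converts the CO2- to
    the water-vapor diffusivity basis, and A/Cs carries mol m-2 s-1).
    """
    Cs = np.asarray(Cs, dtype=float)
    if np.any(Cs <= 0):
        raise InvalidInputError("Cs must be > 0")
    D = np.maximum(np.asarray(D, dtype=float), d_floor)
    out = 1.6 * np.asarray(A, dtype=float) / Cs * (1.0 + g1 / np.sqrt(D))
    return out if out.ndim else float(out)


def bbl_gs(A, Cs, D, alpha, d1, gamma_star: float = GAMMA_STAR_25):
    """Ball-Berry-Leuning model (g0 omitted).

    gs = alpha A / ((Cs - Gamma*) (1 + D/d1)).
    """
    _check_cs_gamma(Cs, gamma_star)
    A = np.asarray(A, dtype=float)
    out = alpha * A / (
        (np.asarray(Cs, dtype=float) - gamma_star)
        * (1.0 + np.asarray(D, dtype=float) / d1)
    )
    return out if out.ndim else float(out)


def _survival_raw(psi, b, c):
    """exp(-(|psi|/c)^b) with array-valued psi, b and c."""
    psi = np.asarray(psi, dtype=float)
    if np.any(psi > 0):
        raise InvalidInputError("psi must be <= 0 MPa")
    b, c = np.asarray(b, dtype=float), np.asarray(c, dtype=float)
    if np.any(b <= 0) or np.any(c <= 0):
        raise InvalidInputError("Weibull requires b, c > 0")
    with np.errstate(over="ignore"):  # huge (|psi|/c)^b -> exp(-inf) = 0
        return np.exp(-((np.abs(psi) / c) ** b))


def tuzet_gs(A, Cs, psi, alpha, b, c, gamma_star: float = GAMMA_STAR_25):
    """Tuzet variant: hydraulic (Weibull) term replaces the VPD term.

    gs = alpha A exp(-(|psi|/c)^b) / (Cs - Gamma*), psi <= 0 MPa.
    """
    _check_cs_gamma(Cs, gamma_star)
    out = alpha * np.asarray(A, dtype=float) * _survival_raw(psi, b, c) / (
        np.asarray(Cs, dtype=float) - gamma_star
    )
    return out if np.ndim(out) else float(out)


def bblh_gs(A, Cs, D, psi, alpha, d1, b, c, gamma_star: float = GAMMA_STAR_25):
    """BBL plus the Weibull hydraulic term (the combined model).

    gs = alpha A exp(-(|psi|/c)^b) / ((Cs - Gamma*) (1 + D/d1)).

    Reduces exactly to :func:`bbl_gs` at psi = 0 and to :func:`tuzet_gs`
    at D = 0.
    """
    base = bbl_gs(A, Cs, D, alpha, d1, gamma_star)
    out = np.asarray(base) * _survival_raw(psi, b, c)
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class WeibullCurve:
    """Survival-form Weibull, S(psi) = exp(-(|psi|/c)^b).

    Used both for stomatal closure (Tuzet / BBL.H hydraulic term) and for
    xylem vulnerability. ``b`` is the dimensionless shape (steepness),
    ``c`` the scale in MPa magnitude (|psi| at which S = 1/e).
    """

    b: float
    c: float

    def __post_init__(self) -> None:
        if self.b <= 0 or self.c <= 0:
            raise InvalidInputError(f"Weibull requires b, c > 0; got {self}")

    @property
    def psi_at_half(self) -> float:
        """Signed psi (MPa) at which S = 0.5: -c (ln 2)^(1/b)."""
        return -self.c * math.log(2.0) ** (1.0 / self.b)


def weibull_survival(psi, curve: WeibullCurve):
    """Fraction of conductance (or conductivity) remaining at psi <= 0."""
    out = _survival_raw(psi, curve.b, curve.c)
    return out if out.ndim else float(out)


def plc(psi, curve: WeibullCurve):
    """Percent loss of conductivity at psi: 100 (1 - S(psi))."""
    out = 100.0 * (1.0 - weibull_survival(psi, curve))
    return out if np.ndim(out) else float(out)


def weibull_from_p50_p88(P50: float, P88: float) -> WeibullCurve:
    """Weibull curve consistent with 50% loss at P50 and 88% loss at P88.

    Closed form: with L50 = ln 2 and L88 = ln(1/0.12),
    b = ln(L88/L50) / ln(|P88|/|P50|), c = |P50| / L50^(1/b).
    """
    if not (P50 < 0 and P88 < 0):
        raise InvalidInputError("P50 and P88 must be negative MPa")
    if abs(P88) <= abs(P50):
        raise InvalidInputError(
            f"|P88| must exceed |P50|; got P50={P50}, P88={P88}"
        )
    l50 = math.log(2.0)
    l88 = math.log(1.0 / 0.12)
    b = math.log(l88 / l50) / math.log(abs(P88) / abs(P50))
    c = abs(P50) / l50 ** (1.0 / b)
    return WeibullCurve(b=b, c=c)


@dataclass(frozen=True)
class StomatalParams:
    """Parameter set for one stomatal model.

    ``model_id`` selects which fields are free: M -> g1; BBL -> alpha, d1;
    T -> alpha, b, c; BBL.H -> alpha, d1, b, c. All free parameters are
    strictly positive in the internal magnitude convention.
    """

    model_id: str
    g1: Optional[float] = None          # Medlyn slope, kPa^0.5
    alpha: Optional[float] = None       # BBL-family slope, dimensionless
    d1: Optional[float] = None          # VPD sensitivity, kPa
    b: Optional[float] = None           # Weibull shape
    c: Optional[float] = None           # Weibull scale, MPa magnitude
    gamma_star: float = GAMMA_STAR_25   # CO2 compensation point, umol mol-1

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise InvalidInputError(
                f"unknown model_id {self.model_id!r}; expected one of {MODEL_IDS}"
            )
        for name in FREE_PARAMS[self.model_id]:
            v = getattr(self, name)
            if v is None or v <= 0:
                raise InvalidInputError(
                    f"{self.model_id} requires {name} > 0, got {v}"
                )

    @property
    def free_values(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in FREE_PARAMS[self.model_id])

    @property
    def closure_curve(self) -> Optional[WeibullCurve]:
        """Stomatal-closure Weibull, for the psi-aware models."""
        if self.b is None or self.c is None:
            return None
        return WeibullCurve(b=self.b, c=self.c)

    def with_values(self, values) -> "StomatalParams":
        """New params with the free fields replaced (canonical order)."""
        names = FREE_PARAMS[self.model_id]
        if len(values) != len(names):
            raise InvalidInputError(
                f"{self.model_id} expects {len(names)} values, got {len(values)}"
            )
        return replace(self, **dict(zip(names, map(float, values))))


def params_from_values(model_id: str, values, gamma_star: float = GAMMA_STAR_25
                       ) -> StomatalParams:
    """Build a StomatalParams from a free-parameter vector."""
    names = FREE_PARAMS[model_id]
    if len(values) != len(names):
        raise InvalidInputError(
            f"{model_id} expects {len(names)} values, got {len(values)}"
        )
    return StomatalParams(model_id=model_id, gamma_star=gamma_star,
                          **dict(zip(names, map(float, values))))


def predict_gs(params: StomatalParams, A, Cs, D=None, psi=None):
    """Evaluate the model selected by ``params.model_id``.

    ``D`` is required for M, BBL and BBL.H; ``psi`` for T and BBL.H.
    """
    m = params.model_id
    if m in ("M", "BBL", "BBL.H") and D is None:
        raise InvalidInputError(f"model {m} requires D")
    if m in ("T", "BBL.H") and psi is None:
        raise InvalidInputError(f"model {m} requires psi")
    if m == "M":
        return medlyn_gs(A, Cs, D, params.g1)
    if m == "BBL":
        return bbl_gs(A, Cs, D, params.alpha, params.d1, params.gamma_star)
    if m == "T":
        return tuzet_gs(A, Cs, psi, params.alpha, params.b, params.c,
                        params.gamma_star)
    return bblh_gs(A, Cs, D, psi, params.alpha, params.d1, params.b, params.c,
                   params.gamma_star)
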