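"""Forward simulation of gas-exchange campaigns with known ground truth.

The raw multi-species compilation the analysis is designed for is not
publicly deposited, so the pipeline is exercised on synthetic campaigns
generated by a coupled leaf: a stomatal model (BBL.H truth by default)
interacts with Farquhar photosynthesis and a single-resistance soil-to-leaf
water transport law,

    psi_leaf = psi_soil - E / K,   E = gs D / Patm,

optionally with hydraulic feedback K_eff = K * S(psi_leaf) from the xylem
Weibull. The cycle gs -> E -> psi_leaf -> gs (and A -> Ci -> A) is solved
by damped fixed-point iteration per record. Campaigns emulate the
statistical structure of field datasets: wet-skewed sampling of soil water
potential, multiplicative lognormal noise on gs (gas-exchange error grows
with flux) and additive Gaussian noise on psi (pressure-chamber error is
roughly absolute).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import COLUMNS, SpeciesDataset
from .exceptions import InvalidInputError, StomatafitError
from .farquhar import (FarquharParams, arrhenius, electron_transport,
                       farquhar_a)
from .models import (StomatalParams, WeibullCurve, predict_gs,
                     weibull_from_p50_p88, weibull_survival)

log = logging.getLogger(__name__)

PATM_KPA = 101.3

#: Floor on gs inside the solver (mol m-2 s-1); avoids division by zero in
#: the Ci update and stands in for the closed-stomata branch.
GS_FLOOR = 1e-4


@dataclass(frozen=True)
class TrueSpecies:
    """Generating truth for one synthetic species.

    ``k_plant`` is whole-plant hydraulic conductance per unit leaf area
    (mol m-2 s-1 MPa-1). With ``plc_feedback`` the transport conductance
    declines as k_plant * S(psi_leaf) along the xylem Weibull.
    """

    species_id: str
    params: StomatalParams
    k_plant: float
    p50: float
    p88: float
    farquhar: FarquharParams = field(default_factory=FarquharParams)
    plc_feedback: bool = True

    def __post_init__(self) -> None:
        if self.k_plant <= 0:
            raise InvalidInputError("k_plant must be positive")

    @property
    def model_id(self) -> str:
        return self.params.model_id

    @property
    def xylem(self) -> WeibullCurve:
        return weibull_from_p50_p88(self.p50, self.p88)

    @property
    def psi_gs50_true(self) -> Optional[float]:
        """Closed-form stomatal-closure midpoint, -c (ln 2)^(1/b)."""
        curve = self.params.closure_curve
        return None if curve is None else curve.psi_at_half


@dataclass(frozen=True)
class CampaignConfig:
    """Sampling design of one measurement campaign.

    ``wet_skew`` is the fraction of records drawn from the wet mode of the
    soil-water-potential mixture (field datasets typically over-sample
    benign conditions); ``psi_min`` the dry end of the campaign (MPa).
    Noise: ``gs_noise_cv`` multiplicative lognormal CV on gs,
    ``psi_noise_sd`` additive Gaussian sd (MPa) on both psi measurements.
    """

    n_obs: int = 300
    psi_min: float = -4.0
    wet_skew: float = 0.8
    gs_noise_cv: float = 0.10
    psi_noise_sd: float = 0.05
    d_median: float = 1.5      # kPa, lognormal
    d_sigma: float = 0.4
    tleaf_mean: float = 25.0   # C, truncated normal
    tleaf_sd: float = 4.0
    par_range: tuple[float, float] = (400.0, 2000.0)
    ca_mean: float = 400.0     # umol mol-1
    ca_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_obs < 1:
            raise InvalidInputError("n_obs must be >= 1")
        if not 0.0 <= self.wet_skew <= 1.0:
            raise InvalidInputError("wet_skew must lie in [0, 1]")
        if self.psi_min >= 0:
            raise InvalidInputError("psi_min must be negative")


def solve_leaf(species: TrueSpecies, psi_soil, D, Tleaf, PAR, Ca,
               tol: float = 1e-8, max_iter: int = 1500,
               damping: float = 0.5):
    """Solve the coupled leaf for one or many environmental states.

    Damped fixed-point iteration over the outer cycle
    gs = stomatal_model(A, Ca, D, psi_leaf), E = gs D/Patm,
    psi_leaf = psi_soil - E/K_eff; at each sweep the inner carbon balance
    (Farquhar demand = diffusion supply, A(Ci) = gs (Ca - Ci)/1.6) is solved
    for Ci by bisection — the balance is monotone in Ci, so this inner step
    is unconditionally stable even as stomata shut.

    Returns (gs, A, Ci, psi_leaf, E, converged); arrays broadcast from the
    inputs, converged a boolean mask (relative change below ``tol`` within
    ``max_iter`` sweeps). Records where stomata shut return the gs-floor
    solution with A pinned near -Rd.
    """
    psi_soil, D, Tleaf, PAR, Ca = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(v, dtype=float))
          for v in (psi_soil, D, Tleaf, PAR, Ca)))
    if np.any(psi_soil > 0):
        raise InvalidInputError("psi_soil must be <= 0")
    if np.any(D < 0) or np.any(PAR < 0) or np.any(Ca <= 0):
        raise InvalidInputError("environment values must be positive")
    scalar = psi_soil.size == 1 and np.ndim(psi_soil) == 1

    # temperature/light-dependent Farquhar terms are fixed per record;
    # precompute them so the inner bisection is cheap algebra
    fp = species.farquhar
    vcmax = arrhenius(fp.Vcmax25, fp.Ea_Vcmax, Tleaf)
    jmax = arrhenius(fp.Jmax25, fp.Ea_Jmax, Tleaf)
    rd = arrhenius(fp.Rd25, fp.Ea_Rd, Tleaf)
    gstar = arrhenius(fp.gamma_star25, fp.Ea_gamma_star, Tleaf)
    km = arrhenius(fp.Kc25, fp.Ea_Kc, Tleaf) * (
        1.0 + fp.O / arrhenius(fp.Ko25, fp.Ea_Ko, Tleaf))
    j4 = electron_transport(PAR, jmax, fp.theta_j, fp.quantum_yield) / 4.0

    def a_of_ci(ci_, idx):
        ac = vcmax[idx] * (ci_ - gstar[idx]) / (ci_ + km[idx])
        aj = j4[idx] * (ci_ - gstar[idx]) / (ci_ + 2.0 * gstar[idx])
        return np.minimum(ac, aj) - rd[idx]

    def solve_ci(gs_now, idx, Ca_) -> np.ndarray:
        lo = np.full(gs_now.shape, 1.0)
        hi = np.full(gs_now.shape, 2000.0)
        for _ in range(45):
            mid = 0.5 * (lo + hi)
            f = a_of_ci(mid, idx) - gs_now * (Ca_ - mid) / 1.6
            hi = np.where(f > 0, mid, hi)
            lo = np.where(f > 0, lo, mid)
        return 0.5 * (lo + hi)

    xylem = species.xylem
    gs = np.full(psi_soil.shape, 0.15)
    psi_leaf = psi_soil.copy()
    converged = np.zeros(psi_soil.shape, dtype=bool)
    active = np.arange(psi_soil.size)
    for _ in range(max_iter):
        ps, d_, ca_ = (v[active] for v in (psi_soil, D, Ca))
        g = gs[active]
        pl = psi_leaf[active]
        ci_a = solve_ci(g, active, ca_)
        A_a = a_of_ci(ci_a, active)
        gs_t = np.asarray(predict_gs(species.params, A_a, ca_, d_, pl))
        gs_t = np.clip(gs_t, GS_FLOOR, 5.0)
        gs_new = damping * gs_t + (1.0 - damping) * g
        E = gs_new * d_ / PATM_KPA
        k_eff = species.k_plant
        if species.plc_feedback:
            k_eff = k_eff * np.maximum(
                weibull_survival(np.minimum(pl, 0.0), xylem), 1e-3)
        psi_t = np.maximum(ps - E / k_eff, -20.0)
        psi_new = damping * psi_t + (1.0 - damping) * pl
        d_gs = np.abs(gs_new - g) / np.maximum(g, GS_FLOOR)
        d_psi = np.abs(psi_new - pl) / np.maximum(np.abs(pl), 0.1)
        gs[active] = gs_new
        psi_leaf[active] = psi_new
        done = (d_gs < tol) & (d_psi < tol)
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break
    all_idx = np.arange(psi_soil.size)
    ci = solve_ci(gs, all_idx, Ca)
    A = a_of_ci(ci, all_idx)
    E = gs * D / PATM_KPA
    if scalar:
        return (float(gs[0]), float(A[0]), float(ci[0]), float(psi_leaf[0]),
                float(E[0]), bool(converged[0]))
    return gs, A, ci, psi_leaf, E, converged


def coupling_residuals(species: TrueSpecies, gs, A, Ci, psi_leaf,
                       psi_soil, D, Tleaf, PAR, Ca) -> dict[str, np.ndarray]:
    """Plug-back residuals of the four coupling equations at a solution.

    For a converged, non-floored record each residual should be < 1e-6
    (relative). Used as the independent oracle on the solver.
    """
    gs = np.asarray(gs, dtype=float)
    A_chk = np.asarray(farquhar_a(Ci, Tleaf, PAR, species.farquhar))
    gs_chk = np.asarray(predict_gs(species.params, A, Ca, D, psi_leaf))
    ci_chk = np.asarray(Ca) - 1.6 * np.asarray(A) / gs
    E = gs * np.asarray(D) / PATM_KPA
    k_eff = species.k_plant
    if species.plc_feedback:
        k_eff = k_eff * np.maximum(
            weibull_survival(np.minimum(psi_leaf, 0.0), species.xylem), 1e-3)
    psi_chk = np.asarray(psi_soil) - E / k_eff
    return {
        "gs": np.abs(gs - gs_chk) / np.maximum(gs, GS_FLOOR),
        "A": np.abs(np.asarray(A) - A_chk) / np.maximum(np.abs(A_chk), 1.0),
        "Ci": np.abs(np.asarray(Ci) - ci_chk) / np.maximum(np.asarray(Ci), 1.0),
        "psi_leaf": np.abs(np.asarray(psi_leaf) - psi_chk)
        / np.maximum(np.abs(psi_chk), 0.1),
    }


def _draw_psi_soil(rng: np.random.Generator, cfg: CampaignConfig
                   ) -> np.ndarray:
    """Beta-mixture draw of soil water potential on [psi_min, 0]: a wet mode
    hugging 0 and a dry mode reaching the campaign minimum."""
    wet = rng.random(cfg.n_obs) < cfg.wet_skew
    u = np.where(wet, rng.beta(1.5, 8.0, cfg.n_obs),
                 rng.beta(5.0, 2.0, cfg.n_obs))
    return cfg.psi_min * u


def simulate_campaign(species: TrueSpecies, config: CampaignConfig
                      ) -> SpeciesDataset:
    """Simulate one campaign; fully reproducible from ``config.seed``.

    psi_pd is the (noisy) soil water potential, psi_md the (noisy) solved
    leaf water potential. Aborts when more than 20% of draws fail to
    converge (a sign the coupled parameters are unphysical).
    """
    rng = np.random.default_rng(config.seed)
    psi_soil = _draw_psi_soil(rng, config)
    D = np.clip(rng.lognormal(math.log(config.d_median), config.d_sigma,
                              config.n_obs), 0.1, 6.0)
    tleaf = np.clip(rng.normal(config.tleaf_mean, config.tleaf_sd,
                               config.n_obs), 5.0, 45.0)
    par = rng.uniform(*config.par_range, config.n_obs)
    ca = np.clip(rng.normal(config.ca_mean, config.ca_sd, config.n_obs),
                 300.0, 500.0)

    gs, A, _ci, psi_leaf, _E, ok = solve_leaf(species, psi_soil, D, tleaf,
                                              par, ca)
    frac_bad = 1.0 - ok.mean()
    if frac_bad > 0.20:
        raise StomatafitError(
            f"{species.species_id}: {frac_bad:.0%} of leaf solutions failed "
            "to converge; check k_plant / closure parameters")
    if frac_bad > 0:
        log.info("%s: excluded %d non-converged records", species.species_id,
                 int((~ok).sum()))

    # measurement noise (drawn after solving so the physical truth is clean)
    if config.gs_noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.gs_noise_cv ** 2))
        gs_obs = gs * rng.lognormal(-0.5 * sigma ** 2, sigma, config.n_obs)
    else:
        gs_obs = gs.copy()
    psi_md = np.minimum(
        psi_leaf + rng.normal(0.0, config.psi_noise_sd, config.n_obs), 0.0)
    psi_pd = np.minimum(
        psi_soil + rng.normal(0.0, config.psi_noise_sd, config.n_obs), 0.0)

    df = pd.DataFrame({
        "gs": gs_obs, "A": A, "Cs": ca, "D": D, "Tleaf": tleaf,
        "psi_md": psi_md, "psi_pd": psi_pd, "PAR": par})[COLUMNS]
    df = df.loc[ok].reset_index(drop=True)
    return SpeciesDataset(
        species_id=species.species_id, data=df, p50=species.p50,
        p88=species.p88,
        meta={"truth_model": species.model_id, "seed": config.seed,
              "n_nonconverged": int((~ok).sum())})


@dataclass(frozen=True)
class PanelConfigSynthetic:
    """Species-level priors and campaign settings for a synthetic panel."""

    n_species: int = 24
    strategy_mix: float = 0.5    # fraction of conservative (isohydric) species
    truth_model: str = "BBL.H"
    n_obs: int = 300
    gs_noise_cv: float = 0.10
    psi_noise_sd: float = 0.05
    wet_skew: float = 0.8
    frac_no_a: float = 10.0 / 34.0       # species without measured A
    frac_predawn_only: float = 3.0 / 34.0
    psi_margin: float = 1.0      # MPa beyond true psi_gs50 the campaign reaches


def draw_true_species(rng: np.random.Generator, species_id: str,
                      conservative: bool, truth_model: str = "BBL.H"
                      ) -> TrueSpecies:
    """Draw one species' generating parameters from lognormal priors.

    Conservative (isohydric) species close stomata well before xylem P50
    (closure scale c at 40-70% of |P50|); risky (anisohydric) species delay
    closure (85-110% of |P50|).
    """
    p50 = -float(np.clip(rng.lognormal(math.log(3.0), 0.30), 1.2, 8.0))
    p88 = p50 * float(rng.uniform(1.35, 1.8))
    ratio = float(rng.uniform(0.40, 0.70) if conservative
                  else rng.uniform(0.85, 1.10))
    b = float(rng.uniform(1.5, 4.0))
    c = ratio * abs(p50)
    alpha = float(rng.lognormal(math.log(9.0), 0.25))
    d1 = float(rng.lognormal(math.log(1.2), 0.30))
    g1 = float(rng.lognormal(math.log(3.5), 0.30))
    if truth_model == "BBL.H":
        params = StomatalParams("BBL.H", alpha=alpha, d1=d1, b=b, c=c)
    elif truth_model == "BBL":
        params = StomatalParams("BBL", alpha=alpha, d1=d1)
    elif truth_model == "T":
        params = StomatalParams("T", alpha=alpha, b=b, c=c)
    elif truth_model == "M":
        params = StomatalParams("M", g1=g1)
    else:
        raise InvalidInputError(f"unknown truth model {truth_model!r}")
    vcmax = float(np.clip(rng.normal(60.0, 10.0), 30.0, 100.0))
    farq = FarquharParams(Vcmax25=vcmax, Jmax25=1.67 * vcmax,
                          Rd25=0.015 * vcmax)
    k_plant = float(rng.lognormal(math.log(4e-3), 0.4))
    return TrueSpecies(species_id=species_id, params=params, farquhar=farq,
                       k_plant=k_plant, p50=p50, p88=p88)


def make_panel(n_species: int = 24, strategy_mix: float = 0.5, seed: int = 0,
               config: Optional[PanelConfigSynthetic] = None
               ) -> tuple[list[TrueSpecies], list[SpeciesDataset],
                          pd.DataFrame]:
    """Generate a multi-species panel of campaigns plus its hidden truth.

    A ``strategy_mix`` fraction of species is conservative. Each campaign's
    dry end reaches ``psi_margin`` MPa beyond the species' true closure
    midpoint. Some species are flagged "no A measured" / "predawn-only psi"
    (in the field-data proportions 10/34 and 3/34) to exercise the
    pipeline's substitution paths. Returns (truths, datasets, truth table).
    """
    if n_species < 1:
        raise InvalidInputError("n_species must be >= 1")
    cfg = config or PanelConfigSynthetic(n_species=n_species,
                                         strategy_mix=strategy_mix)
    rng = np.random.default_rng(seed)
    n_cons = int(round(cfg.strategy_mix * n_species))
    conservative = np.zeros(n_species, dtype=bool)
    conservative[rng.permutation(n_species)[:n_cons]] = True
    n_no_a = int(round(cfg.frac_no_a * n_species))
    n_pd_only = int(round(cfg.frac_predawn_only * n_species))
    order = rng.permutation(n_species)
    no_a = np.zeros(n_species, dtype=bool)
    no_a[order[:n_no_a]] = True
    pd_only = np.zeros(n_species, dtype=bool)
    pd_only[order[n_no_a:n_no_a + n_pd_only]] = True

    truths: list[TrueSpecies] = []
    datasets: list[SpeciesDataset] = []
    rows = []
    for i in range(n_species):
        sp = draw_true_species(rng, f"SP{i + 1:03d}", bool(conservative[i]),
                               cfg.truth_model)
        gs50 = sp.psi_gs50_true
        reach = abs(gs50) + cfg.psi_margin if gs50 is not None else \
            abs(sp.p50) + cfg.psi_margin
        camp = CampaignConfig(
            n_obs=cfg.n_obs, psi_min=-float(np.clip(reach, 1.5, 9.0)),
            wet_skew=cfg.wet_skew, gs_noise_cv=cfg.gs_noise_cv,
            psi_noise_sd=cfg.psi_noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)))
        ds = simulate_campaign(sp, camp)
        if no_a[i]:
            ds.data["A"] = np.nan
            ds.has_assimilation = False
        if pd_only[i]:
            ds.data["psi_md"] = np.nan
            ds.predawn_only = True
        truths.append(sp)
        datasets.append(ds)
        rows.append({
            "species_id": sp.species_id, "truth_model": sp.model_id,
            "conservative": bool(conservative[i]),
            "alpha": sp.params.alpha, "d1": sp.params.d1,
            "b": sp.params.b, "c": sp.params.c, "g1": sp.params.g1,
            "k_plant": sp.k_plant, "p50": sp.p50, "p88": sp.p88,
            "psi_gs50_true": gs50, "no_a": bool(no_a[i]),
            "predawn_only": bool(pd_only[i]),
            "campaign_psi_min": camp.psi_min, "campaign_seed": camp.seed})
    return truths, datasets, pd.DataFrame(rows)


def flat_truth_species(rng_or_seed, species_id: str = "FLAT") -> TrueSpecies:
    """A species whose gs has no psi dependence (BBL truth): the null
    generator for false-positive checks on psi_gs50 detection."""
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    sp = draw_true_species(rng, species_id, conservative=False,
                           truth_model="BBL")
    # no hydraulic feedback either: psi has no causal path to gs
    return replace(sp, plc_feedback=False)
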