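"""Per-species parameter estimation and AIC model selection.

Each stomatal model is fit by minimizing the sum of squared errors between
predicted and observed gs with Nelder-Mead simplex runs launched from
multiple Latin-hypercube starting points in log-parameter space (the
objective has local minima; log-parameters keep it smooth while enforcing
positivity). Models are then compared within species by

    AIC = n ln(SSE/n) + 2k

(the least-squares form; the additive constant drops out of within-species
differences), with a difference of more than ``AIC_THRESHOLD`` = 3 treated
as decisive evidence for one model over another, and pairwise relative
likelihood 1/(1 + exp(-|dAIC|/2)).
"""
from __future__ import annotations

import hashlib
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .dataset import SpeciesDataset
from .exceptions import InvalidInputError, UndefinedSignal
from .models import (FREE_PARAMS, GAMMA_STAR_25, StomatalParams,
                     params_from_values, predict_gs)

log = logging.getLogger(__name__)

#: dAIC above which one model is decisively preferred.
AIC_THRESHOLD = 3.0

#: Multistart search bounds (natural scale); sampling is log-uniform.
PARAM_BOUNDS = {
    "g1": (0.1, 20.0),
    "alpha": (0.5, 50.0),
    "d1": (0.05, 10.0),
    "b": (0.3, 15.0),
    "c": (0.2, 12.0),
}

DEFAULT_N_STARTS = 20


@dataclass
class FitResult:
    """Best-fit parameters and fit statistics for one (species, model)."""

    species_id: str
    model_id: str
    params: StomatalParams
    sse: float
    n: int
    k: int
    aic: float
    r2: float
    rmse: float
    n_starts: int
    converged: bool
    best_start_index: int
    records_hash: str = ""

    def predict(self, dataset: SpeciesDataset) -> np.ndarray:
        """Predicted gs on the rows this model can evaluate."""
        A, Cs, D, psi, _ = _covariates(dataset, self.model_id)
        return np.asarray(predict_gs(self.params, A, Cs, D, psi))


@dataclass
class ModelSelection:
    """Within-species AIC comparison across models."""

    species_id: str
    aics: dict[str, float]
    delta_aics: dict[str, float]
    best_model_id: str  # a model id, or "ambiguous"
    relative_likelihoods: dict[str, float] = field(default_factory=dict)


def aic_from_sse(sse: float, n: int, k: int) -> float:
    """Least-squares AIC, n ln(SSE/n) + 2k; -inf sentinel at SSE = 0."""
    if n <= 0:
        raise InvalidInputError("n must be positive")
    if sse < 0:
        raise InvalidInputError("sse must be non-negative")
    if sse == 0.0:
        warnings.warn("SSE = 0: AIC is -inf (perfect fit)", RuntimeWarning,
                      stacklevel=2)
        return -math.inf
    return n * math.log(sse / n) + 2.0 * k


def goodness_of_fit(observed, predicted) -> tuple[float, float]:
    """(R^2, RMSE) of predictions against observations.

    R^2 = 1 - SSE/SStot about the observed mean (can be negative); RMSE in
    the units of gs.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise InvalidInputError("need equal-length series of length >= 2")
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot == 0.0 or np.ptp(obs) == 0:
        raise UndefinedSignal("R^2 undefined for constant observations")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sstot, math.sqrt(sse / obs.size)


def regression_r2(observed, predicted) -> float:
    """Squared Pearson correlation of predicted vs observed (the alternative
    'OLS regression R^2' convention); secondary to :func:`goodness_of_fit`."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise UndefinedSignal("correlation undefined for constant series")
    return float(np.corrcoef(obs, pred)[0, 1] ** 2)


def _covariates(dataset: SpeciesDataset, model_id: str,
                row_mask: Optional[np.ndarray] = None):
    """Extract (A, Cs, D, psi, rows) arrays for a model, dropping rows with
    missing required covariates. psi is midday, predawn where midday absent."""
    df = dataset.data
    need = ["gs", "A", "Cs", "D"]
    psi = dataset.psi
    ok = df[need].notna().all(axis=1)
    if model_id in ("T", "BBL.H"):
        if psi.isna().all():
            raise InvalidInputError(
                f"{dataset.species_id}: model {model_id} requires leaf water "
                "potential but none is present"
            )
        ok &= psi.notna()
    if row_mask is not None:
        ok &= pd.Series(row_mask, index=df.index)
    rows = np.flatnonzero(ok.to_numpy())
    sub = df.loc[ok]
    return (sub["A"].to_numpy(), sub["Cs"].to_numpy(), sub["D"].to_numpy(),
            psi[ok].to_numpy(), rows)


def _rows_hash(rows: np.ndarray) -> str:
    return hashlib.md5(np.ascontiguousarray(rows, dtype=np.int64).tobytes()
                       ).hexdigest()


def common_row_mask(dataset: SpeciesDataset,
                    model_ids: Iterable[str]) -> np.ndarray:
    """Rows usable by *every* listed model (AIC comparability requires fits
    on identical record subsets)."""
    mask = np.ones(len(dataset), dtype=bool)
    for m in model_ids:
        _, _, _, _, rows = _covariates(dataset, m)
        sub = np.zeros(len(dataset), dtype=bool)
        sub[rows] = True
        mask &= sub
    return mask


def sse_for_values(dataset: SpeciesDataset, model_id: str, values,
                   gamma_star: float = GAMMA_STAR_25,
                   row_mask: Optional[np.ndarray] = None) -> float:
    """SSE of a model at a given free-parameter vector (natural scale)."""
    A, Cs, D, psi, rows = _covariates(dataset, model_id, row_mask)
    gs_obs = dataset.data["gs"].to_numpy()[rows]
    params = params_from_values(model_id, values, gamma_star)
    pred = np.asarray(predict_gs(params, A, Cs, D, psi))
    return float(np.sum((gs_obs - pred) ** 2))


def fit_model(dataset: SpeciesDataset, model_id: str,
              n_starts: int = DEFAULT_N_STARTS, seed: int = 0,
              gamma_star: float = GAMMA_STAR_25,
              row_mask: Optional[np.ndarray] = None) -> FitResult:
    """Fit one stomatal model to one species by multistart Nelder-Mead.

    Starting points are a Latin-hypercube sample in log-parameter space over
    :data:`PARAM_BOUNDS` (plus the bounds midpoint); the best converged run
    is kept. ``row_mask`` restricts the records used (e.g. to the subset all
    models can evaluate). Deterministic for a given seed.
    """
    names = FREE_PARAMS[model_id]
    k = len(names)
    A, Cs, D, psi, rows = _covariates(dataset, model_id, row_mask)
    n = len(rows)
    if n < k + 2:
        raise InvalidInputError(
            f"{dataset.species_id}/{model_id}: need at least k+2={k + 2} "
            f"complete records, have {n}"
        )
    gs_obs = dataset.data["gs"].to_numpy()[rows]

    def objective(log_theta: np.ndarray) -> float:
        # clip keeps exp() finite and positive when the simplex roams
        params = params_from_values(
            model_id, np.exp(np.clip(log_theta, -30.0, 30.0)), gamma_star)
        pred = np.asarray(predict_gs(params, A, Cs, D, psi))
        return float(np.sum((gs_obs - pred) ** 2))

    lo = np.log([PARAM_BOUNDS[p][0] for p in names])
    hi = np.log([PARAM_BOUNDS[p][1] for p in names])
    sampler = qmc.LatinHypercube(d=k, seed=seed)
    starts = lo + sampler.random(n=n_starts) * (hi - lo)
    starts = np.vstack([starts, (lo + hi) / 2.0])  # midpoint safety start

    best = None
    best_idx = -1
    any_converged = False
    for i, x0 in enumerate(starts):
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-10,
                                "fatol": 1e-12, "adaptive": True})
        any_converged |= bool(res.success)
        if best is None or res.fun < best.fun:
            best, best_idx = res, i
    if not any_converged:
        log.warning("%s/%s: no Nelder-Mead start converged; returning best "
                    "incumbent", dataset.species_id, model_id)

    values = np.exp(np.clip(best.x, -30.0, 30.0))
    sse = float(best.fun)
    r2, rmse = goodness_of_fit(
        gs_obs, np.asarray(predict_gs(
            params_from_values(model_id, values, gamma_star), A, Cs, D, psi)))
    return FitResult(
        species_id=dataset.species_id, model_id=model_id,
        params=params_from_values(model_id, values, gamma_star),
        sse=sse, n=n, k=k, aic=aic_from_sse(sse, n, k) if sse > 0
        else -math.inf,
        r2=r2, rmse=rmse, n_starts=len(starts), converged=any_converged,
        best_start_index=best_idx, records_hash=_rows_hash(rows))


def relative_likelihood(delta_aic: float) -> float:
    """Pairwise Akaike relative likelihood, 1/(1 + exp(-|dAIC|/2))."""
    return 1.0 / (1.0 + math.exp(-abs(delta_aic) / 2.0))


def select_model(fits: Sequence[FitResult],
                 threshold: float = AIC_THRESHOLD) -> ModelSelection:
    """AIC selection among >= 2 fits of the same species on the same records.

    The minimum-AIC model is declared best only when every competitor's
    dAIC exceeds ``threshold``; otherwise the selection is "ambiguous".
    """
    if len(fits) < 2:
        raise InvalidInputError("need >= 2 fits to select among")
    species = {f.species_id for f in fits}
    if len(species) != 1:
        raise InvalidInputError(f"fits span multiple species: {species}")
    hashes = {f.records_hash for f in fits}
    if len(hashes) != 1:
        raise InvalidInputError(
            "fits were computed on differing record subsets; AICs are not "
            "comparable (refit with a common row mask)"
        )
    aics = {f.model_id: f.aic for f in fits}
    best_id = min(aics, key=aics.get)
    deltas = {m: a - aics[best_id] for m, a in aics.items()}
    rivals = [m for m in aics if m != best_id]
    decisive = all(deltas[m] > threshold for m in rivals)
    rel = {m: relative_likelihood(deltas[m]) for m in rivals}
    return ModelSelection(
        species_id=fits[0].species_id, aics=aics, delta_aics=deltas,
        best_model_id=best_id if decisive else "ambiguous",
        relative_likelihoods=rel)


def fit_all(panel: Iterable[SpeciesDataset],
            model_ids: Sequence[str] = ("M", "BBL", "BBL.H", "T"),
            n_starts: int = DEFAULT_N_STARTS, seed: int = 0,
            threshold: float = AIC_THRESHOLD,
            ) -> tuple[list[FitResult], list[ModelSelection], list[str]]:
    """Fit every model to every species with measured assimilation.

    Species lacking measured A are skipped (logged); psi-aware models are
    dropped for species without any psi column. All models for a species are
    fit on the common record subset so their AICs are comparable. Returns
    (fits, selections, skipped species ids).
    """
    fits: list[FitResult] = []
    selections: list[ModelSelection] = []
    skipped: list[str] = []
    for i, ds in enumerate(panel):
        if not ds.has_assimilation or ds.data["A"].notna().sum() == 0:
            log.info("skipping %s: no direct assimilation measurements",
                     ds.species_id)
            skipped.append(ds.species_id)
            continue
        usable = list(model_ids)
        if ds.psi.isna().all():
            usable = [m for m in usable if m not in ("T", "BBL.H")]
            log.info("%s: no psi column; skipping T/BBL.H", ds.species_id)
        mask = common_row_mask(ds, usable)
        sp_fits = [fit_model(ds, m, n_starts=n_starts, seed=seed + 7919 * i,
                             row_mask=mask) for m in usable]
        fits.extend(sp_fits)
        if len(sp_fits) >= 2:
            selections.append(select_model(sp_fits, threshold=threshold))
    return fits, selections, skipped


def fits_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Tidy table of fit results (one row per species x model)."""
    rows = []
    for f in fits:
        row = {"species_id": f.species_id, "model_id": f.model_id,
               "g1": f.params.g1, "alpha": f.params.alpha, "d1": f.params.d1,
               "b": f.params.b, "c": f.params.c,
               "gamma_star": f.params.gamma_star,
               "sse": f.sse, "n": f.n, "k": f.k, "aic": f.aic, "r2": f.r2,
               "rmse": f.rmse, "n_starts": f.n_starts,
               "converged": f.converged}
        rows.append(row)
    return pd.DataFrame(rows)


def selections_to_frame(selections: Sequence[ModelSelection]) -> pd.DataFrame:
    rows = []
    for s in selections:
        row = {"species_id": s.species_id, "best_model": s.best_model_id}
        for m, a in s.aics.items():
            row[f"aic_{m}"] = a
        for m, d in s.delta_aics.items():
            row[f"daic_{m}"] = d
        rows.append(row)
    return pd.DataFrame(rows)
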