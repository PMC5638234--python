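"""Marginal dependence of gs on leaf water potential via a bagged-tree surrogate.

A random-forest regression surrogate (500 trees, minimum node size 5)
predicts gs from {psi_leaf, D, A, Ca}; the marginal effect of psi is then
extracted by partial dependence — at each grid value psi0, every record's
psi is replaced by psi0 and the surrogate's predictions are averaged. The
raw curve is rescaled to the species' observed degree of stomatal closure
(wet-end anchored at 1; the dry-end anchor is the ratio of the lowest to the
highest gs measured under high light and near-ambient CO2), classified by
shape (Weibull-like / sigmoidal / negative-exponential / erratic), and the
water potential at 50% loss of conductance (psi_gs50) is read off the
scaled curve.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit
from sklearn.ensemble import RandomForestRegressor

from .dataset import SpeciesDataset
from .exceptions import InvalidInputError, SpeciesExcluded, UndefinedSignal
from .farquhar import FarquharParams, farquhar_a

log = logging.getLogger(__name__)

FEATURES = ["psi", "D", "A", "Ca"]

#: Cumulative upward movement (as a fraction of curve range) above which a
#: curve is called erratic.
ERRATIC_WIGGLE_FRACTION = 0.15

#: High-light threshold for the rescaling anchor (umol m-2 s-1).
PAR_HIGH = 800.0

#: CO2 window (fraction of campaign median) for the rescaling anchor.
CA_TOLERANCE = 0.10

DEFAULT_GRID_POINTS = 50

SHAPE_CLASSES = ("weibull-like", "sigmoidal", "negative-exponential",
                 "erratic")


@dataclass
class Surrogate:
    """Fitted random-forest surrogate plus its training design."""

    forest: RandomForestRegressor
    design: pd.DataFrame  # columns FEATURES, rows used for training
    gs: np.ndarray
    oob_r2: float
    species_id: str = ""

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(X[FEATURES].to_numpy())


@dataclass
class PartialDependenceCurve:
    """Marginal gs(psi) curve with rescaling and shape metadata."""

    species_id: str
    psi_grid: np.ndarray        # MPa, descending from 0
    response: np.ndarray        # raw mean surrogate prediction, mol m-2 s-1
    scaled_response: np.ndarray  # dimensionless, wet end = 1
    shape_class: str
    psi_gs50: Optional[float]   # MPa, None when undefined
    gs50_extrapolated: bool = False
    surrogate_oos_r2: float = float("nan")
    flags: list[str] = field(default_factory=list)


def _design_frame(dataset: SpeciesDataset,
                  farquhar_params: Optional[FarquharParams] = None,
                  default_par: float = 1500.0) -> tuple[pd.DataFrame, np.ndarray]:
    """Training design {psi, D, A, Ca} and gs target, with missing A filled
    by the Farquhar model (Ci from a Ball-Berry-style guess, 0.7 Ca)."""
    df = dataset.data
    psi = dataset.psi
    A = df["A"].copy()
    if A.isna().any():
        fill = A.isna()
        par = df["PAR"].fillna(default_par)
        ci = 0.7 * df["Cs"]
        A_model = farquhar_a(ci.to_numpy(), df["Tleaf"].to_numpy(),
                             par.to_numpy(), farquhar_params)
        A = A.where(~fill, pd.Series(A_model, index=df.index))
        log.info("%s: filled %d missing A values with the Farquhar model",
                 dataset.species_id, int(fill.sum()))
    X = pd.DataFrame({"psi": psi, "D": df["D"], "A": A, "Ca": df["Cs"]})
    ok = X.notna().all(axis=1) & df["gs"].notna()
    return X.loc[ok].reset_index(drop=True), df.loc[ok, "gs"].to_numpy()


def fit_surrogate(dataset: SpeciesDataset, n_trees: int = 500,
                  min_node: int = 5, seed: int = 0,
                  farquhar_params: Optional[FarquharParams] = None
                  ) -> Surrogate:
    """Fit the bagged regression-tree surrogate gs ~ {psi, D, A, Ca}.

    Species with fewer than three distinct psi values are excluded (the
    marginal psi curve cannot be reconstructed); raises
    :class:`SpeciesExcluded`, which panel drivers catch and log. The
    out-of-bag R^2 estimates out-of-sample explanatory power.
    """
    if dataset.n_distinct_psi() < 3:
        raise SpeciesExcluded(
            f"{dataset.species_id}: fewer than 3 distinct leaf water "
            "potential values"
        )
    X, gs = _design_frame(dataset, farquhar_params)
    # min_node follows the convention that a node with fewer than min_node
    # observations is not split further. One of p/3 features per split
    # (regression-forest default): considering all features lets greedy
    # splits ride the collinear assimilation covariate and flattens the
    # marginal psi response.
    forest = RandomForestRegressor(
        n_estimators=n_trees, min_samples_split=min_node,
        max_features=1.0 / 3.0, bootstrap=True, oob_score=True,
        random_state=seed, n_jobs=1)
    with warnings.catch_warnings():
        # tiny fixtures can leave some rows never out-of-bag
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        forest.fit(X.to_numpy(), gs)
    oob = float(forest.oob_score_) if np.isfinite(forest.oob_score_) else float("nan")
    return Surrogate(forest=forest, design=X, gs=gs, oob_r2=oob,
                     species_id=dataset.species_id)


def default_psi_grid(dataset: SpeciesDataset,
                     n_points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Descending grid from 0 to the most negative observed working psi."""
    lo = float(dataset.psi.min())
    return np.linspace(0.0, lo, n_points)


def partial_dependence(surrogate: Surrogate, psi_grid: np.ndarray,
                       variable: str = "psi") -> np.ndarray:
    """Raw marginal curve: mean prediction with ``variable`` set to each
    grid value, all other covariates held at their observed values.

    The psi marginal is the primary analysis; marginals on D, A or Ca are
    available as diagnostics.
    """
    if variable not in FEATURES:
        raise InvalidInputError(f"variable must be one of {FEATURES}")
    grid = np.asarray(psi_grid, dtype=float)
    if grid.size == 0:
        raise InvalidInputError("empty grid")
    out = np.empty(grid.size)
    X = surrogate.design.copy()
    for i, v0 in enumerate(grid):
        X[variable] = v0
        out[i] = float(np.mean(surrogate.predict(X)))
    return out


def closure_anchor(dataset: SpeciesDataset, par_high: float = PAR_HIGH,
                   ca_tolerance: float = CA_TOLERANCE) -> tuple[float, str]:
    """Observed degree of stomatal closure, min gs / max gs.

    Records are filtered to high light (PAR >= ``par_high``, or the top PAR
    quartile when few records reach it; no light filter when PAR was not
    recorded) and near-median CO2 (within ``ca_tolerance`` of the campaign
    median). Falls back to unfiltered extremes when the filter empties the
    campaign. Returns (anchor in [0, 1], filter description).
    """
    df = dataset.data
    gs = df["gs"]
    mask = gs.notna()
    note = "unfiltered"
    par = df["PAR"]
    if par.notna().sum() >= 4:
        thresh = par_high
        if (par >= par_high).sum() < 4:
            thresh = float(par.quantile(0.75))
        mask &= par >= thresh
        note = f"PAR>={thresh:g}"
    ca = df["Cs"]
    med = float(ca.median())
    mask &= (ca - med).abs() <= ca_tolerance * med
    note += f", |Ca-{med:g}|<={ca_tolerance:.0%}"
    if not mask.any():
        warnings.warn("light/CO2 filter removed all records; using "
                      "unfiltered gs extremes", RuntimeWarning, stacklevel=2)
        mask = gs.notna()
        note = "fallback-unfiltered"
    sub = gs[mask]
    gmax = float(sub.max())
    if gmax <= 0:
        return 1.0, note + " (degenerate)"
    return max(float(sub.min()), 0.0) / gmax, note


def rescale_curve(response: np.ndarray, dataset: SpeciesDataset,
                  par_high: float = PAR_HIGH,
                  ca_tolerance: float = CA_TOLERANCE
                  ) -> tuple[np.ndarray, list[str]]:
    """Affine rescale of a raw marginal curve to the observed closure range.

    The curve's wet-end value maps to 1 and its minimum to the closure
    anchor: a species whose highest measured gs is 100 and lowest
    water-stressed gs is 40 spans [0.4, 1]. Order-preserving.
    """
    resp = np.asarray(response, dtype=float)
    flags: list[str] = []
    low, note = closure_anchor(dataset, par_high, ca_tolerance)
    if "fallback" in note:
        flags.append("anchor-fallback-unfiltered")
    wet = resp[0]
    rmin = resp.min()
    if wet - rmin <= 1e-12 or low >= 1.0:
        flags.append("no-closure-observed")
        return np.ones_like(resp), flags
    scaled = low + (1.0 - low) * (resp - rmin) / (wet - rmin)
    return scaled, flags


# ---------------------------------------------------------------- templates

def _weibull_template(x, b, c, yf):
    return yf + (1.0 - yf) * np.exp(-((x / c) ** b))


def _logistic_template(x, x0, s, yf):
    norm = 1.0 + np.exp(-x0 / s)
    return yf + (1.0 - yf) * norm / (1.0 + np.exp((x - x0) / s))


def _negexp_template(x, lam, yf):
    return yf + (1.0 - yf) * np.exp(-x / lam)


def _fit_template(func, x, y, p0, bounds):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(func, x, y, p0=p0, bounds=bounds,
                                maxfev=5000)
        sse = float(np.sum((func(x, *popt) - y) ** 2))
        return popt, sse
    except (RuntimeError, ValueError):
        return None, np.inf


def fit_shape_templates(psi_grid: np.ndarray, scaled: np.ndarray) -> dict:
    """Least-squares fits of the three admissible closure templates to the
    scaled curve (as functions of |psi|). Returns per-template (params, sse)."""
    x = np.abs(np.asarray(psi_grid, dtype=float))
    y = np.asarray(scaled, dtype=float)
    span = max(x.max(), 1e-6)
    out = {}
    out["weibull-like"] = _fit_template(
        _weibull_template, x, y, p0=[2.0, 0.5 * span, max(y.min() - 0.05, 0.0)],
        bounds=([0.1, 1e-3, -0.5], [30.0, 10.0 * span, 1.0]))
    out["sigmoidal"] = _fit_template(
        _logistic_template, x, y, p0=[0.5 * span, 0.1 * span,
                                      max(y.min() - 0.05, 0.0)],
        bounds=([1e-3, 1e-3, -0.5], [10.0 * span, 5.0 * span, 1.0]))
    out["negative-exponential"] = _fit_template(
        _negexp_template, x, y, p0=[0.5 * span, max(y.min() - 0.05, 0.0)],
        bounds=([1e-3, -0.5], [20.0 * span, 1.0]))
    return out


def classify_shape(psi_grid: np.ndarray, scaled: np.ndarray
                   ) -> tuple[str, dict]:
    """Classify a scaled marginal curve.

    "erratic" when cumulative upward movement (toward more negative psi)
    exceeds :data:`ERRATIC_WIGGLE_FRACTION` of the curve's range, or the
    curve rises overall; otherwise the best-fitting template among Weibull,
    logistic and negative-exponential. Returns (class, template fits).
    """
    y = np.asarray(scaled, dtype=float)
    if y.size < 5:
        raise InvalidInputError("need >= 5 grid points to classify")
    rng = float(y.max() - y.min())
    if rng <= 1e-12:
        return "erratic", {}
    diffs = np.diff(y)  # along decreasing psi: closure should be <= 0
    upward = float(np.sum(diffs[diffs > 0]))
    if upward > ERRATIC_WIGGLE_FRACTION * rng or y[-1] > y[0]:
        return "erratic", {}
    fits = fit_shape_templates(psi_grid, y)
    best = min(fits, key=lambda k: fits[k][1])
    if not np.isfinite(fits[best][1]):
        return "erratic", fits
    return best, fits


def psi_gs50_from_curve(psi_grid: np.ndarray, scaled: np.ndarray,
                        shape_class: str,
                        template_fits: Optional[dict] = None
                        ) -> tuple[float, bool]:
    """Water potential at 50% loss of stomatal conductance.

    Found by monotone linear interpolation between the bracketing grid
    points; when the curve never reaches 0.5, solved from the fitted Weibull
    template instead and flagged extrapolated. Undefined (raises) for
    erratic curves.
    """
    if shape_class == "erratic":
        raise UndefinedSignal("psi_gs50 undefined for an erratic curve")
    psi = np.asarray(psi_grid, dtype=float)
    y = np.asarray(scaled, dtype=float)
    below = np.flatnonzero(y <= 0.5)
    if below.size:
        j = below[0]
        if j == 0:
            return float(psi[0]), False
        i = j - 1
        frac = (y[i] - 0.5) / (y[i] - y[j])
        return float(psi[i] + frac * (psi[j] - psi[i])), False
    # extrapolate from the Weibull template
    fits = template_fits or fit_shape_templates(psi, y)
    popt, sse = fits.get("weibull-like", (None, np.inf))
    if popt is None or not np.isfinite(sse):
        raise UndefinedSignal("0.5 level not bracketed and Weibull template "
                              "fit failed")
    b, c, yf = popt
    if yf >= 0.5:
        raise UndefinedSignal("fitted closure floor is above 0.5; psi_gs50 "
                              "not identifiable")
    # solve yf + (1-yf) exp(-(x/c)^b) = 0.5
    x50 = c * (-np.log((0.5 - yf) / (1.0 - yf))) ** (1.0 / b)
    return -float(x50), True


def analyze_species(dataset: SpeciesDataset, n_trees: int = 500,
                    min_node: int = 5, seed: int = 0,
                    n_grid: int = DEFAULT_GRID_POINTS,
                    farquhar_params: Optional[FarquharParams] = None
                    ) -> PartialDependenceCurve:
    """Full per-species marginal-curve analysis.

    Fits the surrogate, extracts and rescales the partial-dependence curve,
    classifies its shape and locates psi_gs50 (None when the curve is
    erratic or the 0.5 level is unidentifiable).
    """
    surr = fit_surrogate(dataset, n_trees=n_trees, min_node=min_node,
                         seed=seed, farquhar_params=farquhar_params)
    grid = default_psi_grid(dataset, n_grid)
    raw = partial_dependence(surr, grid)
    scaled, flags = rescale_curve(raw, dataset)
    shape, fits = classify_shape(grid, scaled)
    gs50: Optional[float] = None
    extrap = False
    if shape != "erratic":
        try:
            gs50, extrap = psi_gs50_from_curve(grid, scaled, shape, fits)
        except UndefinedSignal as e:
            flags.append(str(e))
    return PartialDependenceCurve(
        species_id=dataset.species_id, psi_grid=grid, response=raw,
        scaled_response=scaled, shape_class=shape, psi_gs50=gs50,
        gs50_extrapolated=extrap, surrogate_oos_r2=surr.oob_r2, flags=flags)


def curves_to_frame(curves: list[PartialDependenceCurve]) -> pd.DataFrame:
    """Tidy long-format table of all curves."""
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "species_id": c.species_id, "psi": c.psi_grid,
            "response": c.response, "scaled_response": c.scaled_response}))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["species_id", "psi", "response", "scaled_response"])


def summary_frame(curves: list[PartialDependenceCurve]) -> pd.DataFrame:
    return pd.DataFrame([{
        "species_id": c.species_id, "shape_class": c.shape_class,
        "psi_gs50": c.psi_gs50, "gs50_extrapolated": c.gs50_extrapolated,
        "surrogate_oos_r2": c.surrogate_oos_r2,
        "flags": ";".join(c.flags)} for c in curves])
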