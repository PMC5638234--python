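"""Residual bias diagnostics and collinearity screens.

For each fitted model, residuals (observed - predicted gs) are regressed on
leaf temperature, VPD and predawn water potential (the soil-moisture proxy):
a significant slope marks a persistent prediction bias along that driver.
Dry-condition bias is summarized as the percent over/under-prediction over
the records at or below the species' 10th-percentile predawn psi
(negative = over-prediction). Collinearity risk between VPD and psi is
screened with variance inflation factors and by correlating the AIC gain of
the hydraulic model with the within-species VPD-psi correlation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .dataset import SpeciesDataset
from .exceptions import InvalidInputError, UndefinedSignal
from .fitting import FitResult, _covariates

log = logging.getLogger(__name__)

DRY_PERCENTILE = 10.0


@dataclass
class BiasReport:
    """Residual-bias summary for one (species, model) pair.

    Slopes are OLS slopes of residuals on each covariate; negative slopes on
    Tleaf/VPD and positive slopes on psi_s indicate over-prediction under
    dry conditions. ``pct_bias_dry`` is negative when the model
    over-predicts gs in the dry-soil subset.
    """

    species_id: str
    model_id: str
    slope_tleaf: Optional[tuple[float, float, float]]  # (slope, se, p)
    slope_vpd: Optional[tuple[float, float, float]]
    slope_psis: Optional[tuple[float, float, float]]
    pct_bias_dry: Optional[float]
    n_dry: int
    psi_dry_threshold: Optional[float]


@dataclass
class CollinearityReport:
    """VIFs, VPD-psi correlations and cross-species screens."""

    vifs: pd.DataFrame                 # species_id x predictor
    corr_vpd_psi: pd.Series            # per species
    cross_species_r: Optional[float] = None   # dAIC gain vs corr(D, psi)
    cross_species_p: Optional[float] = None
    parameter_correlations: pd.DataFrame = field(
        default_factory=pd.DataFrame)  # pairwise r/p among BBL.H params


def residuals(fit: FitResult, dataset: SpeciesDataset) -> pd.DataFrame:
    """Per-record residuals (observed - predicted gs) with covariates.

    Rows lacking a covariate the model needs are dropped (count logged).
    The residual sum is generally nonzero: the fits are nonlinear with no
    intercept.
    """
    if fit.species_id != dataset.species_id:
        raise InvalidInputError(
            f"fit is for {fit.species_id}, dataset is {dataset.species_id}")
    A, Cs, D, psi, rows = _covariates(dataset, fit.model_id)
    dropped = len(dataset) - len(rows)
    if dropped:
        log.info("%s/%s: dropped %d records lacking covariates",
                 fit.species_id, fit.model_id, dropped)
    from .models import predict_gs
    pred = np.asarray(predict_gs(fit.params, A, Cs, D, psi))
    sub = dataset.data.iloc[rows]
    return pd.DataFrame({
        "residual": sub["gs"].to_numpy() - pred,
        "predicted": pred, "observed": sub["gs"].to_numpy(),
        "Tleaf": sub["Tleaf"].to_numpy(), "D": sub["D"].to_numpy(),
        "psi_pd": sub["psi_pd"].to_numpy()})


def bias_slope(resid: Sequence[float], covariate: Sequence[float]
               ) -> tuple[float, float, float]:
    """OLS slope of residuals on a covariate with its SE and t-test p-value."""
    y = np.asarray(resid, dtype=float)
    x = np.asarray(covariate, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if y.size < 3:
        raise InvalidInputError("need >= 3 records for a bias regression")
    if np.ptp(x) == 0:
        raise UndefinedSignal("covariate is constant; slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.params[1]), float(model.bse[1]), float(model.pvalues[1])


def pct_bias_dry(fit: FitResult, dataset: SpeciesDataset,
                 percentile: float = DRY_PERCENTILE
                 ) -> tuple[float, int, float]:
    """Percent over/under-prediction in the dry-soil subset.

    The subset is records with predawn psi at or below the species'
    ``percentile``-th percentile (linear-interpolation quantile). Returns
    (100 (mean obs - mean pred)/mean obs, n_dry, threshold); the
    ratio-of-means form avoids division by near-zero individual records.
    Negative values mean the model over-predicts gs when soils are dry.
    """
    res = residuals(fit, dataset)
    res = res[np.isfinite(res["psi_pd"])]
    if len(res) < 10:
        raise InvalidInputError(
            f"{dataset.species_id}: need >= 10 records with predawn psi")
    thresh = float(np.percentile(res["psi_pd"], percentile))
    dry = res[res["psi_pd"] <= thresh]
    if dry.empty:
        raise UndefinedSignal("dry subset is empty")
    mean_obs = float(dry["observed"].mean())
    if mean_obs == 0:
        raise UndefinedSignal("mean observed gs in dry subset is zero")
    bias = 100.0 * (mean_obs - float(dry["predicted"].mean())) / mean_obs
    return bias, len(dry), thresh


def bias_report(fit: FitResult, dataset: SpeciesDataset,
                percentile: float = DRY_PERCENTILE) -> BiasReport:
    """Full residual-bias diagnostics for one fit."""
    res = residuals(fit, dataset)

    def safe_slope(col):
        vals = res[col]
        try:
            return bias_slope(res["residual"], vals)
        except (InvalidInputError, UndefinedSignal):
            return None

    try:
        bias, n_dry, thresh = pct_bias_dry(fit, dataset, percentile)
    except (InvalidInputError, UndefinedSignal):
        bias, n_dry, thresh = None, 0, None
    return BiasReport(
        species_id=fit.species_id, model_id=fit.model_id,
        slope_tleaf=safe_slope("Tleaf"), slope_vpd=safe_slope("D"),
        slope_psis=safe_slope("psi_pd"), pct_bias_dry=bias, n_dry=n_dry,
        psi_dry_threshold=thresh)


def species_vifs(dataset: SpeciesDataset) -> pd.Series:
    """Variance inflation factors among {psi, D, A, Ca} from auxiliary
    regressions. Perfectly collinear predictors yield an inf sentinel."""
    df = pd.DataFrame({"psi": dataset.psi, "D": dataset.data["D"],
                       "A": dataset.data["A"], "Ca": dataset.data["Cs"]})
    df = df.dropna(axis=1, how="all").dropna()
    keep = [c for c in df.columns if df[c].nunique() > 1]
    df = df[keep]
    X = sm.add_constant(df.to_numpy())
    out = {}
    for i, col in enumerate(df.columns):
        with np.errstate(divide="ignore"):
            try:
                v = variance_inflation_factor(X, i + 1)
            except Exception:
                v = np.inf
        out[col] = float(v) if np.isfinite(v) else np.inf
    return pd.Series(out, name=dataset.species_id)


def collinearity_screen(panel: Sequence[SpeciesDataset],
                        fits: Sequence[FitResult]) -> CollinearityReport:
    """Panel-wide collinearity diagnostics.

    Per-species VIFs and corr(D, psi); across species, the Pearson
    correlation of the AIC gain of BBL.H over BBL against corr(D, psi)
    (collinearity would produce spurious gains), and pairwise correlations
    among fitted BBL.H parameters.
    """
    vif_rows, corr = {}, {}
    for ds in panel:
        vif_rows[ds.species_id] = species_vifs(ds)
        d = ds.data["D"]
        psi = ds.psi
        ok = d.notna() & psi.notna()
        if ok.sum() >= 3 and d[ok].nunique() > 1 and psi[ok].nunique() > 1:
            corr[ds.species_id] = float(np.corrcoef(d[ok], psi[ok])[0, 1])
    vifs = pd.DataFrame(vif_rows).T
    corr = pd.Series(corr, name="corr_vpd_psi")

    fit_df = pd.DataFrame([{"species_id": f.species_id,
                            "model_id": f.model_id, "aic": f.aic,
                            "alpha": f.params.alpha, "d1": f.params.d1,
                            "b": f.params.b, "c": f.params.c}
                           for f in fits])
    r = p = None
    param_corr = pd.DataFrame()
    if not fit_df.empty:
        piv = fit_df.pivot_table(index="species_id", columns="model_id",
                                 values="aic")
        if {"BBL", "BBL.H"} <= set(piv.columns):
            gain = (piv["BBL"] - piv["BBL.H"]).rename("daic_gain")
            joined = pd.concat([gain, corr], axis=1).dropna()
            if len(joined) >= 3:
                r_, p_ = stats.pearsonr(joined["daic_gain"],
                                        joined["corr_vpd_psi"])
                r, p = float(r_), float(p_)
        bblh = fit_df[fit_df["model_id"] == "BBL.H"]
        cols = ["alpha", "d1", "b", "c"]
        if len(bblh) >= 3:
            rows = []
            for i in range(len(cols)):
                for j in range(i + 1, len(cols)):
                    x, y = bblh[cols[i]], bblh[cols[j]]
                    if x.nunique() > 1 and y.nunique() > 1:
                        r_, p_ = stats.pearsonr(x, y)
                        rows.append({"param_x": cols[i], "param_y": cols[j],
                                     "r": float(r_), "p": float(p_)})
            param_corr = pd.DataFrame(rows)
    return CollinearityReport(vifs=vifs, corr_vpd_psi=corr,
                              cross_species_r=r, cross_species_p=p,
                              parameter_correlations=param_corr)


def bias_reports_to_frame(reports: Sequence[BiasReport]) -> pd.DataFrame:
    rows = []
    for b in reports:
        row = {"species_id": b.species_id, "model_id": b.model_id,
               "pct_bias_dry": b.pct_bias_dry, "n_dry": b.n_dry,
               "psi_dry_threshold": b.psi_dry_threshold}
        for name, tup in (("tleaf", b.slope_tleaf), ("vpd", b.slope_vpd),
                          ("psis", b.slope_psis)):
            if tup is None:
                row[f"slope_{name}"] = row[f"se_{name}"] = row[f"p_{name}"] = np.nan
            else:
                row[f"slope_{name}"], row[f"se_{name}"], row[f"p_{name}"] = tup
        rows.append(row)
    return pd.DataFrame(rows)
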