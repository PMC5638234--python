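"""Coupling of stomatal closure to xylem vulnerability.

Stomatal closure (psi_gs50, from the marginal gs(psi) curve) is compared
with xylem vulnerability (psi_x50 = P50, from the species' Weibull
vulnerability curve). Species that close stomata before substantial
embolism have |psi_gs50| < |psi_x50|, equivalently a percent loss of stem
conductivity at psi_gs50 below 50% — the conservative end of the
risky-conservative strategy axis. A panel-level OLS regression of psi_gs50
on psi_x50 quantifies the coupling.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import SpeciesDataset
from .exceptions import InvalidInputError, UndefinedSignal
from .models import WeibullCurve, plc, weibull_from_p50_p88

log = logging.getLogger(__name__)

#: PLC above which a campaign is considered to have reached substantial
#: water stress.
STRESS_PLC_THRESHOLD = 10.0


@dataclass
class SpeciesHydraulics:
    """Joined stomatal-closure and xylem-vulnerability traits for a species."""

    species_id: str
    p50: float
    p88: float
    psi_gs50: Optional[float] = None
    gs50_extrapolated: bool = False
    plc_at_min_psi: Optional[float] = None

    def __post_init__(self) -> None:
        self.vulnerability: WeibullCurve = weibull_from_p50_p88(self.p50,
                                                                self.p88)


@dataclass
class Gs50P50Regression:
    slope: float
    intercept: float
    r2: float
    t: float
    p: float
    n: int
    below_1to1_count: int


def plc_at_psi_gs50(species: SpeciesHydraulics) -> float:
    """Percent loss of stem conductivity at the stomatal-closure midpoint."""
    if species.psi_gs50 is None:
        raise UndefinedSignal(
            f"{species.species_id}: psi_gs50 undefined")
    return plc(species.psi_gs50, species.vulnerability)


def plc_at_min_observed_psi(dataset: SpeciesDataset,
                            vulnerability: WeibullCurve) -> float:
    """PLC at the most negative observed leaf water potential.

    Flags whether the campaign reached substantial water stress (>10%
    embolism screen): compare against :data:`STRESS_PLC_THRESHOLD`.
    """
    return plc(dataset.min_psi, vulnerability)


def campaign_water_stressed(dataset: SpeciesDataset,
                            vulnerability: WeibullCurve,
                            threshold: float = STRESS_PLC_THRESHOLD) -> bool:
    return plc_at_min_observed_psi(dataset, vulnerability) > threshold


def below_1to1(species: SpeciesHydraulics) -> bool:
    """True when stomata close before 50% embolism: |psi_gs50| < |psi_x50|.

    Equivalent to PLC(psi_gs50) < 50% and to the species falling below the
    1:1 line in the (psi_x50, psi_gs50) magnitude plane.
    """
    if species.psi_gs50 is None:
        raise UndefinedSignal(f"{species.species_id}: psi_gs50 undefined")
    return abs(species.psi_gs50) < abs(species.p50)


def gs50_vs_p50_regression(panel: Sequence[SpeciesHydraulics],
                           include_extrapolated: bool = True
                           ) -> Gs50P50Regression:
    """OLS of psi_gs50 (y) on psi_x50 (x) across species, both signed MPa.

    Also counts species strictly below the 1:1 line (closure before 50%
    embolism). Species without a defined psi_gs50 are omitted (logged);
    extrapolated estimates can be excluded with the toggle.
    """
    pts = []
    for s in panel:
        if s.psi_gs50 is None:
            log.info("%s: psi_gs50 undefined; omitted from regression",
                     s.species_id)
            continue
        if s.gs50_extrapolated and not include_extrapolated:
            continue
        pts.append((s.p50, s.psi_gs50, below_1to1(s)))
    if len(pts) < 3:
        raise InvalidInputError(
            f"need >= 3 species with both psi_gs50 and p50, have {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return Gs50P50Regression(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r2=float(model.rsquared), t=float(model.tvalues[1]),
        p=float(model.pvalues[1]), n=len(pts),
        below_1to1_count=int(sum(p[2] for p in pts)))


def panel_plc_summary(panel: Sequence[SpeciesHydraulics]
                      ) -> tuple[float, float, int]:
    """(mean, median, n) of PLC at psi_gs50 over species where defined."""
    vals = []
    for s in panel:
        try:
            vals.append(plc_at_psi_gs50(s))
        except UndefinedSignal:
            log.info("%s: omitted from PLC summary", s.species_id)
    if not vals:
        raise UndefinedSignal("no species with defined psi_gs50")
    arr = np.asarray(vals)
    return float(arr.mean()), float(np.median(arr)), len(vals)


def hydraulics_to_frame(panel: Sequence[SpeciesHydraulics]) -> pd.DataFrame:
    rows = []
    for s in panel:
        try:
            plc50 = plc_at_psi_gs50(s)
            below = below_1to1(s)
        except UndefinedSignal:
            plc50, below = np.nan, None
        rows.append({"species_id": s.species_id, "p50": s.p50, "p88": s.p88,
                     "weibull_b": s.vulnerability.b,
                     "weibull_c": s.vulnerability.c,
                     "psi_gs50": s.psi_gs50,
                     "gs50_extrapolated": s.gs50_extrapolated,
                     "plc_at_gs50": plc50, "below_1to1": below,
                     "plc_at_min_psi": s.plc_at_min_psi})
    return pd.DataFrame(rows)
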