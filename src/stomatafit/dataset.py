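"""Containers for leaf gas-exchange campaigns.

A campaign is a set of concurrent measurements of stomatal conductance
(gs, mol m-2 s-1), net assimilation (A, umol m-2 s-1), leaf-surface CO2
(Cs, umol mol-1), vapor pressure deficit (D, kPa), leaf temperature
(Tleaf, C), and leaf water potential (psi, MPa <= 0) — midday and/or
predawn — optionally with photosynthetic photon flux (PAR).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

#: Canonical column order of the in-memory measurement table.
COLUMNS = ["gs", "A", "Cs", "D", "Tleaf", "psi_md", "psi_pd", "PAR"]

#: Canonical CSV header (units encoded in the names).
CSV_COLUMNS = {
    "gs": "gs_mol_m2_s",
    "A": "A_umol_m2_s",
    "Cs": "Cs_umol_mol",
    "D": "D_kPa",
    "Tleaf": "Tleaf_C",
    "psi_md": "psi_md_MPa",
    "psi_pd": "psi_pd_MPa",
    "PAR": "PAR_umol_m2_s",
}


@dataclass
class GasExchangeRecord:
    """One concurrent measurement set.

    Missing optional quantities are represented as ``None`` (``NaN`` in the
    tabular form). At least one of ``psi_md``/``psi_pd`` must be present.
    """

    gs: float
    Cs: float
    D: float
    Tleaf: float
    A: Optional[float] = None
    psi_md: Optional[float] = None
    psi_pd: Optional[float] = None
    PAR: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gs < 0:
            raise InvalidInputError(f"gs must be >= 0, got {self.gs}")
        if self.Cs <= 0:
            raise InvalidInputError(f"Cs must be > 0, got {self.Cs}")
        if self.D < 0:
            raise InvalidInputError(f"D must be >= 0, got {self.D}")
        for name in ("psi_md", "psi_pd"):
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and v > 0:
                raise InvalidInputError(f"{name} must be <= 0 MPa, got {v}")
        md, pd_ = self.psi_md, self.psi_pd
        if (md is None or np.isnan(md)) and (pd_ is None or np.isnan(pd_)):
            raise InvalidInputError("at least one of psi_md/psi_pd required")


@dataclass
class SpeciesDataset:
    """A species' gas-exchange records plus hydraulic metadata.

    Parameters
    ----------
    species_id
        Species label.
    data
        DataFrame with the columns in :data:`COLUMNS`; missing values NaN.
    p50, p88
        Xylem water potentials (MPa, negative) at 50% / 88% loss of stem
        hydraulic conductivity, when known.
    predawn_only
        True when midday psi was never measured and predawn psi substitutes.
    has_assimilation
        True when A was measured directly (not model-filled).
    """

    species_id: str
    data: pd.DataFrame
    p50: Optional[float] = None
    p88: Optional[float] = None
    predawn_only: bool = False
    has_assimilation: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidInputError(f"dataset missing columns: {missing}")
        self.data = self.data[COLUMNS].reset_index(drop=True)
        if self.data["psi_md"].isna().all() and self.data["psi_pd"].isna().all():
            raise InvalidInputError(
                f"{self.species_id}: no leaf water potential measurements"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def psi(self) -> pd.Series:
        """Working leaf water potential: midday, predawn where midday absent."""
        return self.data["psi_md"].fillna(self.data["psi_pd"])

    @property
    def min_psi(self) -> float:
        """Most negative observed water potential (midday or predawn)."""
        vals = pd.concat([self.data["psi_md"], self.data["psi_pd"]]).dropna()
        return float(vals.min())

    def n_distinct_psi(self) -> int:
        return int(self.psi.dropna().round(6).nunique())


def records_to_frame(records: list[GasExchangeRecord]) -> pd.DataFrame:
    """Stack validated records into the canonical table."""
    rows = [
        {c: (np.nan if getattr(r, c) is None else getattr(r, c)) for c in COLUMNS}
        for r in records
    ]
    return pd.DataFrame(rows, columns=COLUMNS)
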