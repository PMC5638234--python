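"""Readers and writers for gas-exchange campaign tables.

Canonical CSV schema (units in the header names): ``species``,
``gs_mol_m2_s``, ``A_umol_m2_s``, ``Cs_umol_mol``, ``D_kPa``, ``Tleaf_C``,
``psi_md_MPa``, ``psi_pd_MPa``, ``PAR_umol_m2_s``. A ``column_map``
translates heterogeneous source headers onto this schema (field
compilations rarely share a format). gs reported in mmol (median > 10) is
auto-rescaled to mol with a warning.
"""
from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .dataset import COLUMNS, CSV_COLUMNS, SpeciesDataset
from .exceptions import SchemaError

log = logging.getLogger(__name__)

REQUIRED = ["gs", "Cs", "D", "Tleaf"]

#: gs medians above this are taken to be mmol m-2 s-1 and rescaled.
GS_MMOL_HEURISTIC = 10.0


def _resolve_columns(df: pd.DataFrame,
                     column_map: Optional[Mapping[str, str]]) -> dict[str, str]:
    """Map canonical field -> source column, via column_map then the
    canonical CSV names, then bare field names."""
    resolved: dict[str, str] = {}
    for canon in COLUMNS + ["species"]:
        candidates = []
        if column_map and canon in column_map:
            candidates.append(column_map[canon])
        candidates.append(CSV_COLUMNS.get(canon, canon))
        candidates.append(canon)
        for cand in candidates:
            if cand in df.columns:
                resolved[canon] = cand
                break
    return resolved


def read_gas_exchange_csv(path, column_map: Optional[Mapping[str, str]] = None,
                          species: Optional[str] = None
                          ) -> dict[str, SpeciesDataset]:
    """Read one or more species' campaigns from a CSV.

    Returns {species_id: SpeciesDataset}. Non-numeric cells reject the row
    (counted, logged); a file with neither psi column is a schema error
    (leaf water potential is an inclusion criterion).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    raw = pd.read_csv(path)
    resolved = _resolve_columns(raw, column_map)
    missing = [c for c in REQUIRED if c not in resolved]
    if missing:
        raise SchemaError(
            f"{path.name}: cannot resolve required columns {missing}; "
            f"available: {list(raw.columns)}; pass a column_map")
    if "psi_md" not in resolved and "psi_pd" not in resolved:
        raise SchemaError(
            f"{path.name}: neither midday nor predawn water potential "
            "column found (inclusion requires concurrent psi)")

    df = pd.DataFrame(index=raw.index)
    for canon in COLUMNS:
        if canon in resolved:
            df[canon] = pd.to_numeric(raw[resolved[canon]], errors="coerce")
        else:
            df[canon] = np.nan
    n_bad = int((raw[resolved["gs"]].notna()
                 & df["gs"].isna()).sum())
    complete = df[REQUIRED].notna().all(axis=1)
    n_bad += int((~complete).sum())
    if n_bad:
        log.warning("%s: rejected %d rows with non-numeric or missing "
                    "required cells", path.name, n_bad)
    df = df[complete]

    med = float(df["gs"].median())
    if med > GS_MMOL_HEURISTIC:
        warnings.warn(
            f"{path.name}: gs median {med:.1f} looks like mmol m-2 s-1; "
            "rescaling to mol", UserWarning, stacklevel=2)
        df["gs"] = df["gs"] / 1000.0

    if "species" in resolved:
        groups = raw.loc[df.index, resolved["species"]].astype(str)
    else:
        groups = pd.Series(species or path.stem, index=df.index)

    out: dict[str, SpeciesDataset] = {}
    for sp, sub in df.groupby(groups):
        predawn_only = sub["psi_md"].isna().all()
        out[str(sp)] = SpeciesDataset(
            species_id=str(sp), data=sub.reset_index(drop=True),
            predawn_only=predawn_only,
            has_assimilation=bool(sub["A"].notna().any()))
    return out


def write_gas_exchange_csv(datasets, path) -> Path:
    """Write one or more SpeciesDataset to the canonical CSV schema.

    Round-trips losslessly through :func:`read_gas_exchange_csv` for all
    defined fields.
    """
    if isinstance(datasets, SpeciesDataset):
        datasets = [datasets]
    frames = []
    for ds in datasets:
        d = ds.data.rename(columns=CSV_COLUMNS).copy()
        d.insert(0, "species", ds.species_id)
        frames.append(d)
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return path


def write_truth_json(truth_table: pd.DataFrame, path) -> Path:
    """Hidden-truth record of a synthetic panel (for test harnesses)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = json.loads(truth_table.to_json(orient="records"))
    path.write_text(json.dumps(records, indent=1))
    return path
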