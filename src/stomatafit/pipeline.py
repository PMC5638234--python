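"""End-to-end pipeline driver: simulate/read -> fit -> PD -> bias -> hydraulics.

All stage outputs are CSVs under the configured output directory plus a
JSON run manifest recording seeds, counts and species exclusions, so any
run can be reproduced from the manifest alone.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dataset import SpeciesDataset
from .drought_bias import (bias_report, bias_reports_to_frame,
                           collinearity_screen)
from .exceptions import (ConfigError, SpeciesExcluded, StomatafitError,
                         UndefinedSignal)
from .fitting import (fit_all, fits_to_frame, selections_to_frame)
from .hydraulics_link import (Gs50P50Regression, SpeciesHydraulics,
                              gs50_vs_p50_regression, hydraulics_to_frame,
                              panel_plc_summary, plc_at_min_observed_psi)
from .io import read_gas_exchange_csv, write_gas_exchange_csv, write_truth_json
from .partial_dependence import (analyze_species, curves_to_frame,
                                 summary_frame)
from .synthetic import PanelConfigSynthetic, make_panel

log = logging.getLogger(__name__)

ALL_MODELS = ("M", "BBL", "BBL.H", "T")


@dataclass
class PanelConfig:
    """Configuration of a full pipeline run (JSON-serializable)."""

    input_csv: Optional[str] = None      # read this instead of simulating
    simulate: Optional[dict] = None      # kwargs for PanelConfigSynthetic
    models: Sequence[str] = ALL_MODELS
    n_starts: int = 20
    n_trees: int = 500
    min_node: int = 5
    n_grid: int = 50
    bias_percentile: float = 10.0
    seed: int = 0
    out_dir: str = "stomatafit_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        bad = [m for m in self.models if m not in ALL_MODELS]
        if bad:
            raise ConfigError(f"unknown model ids {bad}; choose from "
                              f"{ALL_MODELS}")
        if self.input_csv and self.simulate:
            raise ConfigError("give either input_csv or simulate, not both")

    @classmethod
    def from_json(cls, path) -> "PanelConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as e:
            raise ConfigError(f"cannot read config {path}: {e}") from e
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class ReportBundle:
    """In-memory handles to everything a run produced."""

    manifest: dict
    fits: pd.DataFrame = field(default_factory=pd.DataFrame)
    selections: pd.DataFrame = field(default_factory=pd.DataFrame)
    pd_curves: pd.DataFrame = field(default_factory=pd.DataFrame)
    pd_summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    bias: pd.DataFrame = field(default_factory=pd.DataFrame)
    hydraulics: pd.DataFrame = field(default_factory=pd.DataFrame)
    regression: Optional[Gs50P50Regression] = None


def _load_panel(config: PanelConfig, out: Path):
    if config.input_csv:
        datasets = list(read_gas_exchange_csv(config.input_csv).values())
        return None, datasets, None
    sim_kwargs = dict(config.simulate or {})
    sim = PanelConfigSynthetic(**sim_kwargs)
    truths, datasets, truth = make_panel(
        n_species=sim.n_species, strategy_mix=sim.strategy_mix,
        seed=config.seed, config=sim)
    write_gas_exchange_csv(datasets, out / "panel.csv")
    write_truth_json(truth, out / "panel_truth.json")
    return truths, datasets, truth


def run_pipeline(config: PanelConfig) -> ReportBundle:
    """Execute every stage, preserving partial outputs on failure.

    The manifest records versions, seeds, per-stage record counts and every
    species exclusion with its reason; it is written even when a stage
    fails (with the failure point).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "stomatafit_version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stages": {}, "exclusions": [],
    }
    bundle = ReportBundle(manifest=manifest)
    try:
        truths, datasets, truth = _load_panel(config, out)
        manifest["stages"]["load"] = {
            "n_species": len(datasets),
            "n_records": int(sum(len(d) for d in datasets)),
            "source": config.input_csv or "synthetic"}

        # ---- model fitting + selection
        psi_models = [m for m in config.models if m in ("T", "BBL.H")]
        fits, selections, skipped = fit_all(
            datasets, model_ids=config.models, n_starts=config.n_starts,
            seed=config.seed)
        for sp in skipped:
            manifest["exclusions"].append(
                {"species_id": sp, "stage": "fitting",
                 "reason": "no direct assimilation measurements"})
        bundle.fits = fits_to_frame(fits)
        bundle.selections = selections_to_frame(selections)
        bundle.fits.to_csv(out / "fits.csv", index=False)
        bundle.selections.to_csv(out / "selection.csv", index=False)
        manifest["stages"]["fitting"] = {
            "n_fits": len(fits), "n_selections": len(selections),
            "n_skipped": len(skipped)}

        # ---- partial dependence
        curves = []
        for i, ds in enumerate(datasets):
            try:
                curves.append(analyze_species(
                    ds, n_trees=config.n_trees, min_node=config.min_node,
                    seed=config.seed + 104729 + i, n_grid=config.n_grid))
            except SpeciesExcluded as e:
                manifest["exclusions"].append(
                    {"species_id": ds.species_id, "stage": "pd",
                     "reason": str(e)})
        bundle.pd_curves = curves_to_frame(curves)
        bundle.pd_summary = summary_frame(curves)
        bundle.pd_curves.to_csv(out / "pd_curves.csv", index=False)
        bundle.pd_summary.to_csv(out / "pd_summary.csv", index=False)
        n_err = int((bundle.pd_summary["shape_class"] == "erratic").sum()) \
            if len(bundle.pd_summary) else 0
        manifest["stages"]["pd"] = {"n_curves": len(curves),
                                    "n_erratic": n_err}

        # ---- drought bias + collinearity
        by_sp = {d.species_id: d for d in datasets}
        reports = [bias_report(f, by_sp[f.species_id],
                               percentile=config.bias_percentile)
                   for f in fits]
        bundle.bias = bias_reports_to_frame(reports)
        bundle.bias.to_csv(out / "bias.csv", index=False)
        coll = collinearity_screen(datasets, fits)
        coll.vifs.to_csv(out / "vifs.csv")
        manifest["stages"]["bias"] = {
            "n_reports": len(reports),
            "collinearity_cross_species_p": coll.cross_species_p}

        # ---- hydraulics coupling
        if not psi_models and truths is None:
            log.info("no psi-aware model in config; hydraulic coupling "
                     "skipped")
            manifest["stages"]["hydraulics"] = {"skipped": True}
        else:
            gs50 = {c.species_id: (c.psi_gs50, c.gs50_extrapolated)
                    for c in curves}
            hyd = []
            for ds in datasets:
                if ds.p50 is None or ds.p88 is None:
                    manifest["exclusions"].append(
                        {"species_id": ds.species_id, "stage": "hydraulics",
                         "reason": "no xylem P50/P88"})
                    continue
                g, ex = gs50.get(ds.species_id, (None, False))
                sh = SpeciesHydraulics(
                    species_id=ds.species_id, p50=ds.p50, p88=ds.p88,
                    psi_gs50=g, gs50_extrapolated=ex)
                sh.plc_at_min_psi = plc_at_min_observed_psi(
                    ds, sh.vulnerability)
                hyd.append(sh)
            bundle.hydraulics = hydraulics_to_frame(hyd)
            bundle.hydraulics.to_csv(out / "hydraulics.csv", index=False)
            stage: dict = {"n_species": len(hyd)}
            try:
                reg = gs50_vs_p50_regression(hyd)
                bundle.regression = reg
                stage["gs50_vs_p50"] = dataclasses.asdict(reg)
                mean_plc, med_plc, n_plc = panel_plc_summary(hyd)
                stage["plc_at_gs50"] = {"mean": mean_plc, "median": med_plc,
                                        "n": n_plc}
            except (StomatafitError, UndefinedSignal) as e:
                stage["regression_error"] = str(e)
            manifest["stages"]["hydraulics"] = stage
    except Exception as e:  # manifest must record the failure point
        manifest["failure"] = {"stage": _current_stage(manifest), "error": str(e)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=_json_default))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=_json_default))
    return bundle


def _current_stage(manifest: dict) -> str:
    done = list(manifest["stages"])
    order = ["load", "fitting", "pd", "bias", "hydraulics"]
    for s in order:
        if s not in done:
            return s
    return "finalize"


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")
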