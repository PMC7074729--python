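"""End-to-end orchestration: respirometry -> kinetics -> mass balance ->
treatment statistics, reading the documented CSV dialects and writing a
report bundle (plain CSVs plus a JSON summary).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from . import kinetics, mass_balance, respirometry, stats_compare
from .errors import FitError, InputError
from .types import Fuel, RespirationSeries, Setup

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    metadata_csv: str = ""
    titration_csv: Optional[str] = None
    co2_csv: Optional[str] = None  # pre-converted alternative to titration_csv
    endpoint_csv: Optional[str] = None
    out_dir: Optional[str] = None
    objective_space: str = "log"  # {log, linear}
    min_points_per_phase: int = 3
    max_phases: int = 3
    mineral_basis: str = "carbon"  # {carbon, ch2}
    volat_overrides: Dict[str, float] = field(default_factory=dict)
    response_variable: str = "cumulative_co2"  # {cumulative_co2, k}
    average_before_subtract: bool = False
    mg_co2_per_meq: float = 22.0

    def __post_init__(self):
        if self.objective_space not in ("log", "linear"):
            raise InputError(f"objective_space must be 'log' or 'linear', got {self.objective_space!r}")
        if self.mineral_basis not in ("carbon", "ch2"):
            raise InputError(f"mineral_basis must be 'carbon' or 'ch2', got {self.mineral_basis!r}")
        if self.response_variable not in ("cumulative_co2", "k"):
            raise InputError(f"response_variable must be 'cumulative_co2' or 'k'")
        if not (1 <= self.max_phases <= 3):
            raise InputError("max_phases must be in 1..3")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class AnalysisResult:
    respiration: pd.DataFrame
    fits: pd.DataFrame
    k_summary: pd.DataFrame
    balance: pd.DataFrame
    stats: pd.DataFrame
    summary: dict


def _load_series(cfg: PipelineConfig, specs) -> Dict[str, RespirationSeries]:
    if cfg.titration_csv:
        records = rio.read_titration(cfg.titration_csv)
        series = {}
        for mid, recs in records.items():
            if mid not in specs:
                raise InputError(f"titration data for unknown microcosm {mid!r}")
            series[mid] = respirometry.records_to_series(
                specs[mid], recs, mg_co2_per_meq=cfg.mg_co2_per_meq
            )
        return series
    if cfg.co2_csv:
        frames = rio.read_co2(cfg.co2_csv)
        series = {}
        for mid, df in frames.items():
            if mid not in specs:
                raise InputError(f"CO2 data for unknown microcosm {mid!r}")
            series[mid] = RespirationSeries(
                microcosm=specs[mid],
                days=df["day"].to_numpy(dtype=float),
                daily_co2=df["co2_mg"].to_numpy(dtype=float),
            )
        return series
    raise InputError("either titration_csv or co2_csv must be provided")


def _subtract_baselines(cfg: PipelineConfig, series: Dict[str, RespirationSeries]):
    """Per-setup control baseline subtraction (per replicate by default)."""
    net = {}
    for setup in Setup:
        setup_series = [s for s in series.values() if s.microcosm.setup == setup]
        if not setup_series:
            continue
        baseline = respirometry.control_baseline(setup_series)
        fuels = [s for s in setup_series if s.microcosm.fuel != Fuel.CONTROL]
        if not fuels:
            continue
        if baseline is None:
            raise InputError(
                f"no CONTROL microcosm for setup {setup.value}; "
                "baseline subtraction is required"
            )
        if cfg.average_before_subtract:
            by_fuel: Dict[Fuel, list] = {}
            for s in fuels:
                by_fuel.setdefault(s.microcosm.fuel, []).append(s)
            for fuel, group in by_fuel.items():
                avg = respirometry.average_series(group)
                net[avg.microcosm.id] = respirometry.subtract_baseline(avg, baseline)
        else:
            for s in fuels:
                net[s.microcosm.id] = respirometry.subtract_baseline(s, baseline)
    return net


def analyze(cfg: PipelineConfig) -> AnalysisResult:
    """Run the full analysis; returns all report frames and, if
    ``cfg.out_dir`` is set, writes the report bundle (only after every
    stage succeeded — no partial bundles)."""
    specs = rio.read_metadata(cfg.metadata_csv)
    raw = _load_series(cfg, specs)
    net = _subtract_baselines(cfg, raw)

    fit_rows, k_rows = [], []
    whole_k: Dict[str, float] = {}
    by_fuel_k: Dict[str, list] = {}
    for mid, s in sorted(net.items()):
        sub = kinetics.build_substrate_series(s, c0=s.microcosm.fuel_mass, include_day_zero=True)
        for n_phases in range(1, cfg.max_phases + 1):
            try:
                fit = kinetics.fit_piecewise(
                    sub, n_phases,
                    min_points_per_phase=cfg.min_points_per_phase,
                    objective=cfg.objective_space,
                )
            except FitError:
                continue
            for idx, ph in enumerate(fit.phases):
                fit_rows.append(
                    {
                        "microcosm_id": mid,
                        "n_phases": n_phases,
                        "phase_index": idx + 1,
                        "t_start": ph.t_start,
                        "t_end": ph.t_end,
                        "k_per_day": ph.k,
                        "rmse": fit.rmse,
                    }
                )
            if n_phases == 1:
                whole_k[mid] = fit.phases[0].k
                by_fuel_k.setdefault(s.microcosm.fuel.value, []).append(fit.phases[0].k)

    for fuel, ks in sorted(by_fuel_k.items()):
        summ = kinetics.summarize_k(ks)
        k_rows.append(
            {
                "fuel": fuel,
                "mean_k_per_day": summ.mean,
                "se_k_per_day": summ.se,
                "n_replicates": summ.n,
                "se_defined": summ.se_defined,
            }
        )

    balance_rows = []
    if cfg.endpoint_csv:
        endpoint = rio.read_endpoint(cfg.endpoint_csv)
        by_group = {(s.microcosm.fuel, s.microcosm.setup): s for s in net.values()}
        for mid, row in sorted(endpoint.items()):
            if mid in net:
                resp_series = net[mid]
            elif cfg.average_before_subtract and mid in specs:
                # replicates were averaged; use the averaged series of the group
                key = (specs[mid].fuel, specs[mid].setup)
                if key not in by_group:
                    raise InputError(f"endpoint data for microcosm {mid!r} without respiration data")
                resp_series = by_group[key]
            else:
                raise InputError(f"endpoint data for microcosm {mid!r} without respiration data")
            spec = specs[mid]
            dro = rio.dro_from_endpoint(row)
            nitro = rio.nitrogen_from_endpoint(row, spec)
            volat = cfg.volat_overrides.get(spec.fuel.value)
            bal = mass_balance.assemble_balance(
                resp_series, dro, nitro, spec,
                volat_assumed_pct=volat, mineral_basis=cfg.mineral_basis,
            )
            balance_rows.append(
                {
                    "microcosm_id": mid,
                    "fuel": spec.fuel.value,
                    "c_initial_mg": bal.c_initial,
                    "pct_mineralized": bal.pct_mineralized,
                    "pct_residual_dro": bal.pct_residual_dro,
                    "pct_biomass": bal.pct_biomass,
                    "pct_volatilized": bal.pct_volatilized,
                    "pct_unaccounted": bal.pct_unaccounted,
                    "biomass_capped": bal.biomass_capped,
                    "over_recovery": bal.over_recovery,
                }
            )

    # treatment comparison across fuels on the chosen response variable
    responses: Dict[str, list] = {}
    for mid, s in net.items():
        fuel = s.microcosm.fuel.value
        if cfg.response_variable == "cumulative_co2":
            responses.setdefault(fuel, []).append(s.total_co2)
        else:
            if mid in whole_k:
                responses.setdefault(fuel, []).append(whole_k[mid])
    stats_rows = []
    usable = {f: v for f, v in responses.items() if len(v) >= 2}
    if len(usable) >= 2:
        labels = sorted(usable)
        res = stats_compare.anova_tukey([usable[f] for f in labels], labels)
        stats_rows.append(
            {
                "comparison": f"anova:{cfg.response_variable}",
                "groups": "|".join(labels),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "degenerate": res.degenerate,
            }
        )
        for a, b, p, sig in res.pairwise:
            stats_rows.append(
                {
                    "comparison": f"tukey:{a}-vs-{b}",
                    "groups": f"{a}|{b}",
                    "statistic": np.nan,
                    "p_value": p,
                    "degenerate": False,
                    "significant": sig,
                }
            )

    result = AnalysisResult(
        respiration=rio.respiration_frame([net[m] for m in sorted(net)]),
        fits=pd.DataFrame(fit_rows),
        k_summary=pd.DataFrame(k_rows),
        balance=pd.DataFrame(balance_rows),
        stats=pd.DataFrame(stats_rows),
        summary={
            "n_microcosms": len(net),
            "fuels": sorted(by_fuel_k),
            "whole_window_k": {
                r["fuel"]: {"mean": r["mean_k_per_day"], "se": r["se_k_per_day"], "n": r["n_replicates"]}
                for r in k_rows
            },
            "balance_closure_ok": all(
                abs(sum(r[c] for c in (
                    "pct_mineralized", "pct_residual_dro", "pct_biomass",
                    "pct_volatilized", "pct_unaccounted")) - 100.0) < 1e-6
                for r in balance_rows
            ),
        },
    )
    if cfg.out_dir:
        write_bundle(result, cfg.out_dir)
    return result


def write_bundle(result: AnalysisResult, out_dir) -> Dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("respiration", "fits", "k_summary", "balance", "stats"):
        df = getattr(result, name)
        paths[name] = out / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(result.summary, indent=2, sort_keys=True))
    return paths
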