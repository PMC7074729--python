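"""Plain-text I/O: the CSV dialects consumed and produced by the pipeline
and the generator, plus the truth.json of booked generating parameters.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from .errors import InputError
from .types import (
    DroResult,
    Fuel,
    MicrocosmSpec,
    NitrogenBudget,
    RespirationSeries,
    Setup,
    TitrationRecord,
)

METADATA_COLUMNS = [
    "microcosm_id", "fuel", "fuel_mass_mg", "soil_mass_g", "n_added_mg",
    "setup", "replicate", "temperature_c",
]
TITRATION_COLUMNS = [
    "microcosm_id", "day", "blank_volume_ml", "sample_volume_ml", "normality",
]
CO2_COLUMNS = ["microcosm_id", "day", "co2_mg"]
ENDPOINT_COLUMNS = ["microcosm_id", "dro_measured_mg", "surrogate_recovery", "n_final_mg"]


def _read_csv(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file does not exist: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise InputError(f"input file is empty: {path}") from None
    if df.empty:
        raise InputError(f"input file has no data rows: {path}")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    return df


def read_metadata(path) -> Dict[str, MicrocosmSpec]:
    df = _read_csv(path, METADATA_COLUMNS)
    specs = {}
    for i, row in df.iterrows():
        try:
            spec = MicrocosmSpec(
                id=str(row["microcosm_id"]),
                fuel=Fuel(str(row["fuel"])),
                fuel_mass=float(row["fuel_mass_mg"]),
                soil_mass=float(row["soil_mass_g"]),
                n_added=float(row["n_added_mg"]),
                setup=Setup(str(row["setup"])),
                replicate=int(row["replicate"]),
                temperature=float(row["temperature_c"]),
            )
        except (ValueError, KeyError) as exc:
            raise InputError(f"{path}: bad metadata row {i + 2}: {exc}") from exc
        if spec.id in specs:
            raise InputError(f"{path}: duplicate microcosm_id {spec.id!r} at row {i + 2}")
        specs[spec.id] = spec
    return specs


def read_titration(path) -> Dict[str, List[TitrationRecord]]:
    df = _read_csv(path, TITRATION_COLUMNS)
    out: Dict[str, List[TitrationRecord]] = {}
    for i, row in df.iterrows():
        try:
            rec = TitrationRecord(
                day=float(row["day"]),
                blank_volume=float(row["blank_volume_ml"]),
                sample_volume=float(row["sample_volume_ml"]),
                normality=float(row["normality"]),
                trap_volume=float(row.get("trap_volume_ml", 20.0)),
            )
        except (ValueError, KeyError) as exc:
            raise InputError(f"{path}: bad titration row {i + 2}: {exc}") from exc
        out.setdefault(str(row["microcosm_id"]), []).append(rec)
    return out


def read_co2(path) -> Dict[str, pd.DataFrame]:
    """Pre-converted per-day CO2 masses, one frame per microcosm."""
    df = _read_csv(path, CO2_COLUMNS)
    if df[["day", "co2_mg"]].isna().any().any():
        bad = int(df[df[["day", "co2_mg"]].isna().any(axis=1)].index[0]) + 2
        raise InputError(f"{path}: missing value at row {bad}")
    return {str(mid): g.sort_values("day") for mid, g in df.groupby("microcosm_id")}


def read_endpoint(path) -> Dict[str, dict]:
    df = _read_csv(path, ENDPOINT_COLUMNS)
    out = {}
    for i, row in df.iterrows():
        try:
            out[str(row["microcosm_id"])] = {
                "dro_measured_mg": float(row["dro_measured_mg"]),
                "surrogate_recovery": float(row["surrogate_recovery"]),
                "n_final_mg": float(row["n_final_mg"]),
            }
        except ValueError as exc:
            raise InputError(f"{path}: bad endpoint row {i + 2}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# writers


def respiration_frame(series_list) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for day, daily, cum in zip(s.days, s.daily_co2, s.cumulative_co2):
            rows.append(
                {
                    "microcosm_id": s.microcosm.id,
                    "day": day,
                    "daily_co2_mg": daily,
                    "cumulative_co2_mg": cum,
                    "baseline_subtracted": s.baseline_subtracted,
                }
            )
    return pd.DataFrame(rows)


def metadata_frame(specs) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "microcosm_id": s.id,
                "fuel": s.fuel.value,
                "fuel_mass_mg": s.fuel_mass,
                "soil_mass_g": s.soil_mass,
                "n_added_mg": s.n_added,
                "setup": s.setup.value,
                "replicate": s.replicate,
                "temperature_c": s.temperature,
            }
            for s in specs
        ]
    )


def write_cohort(cohort, outdir) -> Dict[str, Path]:
    """Write a simulated cohort as the CSV dialects the readers consume,
    plus a truth.json of booked generating parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": outdir / "metadata.csv",
        "titration": outdir / "titration.csv",
        "endpoint": outdir / "endpoint.csv",
        "truth": outdir / "truth.json",
    }
    metadata_frame([m.spec for m in cohort.microcosms]).to_csv(paths["metadata"], index=False)

    tit_rows = []
    for m in cohort.microcosms:
        for r in m.records:
            tit_rows.append(
                {
                    "microcosm_id": m.spec.id,
                    "day": r.day,
                    "blank_volume_ml": r.blank_volume,
                    "sample_volume_ml": r.sample_volume,
                    "normality": r.normality,
                    "trap_volume_ml": r.trap_volume,
                }
            )
    pd.DataFrame(tit_rows).to_csv(paths["titration"], index=False)

    end_rows = []
    for m in cohort.microcosms:
        if m.dro is None:
            continue
        end_rows.append(
            {
                "microcosm_id": m.spec.id,
                "dro_measured_mg": m.dro.measured_mass,
                "surrogate_recovery": m.dro.surrogate_recovery,
                "n_final_mg": m.nitrogen.n_final if m.nitrogen else 0.0,
            }
        )
    if end_rows:
        pd.DataFrame(end_rows).to_csv(paths["endpoint"], index=False)
    else:
        paths.pop("endpoint")

    truth = {m.spec.id: m.truth for m in cohort.microcosms if m.truth is not None}
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths


def dro_from_endpoint(row: dict) -> DroResult:
    from .mass_balance import correct_dro

    return correct_dro(row["dro_measured_mg"], row["surrogate_recovery"])


def nitrogen_from_endpoint(row: dict, spec: MicrocosmSpec) -> Optional[NitrogenBudget]:
    if spec.n_added <= 0:
        return None
    return NitrogenBudget(n_initial=spec.n_added, n_final=row["n_final_mg"])
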