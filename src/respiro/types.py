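"""Domain types shared across the pipeline.

All masses are milligrams unless a field name says otherwise; days are real
numbers measured from fuel application (day 0); intervals are half-open
(prev_day, day].
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError


class Fuel(str, Enum):
    DIESEL = "DIESEL"
    HTG = "HTG"
    SYNTROLEUM = "SYNTROLEUM"
    B20 = "B20"
    B100 = "B100"
    CONTROL = "CONTROL"


class Setup(str, Enum):
    SOIL_BED = "SOIL_BED"
    GRID_WITH_SOIL = "GRID_WITH_SOIL"
    GRID_NO_SOIL = "GRID_NO_SOIL"


@dataclass(frozen=True)
class MicrocosmSpec:
    """One experimental unit: what was put in the jar."""

    id: str
    fuel: Fuel
    fuel_mass: float  # mg
    soil_mass: float  # g; 0 allowed (grid setups)
    n_added: float  # mg N
    setup: Setup = Setup.SOIL_BED
    replicate: int = 1
    temperature: float = 20.0  # degC

    def __post_init__(self):
        if (self.fuel == Fuel.CONTROL) != (self.fuel_mass == 0):
            raise ConfigError(
                f"microcosm {self.id}: fuel_mass must be 0 iff fuel is CONTROL "
                f"(got fuel={self.fuel.value}, fuel_mass={self.fuel_mass})"
            )
        if self.soil_mass < 0:
            raise ConfigError(f"microcosm {self.id}: soil_mass must be >= 0")
        if self.replicate < 1:
            raise ConfigError(f"microcosm {self.id}: replicate must be >= 1")


@dataclass(frozen=True)
class TitrationRecord:
    """One trap back-titration reading.

    ``blank_volume`` and ``sample_volume`` are mL of acid titrant for the
    blank and sample traps; ``normality`` is the titrant strength in eq/L;
    ``trap_volume`` is the mL of NaOH in the trap (bookkeeping only).
    """

    day: float
    blank_volume: float
    sample_volume: float
    normality: float = 1.0
    trap_volume: float = 20.0

    def __post_init__(self):
        if self.day < 0:
            raise ConfigError(f"titration record: day must be >= 0, got {self.day}")
        if self.normality <= 0:
            raise ConfigError(f"titration record day {self.day}: normality must be > 0")
        if self.sample_volume < 0:
            raise ConfigError(f"titration record day {self.day}: sample_volume must be >= 0")


@dataclass
class RespirationSeries:
    """Per-day and cumulative net CO2 production for one microcosm.

    ``daily_co2[i]`` is the mass trapped over the interval
    ``(days[i-1], days[i]]`` (from day 0 for the first point).
    ``daily_co2_raw`` retains pre-floor values after baseline subtraction
    for audit; ``interpolated_days`` flags days filled by interpolation.
    """

    microcosm: MicrocosmSpec
    days: np.ndarray
    daily_co2: np.ndarray
    cumulative_co2: np.ndarray = field(default=None)
    baseline_subtracted: bool = False
    daily_co2_raw: Optional[np.ndarray] = None
    interpolated_days: tuple = ()

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.daily_co2 = np.asarray(self.daily_co2, dtype=float)
        if self.days.ndim != 1 or self.days.shape != self.daily_co2.shape:
            raise ConfigError("days and daily_co2 must be 1-D arrays of equal length")
        if len(self.days) and np.any(np.diff(self.days) <= 0):
            raise ConfigError("days must be strictly increasing")
        if self.cumulative_co2 is None:
            self.cumulative_co2 = np.cumsum(self.daily_co2)
        else:
            self.cumulative_co2 = np.asarray(self.cumulative_co2, dtype=float)

    @property
    def total_co2(self) -> float:
        return float(self.cumulative_co2[-1]) if len(self.cumulative_co2) else 0.0


@dataclass
class SubstrateSeries:
    """Remaining contaminant mass reconstructed from respiration."""

    microcosm: MicrocosmSpec
    days: np.ndarray
    c_t: np.ndarray  # mg remaining at each day
    c0: float  # mg initially present
    clipped: np.ndarray = None  # mask of points clipped at the log floor

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.c_t = np.asarray(self.c_t, dtype=float)
        if self.clipped is None:
            self.clipped = np.zeros(len(self.days), dtype=bool)


@dataclass(frozen=True)
class Phase:
    t_start: float
    t_end: float
    k: float  # per day
    c_start: float  # mg at t_start (fitted)


@dataclass
class PiecewiseFit:
    """Contiguous phases with per-phase first-order rate constants."""

    phases: list  # list[Phase]
    rmse: float  # ln-space RMSE over all fitted points
    n_phases: int
    breakpoints: tuple = ()  # interior breakpoint days
    warnings: tuple = ()

    def __post_init__(self):
        if not (1 <= self.n_phases <= 3):
            raise ConfigError(f"n_phases must be in 1..3, got {self.n_phases}")
        for p in self.phases:
            if p.k < 0:
                raise ConfigError("phase rate constants must be >= 0")
        if self.rmse < 0:
            raise ConfigError("rmse must be >= 0")

    @property
    def whole_window_k(self) -> Optional[float]:
        return self.phases[0].k if self.n_phases == 1 else None


@dataclass
class NitrogenBudget:
    """Initial vs final extractable nitrogen for one microcosm."""

    n_initial: float  # mg N
    n_final: float  # mg N
    pct_used: float = None

    def __post_init__(self):
        if self.pct_used is None:
            if self.n_initial <= 0:
                raise ConfigError("n_initial must be > 0 to derive pct_used")
            self.pct_used = 100.0 * (self.n_initial - self.n_final) / self.n_initial
        if not (0.0 <= self.pct_used <= 100.0):
            raise ConfigError(f"pct_used out of range [0, 100]: {self.pct_used}")


@dataclass
class DroResult:
    """Diesel-range-organics endpoint with surrogate-recovery correction."""

    measured_mass: float  # mg, instrument-reported
    surrogate_recovery: float  # fraction
    spiked_mass: float = 0.0  # mg, recovery-check spike (bookkeeping)
    corrected_mass: float = None
    pct_remaining: float = None
    recovery_flagged: bool = False


@dataclass
class CarbonBalance:
    """Endpoint partition of initial fuel carbon; components sum to 100."""

    c_initial: float  # mg C
    pct_mineralized: float
    pct_residual_dro: float
    pct_biomass: float
    pct_volatilized: float
    pct_unaccounted: float
    biomass_capped: bool = False
    over_recovery: bool = False

    def components(self) -> np.ndarray:
        return np.array(
            [
                self.pct_mineralized,
                self.pct_residual_dro,
                self.pct_biomass,
                self.pct_volatilized,
                self.pct_unaccounted,
            ]
        )

    @property
    def total(self) -> float:
        return float(self.components().sum())


@dataclass
class ComparisonResult:
    """Outcome of a treatment comparison test."""

    groups: Sequence[str]
    statistic: float
    p_value: float
    pairwise: list = field(default_factory=list)  # (a, b, adjusted_p, significant)
    degenerate: bool = False
    test: str = ""
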