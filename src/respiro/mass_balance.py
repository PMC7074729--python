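"""Endpoint carbon partition: mineralized / residual DRO / biomass /
volatilized / unaccounted, with surrogate-recovery correction of the
measured diesel-range organics.

Biomass is estimated from nitrogen depletion using the conventional
C5H7O2N cell stoichiometry: each mg of N assimilated fixes 60/14 mg of
biomass carbon.
"""
from __future__ import annotations

import logging
from typing import Optional

from .errors import BalanceError, InputError, OverdrawError
from .kinetics import C_FRACTION_CH2, C_FRACTION_CO2, fuel_carbon
from .types import (
    CarbonBalance,
    DroResult,
    Fuel,
    MicrocosmSpec,
    NitrogenBudget,
    RespirationSeries,
)

logger = logging.getLogger(__name__)

#: mg biomass C fixed per mg N assimilated (C5H7O2N: 5*12 g C / 14 g N).
BIOMASS_C_PER_N = 60.0 / 14.0

#: assumed volatilization allowance (% of initial C) per fuel: up to 20%
#: for petroleum-derived fuels, insignificant for pure biodiesel, and
#: blend-proportional for B20.
VOLATILIZATION_DEFAULTS = {
    Fuel.DIESEL: 20.0,
    Fuel.HTG: 20.0,
    Fuel.SYNTROLEUM: 20.0,
    Fuel.B20: 4.0,
    Fuel.B100: 0.0,
    Fuel.CONTROL: 0.0,
}

#: surrogate recoveries outside this band are flagged as suspect.
RECOVERY_FLAG_RANGE = (0.5, 1.5)


def nitrogen_amendment(
    concentration_mg_per_ml: float, volume_ml: float, soil_kg: float
) -> float:
    """mg N per kg dry soil delivered by a fertilizer solution."""
    if soil_kg <= 0:
        raise InputError("soil mass must be positive")
    return concentration_mg_per_ml * volume_ml / soil_kg


def biomass_from_nitrogen(
    pct_n_used: float, n_initial: float, c_initial: float
) -> float:
    """Percent of initial fuel C converted to biomass, from N depletion."""
    if c_initial <= 0:
        raise InputError("c_initial must be positive")
    if n_initial <= 0:
        raise InputError("n_initial must be positive")
    if not 0.0 <= pct_n_used <= 100.0:
        raise InputError(f"pct_n_used out of range [0, 100]: {pct_n_used}")
    return pct_n_used * (n_initial * BIOMASS_C_PER_N) / c_initial


def pct_mineralized(
    cumulative_co2: float, c_initial: float, basis: str = "carbon"
) -> float:
    """Percent of initial fuel C evolved as CO2.

    ``basis='carbon'`` counts the carbon in the evolved CO2 (12/44);
    ``basis='ch2'`` counts CH2-equivalent substrate mass (14/44) over
    initial fuel mass carbon-equivalent — both give the same number when
    fuel and CO2 share the CH2 carbon fraction, so carbon is the default.
    """
    if cumulative_co2 < 0 or c_initial <= 0:
        raise InputError("cumulative CO2 must be >= 0 and c_initial > 0")
    if basis == "carbon":
        pct = 100.0 * (cumulative_co2 * C_FRACTION_CO2) / c_initial
    elif basis == "ch2":
        pct = 100.0 * (cumulative_co2 * (14.0 / 44.0)) / (c_initial / C_FRACTION_CH2)
    else:
        raise InputError(f"unknown mineralization basis: {basis!r}")
    if pct > 100.0 + 1e-9:
        raise OverdrawError(
            f"mineralized carbon ({pct:.1f}%) exceeds initial carbon — "
            "overdraw (wrong c_initial or un-subtracted baseline?)"
        )
    return pct


def correct_dro(measured: float, surrogate_recovery: float) -> DroResult:
    """Surrogate-recovery-corrected DRO mass.

    Recoveries outside [0.5, 1.5] are corrected anyway but flagged.
    """
    if surrogate_recovery <= 0:
        raise InputError(f"surrogate recovery must be > 0, got {surrogate_recovery}")
    if measured < 0:
        raise InputError("measured DRO mass must be >= 0")
    lo, hi = RECOVERY_FLAG_RANGE
    flagged = not (lo <= surrogate_recovery <= hi)
    if flagged:
        logger.warning("surrogate recovery %.2f outside [%.1f, %.1f]", surrogate_recovery, lo, hi)
    return DroResult(
        measured_mass=measured,
        surrogate_recovery=surrogate_recovery,
        corrected_mass=measured / surrogate_recovery,
        recovery_flagged=flagged,
    )


def assemble_balance(
    resp: RespirationSeries,
    dro: DroResult,
    nitro: Optional[NitrogenBudget],
    spec: MicrocosmSpec,
    volat_assumed_pct: Optional[float] = None,
    dro_carbon_fraction: float = C_FRACTION_CH2,
    mineral_basis: str = "carbon",
) -> CarbonBalance:
    """Close the endpoint carbon balance for one microcosm.

    ``pct_unaccounted`` is the closing term, so components always sum to
    exactly 100. Biomass is capped at the unallocated remainder if the
    measured components alone would overshoot; if they overshoot even
    with zero biomass the (negative) closure is kept and flagged as
    over-recovery.
    """
    if volat_assumed_pct is None:
        volat_assumed_pct = VOLATILIZATION_DEFAULTS[spec.fuel]
    if not 0.0 <= volat_assumed_pct <= 20.0:
        raise BalanceError(
            f"volatilization allowance must be in [0, 20]%, got {volat_assumed_pct}"
        )
    c_initial = fuel_carbon(spec.fuel_mass)
    if c_initial <= 0:
        raise BalanceError(f"microcosm {spec.id}: no fuel carbon to balance")
    p_min = pct_mineralized(resp.total_co2, c_initial, basis=mineral_basis)
    if dro.corrected_mass is None:
        dro = correct_dro(dro.measured_mass, dro.surrogate_recovery)
    p_res = 100.0 * dro.corrected_mass * dro_carbon_fraction / c_initial
    if nitro is not None and nitro.n_initial > 0:
        p_bio = biomass_from_nitrogen(nitro.pct_used, nitro.n_initial, c_initial)
    else:
        p_bio = 0.0

    for name, val in (("mineralized", p_min), ("residual_dro", p_res), ("biomass", p_bio)):
        if val > 100.0 + 1e-9:
            raise BalanceError(f"component {name} exceeds 100%: {val:.1f}")

    capped = False
    remainder = 100.0 - (p_min + p_res + volat_assumed_pct)
    if p_bio > remainder + 1e-9:
        capped = True
        new_bio = max(remainder, 0.0)
        logger.warning(
            "microcosm %s: biomass %.1f%% capped at %.1f%% to close the balance",
            spec.id, p_bio, new_bio,
        )
        p_bio = new_bio
    p_unacc = 100.0 - (p_min + p_res + p_bio + volat_assumed_pct)
    over = p_unacc < -1e-9
    if over:
        logger.warning(
            "microcosm %s: over-recovery, components exceed 100%% by %.2f points",
            spec.id, -p_unacc,
        )
    return CarbonBalance(
        c_initial=c_initial,
        pct_mineralized=p_min,
        pct_residual_dro=p_res,
        pct_biomass=p_bio,
        pct_volatilized=volat_assumed_pct,
        pct_unaccounted=p_unacc,
        biomass_capped=capped,
        over_recovery=over,
    )
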