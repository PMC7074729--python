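"""Trap-titration records -> per-day and cumulative net CO2 series.

Evolved CO2 is captured in an NaOH trap, the carbonate precipitated with
BaCl2, and the residual NaOH back-titrated with acid; the difference
between blank and sample titrant volumes is proportional to the trapped
CO2 mass (22 mg CO2 per milliequivalent of NaOH consumed).
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import DayGridError, InputError, NegativeCO2Error
from .types import Fuel, MicrocosmSpec, RespirationSeries, TitrationRecord

#: mg CO2 per milliequivalent of NaOH consumed (CO2 + 2 NaOH -> Na2CO3 + H2O;
#: 44 mg/mmol over 2 meq/mmol).
MG_CO2_PER_MEQ = 22.0


def titration_to_co2(rec: TitrationRecord, mg_co2_per_meq: float = MG_CO2_PER_MEQ) -> float:
    """Convert one back-titration reading to mg CO2 trapped.

    Raises :class:`NegativeCO2Error` if the sample trap consumed more
    titrant than the blank (which would imply negative trapped CO2).
    """
    if rec.sample_volume > rec.blank_volume:
        raise NegativeCO2Error(rec.day, rec.blank_volume, rec.sample_volume)
    return (rec.blank_volume - rec.sample_volume) * rec.normality * mg_co2_per_meq


def records_to_series(
    microcosm: MicrocosmSpec,
    records: Iterable[TitrationRecord],
    mg_co2_per_meq: float = MG_CO2_PER_MEQ,
) -> RespirationSeries:
    """Build a raw (not baseline-subtracted) series from titration records.

    Each trap reading is attributed to the interval since the previous
    opening, so irregular sampling is handled naturally.
    """
    recs = sorted(records, key=lambda r: r.day)
    if not recs:
        raise InputError(f"microcosm {microcosm.id}: no titration records")
    days = np.array([r.day for r in recs], dtype=float)
    if np.any(np.diff(days) <= 0):
        raise InputError(f"microcosm {microcosm.id}: duplicate sampling days")
    daily = np.array([titration_to_co2(r, mg_co2_per_meq) for r in recs])
    return RespirationSeries(microcosm=microcosm, days=days, daily_co2=daily)


def accumulate(series: RespirationSeries) -> RespirationSeries:
    """Recompute the cumulative series as the running sum of dailies."""
    series.cumulative_co2 = np.cumsum(series.daily_co2)
    return series


def subtract_baseline(
    sample: RespirationSeries, control: RespirationSeries
) -> RespirationSeries:
    """Net fuel-derived respiration: sample minus control, floored at 0.

    Both series must share the same day grid (use :func:`resample` first
    if they do not). The unfloored difference is retained in
    ``daily_co2_raw`` for audit.
    """
    if len(sample.days) != len(control.days) or not np.allclose(sample.days, control.days):
        missing = sorted(set(sample.days.tolist()) ^ set(control.days.tolist()))
        raise DayGridError(missing)
    raw = sample.daily_co2 - control.daily_co2
    net = np.maximum(raw, 0.0)
    out = RespirationSeries(
        microcosm=sample.microcosm,
        days=sample.days.copy(),
        daily_co2=net,
        baseline_subtracted=True,
        daily_co2_raw=raw,
        interpolated_days=sample.interpolated_days,
    )
    return accumulate(out)


def resample(series: RespirationSeries, target_days: Sequence[float]) -> RespirationSeries:
    """Align a series onto ``target_days`` by linear interpolation of the
    cumulative curve. Interpolated days are flagged; extrapolation beyond
    the observed span is refused.
    """
    target = np.asarray(target_days, dtype=float)
    if np.any(target < series.days[0] - 1e-12) or np.any(target > series.days[-1] + 1e-12):
        raise DayGridError(
            [d for d in target.tolist() if d < series.days[0] or d > series.days[-1]]
        )
    cum = np.interp(target, series.days, series.cumulative_co2)
    daily = np.diff(np.concatenate([[0.0], cum]))
    observed = set(np.round(series.days, 9).tolist())
    interp = tuple(d for d in target.tolist() if round(d, 9) not in observed)
    return RespirationSeries(
        microcosm=series.microcosm,
        days=target,
        daily_co2=daily,
        cumulative_co2=cum,
        baseline_subtracted=series.baseline_subtracted,
        interpolated_days=interp,
    )


def average_daily_rate(series: RespirationSeries, window: tuple = None) -> float:
    """Average net CO2 evolution rate (mg/day) over ``window``.

    ``window`` is a half-open interval (t0, t1]; defaults to the full
    span from day 0 to the last sampling day.
    """
    t0, t1 = window if window is not None else (0.0, float(series.days[-1]))
    if t1 <= t0:
        raise InputError(f"empty window ({t0}, {t1}]")
    if t0 < 0 or t1 > series.days[-1] + 1e-12:
        raise InputError(f"window ({t0}, {t1}] outside series span (0, {series.days[-1]}]")
    mask = (series.days > t0) & (series.days <= t1 + 1e-12)
    return float(series.daily_co2[mask].sum() / (t1 - t0))


def average_series(
    series_list: Sequence[RespirationSeries], microcosm: Optional[MicrocosmSpec] = None
) -> RespirationSeries:
    """Pointwise mean of replicate series sharing a day grid."""
    if not series_list:
        raise InputError("no series to average")
    days = series_list[0].days
    for s in series_list[1:]:
        if len(s.days) != len(days) or not np.allclose(s.days, days):
            raise DayGridError(sorted(set(days.tolist()) ^ set(s.days.tolist())))
    daily = np.mean([s.daily_co2 for s in series_list], axis=0)
    out = RespirationSeries(
        microcosm=microcosm or series_list[0].microcosm,
        days=days.copy(),
        daily_co2=daily,
        baseline_subtracted=all(s.baseline_subtracted for s in series_list),
    )
    return accumulate(out)


def control_baseline(
    series_list: Sequence[RespirationSeries],
) -> Optional[RespirationSeries]:
    """Average of the control (no-fuel) series in a collection, or None."""
    controls = [s for s in series_list if s.microcosm.fuel == Fuel.CONTROL]
    if not controls:
        return None
    return average_series(controls)
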