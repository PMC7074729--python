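"""Stoichiometric substrate reconstruction and piecewise first-order fitting.

Aerobic mineralization is modelled on a CH2 monomer basis
(2 CH2 + 3 O2 -> 2 CO2 + 2 H2O), so 44 mg of evolved CO2 corresponds to
14 mg of hydrocarbon consumed and the fuel carries 12/14 of its mass as
carbon. The remaining-substrate trajectory is fitted with one to three
contiguous first-order phases, ln C_t = ln C_0 - k t per phase, with C
continuous at phase boundaries; breakpoints are chosen by exhaustive
search over observed sampling days, minimizing ln-space RMSE.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares, lsq_linear

from .errors import FitError, InputError, OverdrawError
from .types import Phase, PiecewiseFit, RespirationSeries, SubstrateSeries

#: mg CH2-equivalent hydrocarbon consumed per mg CO2 evolved.
CO2_TO_CH2 = 14.0 / 44.0
#: carbon mass fraction of a CH2 monomer.
C_FRACTION_CH2 = 12.0 / 14.0
#: carbon mass fraction of CO2.
C_FRACTION_CO2 = 12.0 / 44.0


def co2_to_mineralized(co2):
    """mg of CH2-equivalent hydrocarbon mineralized per mg CO2 evolved."""
    co2 = np.asarray(co2, dtype=float)
    if np.any(co2 < 0):
        raise InputError("CO2 mass must be non-negative")
    out = co2 * CO2_TO_CH2
    return float(out) if out.ndim == 0 else out


def fuel_carbon(fuel_mass: float) -> float:
    """mg C in a fuel dose under the CH2 composition assumption."""
    if fuel_mass < 0:
        raise InputError("fuel mass must be non-negative")
    return fuel_mass * C_FRACTION_CH2


def build_substrate_series(
    resp: RespirationSeries,
    c0: float,
    include_day_zero: bool = False,
    floor_frac: float = 1e-6,
) -> SubstrateSeries:
    """Remaining contaminant C_t = C_0 - mineralized(cumulative CO2).

    Values are clipped at a small positive floor so a log-linear fit is
    always defined; clipped points are flagged (and excluded from fits).
    Mineralized mass exceeding ``c0`` beyond the floor tolerance raises
    :class:`OverdrawError` — the usual causes are a wrong ``c0`` or a
    series that was never baseline-subtracted.
    """
    if c0 <= 0:
        raise InputError("c0 must be positive")
    if not resp.baseline_subtracted:
        raise InputError(
            f"microcosm {resp.microcosm.id}: respiration series must be "
            "baseline-subtracted before substrate reconstruction"
        )
    mineralized = co2_to_mineralized(resp.cumulative_co2)
    raw = c0 - mineralized
    tol = floor_frac * c0
    if np.any(raw < -tol):
        raise OverdrawError(
            f"stoichiometric overdraw for microcosm {resp.microcosm.id}: "
            f"mineralized {mineralized.max():.1f} mg exceeds c0 = {c0:.1f} mg "
            "(wrong c0 or un-subtracted baseline?)"
        )
    pos = raw[raw > 0]
    floor = max(tol, (pos.min() * 1e-3) if len(pos) else 0.0)
    c_t = np.maximum(raw, floor)
    clipped = raw < floor
    days = resp.days
    if include_day_zero and (len(days) == 0 or days[0] > 0):
        days = np.concatenate([[0.0], days])
        c_t = np.concatenate([[c0], c_t])
        clipped = np.concatenate([[False], clipped])
    return SubstrateSeries(
        microcosm=resp.microcosm, days=days, c_t=c_t, c0=c0, clipped=clipped
    )


# ---------------------------------------------------------------------------
# fitting


def _segment_design(days: np.ndarray, bounds: Sequence[float]) -> np.ndarray:
    """Design matrix of the continuous piecewise-log-linear model.

    Columns: intercept (ln C at the fitted span's start), then one ramp
    per phase whose coefficient is that phase's rate constant k (>= 0).
    """
    n_phases = len(bounds) - 1
    a = np.ones((len(days), n_phases + 1))
    for j in range(n_phases):
        a[:, j + 1] = -np.clip(days - bounds[j], 0.0, bounds[j + 1] - bounds[j])
    return a


def _fit_placement(days, ln_c, bounds, objective="log", c_lin=None):
    """Joint constrained fit of all phases for one breakpoint placement.

    Returns (params, rmse) where params = [ln c_start, k_1, ..., k_p].
    """
    a = _segment_design(days, bounds)
    p = a.shape[1] - 1
    lb = np.concatenate([[-np.inf], np.zeros(p)])
    ub = np.full(p + 1, np.inf)
    res = lsq_linear(a, ln_c, bounds=(lb, ub), method="bvls")
    x = res.x
    if objective == "linear":
        # refine in linear C-space starting from the log-space solution
        def resid(params):
            return np.exp(a @ params) - c_lin

        nl = least_squares(resid, x, bounds=(lb, ub))
        x = nl.x
        rmse = float(np.sqrt(np.mean(resid(x) ** 2)))
    else:
        rmse = float(np.sqrt(np.mean((a @ x - ln_c) ** 2)))
    return x, rmse


def _fit_points(s: SubstrateSeries, t_start, t_end):
    mask = np.ones(len(s.days), dtype=bool)
    if t_start is not None:
        mask &= s.days >= t_start - 1e-12
    if t_end is not None:
        mask &= s.days <= t_end + 1e-12
    mask &= ~s.clipped
    days = s.days[mask]
    c = s.c_t[mask]
    if np.any(c <= 0):
        raise FitError("non-positive substrate values in fitting window")
    return days, c


def fit_single_phase(
    s: SubstrateSeries,
    t_start: Optional[float] = None,
    t_end: Optional[float] = None,
    objective: str = "log",
) -> tuple:
    """First-order rate constant over one window.

    Minimizes RMSE between ln C_t and the line ln C_start - k (t - t_start);
    both the intercept and k are fitted, with k clamped at 0. Returns
    ``(k, rmse)``.
    """
    days, c = _fit_points(s, t_start, t_end)
    if len(days) < 3:
        raise FitError(f"need >= 3 points in window, got {len(days)}")
    x, rmse = _fit_placement(days, np.log(c), [days[0], days[-1]], objective, c)
    return float(x[1]), rmse


def fit_piecewise(
    s: SubstrateSeries,
    n_phases: int = 2,
    min_points_per_phase: int = 3,
    objective: str = "log",
) -> PiecewiseFit:
    """Best piecewise first-order fit over all breakpoint placements.

    Breakpoints are restricted to observed sampling days; every phase
    must span at least ``min_points_per_phase`` observations (boundary
    points are shared — the model is continuous there). All phases are
    fitted jointly by constrained linear least squares in ln-space, so
    total RMSE is non-increasing in ``n_phases``.
    """
    if not 1 <= n_phases <= 3:
        raise FitError(f"n_phases must be 1..3, got {n_phases}")
    days, c = _fit_points(s, None, None)
    n = len(days)
    m = min_points_per_phase
    if n < n_phases * m:
        raise FitError(
            f"series too short for {n_phases} phases: need at least "
            f"{n_phases * m} positive points, got {n}"
        )
    ln_c = np.log(c)

    best = None
    for cut in itertools.combinations(range(m - 1, n - m + 1), n_phases - 1):
        idx = list(cut)
        if any(b - a < m - 1 for a, b in zip(idx, idx[1:])):
            continue
        if idx and (idx[0] < m - 1 or (n - 1) - idx[-1] < m - 1):
            continue
        bounds = [days[0]] + [days[i] for i in idx] + [days[-1]]
        x, rmse = _fit_placement(days, ln_c, bounds, objective, c)
        if best is None or rmse < best[1] - 1e-15:
            best = (x, rmse, bounds)
    if best is None:  # pragma: no cover - guarded by the length check
        raise FitError("no admissible breakpoint placement")
    x, rmse, bounds = best
    phases = []
    warnings = []
    ln_start = x[0]
    for j in range(n_phases):
        k = float(x[j + 1])
        if k == 0.0:
            warnings.append(
                f"phase {j + 1}: fitted slope clamped at k = 0 (non-decaying segment)"
            )
        phases.append(
            Phase(t_start=float(bounds[j]), t_end=float(bounds[j + 1]), k=k,
                  c_start=float(np.exp(ln_start)))
        )
        ln_start -= k * (bounds[j + 1] - bounds[j])
    return PiecewiseFit(
        phases=phases,
        rmse=rmse,
        n_phases=n_phases,
        breakpoints=tuple(float(b) for b in bounds[1:-1]),
        warnings=tuple(warnings),
    )


@dataclass
class KSummary:
    """Per-group summary of whole-window rate constants."""

    mean: float
    se: float
    n: int
    se_defined: bool
    ks: tuple


def summarize_k(fits: Sequence) -> KSummary:
    """Mean and standard error of whole-window k over replicates.

    Accepts :class:`PiecewiseFit` objects (their first-phase k when
    single-phase) or bare floats. With a single replicate the SE is
    undefined and reported as 0 with ``se_defined=False``.
    """
    ks = []
    for f in fits:
        if isinstance(f, PiecewiseFit):
            if f.n_phases != 1:
                raise InputError(
                    "summarize_k expects whole-window (single-phase) fits; "
                    f"got n_phases={f.n_phases}"
                )
            ks.append(f.phases[0].k)
        else:
            ks.append(float(f))
    if not ks:
        raise InputError("no replicates to summarize")
    arr = np.array(ks)
    if len(arr) == 1:
        return KSummary(float(arr[0]), 0.0, 1, False, tuple(arr))
    se = float(arr.std(ddof=1) / np.sqrt(len(arr)))
    return KSummary(float(arr.mean()), se, len(arr), True, tuple(arr))
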