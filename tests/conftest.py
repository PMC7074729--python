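"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from respiro import synthetic_data as sd
from respiro import io as rio
from respiro.types import Fuel, MicrocosmSpec, RespirationSeries, Setup


def make_spec(
    mid="M1", fuel=Fuel.DIESEL, fuel_mass=2000.0, soil_mass=1000.0,
    n_added=300.0, setup=Setup.SOIL_BED, replicate=1,
) -> MicrocosmSpec:
    return MicrocosmSpec(
        id=mid, fuel=fuel, fuel_mass=fuel_mass, soil_mass=soil_mass,
        n_added=n_added, setup=setup, replicate=replicate,
    )


def make_series(daily, days=None, spec=None, subtracted=False) -> RespirationSeries:
    daily = np.asarray(daily, dtype=float)
    if days is None:
        days = np.arange(1, len(daily) + 1, dtype=float)
    return RespirationSeries(
        microcosm=spec or make_spec(),
        days=np.asarray(days, dtype=float),
        daily_co2=daily,
        baseline_subtracted=subtracted,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_cohort():
    cfg = sd.GeneratorConfig(seed=7, noise_sd_frac=0.0, replicates=2)
    return sd.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    cfg = sd.GeneratorConfig(seed=11, replicates=3)
    return sd.simulate_cohort(cfg)


@pytest.fixture
def cohort_dir(tmp_path, noisy_cohort):
    return rio.write_cohort(noisy_cohort, tmp_path / "cohort")


# ---------------------------------------------------------------------------
# independent oracle: brute-force piecewise fit
#
# Enumerates every admissible breakpoint placement and minimizes the
# ln-space RMSE of the continuous piecewise model by generic bounded
# nonlinear optimization (L-BFGS-B) — a different code path from the
# package's constrained linear least squares.


def _oracle_model(params, days, bounds):
    ln_c = np.full_like(days, params[0], dtype=float)
    for j in range(len(bounds) - 1):
        ln_c -= params[j + 1] * np.clip(days - bounds[j], 0.0, bounds[j + 1] - bounds[j])
    return ln_c


def oracle_fit_placement(days, ln_c, bounds):
    p = len(bounds) - 1

    def sse(params):
        r = _oracle_model(params, days, bounds) - ln_c
        return float(r @ r)

    x0 = np.concatenate([[ln_c[0]], np.full(p, 0.01)])
    res = minimize(
        sse, x0, method="L-BFGS-B",
        bounds=[(None, None)] + [(0.0, None)] * p,
        options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12},
    )
    return res.x, float(np.sqrt(res.fun / len(days)))


def oracle_piecewise(days, c, n_phases, min_points=3):
    """Best (rmse, breakpoints) over all placements, by brute force."""
    days = np.asarray(days, dtype=float)
    ln_c = np.log(np.asarray(c, dtype=float))
    n = len(days)
    m = min_points
    best = None
    for cut in itertools.combinations(range(m - 1, n - m + 1), n_phases - 1):
        idx = list(cut)
        if any(b - a < m - 1 for a, b in zip(idx, idx[1:])):
            continue
        if idx and (idx[0] < m - 1 or (n - 1) - idx[-1] < m - 1):
            continue
        bounds = [days[0]] + [days[i] for i in idx] + [days[-1]]
        _, rmse = oracle_fit_placement(days, ln_c, bounds)
        if best is None or rmse < best[0] - 1e-15:
            best = (rmse, tuple(bounds[1:-1]))
    return best


def random_decay_series(rng, n_points, n_phases, noise_sd=0.05):
    """Random piecewise-exponential decay with log-space noise (always
    positive), for oracle-equivalence checks."""
    days = np.sort(rng.choice(np.arange(0, 2 * n_points), size=n_points, replace=False)).astype(float)
    bounds = np.sort(rng.choice(days[1:-1], size=n_phases - 1, replace=False)) if n_phases > 1 else []
    ks = rng.uniform(0.0, 0.2, size=n_phases)
    ln_c = np.full(n_points, np.log(1000.0))
    lo = days[0]
    for j, k in enumerate(ks):
        hi = bounds[j] if j < len(ks) - 1 else days[-1]
        ln_c -= k * np.clip(days - lo, 0.0, hi - lo)
        lo = hi
    ln_c += rng.normal(0.0, noise_sd, size=n_points)
    return days, np.exp(ln_c)
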