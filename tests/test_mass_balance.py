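import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_series, make_spec
from respiro import mass_balance as mb
from respiro.errors import BalanceError, InputError, OverdrawError
from respiro.kinetics import C_FRACTION_CH2
from respiro.types import DroResult, Fuel, NitrogenBudget


class TestNitrogenAmendment:
    def test_paper_setup(self):
        assert mb.nitrogen_amendment(30.0, 10.0, 1.0) == pytest.approx(300.0)

    def test_zero_soil_errors(self):
        with pytest.raises(InputError):
            mb.nitrogen_amendment(30.0, 10.0, 0.0)


class TestBiomassFromNitrogen:
    def test_zero(self):
        assert mb.biomass_from_nitrogen(0.0, 300.0, 1700.0) == 0.0

    def test_diesel_approximately_ten_percent(self):
        pct = mb.biomass_from_nitrogen(12.0, 300.0, 1700.0)
        assert round(pct, 2) == 9.08
        assert round(pct / 10) * 10 == 10  # "approximately 10%"

    def test_high_depletion(self):
        assert mb.biomass_from_nitrogen(38.4, 300.0, 1700.0) == pytest.approx(29.0, abs=0.05)

    def test_nonpositive_c_initial_errors(self):
        with pytest.raises(InputError):
            mb.biomass_from_nitrogen(10.0, 300.0, 0.0)

    @given(
        pct=st.floats(0, 100),
        n0=st.floats(1, 1000),
        c0=st.floats(100, 10000),
        lam=st.floats(0.1, 2.0),
    )
    def test_linearity(self, pct, n0, c0, lam):
        base = mb.biomass_from_nitrogen(pct, n0, c0)
        if pct * lam <= 100:
            assert mb.biomass_from_nitrogen(pct * lam, n0, c0) == pytest.approx(lam * base, rel=1e-9)
        assert mb.biomass_from_nitrogen(pct, n0 * lam, c0) == pytest.approx(lam * base, rel=1e-9)
        assert mb.biomass_from_nitrogen(pct, n0, c0 * lam) == pytest.approx(base / lam, rel=1e-9)


class TestPctMineralized:
    def test_zero(self):
        assert mb.pct_mineralized(0.0, 100.0) == 0.0

    def test_derived_example(self):
        assert mb.pct_mineralized(44.0, 120.0) == pytest.approx(10.0)

    def test_complete_mineralization(self):
        c = 500.0
        assert mb.pct_mineralized(c * 44 / 12, c) == pytest.approx(100.0)

    def test_overdraw(self):
        with pytest.raises(OverdrawError):
            mb.pct_mineralized(200.0 * 44 / 12, 100.0)

    def test_ch2_basis_matches_carbon_basis(self):
        # fuel carbon and CO2 carbon share the CH2 assumption, so the two
        # bases coincide numerically
        assert mb.pct_mineralized(440.0, 1714.2857, basis="ch2") == pytest.approx(
            mb.pct_mineralized(440.0, 1714.2857, basis="carbon")
        )


class TestCorrectDro:
    def test_full_recovery(self):
        assert mb.correct_dro(100.0, 1.0).corrected_mass == pytest.approx(100.0)

    def test_partial_recovery(self):
        assert mb.correct_dro(80.0, 0.8).corrected_mass == pytest.approx(100.0)

    def test_zero_recovery_errors(self):
        with pytest.raises(InputError):
            mb.correct_dro(100.0, 0.0)

    def test_out_of_band_flagged(self):
        assert mb.correct_dro(100.0, 0.3).recovery_flagged
        assert mb.correct_dro(100.0, 1.6).recovery_flagged
        assert not mb.correct_dro(100.0, 0.9).recovery_flagged


def no_resp_series(n=5):
    return make_series([0.0] * n, subtracted=True)


class TestAssembleBalance:
    def test_unreacted_microcosm(self):
        spec = make_spec(fuel_mass=2000.0)
        dro = mb.correct_dro(2000.0, 1.0)  # full fuel mass recovered as DRO
        nitro = NitrogenBudget(n_initial=300.0, n_final=300.0)
        bal = mb.assemble_balance(no_resp_series(), dro, nitro, spec, volat_assumed_pct=0.0)
        assert bal.pct_residual_dro == pytest.approx(100.0)
        assert bal.pct_mineralized == 0.0
        assert bal.pct_biomass == 0.0
        assert bal.pct_unaccounted == pytest.approx(0.0, abs=1e-9)

    def test_arithmetic_closure_example(self):
        # mineralized 34%, residual 45%, biomass 16%, volatilized 0 -> unaccounted 5%
        spec = make_spec(fuel_mass=2000.0)
        c_init = 2000.0 * C_FRACTION_CH2
        resp = make_series([0.34 * c_init * 44 / 12], subtracted=True)
        dro = mb.correct_dro(0.45 * 2000.0, 1.0)
        pct_n = 16.0 * c_init / (300.0 * mb.BIOMASS_C_PER_N)
        nitro = NitrogenBudget(n_initial=300.0, n_final=300.0 * (1 - pct_n / 100))
        bal = mb.assemble_balance(resp, dro, nitro, spec, volat_assumed_pct=0.0)
        assert bal.pct_mineralized == pytest.approx(34.0)
        assert bal.pct_residual_dro == pytest.approx(45.0)
        assert bal.pct_biomass == pytest.approx(16.0)
        assert bal.pct_unaccounted == pytest.approx(5.0)
        assert bal.total == pytest.approx(100.0, abs=1e-9)

    def test_volatilization_defaults_per_fuel(self):
        for fuel, expect in ((Fuel.DIESEL, 20.0), (Fuel.B20, 4.0), (Fuel.B100, 0.0)):
            spec = make_spec(mid=fuel.value, fuel=fuel, fuel_mass=2000.0)
            dro = mb.correct_dro(100.0, 1.0)
            bal = mb.assemble_balance(no_resp_series(), dro, None, spec)
            assert bal.pct_volatilized == expect

    def test_biomass_capped_when_closure_negative(self):
        spec = make_spec(fuel_mass=2000.0)
        c_init = 2000.0 * C_FRACTION_CH2
        resp = make_series([0.5 * c_init * 44 / 12], subtracted=True)
        dro = mb.correct_dro(0.45 * 2000.0, 1.0)  # 45% residual
        nitro = NitrogenBudget(n_initial=300.0, n_final=100.0)  # 66.7% N used -> huge biomass
        bal = mb.assemble_balance(resp, dro, nitro, spec, volat_assumed_pct=0.0)
        assert bal.biomass_capped
        assert bal.pct_biomass == pytest.approx(5.0)
        assert bal.total == pytest.approx(100.0, abs=1e-9)
        assert not bal.over_recovery

    def test_over_recovery_flagged(self):
        spec = make_spec(fuel_mass=2000.0)
        c_init = 2000.0 * C_FRACTION_CH2
        resp = make_series([0.6 * c_init * 44 / 12], subtracted=True)
        dro = mb.correct_dro(0.55 * 2000.0, 1.0)
        bal = mb.assemble_balance(resp, dro, None, spec, volat_assumed_pct=0.0)
        assert bal.over_recovery
        assert bal.pct_unaccounted < 0
        assert bal.total == pytest.approx(100.0, abs=1e-9)

    def test_component_over_100_errors(self):
        spec = make_spec(fuel_mass=2000.0)
        dro = mb.correct_dro(3000.0, 1.0)  # > initial fuel mass
        with pytest.raises(BalanceError, match="residual"):
            mb.assemble_balance(no_resp_series(), dro, None, spec, volat_assumed_pct=0.0)

    def test_volat_out_of_range_errors(self):
        spec = make_spec(fuel_mass=2000.0)
        dro = mb.correct_dro(100.0, 1.0)
        with pytest.raises(BalanceError):
            mb.assemble_balance(no_resp_series(), dro, None, spec, volat_assumed_pct=25.0)

    @given(
        min_frac=st.floats(0, 0.5),
        res_frac=st.floats(0, 0.4),
        n_used=st.floats(0, 40),
        volat=st.floats(0, 20),
    )
    def test_closure_always_exact(self, min_frac, res_frac, n_used, volat):
        spec = make_spec(fuel_mass=2000.0)
        c_init = 2000.0 * C_FRACTION_CH2
        resp = make_series([min_frac * c_init * 44 / 12], subtracted=True)
        dro = mb.correct_dro(res_frac * 2000.0, 1.0)
        nitro = NitrogenBudget(n_initial=300.0, n_final=300.0 * (1 - n_used / 100))
        bal = mb.assemble_balance(resp, dro, nitro, spec, volat_assumed_pct=volat)
        assert bal.total == pytest.approx(100.0, abs=1e-6)


class TestGeneratorConsistency:
    def test_booked_fractions_match_assembly_at_zero_noise(self, noiseless_cohort):
        from respiro import respirometry as rp

        by_setup = {}
        for m in noiseless_cohort.microcosms:
            by_setup.setdefault(m.spec.setup, []).append(m)
        for setup, members in by_setup.items():
            series = {m.spec.id: rp.records_to_series(m.spec, m.records) for m in members}
            baseline = rp.control_baseline(list(series.values()))
            for m in members:
                if m.truth is None:
                    continue
                net = rp.subtract_baseline(series[m.spec.id], baseline)
                bal = mb.assemble_balance(
                    net, m.dro, m.nitrogen, m.spec, volat_assumed_pct=m.truth["pct_volatilized"]
                )
                for key in ("pct_mineralized", "pct_residual_dro", "pct_biomass", "pct_unaccounted"):
                    assert getattr(bal, key) == pytest.approx(m.truth[key], abs=1.0), (m.spec.id, key)
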