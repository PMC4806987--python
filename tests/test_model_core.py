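"""Algebraic variables, flux laws and right-hand sides of both variants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import haloresp as hr
from haloresp.model_core import (
    EG_PARAM_NAMES,
    LN10,
    DomainError,
    make_ode,
    parameter_set_names,
    reference_algebraic,
)

# Published algebraic values carry ~1e-4 internal rounding inconsistencies
# (e.g. the printed Δμ's do not exactly match the printed pmf at T = 298 K),
# so "agreement to 4 significant figures" is asserted at rtol 2e-4.
REFERENCE_RTOL = 2e-4


class TestComputeAlgebraic:
    def test_reference_state_closure(self, env, initial_state):
        """The default initial state reproduces every published algebraic
        variable (extracellular concentrations, gradients, pmf, Δμ's)."""
        alg = hr.compute_algebraic(initial_state, env)
        for name, expected in reference_algebraic().items():
            assert getattr(alg, name) == pytest.approx(
                expected, rel=REFERENCE_RTOL), name

    def test_pmf_equals_dpsi_without_ph_gradient(self, env):
        # Hi = Ho exactly when Hi equals the suspension-average concentration
        state = hr.StateVector(Hi=env.Htot, ATP=1e-3, Ki=2.3, Nai=1.9,
                               dPsi=0.123)
        alg = hr.compute_algebraic(state, env)
        assert alg.dpH == pytest.approx(0.0, abs=1e-12)
        assert alg.pmf == pytest.approx(state.dPsi, rel=1e-12)

    def test_dmu_na_independent_arithmetic(self, env, initial_state):
        # hand evaluation of the sodium free energy at the initial state
        expected = 96485 * 0.08 - 8.314462 * 298 * math.log(10) * (-0.30103)
        alg = hr.compute_algebraic(initial_state, env)
        assert alg.dmuNa == pytest.approx(expected, rel=1e-4)
        assert alg.dmuH == pytest.approx(env.F * alg.pmf, rel=1e-12)

    def test_compartment_conservation(self, env, initial_state):
        alg = hr.compute_algebraic(initial_state, env)
        for inside, outside, total in (
                (initial_state.Hi, alg.Ho, env.Htot),
                (initial_state.Ki, alg.Ko, env.Ktot),
                (initial_state.Nai, alg.Nao, env.Natot)):
            lhs = inside * env.a1 + outside * env.a2
            assert lhs == pytest.approx(total * env.V_susp, rel=1e-12)

    @pytest.mark.parametrize("species,state_kw", [
        ("H", {"Hi": -1e-9}),
        ("K", {"Ki": 1e9}),       # drains the extracellular pool negative
        ("Na", {"Nai": 1e9}),
    ])
    def test_domain_error_names_species(self, env, species, state_kw):
        base = {"Hi": 1e-7, "ATP": 1e-3, "Ki": 2.3, "Nai": 1.9, "dPsi": 0.08}
        base.update(state_kw)
        with pytest.raises(DomainError, match=species):
            hr.compute_algebraic(hr.StateVector(**base), env)


class TestComputeFluxes:
    def test_en5_antiport_flux_value(self, env, initial_state, en5):
        alg = hr.compute_algebraic(initial_state, env)
        fluxes = hr.compute_fluxes(initial_state, alg, en5, env)
        # alpha_NaH * (dpNa - dpH) with the published gradients
        assert fluxes.J_NaH == pytest.approx(
            3.693e-4 * (-0.30103 + 0.5), rel=1e-3)

    def test_zero_drivers_zero_fluxes(self, env, en5):
        state = hr.StateVector(Hi=1e-7, ATP=1e-3, Ki=2.3, Nai=1.9, dPsi=0.0)
        alg = hr.AlgebraicState(Ho=1e-7, Ko=2.3, Nao=1.9,
                                ADP=env.Atot - 1e-3, pmf=0.0,
                                dpH=0.2, dpNa=0.2, dpK=0.0,
                                dmuH=0.0, dmuNa=0.0, dmuK=0.0)
        fluxes = hr.compute_fluxes(state, alg, en5, env)
        assert fluxes.J_ATPS == 0.0
        assert fluxes.J_NaH == 0.0
        assert fluxes.J_K == 0.0
        assert fluxes.J_ETCP == en5.beta_ETCP  # exp(0) = 1
        assert fluxes.J_ATPuse == en5.alpha_ATPuse * state.ATP

    def test_electrogenic_reversal_point(self, env, initial_state, eg1):
        """The antiport flux vanishes where n_NaH·Δμ_H = Δμ_Na, which at
        the initial state happens near n_NaH = 0.8926."""
        alg = hr.compute_algebraic(initial_state, env)
        n_star = alg.dmuNa / alg.dmuH
        assert n_star == pytest.approx(0.8926, rel=1e-3)
        params = eg1.with_values(n_NaH=n_star)
        fluxes = hr.compute_fluxes(initial_state, alg, params, env)
        assert abs(fluxes.J_NaH) < 1e-10
        # below the reversal ratio the antiport runs in reverse (Na in)
        below = hr.compute_fluxes(
            initial_state, alg, eg1, env)  # EG1 has n_NaH = 0.76 < n*
        assert below.J_NaH < 0

    def test_negative_adp_with_fractional_order_raises(self, env, en5):
        state = hr.StateVector(Hi=1e-7, ATP=env.Atot * 1.1, Ki=2.3,
                               Nai=1.9, dPsi=0.08)
        alg = hr.compute_algebraic(state, env)
        assert alg.ADP < 0
        with pytest.raises(DomainError, match="ADP"):
            hr.compute_fluxes(state, alg, en5, env)

    def test_negative_pmf_warns_and_clamps_synthase(self, env, en5):
        state = hr.StateVector(Hi=1e-6, ATP=1e-3, Ki=2.3, Nai=1.9,
                               dPsi=-0.2)
        alg = hr.compute_algebraic(state, env)
        assert alg.pmf < 0
        with pytest.warns(UserWarning, match="pmf"):
            fluxes = hr.compute_fluxes(state, alg, en5, env)
        assert fluxes.J_ATPS == 0.0


class TestRhs:
    def test_zero_parameters_zero_derivative(self, env, initial_state):
        params = hr.ModelParams(variant="EN", beta_ATPS=0, gamma_ATPS_ADP=0,
                                beta_ETCP=0, gamma_ETCP_pmf=0, alpha_NaH=0,
                                alpha_K=0, alpha_ATPuse=0, beta_mempot=0)
        dy = hr.rhs(0.0, initial_state, params, env)
        assert np.all(dy == 0.0)

    def test_en5_atp_derivative_arithmetic(self, env, initial_state, en5):
        """dATP/dt at the initial state from an independent hand
        evaluation of the synthase and consumption laws."""
        alg = hr.compute_algebraic(initial_state, env)
        J_ATPS = 0.042 * (1.712e-3) ** 0.174 * alg.pmf
        expected = J_ATPS - 0.779 * 5.88e-4
        dy = hr.rhs(0.0, initial_state, en5, env)
        assert dy[1] == pytest.approx(expected, rel=1e-6)

    def test_en_eg_coincide_without_antiport(self, env, initial_state, en5):
        en = en5.with_values(alpha_NaH=0.0)
        eg = hr.ModelParams(variant="EG", n_NaH=1.7, **{
            n: getattr(en, n) for n in en.free_names if n != "n_NaH"})
        assert np.allclose(hr.rhs(0.0, initial_state, en, env),
                           hr.rhs(0.0, initial_state, eg, env),
                           rtol=1e-14, atol=0)

    @pytest.mark.parametrize("set_name", ["EN5", "EG1"])
    def test_make_ode_matches_dataclass_rhs(self, env, set_name):
        from conftest import random_admissible_states

        params = hr.load_parameter_set(set_name)
        f = make_ode(params, env)
        rng = np.random.default_rng(42)
        for state in random_admissible_states(env, rng, 25):
            expected = hr.rhs(0.0, state, params, env)
            assert np.allclose(f(0.0, state.as_array()), expected,
                               rtol=1e-12, atol=1e-300)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    hi=st.floats(1e-9, 2e-4), atp=st.floats(1e-6, 0.00229),
    ki=st.floats(1e-2, 17.0), nai=st.floats(1e-2, 2500.0),
    dpsi=st.floats(-0.25, 0.25),
    n_nah=st.floats(0.3, 3.0),
    variant=st.sampled_from(["EN", "EG"]),
)
def test_charge_balance_identity(hi, atp, ki, nai, dpsi, n_nah, variant):
    """For both variants, dΔΨ/dt = −β_mempot · d([Hi]+[Ki]+[Nai])/dt is an
    exact algebraic identity of the flux bookkeeping."""
    env = hr.default_environment()
    kw = dict(beta_ATPS=0.042, gamma_ATPS_ADP=0.174, beta_ETCP=0.085,
              gamma_ETCP_pmf=0.355, alpha_NaH=0.7, alpha_K=0.6,
              alpha_ATPuse=0.779, beta_mempot=105.6)
    params = hr.ModelParams(variant=variant,
                            n_NaH=n_nah if variant == "EG" else None, **kw)
    state = hr.StateVector(Hi=hi, ATP=atp, Ki=ki, Nai=nai, dPsi=dpsi)
    dy = hr.rhs(0.0, state, params, env)
    lhs = dy[4]
    rhs_val = -params.beta_mempot * (dy[0] + dy[2] + dy[3])
    assert lhs == pytest.approx(rhs_val, rel=1e-12, abs=1e-18)


class TestFixtures:
    def test_all_named_sets_load_and_validate(self):
        names = parameter_set_names()
        assert len(names) == 10
        for name in names:
            params = hr.load_parameter_set(name)
            assert params.n_free == (9 if name.startswith("EG") else 8)
            assert params.n_syn == 4
            assert params.h_per_O2 == 10.0

    def test_unknown_set_lists_known_names(self):
        with pytest.raises(KeyError, match="EN5"):
            hr.load_parameter_set("EN99")

    def test_parameter_vector_roundtrip(self, eg1):
        vec = eg1.to_vector()
        assert len(vec) == 9
        back = hr.ModelParams.from_vector(vec, "EG")
        assert back.n_NaH == eg1.n_NaH
        assert tuple(back.free_names) == EG_PARAM_NAMES

    def test_environment_volume_invariant(self):
        with pytest.raises(DomainError, match="V_susp"):
            hr.Environment(a1=1e-6, a2=1e-6, V_susp=1e-3)
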