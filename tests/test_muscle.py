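"""Hill-muscle primitives: elastic elements, dynamics, forward simulation."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitmet.muscle import (
    MuscleParams,
    MuscleState,
    activation_rate,
    contraction_residual,
    contractile_force,
    elastic_force,
    force_length,
    force_velocity,
    forward_simulate,
    load_muscles,
    passive_equilibrium,
)


class TestElasticForce:
    @pytest.mark.parametrize("length,slack,k,expected", [
        (0.10, 0.10, 1e5, 0.0),          # at slack
        (0.08, 0.10, 1e5, 0.0),          # below slack
        (0.11, 0.10, 1e5, 10.0),         # k * 0.01^2
    ])
    def test_quadratic_law(self, length, slack, k, expected):
        assert elastic_force(length, slack, k) == pytest.approx(expected)

    def test_negative_stiffness_rejected(self):
        with pytest.raises(ValueError):
            elastic_force(0.1, 0.1, -1.0)


class TestForceLength:
    def test_maximal_at_optimum(self, soleus):
        ls = np.linspace(0.4, 1.6, 241) * soleus.l_CE_opt
        fl = force_length(ls, soleus)
        assert fl.max() == pytest.approx(force_length(soleus.l_CE_opt, soleus))
        assert force_length(soleus.l_CE_opt, soleus) == pytest.approx(1.0)


class TestForceVelocity:
    def test_unity_at_zero_velocity(self, soleus):
        assert force_velocity(0.0, soleus) == pytest.approx(1.0, abs=1e-3)

    def test_monotone_and_bounded(self, soleus):
        v = np.linspace(-1.5, 2.0, 2000) * soleus.v_CE_max * soleus.l_CE_opt
        fv = force_velocity(v, soleus)
        assert np.all(np.diff(fv) > -1e-12)
        assert fv.max() <= soleus.g_max + 1e-9

    def test_zero_force_at_max_shortening(self, soleus):
        v = -soleus.v_CE_max * soleus.l_CE_opt
        assert abs(force_velocity(v, soleus)) < 5e-3


class TestActivationRate:
    def test_equilibrium(self, soleus):
        assert activation_rate(0.3, 0.3, soleus) == pytest.approx(0.0)

    def test_full_excitation_from_rest(self, soleus):
        # (u - a) * u / T_act with u=1, a=0, T_act=0.01
        assert activation_rate(0.0, 1.0, soleus) == pytest.approx(
            1.0 / soleus.T_act)

    def test_full_deactivation(self, soleus):
        # (0 - 1) * 1 / T_deact with T_deact=0.04
        assert activation_rate(1.0, 0.0, soleus) == pytest.approx(
            -1.0 / soleus.T_deact)


class TestContractionResidual:
    def test_passive_rest_is_balanced(self, soleus):
        l_mt = soleus.l_MT_ref
        state = MuscleState(a=0.0, u=0.0, l_CE=soleus.l_CE_opt, v_CE=0.0)
        assert contraction_residual(state, l_mt, soleus) == pytest.approx(0.0)

    def test_isometric_balance_at_optimum(self, soleus):
        # SEE stretch chosen so F_SEE = F_max while the CE is isometric at
        # its optimum with full activation
        stretch = np.sqrt(soleus.F_max / soleus.k_SEE)
        l_mt = soleus.tendon_slack_length + stretch + soleus.l_CE_opt
        state = MuscleState(a=1.0, u=1.0, l_CE=soleus.l_CE_opt, v_CE=0.0)
        resid = contraction_residual(state, l_mt, soleus)
        # f_V(0) deviates from 1 by the smoothing bridge only
        assert abs(resid) < 5e-3 * soleus.F_max

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a=st.floats(0, 1), l_rel=st.floats(0.6, 1.5),
           v_rel=st.floats(-0.8, 0.8), stretch_mm=st.floats(0, 10))
    def test_matches_hand_coded_formula(self, soleus, a, l_rel, v_rel,
                                        stretch_mm):
        l_ce = l_rel * soleus.l_CE_opt
        v_ce = v_rel * soleus.v_CE_max * soleus.l_CE_opt
        l_mt = l_ce + soleus.tendon_slack_length + stretch_mm * 1e-3
        state = MuscleState(a=a, u=a, l_CE=l_ce, v_CE=v_ce)
        got = contraction_residual(state, l_mt, soleus)
        # independent evaluation of each element
        f_see = soleus.k_SEE * max(l_mt - l_ce - soleus.tendon_slack_length,
                                   0.0) ** 2
        f_pee = soleus.k_PEE * max(l_ce - soleus.pee_slack_length, 0.0) ** 2
        f_ce = (a * soleus.F_max * force_length(l_ce, soleus)
                * force_velocity(v_ce, soleus)
                + soleus.damping * soleus.F_max * v_ce
                / (soleus.v_CE_max * soleus.l_CE_opt))
        assert got == pytest.approx(f_see - f_pee - f_ce, rel=1e-9, abs=1e-6)

    def test_rejects_non_finite_state(self, soleus):
        state = MuscleState(a=np.nan, u=0.0, l_CE=0.05, v_CE=0.0)
        with pytest.raises(ValueError):
            contraction_residual(state, 0.3, soleus)


class TestWorkIdentity:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(f=st.floats(-100, 5000), v=st.floats(-0.5, 0.5))
    def test_fiber_power(self, f, v):
        state = MuscleState(a=0.5, u=0.5, l_CE=0.05, v_CE=v, F_CE=f)
        assert state.w_dot == pytest.approx(-f * v)


class TestPassiveEquilibrium:
    def test_unique_engaged_equilibrium(self, soleus):
        # long enough that tendon and PEE slack regions overlap, so both
        # elements are engaged at equilibrium
        l_mt = soleus.tendon_slack_length + 1.3 * soleus.l_CE_opt
        l_eq = passive_equilibrium(l_mt, soleus)
        f_see = elastic_force(l_mt - l_eq, soleus.tendon_slack_length,
                              soleus.k_SEE)
        f_pee = elastic_force(l_eq, soleus.pee_slack_length, soleus.k_PEE)
        assert f_see == pytest.approx(f_pee, abs=1e-6)
        # uniqueness: the balance changes sign exactly once on a scan
        ls = np.linspace(1e-3, l_mt - 1e-3, 4000)
        bal = (elastic_force(l_mt - ls, soleus.tendon_slack_length, soleus.k_SEE)
               - elastic_force(ls, soleus.pee_slack_length, soleus.k_PEE))
        assert np.sum(np.diff(np.sign(bal)) != 0) == 1

    def test_slack_region_force_free(self, soleus):
        l_mt = soleus.l_MT_ref - 0.01
        l_eq = passive_equilibrium(l_mt, soleus)
        assert elastic_force(l_mt - l_eq, soleus.tendon_slack_length,
                             soleus.k_SEE) == pytest.approx(0.0)


class TestForwardSimulate:
    def test_passive_equilibrium_persists(self, soleus):
        n = 50
        q = np.zeros((n, 3))
        state, moments = forward_simulate(np.zeros(n), q, soleus, dt=0.01,
                                          n_cycles=2)
        assert np.allclose(state.a, 0.0, atol=1e-12)
        assert np.ptp(state.l_CE) < 1e-6
        assert np.allclose(moments, 0.0, atol=1e-6)

    def test_step_response_monotone(self, soleus):
        n = 80
        u = np.zeros(n)
        u[10:] = 0.8
        q = np.zeros((n, 3))
        state, _ = forward_simulate(u, q, soleus, dt=0.01, n_cycles=1)
        rise = state.a[10:40]
        assert np.all(np.diff(rise) > -1e-12)
        assert rise[-1] < 0.8 + 1e-9

    def test_trajectory_satisfies_contraction_residual(self, soleus):
        n = 60
        rng = np.random.default_rng(0)
        u = 0.3 + 0.2 * np.sin(2 * np.pi * np.arange(n) / n)
        q = np.zeros((n, 3))
        q[:, 2] = 0.1 * np.sin(2 * np.pi * np.arange(n) / n)
        state, _ = forward_simulate(u, q, soleus, dt=0.01)
        l_mt = soleus.musculotendon_length(q)
        resid = contraction_residual(state, l_mt, soleus)
        assert np.abs(resid).max() < 1e-6 * soleus.F_max


class TestParameterIO:
    def test_invalid_time_constants_rejected(self):
        yaml_text = """
bad_muscle:
  F_max: 100.0
  l_CE_opt: 0.05
  width: 0.5
  v_CE_max: 10.0
  T_act: 0.05
  T_deact: 0.01
  tendon_slack_length: 0.2
  pee_slack_length: 0.06
  k_SEE: 1.0e6
  k_PEE: 1.0e5
  moment_arms: {ankle: 0.05}
  fast_twitch_fraction: 0.5
"""
        with pytest.raises(ValueError, match="T_act"):
            load_muscles(io.StringIO(yaml_text))

    def test_biarticular_span_enforced(self):
        yaml_text = """
gastrocnemius:
  F_max: 100.0
  l_CE_opt: 0.05
  width: 0.5
  v_CE_max: 10.0
  T_act: 0.01
  T_deact: 0.04
  tendon_slack_length: 0.2
  pee_slack_length: 0.06
  k_SEE: 1.0e6
  k_PEE: 1.0e5
  moment_arms: {ankle: 0.05}
  fast_twitch_fraction: 0.5
"""
        with pytest.raises(ValueError, match="biarticular"):
            load_muscles(io.StringIO(yaml_text))

    def test_default_set_is_valid(self, muscles):
        assert len(muscles) == 8
        names = {m.name for m in muscles}
        assert {"soleus", "gastrocnemius", "vasti"} <= names
        for m in muscles:
            assert m.F_max > 0 and m.mass() > 0
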