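"""Metabolic energy models: analytic values, conservation, orderings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitmet.energy import (
    GRID_ACTIVATIONS,
    HEAT_MODELS,
    MUSCLE_MODELS,
    joint_breakdown,
    metabolic_cost,
    mine97_phi,
    rate_heat_model,
    rate_kim15,
    rate_marg68,
    rate_mine97,
    verification_grid,
)
from gaitmet.muscle import MuscleState, contractile_force


class TestMarg68:
    def test_isometric_rate_is_zero(self):
        assert rate_marg68(0.0, 0.0) == 0.0

    def test_shortening_efficiency_25_percent(self):
        # 1 W of fiber work costs 4 W metabolically
        assert rate_marg68(1.0, -0.1) == pytest.approx(4.0)

    def test_lengthening_efficiency_120_percent(self):
        # absorbing 1.2 W of work costs 1 W
        assert rate_marg68(-1.2, 0.1) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(f=st.floats(0, 5000), v=st.floats(-0.5, 0.5))
    def test_never_negative(self, f, v):
        w = -f * v
        assert rate_marg68(w, v) >= 0.0


class TestMine97:
    def test_phi_at_zero_velocity(self):
        assert mine97_phi(0.0) == pytest.approx(0.054)

    def test_zero_activation_zero_rate(self, soleus):
        assert rate_mine97(0.0, soleus, -0.03) == 0.0

    def test_linear_in_activation(self, soleus):
        r1 = rate_mine97(0.25, soleus, -0.02)
        r2 = rate_mine97(0.75, soleus, -0.02)
        assert r2 == pytest.approx(3.0 * r1)

    def test_matches_independent_arithmetic(self, soleus):
        vbar_shortening = 0.5
        v_ce = -vbar_shortening * soleus.v_CE_max * soleus.l_CE_opt
        got = rate_mine97(1.0, soleus, v_ce)
        phi = (0.054 + 0.506 * 0.5 + 2.46 * 0.25) / (
            1 - 1.13 * 0.5 + 12.8 * 0.25 - 1.64 * 0.125)
        expected = soleus.F_max * soleus.v_CE_max * soleus.l_CE_opt * phi
        assert got == pytest.approx(expected, rel=1e-12)

    def test_nonnegative_over_velocity_range(self, soleus):
        v = np.linspace(-1, 1, 201) * soleus.v_CE_max * soleus.l_CE_opt
        assert np.all(rate_mine97(1.0, soleus, v) >= 0.0)


class TestKim15:
    maxima = {"q_dot_max": 2.0, "positive_power_max": 20.0}

    def test_zero_moment_zero_rate(self):
        assert rate_kim15(0.0, 1.0, self.maxima) == 0.0

    def test_negative_power_heat_coefficient(self):
        # lowering: M > 0, q_dot < 0 -> negative power with the 1.423 rate
        M, q_dot = 10.0, -1.0
        got = rate_kim15(M, q_dot, self.maxima)
        expected = 0.054 * 2.0 * 10.0 + 1.423 * 10.0 + (-10.0)
        assert got == pytest.approx(expected)

    def test_positive_power_hand_computed(self):
        M, q_dot = 10.0, 1.0
        got = rate_kim15(M, q_dot, self.maxima, cocontraction=0.0)
        expected = 0.054 * 2.0 * 10.0 + 0.283 * 10.0 + 10.0
        assert got == pytest.approx(expected)

    def test_missing_maxima_rejected(self):
        with pytest.raises(ValueError):
            rate_kim15(1.0, 1.0, {"q_dot_max": 2.0})


def _state(soleus, a, vbar):
    v_ce = vbar * soleus.v_CE_max * soleus.l_CE_opt
    f_ce = contractile_force(a, soleus.l_CE_opt, v_ce, soleus)
    return MuscleState(a=a, u=a, l_CE=soleus.l_CE_opt, v_CE=v_ce,
                       F_CE=f_ce, F_SEE=f_ce)


class TestHeatModels:
    def test_unknown_model_rejected(self, soleus):
        with pytest.raises(ValueError):
            rate_heat_model("SMITH99", _state(soleus, 0.5, 0.0), 0.5, 1.0,
                            soleus)

    @pytest.mark.parametrize("model", HEAT_MODELS)
    def test_component_identity(self, model, soleus):
        """E = w + h_a + h_m + h_sl exactly, for random states."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.uniform(0, 1)
            vbar = rng.uniform(-0.9, 0.9)
            s = _state(soleus, a, vbar)
            out = rate_heat_model(model, s, a, 1.0, soleus)
            assert out.E == pytest.approx(
                out.w_dot + out.h_a + out.h_m + out.h_sl, rel=1e-12, abs=1e-9)

    @pytest.mark.parametrize("model", HEAT_MODELS)
    def test_rest_state_has_no_work(self, model, soleus):
        s = _state(soleus, 0.0, 0.0)
        out = rate_heat_model(model, s, 0.0, 1.0, soleus)
        assert out.w_dot == 0.0
        assert out.E >= 0.0  # basal terms cannot be negative at rest

    @pytest.mark.parametrize("model", HEAT_MODELS)
    def test_lengthening_rate_negative_without_clamp(self, model, soleus):
        s = _state(soleus, 1.0, 1.0)  # lengthening at 1 l_opt/s
        out = rate_heat_model(model, s, 1.0, 1.0, soleus)
        assert out.E < 0.0


class TestMetabolicCost:
    def test_constant_rate_single_muscle(self):
        rates = np.full((100, 1), 5.0)
        assert metabolic_cost(rates, T=1.0, m=70.0, v=1.3) == pytest.approx(
            5.0 / (70.0 * 1.3))

    def test_clamp_equals_subtract_on_nonnegative(self):
        rng = np.random.default_rng(0)
        rates = rng.uniform(0, 10, size=(100, 8))
        a = metabolic_cost(rates, 1.1, 70, 1.3, "subtract")
        b = metabolic_cost(rates, 1.1, 70, 1.3, "clamp_zero")
        assert a == pytest.approx(b)

    def test_clamp_dominates_subtract_on_mixed_signs(self):
        rng = np.random.default_rng(1)
        rates = rng.uniform(-5, 10, size=(100, 8))
        assert metabolic_cost(rates, 1.1, 70, 1.3, "clamp_zero") >= \
            metabolic_cost(rates, 1.1, 70, 1.3, "subtract")

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            metabolic_cost(np.ones((100, 1)), 1.0, 70, 1.3, "ignore")

    def test_nonpositive_scalars_rejected(self):
        with pytest.raises(ValueError):
            metabolic_cost(np.ones((100, 1)), 0.0, 70, 1.3)


class TestJointBreakdown:
    def test_monoarticular_assigns_fully(self, muscle_map):
        rates = np.full((100, 1), 10.0)
        out = joint_breakdown(rates, [muscle_map["soleus"]], 1.0, 70, 1.3)
        assert out["ankle"] > 0
        assert out["hip"] == 0 and out["knee"] == 0

    def test_biarticular_moment_arm_ratio(self, muscle_map):
        from dataclasses import replace

        gastroc = replace(muscle_map["gastrocnemius"],
                          moment_arms={"knee": -0.02, "ankle": 0.04})
        rates = np.full((100, 1), 9.0)
        out = joint_breakdown(rates, [gastroc], 1.0, 70, 1.3)
        total = out["knee"] + out["ankle"]
        assert out["knee"] == pytest.approx(total / 3.0)
        assert out["ankle"] == pytest.approx(2.0 * total / 3.0)

    def test_sum_over_joints_equals_total(self, muscles):
        rng = np.random.default_rng(2)
        rates = rng.uniform(-2, 10, size=(100, len(muscles)))
        out = joint_breakdown(rates, muscles, 1.1, 70, 1.3)
        total = metabolic_cost(rates, 1.1, 70, 1.3)
        assert sum(out.values()) == pytest.approx(total, rel=1e-12)

    def test_zero_moment_arms_rejected(self, muscle_map):
        from dataclasses import replace

        with pytest.raises(ValueError):
            bad = replace(muscle_map["soleus"], moment_arms={"ankle": 1e-12})
            object.__setattr__(bad, "moment_arms", {})
            joint_breakdown(np.ones((100, 1)), [bad], 1.0, 70, 1.3)


class TestVerificationGrid:
    @pytest.fixture(scope="class")
    def grids(self, soleus):
        return {m: verification_grid(m, soleus) for m in MUSCLE_MODELS}

    def test_shape_and_cells(self, grids):
        for tab in grids.values():
            assert len(tab) == 15
            assert set(tab.activation.unique()) == set(GRID_ACTIVATIONS)

    def test_marg68_isometric_column_is_zero(self, grids):
        iso = grids["MARG68"].query("condition == 'isometric'")
        assert np.allclose(iso.E, 0.0)

    def test_marg68_shortening_dominates_at_full_activation(self, grids):
        def cell(model, cond):
            t = grids[model]
            return float(t[(t.condition == cond) & (t.activation == 1.0)].E.iloc[0])

        marg = cell("MARG68", "shortening")
        for model in MUSCLE_MODELS:
            if model != "MARG68":
                assert marg > 2.0 * cell(model, "shortening")

    def test_lengthening_signs(self, grids):
        def cell(model):
            t = grids[model]
            return float(t[(t.condition == "lengthening")
                           & (t.activation == 1.0)].E.iloc[0])

        assert cell("MARG68") > 0 and cell("MINE97") > 0
        for model in HEAT_MODELS:
            assert cell(model) < 0
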