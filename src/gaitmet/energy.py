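"""Metabolic energy-expenditure models and the cost-of-transport integral.

Seven models estimate the whole-body metabolic cost of walking, C_calc in
J/kg/m.  Six operate per muscle from Hill-model states:

* ``MARG68`` -- pure efficiency model: muscles are 25% efficient when
  shortening and 120% efficient when lengthening, so the rate is always
  nonnegative and zero in isometric conditions.
* ``MINE97`` -- empirical rational function phi of the normalized
  contractile-element velocity: E = a * F_max * v_CE_max * phi(vbar).
* ``BHAR04``, ``HOUD06``, ``UMBE03``, ``LICH05`` -- heat-rate models that
  decompose the rate as E = w_dot + h_a + h_m + h_sl (fiber work rate plus
  activation, maintenance and shortening/lengthening heat rates).

``KIMR15`` works at the joint level from moments and angular velocities.

The cost integral divides the cycle-integrated summed rates by duration,
body mass and speed.  Negative instantaneous rates (possible for the four
heat-rate models during lengthening) are either subtracted (default) or
clamped to zero before integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from gaitmet.muscle import (
    JOINTS,
    MuscleParams,
    MuscleState,
    SPECIFIC_TENSION,
    force_length,
)

MUSCLE_MODELS = ("BHAR04", "HOUD06", "UMBE03", "LICH05", "MINE97", "MARG68")
HEAT_MODELS = ("BHAR04", "HOUD06", "UMBE03", "LICH05")
ALL_MODELS = MUSCLE_MODELS + ("KIMR15",)


def load_energy_constants(path=None) -> dict:
    """Load the per-model constant tables (shipped YAML by default)."""
    if path is None:
        ref = resources.files("gaitmet.data").joinpath("energy_constants.yaml")
        with ref.open() as fh:
            return yaml.safe_load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)


_CONSTANTS = None


def _constants(model: str) -> dict:
    global _CONSTANTS
    if _CONSTANTS is None:
        _CONSTANTS = load_energy_constants()
    return _CONSTANTS[model]


@dataclass
class EnergyRateSample:
    """Energy rate of one muscle (or joint), with heat components in W.

    For the four heat-rate models the components satisfy
    ``E = w_dot + h_a + h_m + h_sl`` exactly.
    """

    model: str
    E: np.ndarray | float
    w_dot: np.ndarray | float = 0.0
    h_a: np.ndarray | float = 0.0
    h_m: np.ndarray | float = 0.0
    h_sl: np.ndarray | float = 0.0


@dataclass
class EnergyResult:
    """Metabolic cost of one trial under one model, with joint breakdown."""

    model: str
    C_calc: float
    per_joint: Mapping[str, float]
    options: Mapping[str, object] = field(default_factory=dict)


# ----------------------------------------------------------------------
# individual models
# ----------------------------------------------------------------------


def rate_marg68(w_dot, v_ce):
    """Efficiency-based rate: w/0.25 when shortening, -w/1.2 when lengthening.

    ``v_ce`` is lengthening-positive; ``w_dot = -F_CE*v_CE`` so shortening
    means positive work rate.  The result is nonnegative and exactly zero
    for isometric states.
    """
    c = _constants("MARG68")
    w = np.asarray(w_dot, float)
    v = np.asarray(v_ce, float)
    out = np.where(v < 0.0, w / c["eff_shortening"], -w / c["eff_lengthening"])
    return np.where(v == 0.0, 0.0, out)


def mine97_phi(vbar):
    """Empirical velocity function of MINE97 (vbar shortening-positive)."""
    c = _constants("MINE97")
    v = np.asarray(vbar, float)
    n0, n1, n2 = c["num"]
    d0, d1, d2, d3 = c["den"]
    num = n0 + n1 * v + n2 * v**2
    den = d0 + d1 * v + d2 * v**2 + d3 * v**3
    if np.any(den <= 0):
        raise ValueError("MINE97 velocity function outside validity domain")
    return num / den


def rate_mine97(a, params: MuscleParams, v_ce):
    """E = a * F_max * v_CE_max * phi(vbar), linear in activation.

    ``v_ce`` is lengthening-positive (m/s) and is internally negated to the
    shortening-positive normalized velocity of the original formulation;
    values beyond one optimal length per maximum-velocity are clamped.
    """
    v_max_abs = params.v_CE_max * params.l_CE_opt
    vbar = np.clip(-np.asarray(v_ce, float) / v_max_abs, -1.0, 1.0)
    return np.asarray(a, float) * params.F_max * v_max_abs * mine97_phi(vbar)


def rate_kim15(M, q_dot, cycle_maxima: Mapping[str, float], cocontraction=0.0):
    """Joint-level rate: E = h + p with p = M * q_dot.

    ``q_dot`` must be the angular velocity in the convention in which
    ``M * q_dot`` is joint power.  ``cycle_maxima`` provides the maxima over
    the whole gait cycle: ``q_dot_max`` (rad/s) and ``positive_power_max``
    (W).  The heat rate uses the activation/maintenance coefficient on
    |M|, the power-sign-dependent shortening-lengthening coefficient on
    |M*q_dot|, and the cocontraction rate on the cycle's peak power.
    """
    for key in ("q_dot_max", "positive_power_max"):
        if key not in cycle_maxima:
            raise ValueError(f"cycle_maxima missing {key!r}")
    c = _constants("KIMR15")
    M = np.asarray(M, float)
    q_dot = np.asarray(q_dot, float)
    p = M * q_dot
    h_sl_coeff = np.where(p >= 0.0, c["h_SL_pos"], c["h_SL_neg"])
    h = (
        c["h_M"] * cycle_maxima["q_dot_max"] * np.abs(M)
        + h_sl_coeff * np.abs(p)
        + cocontraction * cycle_maxima["positive_power_max"]
    )
    return h + p


def _umberger_A(u, a):
    """Effective activation driving the heat rates (stimulation-weighted)."""
    u = np.asarray(u, float)
    a = np.asarray(a, float)
    return np.where(u > a, u, (u + a) / 2.0)


def rate_heat_model(
    model: str,
    state: MuscleState,
    u,
    stim_time: float,
    params: MuscleParams,
    specific_tension: float = SPECIFIC_TENSION,
    updated_lengthening: bool = True,
) -> EnergyRateSample:
    """Energy rate of one of the four heat-rate models (Eq. E = w+ha+hm+hsl).

    ``stim_time`` (s) is consumed by BHAR04 (activation-heat decay) and
    LICH05 (labile maintenance-heat decay).  ``updated_lengthening``
    selects the updated lengthening-heat coefficient of UMBE03.
    """
    if model not in HEAT_MODELS:
        raise ValueError(f"unknown heat-rate model {model!r}")
    c = _constants(model)
    mass = params.mass(specific_tension)
    ft = params.fast_twitch_fraction
    a = np.asarray(state.a, float)
    u = np.asarray(u, float)
    l_ce = np.asarray(state.l_CE, float)
    v_ce = np.asarray(state.v_CE, float)
    f_ce = np.asarray(state.F_CE, float)
    f_iso = force_length(l_ce, params)
    v_short = np.maximum(-v_ce, 0.0)   # shortening speed, m/s
    v_len = np.maximum(v_ce, 0.0)      # lengthening speed, m/s
    w_dot = -f_ce * v_ce
    zeros = np.zeros_like(a * v_ce)

    if model == "BHAR04":
        phi = c["phi_inf"] + np.exp(-stim_time / c["tau_phi"])
        h_a = mass * phi * u * ((1 - ft) * c["act_slow"] + ft * c["act_fast"])
        h_m = mass * f_iso * a * ((1 - ft) * c["maint_slow"] + ft * c["maint_fast"])
        alpha_s = c["short_iso"] * a * params.F_max * f_iso + c["short_ce"] * f_ce
        h_sl = alpha_s * v_short + c["lengthen_ce"] * f_ce * v_len
    elif model == "UMBE03":
        S = c["aerobic_scale"]
        A = _umberger_A(u, a)
        vbar_max = params.v_CE_max
        alpha_st = c["alpha_st_numer"] / (vbar_max / c["vmax_st_ratio"])
        alpha_ft = c["alpha_ft_numer"] / vbar_max
        coeff = c["alpha_len_updated"] if updated_lengthening else c["alpha_len_orig"]
        alpha_len = coeff * alpha_st
        length_fac = np.where(l_ce > params.l_CE_opt, 0.4 + 0.6 * f_iso, 1.0)
        short_fac = np.where(l_ce > params.l_CE_opt, f_iso, 1.0)
        h_am = (c["am_fast"] * ft + c["am_base"]) * A ** c["act_exp_am"] * length_fac
        vbar_s = v_short / params.l_CE_opt   # l_opt per second
        vbar_l = v_len / params.l_CE_opt
        h_short = (alpha_st * (1 - ft) + alpha_ft * ft) * vbar_s \
            * A ** c["act_exp_short"] * short_fac
        h_long = alpha_len * vbar_l * A
        h_a = zeros + S * mass * h_am      # activation+maintenance reported jointly
        h_m = zeros
        h_sl = S * mass * (h_short + h_long)
    elif model == "HOUD06":
        h_a = mass * c["act_coeff"] * a + zeros
        h_m = mass * c["maint_coeff"] * a * f_iso + zeros
        h_sl = c["short_ce"] * f_ce * v_short
    else:  # LICH05
        v_max_abs = params.v_CE_max * params.l_CE_opt
        maint = c["maint_sustained"] + c["maint_labile"] * np.exp(
            -stim_time / c["tau_labile"]
        )
        h_m = a * params.F_max * v_max_abs * maint + zeros
        h_a = zeros
        h_sl = (
            c["short_coeff"] * a * f_iso * params.F_max * v_short
            + c["lengthen_coeff"] * a * f_iso * params.F_max * v_len
        )

    E = w_dot + h_a + h_m + h_sl
    return EnergyRateSample(model=model, E=E, w_dot=w_dot, h_a=h_a, h_m=h_m, h_sl=h_sl)


# ----------------------------------------------------------------------
# cost integral and joint breakdown
# ----------------------------------------------------------------------


def metabolic_cost(rates, T, m, v, negative_work: str = "subtract"):
    """Cost of transport C = (1 / T m v) * integral of summed rates (J/kg/m).

    ``rates`` has shape (n_nodes, n_entities): the instantaneous energy
    rates (W) of each muscle (or joint) at the collocation nodes of one
    gait cycle.  The integral uses the Backward-Euler-consistent rectangle
    rule.  ``negative_work='clamp_zero'`` floors each entity's rate at zero
    before integrating (the no-negative-work variant); ``'subtract'`` keeps
    negative rates.
    """
    if T <= 0 or m <= 0 or v <= 0:
        raise ValueError("T, m and v must be positive")
    rates = np.atleast_2d(np.asarray(rates, float))
    if negative_work == "clamp_zero":
        rates = np.maximum(rates, 0.0)
    elif negative_work != "subtract":
        raise ValueError(f"unknown negative_work mode {negative_work!r}")
    return float(rates.sum(axis=1).mean() / (m * v))


def joint_breakdown(rates, muscles: list[MuscleParams], T, m, v,
                    negative_work: str = "subtract") -> dict[str, float]:
    """Split the per-muscle cost over hip, knee and ankle (J/kg/m).

    Monoarticular muscles assign fully to their joint; biarticular muscles
    are split by the ratio of the magnitudes of their moment arms.  The
    joint costs sum to the total C_calc computed from the same rates.
    """
    rates = np.atleast_2d(np.asarray(rates, float))
    out = {j: 0.0 for j in JOINTS}
    for i, mus in enumerate(muscles):
        arms = np.array([abs(mus.moment_arms.get(j, 0.0)) for j in JOINTS])
        total = arms.sum()
        if total == 0:
            raise ValueError(f"{mus.name}: all moment arms are zero")
        c_i = metabolic_cost(rates[:, [i]], T, m, v, negative_work)
        for j, w in zip(JOINTS, arms / total):
            out[j] += w * c_i
    return out


# ----------------------------------------------------------------------
# rates over a solved gait cycle
# ----------------------------------------------------------------------


def stimulation_time(u: np.ndarray, T: float, threshold: float = 0.05) -> float:
    """Stimulation duration per cycle: time with stimulation above threshold."""
    frac = float(np.mean(np.asarray(u, float) > threshold))
    return max(frac * T, 0.05)


def trajectory_rates(model: str, traj, cycle=None,
                     specific_tension: float = SPECIFIC_TENSION,
                     updated_lengthening: bool = True,
                     cocontraction: float = 0.0) -> np.ndarray:
    """Instantaneous energy rates (W) at the 100 nodes of a solved cycle.

    For the six muscle-level models ``traj`` is a
    :class:`~gaitmet.estimation.MuscleStateTrajectory` and the result has
    one column per muscle.  For KIMR15 the ``cycle``
    (:class:`~gaitmet.inverse_dynamics.CycleTrajectory`) supplies joint
    moments and angular velocities and the result has one column per
    joint.  Rates are for one leg; a symmetric gait doubles them.
    """
    if model == "KIMR15":
        if cycle is None:
            raise ValueError("KIMR15 requires the cycle trajectory")
        n = cycle.joint_angles.shape[0]
        h = cycle.duration / n
        q = -cycle.joint_angles           # extension/plantarflexion positive
        q_dot = (q - np.roll(q, 1, axis=0)) / h
        M = cycle.joint_moments
        p = M * q_dot
        out = np.empty_like(M)
        for j in range(M.shape[1]):
            maxima = {"q_dot_max": float(np.abs(q_dot[:, j]).max()),
                      "positive_power_max": float(np.maximum(p[:, j], 0.0).max())}
            out[:, j] = rate_kim15(M[:, j], q_dot[:, j], maxima, cocontraction)
        return out

    n = traj.a.shape[0]
    T = traj.h * n
    out = np.empty((n, len(traj.muscles)))
    for i, mus in enumerate(traj.muscles):
        state = traj.state(i)
        if model in HEAT_MODELS:
            t_stim = stimulation_time(traj.u[:, i], T)
            out[:, i] = rate_heat_model(
                model, state, traj.u[:, i], t_stim, mus,
                specific_tension=specific_tension,
                updated_lengthening=updated_lengthening).E
        elif model == "MINE97":
            out[:, i] = rate_mine97(state.a, mus, state.v_CE)
        elif model == "MARG68":
            out[:, i] = rate_marg68(state.w_dot, state.v_CE)
        else:
            raise ValueError(f"unknown model {model!r}")
    return out


# ----------------------------------------------------------------------
# soleus verification grid
# ----------------------------------------------------------------------

GRID_ACTIVATIONS = (0.05, 0.25, 0.5, 0.75, 1.0)
GRID_CONDITIONS = ("shortening", "isometric", "lengthening")


def muscle_rate(model: str, state: MuscleState, u, stim_time: float,
                params: MuscleParams, **kwargs):
    """Energy rate (W) of any muscle-level model for a given state."""
    if model in HEAT_MODELS:
        return rate_heat_model(model, state, u, stim_time, params, **kwargs).E
    if model == "MINE97":
        return rate_mine97(state.a, params, state.v_CE)
    if model == "MARG68":
        return rate_marg68(state.w_dot, state.v_CE)
    raise ValueError(f"unknown muscle-level model {model!r}")


def verification_grid(model: str, params: MuscleParams):
    """15-cell table of E (W): 3 velocities x 5 activation levels.

    Conditions are shortening at 1 l_CE_opt/s, isometric, and lengthening
    at 1 l_CE_opt/s, with the contractile element at its optimal length,
    stimulation equal to activation, and stimulation time 1 s.
    """
    import pandas as pd

    from gaitmet.muscle import contractile_force

    rows = []
    for cond in GRID_CONDITIONS:
        v_ce = {"shortening": -1.0, "isometric": 0.0, "lengthening": 1.0}[cond]
        v_ce *= params.l_CE_opt
        for a in GRID_ACTIVATIONS:
            f_ce = contractile_force(a, params.l_CE_opt, v_ce, params)
            state = MuscleState(a=a, u=a, l_CE=params.l_CE_opt, v_CE=v_ce,
                                F_CE=f_ce, F_SEE=f_ce, F_PEE=0.0)
            E = float(muscle_rate(model, state, a, 1.0, params))
            rows.append({"model": model, "condition": cond,
                         "activation": a, "E": E})
    return pd.DataFrame(rows)
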