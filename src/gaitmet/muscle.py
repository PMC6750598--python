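"""Three-element Hill-type muscle model with quadratic elastic elements.

Each muscle is a contractile element (CE) in series with a quadratic series
elastic element (SEE), with a quadratic parallel elastic element (PEE)
across the CE.  The CE has first-order activation dynamics, a Gaussian
force-length relationship and a Hill-hyperbolic force-velocity relationship.

Sign conventions
----------------
* ``v_CE`` is positive when the fiber **lengthens** (eccentric) and negative
  when it shortens.  Fiber mechanical power is ``w_dot = -F_CE * v_CE``,
  positive during shortening.
* Joint moments and the generalized joint angles used for musculotendon
  length follow the hip/knee-extension-positive, ankle-plantarflexion-
  positive convention.  The musculotendon length is affine in the joint
  angles with constant moment arms ``d``:  ``l_MT = l_MT_ref - sum_j d_j q_j``,
  and the muscle contributes ``d_j * F_SEE`` to the net moment at joint j.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

JOINTS = ("hip", "knee", "ankle")

#: Muscle groups of the sagittal-plane lower-extremity model, one leg.
MUSCLE_NAMES = (
    "iliopsoas",
    "glutei",
    "hamstrings",
    "rectus_femoris",
    "vasti",
    "gastrocnemius",
    "soleus",
    "tibialis_anterior",
)

BIARTICULAR = {"hamstrings", "rectus_femoris", "gastrocnemius"}

#: Muscle density in kg/m^3, used to derive muscle mass from F_max and
#: optimal fiber length via the specific tension sigma.
MUSCLE_DENSITY = 1059.7

#: Default specific tension (Pa), the classic 33 N/cm^2.  Doubling it halves
#: the muscle mass used by the mass-specific heat-rate models (a
#: sensitivity case).
SPECIFIC_TENSION = 0.33e6


@dataclass(frozen=True)
class MuscleParams:
    """Parameters of one Hill-type muscle group.

    Lengths in m, forces in N, times in s; ``v_CE_max`` in optimal fiber
    lengths per second.  ``moment_arms`` maps joint name -> constant moment
    arm (m), signed so a positive product ``d * F`` is an extension moment
    at hip/knee and a plantarflexion moment at the ankle.
    """

    name: str
    F_max: float
    l_CE_opt: float
    width: float
    v_CE_max: float
    T_act: float
    T_deact: float
    tendon_slack_length: float
    pee_slack_length: float
    k_SEE: float
    k_PEE: float
    moment_arms: Mapping[str, float]
    fast_twitch_fraction: float
    l_MT_ref: float = 0.0
    a_f: float = 0.25        # Hill force-velocity curvature
    g_max: float = 1.5       # eccentric force plateau
    damping: float = 0.01    # CE parallel damping, fraction of F_max per v_max

    def __post_init__(self) -> None:
        if self.F_max <= 0:
            raise ValueError(f"{self.name}: F_max must be positive")
        if self.l_CE_opt <= 0 or self.v_CE_max <= 0:
            raise ValueError(f"{self.name}: lengths/velocities must be positive")
        if self.T_act > self.T_deact:
            raise ValueError(f"{self.name}: requires T_act <= T_deact")
        if not 0.0 <= self.fast_twitch_fraction <= 1.0:
            raise ValueError(f"{self.name}: fast_twitch_fraction outside [0, 1]")
        arms = {j: d for j, d in self.moment_arms.items() if d != 0.0}
        unknown = set(arms) - set(JOINTS)
        if unknown:
            raise ValueError(f"{self.name}: unknown joints {unknown}")
        if self.name in BIARTICULAR and len(arms) != 2:
            raise ValueError(f"{self.name}: biarticular muscle must span 2 joints")
        if self.l_MT_ref == 0.0:
            # neutral standing pose (all generalized angles zero): CE at its
            # optimal length with the tendon just slack
            object.__setattr__(
                self, "l_MT_ref", self.tendon_slack_length + self.l_CE_opt
            )

    @property
    def spanned_joints(self) -> tuple[str, ...]:
        return tuple(j for j in JOINTS if self.moment_arms.get(j, 0.0) != 0.0)

    def mass(self, specific_tension: float = SPECIFIC_TENSION) -> float:
        """Muscle mass in kg: F_max * l_CE_opt * rho / sigma."""
        return self.F_max * self.l_CE_opt * MUSCLE_DENSITY / specific_tension

    # -- musculotendon geometry ------------------------------------------

    def musculotendon_length(self, q: Mapping[str, float] | np.ndarray):
        """l_MT from generalized joint angles (extension/plantarflexion +).

        ``q`` is either a mapping joint -> angle (rad) or an array of shape
        (..., 3) ordered as :data:`JOINTS`.
        """
        if isinstance(q, Mapping):
            dq = sum(self.moment_arms.get(j, 0.0) * q.get(j, 0.0) for j in JOINTS)
        else:
            q = np.asarray(q, float)
            d = np.array([self.moment_arms.get(j, 0.0) for j in JOINTS])
            dq = q @ d
        return self.l_MT_ref - dq


@dataclass
class MuscleState:
    """Instantaneous (or trajectory of) muscle state variables."""

    a: np.ndarray | float
    u: np.ndarray | float
    l_CE: np.ndarray | float
    v_CE: np.ndarray | float
    F_CE: np.ndarray | float = 0.0
    F_SEE: np.ndarray | float = 0.0
    F_PEE: np.ndarray | float = 0.0

    @property
    def w_dot(self):
        """Fiber mechanical power (W), positive when shortening."""
        return -np.asarray(self.F_CE) * np.asarray(self.v_CE)


# -- elementary relations ------------------------------------------------


def elastic_force(length, slack, k):
    """Quadratic spring: zero below slack length, k*(length-slack)^2 above."""
    if k < 0:
        raise ValueError("stiffness must be nonnegative")
    stretch = np.maximum(np.asarray(length, float) - slack, 0.0)
    return k * stretch**2


def elastic_force_derivative(length, slack, k):
    stretch = np.maximum(np.asarray(length, float) - slack, 0.0)
    return 2.0 * k * stretch


def force_length(l_ce, params: MuscleParams):
    """Gaussian active force-length curve, maximal (=1) at l_CE_opt."""
    x = (np.asarray(l_ce, float) / params.l_CE_opt - 1.0) / params.width
    return np.exp(-(x**2))


def force_length_derivative(l_ce, params: MuscleParams):
    x = (np.asarray(l_ce, float) / params.l_CE_opt - 1.0) / params.width
    return np.exp(-(x**2)) * (-2.0 * x) / (params.width * params.l_CE_opt)


_V_LIN = -0.95  # below this normalized velocity the Hill curve is linearized
_V_BLEND = 0.02  # half-width of the C2 bridge between the two branches


def _fv_kernel(vbar, af, gmax):
    """Hill force-velocity factor and first two derivatives (normalized).

    Classic Hill hyperbola when shortening, saturating hyperbola
    (plateau ``gmax``) when lengthening.  A quintic Hermite bridge on
    |vbar| < 0.05 joins the branches with continuous curvature, and below
    the maximum shortening velocity the curve continues linearly; the
    result is C2 except at the (rarely visited) linearization point,
    monotone increasing, and bounded by the eccentric plateau.
    """
    vbar = np.asarray(vbar, float)
    c = (gmax - 1.0) * af / (1.0 + af)   # matches concentric slope at v=0
    vb = np.clip(vbar, _V_LIN, None)
    con = (1.0 + vb) / (1.0 - vb / af)
    dcon = (1.0 + 1.0 / af) / (1.0 - vb / af) ** 2
    d2con = 2.0 * (1.0 + 1.0 / af) / (af * (1.0 - vb / af) ** 3)
    ecc = (gmax * vb + c) / (vb + c)
    decc = c * (gmax - 1.0) / (vb + c) ** 2
    d2ecc = -2.0 * c * (gmax - 1.0) / (vb + c) ** 3

    f = np.where(vb < 0.0, con, ecc)
    df = np.where(vb < 0.0, dcon, decc)
    d2f = np.where(vb < 0.0, d2con, d2ecc)

    # quintic Hermite bridge on [-delta, delta]
    d = _V_BLEND
    if np.isscalar(af):
        afl = af
        gml = gmax
    else:
        afl, gml = af, gmax
    cl = c
    fm = (1.0 - d) / (1.0 + d / afl)
    dm = (1.0 + 1.0 / afl) / (1.0 + d / afl) ** 2
    d2m = 2.0 * (1.0 + 1.0 / afl) / (afl * (1.0 + d / afl) ** 3)
    fp = (gml * d + cl) / (d + cl)
    dp = cl * (gml - 1.0) / (d + cl) ** 2
    d2p = -2.0 * cl * (gml - 1.0) / (d + cl) ** 3
    t = (vb + d) / (2.0 * d)
    # quintic Hermite basis on t in [0, 1] with step 2d
    hstep = 2.0 * d
    t2, t3, t4, t5 = t**2, t**3, t**4, t**5
    H0 = 1 - 10 * t3 + 15 * t4 - 6 * t5
    H1 = t - 6 * t3 + 8 * t4 - 3 * t5
    H2 = 0.5 * t2 - 1.5 * t3 + 1.5 * t4 - 0.5 * t5
    H3 = 0.5 * t3 - t4 + 0.5 * t5
    H4 = -4 * t3 + 7 * t4 - 3 * t5
    H5 = 10 * t3 - 15 * t4 + 6 * t5
    bridge = (fm * H0 + dm * hstep * H1 + d2m * hstep**2 * H2
              + d2p * hstep**2 * H3 + dp * hstep * H4 + fp * H5)
    dH0 = -30 * t2 + 60 * t3 - 30 * t4
    dH1 = 1 - 18 * t2 + 32 * t3 - 15 * t4
    dH2 = t - 4.5 * t2 + 6 * t3 - 2.5 * t4
    dH3 = 1.5 * t2 - 4 * t3 + 2.5 * t4
    dH4 = -12 * t2 + 28 * t3 - 15 * t4
    dH5 = 30 * t2 - 60 * t3 + 30 * t4
    dbridge = (fm * dH0 + dm * hstep * dH1 + d2m * hstep**2 * dH2
               + d2p * hstep**2 * dH3 + dp * hstep * dH4 + fp * dH5) / hstep
    d2H0 = -60 * t + 180 * t2 - 120 * t3
    d2H1 = -36 * t + 96 * t2 - 60 * t3
    d2H2 = 1 - 9 * t + 18 * t2 - 10 * t3
    d2H3 = 3 * t - 12 * t2 + 10 * t3
    d2H4 = -24 * t + 84 * t2 - 60 * t3
    d2H5 = 60 * t - 180 * t2 + 120 * t3
    d2bridge = (fm * d2H0 + dm * hstep * d2H1 + d2m * hstep**2 * d2H2
                + d2p * hstep**2 * d2H3 + dp * hstep * d2H4
                + fp * d2H5) / hstep**2
    inb = np.abs(vb) < d
    f = np.where(inb, bridge, f)
    df = np.where(inb, dbridge, df)
    d2f = np.where(inb, d2bridge, d2f)

    # linear continuation below the maximum shortening velocity
    f0 = (1.0 + _V_LIN) / (1.0 - _V_LIN / af)
    s0 = (1.0 + 1.0 / af) / (1.0 - _V_LIN / af) ** 2
    below = vbar < _V_LIN
    f = np.where(below, f0 + s0 * (vbar - _V_LIN), f)
    df = np.where(below, s0, df)
    d2f = np.where(below, 0.0, d2f)
    return f, df, d2f


def force_velocity(v_ce, params: MuscleParams):
    """Hill force-velocity factor; ``v_ce`` in m/s, lengthening positive.

    See :func:`_fv_kernel` for the functional form (C2-smooth, monotone,
    bounded by the eccentric plateau ``g_max``).
    """
    vbar = np.asarray(v_ce, float) / (params.v_CE_max * params.l_CE_opt)
    f, _, _ = _fv_kernel(vbar, params.a_f, params.g_max)
    return f


def force_velocity_derivative(v_ce, params: MuscleParams):
    scale = params.v_CE_max * params.l_CE_opt
    _, df, _ = _fv_kernel(np.asarray(v_ce, float) / scale, params.a_f,
                          params.g_max)
    return df / scale


def contractile_force(a, l_ce, v_ce, params: MuscleParams):
    """F_CE = a F_max f_L f_V + small parallel damping.

    The damping term (default 1% of F_max at the maximum contraction
    velocity) regularizes the contractile element: without it the fiber
    length is force-indeterminate whenever activation and both elastic
    elements are slack, which stalls implicit integrators and the
    collocation solver alike.
    """
    v_ce = np.asarray(v_ce, float)
    active = (
        np.asarray(a, float)
        * params.F_max
        * force_length(l_ce, params)
        * force_velocity(v_ce, params)
    )
    damp = params.damping * params.F_max * v_ce / (params.v_CE_max * params.l_CE_opt)
    return active + damp


def see_length(l_mt, l_ce):
    return np.asarray(l_mt, float) - np.asarray(l_ce, float)


def contraction_residual(state: MuscleState, l_mt, params: MuscleParams):
    """Force balance F_SEE - F_PEE - F_CE of the three-element muscle (N)."""
    arrs = [np.asarray(x, float) for x in (state.a, state.l_CE, state.v_CE, l_mt)]
    if not all(np.all(np.isfinite(x)) for x in arrs):
        raise ValueError("non-finite muscle state")
    f_see = elastic_force(see_length(l_mt, state.l_CE), params.tendon_slack_length,
                          params.k_SEE)
    f_pee = elastic_force(state.l_CE, params.pee_slack_length, params.k_PEE)
    f_ce = contractile_force(state.a, state.l_CE, state.v_CE, params)
    return f_see - f_pee - f_ce


def activation_rate(a, u, params: MuscleParams):
    """First-order activation dynamics rate (1/s).

    da/dt = (u - a) * (u / T_act + (1 - u) / T_deact): activation is driven
    toward the stimulation with a rate constant that blends the activation
    and deactivation time constants by the stimulation level.
    """
    a = np.asarray(a, float)
    u = np.asarray(u, float)
    return (u - a) * (u / params.T_act + (1.0 - u) / params.T_deact)


def passive_equilibrium(l_mt: float, params: MuscleParams) -> float:
    """Contractile-element length at passive rest (a=0, v=0) for given l_MT.

    Unique when either elastic element is engaged; inside the doubly-slack
    configuration any fiber length in the force-free interval is an
    equilibrium and the interval midpoint is returned.
    """
    lo, hi = 1e-6, l_mt - 1e-6

    def balance(l_ce):
        f_see = elastic_force(l_mt - l_ce, params.tendon_slack_length, params.k_SEE)
        f_pee = elastic_force(l_ce, params.pee_slack_length, params.k_PEE)
        return f_see - f_pee

    if l_mt <= params.tendon_slack_length + params.pee_slack_length:
        lo_free = max(l_mt - params.tendon_slack_length, lo)
        return float(0.5 * (lo_free + min(params.pee_slack_length, hi)))
    return float(brentq(balance, lo, hi, xtol=1e-12))


# -- forward simulation (oracle for the collocation solver) --------------


def _backward_euler_activation(a_prev, u, h, params):
    """Closed-form Backward Euler step of the activation dynamics."""
    rate_const = u / params.T_act + (1.0 - u) / params.T_deact
    return (a_prev + h * u * rate_const) / (1.0 + h * rate_const)


def forward_simulate(
    u_trajectory: np.ndarray,
    joint_angles: np.ndarray,
    params: MuscleParams,
    dt: float,
    n_cycles: int = 4,
) -> tuple[MuscleState, np.ndarray]:
    """Integrate one muscle's dynamics over a periodic input.

    ``u_trajectory`` (n,) and ``joint_angles`` (n, 3) describe one cycle
    sampled at ``dt`` (generalized angles, extension/plantarflexion
    positive).  The cycle is repeated ``n_cycles`` times from passive
    equilibrium so transients die out, and the final cycle is returned.

    Returns the :class:`MuscleState` trajectory (arrays of length n) and
    the muscle's joint-moment contribution D * F_SEE, shape (n, 3).
    """
    u_traj = np.asarray(u_trajectory, float)
    q = np.asarray(joint_angles, float)
    n = u_traj.shape[0]
    l_mt = params.musculotendon_length(q)

    a = float(u_traj[0])
    l_ce = passive_equilibrium(float(l_mt[0]), params)

    out_a = np.empty(n)
    out_u = np.empty(n)
    out_l = np.empty(n)
    out_v = np.empty(n)

    for cyc in range(n_cycles):
        for k in range(n):
            u_k = float(u_traj[k])
            a = _backward_euler_activation(a, u_k, dt, params)
            l_prev = l_ce

            def residual(l_new):
                st = MuscleState(a=a, u=u_k, l_CE=l_new, v_CE=(l_new - l_prev) / dt)
                return float(contraction_residual(st, float(l_mt[k]), params))

            lo = max(1e-4, l_prev - dt * params.v_CE_max * params.l_CE_opt)
            hi = l_prev + dt * 5.0 * params.v_CE_max * params.l_CE_opt
            r_lo, r_hi = residual(lo), residual(hi)
            if r_lo * r_hi > 0:
                raise RuntimeError(
                    f"implicit contraction step failed at node {k}: "
                    f"residual({lo:.4f})={r_lo:.3g}, residual({hi:.4f})={r_hi:.3g}"
                )
            l_ce = brentq(residual, lo, hi, xtol=1e-12)
            if cyc == n_cycles - 1:
                out_a[k] = a
                out_u[k] = u_k
                out_l[k] = l_ce
                out_v[k] = (l_ce - l_prev) / dt

    f_see = elastic_force(l_mt - out_l, params.tendon_slack_length, params.k_SEE)
    f_pee = elastic_force(out_l, params.pee_slack_length, params.k_PEE)
    f_ce = f_see - f_pee
    state = MuscleState(a=out_a, u=out_u, l_CE=out_l, v_CE=out_v,
                        F_CE=f_ce, F_SEE=f_see, F_PEE=f_pee)
    d = np.array([params.moment_arms.get(j, 0.0) for j in JOINTS])
    moments = f_see[:, None] * d[None, :]
    return state, moments


# -- parameter I/O -------------------------------------------------------


def load_muscles(path_or_stream) -> list[MuscleParams]:
    """Load and validate a YAML muscle-parameter file.

    One block per muscle; keys exactly as the :class:`MuscleParams` fields.
    """
    if hasattr(path_or_stream, "read"):
        raw = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            raw = yaml.safe_load(fh)
    muscles = []
    for name, block in raw.items():
        block = dict(block)
        # YAML 1.1 reads exponents without a signed power as strings
        block["moment_arms"] = {j: float(d)
                                for j, d in dict(block.get("moment_arms", {})).items()}
        for key, val in block.items():
            if key != "moment_arms":
                block[key] = float(val)
        muscles.append(MuscleParams(name=name, **block))
    return muscles


def default_muscles() -> list[MuscleParams]:
    """The shipped eight-muscle sagittal-plane parameter set (one leg)."""
    ref = resources.files("gaitmet.data").joinpath("muscles.yaml")
    with ref.open() as fh:
        return load_muscles(fh)
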