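"""Muscle-state estimation by direct collocation over one periodic cycle.

Given the averaged gait cycle (joint angles and Winter joint moments at
100 nodes) and a set of Hill-type muscles, the dynamic optimization finds
stimulations u(t), activations a(t) and contractile-element lengths
l_CE(t) that minimize the integral of summed squared activations subject
to, at every node,

* the contraction force balance  F_SEE - F_PEE - F_CE = 0,
* the activation dynamics        da/dt = (u-a)(u/T_act + (1-u)/T_deact),
* moment matching                D F_SEE = M_winter,

with Backward-Euler discretization (node 0 wraps to node 99, which makes
the trajectories periodic by construction) and bounds 0 <= u, a <= 1.

The transcribed nonlinear program is solved in stages: a sequential
node-by-node effort minimization (exact Backward-Euler dynamics steps)
provides an effort-lean warm start, and an augmented-Lagrangian scheme —
formulated in a tendon-force coordinate that removes the stiff
series-elastic spring constant from the constraint curvature, with
bound-constrained trust-region Gauss-Newton inner solves on analytic
sparse Jacobians — restores feasibility, followed by a final feasibility
polish.  Any solver meeting the tolerance contract (scaled constraint
violation below the requested tolerance) is acceptable; the
implementation below is deterministic and needs no external NLP library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gaitmet.inverse_dynamics import CycleTrajectory, JOINTS
from gaitmet.muscle import (
    MuscleParams,
    MuscleState,
    elastic_force,
    elastic_force_derivative,
    force_length,
    force_length_derivative,
    force_velocity,
    force_velocity_derivative,
)

OBJECTIVES = ("activation_squared", "activation_cubed", "volume_weighted_cubed")


class SolverFailure(RuntimeError):
    """Raised when the NLP does not reach the constraint tolerance."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class CollocationProblem:
    """Transcribed dynamic optimization problem.

    Unknowns per node: u, a, l_CE for each muscle (layout: three stacked
    (n_nodes, n_muscles) blocks).  Constraints per node: one contraction
    and one activation-dynamics residual per muscle plus one
    moment-matching residual per spanned joint; Backward Euler with the
    first node wrapping to the last enforces periodicity structurally.
    """

    muscles: list
    l_mt: np.ndarray          # (n, m) musculotendon lengths
    target_moments: np.ndarray  # (n, j) in the muscle moment convention
    joints: tuple             # joint names with at least one spanned muscle
    h: float                  # node spacing, T / n_nodes
    n_nodes: int = 100
    objective: str = "activation_squared"
    moment_scale: np.ndarray = field(default=None)
    #: half-width (m) of the C2 smoothing of the slack-spring kinks used
    #: inside the solver; the induced force bias k*eps^2/4 is far below
    #: the constraint tolerance
    eps: float = 1e-5

    def __post_init__(self):
        if self.moment_scale is None:
            self.moment_scale = np.maximum(
                np.abs(self.target_moments).max(axis=0), 20.0)
        self._d = np.array([[mus.moment_arms.get(j, 0.0) for j in self.joints]
                            for mus in self.muscles])  # (m, j)
        self._fmax = np.array([mus.F_max for mus in self.muscles])
        self._lopt = np.array([mus.l_CE_opt for mus in self.muscles])
        self._tact = np.array([mus.T_act for mus in self.muscles])
        self._tdeact = np.array([mus.T_deact for mus in self.muscles])
        self._bdamp = np.array([mus.damping * mus.F_max
                                / (mus.v_CE_max * mus.l_CE_opt)
                                for mus in self.muscles])
        self._width = np.array([mus.width for mus in self.muscles])
        self._af = np.array([mus.a_f for mus in self.muscles])
        self._gmax = np.array([mus.g_max for mus in self.muscles])
        self._vmax_abs = np.array([mus.v_CE_max * mus.l_CE_opt
                                   for mus in self.muscles])

    @property
    def n_muscles(self) -> int:
        return len(self.muscles)

    @property
    def n_unknowns(self) -> int:
        return 3 * self.n_nodes * self.n_muscles

    @property
    def n_constraints(self) -> int:
        return self.n_nodes * (2 * self.n_muscles + len(self.joints))

    # -- variable layout --------------------------------------------------
    # The solver works with u, a and the optimal-length-normalized fiber
    # length (l_CE / l_CE_opt), which keeps all unknowns O(1).

    def split(self, x):
        n, m = self.n_nodes, self.n_muscles
        u, a, lt = x.reshape(3, n, m)
        return u, a, lt * self._lopt

    def join(self, u, a, l):
        return np.stack([u, a, l / self._lopt]).ravel()

    def initial_guess(self):
        """a = u = 0.1, l_CE at passive equilibrium (deterministic)."""
        from gaitmet.muscle import passive_equilibrium

        n, m = self.n_nodes, self.n_muscles
        l = np.empty((n, m))
        for i, mus in enumerate(self.muscles):
            for k in range(n):
                l[k, i] = passive_equilibrium(float(self.l_mt[k, i]), mus)
        return self.join(np.full((n, m), 0.1), np.full((n, m), 0.1), l)

    def bounds(self):
        n, m = self.n_nodes, self.n_muscles
        lo = np.concatenate([np.zeros(2 * n * m),
                             np.full(n * m, 0.15)])
        hi = np.concatenate([np.ones(2 * n * m),
                             np.full(n * m, 1.8)])
        return np.stack([lo, hi], axis=1)

    # -- model quantities -------------------------------------------------

    def _spring(self, x, k):
        """C2-smoothed slack spring: value, d/dx and d2/dx2."""
        hyp = np.sqrt(x**2 + self.eps**2)
        sx = 0.5 * (x + hyp)
        dsx = 0.5 * (1.0 + x / hyp)
        d2sx = 0.5 * self.eps**2 / hyp**3
        f = k * sx**2
        df = 2.0 * k * sx * dsx
        d2f = 2.0 * k * (dsx**2 + sx * d2sx)
        return f, df, d2f

    def _forces(self, a, l):
        """Element forces and their partials at all nodes (vectorized)."""
        mus = self.muscles
        see_slack = np.array([m.tendon_slack_length for m in mus])
        pee_slack = np.array([m.pee_slack_length for m in mus])
        k_see = np.array([m.k_SEE for m in mus])
        k_pee = np.array([m.k_PEE for m in mus])
        f_see, dsee_dx, _ = self._spring(self.l_mt - l - see_slack, k_see)
        df_see_dl = -dsee_dx
        f_pee, df_pee_dl, _ = self._spring(l - pee_slack, k_pee)
        return f_see, df_see_dl, f_pee, df_pee_dl

    def _fl_fv(self, l, v, second: bool = False):
        from gaitmet.muscle import _fv_kernel

        x = (l / self._lopt - 1.0) / self._width
        fl = np.exp(-(x**2))
        dfl = fl * (-2.0 * x) / (self._width * self._lopt)
        fv, dfv_n, d2fv_n = _fv_kernel(v / self._vmax_abs, self._af, self._gmax)
        dfv = dfv_n / self._vmax_abs
        if not second:
            return fl, dfl, fv, dfv
        d2fl = fl * (4.0 * x**2 - 2.0) / (self._width * self._lopt) ** 2
        d2fv = d2fv_n / self._vmax_abs**2
        return fl, dfl, d2fl, fv, dfv, d2fv

    def constraints(self, x):
        """Scaled residual vector, length :attr:`n_constraints`."""
        u, a, l = self.split(x)
        h = self.h
        v = (l - np.roll(l, 1, axis=0)) / h
        f_see, _, f_pee, _ = self._forces(a, l)
        fl, _, fv, _ = self._fl_fv(l, v)
        f_ce = a * self._fmax * fl * fv + self._bdamp * v
        c_con = (f_see - f_pee - f_ce) / self._fmax
        rc = u / self._tact + (1.0 - u) / self._tdeact
        c_act = (a - np.roll(a, 1, axis=0)) - h * (u - a) * rc
        c_mom = (f_see @ self._d - self.target_moments) / self.moment_scale
        return np.concatenate([c_con.ravel(), c_act.ravel(), c_mom.ravel()])

    def objective_value_grad(self, x):
        u, a, l = self.split(x)
        n, m = self.n_nodes, self.n_muscles
        g = np.zeros((3, n, m))
        if self.objective == "activation_squared":
            f = self.h * float((a**2).sum())
            g[1] = 2.0 * self.h * a
        elif self.objective == "activation_cubed":
            f = self.h * float((a**3).sum())
            g[1] = 3.0 * self.h * a**2
        elif self.objective == "volume_weighted_cubed":
            w = self._fmax * self._lopt
            w = w / w.mean()
            f = self.h * float((w * a**3).sum())
            g[1] = 3.0 * self.h * w * a**2
        else:
            raise ValueError(f"unknown objective {self.objective!r}")
        return f, g.ravel()

    def lagrangian_value_grad(self, x, lam, mu):
        """phi = f + lam.c + mu/2 |c|^2 and its analytic gradient."""
        u, a, l = self.split(x)
        h = self.h
        v = (l - np.roll(l, 1, axis=0)) / h
        f_see, df_see_dl, f_pee, df_pee_dl = self._forces(a, l)
        fl, dfl, fv, dfv = self._fl_fv(l, v)
        f_ce = a * self._fmax * fl * fv + self._bdamp * v

        c_con = (f_see - f_pee - f_ce) / self._fmax
        rc = u / self._tact + (1.0 - u) / self._tdeact
        drc = 1.0 / self._tact - 1.0 / self._tdeact
        c_act = (a - np.roll(a, 1, axis=0)) - h * (u - a) * rc
        c_mom = (f_see @ self._d - self.target_moments) / self.moment_scale

        c = np.concatenate([c_con.ravel(), c_act.ravel(), c_mom.ravel()])
        y = lam + mu * c
        nm = self.n_nodes * self.n_muscles
        y1 = y[:nm].reshape(self.n_nodes, self.n_muscles)
        y2 = y[nm:2 * nm].reshape(self.n_nodes, self.n_muscles)
        y3 = y[2 * nm:].reshape(self.n_nodes, len(self.joints))

        f_obj, g = self.objective_value_grad(x)
        phi = f_obj + float(lam @ c) + 0.5 * mu * float(c @ c)
        g = g.reshape(3, self.n_nodes, self.n_muscles).copy()

        # contraction rows
        dc_da = -fl * fv * 1.0                       # * F_max / F_max
        dc_dl_local = (df_see_dl - df_pee_dl
                       - a * self._fmax * dfl * fv) / self._fmax \
            - (a * fl * dfv + self._bdamp / self._fmax) / h
        dc_dl_prev = (a * fl * dfv + self._bdamp / self._fmax) / h
        g[1] += y1 * dc_da
        g[2] += y1 * dc_dl_local + np.roll(y1 * dc_dl_prev, -1, axis=0)
        # activation rows
        g[1] += y2 * (1.0 + h * rc)
        g[1] -= np.roll(y2, -1, axis=0)
        g[0] += y2 * (-h) * (rc + (u - a) * drc)
        # moment rows
        g[2] += (y3 / self.moment_scale) @ self._d.T * df_see_dl

        g[2] *= self._lopt  # chain rule onto the normalized fiber length
        return phi, g.ravel(), c

    # -- tendon-force coordinate (internal solver space) ------------------
    # The stiff series elastic element makes the NLP badly conditioned in
    # fiber-length coordinates: the spring constant k_SEE enters the
    # constraint curvature directly.  Internally the solver therefore
    # replaces l_CE by a normalized tendon-force coordinate w with
    #   F_SEE = F_max * sigma(w)^2,  sigma = smooth-max(w, 0),
    #   l_CE  = l_MT - slack - sqrt(F_max/k_SEE) * sigma - kappa (sigma - w),
    # so that for w > 0 the tendon is taut with stretch sqrt(F_SEE/k_SEE)
    # and for w < 0 the fiber shortens into the slack gap with compliance
    # kappa.  All constraint curvatures are then O(1) in the scaled
    # variables.  The mapping is exact (the smooth sigma > 0 always maps
    # onto a taut-tendon stretch), so a solution found in w-space
    # satisfies the original fiber-length-space constraints.

    _w_eps = 1e-4

    @property
    def _w_geom(self):
        if not hasattr(self, "_w_geom_cache"):
            k_see = np.array([m.k_SEE for m in self.muscles])
            see_slack = np.array([m.tendon_slack_length for m in self.muscles])
            self._w_geom_cache = (np.sqrt(self._fmax / k_see), see_slack,
                                  0.5 * self._lopt)
        return self._w_geom_cache

    def _sigma(self, w):
        hyp = np.sqrt(w**2 + self._w_eps**2)
        s = 0.5 * (w + hyp)
        ds = 0.5 * (1.0 + w / hyp)
        d2s = 0.5 * self._w_eps**2 / hyp**3
        return s, ds, d2s

    def _l_of_w(self, w):
        """Fiber lengths and dl/dw, d2l/dw2 from the force coordinate."""
        sqrt_fk, see_slack, kappa = self._w_geom
        s, ds, d2s = self._sigma(w)
        l = self.l_mt - see_slack - sqrt_fk * s + kappa * (s - w)
        dl = (kappa - sqrt_fk) * ds - kappa
        d2l = (kappa - sqrt_fk) * d2s
        return l, dl, d2l, s, ds, d2s

    def w_from_x(self, x):
        """Convert external unknowns (u, a, l) to internal (u, a, w)."""
        sqrt_fk, see_slack, kappa = self._w_geom
        u, a, l = self.split(x)
        stretch = self.l_mt - see_slack - l
        w = np.where(stretch > 0.0, stretch / sqrt_fk, stretch / kappa)
        return np.stack([u, a, w]).ravel()

    def x_from_w(self, xw):
        n, m = self.n_nodes, self.n_muscles
        u, a, w = xw.reshape(3, n, m)
        l, _, _, _, _, _ = self._l_of_w(w)
        return self.join(np.clip(u, 0.0, 1.0), np.clip(a, 0.0, 1.0), l)

    def w_bounds(self):
        n, m = self.n_nodes, self.n_muscles
        lo = np.concatenate([np.zeros(2 * n * m), np.full(n * m, -1.6)])
        hi = np.concatenate([np.ones(2 * n * m), np.full(n * m, 1.35)])
        return lo, hi

    def _w_parts(self, xw):
        n, m = self.n_nodes, self.n_muscles
        u, a, w = xw.reshape(3, n, m)
        h = self.h
        l, dl, d2l, s, ds, d2s = self._l_of_w(w)
        l_prev = np.roll(l, 1, axis=0)
        dl_prev = np.roll(dl, 1, axis=0)
        d2l_prev = np.roll(d2l, 1, axis=0)
        v = (l - l_prev) / h
        k_pee = np.array([mm.k_PEE for mm in self.muscles])
        pee_slack = np.array([mm.pee_slack_length for mm in self.muscles])
        f_pee, dpee, d2pee = self._spring(l - pee_slack, k_pee)
        fl, dfl, d2fl, fv, dfv, d2fv = self._fl_fv(l, v, second=True)
        return (u, a, w, l, dl, d2l, dl_prev, d2l_prev, v, f_pee, dpee,
                d2pee, fl, dfl, d2fl, fv, dfv, d2fv, s, ds, d2s)

    def w_constraints(self, xw):
        (u, a, w, l, dl, d2l, dl_prev, d2l_prev, v, f_pee, dpee, d2pee,
         fl, dfl, d2fl, fv, dfv, d2fv, s, ds, d2s) = self._w_parts(xw)
        h = self.h
        f_see = self._fmax * s**2
        c_con = s**2 - (f_pee + a * self._fmax * fl * fv
                        + self._bdamp * v) / self._fmax
        rc = u / self._tact + (1.0 - u) / self._tdeact
        c_act = (a - np.roll(a, 1, axis=0)) - h * (u - a) * rc
        c_mom = (f_see @ self._d - self.target_moments) / self.moment_scale
        return np.concatenate([c_con.ravel(), c_act.ravel(), c_mom.ravel()])

    def w_jacobian(self, xw):
        from scipy import sparse

        n, m, nj = self.n_nodes, self.n_muscles, len(self.joints)
        nm = n * m
        (u, a, w, l, dl, d2l, dl_prev, d2l_prev, v, f_pee, dpee, d2pee,
         fl, dfl, d2fl, fv, dfv, d2fv, s, ds, d2s) = self._w_parts(xw)
        h = self.h
        rc = u / self._tact + (1.0 - u) / self._tdeact
        drc = 1.0 / self._tact - 1.0 / self._tdeact
        # G(l_k, l_prev, a) = -(F_PEE + a F fl fv + b v)/F
        G_l = -(dpee + a * self._fmax * (dfl * fv + fl * dfv / h)
                + self._bdamp / h) / self._fmax
        G_p = (a * self._fmax * fl * dfv + self._bdamp) / (h * self._fmax)
        data = [
            -fl * fv,                              # dc_con/da
            2.0 * s * ds + G_l * dl,               # dc_con/dw_k
            G_p * dl_prev,                         # dc_con/dw_prev
            (1.0 + h * rc),                        # dc_act/da_k
            np.full((n, m), -1.0),                 # dc_act/da_prev
            (-h) * (rc + (u - a) * drc),           # dc_act/du
        ]
        for i in range(m):
            for j in range(nj):
                if self._d[i, j] != 0.0:
                    data.append(self._d[i, j] * self._fmax[i]
                                * 2.0 * s[:, i] * ds[:, i]
                                / self.moment_scale[j])
        rows, cols = self._ls_pattern()
        ncon = self.n_constraints
        keep = rows < ncon  # drop the objective rows of the shared pattern
        data = np.concatenate([np.asarray(d).ravel() for d in data])
        return sparse.csr_matrix((data, (rows[:data.size], cols[:data.size])),
                                 shape=(ncon, self.n_unknowns))

    def w_constraint_hessian(self, xw, vlam):
        from scipy import sparse

        n, m, nj = self.n_nodes, self.n_muscles, len(self.joints)
        nm = n * m
        (u, a, w, l, dl, d2l, dl_prev, d2l_prev, v, f_pee, dpee, d2pee,
         fl, dfl, d2fl, fv, dfv, d2fv, s, ds, d2s) = self._w_parts(xw)
        h = self.h
        v1 = vlam[:nm].reshape(n, m)
        v2 = vlam[nm:2 * nm].reshape(n, m)
        v3 = vlam[2 * nm:].reshape(n, nj)
        fmax = self._fmax
        G_l = -(dpee + a * fmax * (dfl * fv + fl * dfv / h)
                + self._bdamp / h) / fmax
        G_ll = -(d2pee + a * fmax * (d2fl * fv + 2.0 * dfl * dfv / h
                                     + fl * d2fv / h**2)) / fmax
        G_lp = a * (dfl * dfv / h + fl * d2fv / h**2)
        G_pp = -a * fl * d2fv / h**2
        G_p = (a * fmax * fl * dfv + self._bdamp) / (h * fmax)
        G_al = -(dfl * fv + fl * dfv / h)
        G_ap = fl * dfv / h

        H_ww = v1 * (2.0 * (ds**2 + s * d2s) + G_ll * dl**2 + G_l * d2l) \
            + (v3 / self.moment_scale) @ self._d.T \
            * fmax * 2.0 * (ds**2 + s * d2s)
        H_wp = v1 * (G_lp * dl * dl_prev)
        H_pp = v1 * (G_pp * dl_prev**2 + G_p * d2l_prev)
        H_aw = v1 * (G_al * dl)
        H_ap = v1 * (G_ap * dl_prev)
        drc = 1.0 / self._tact - 1.0 / self._tdeact
        H_uu = v2 * (-2.0 * h * drc)
        H_ua = v2 * (h * drc)

        K = np.arange(n)[:, None]
        Km = np.broadcast_to(K, (n, m))
        Im = np.broadcast_to(np.arange(m)[None, :], (n, m))
        Kprev = (Km - 1) % n
        iu = Km * m + Im
        ia = nm + Km * m + Im
        iw = 2 * nm + Km * m + Im
        iwp = 2 * nm + Kprev * m + Im
        rows = np.concatenate([z.ravel() for z in
                               (iw, iw, iwp, iwp, ia, iw, ia, iwp,
                                iu, iu, ia)])
        cols = np.concatenate([z.ravel() for z in
                               (iw, iwp, iw, iwp, iw, ia, iwp, ia,
                                iu, ia, iu)])
        data = np.concatenate([z.ravel() for z in
                               (H_ww, H_wp, H_wp, H_pp, H_aw, H_aw,
                                H_ap, H_ap, H_uu, H_ua, H_ua)])
        return sparse.csr_matrix((data, (rows, cols)),
                                 shape=(self.n_unknowns, self.n_unknowns))

    # -- exact second derivatives (for the interior-point solver) --------

    def constraint_hessian(self, x, v):
        """Sparse Hessian of v . c(x) in the scaled variables.

        Second derivatives are nonzero only inside each node-muscle block
        (a_k, l_k, l_{k-1}, u_k), so the matrix is assembled from a static
        pattern.  The quadratic elastic elements contribute constant
        curvature wherever they are engaged, which is what makes exact
        Hessians essential for this problem.
        """
        from scipy import sparse

        n, m, nj = self.n_nodes, self.n_muscles, len(self.joints)
        nm = n * m
        u, a, l = self.split(x)
        h = self.h
        vel = (l - np.roll(l, 1, axis=0)) / h
        mus = self.muscles
        see_slack = np.array([mm.tendon_slack_length for mm in mus])
        pee_slack = np.array([mm.pee_slack_length for mm in mus])
        k_see = np.array([mm.k_SEE for mm in mus])
        k_pee = np.array([mm.k_PEE for mm in mus])
        _, _, d2see = self._spring(self.l_mt - l - see_slack, k_see)
        _, _, d2pee = self._spring(l - pee_slack, k_pee)
        fl, dfl, d2fl, fv, dfv, d2fv = self._fl_fv(l, vel, second=True)

        v1 = v[:nm].reshape(n, m)                      # contraction rows
        v2 = v[nm:2 * nm].reshape(n, m)                # activation rows
        v3 = v[2 * nm:].reshape(n, nj)                 # moment rows

        lopt = self._lopt
        fmax = self._fmax
        # contraction: c1 = (F_SEE - F_PEE - a fmax fl fv - b vel)/fmax
        c1_ll = (d2see + d2pee) / fmax \
            - a * (d2fl * fv + 2.0 * dfl * dfv / h + fl * d2fv / h**2)
        c1_lp = a * (dfl * dfv / h + fl * d2fv / h**2)   # d2/dl dl_prev
        c1_pp = -a * fl * d2fv / h**2
        c1_al = -(dfl * fv + fl * dfv / h)
        c1_ap = fl * dfv / h
        # moment rows add spring curvature: sum_j v3_j d_ij 2 k_see / Mscale
        mom_ll = (v3 / self.moment_scale) @ self._d.T * d2see
        # activation rows: c2 = (a - a_prev) - h (u - a) rc(u)
        drc = 1.0 / self._tact - 1.0 / self._tdeact
        c2_uu = -2.0 * h * drc
        c2_ua = h * (1.0 / self._tact * 0 + drc) + h * (
            1.0 / self._tdeact * 0)  # d2c2/du da = h * rc'(u)? see below
        # c2 partials: dc2/du = -h[rc + (u-a) drc]; d2/du2 = -2 h drc;
        # d2/du da = h drc
        c2_ua = h * drc

        H_ll = (v1 * c1_ll + mom_ll) * lopt**2
        H_lp = (v1 * c1_lp) * lopt**2
        H_pp = (v1 * c1_pp) * lopt**2
        H_al = (v1 * c1_al) * lopt
        H_ap = (v1 * c1_ap) * lopt
        H_uu = v2 * c2_uu
        H_ua = v2 * c2_ua

        K = np.arange(n)[:, None]
        Km = np.broadcast_to(K, (n, m))
        Im = np.broadcast_to(np.arange(m)[None, :], (n, m))
        Kprev = (Km - 1) % n
        iu = Km * m + Im
        ia = nm + Km * m + Im
        il = 2 * nm + Km * m + Im
        ilp = 2 * nm + Kprev * m + Im

        rows = np.concatenate([z.ravel() for z in
                               (il, il, ilp, ilp, ia, il, ia, ilp, iu, iu, ia)])
        cols = np.concatenate([z.ravel() for z in
                               (il, ilp, il, ilp, il, ia, ilp, ia, iu, ia, iu)])
        # H_pp accumulates on the (lp, lp) diagonal; H_ll on (l, l)
        data = np.concatenate([z.ravel() for z in
                               (H_ll, H_lp, H_lp, H_pp, H_al, H_al,
                                H_ap, H_ap, H_uu, H_ua, H_ua)])
        return sparse.csr_matrix((data, (rows, cols)),
                                 shape=(self.n_unknowns, self.n_unknowns))

    def objective_hessian(self, x):
        from scipy import sparse

        n, m = self.n_nodes, self.n_muscles
        nm = n * m
        _, a, _ = self.split(x)
        if self.objective == "activation_squared":
            d = np.full(nm, 2.0 * self.h)
        elif self.objective == "activation_cubed":
            d = (6.0 * self.h * a).ravel()
        else:
            w = self._fmax * self._lopt
            w = w / w.mean()
            d = (6.0 * self.h * w * a).ravel()
        diag = np.zeros(self.n_unknowns)
        diag[nm:2 * nm] = d
        return sparse.diags(diag)

    # -- least-squares formulation ---------------------------------------
    # The augmented Lagrangian f + lam.c + mu/2 |c|^2 is an exact sum of
    # squares: 0.5 |sqrt(mu) c + lam/sqrt(mu)|^2 + 0.5 |r_obj|^2 (+ const),
    # with the activation-effort objective contributing residual rows of
    # its own.  This lets a trust-region least-squares solver with an
    # analytic sparse Jacobian do the heavy lifting.

    def _objective_residuals(self, a):
        h = self.h
        if self.objective == "activation_squared":
            return np.sqrt(2.0 * h) * a, np.full_like(a, np.sqrt(2.0 * h))
        if self.objective == "activation_cubed":
            return (np.sqrt(2.0 * h) * a**1.5,
                    np.sqrt(2.0 * h) * 1.5 * np.sqrt(np.maximum(a, 0.0)))
        w = self._fmax * self._lopt
        w = np.sqrt(w / w.mean())
        return (np.sqrt(2.0 * h) * w * a**1.5,
                np.sqrt(2.0 * h) * w * 1.5 * np.sqrt(np.maximum(a, 0.0)))

    def _ls_pattern(self):
        """Static sparsity pattern (rows, cols) of the stacked Jacobian."""
        if hasattr(self, "_pattern"):
            return self._pattern
        n, m, nj = self.n_nodes, self.n_muscles, len(self.joints)
        nm = n * m
        K = np.arange(n)[:, None]
        Km = np.broadcast_to(K, (n, m))
        Im = np.broadcast_to(np.arange(m)[None, :], (n, m))
        Kprev = (Km - 1) % n
        rows, cols = [], []
        r_con = Km * m + Im
        rows += [r_con, r_con, r_con]
        cols += [nm + Km * m + Im, 2 * nm + Km * m + Im, 2 * nm + Kprev * m + Im]
        r_act = nm + Km * m + Im
        rows += [r_act, r_act, r_act]
        cols += [nm + Km * m + Im, nm + Kprev * m + Im, Km * m + Im]
        for i in range(m):
            for j in range(nj):
                if self._d[i, j] != 0.0:
                    rows.append(2 * nm + K * nj + j)
                    cols.append(2 * nm + K * m + i)
        r_obj = 2 * nm + n * nj + Km * m + Im
        rows.append(r_obj)
        cols.append(nm + Km * m + Im)
        self._pattern = (
            np.concatenate([np.asarray(r).ravel() for r in rows]),
            np.concatenate([np.asarray(c).ravel() for c in cols]),
        )
        return self._pattern

    def ls_residuals(self, x, lam, mu):
        smu = np.sqrt(mu)
        c = self.constraints(x)
        _, a, _ = self.split(x)
        r_obj, _ = self._objective_residuals(a)
        return np.concatenate([smu * c + lam / smu, r_obj.ravel()])

    def ls_jacobian(self, x, lam, mu):
        from scipy import sparse

        n, m, nj = self.n_nodes, self.n_muscles, len(self.joints)
        nm = n * m
        smu = np.sqrt(mu)
        u, a, l = self.split(x)
        h = self.h
        v = (l - np.roll(l, 1, axis=0)) / h
        f_see, df_see_dl, f_pee, df_pee_dl = self._forces(a, l)
        fl, dfl, fv, dfv = self._fl_fv(l, v)
        rc = u / self._tact + (1.0 - u) / self._tdeact
        drc = 1.0 / self._tact - 1.0 / self._tdeact
        lopt = self._lopt
        data = [
            smu * (-fl * fv),
            smu * ((df_see_dl - df_pee_dl - a * self._fmax * dfl * fv)
                   / self._fmax
                   - (a * fl * dfv + self._bdamp / self._fmax) / h) * lopt,
            smu * ((a * fl * dfv + self._bdamp / self._fmax) / h) * lopt,
            smu * (1.0 + h * rc),
            smu * np.full((n, m), -1.0),
            smu * (-h) * (rc + (u - a) * drc),
        ]
        for i in range(m):
            for j in range(nj):
                if self._d[i, j] != 0.0:
                    data.append(smu * self._d[i, j] * df_see_dl[:, i]
                                * lopt[i] / self.moment_scale[j])
        _, dr_obj = self._objective_residuals(a)
        data.append(dr_obj)
        rows, cols = self._ls_pattern()
        data = np.concatenate([np.asarray(d).ravel() for d in data])
        n_res = 2 * nm + n * nj + nm
        return sparse.csr_matrix((data, (rows, cols)),
                                 shape=(n_res, self.n_unknowns))


@dataclass
class MuscleStateTrajectory:
    """Solution of the collocation problem at the 100 nodes."""

    muscles: list
    u: np.ndarray
    a: np.ndarray
    l_CE: np.ndarray
    v_CE: np.ndarray
    F_CE: np.ndarray
    F_SEE: np.ndarray
    F_PEE: np.ndarray
    moments: np.ndarray           # (n, j) reconstructed D F_SEE
    joints: tuple
    h: float
    objective_value: float
    max_violation: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def w_dot(self):
        """Fiber mechanical power (W), positive when shortening."""
        return -self.F_CE * self.v_CE

    def state(self, i: int) -> MuscleState:
        return MuscleState(a=self.a[:, i], u=self.u[:, i], l_CE=self.l_CE[:, i],
                           v_CE=self.v_CE[:, i], F_CE=self.F_CE[:, i],
                           F_SEE=self.F_SEE[:, i], F_PEE=self.F_PEE[:, i])

    def to_frame(self):
        import pandas as pd

        cols = {}
        for i, mus in enumerate(self.muscles):
            for ch in ("u", "a", "l_CE", "v_CE", "F_CE", "F_SEE", "F_PEE"):
                cols[f"{mus.name}_{ch}"] = getattr(self, ch)[:, i]
        return pd.DataFrame(cols)


def build_problem(cycle: CycleTrajectory, muscles: list[MuscleParams],
                  objective: str = "activation_squared") -> CollocationProblem:
    """Transcribe a cycle + muscle set into a collocation problem.

    The Winter-convention cycle angles (flexion/dorsiflexion positive) are
    negated into the extension/plantarflexion-positive generalized angles
    the moment-arm matrix is defined in; Winter moments already share the
    muscle moment convention.  Joints spanned by no muscle must carry a
    zero target moment.
    """
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}")
    n = cycle.joint_angles.shape[0]
    q = -cycle.joint_angles  # generalized angles
    spanned = tuple(j for j in JOINTS
                    if any(m.moment_arms.get(j, 0.0) != 0.0 for m in muscles))
    for jname in JOINTS:
        if jname not in spanned:
            col = JOINTS.index(jname)
            if np.abs(cycle.joint_moments[:, col]).max() > 1e-9:
                raise ValueError(
                    f"nonzero target moment at joint {jname!r} spanned by no muscle")
    l_mt = np.stack([m.musculotendon_length(q) for m in muscles], axis=1)
    cols = [JOINTS.index(j) for j in spanned]
    target = cycle.joint_moments[:, cols]
    return CollocationProblem(muscles=list(muscles), l_mt=l_mt,
                              target_moments=target, joints=spanned,
                              h=cycle.duration / n, n_nodes=n,
                              objective=objective)


class _NodeSolver:
    """Per-node subproblem in activation space.

    With the Backward-Euler transcription, fixing the activations a at a
    node determines the fiber lengths through the contraction balance
    (a monotone scalar equation per muscle, solved by safeguarded Newton),
    and hence the tendon forces and joint moments.  Activation-dynamics
    feasibility is the exact box [a_lo, a_hi] reachable from the previous
    node's activation with stimulation in [0, 1]; the stimulation follows
    in closed form afterwards.  Each node is then a small smooth NLP:
    minimize effort over a inside its box subject to moment matching,
    solved with SLSQP and analytic implicit-function gradients.
    """

    def __init__(self, problem: CollocationProblem, eps: float = 1e-5):
        self.p = problem
        mus = problem.muscles
        self.see_slack = np.array([m.tendon_slack_length for m in mus])
        self.pee_slack = np.array([m.pee_slack_length for m in mus])
        self.k_see = np.array([m.k_SEE for m in mus])
        self.k_pee = np.array([m.k_PEE for m in mus])
        self.vmax_abs = np.array([m.v_CE_max * m.l_CE_opt for m in mus])
        self.fmax = problem._fmax
        self.lopt = problem._lopt
        self.mus = list(mus)
        self.alpha = 1.0 / problem._tact
        self.beta = 1.0 / problem._tdeact
        #: smoothing half-width (m) of the slack-spring kink; keeps the
        #: moment Jacobian nonsingular when elements go slack.  The force
        #: bias at the kink is k eps^2 / 4, far below the constraint
        #: tolerance at the default eps.
        self.eps = eps
        self.width = np.array([m.width for m in mus])
        self.a_f = np.array([m.a_f for m in mus])
        self.g_max = np.array([m.g_max for m in mus])

    def _fl(self, l):
        """Vectorized Gaussian force-length and derivative."""
        x = (l / self.lopt - 1.0) / self.width
        fl = np.exp(-(x**2))
        dfl = fl * (-2.0 * x) / (self.width * self.lopt)
        return fl, dfl

    def _fv(self, v):
        """Vectorized Hill force-velocity and derivative (C2, monotone)."""
        from gaitmet.muscle import _fv_kernel

        f, df, _ = _fv_kernel(v / self.vmax_abs, self.a_f, self.g_max)
        return f, df / self.vmax_abs

    def _smooth_spring(self, x, k):
        """k * smoothmax(x, 0)^2 and its derivative."""
        hyp = np.sqrt(x**2 + self.eps**2)
        sx = 0.5 * (x + hyp)
        f = k * sx**2
        df = k * sx * (1.0 + x / hyp)
        return f, df

    def activation_bounds(self, a_prev):
        """Reachable [a_lo, a_hi] after one Backward-Euler step."""
        h = self.p.h
        a_hi = (a_prev + h * self.alpha) / (1.0 + h * self.alpha)
        a_lo = a_prev / (1.0 + h * self.beta)
        return a_lo, a_hi

    def _residual(self, l, a, l_prev, l_mt):
        """Contraction residual R(l; a) and dR/dl, dR/da (vectorized)."""
        h = self.p.h
        v = (l - l_prev) / h
        f_see, dsee_dx = self._smooth_spring(l_mt - l - self.see_slack, self.k_see)
        f_pee, dpee = self._smooth_spring(l - self.pee_slack, self.k_pee)
        fl, dfl = self._fl(l)
        fv, dfv = self._fv(v)
        R = f_see - f_pee - a * self.fmax * fl * fv - self.p._bdamp * v
        dR_dl = (-dsee_dx - dpee
                 - a * self.fmax * (dfl * fv + fl * dfv / h)
                 - self.p._bdamp / h)
        dR_da = -self.fmax * fl * fv
        return R, dR_dl, dR_da, f_see, -dsee_dx

    def _l_from_a(self, a, l_prev, l_mt, l_warm):
        """Solve the contraction balance for l given a (safeguarded Newton).

        R is strictly decreasing in l (damping guarantees it), so the root
        is unique; a bisection bracket backs up the Newton iteration.
        """
        lo = np.full_like(a, 1e-4)
        hi = l_mt - 1e-6
        l = np.clip(l_warm, lo + 1e-9, hi - 1e-9)
        R_scale = np.maximum(self.fmax, 1.0)
        for _ in range(30):
            R, dR_dl, _, _, _ = self._residual(l, a, l_prev, l_mt)
            if np.all(np.abs(R) < 1e-7 * R_scale):
                break
            hi = np.where(R < 0, np.minimum(hi, l), hi)
            lo = np.where(R > 0, np.maximum(lo, l), lo)
            step = -R / dR_dl
            l_new = l + step
            bad = (l_new <= lo) | (l_new >= hi) | ~np.isfinite(l_new)
            l = np.where(bad, 0.5 * (lo + hi), l_new)
        return l

    def states_for(self, a, a_prev, l_prev, l_mt, l_warm):
        """l, tendon force and dF/da for the given activations."""
        l = self._l_from_a(a, l_prev, l_mt, l_warm)
        R, dR_dl, dR_da, f_see, dsee_dl = self._residual(l, a, l_prev, l_mt)
        dl_da = -dR_da / dR_dl
        dF_da = dsee_dl * dl_da
        return l, f_see, dF_da

    def solve_node(self, a0, a_prev, l_prev, l_mt, target, l_warm,
                   tol: float = 1e-6):
        """Effort-minimal activations matching the node's moments."""
        from scipy.optimize import minimize as sp_minimize

        p = self.p
        a_lo, a_hi = self.activation_bounds(a_prev)
        a_lo = np.clip(a_lo, 0.0, 1.0)
        a_hi = np.clip(a_hi, 0.0, 1.0)
        x0 = np.clip(a0, a_lo, a_hi)

        if p.objective == "activation_squared":
            eff, deff = (lambda A: A**2), (lambda A: 2.0 * A)
        elif p.objective == "activation_cubed":
            eff, deff = (lambda A: A**3), (lambda A: 3.0 * A**2)
        else:
            w = p._fmax * p._lopt
            w = w / w.mean()
            eff, deff = (lambda A: w * A**3), (lambda A: 3.0 * w * A**2)

        cache = {}

        def evaluate(a):
            key = a.tobytes()
            if key not in cache:
                if len(cache) > 4:
                    cache.clear()
                cache[key] = self.states_for(a, a_prev, l_prev, l_mt, l_warm)
            return cache[key]

        def eq(a):
            _, f_see, _ = evaluate(a)
            return (f_see @ p._d - target) / p.moment_scale

        def eq_jac(a):
            _, _, dF_da = evaluate(a)
            return (p._d * dF_da[:, None]).T / p.moment_scale[:, None]

        res = sp_minimize(lambda a: float(eff(a).sum()), x0, jac=deff,
                          method="SLSQP", bounds=list(zip(a_lo, a_hi)),
                          constraints=[{"type": "eq", "fun": eq,
                                        "jac": eq_jac}],
                          options={"maxiter": 30, "ftol": 1e-10})
        a = np.clip(res.x, a_lo, a_hi)
        l, f_see, _ = self.states_for(a, a_prev, l_prev, l_mt, l_warm)
        cviol = float(np.abs((f_see @ p._d - target) / p.moment_scale).max())
        if cviol > max(min(0.5 * tol, 1e-3), 1e-6):
            # occasional SLSQP failures (singular subproblems at slack
            # configurations) are recovered by a mid-box restart
            alt0 = np.clip(0.5 * (a_lo + a_hi), a_lo, a_hi)
            res_b = sp_minimize(lambda av: float(eff(av).sum()), alt0,
                                jac=deff, method="SLSQP",
                                bounds=list(zip(a_lo, a_hi)),
                                constraints=[{"type": "eq", "fun": eq,
                                              "jac": eq_jac}],
                                options={"maxiter": 30, "ftol": 1e-10})
            a_b = np.clip(res_b.x, a_lo, a_hi)
            l_b, f_b, _ = self.states_for(a_b, a_prev, l_prev, l_mt, l_warm)
            cv_b = float(np.abs((f_b @ p._d - target)
                                / p.moment_scale).max())
            if cv_b < cviol:
                a, l, f_see, cviol = a_b, l_b, f_b, cv_b
        u = self._stimulation(a, a_prev)
        return u, a, l, cviol

    def _stimulation(self, a, a_prev):
        """Invert the Backward-Euler activation step for u in [0, 1]."""
        h = self.p.h
        r = (a - a_prev) / h
        A = self.alpha - self.beta
        # rc(u) (u - a) = r with rc = beta + A u  ->  quadratic in u
        qa = A
        qb = self.beta - A * a
        qc = -self.beta * a - r
        disc = np.maximum(qb**2 - 4.0 * qa * qc, 0.0)
        u = (-qb + np.sqrt(disc)) / (2.0 * qa)
        return np.clip(u, 0.0, 1.0)


def _sequential_solve(problem: CollocationProblem, tol: float,
                      max_sweeps: int = 6) -> np.ndarray:
    """Sweep the cycle until periodic; returns the stacked unknown vector."""
    from gaitmet.muscle import passive_equilibrium

    n, m = problem.n_nodes, problem.n_muscles
    a = np.zeros((n, m))
    u = np.zeros((n, m))
    l = np.empty((n, m))
    for i, mus in enumerate(problem.muscles):
        l[:, i] = [passive_equilibrium(float(problem.l_mt[k, i]), mus)
                   for k in range(n)]
    a_prev = np.zeros(m)
    l_prev = l[-1].copy()
    worst = np.inf
    worst_prev = np.inf
    for sweep in range(max_sweeps):
        node_solver = _NodeSolver(problem, eps=1e-4 if sweep == 0 else 1e-5)
        a_start, l_start = a_prev.copy(), l_prev.copy()
        worst = 0.0
        for k in range(n):
            # fast path: if the passive decay from the previous node
            # already matches this node's moments, skip the NLP
            a_lo, _ = node_solver.activation_bounds(a_prev)
            a_try = np.clip(a_lo, 0.0, 1.0)
            l_try, f_try, _ = node_solver.states_for(
                a_try, a_prev, l_prev, problem.l_mt[k], l[k])
            cv_try = float(np.abs((f_try @ problem._d
                                   - problem.target_moments[k])
                                  / problem.moment_scale).max())
            if cv_try <= 0.5 * tol:
                uk, ak, lk, cviol = (np.zeros(m), a_try, l_try, cv_try)
            else:
                a0 = a[k] if sweep > 0 else a_prev
                uk, ak, lk, cviol = node_solver.solve_node(
                    a0, a_prev, l_prev, problem.l_mt[k],
                    problem.target_moments[k], l[k], tol)
            u[k], a[k], l[k] = uk, ak, lk
            a_prev, l_prev = ak, lk
            worst = max(worst, cviol)
        drift = max(np.abs(a_prev - a_start).max(),
                    np.abs(l_prev - l_start).max() / problem._lopt.min())
        if sweep > 0 and drift < 1e-10 and worst <= tol:
            break
        if sweep > 1 and worst > 0.5 * worst_prev:
            break  # sweeps stopped improving; hand over to the NLP stages
        worst_prev = worst
    return problem.join(u, a, l)


def _propagate_states(problem: CollocationProblem, x, n_passes: int = 4):
    """Re-integrate (a, l_CE) exactly from the stimulations in ``x``.

    Runs the closed-form Backward-Euler activation step and the Newton
    contraction step around the cycle a few times so the state trajectory
    is exactly periodic and dynamics-consistent; only the moment-matching
    residual can remain.  Used to exactify near-feasible iterates.
    """
    ns = _NodeSolver(problem, eps=problem.eps)
    n, m = problem.n_nodes, problem.n_muscles
    u, a, l = problem.split(x)
    u = np.clip(u, 0.0, 1.0)
    a = a.copy()
    l = l.copy()
    h = problem.h
    for _ in range(n_passes):
        a_prev = a[-1].copy()
        l_prev = l[-1].copy()
        for k in range(n):
            rc = u[k] / problem._tact + (1.0 - u[k]) / problem._tdeact
            a[k] = np.clip((a_prev + h * u[k] * rc) / (1.0 + h * rc), 0.0, 1.0)
            l[k] = ns._l_from_a(a[k], l_prev, problem.l_mt[k], l[k])
            a_prev, l_prev = a[k], l[k]
    return problem.join(u, a, l)


def solve(problem: CollocationProblem, init: np.ndarray | str = "default",
          seed: int | None = None, tol: float = 1e-6,
          max_sweeps: int = 6, tc_maxiter: int = 800,
          polish_nfev: int = 120) -> MuscleStateTrajectory:
    """Solve the transcribed dynamic optimization problem.

    Three deterministic stages:

    1. *Sequential sweep*: the Backward-Euler transcription is solved node
       by node (exact dynamics steps; small SLSQP in activation space per
       node against the moment equalities), swept over the cycle until the
       periodic state repeats.  On problems without inter-node redundancy
       (few muscles, realizable moments) this alone reaches the tolerance.
    2. *Augmented Lagrangian*: the full NLP, reformulated in a tendon-force
       coordinate that removes the stiff series-elastic spring constant
       from the constraint curvature, is solved by an augmented-Lagrangian
       scheme whose bound-constrained least-squares subproblems (constraint
       rows plus effort-objective rows) are handled by a trust-region
       Gauss-Newton method with analytic sparse Jacobians.
    3. *Feasibility polish*: a final Gauss-Newton pass on the constraint
       residuals alone in the same coordinate.

    ``seed`` is accepted for interface uniformity but unused (the default
    strategy is deterministic).  Raises :class:`SolverFailure` when the
    scaled constraint violation cannot be brought below ``tol`` (e.g.
    target moments exceeding total muscle strength).
    """
    from scipy import sparse
    from scipy.optimize import Bounds, NonlinearConstraint, least_squares

    if isinstance(init, str):
        x = _sequential_solve(problem, tol, max_sweeps)
    else:
        x = np.asarray(init, float)
    cmax = float(np.abs(problem.constraints(x)).max())
    f_obj, _ = problem.objective_value_grad(x)
    history = [{"stage": "sequential", "cmax": cmax, "objective": f_obj}]
    best = (cmax, f_obj, x)

    def consider(tag, x_new):
        nonlocal best
        c_new = float(np.abs(problem.constraints(x_new)).max())
        f_new, _ = problem.objective_value_grad(x_new)
        history.append({"stage": tag, "cmax": c_new, "objective": f_new})
        if c_new < best[0]:
            best = (c_new, f_new, x_new)

    if cmax > tol:
        consider("propagate", _propagate_states(problem, x))
        cmax = best[0]

    if cmax > tol and tc_maxiter > 0:
        from scipy import sparse

        n, m = problem.n_nodes, problem.n_muscles
        nm = n * m
        lo, hi = problem.w_bounds()
        xw = np.clip(problem.w_from_x(best[2]), lo, hi)
        nc = problem.n_constraints
        lam = np.zeros(nc)
        mu = 1e4
        sob = np.sqrt(2.0 * problem.h)
        if problem.objective == "activation_squared":
            obj_rows = lambda a: sob * a
            obj_diag = lambda a: np.full(nm, sob)
        elif problem.objective == "activation_cubed":
            obj_rows = lambda a: sob * np.clip(a, 0, None) ** 1.5
            obj_diag = lambda a: sob * 1.5 * np.sqrt(np.clip(a, 0, None))
        else:
            wgt = problem._fmax * problem._lopt
            wgt = np.tile(np.sqrt(wgt / wgt.mean()), n)
            obj_rows = lambda a: sob * wgt * np.clip(a, 0, None) ** 1.5
            obj_diag = lambda a: sob * wgt * 1.5 * np.sqrt(np.clip(a, 0, None))

        idx = np.arange(nm)

        def alm_resid(z):
            c = problem.w_constraints(z)
            a = z[nm:2 * nm]
            return np.concatenate([np.sqrt(mu) * c + lam / np.sqrt(mu),
                                   obj_rows(a)])

        def alm_jac(z):
            J = problem.w_jacobian(z) * np.sqrt(mu)
            a = z[nm:2 * nm]
            D = sparse.csr_matrix((obj_diag(a), (idx, idx + nm)),
                                  shape=(nm, problem.n_unknowns))
            return sparse.vstack([J, D], format="csr")

        # augmented-Lagrangian outer loop: feasibility improves while the
        # effort objective is carried along as least-squares rows
        n_outer = max(1, tc_maxiter // 80)
        for outer in range(n_outer):
            res = least_squares(alm_resid, xw, jac=alm_jac, bounds=(lo, hi),
                                method="trf", tr_solver="lsmr", max_nfev=80,
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            xw = np.clip(res.x, lo, hi)
            c = problem.w_constraints(xw)
            cmax_w = float(np.abs(c).max())
            if cmax_w <= 0.8 * tol:
                break
            lam = lam + mu * c
            if outer >= 2 and cmax_w > 0.02:
                mu = min(mu * 5.0, 1e8)
        x_alm = problem.x_from_w(xw)
        consider("augmented_lagrangian", x_alm)

        if best[0] > tol and polish_nfev > 0:
            xw = np.clip(problem.w_from_x(best[2]), lo, hi)
            res2 = least_squares(
                problem.w_constraints, xw,
                jac=lambda z: sparse.csr_matrix(problem.w_jacobian(z)),
                bounds=(lo, hi), method="trf", tr_solver="lsmr",
                max_nfev=polish_nfev, xtol=1e-15, ftol=1e-15, gtol=1e-15)
            x_p = problem.x_from_w(np.clip(res2.x, lo, hi))
            consider("polish", x_p)
            if best[0] > tol:
                consider("propagate2", _propagate_states(problem, best[2]))

    cmax, f_obj, x = best
    if cmax > tol:
        c = problem.constraints(x)
        node = int(np.argmax(np.abs(c)) // max(problem.n_muscles, 1)
                   % problem.n_nodes)
        raise SolverFailure(
            f"constraint violation {cmax:.2e} exceeds tolerance {tol:.0e} "
            f"(worst near node {node}); the target moments may exceed "
            f"total muscle strength",
            diagnostics={"history": history, "max_violation": cmax})

    u, a, l = problem.split(x)
    v = (l - np.roll(l, 1, axis=0)) / problem.h
    f_see, _, f_pee, _ = problem._forces(a, l)
    f_ce = f_see - f_pee
    return MuscleStateTrajectory(
        muscles=problem.muscles, u=u, a=a, l_CE=l, v_CE=v, F_CE=f_ce,
        F_SEE=f_see, F_PEE=f_pee, moments=f_see @ problem._d,
        joints=problem.joints, h=problem.h, objective_value=f_obj,
        max_violation=cmax,
        diagnostics={"history": history})


def alternative_objectives(problem: CollocationProblem, kind: str,
                           **kwargs) -> MuscleStateTrajectory:
    """Solve with a swapped objective (cubed / volume-weighted cubed)."""
    if kind not in OBJECTIVES:
        raise ValueError(f"unknown objective kind {kind!r}")
    alt = CollocationProblem(
        muscles=problem.muscles, l_mt=problem.l_mt,
        target_moments=problem.target_moments, joints=problem.joints,
        h=problem.h, n_nodes=problem.n_nodes, objective=kind,
        moment_scale=problem.moment_scale)
    return solve(alt, **kwargs)


def constraint_jacobian(problem: CollocationProblem, x) -> np.ndarray:
    """Dense constraint Jacobian assembled from the analytic adjoint.

    Row r is obtained as the gradient of the Lagrangian with multiplier
    e_r and zero penalty; intended for structural verification on small
    problems, not for solving.
    """
    n_con = problem.n_constraints
    J = np.empty((n_con, problem.n_unknowns))
    zero_obj = problem.objective
    for r in range(n_con):
        lam = np.zeros(n_con)
        lam[r] = 1.0
        _, g, _ = problem.lagrangian_value_grad(x, lam, 0.0)
        _, g0 = problem.objective_value_grad(x)
        J[r] = g - g0
    assert problem.objective == zero_obj
    return J
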