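"""Compiled numerical kernels for the planar sit-to-stand model.

The three-link chain (shank, thigh, HAT) on a welded foot is expressed in
absolute segment angles ``phi = W q`` with the constant map
``W = [[1,0,0],[1,-1,0],[1,-1,1]]`` for ``q = (ankle, knee, hip)``
(flexion-positive joint convention, zero upright).  In absolute angles the
chain is the classic n-link pendulum:

    M_abs[j,k] = A[j,k] cos(phi_j - phi_k) + delta_jk I_j
    h_abs[j]   = sum_k A[j,k] sin(phi_j - phi_k) phidot_k^2
    dV/dphi_j  = -g Mw[j] sin(phi_j)

with constant coefficient matrices ``A[j,k] = sum_i m_i a_ij a_ik`` and
``Mw[j] = sum_i m_i a_ij`` built from the segment geometry
(``a`` maps absolute angles to segment-COM positions).  Joint-space
quantities follow by congruence with ``W``.  The chair is a 2-D point
constraint on the femur-head (hip-centre) point enforced with Lagrange
multipliers and light Baumgarte stabilization; the multiplier pair is the
seat reaction used for the release test and for the chair-contact cost.

Everything here is ``numba.njit``-compiled; the public modules wrap these
kernels with typed, documented interfaces.
"""

from __future__ import annotations

import numpy as np
from numba import njit

W_MAP = np.array([[1.0, 0.0, 0.0],
                  [1.0, -1.0, 0.0],
                  [1.0, -1.0, 1.0]])


# ---------------------------------------------------------------------------
# Hill characteristic curves
# ---------------------------------------------------------------------------

@njit(cache=True)
def fl_active(l_norm, width):
    """Gaussian active force-length multiplier, peak 1 at l_norm = 1."""
    x = (l_norm - 1.0) / width
    return np.exp(-x * x)


@njit(cache=True)
def fv_hill(v_norm, a_curv, ecc_max, ecc_c):
    """Hill force-velocity multiplier.

    Concentric (v_norm < 0): hyperbolic, 0 at v_norm = -1, 1 at rest.
    Eccentric (v_norm > 0): saturating rise to ``ecc_max``.
    """
    if v_norm <= -1.0:
        return 0.0
    if v_norm < 0.0:
        return (1.0 + v_norm) / (1.0 - v_norm / a_curv)
    return 1.0 + (ecc_max - 1.0) * v_norm / (v_norm + ecc_c)


@njit(cache=True)
def fp_passive(l_norm, k, strain):
    """Exponential passive force-length multiplier; 0 at or below slack.

    The exponent is capped so pathological postures produce huge but
    finite forces (divergent roll-outs must stay rankable).
    """
    if l_norm <= 1.0:
        return 0.0
    arg = k * (l_norm - 1.0) / strain
    if arg > 40.0:
        arg = 40.0
    return (np.exp(arg) - 1.0) / (np.exp(k) - 1.0)


# ---------------------------------------------------------------------------
# Musculotendon mechanics (rigid tendon)
# ---------------------------------------------------------------------------

@njit(cache=True)
def muscle_path(q, qdot, L0, armc, m):
    """Path length + velocity of muscle ``m`` (polynomial moment arms).

    arm_j(q) = c0 + c1 q + c2 q^2 + c3 q^3;  dL/dq_j = -arm_j.
    """
    plen = L0[m]
    pvel = 0.0
    for j in range(3):
        c0 = armc[m, j, 0]
        c1 = armc[m, j, 1]
        c2 = armc[m, j, 2]
        c3 = armc[m, j, 3]
        qj = q[j]
        arm = c0 + qj * (c1 + qj * (c2 + qj * c3))
        integ = qj * (c0 + qj * (0.5 * c1 + qj * (c2 / 3.0 + qj * 0.25 * c3)))
        plen -= integ
        pvel -= arm * qdot[j]
    return plen, pvel


@njit(cache=True)
def muscle_forces_and_torques(q, qdot, act,
                              fmax, lopt, slack, cospen, vmax, L0, armc,
                              fl_width, fv_a, fv_emax, fv_ec, fp_k, fp_strain,
                              out_force, out_active, out_passive, out_tau):
    """Tendon forces of all muscles and their joint torques at one state."""
    n = fmax.shape[0]
    for j in range(3):
        out_tau[j] = 0.0
    for m in range(n):
        plen, pvel = muscle_path(q, qdot, L0, armc, m)
        lf = (plen - slack[m]) / cospen[m]
        ln = lf / lopt[m]
        if ln < 1e-6:
            ln = 1e-6
        vn = (pvel / cospen[m]) / (lopt[m] * vmax[m])
        f_act = act[m] * fl_active(ln, fl_width) * fv_hill(vn, fv_a, fv_emax, fv_ec) * cospen[m]
        f_pas = fp_passive(ln, fp_k, fp_strain)
        force = fmax[m] * (f_act + f_pas)
        out_force[m] = force
        out_active[m] = fmax[m] * f_act
        out_passive[m] = fmax[m] * f_pas
        for j in range(3):
            c0 = armc[m, j, 0]
            c1 = armc[m, j, 1]
            c2 = armc[m, j, 2]
            c3 = armc[m, j, 3]
            qj = q[j]
            arm = c0 + qj * (c1 + qj * (c2 + qj * c3))
            out_tau[j] += force * arm


@njit(cache=True)
def limit_torques(q, qdot, lim_lo, lim_up, lim_scale, lim_rate, lim_damp, out):
    """Ligament limit torque per joint (N m): exponential restoring spring
    plus a damper active only outside the range (an inelastic catch, the
    standard coordinate-limit-force form).

    The spring magnitude saturates at 500 N m — far beyond physiological
    loads, but bounded so that deep penetrations of blown-up candidates
    remain integrable at the roll-out step sizes in use.
    """
    cap = 500.0
    for j in range(3):
        qj = q[j]
        if qj > lim_up[j]:
            arg = min(lim_rate[j] * (qj - lim_up[j]), 30.0)
            spring = min(lim_scale[j] * (np.exp(arg) - 1.0), cap)
            out[j] = -spring - lim_damp[j] * qdot[j]
        elif qj < lim_lo[j]:
            arg = min(lim_rate[j] * (lim_lo[j] - qj), 30.0)
            spring = min(lim_scale[j] * (np.exp(arg) - 1.0), cap)
            out[j] = spring - lim_damp[j] * qdot[j]
        else:
            out[j] = 0.0


# ---------------------------------------------------------------------------
# Rigid-body dynamics
# ---------------------------------------------------------------------------

@njit(cache=True)
def mass_and_bias(q, qdot, acoef, dphase, masses, Iseg, g):
    """Joint-space mass matrix and bias so that  M qdd + bias = Q_gen.

    ``acoef[i, j]`` weights the unit vector of absolute angle
    ``phi_j + dphase[i, j]`` in segment i's COM position; the phase
    offsets carry perpendicular (anterior) COM components.
    """
    phi = np.empty(3)
    phid = np.empty(3)
    phi[0] = q[0]
    phi[1] = q[0] - q[1]
    phi[2] = q[0] - q[1] + q[2]
    phid[0] = qdot[0]
    phid[1] = qdot[0] - qdot[1]
    phid[2] = qdot[0] - qdot[1] + qdot[2]

    M_abs = np.zeros((3, 3))
    h_abs = np.zeros(3)
    for i in range(3):
        mi = masses[i]
        for j in range(3):
            aij = acoef[i, j]
            if aij == 0.0:
                continue
            pj = phi[j] + dphase[i, j]
            for k in range(3):
                aik = acoef[i, k]
                if aik == 0.0:
                    continue
                d = pj - (phi[k] + dphase[i, k])
                M_abs[j, k] += mi * aij * aik * np.cos(d)
                h_abs[j] += mi * aij * aik * np.sin(d) * phid[k] * phid[k]
            h_abs[j] -= g * mi * aij * np.sin(pj)
    for j in range(3):
        M_abs[j, j] += Iseg[j]

    Mq = W_MAP.T @ (M_abs @ W_MAP)
    bias = W_MAP.T @ h_abs
    return Mq, bias


@njit(cache=True)
def assist_gen_force(q, acoef, dphase, fx, fy):
    """Generalized force of a point force applied at the torso COM."""
    phi = np.empty(3)
    phi[0] = q[0]
    phi[1] = q[0] - q[1]
    phi[2] = q[0] - q[1] + q[2]
    Qa = np.empty(3)
    for j in range(3):
        pj = phi[j] + dphase[2, j]
        Qa[j] = acoef[2, j] * (np.cos(pj) * fx - np.sin(pj) * fy)
    return W_MAP.T @ Qa


@njit(cache=True)
def seat_jacobian(q, qdot, L1, L2, ax, ay, sx, sy, beta):
    """Constraint Jacobian, violation and acceleration RHS for the seat.

    Returns (Jq, rhs) with  Jq qdd = rhs  enforcing the femur-head point,
    including Baumgarte terms -2 beta cdot - beta^2 c.
    """
    phi0 = q[0]
    phi1 = q[0] - q[1]
    phid0 = qdot[0]
    phid1 = qdot[0] - qdot[1]
    s0 = np.sin(phi0)
    c0 = np.cos(phi0)
    s1 = np.sin(phi1)
    c1 = np.cos(phi1)

    J_abs = np.zeros((2, 3))
    J_abs[0, 0] = L1 * c0
    J_abs[0, 1] = L2 * c1
    J_abs[1, 0] = -L1 * s0
    J_abs[1, 1] = -L2 * s1
    Jq = J_abs @ W_MAP

    cviol = np.empty(2)
    cviol[0] = ax + L1 * s0 + L2 * s1 - sx
    cviol[1] = ay + L1 * c0 + L2 * c1 - sy
    cdot = Jq @ qdot

    gamma = np.empty(2)
    gamma[0] = -L1 * phid0 * phid0 * s0 - L2 * phid1 * phid1 * s1
    gamma[1] = -L1 * phid0 * phid0 * c0 - L2 * phid1 * phid1 * c1

    rhs = -gamma - 2.0 * beta * cdot - beta * beta * cviol
    return Jq, rhs


@njit(cache=True)
def forward_dyn(q, qdot, tau, fax, fay, engaged,
                acoef, dphase, masses, Iseg, g, L1, L2, ax, ay, sx, sy, beta):
    """Constrained forward dynamics at one state.

    ``tau`` is the total joint torque (muscles + limit springs + anything
    external already mapped to joints); ``(fax, fay)`` the assist force at
    the torso COM.  Returns ``(qdd, lam)``; ``lam`` is the seat reaction on
    the body, zero when the constraint is disengaged.
    """
    Mq, bias = mass_and_bias(q, qdot, acoef, dphase, masses, Iseg, g)
    Q = tau + assist_gen_force(q, acoef, dphase, fax, fay) - bias
    lam = np.zeros(2)
    if engaged:
        Jq, rhs_c = seat_jacobian(q, qdot, L1, L2, ax, ay, sx, sy, beta)
        K = np.zeros((5, 5))
        K[:3, :3] = Mq
        K[:3, 3:] = -Jq.T
        K[3:, :3] = Jq
        rhs = np.empty(5)
        rhs[:3] = Q
        rhs[3:] = rhs_c
        sol = np.linalg.solve(K, rhs)
        qdd = sol[:3]
        lam = sol[3:5]
    else:
        qdd = np.linalg.solve(Mq, Q)
    return qdd, lam


@njit(cache=True)
def body_points(q, acoef, dphase, ax, ay, L1, L2):
    """Segment COM positions plus hip point at a posture."""
    phi = np.empty(3)
    phi[0] = q[0]
    phi[1] = q[0] - q[1]
    phi[2] = q[0] - q[1] + q[2]
    p = np.empty((3, 2))
    for i in range(3):
        p[i, 0] = ax
        p[i, 1] = ay
        for j in range(3):
            pj = phi[j] + dphase[i, j]
            p[i, 0] += acoef[i, j] * np.sin(pj)
            p[i, 1] += acoef[i, j] * np.cos(pj)
    hip = np.empty(2)
    hip[0] = ax + L1 * np.sin(phi[0]) + L2 * np.sin(phi[1])
    hip[1] = ay + L1 * np.cos(phi[0]) + L2 * np.cos(phi[1])
    return p, hip, phi


@njit(cache=True)
def instrument(q, qdot, qdd, lam, fax, fay,
               masses, Iseg, acoef, dphase, g, L1, L2, ax, ay,
               m_foot, fcx, fcy):
    """Whole-body bookkeeping at one sample.

    Returns (com, com_vel, feet_force, feet_moment) where ``feet_moment``
    is the ground-reaction moment about the ground point below the ankle,
    sign convention: positive tips the body toe-ward, so that
    ``zmp_x = ankle_x - feet_moment / F_y``.
    """
    p, hip, phi = body_points(q, acoef, dphase, ax, ay, L1, L2)
    phid = np.empty(3)
    phidd = np.empty(3)
    phid[0] = qdot[0]
    phid[1] = qdot[0] - qdot[1]
    phid[2] = qdot[0] - qdot[1] + qdot[2]
    phidd[0] = qdd[0]
    phidd[1] = qdd[0] - qdd[1]
    phidd[2] = qdd[0] - qdd[1] + qdd[2]

    total_m = masses[0] + masses[1] + masses[2] + m_foot
    com = np.zeros(2)
    comv = np.zeros(2)
    ffx = 0.0
    ffy = 0.0
    m_ccw = 0.0
    g0x = ax  # ground point below ankle

    for i in range(3):
        vx = 0.0
        vy = 0.0
        accx = 0.0
        accy = 0.0
        for j in range(3):
            pj = phi[j] + dphase[i, j]
            ux = np.sin(pj)
            uy = np.cos(pj)
            ex = np.cos(pj)
            ey = -np.sin(pj)
            vx += acoef[i, j] * phid[j] * ex
            vy += acoef[i, j] * phid[j] * ey
            accx += acoef[i, j] * (phidd[j] * ex - phid[j] * phid[j] * ux)
            accy += acoef[i, j] * (phidd[j] * ey - phid[j] * phid[j] * uy)
        mi = masses[i]
        com[0] += mi * p[i, 0]
        com[1] += mi * p[i, 1]
        comv[0] += mi * vx
        comv[1] += mi * vy
        ffx += mi * accx
        ffy += mi * accy
        rx = p[i, 0] - g0x
        ry = p[i, 1]
        # dH/dt term + gravity moment (gravity force (0, -mi g))
        m_ccw += Iseg[i] * phidd[i] + rx * mi * accy - ry * mi * accx
        m_ccw += rx * mi * g

    com[0] = (com[0] + m_foot * fcx) / total_m
    com[1] = (com[1] + m_foot * fcy) / total_m
    comv[0] /= total_m
    comv[1] /= total_m

    ffx += -lam[0] - fax
    ffy += total_m * g - lam[1] - fay

    # foot gravity, seat reaction at hip, assist at torso COM
    m_ccw += (fcx - g0x) * m_foot * g
    m_ccw -= (hip[0] - g0x) * lam[1] - hip[1] * lam[0]
    m_ccw -= (p[2, 0] - g0x) * fay - p[2, 1] * fax

    feet_force = np.empty(2)
    feet_force[0] = ffx
    feet_force[1] = ffy
    feet_moment = -m_ccw
    return com, comv, feet_force, feet_moment


# ---------------------------------------------------------------------------
# Excitation interpolation
# ---------------------------------------------------------------------------

@njit(cache=True)
def excitation_at_time(t, nodes, node_dt, default_act, out):
    """Piecewise-linear excitation; node k lives at time (k+1) * node_dt."""
    n_act, n_nodes = nodes.shape
    for a in range(n_act):
        if t <= 0.0:
            out[a] = default_act[a]
            continue
        x = t / node_dt
        k = int(np.floor(x)) - 1  # left node index, -1 = the default point
        if k >= n_nodes - 1:
            out[a] = nodes[a, n_nodes - 1]
        elif k < 0:
            out[a] = default_act[a] + (nodes[a, 0] - default_act[a]) * x
        else:
            frac = x - (k + 1)
            out[a] = nodes[a, k] + (nodes[a, k + 1] - nodes[a, k]) * frac


@njit(cache=True)
def activation_rate(exc, act, act_tau, deact_tau, out):
    """First-order activation dynamics toward the excitation."""
    n = exc.shape[0]
    for i in range(n):
        tau = act_tau[i] if exc[i] > act[i] else deact_tau[i]
        out[i] = (exc[i] - act[i]) / tau


# ---------------------------------------------------------------------------
# Full roll-out
# ---------------------------------------------------------------------------

@njit(cache=True)
def rollout(q0, qd0, act0, engaged0,
            nodes, node_dt, default_act, t_f,
            dt, qdot_cap, beta,
            acoef, dphase, masses, Iseg, g, L1, L2, ax, ay, sx, sy, mu,
            m_foot, fcx, fcy,
            fmax, lopt, slack, cospen, vmax, L0, armc,
            act_tau, deact_tau,
            fl_width, fv_a, fv_emax, fv_ec, fp_k, fp_strain,
            lim_lo, lim_up, lim_scale, lim_rate, lim_damp, damping,
            n_assist, assist_dirs, assist_fmax,
            use_muscles, use_springs):
    """Fixed-step RK4 roll-out with per-step seat-release handling.

    Returns a tuple of time-series arrays (length ``n_used``), the index of
    seat release (-1 if the model never left the chair) and a failure flag
    set when any joint speed exceeds ``qdot_cap`` (partial series kept so
    the cost function can still rank the candidate).
    """
    n_mus = fmax.shape[0]
    n_act = n_mus + n_assist
    n_steps = int(np.round(t_f / dt))
    n = n_steps + 1

    ts = np.empty(n)
    qs = np.empty((n, 3))
    qds = np.empty((n, 3))
    qdds = np.empty((n, 3))
    acts = np.empty((n, n_act))
    mfor = np.empty((n, n_mus))
    mact = np.empty((n, n_mus))
    mpas = np.empty((n, n_mus))
    tlim = np.empty((n, 3))
    seatf = np.empty((n, 2))
    feetf = np.empty((n, 2))
    feetm = np.empty(n)
    coms = np.empty((n, 2))
    comvs = np.empty((n, 2))
    assists = np.empty((n, 2))

    q = q0.copy()
    qd = qd0.copy()
    act = act0.copy()
    engaged = engaged0
    release_idx = -1
    failed = False
    n_used = n

    exc = np.empty(n_act)
    actdot = np.empty(n_act)
    force = np.empty(n_mus)
    fact = np.empty(n_mus)
    fpas = np.empty(n_mus)
    tau = np.empty(3)
    tl = np.empty(3)

    # scratch for RK4
    kq = np.empty((4, 3))
    kqd = np.empty((4, 3))
    kact = np.empty((4, n_act))

    for i in range(n):
        t = i * dt

        # non-finite state (blown-up candidate): truncate, keep the series
        finite = True
        for j in range(3):
            if not (np.isfinite(q[j]) and np.isfinite(qd[j])):
                finite = False
        for a in range(n_act):
            if not np.isfinite(act[a]):
                finite = False
        if not finite:
            failed = True
            n_used = max(i, 1)
            break

        # --- instrument current state (also provides k1) -----------------
        fax = 0.0
        fay = 0.0
        if n_assist > 0:
            for a in range(n_assist):
                fa = act[n_mus + a] * assist_fmax
                fax += fa * assist_dirs[a, 0]
                fay += fa * assist_dirs[a, 1]

        if use_muscles and n_mus > 0:
            muscle_forces_and_torques(q, qd, act[:n_mus],
                                      fmax, lopt, slack, cospen, vmax, L0, armc,
                                      fl_width, fv_a, fv_emax, fv_ec, fp_k, fp_strain,
                                      force, fact, fpas, tau)
        else:
            for m in range(n_mus):
                force[m] = 0.0
                fact[m] = 0.0
                fpas[m] = 0.0
            for j in range(3):
                tau[j] = 0.0
        if use_springs:
            limit_torques(q, qd, lim_lo, lim_up, lim_scale, lim_rate, lim_damp, tl)
        else:
            for j in range(3):
                tl[j] = 0.0
        tau_tot = tau + tl
        if use_springs:
            for j in range(3):
                tau_tot[j] -= damping[j] * qd[j]

        qdd, lam = forward_dyn(q, qd, tau_tot, fax, fay, engaged,
                               acoef, dphase, masses, Iseg, g,
                               L1, L2, ax, ay, sx, sy, beta)

        if engaged:
            if lam[1] <= 0.0 or np.abs(lam[0]) > mu * lam[1]:
                engaged = False
                release_idx = i
                qdd, lam = forward_dyn(q, qd, tau_tot, fax, fay, False,
                                       acoef, dphase, masses, Iseg, g,
                                       L1, L2, ax, ay, sx, sy, beta)

        com, comv, ff, fm = instrument(q, qd, qdd, lam, fax, fay,
                                       masses, Iseg, acoef, dphase, g,
                                       L1, L2, ax, ay, m_foot, fcx, fcy)

        ts[i] = t
        for j in range(3):
            qs[i, j] = q[j]
            qds[i, j] = qd[j]
            qdds[i, j] = qdd[j]
            tlim[i, j] = tl[j]
        for a in range(n_act):
            acts[i, a] = act[a]
        for m in range(n_mus):
            mfor[i, m] = force[m]
            mact[i, m] = fact[m]
            mpas[i, m] = fpas[m]
        seatf[i, 0] = lam[0]
        seatf[i, 1] = lam[1]
        feetf[i, 0] = ff[0]
        feetf[i, 1] = ff[1]
        feetm[i] = fm
        coms[i, 0] = com[0]
        coms[i, 1] = com[1]
        comvs[i, 0] = comv[0]
        comvs[i, 1] = comv[1]
        assists[i, 0] = fax
        assists[i, 1] = fay

        if np.abs(qd[0]) > qdot_cap or np.abs(qd[1]) > qdot_cap or np.abs(qd[2]) > qdot_cap:
            failed = True
            n_used = i + 1
            break
        if i == n - 1:
            break

        # --- RK4 step ----------------------------------------------------
        kq[0] = qd
        kqd[0] = qdd
        excitation_at_time(t, nodes, node_dt, default_act, exc)
        activation_rate(exc, act, act_tau, deact_tau, actdot)
        kact[0] = actdot

        blown = False
        for stage in range(1, 4):
            if stage < 3:
                h = 0.5 * dt
            else:
                h = dt
            qtmp = q + h * kq[stage - 1]
            qdtmp = qd + h * kqd[stage - 1]
            for j in range(3):
                if not (np.isfinite(qtmp[j]) and np.isfinite(qdtmp[j])):
                    blown = True
            if blown:
                break
            atmp = act + h * kact[stage - 1]
            for a2 in range(n_act):
                if atmp[a2] < 0.0:
                    atmp[a2] = 0.0
                elif atmp[a2] > 1.0:
                    atmp[a2] = 1.0
            ttmp = t + h

            fax2 = 0.0
            fay2 = 0.0
            if n_assist > 0:
                for a2 in range(n_assist):
                    fa = atmp[n_mus + a2] * assist_fmax
                    fax2 += fa * assist_dirs[a2, 0]
                    fay2 += fa * assist_dirs[a2, 1]
            if use_muscles and n_mus > 0:
                muscle_forces_and_torques(qtmp, qdtmp, atmp[:n_mus],
                                          fmax, lopt, slack, cospen, vmax, L0, armc,
                                          fl_width, fv_a, fv_emax, fv_ec, fp_k, fp_strain,
                                          force, fact, fpas, tau)
            else:
                for j in range(3):
                    tau[j] = 0.0
            if use_springs:
                limit_torques(qtmp, qdtmp, lim_lo, lim_up, lim_scale, lim_rate,
                              lim_damp, tl)
                for j in range(3):
                    tl[j] -= damping[j] * qdtmp[j]
            else:
                for j in range(3):
                    tl[j] = 0.0
            qdd2, _lam2 = forward_dyn(qtmp, qdtmp, tau + tl, fax2, fay2, engaged,
                                      acoef, dphase, masses, Iseg, g,
                                      L1, L2, ax, ay, sx, sy, beta)
            excitation_at_time(ttmp, nodes, node_dt, default_act, exc)
            activation_rate(exc, atmp, act_tau, deact_tau, actdot)
            kq[stage] = qdtmp
            kqd[stage] = qdd2
            kact[stage] = actdot

        if blown:
            failed = True
            n_used = i + 1
            break

        q = q + (dt / 6.0) * (kq[0] + 2.0 * kq[1] + 2.0 * kq[2] + kq[3])
        qd = qd + (dt / 6.0) * (kqd[0] + 2.0 * kqd[1] + 2.0 * kqd[2] + kqd[3])
        act = act + (dt / 6.0) * (kact[0] + 2.0 * kact[1] + 2.0 * kact[2] + kact[3])
        for a in range(n_act):
            if act[a] < 0.0:
                act[a] = 0.0
            elif act[a] > 1.0:
                act[a] = 1.0

    return (ts[:n_used], qs[:n_used], qds[:n_used], qdds[:n_used],
            acts[:n_used], mfor[:n_used], mact[:n_used], mpas[:n_used],
            tlim[:n_used], seatf[:n_used], feetf[:n_used], feetm[:n_used],
            coms[:n_used], comvs[:n_used], assists[:n_used],
            release_idx, failed)
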