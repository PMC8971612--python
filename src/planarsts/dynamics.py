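"""Forward/inverse dynamics of the planar chain and balance bookkeeping.

Wraps the compiled kernels with typed interfaces operating on
:class:`~planarsts.params.PlanarModel`.  The generalized coordinates are
``q = (ankle, knee, hip)`` in radians, flexion-positive, zero upright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .params import DEG, JOINTS, JointLimits, PlanarModel


class NumericalError(RuntimeError):
    """Singular mass matrix / rank-deficient constraint, with state dump."""


class ZmpUndefinedError(ValueError):
    """ZMP requested with non-positive vertical ground force."""


@dataclass
class PackedModel:
    """Plain-array view of a PlanarModel consumed by the compiled kernels."""

    Iseg: np.ndarray
    acoef: np.ndarray
    dphase: np.ndarray
    masses: np.ndarray
    g: float
    L1: float
    L2: float
    ax: float
    ay: float
    sx: float
    sy: float
    mu: float
    m_foot: float
    fcx: float
    fcy: float
    fmax: np.ndarray
    lopt: np.ndarray
    slack: np.ndarray
    cospen: np.ndarray
    vmax: np.ndarray
    L0: np.ndarray
    armc: np.ndarray
    act_tau: np.ndarray
    deact_tau: np.ndarray
    fl_width: float
    fv_a: float
    fv_emax: float
    fv_ec: float
    fp_k: float
    fp_strain: float
    lim_lo: np.ndarray
    lim_up: np.ndarray
    lim_scale: np.ndarray
    lim_rate: np.ndarray
    lim_damp: np.ndarray
    damping: np.ndarray
    n_assist: int
    assist_dirs: np.ndarray
    assist_fmax: float
    assist_tau: float


def pack_model(model: PlanarModel) -> PackedModel:
    """Precompute the constant coefficient arrays of the chain.

    ``acoef[i, j]`` is the (constant) coefficient of the absolute-angle
    unit vector ``u(phi_j + dphase[i, j])`` in segment i's COM position.
    An anterior (perpendicular) COM component of a segment appears as the
    phase offset ``atan2(com_forward, com_offset)`` on its own diagonal
    term, with the radius ``hypot(com_offset, com_forward)``.
    """
    segs = model.segments
    L1, L2 = segs[0].length, segs[1].length
    acoef = np.array([[segs[0].com_offset, 0.0, 0.0],
                      [L1, segs[1].com_offset, 0.0],
                      [L1, L2, segs[2].com_offset]])
    dphase = np.zeros((3, 3))
    for i, seg in enumerate(segs):
        fwd = getattr(seg, "com_forward", 0.0)
        if fwd:
            acoef[i, i] = math.hypot(seg.com_offset, fwd)
            dphase[i, i] = math.atan2(fwd, seg.com_offset)
    masses = np.array([s.mass for s in segs])
    Iseg = np.array([s.inertia for s in segs])

    n_mus = model.n_muscles
    armc = np.zeros((max(n_mus, 1), 3, 4))
    for mi, m in enumerate(model.muscles):
        for j, joint in enumerate(JOINTS):
            arm = m.arms.get(joint)
            if arm is None:
                continue
            if isinstance(arm, (int, float)):
                armc[mi, j, 0] = float(arm)
            else:
                coeffs = list(arm)[:4]
                for k, c in enumerate(coeffs):
                    armc[mi, j, k] = float(c)

    def arr(attr):
        vals = [getattr(m, attr) for m in model.muscles]
        return np.array(vals if vals else [0.0])

    cv = model.curves
    assist = model.assist
    return PackedModel(
        Iseg=Iseg, acoef=acoef, dphase=dphase, masses=masses,
        g=model.gravity, L1=L1, L2=L2,
        ax=model.foot.ankle[0], ay=model.foot.ankle[1],
        sx=model.chair.seat_point[0], sy=model.chair.seat_point[1],
        mu=model.chair.mu,
        m_foot=model.foot.mass, fcx=model.foot.com[0], fcy=model.foot.com[1],
        fmax=arr("f_max"), lopt=arr("optimal_fiber_length"),
        slack=arr("tendon_slack_length"),
        cospen=np.cos(arr("pennation_opt")) if n_mus else np.array([1.0]),
        vmax=arr("v_max"), L0=arr("path_length_ref"), armc=armc,
        act_tau=arr("act_tau"), deact_tau=arr("deact_tau"),
        fl_width=cv.fl_width, fv_a=cv.fv_a, fv_emax=cv.fv_ecc_max,
        fv_ec=cv.fv_ecc_c, fp_k=cv.fp_k, fp_strain=cv.fp_strain,
        lim_lo=np.array([model.limit_for(j).lower * DEG for j in JOINTS]),
        lim_up=np.array([model.limit_for(j).upper * DEG for j in JOINTS]),
        lim_scale=np.array([model.limit_for(j).scale for j in JOINTS]),
        lim_rate=np.array([model.limit_for(j).rate for j in JOINTS]),
        lim_damp=np.array([model.limit_for(j).damping for j in JOINTS]),
        damping=np.asarray(model.joint_damping, dtype=float),
        n_assist=2 if assist.enabled else 0,
        assist_dirs=np.array(assist.directions, dtype=float),
        assist_fmax=assist.f_max,
        assist_tau=assist.tau,
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def mass_matrix(model: PlanarModel, q: np.ndarray,
                packed: PackedModel | None = None) -> np.ndarray:
    pm = packed or pack_model(model)
    Mq, _ = K.mass_and_bias(np.asarray(q, float), np.zeros(3),
                            pm.acoef, pm.dphase, pm.masses, pm.Iseg, pm.g)
    return Mq


def bias_forces(model: PlanarModel, q, qdot, packed=None) -> np.ndarray:
    """Coriolis/centrifugal + gravity bias so that  M qdd + bias = Q."""
    pm = packed or pack_model(model)
    _, bias = K.mass_and_bias(np.asarray(q, float), np.asarray(qdot, float),
                              pm.acoef, pm.dphase, pm.masses, pm.Iseg, pm.g)
    return bias


def forward_dynamics(model: PlanarModel, q, qdot, joint_torques,
                     assist_force=(0.0, 0.0), seat_engaged: bool = False,
                     locked_joints: tuple = (), packed: PackedModel | None = None):
    """Accelerations and seat reaction for given joint torques.

    ``joint_torques`` are the total generalized forces at (ankle, knee,
    hip) excluding gravity/inertia, e.g. muscle + limit-spring torques.
    ``locked_joints`` holds those joints at zero acceleration (useful for
    reduced-DOF oracles).  Returns ``(qdd, seat_reaction)``.
    """
    pm = packed or pack_model(model)
    q = np.asarray(q, float)
    qdot = np.asarray(qdot, float)
    tau = np.asarray(joint_torques, float)
    fax, fay = float(assist_force[0]), float(assist_force[1])

    if locked_joints:
        if seat_engaged:
            raise NumericalError("locked joints and the seat constraint cannot be combined")
        Mq, bias = K.mass_and_bias(q, qdot, pm.acoef, pm.dphase, pm.masses,
                                   pm.Iseg, pm.g)
        Q = tau + K.assist_gen_force(q, pm.acoef, pm.dphase, fax, fay) - bias
        free = [j for j in range(3) if JOINTS[j] not in locked_joints]
        qdd = np.zeros(3)
        sub = Mq[np.ix_(free, free)]
        try:
            qdd[free] = np.linalg.solve(sub, Q[free])
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise NumericalError(f"singular reduced mass matrix at q={q}") from exc
        return qdd, np.zeros(2)

    try:
        qdd, lam = K.forward_dyn(q, qdot, tau, fax, fay, seat_engaged,
                                 pm.acoef, pm.dphase, pm.masses, pm.Iseg, pm.g,
                                 pm.L1, pm.L2, pm.ax, pm.ay, pm.sx, pm.sy,
                                 model.integrator.baumgarte_beta)
    except Exception as exc:  # singular KKT system
        raise NumericalError(
            f"dynamics solve failed at q={q}, qdot={qdot}, tau={tau}") from exc
    return qdd, lam


def inverse_dynamics(model: PlanarModel, q, qdot, qdd,
                     seat_force=(0.0, 0.0), assist_force=(0.0, 0.0),
                     packed: PackedModel | None = None) -> np.ndarray:
    """Generalized-force residual of the recorded motion.

    Returns the joint torques that, together with the supplied external
    seat/assist forces, reproduce ``qdd``:
    ``tau = M qdd + bias - J_seat^T F_seat - J_torso^T F_assist``.
    """
    pm = packed or pack_model(model)
    q = np.asarray(q, float)
    qdot = np.asarray(qdot, float)
    qdd = np.asarray(qdd, float)
    Mq, bias = K.mass_and_bias(q, qdot, pm.acoef, pm.dphase, pm.masses,
                               pm.Iseg, pm.g)
    tau = Mq @ qdd + bias
    fax, fay = assist_force
    if fax or fay:
        tau -= K.assist_gen_force(q, pm.acoef, pm.dphase, float(fax), float(fay))
    fsx, fsy = seat_force
    if fsx or fsy:
        Jq, _ = K.seat_jacobian(q, qdot, pm.L1, pm.L2, pm.ax, pm.ay,
                                pm.sx, pm.sy, 0.0)
        tau -= Jq.T @ np.array([fsx, fsy], dtype=float)
    return tau


def limit_spring_torque(limits: JointLimits, q_joint: float) -> float:
    """Restoring ligament torque (N m) at joint angle ``q_joint`` (radians).

    Zero strictly inside the physiological range; exponential restoring
    torque (continuous from zero at the limit) outside.
    """
    lo = limits.lower * DEG
    up = limits.upper * DEG
    mid = 0.5 * (lo + up)
    out = np.zeros(3)
    K.limit_torques(np.array([q_joint, mid, mid]), np.zeros(3),
                    np.array([lo, lo, lo]), np.array([up, up, up]),
                    np.full(3, limits.scale), np.full(3, limits.rate),
                    np.zeros(3), out)
    return float(out[0])


def check_seat_release(seat_reaction, mu: float) -> bool:
    """True once the chair constraint must be dropped.

    Release fires when the vertical reaction turns non-compressive
    (``F_y <= 0``) or the tangential reaction leaves the friction cone
    (``|F_x| > mu F_y``).
    """
    fx, fy = float(seat_reaction[0]), float(seat_reaction[1])
    return fy <= 0.0 or abs(fx) > mu * fy


def compute_com(model: PlanarModel, q, packed=None) -> np.ndarray:
    """Whole-body COM (m), mass-weighted including the welded foot."""
    pm = packed or pack_model(model)
    com, _, _, _ = K.instrument(np.asarray(q, float), np.zeros(3), np.zeros(3),
                                np.zeros(2), 0.0, 0.0,
                                pm.masses, pm.Iseg, pm.acoef, pm.dphase, pm.g,
                                pm.L1, pm.L2, pm.ax, pm.ay,
                                pm.m_foot, pm.fcx, pm.fcy)
    return com


def compute_com_vel(model: PlanarModel, q, qdot, packed=None) -> np.ndarray:
    """Whole-body COM velocity (m/s); the welded foot contributes zero."""
    pm = packed or pack_model(model)
    _, comv, _, _ = K.instrument(np.asarray(q, float), np.asarray(qdot, float),
                                 np.zeros(3), np.zeros(2), 0.0, 0.0,
                                 pm.masses, pm.Iseg, pm.acoef, pm.dphase, pm.g,
                                 pm.L1, pm.L2, pm.ax, pm.ay,
                                 pm.m_foot, pm.fcx, pm.fcy)
    return comv


def compute_zmp(feet_force, feet_moment: float, ref_x: float) -> float:
    """Ground-line x where the reaction wrench has zero tipping moment.

    ``feet_moment`` is the reaction moment about the ground point at
    ``ref_x`` with the package convention that a positive moment tips the
    body toe-ward, hence ``zmp_x = ref_x - feet_moment / F_y``.
    """
    fy = float(feet_force[1])
    if fy <= 0.0:
        raise ZmpUndefinedError(f"vertical ground force must be positive, got {fy}")
    return ref_x - float(feet_moment) / fy


def mechanical_energy(model: PlanarModel, q, qdot, packed=None) -> float:
    """Kinetic + gravitational potential energy of the linkage (J)."""
    pm = packed or pack_model(model)
    q = np.asarray(q, float)
    qdot = np.asarray(qdot, float)
    Mq, _ = K.mass_and_bias(q, qdot, pm.acoef, pm.dphase, pm.masses,
                            pm.Iseg, pm.g)
    T = 0.5 * qdot @ Mq @ qdot
    p, _, _ = K.body_points(q, pm.acoef, pm.dphase, pm.ax, pm.ay, pm.L1, pm.L2)
    V = pm.g * float(pm.masses @ p[:, 1])
    return float(T + V)


def hip_point(model: PlanarModel, q, packed=None) -> np.ndarray:
    """Femur-head (hip-centre) position in the ground frame."""
    pm = packed or pack_model(model)
    _, hip, _ = K.body_points(np.asarray(q, float), pm.acoef, pm.dphase,
                              pm.ax, pm.ay, pm.L1, pm.L2)
    return hip
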