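"""Tracking-based failure diagnosis (computed-muscle-control style).

To ask *which* muscle's weakness makes sit-to-stand fail, a weakened model
is driven along a reference kinematic trajectory: a proportional-derivative
law converts tracking error into desired accelerations a small lookahead
ahead, and a static optimization (the "fast target") distributes the
required generalized forces over the muscles — bounded by their
instantaneous force capability — plus idealized per-joint reserve
actuators.  Reserves produce little torque per unit control, so they are
recruited only where the muscles saturate; their peak torques flag the
insufficient joint.  Chair-constraint forces recorded during the forward
simulation are supplied as external forces, since the tracked model does
not carry the event-released constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from . import _kernels as K
from .dynamics import PackedModel, pack_model
from .params import JOINTS, PlanarModel
from .simulate import SimulationResult


@dataclass
class TrackingConfig:
    """Gains and actuator bounds of the tracking stage.

    ``kp``/``kv`` are per-DOF feedback gains on position and velocity error
    (defaults a critically-damped pairing kv = 2 sqrt(kp));
    ``reserve_optimal_torques`` is the torque each reserve produces per
    unit control — small values make a reserve "expensive" and thus
    favour the muscles and the other reserves.
    """

    kp: tuple = (100.0, 100.0, 100.0)       # 1/s^2
    kv: tuple = (20.0, 20.0, 20.0)          # 1/s
    lookahead_T: float = 0.01               # s
    reserve_optimal_torques: tuple = (1.0, 1.0, 1.0)  # N m per unit control
    reserve_control_bound: float = 100.0
    step: float = 0.01                      # s
    substeps: int = 10                      # RK4 substeps per control step
    abort_error: float = 1.0                # rad, tracking-failure threshold


@dataclass
class TrackingResult:
    """Per-step controls and reserve torques from one tracking run."""

    times: np.ndarray
    controls: np.ndarray          # (n, n_muscles + 3)
    reserve_torques: np.ndarray   # (n, 3) N m
    tracking_error: np.ndarray    # (n, 3) rad
    peak_reserve: np.ndarray      # (3,) signed extremum per DOF
    slack: np.ndarray             # (n, 3) unmet acceleration (rad/s^2)
    aborted: bool = False

    @property
    def peak_reserve_magnitude(self) -> np.ndarray:
        return np.abs(self.peak_reserve)


@dataclass
class ReferenceTrajectory:
    """Spline-differentiable reference kinematics q_exp(t)."""

    times: np.ndarray
    q: np.ndarray  # (n, 3) rad

    def __post_init__(self):
        self._spline = CubicSpline(self.times, self.q, axis=0)
        self._dspline = self._spline.derivative()
        self._ddspline = self._dspline.derivative()

    @classmethod
    def from_simulation(cls, result: SimulationResult, stride: int = 10):
        return cls(times=result.times[::stride].copy(), q=result.q[::stride].copy())

    def _clip_t(self, t):
        return float(np.clip(t, self.times[0], self.times[-1]))

    def q_at(self, t):
        return self._spline(self._clip_t(t))

    def qdot_at(self, t):
        return self._dspline(self._clip_t(t))

    def qddot_at(self, t):
        # held at the last sample beyond the reference end
        tc = self._clip_t(t)
        return self._ddspline(tc)


@dataclass
class ExternalForceSeries:
    """Recorded seat (femur-head) and assistance (torso COM) force series."""

    times: np.ndarray
    seat: np.ndarray    # (n, 2) N
    assist: np.ndarray  # (n, 2) N

    @classmethod
    def from_simulation(cls, result: SimulationResult):
        return cls(times=result.times.copy(), seat=result.seat_force.copy(),
                   assist=result.assist_force.copy())

    def at(self, t: float):
        t = float(np.clip(t, self.times[0], self.times[-1]))
        seat = np.array([np.interp(t, self.times, self.seat[:, k]) for k in range(2)])
        assist = np.array([np.interp(t, self.times, self.assist[:, k]) for k in range(2)])
        return seat, assist


def desired_accelerations(ref: ReferenceTrajectory, t: float, q, qdot,
                          config: TrackingConfig) -> np.ndarray:
    """PD law: feedforward reference acceleration at t+T plus error feedback."""
    kp = np.asarray(config.kp, dtype=float)
    kv = np.asarray(config.kv, dtype=float)
    T = config.lookahead_T
    return (ref.qddot_at(t + T)
            + kv * (ref.qdot_at(t) - np.asarray(qdot, float))
            + kp * (ref.q_at(t) - np.asarray(q, float)))


def fast_target_solve(A: np.ndarray, b: np.ndarray,
                      lb: np.ndarray, ub: np.ndarray,
                      max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Minimize sum of squared controls subject to A e = b and bounds.

    Primal active-set method for the strictly convex QP
    ``min ||e||^2  s.t.  A e = b,  lb <= e <= ub``: solve the minimum-norm
    equality-constrained problem on the free variables, clamp the worst
    violator, and release clamped variables whose bound multiplier turns
    negative.  Returns ``(e, slack)`` where ``slack = A e - b`` is nonzero
    only when the bounds make the equalities unreachable.
    """
    m, n = A.shape
    e = np.zeros(n)
    fixed = np.full(n, 0, dtype=int)  # 0 free, +1 at ub, -1 at lb

    for _ in range(max_iter):
        free = fixed == 0
        r = b - A[:, ~free] @ e[~free] if (~free).any() else b.copy()
        Af = A[:, free]
        if Af.shape[1] > 0:
            G = Af @ Af.T
            try:
                nu = np.linalg.solve(G, r)
            except np.linalg.LinAlgError:
                nu = np.linalg.lstsq(G, r, rcond=None)[0]
            ef = Af.T @ nu
            e[free] = ef
        else:
            nu = np.linalg.lstsq(A @ A.T, r, rcond=None)[0]

        # clamp the worst bound violation among free variables
        viol_hi = np.where(free, e - ub, 0.0)
        viol_lo = np.where(free, lb - e, 0.0)
        worst_hi = int(np.argmax(viol_hi))
        worst_lo = int(np.argmax(viol_lo))
        if viol_hi[worst_hi] > 1e-12 or viol_lo[worst_lo] > 1e-12:
            if viol_hi[worst_hi] >= viol_lo[worst_lo]:
                fixed[worst_hi] = 1
                e[worst_hi] = ub[worst_hi]
            else:
                fixed[worst_lo] = -1
                e[worst_lo] = lb[worst_lo]
            continue

        # KKT multipliers of clamped variables: release if sign is wrong
        # (stationarity: 2e = A^T nu* with nu* = 2 nu on the free set)
        kappa = 2.0 * (e - A.T @ nu)
        release = None
        worst = 1e-9
        for i in np.nonzero(fixed)[0]:
            # at an upper bound the multiplier must push down (kappa <= 0)
            val = kappa[i] if fixed[i] == 1 else -kappa[i]
            if val > worst:
                worst = val
                release = i
        if release is None:
            break
        fixed[release] = 0

    e = np.clip(e, lb, ub)
    slack = A @ e - b
    return e, slack


def _capabilities(pm: PackedModel, q, qdot):
    """Instantaneous active force capability + passive force per muscle."""
    n = len(pm.fmax)
    cap = np.empty(n)
    pas = np.empty(n)
    arms = np.empty((n, 3))
    for mi in range(n):
        plen, pvel = K.muscle_path(q, qdot, pm.L0, pm.armc, mi)
        ln = max((plen - pm.slack[mi]) / pm.cospen[mi] / pm.lopt[mi], 1e-6)
        vn = (pvel / pm.cospen[mi]) / (pm.lopt[mi] * pm.vmax[mi])
        cap[mi] = (pm.fmax[mi] * K.fl_active(ln, pm.fl_width)
                   * K.fv_hill(vn, pm.fv_a, pm.fv_emax, pm.fv_ec) * pm.cospen[mi])
        pas[mi] = pm.fmax[mi] * K.fp_passive(ln, pm.fp_k, pm.fp_strain)
        for j in range(3):
            c = pm.armc[mi, j]
            arms[mi, j] = c[0] + q[j] * (c[1] + q[j] * (c[2] + q[j] * c[3]))
    return cap, pas, arms


def track(model: PlanarModel, reference: ReferenceTrajectory,
          external_forces: ExternalForceSeries | None,
          config: TrackingConfig | None = None,
          t_start: float | None = None, t_end: float | None = None) -> TrackingResult:
    """Step the model along the reference with PD + fast-target control.

    Controls are frozen over each control step while the skeleton is
    integrated with RK4 substeps.  Muscle activation dynamics are bypassed
    (the static stage commands force directly against the instantaneous
    capability), matching the convex fast-target formulation.
    """
    cfg = config or TrackingConfig()
    pm = pack_model(model)
    t0 = reference.times[0] if t_start is None else float(t_start)
    t1 = reference.times[-1] if t_end is None else float(t_end)
    if t1 <= t0:
        n_mus = model.n_muscles
        empty = np.zeros((0, 3))
        return TrackingResult(times=np.zeros(0), controls=np.zeros((0, n_mus + 3)),
                              reserve_torques=empty, tracking_error=empty,
                              peak_reserve=np.zeros(3), slack=empty)

    n_mus = model.n_muscles
    res_opt = np.asarray(cfg.reserve_optimal_torques, dtype=float)
    lb = np.concatenate([np.zeros(n_mus), -cfg.reserve_control_bound * np.ones(3)])
    ub = np.concatenate([np.ones(n_mus), cfg.reserve_control_bound * np.ones(3)])

    times = np.arange(t0, t1 - 1e-12, cfg.step)
    q = reference.q_at(t0).copy()
    qd = reference.qdot_at(t0).copy()

    rows_ctrl = []
    rows_res = []
    rows_err = []
    rows_slack = []
    aborted = False

    damping = pm.damping
    for t in times:
        qdd_star = desired_accelerations(reference, t, q, qd, cfg)

        Mq, bias = K.mass_and_bias(q, qd, pm.acoef, pm.dphase, pm.masses,
                                   pm.Iseg, pm.g)
        tl = np.zeros(3)
        K.limit_torques(q, qd, pm.lim_lo, pm.lim_up, pm.lim_scale, pm.lim_rate,
                        pm.lim_damp, tl)
        tau_passive = tl - damping * qd

        seat_f = np.zeros(2)
        assist_f = np.zeros(2)
        if external_forces is not None:
            seat_f, assist_f = external_forces.at(t)
        Q_ext = np.zeros(3)
        if seat_f.any():
            Jq, _ = K.seat_jacobian(q, qd, pm.L1, pm.L2, pm.ax, pm.ay,
                                    pm.sx, pm.sy, 0.0)
            Q_ext += Jq.T @ seat_f
        if assist_f.any():
            Q_ext += K.assist_gen_force(q, pm.acoef, pm.dphase,
                                        assist_f[0], assist_f[1])

        cap, pas, arms = _capabilities(pm, q, qd)
        tau_pas_mus = arms.T @ pas

        A = np.zeros((3, n_mus + 3))
        for mi in range(n_mus):
            A[:, mi] = cap[mi] * arms[mi]
        A[:, n_mus:] = np.diag(res_opt)
        b = Mq @ qdd_star + bias - Q_ext - tau_passive - tau_pas_mus

        e, slack = fast_target_solve(A, b, lb, ub)
        tau_applied = A @ e + tau_pas_mus + tau_passive + Q_ext

        err = reference.q_at(t) - q
        rows_ctrl.append(e)
        rows_res.append(e[n_mus:] * res_opt)
        rows_err.append(err)
        rows_slack.append(slack)
        if np.max(np.abs(err)) > cfg.abort_error:
            aborted = True
            break

        # advance skeleton with frozen generalized force
        h = cfg.step / cfg.substeps
        for _ in range(cfg.substeps):
            def f(qq, qqd):
                Mx, bx = K.mass_and_bias(qq, qqd, pm.acoef, pm.dphase,
                                         pm.masses, pm.Iseg, pm.g)
                return np.linalg.solve(Mx, tau_applied - bx)
            k1q, k1v = qd, f(q, qd)
            k2q, k2v = qd + 0.5 * h * k1v, f(q + 0.5 * h * k1q, qd + 0.5 * h * k1v)
            k3q, k3v = qd + 0.5 * h * k2v, f(q + 0.5 * h * k2q, qd + 0.5 * h * k2v)
            k4q, k4v = qd + h * k3v, f(q + h * k3q, qd + h * k3v)
            q = q + (h / 6.0) * (k1q + 2 * k2q + 2 * k3q + k4q)
            qd = qd + (h / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v)

    n = len(rows_ctrl)
    res_t = np.array(rows_res) if n else np.zeros((0, 3))
    peak = np.zeros(3)
    for j in range(3):
        if n:
            col = res_t[:, j]
            peak[j] = col[int(np.argmax(np.abs(col)))]
    return TrackingResult(times=times[:n], controls=np.array(rows_ctrl) if n else np.zeros((0, n_mus + 3)),
                          reserve_torques=res_t,
                          tracking_error=np.array(rows_err) if n else np.zeros((0, 3)),
                          peak_reserve=peak,
                          slack=np.array(rows_slack) if n else np.zeros((0, 3)),
                          aborted=aborted)


@dataclass
class FailureDiagnosis:
    """Cross-setup comparison of reserve usage."""

    peaks: dict                 # setup label -> per-joint peak reserve (signed)
    persistent: np.ndarray      # per-joint min over setups of |peak|
    implicated_joint: str | None

    def summary(self) -> str:
        lines = []
        for label, pk in self.peaks.items():
            lines.append(f"{label}: " + ", ".join(
                f"{j} {v:+.2f} Nm" for j, v in zip(JOINTS, pk)))
        if self.implicated_joint is None:
            lines.append("no joint weakness implicated")
        else:
            lines.append(f"implicated weakness: {self.implicated_joint} "
                         f"(reserve persists across both setups)")
        return "\n".join(lines)


def diagnose_failure(result_setup1: TrackingResult,
                     result_setup2: TrackingResult,
                     labels: tuple = ("setup1", "setup2"),
                     tol: float = 1e-6) -> FailureDiagnosis:
    """Name the joint whose reserves persist under both reserve pricings.

    A joint whose reserve stays large *even when that reserve is made
    expensive* cannot be served by the muscles: per joint we take the
    smaller of the two setups' peak magnitudes and implicate the joint
    where that persistent reserve is largest.  Equal persistent reserves
    are reported as a tie (no joint named); all-zero reserves implicate
    nothing.
    """
    p1 = result_setup1.peak_reserve
    p2 = result_setup2.peak_reserve
    persistent = np.minimum(np.abs(p1), np.abs(p2))
    implicated = None
    if np.max(persistent) > tol:
        order = np.argsort(persistent)[::-1]
        if persistent[order[0]] > persistent[order[1]] + tol:
            implicated = JOINTS[order[0]]
    return FailureDiagnosis(peaks={labels[0]: p1.copy(), labels[1]: p2.copy()},
                            persistent=persistent, implicated_joint=implicated)
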