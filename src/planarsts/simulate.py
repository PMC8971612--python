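"""Forward roll-out of the seated model under an open-loop controller."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .control import ControlTrajectory
from .dynamics import PackedModel, pack_model
from .params import IntegratorConfig, PlanarModel


@dataclass
class State:
    """Instantaneous mechanical + activation state."""

    t: float
    q: np.ndarray          # rad, (ankle, knee, hip)
    qdot: np.ndarray       # rad/s
    activations: np.ndarray
    seat_engaged: bool

    def validate(self) -> None:
        if np.any(self.activations < -1e-12) or np.any(self.activations > 1 + 1e-12):
            raise ValueError("activations outside [0, 1]")


@dataclass
class SimulationResult:
    """Time series and events from one forward roll-out.

    ``feet_moment`` follows the package ZMP convention (positive tips the
    body toe-ward about the ground point below the ankle);
    ``seat_force`` is identically zero after the release event.
    ``zmp_x`` is NaN wherever the vertical ground force is not positive.
    """

    times: np.ndarray
    q: np.ndarray
    qdot: np.ndarray
    qddot: np.ndarray
    activations: np.ndarray      # (n, n_actuators) muscles then assists
    muscle_force: np.ndarray     # tendon forces (n, n_muscles)
    muscle_active: np.ndarray
    muscle_passive: np.ndarray
    limit_torque: np.ndarray     # (n, 3)
    seat_force: np.ndarray       # (n, 2)
    feet_force: np.ndarray       # (n, 2)
    feet_moment: np.ndarray      # (n,)
    com: np.ndarray              # (n, 2)
    com_vel: np.ndarray          # (n, 2)
    assist_force: np.ndarray     # (n, 2) summed assistance components
    zmp_x: np.ndarray            # (n,)
    t_seat_release: float | None
    t_f: float
    failed: bool = False
    model_weight: float = 0.0    # mg, N
    feet_ref_x: float = 0.0      # Feet_x: heel-toe midpoint
    n_muscles: int = 0

    @property
    def released(self) -> bool:
        return self.t_seat_release is not None

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def state_at(self, i: int) -> State:
        return State(t=float(self.times[i]), q=self.q[i].copy(),
                     qdot=self.qdot[i].copy(), activations=self.activations[i].copy(),
                     seat_engaged=(self.t_seat_release is None
                                   or self.times[i] < self.t_seat_release))

    def to_frame(self):
        """Tidy per-sample table (one row per time step)."""
        import pandas as pd

        data = {"time": self.times}
        for j, name in enumerate(("ankle", "knee", "hip")):
            data[f"q_{name}"] = self.q[:, j]
            data[f"qdot_{name}"] = self.qdot[:, j]
            data[f"qddot_{name}"] = self.qddot[:, j]
            data[f"limit_torque_{name}"] = self.limit_torque[:, j]
        for a in range(self.activations.shape[1]):
            data[f"activation_{a}"] = self.activations[:, a]
        for m in range(self.muscle_force.shape[1]):
            data[f"muscle_force_{m}"] = self.muscle_force[:, m]
        data["seat_fx"] = self.seat_force[:, 0]
        data["seat_fy"] = self.seat_force[:, 1]
        data["feet_fx"] = self.feet_force[:, 0]
        data["feet_fy"] = self.feet_force[:, 1]
        data["feet_moment"] = self.feet_moment
        data["com_x"] = self.com[:, 0]
        data["com_y"] = self.com[:, 1]
        data["com_vx"] = self.com_vel[:, 0]
        data["com_vy"] = self.com_vel[:, 1]
        data["assist_fx"] = self.assist_force[:, 0]
        data["assist_fy"] = self.assist_force[:, 1]
        data["zmp_x"] = self.zmp_x
        return pd.DataFrame(data)

    def metadata(self) -> dict:
        return {
            "t_f": float(self.t_f),
            "t_seat_release": (None if self.t_seat_release is None
                               else float(self.t_seat_release)),
            "failed": bool(self.failed),
            "n_samples": int(self.n_samples),
        }


def initial_state(model: PlanarModel,
                  default_activation: float = 0.05) -> State:
    """Configured sitting posture with equilibrated muscles.

    With the default rigid tendon the fibre lengths follow directly from
    the path geometry, so equilibration reduces to setting every muscle's
    activation to the default (0.05) and assistance activations to zero.
    """
    act = np.full(model.n_actuators, default_activation)
    act[model.n_muscles:] = 0.0
    return State(t=0.0, q=model.sitting_q(), qdot=np.zeros(3),
                 activations=act, seat_engaged=model.chair.engaged)


def simulate(model: PlanarModel, controller: ControlTrajectory,
             integrator: IntegratorConfig | None = None,
             start: State | None = None,
             packed: PackedModel | None = None,
             use_muscles: bool = True,
             use_springs: bool = True) -> SimulationResult:
    """Integrate activation + skeletal dynamics from t_0 to the controller's t_f.

    The seat constraint is checked each step and removed permanently at
    the first step where it turns non-compressive or slips; roll-outs
    whose joint speeds exceed the divergence cap are flagged ``failed``
    and return the partial series (still rankable by the cost function).
    """
    integ = integrator or model.integrator
    pm = packed or pack_model(model)
    st = start or initial_state(model)
    st.validate()

    n_assist = pm.n_assist
    if controller.layout.n_actuators != model.n_muscles + n_assist:
        raise ValueError(
            f"controller has {controller.layout.n_actuators} actuators, "
            f"model expects {model.n_muscles + n_assist}")

    out = K.rollout(
        st.q.astype(float), st.qdot.astype(float), st.activations.astype(float),
        bool(st.seat_engaged),
        controller.node_values, controller.layout.node_dt,
        controller.layout.default_activation, float(controller.t_f),
        integ.dt, integ.qdot_cap, integ.baumgarte_beta,
        pm.acoef, pm.dphase, pm.masses, pm.Iseg, pm.g,
        pm.L1, pm.L2, pm.ax, pm.ay, pm.sx, pm.sy, pm.mu,
        pm.m_foot, pm.fcx, pm.fcy,
        pm.fmax, pm.lopt, pm.slack, pm.cospen, pm.vmax, pm.L0, pm.armc,
        pm.act_tau, pm.deact_tau,
        pm.fl_width, pm.fv_a, pm.fv_emax, pm.fv_ec, pm.fp_k, pm.fp_strain,
        pm.lim_lo, pm.lim_up, pm.lim_scale, pm.lim_rate, pm.lim_damp, pm.damping,
        n_assist, pm.assist_dirs, pm.assist_fmax,
        bool(use_muscles and model.n_muscles > 0), bool(use_springs))

    (ts, qs, qds, qdds, acts, mfor, mactf, mpasf, tlim, seatf, feetf, feetm,
     coms, comvs, assists, release_idx, failed) = out

    zmp = np.full(len(ts), np.nan)
    ok = feetf[:, 1] > 1e-9
    zmp[ok] = pm.ax - feetm[ok] / feetf[ok, 1]

    t_sr = float(ts[release_idx]) if release_idx >= 0 else None
    return SimulationResult(
        times=ts, q=qs, qdot=qds, qddot=qdds, activations=acts,
        muscle_force=mfor, muscle_active=mactf, muscle_passive=mpasf,
        limit_torque=tlim, seat_force=seatf, feet_force=feetf,
        feet_moment=feetm, com=coms, com_vel=comvs, assist_force=assists,
        zmp_x=zmp, t_seat_release=t_sr, t_f=float(ts[-1]), failed=bool(failed),
        model_weight=model.weight, feet_ref_x=model.foot.midpoint_x,
        n_muscles=model.n_muscles)
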