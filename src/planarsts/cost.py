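"""The ten-term sit-to-stand cost function and the STS-progress scalar.

The objective is a weighted sum of ten penalties evaluated on one forward
roll-out: (1) remaining COM distance to the upright goal, (2) an
exponentially time-weighted chair-contact force, (3) control effort,
(4) effort rate, (5) assistance usage, (6) joint-limit torques, (7) foot
slip, (8) ZMP excursion from the foot midpoint, (9) terminal joint speed,
and (10) deviation of the vertical ground force from body weight after
seat-off.  Terms 7-10 are gated by the progress scalar

    alpha = 1 - min(d(Cf, Cgoal), d(C0, Cgoal)) / d(C0, Cgoal)

so that they only bite once candidate motions start approaching standing;
term 2 carries the complementary ``(1 - alpha)`` factor and its
exponential weight ``exp(t/tau) / (tau (exp(t_f/tau) - 1))`` integrates to
one over the movement, emphasising late chair contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import compute_com
from .params import PlanarModel
from .simulate import SimulationResult

#: Default relative weights w1..w10 and the chair-term time constant
#: tau = t_max / 8.
DEFAULT_WEIGHTS = (800.0, 1.2, 175.0, 70.0, 5.0, 10.0, 0.1, 1000.0, 6.0, 0.3)


class DegenerateStartError(ValueError):
    """alpha undefined: the start COM coincides with the goal COM."""


@dataclass
class CostWeights:
    """Relative weights of the ten cost terms plus the chair time constant."""

    w: tuple = DEFAULT_WEIGHTS
    tau: float = 1.6 / 8.0
    phi8_integral: bool = False  # integral variant of the ZMP term

    def __post_init__(self):
        if len(self.w) != 10:
            raise ValueError("need exactly 10 weights")
        if any(wi < 0 for wi in self.w):
            raise ValueError("weights must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass
class CostBreakdown:
    """alpha, the ten phi terms and their weighted total for one roll-out."""

    alpha: float
    phi: np.ndarray      # 10-vector
    total: float
    c0: np.ndarray
    cf: np.ndarray
    c_goal: np.ndarray

    def as_dict(self) -> dict:
        d = {f"phi{i + 1}": float(p) for i, p in enumerate(self.phi)}
        d["alpha"] = float(self.alpha)
        d["total"] = float(self.total)
        return d


def goal_com(model: PlanarModel, packed=None) -> np.ndarray:
    """COM of the upright standing posture (q = 0)."""
    return compute_com(model, np.zeros(3), packed=packed)


def compute_alpha(cf, c0, c_goal) -> float:
    """STS completion in [0, 1]: 0 still at the start, 1 standing."""
    d0 = float(np.linalg.norm(np.asarray(c0) - np.asarray(c_goal)))
    if d0 <= 0.0:
        raise DegenerateStartError("start COM coincides with goal COM")
    df = float(np.linalg.norm(np.asarray(cf) - np.asarray(c_goal)))
    return 1.0 - min(df, d0) / d0


def exp_weight(t: np.ndarray, t_f: float, tau: float) -> np.ndarray:
    """Normalized increasing exponential: integrates to 1 on [0, t_f]."""
    return np.exp(t / tau) / (tau * (np.expm1(t_f / tau)))


def compute_terms(result: SimulationResult, model: PlanarModel,
                  weights: CostWeights | None = None,
                  packed=None) -> CostBreakdown:
    """Evaluate alpha and the ten phi terms on a roll-out.

    Quadrature is the trapezoid rule on the stored integration grid.  For
    roll-outs that never release the seat, the post-seat-off window of the
    ground-force term degenerates to the final sample, and the alpha-gated
    terms use the computed (near-zero) alpha so failed candidates are
    still ranked smoothly.
    """
    w = weights or CostWeights()
    t = result.times
    t_f = float(t[-1]) if len(t) > 1 else 0.0
    c_goal = goal_com(model, packed=packed)
    c0 = result.com[0]
    cf = result.com[-1]
    alpha = compute_alpha(cf, c0, c_goal)

    phi = np.zeros(10)
    d0 = float(np.linalg.norm(c0 - c_goal))
    phi[0] = float(np.linalg.norm(cf - c_goal)) / d0

    if t_f > 0.0:
        wexp = exp_weight(t, t_f, w.tau)
        phi[1] = (1.0 - alpha) * np.trapezoid(wexp * result.seat_force[:, 1], t)

        acts = result.activations
        n_act = acts.shape[1]
        if n_act:
            phi[2] = np.trapezoid(np.sum(acts ** 2, axis=1), t) / n_act
            adot = np.gradient(acts, t, axis=0)
            phi[3] = np.trapezoid(np.sum(adot ** 2, axis=1), t) / n_act

        assist_mag = np.hypot(result.assist_force[:, 0], result.assist_force[:, 1])
        phi[4] = np.trapezoid(assist_mag, t)
        phi[5] = np.trapezoid(np.sum(np.abs(result.limit_torque), axis=1), t)

        mu = model.chair.mu
        slip = np.abs(result.feet_force[:, 0]) - mu * result.feet_force[:, 1]
        phi[6] = alpha * max(float(np.max(slip)), 0.0)

        zmp_dev = np.abs(result.zmp_x - result.feet_ref_x)
        zmp_dev = np.where(np.isfinite(zmp_dev), zmp_dev, 0.0)
        if w.phi8_integral:
            phi[7] = alpha * np.trapezoid(zmp_dev, t)
        else:
            phi[7] = alpha * float(np.max(zmp_dev))

    phi[8] = alpha * float(np.sum(np.abs(result.qdot[-1])))

    mg = result.model_weight
    if result.t_seat_release is not None:
        mask = t >= result.t_seat_release
    else:
        mask = np.zeros(len(t), dtype=bool)
        mask[-1] = True
    fy = result.feet_force[mask, 1]
    phi[9] = alpha * (abs(float(np.max(fy)) - mg) + abs(float(np.min(fy)) - mg)
                      + abs(float(result.feet_force[-1, 1]) - mg))

    total = float(np.dot(np.asarray(w.w), phi))
    return CostBreakdown(alpha=alpha, phi=phi, total=total,
                         c0=np.asarray(c0, float), cf=np.asarray(cf, float),
                         c_goal=c_goal)


def total_cost(breakdown: CostBreakdown, weights: CostWeights | None = None) -> float:
    """Weighted sum of the ten terms."""
    w = weights or CostWeights()
    return float(np.dot(np.asarray(w.w), breakdown.phi))
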