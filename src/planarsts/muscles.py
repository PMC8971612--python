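"""Hill-type musculotendon mechanics.

Each of the eight lumped muscle groups is a Hill-type unit: first-order
activation dynamics drive a contractile element whose force is the product
of activation, an active force-length curve (Gaussian, peak at the optimal
fibre length), a force-velocity curve (hyperbolic concentric branch, capped
eccentric branch) and the maximum isometric force, plus an exponential
passive-elastic contribution.  The default tendon is rigid, so fibre
kinematics follow directly from the musculotendon path, which in turn is
the integral of the (constant or polynomial) moment-arm model over the
spanned joint angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import _kernels as K
from .params import JOINTS, HillCurves, MusculotendonParams, PlanarModel, _arm_value


class EquilibrationError(RuntimeError):
    """No fibre-length root in the physiological bracket for a muscle."""


@dataclass
class MuscleForceSample:
    """Force decomposition of one muscle at one instant."""

    active_force: float
    passive_force: float
    fiber_length_norm: float
    fiber_velocity_norm: float
    tendon_force: float


def activation_derivative(excitation: float, activation: float,
                          params: MusculotendonParams) -> float:
    """First-order approach of activation toward excitation (1/s).

    The rate constant is ``act_tau`` while the excitation exceeds the
    activation and ``deact_tau`` otherwise.
    """
    if not 0.0 <= excitation <= 1.0:
        raise ValueError(f"excitation {excitation} outside [0, 1]")
    if not 0.0 <= activation <= 1.0:
        raise ValueError(f"activation {activation} outside [0, 1]")
    tau = params.act_tau if excitation > activation else params.deact_tau
    return (excitation - activation) / tau


def active_force_length(l_norm: float, curves: HillCurves | None = None) -> float:
    """Active force-length multiplier in [0, 1], peak 1 at l_norm = 1."""
    cv = curves or HillCurves()
    return float(K.fl_active(float(l_norm), cv.fl_width))


def force_velocity(v_norm: float, curves: HillCurves | None = None) -> float:
    """Force-velocity multiplier: 0 at max shortening, 1 isometric, >1 eccentric."""
    cv = curves or HillCurves()
    return float(K.fv_hill(float(v_norm), cv.fv_a, cv.fv_ecc_max, cv.fv_ecc_c))


def passive_force_length(l_norm: float, curves: HillCurves | None = None) -> float:
    """Passive multiplier: ~0 up to the optimal length, rising exponentially."""
    cv = curves or HillCurves()
    return float(K.fp_passive(float(l_norm), cv.fp_k, cv.fp_strain))


def compute_force(params: MusculotendonParams, activation: float,
                  l_norm: float, v_norm: float = 0.0,
                  curves: HillCurves | None = None) -> MuscleForceSample:
    """Tendon force under the rigid-tendon assumption.

    ``F = f_max (a FL(l) FV(v) cos(pennation) + FP(l))``.
    """
    if not 0.0 <= activation <= 1.0:
        raise ValueError(f"activation {activation} outside [0, 1]")
    cv = curves or HillCurves()
    cos_pen = math.cos(params.pennation_opt)
    active = (params.f_max * activation * active_force_length(l_norm, cv)
              * force_velocity(v_norm, cv) * cos_pen)
    passive = params.f_max * passive_force_length(l_norm, cv)
    return MuscleForceSample(active_force=active, passive_force=passive,
                             fiber_length_norm=float(l_norm),
                             fiber_velocity_norm=float(v_norm),
                             tendon_force=active + passive)


def moment_arm(params: MusculotendonParams, q, joint: str) -> float:
    """Moment arm (m) at a posture; positive drives the joint positive."""
    if joint not in params.spans:
        raise ValueError(f"muscle {params.name} does not span joint {joint!r}")
    qj = float(np.asarray(q, dtype=float)[JOINTS.index(joint)])
    return _arm_value(params.arms[joint], qj)


def path_length_and_velocity(params: MusculotendonParams, q, qdot) -> tuple[float, float]:
    """Musculotendon path length (m) and lengthening velocity (m/s).

    The path is the moment-arm integral: ``dL/dq_j = -arm_j(q_j)``, so
    constant arms give ``L = L_ref - sum_j r_j q_j``.
    """
    q = np.asarray(q, dtype=float)
    qdot = np.asarray(qdot, dtype=float)
    plen = params.path_length_ref
    pvel = 0.0
    for joint in params.spans:
        j = JOINTS.index(joint)
        arm = params.arms[joint]
        if isinstance(arm, (int, float)):
            plen -= float(arm) * q[j]
        else:
            coeffs = list(arm)
            plen -= sum(c * q[j] ** (k + 1) / (k + 1) for k, c in enumerate(coeffs))
        pvel -= _arm_value(arm, q[j]) * qdot[j]
    return plen, pvel


def fiber_length(params: MusculotendonParams, q) -> float:
    """Rigid-tendon fibre length from the path geometry (m)."""
    plen, _ = path_length_and_velocity(params, q, np.zeros(3))
    return (plen - params.tendon_slack_length) / math.cos(params.pennation_opt)


def equilibrate(model: PlanarModel, q, activation: float = 0.05,
                elastic_tendon: bool = False,
                tendon_strain_at_fmax: float = 0.04) -> dict:
    """Initial fibre/tendon state with fibre and tendon forces balanced.

    Rigid tendon (default): the fibre length is fixed by the path and no
    root-finding is needed.  With ``elastic_tendon`` a linear-elastic
    tendon (stiffness ``f_max / (strain * slack)``) is balanced against
    the fibre force by bisection on the equilibrium residual.

    Returns ``{muscle name: (fiber_length m, tendon_force N)}``.
    """
    out = {}
    cv = model.curves
    for m in model.muscles:
        plen, _ = path_length_and_velocity(m, q, np.zeros(3))
        cos_pen = math.cos(m.pennation_opt)
        if not elastic_tendon or m.tendon_slack_length == 0.0:
            lf = (plen - m.tendon_slack_length) / cos_pen
            ln = max(lf / m.optimal_fiber_length, 1e-6)
            s = compute_force(m, activation, ln, 0.0, cv)
            out[m.name] = (lf, max(s.tendon_force, 0.0))
            continue

        k_t = m.f_max / (tendon_strain_at_fmax * m.tendon_slack_length)

        def residual(lf):
            ln = max(lf / m.optimal_fiber_length, 1e-6)
            f_fiber = compute_force(m, activation, ln, 0.0, cv).tendon_force
            lt = plen - lf * cos_pen
            f_tendon = max(k_t * (lt - m.tendon_slack_length), 0.0)
            return f_fiber - f_tendon

        lo = 1e-4 * m.optimal_fiber_length
        hi = 2.5 * m.optimal_fiber_length
        if residual(lo) * residual(hi) > 0:
            raise EquilibrationError(
                f"no equilibrium root for muscle {m.name} in "
                f"[{lo:.4f}, {hi:.4f}] m at activation {activation}")
        lf = brentq(residual, lo, hi, xtol=1e-12)
        ln = max(lf / m.optimal_fiber_length, 1e-6)
        out[m.name] = (lf, compute_force(m, activation, ln, 0.0, cv).tendon_force)
    return out


def joint_torques(model: PlanarModel, q, qdot, activations,
                  packed=None) -> tuple[np.ndarray, np.ndarray]:
    """All-muscle tendon forces and the summed joint torques at one state."""
    from .dynamics import pack_model

    pm = packed or pack_model(model)
    n = model.n_muscles
    force = np.zeros(max(n, 1))
    fact = np.zeros(max(n, 1))
    fpas = np.zeros(max(n, 1))
    tau = np.zeros(3)
    if n:
        K.muscle_forces_and_torques(
            np.asarray(q, float), np.asarray(qdot, float),
            np.asarray(activations, float)[:n],
            pm.fmax, pm.lopt, pm.slack, pm.cospen, pm.vmax, pm.L0, pm.armc,
            pm.fl_width, pm.fv_a, pm.fv_emax, pm.fv_ec, pm.fp_k, pm.fp_strain,
            force, fact, fpas, tau)
    return force[:n], tau
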