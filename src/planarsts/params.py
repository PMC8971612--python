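"""Model description: segments, muscles, joint limits, chair contact.

The model is a planar (sagittal) three-link chain — shank, thigh,
torso+head+arms (HAT) — standing on a foot welded to the ground, actuated
by eight lumped Hill-type musculotendon units and, optionally, two external
assistance point forces at the torso centre of mass.  Joint angles are
zero in the upright posture; positive directions are ankle dorsiflexion,
knee flexion and hip flexion.  Generalized coordinates are ordered
``q = (ankle, knee, hip)``.

Anthropometric defaults are scaled to a 75 kg / 1.70 m adult male from
standard segment-inertia tables (de Leva-style fractions), with everything
above the pelvis plus both arms and the head lumped into the HAT segment.
Muscle maximum isometric strengths are the published values for the eight
lumped muscle groups; fibre/tendon geometry and moment arms are documented
package defaults (constant moment arms by default), all overridable from a
YAML/JSON config.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

DEG = math.pi / 180.0

JOINTS = ("ankle", "knee", "hip")

#: Maximum isometric strengths (N) of the eight lumped muscle groups at
#: zero strength deficit.
MAX_ISOMETRIC_FORCE = {
    "ILPSO": 2697.3,
    "GMAX": 3337.6,
    "RF": 2191.7,
    "HAMS": 4105.5,
    "VAS": 9594.0,
    "GAS": 4690.6,
    "SOL": 7925.0,
    "TA": 2116.8,
}

MUSCLE_ORDER = ("ILPSO", "GMAX", "RF", "HAMS", "VAS", "GAS", "SOL", "TA")


class ConfigurationError(ValueError):
    """Raised when a model configuration violates a physical invariant."""


@dataclass
class SegmentParams:
    """A rigid segment of the chain.

    ``com_offset`` is measured from the segment's ground-side (distal in
    the chain sense: ankle for the shank, knee for the thigh, hip for the
    HAT) joint along the segment axis.
    """

    name: str
    mass: float          # kg
    length: float        # m
    com_offset: float    # m from ground-side joint, along the segment axis
    inertia: float       # kg m^2 about the segment COM
    com_forward: float = 0.0  # m, perpendicular (anterior) COM component

    def validate(self) -> None:
        if not self.mass > 0:
            raise ConfigurationError(f"segment {self.name}: mass must be > 0, got {self.mass}")
        if not self.length > 0:
            raise ConfigurationError(f"segment {self.name}: length must be > 0, got {self.length}")
        if not 0.0 <= self.com_offset <= self.length:
            raise ConfigurationError(
                f"segment {self.name}: com_offset {self.com_offset} outside [0, {self.length}]"
            )
        if self.inertia < 0:
            raise ConfigurationError(f"segment {self.name}: inertia must be >= 0")


@dataclass
class JointLimits:
    """Physiological range of a joint plus the ligament limit-spring curve.

    The restoring torque is identically zero strictly inside
    ``(lower, upper)`` and rises exponentially (continuously from zero)
    outside: ``T = -scale*(exp(rate*(q-upper)) - 1)`` beyond the upper
    limit and mirrored below the lower limit.  Angles in degrees.
    """

    joint: str
    lower: float  # degrees
    upper: float  # degrees
    scale: float = 5.0     # N m
    rate: float = 30.0     # 1/rad
    damping: float = 15.0  # N m s/rad, active only outside the range

    def validate(self) -> None:
        if self.joint not in JOINTS:
            raise ConfigurationError(f"unknown joint {self.joint!r}")
        if not self.lower < self.upper:
            raise ConfigurationError(f"joint {self.joint}: lower {self.lower} !< upper {self.upper}")
        if self.scale < 0 or self.rate <= 0:
            raise ConfigurationError(f"joint {self.joint}: invalid spring params")


@dataclass
class ChairContact:
    """Point-on-point kinematic constraint between femur head and chair.

    ``seat_point`` is the ground-frame anchor of the constrained femur-head
    (hip-centre) point.  The constraint is released for good once its
    vertical reaction turns non-compressive or the tangential reaction
    exceeds the friction cone ``|F_x| > mu * F_y``.
    """

    seat_point: tuple[float, float]
    mu: float
    engaged: bool = True

    def validate(self) -> None:
        if not self.mu > 0:
            raise ConfigurationError(f"chair: mu must be > 0, got {self.mu}")


@dataclass
class MusculotendonParams:
    """Parameters of one lumped Hill-type musculotendon unit.

    Moment arms default to constants per spanned joint (``arms`` maps
    joint name to either a float or polynomial coefficients in the joint
    angle, lowest order first).  The path length is anchored so the fibre
    sits at its optimal length at the reference posture ``q_ref`` (see
    :func:`default_model_config`).
    """

    name: str
    f_max: float                   # N, maximum isometric force (unscaled)
    optimal_fiber_length: float    # m
    tendon_slack_length: float     # m
    pennation_opt: float = 0.0     # rad
    v_max: float = 10.0            # optimal fiber lengths / s
    act_tau: float = 0.01          # s
    deact_tau: float = 0.04        # s
    arms: dict = field(default_factory=dict)   # joint -> float | [c0, c1, ...]
    path_length_ref: float = 0.0   # m, path length at q = 0

    @property
    def spans(self) -> tuple[str, ...]:
        return tuple(j for j in JOINTS if j in self.arms)

    def validate(self) -> None:
        if not self.f_max > 0:
            raise ConfigurationError(f"muscle {self.name}: f_max must be > 0")
        if not self.optimal_fiber_length > 0:
            raise ConfigurationError(f"muscle {self.name}: optimal_fiber_length must be > 0")
        if self.tendon_slack_length < 0:
            raise ConfigurationError(f"muscle {self.name}: tendon_slack_length must be >= 0")
        if not self.spans:
            raise ConfigurationError(f"muscle {self.name}: spans no joint")


@dataclass
class HillCurves:
    """Coefficients of the Hill characteristic curves (shared by muscles).

    Active force-length is a Gaussian of width ``fl_width``; force-velocity
    is the hyperbolic Hill curve with curvature ``fv_a`` on the concentric
    side and a saturating eccentric branch with plateau ``fv_ecc_max``;
    the passive curve is an exponential toe reaching 1.0 at strain
    ``fp_strain``.
    """

    fl_width: float = 0.45
    fv_a: float = 0.25
    fv_ecc_max: float = 1.4
    fv_ecc_c: float = 0.075
    fp_k: float = 4.0
    fp_strain: float = 0.6


@dataclass
class FootGeometry:
    heel_x: float = -0.05   # m
    toe_x: float = 0.17     # m
    ankle: tuple[float, float] = (0.0, 0.09)  # m, ground frame
    mass: float = 1.0       # kg, welded to ground
    com: tuple[float, float] = (0.06, 0.03)   # m, ground frame

    @property
    def midpoint_x(self) -> float:
        """x of the mid point between heel and toes (the Feet_x reference)."""
        return 0.5 * (self.heel_x + self.toe_x)

    def validate(self) -> None:
        if not self.heel_x < self.toe_x:
            raise ConfigurationError("foot: heel_x must be < toe_x")
        if self.mass <= 0:
            raise ConfigurationError("foot: mass must be > 0")


@dataclass
class AssistParams:
    """Two independent point forces (vertical, horizontal) at the torso COM."""

    enabled: bool = False
    f_max: float = 200.0   # N per component
    tau: float = 0.1       # s, first-order activation time constant
    directions: tuple = ((0.0, 1.0), (1.0, 0.0))


@dataclass
class IntegratorConfig:
    dt: float = 0.001            # s, fixed RK4 step
    qdot_cap: float = 50.0       # rad/s divergence abort
    baumgarte_beta: float = 20.0  # 1/s constraint stabilization


@dataclass
class PlanarModel:
    """Full physical description of the planar sit-to-stand model."""

    segments: list            # shank, thigh, torso(HAT) — ground-side first
    muscles: list
    limits: list
    chair: ChairContact
    foot: FootGeometry
    gravity: float = 9.80665  # m/s^2
    lumbar_lock_angle: float = -10.0  # degrees, bookkeeping only (locked joint)
    strength_scale: float = 1.0
    sitting_posture: tuple = (15.0, 85.0, 78.0)  # degrees (ankle, knee, hip)
    joint_damping: tuple = (3.0, 3.0, 3.0)       # N m s/rad, passive viscous
    curves: HillCurves = field(default_factory=HillCurves)
    assist: AssistParams = field(default_factory=AssistParams)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)

    def validate(self) -> None:
        if len(self.segments) != 3:
            raise ConfigurationError("model needs exactly 3 segments (shank, thigh, torso)")
        for s in self.segments:
            s.validate()
        for m in self.muscles:
            m.validate()
        if len(self.limits) != 3:
            raise ConfigurationError("model needs limits for ankle, knee, hip")
        for l in self.limits:
            l.validate()
        self.chair.validate()
        self.foot.validate()
        if not 0.0 < self.strength_scale <= 1.0:
            raise ConfigurationError(
                f"strength_scale must be in (0, 1], got {self.strength_scale}"
            )

    # ---- convenience accessors -------------------------------------------------

    @property
    def muscle_names(self) -> list[str]:
        return [m.name for m in self.muscles]

    @property
    def n_muscles(self) -> int:
        return len(self.muscles)

    @property
    def n_actuators(self) -> int:
        return self.n_muscles + (2 if self.assist.enabled else 0)

    @property
    def total_mass(self) -> float:
        """Total model mass including the welded foot (kg)."""
        return sum(s.mass for s in self.segments) + self.foot.mass

    @property
    def weight(self) -> float:
        """mg of the whole model (N)."""
        return self.total_mass * self.gravity

    def limit_for(self, joint: str) -> JointLimits:
        for l in self.limits:
            if l.joint == joint:
                return l
        raise KeyError(joint)

    def muscle(self, name: str) -> MusculotendonParams:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(name)

    def sitting_q(self) -> np.ndarray:
        return np.array([a * DEG for a in self.sitting_posture])


# ---------------------------------------------------------------------------
# Default configuration
# ---------------------------------------------------------------------------

# Constant moment arms (m) per muscle and joint; sign convention: positive
# arm produces torque in the positive joint direction (dorsiflexion / knee
# flexion / hip flexion).  Values are round numbers in the physiological
# range for each group.
_DEFAULT_ARMS = {
    "ILPSO": {"hip": 0.045},
    "GMAX": {"hip": -0.090},
    "RF": {"hip": 0.040, "knee": -0.045},
    "HAMS": {"hip": -0.080, "knee": 0.025},
    "VAS": {"knee": -0.050},
    "GAS": {"knee": 0.020, "ankle": -0.050},
    "SOL": {"ankle": -0.050},
    "TA": {"ankle": 0.040},
}

_DEFAULT_LOPT = {  # m, effective optimal fiber lengths of the lumped groups
    "ILPSO": 0.20, "GMAX": 0.26, "RF": 0.18, "HAMS": 0.18,
    "VAS": 0.20, "GAS": 0.11, "SOL": 0.10, "TA": 0.11,
}

_DEFAULT_SLACK = {  # m, tendon slack lengths (rigid tendon: only shifts path anchor)
    "ILPSO": 0.10, "GMAX": 0.12, "RF": 0.32, "HAMS": 0.33,
    "VAS": 0.16, "GAS": 0.38, "SOL": 0.26, "TA": 0.22,
}

# Where along the sit-to-stand sweep each muscle's fibre sits at its optimal
# length (fraction of the seated joint angles).  The hip extensors anchor
# closer to standing so their seated passive stretch brakes trunk slump the
# way posterior hip structures do.
_DEFAULT_REF_FRACTION = {
    "ILPSO": 0.6, "GMAX": 0.6, "RF": 0.6, "HAMS": 0.6,
    "VAS": 0.6, "GAS": 0.6, "SOL": 0.6, "TA": 0.6,
}


def default_model_config() -> dict:
    """Default model configuration as a plain dict (YAML/JSON-shaped).

    Anthropometry scales a 75 kg / 1.70 m male with everything but the
    right leg lumped into the HAT segment, so the segment masses plus the
    welded foot sum to the full body mass.
    """
    body_mass = 75.0
    foot_mass = 1.03       # de Leva foot fraction
    shank_mass = 3.25
    thigh_mass = 10.62
    hat_mass = body_mass - foot_mass - shank_mass - thigh_mass  # 60.10
    return {
        "body_mass": body_mass,
        "height": 1.70,
        "gravity": 9.80665,
        "strength_scale": 1.0,
        "assistance": False,
        "lumbar_lock_angle": -10.0,
        "sitting_posture": {"ankle": 15.0, "knee": 85.0, "hip": 78.0},
        "reference_posture_fraction": 0.6,
        "joint_damping": [3.0, 3.0, 3.0],
        "segments": [
            {"name": "shank", "mass": shank_mass, "length": 0.40,
             "com_offset": 0.225, "inertia": 0.0475},
            {"name": "thigh", "mass": thigh_mass, "length": 0.41,
             "com_offset": 0.244, "inertia": 0.1855},
            {"name": "torso", "mass": hat_mass, "length": 0.52,
             "com_offset": 0.32, "com_forward": 0.03, "inertia": 3.0},
        ],
        "foot": {"heel_x": -0.055, "toe_x": 0.17, "ankle": [0.0, 0.09],
                 "mass": foot_mass, "com": [0.06, 0.03]},
        "limits": [
            {"joint": "ankle", "lower": -40.0, "upper": 30.0},
            {"joint": "knee", "lower": 0.0, "upper": 140.0},
            {"joint": "hip", "lower": -30.0, "upper": 120.0},
        ],
        "limit_spring": {"scale": 5.0, "rate": 30.0, "damping": 15.0},
        "chair": {"mu": 0.8, "seat_point": None},  # None -> from sitting posture
        "muscles": [
            {
                "name": name,
                "f_max": MAX_ISOMETRIC_FORCE[name],
                "optimal_fiber_length": _DEFAULT_LOPT[name],
                "tendon_slack_length": _DEFAULT_SLACK[name],
                "pennation_opt": 0.0,
                "v_max": 10.0,
                "act_tau": 0.01,
                "deact_tau": 0.04,
                "reference_fraction": _DEFAULT_REF_FRACTION[name],
                "arms": dict(_DEFAULT_ARMS[name]),
            }
            for name in MUSCLE_ORDER
        ],
        "curves": {},
        "integrator": {"dt": 0.001, "qdot_cap": 50.0, "baumgarte_beta": 20.0},
    }


def _chain_positions(segments: Sequence[SegmentParams], foot: FootGeometry,
                     q: np.ndarray) -> dict:
    """Joint and COM positions of the chain at angles ``q`` (radians)."""
    L = [s.length for s in segments]
    phi = np.array([q[0], q[0] - q[1], q[0] - q[1] + q[2]])
    u = np.stack([np.sin(phi), np.cos(phi)], axis=-1)
    ankle = np.asarray(foot.ankle, dtype=float)
    knee = ankle + L[0] * u[0]
    hip = knee + L[1] * u[1]
    coms = [
        ankle + segments[0].com_offset * u[0],
        knee + segments[1].com_offset * u[1],
        hip + segments[2].com_offset * u[2],
    ]
    return {"ankle": ankle, "knee": knee, "hip": hip, "coms": coms, "phi": phi, "u": u}


def build_model(config: dict | str | Path) -> PlanarModel:
    """Construct a :class:`PlanarModel` from a configuration.

    ``config`` may be a dict, or a path to a YAML/JSON file.  Muscle
    maximum isometric forces are scaled uniformly by ``strength_scale``
    (a value of 0.4 represents a 60 % strength deficit).  The chair anchor
    defaults to the femur-head position the sitting posture implies, so the
    constraint is exactly satisfied at the initial state.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    cfg = copy.deepcopy(config)

    segments = [SegmentParams(**s) for s in cfg["segments"]]
    foot_cfg = dict(cfg["foot"])
    foot_cfg["ankle"] = tuple(foot_cfg["ankle"])
    foot_cfg["com"] = tuple(foot_cfg["com"])
    foot = FootGeometry(**foot_cfg)

    body_mass = cfg.get("body_mass")
    if body_mass is not None:
        seg_mass = sum(s.mass for s in segments)
        if abs(seg_mass + foot.mass - body_mass) > 1e-6:
            raise ConfigurationError(
                f"segment masses ({seg_mass:.3f}) + foot ({foot.mass:.3f}) "
                f"!= body_mass ({body_mass:.3f})"
            )

    spring = cfg.get("limit_spring", {})
    limits = [
        JointLimits(joint=l["joint"], lower=l["lower"], upper=l["upper"],
                    scale=l.get("scale", spring.get("scale", 5.0)),
                    rate=l.get("rate", spring.get("rate", 30.0)),
                    damping=l.get("damping", spring.get("damping", 15.0)))
        for l in cfg["limits"]
    ]

    strength_scale = float(cfg.get("strength_scale", 1.0))
    if not 0.0 < strength_scale <= 1.0:
        raise ConfigurationError(f"strength_scale must be in (0, 1], got {strength_scale}")

    sitting = cfg.get("sitting_posture", {"ankle": 15.0, "knee": 85.0, "hip": 78.0})
    sitting_deg = (sitting["ankle"], sitting["knee"], sitting["hip"])
    q_sit = np.array([a * DEG for a in sitting_deg])
    frac = float(cfg.get("reference_posture_fraction", 0.6))

    muscles = []
    for mcfg in cfg["muscles"]:
        mcfg = dict(mcfg)
        arms = mcfg.pop("arms")
        m_frac = float(mcfg.pop("reference_fraction", frac))
        m = MusculotendonParams(arms=arms, **mcfg)
        m.f_max *= strength_scale  # uniform strength deficit scaling
        # Anchor the path so the fibre is at optimal length at this
        # muscle's reference posture.
        q_ref = m_frac * q_sit
        arm_at = {j: _arm_value(arms[j], q_ref[JOINTS.index(j)]) for j in m.spans}
        path_at_ref = (m.optimal_fiber_length * math.cos(m.pennation_opt)
                       + m.tendon_slack_length)
        # path(q) = path_ref0 - sum_j integral of arm; constant arms: -r*q
        m.path_length_ref = path_at_ref + sum(
            arm_at[j] * q_ref[JOINTS.index(j)] for j in m.spans
        )
        muscles.append(m)

    chair_cfg = cfg.get("chair", {})
    seat_point = chair_cfg.get("seat_point")
    if seat_point is None:
        seat_point = tuple(_chain_positions(segments, foot, q_sit)["hip"])
    if "mu" not in chair_cfg or chair_cfg["mu"] is None:
        raise ConfigurationError("chair.mu is required (no default is silently applied)")
    chair = ChairContact(seat_point=tuple(seat_point), mu=float(chair_cfg["mu"]))

    model = PlanarModel(
        segments=segments,
        muscles=muscles,
        limits=limits,
        chair=chair,
        foot=foot,
        gravity=float(cfg.get("gravity", 9.80665)),
        lumbar_lock_angle=float(cfg.get("lumbar_lock_angle", -10.0)),
        strength_scale=strength_scale,
        sitting_posture=sitting_deg,
        joint_damping=tuple(cfg.get("joint_damping", (3.0, 3.0, 3.0))),
        curves=HillCurves(**cfg.get("curves", {})),
        assist=AssistParams(enabled=bool(cfg.get("assistance", False))),
        integrator=IntegratorConfig(**cfg.get("integrator", {})),
    )
    model.validate()
    return model


def _arm_value(arm, q: float) -> float:
    """Evaluate a moment-arm model (constant or polynomial, lowest order first)."""
    if isinstance(arm, (int, float)):
        return float(arm)
    coeffs = list(arm)
    out = 0.0
    for c in reversed(coeffs):
        out = out * q + c
    return out


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(cfg: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


def model_config_with_scale(strength_scale: float, assistance: bool = False) -> dict:
    cfg = default_model_config()
    cfg["strength_scale"] = strength_scale
    cfg["assistance"] = assistance
    return cfg
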