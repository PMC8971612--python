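"""Open-loop excitation parameterization and assistance actuators.

A candidate motion is encoded as a flat decision vector: one gene per
actuator per 0.1 s node (nodes at ``dt, 2 dt, ..., t_max``) plus one gene
for the movement duration ``t_f``.  Excitations are piecewise linear
between the fixed default activation at ``t_0`` and the node values.
With 8 muscles, 0.1 s nodes and ``t_max`` = 1.6 s this yields 129 decision
variables unassisted and 161 with the two assistance point forces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K

DEFAULT_MUSCLE_ACTIVATION = 0.05
T_MAX_DEFAULT = 1.6
NODE_DT = 0.1
T_F_MIN = 0.1  # exclusive lower bound of the duration gene


class LayoutError(ValueError):
    pass


@dataclass
class ControlLayout:
    """Shape of the decision vector for a given actuator set."""

    actuator_names: list
    n_muscles: int
    t_max: float = T_MAX_DEFAULT
    node_dt: float = NODE_DT

    def __post_init__(self):
        n = self.t_max / self.node_dt
        if abs(n - round(n)) > 1e-9:
            raise LayoutError(f"t_max {self.t_max} is not a multiple of node_dt {self.node_dt}")
        self.n_nodes = int(round(n))

    @property
    def n_actuators(self) -> int:
        return len(self.actuator_names)

    @property
    def size(self) -> int:
        return self.n_actuators * self.n_nodes + 1

    @property
    def default_activation(self) -> np.ndarray:
        """At t_0 every actuator sits at its default activation (not a gene)."""
        d = np.full(self.n_actuators, DEFAULT_MUSCLE_ACTIVATION)
        d[self.n_muscles:] = 0.0  # assistance starts unpowered
        return d


@dataclass
class ControlTrajectory:
    """Piecewise-linear excitation trajectories plus the duration t_f."""

    layout: ControlLayout
    node_values: np.ndarray  # (n_actuators, n_nodes), in [0, 1]
    t_f: float
    clamped: bool = False    # True when decoding clipped out-of-range genes

    @property
    def node_times(self) -> np.ndarray:
        return self.layout.node_dt * np.arange(1, self.layout.n_nodes + 1)

    def excitation_at(self, t: float) -> np.ndarray:
        """Per-actuator excitation at time ``t`` in [0, t_f]."""
        if t < 0 or t > self.t_f + 1e-12:
            raise ValueError(f"t={t} outside [0, t_f={self.t_f}]")
        out = np.empty(self.layout.n_actuators)
        K.excitation_at_time(float(t), self.node_values, self.layout.node_dt,
                             self.layout.default_activation, out)
        return out

    def to_frame(self):
        """Node-resolution table (time column + one column per actuator)."""
        import pandas as pd

        times = np.concatenate([[0.0], self.node_times])
        vals = np.column_stack([self.layout.default_activation, self.node_values])
        data = {"time": times}
        for i, name in enumerate(self.layout.actuator_names):
            data[name] = vals[i]
        return pd.DataFrame(data)


def decision_vector_size(n_actuators: int, t_max: float = T_MAX_DEFAULT,
                         dt: float = NODE_DT) -> int:
    """Number of decision variables: actuators x nodes + the t_f gene."""
    n = t_max / dt
    if abs(n - round(n)) > 1e-9:
        raise LayoutError(f"t_max {t_max} is not an integral multiple of dt {dt}")
    return n_actuators * int(round(n)) + 1


def encode(traj: ControlTrajectory) -> np.ndarray:
    """Flatten a trajectory into a decision vector (genes row-major by actuator)."""
    lay = traj.layout
    vec = np.empty(lay.size)
    vec[:-1] = traj.node_values.ravel()
    vec[-1] = traj.t_f
    return vec


def decode(vector: np.ndarray, layout: ControlLayout) -> ControlTrajectory:
    """Decision vector -> trajectory; out-of-range genes are clamped.

    Node genes clamp to [0, 1]; the duration gene clamps to
    ``(T_F_MIN, t_max]``.  Clamping is recorded on the trajectory.
    """
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (layout.size,):
        raise LayoutError(f"expected vector of length {layout.size}, got {vector.shape}")
    nodes = vector[:-1].reshape(layout.n_actuators, layout.n_nodes)
    clipped = np.clip(nodes, 0.0, 1.0)
    t_f = float(vector[-1])
    t_f_c = min(max(t_f, T_F_MIN + 1e-6), layout.t_max)
    clamped = bool(np.any(clipped != nodes) or t_f_c != t_f)
    return ControlTrajectory(layout=layout, node_values=clipped.copy(),
                             t_f=t_f_c, clamped=clamped)


def sitting_guess(layout: ControlLayout) -> np.ndarray:
    """Initial optimizer mean: the model simply sitting in the chair.

    All muscle nodes at the default activation (0.05), assistance nodes at
    zero, and the duration gene at ``t_max``.
    """
    vec = np.empty(layout.size)
    nodes = np.repeat(layout.default_activation[:, None], layout.n_nodes, axis=1)
    vec[:-1] = nodes.ravel()
    vec[-1] = layout.t_max
    return vec


@dataclass
class AssistActuator:
    """An assistance point force along a fixed direction at the torso COM.

    Excitations pass through first-order activation dynamics with time
    constant ``tau``; the force is ``activation * f_max * direction`` and
    is bounded to [0, f_max] per component.
    """

    direction: tuple
    f_max: float = 200.0
    tau: float = 0.1
    activation: float = 0.0

    def force(self) -> np.ndarray:
        if not 0.0 <= self.activation <= 1.0:
            raise ValueError(f"activation {self.activation} outside [0, 1]")
        d = np.asarray(self.direction, dtype=float)
        d = d / np.linalg.norm(d)
        return self.activation * self.f_max * d


def assist_force_at(actuator: AssistActuator) -> np.ndarray:
    """Instantaneous assistance force (N) of one actuator."""
    return actuator.force()


def layout_for_model(model, t_max: float = T_MAX_DEFAULT) -> ControlLayout:
    names = list(model.muscle_names)
    if model.assist.enabled:
        names += ["assist_vertical", "assist_horizontal"]
    return ControlLayout(actuator_names=names, n_muscles=model.n_muscles, t_max=t_max)
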