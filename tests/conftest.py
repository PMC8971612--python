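import numpy as np
import pytest

import planarsts as ps


@pytest.fixture(scope="session")
def default_model():
    return ps.build_model(ps.default_model_config())


@pytest.fixture(scope="session")
def packed(default_model):
    return ps.pack_model(default_model)


@pytest.fixture(scope="session")
def layout(default_model):
    return ps.layout_for_model(default_model)


@pytest.fixture(scope="session")
def sitting_rollout(default_model, layout):
    """Roll-out of the sitting initial guess (quasi-static reference case)."""
    traj = ps.decode(ps.sitting_guess(layout), layout)
    return ps.simulate(default_model, traj)


@pytest.fixture(scope="session")
def active_rollout(default_model, layout):
    """A deterministic non-trivial roll-out: hand-shaped stand-up attempt.

    Ramps the knee/hip extensors and plantarflexors; not an optimized
    motion, but it releases the seat and produces rich series for the
    dynamics/cost/analysis oracles.
    """
    nodes = np.repeat(layout.default_activation[:, None], layout.n_nodes, axis=1)
    names = layout.actuator_names
    ramp = np.clip(np.linspace(0.2, 1.4, layout.n_nodes), 0, 1)
    for muscle, level in [("VAS", 0.55), ("GMAX", 0.45), ("HAMS", 0.2),
                          ("SOL", 0.25), ("TA", 0.12)]:
        nodes[names.index(muscle)] = np.clip(level * ramp, 0, 1)
    traj = ps.ControlTrajectory(layout=layout, node_values=nodes, t_f=1.4)
    return ps.simulate(default_model, traj)


@pytest.fixture(scope="session")
def seated_sway_rollout(default_model, layout):
    """Smooth seated trunk sway: seat engaged throughout, no limit impacts.

    Gentle hip-flexor/extensor bells rock the torso while the chair keeps
    carrying the body — a physiological, exactly trackable trajectory.
    """
    nodes = np.repeat(layout.default_activation[:, None], layout.n_nodes, axis=1)
    names = layout.actuator_names
    tt = np.linspace(0.1, 1.6, layout.n_nodes)
    bells = {"ILPSO": (0.07, 0.4, 0.2)}
    for muscle, (lvl, t0, w) in bells.items():
        prof = lvl * np.exp(-0.5 * ((tt - t0) / w) ** 2)
        nodes[names.index(muscle)] = np.clip(np.maximum(prof, 0.05), 0, 1)
    traj = ps.ControlTrajectory(layout=layout, node_values=nodes, t_f=1.5)
    res = ps.simulate(default_model, traj)
    assert res.t_seat_release is None, "sway fixture must stay seated"
    return res
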