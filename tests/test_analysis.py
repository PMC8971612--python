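"""Trajectory analysis: inverse-dynamics torques, muscle contributions,
phase segmentation, EMG envelopes and movement event detection."""

import numpy as np
import pytest

import planarsts as ps
from planarsts.analysis import (SegmentationError, contribution_percentages,
                                detect_sts_events, muscle_torque_contributions,
                                process_emg, resultant_joint_torques,
                                segment_phases)
from planarsts.fixtures import synthetic_emg, toy_trajectory
from planarsts.params import DEG


# -- inverse dynamics ---------------------------------------------------------

def test_static_upright_torques_balance_gravity_moments(default_model):
    """At rest the residual torques are minus the gravity moments per joint
    (the actuation needed to hold the posture)."""
    from planarsts.simulate import SimulationResult

    n = 3
    q = np.tile([0.05, 0.1, -0.05], (n, 1))
    res = SimulationResult(
        times=np.linspace(0, 0.01, n), q=q, qdot=np.zeros((n, 3)),
        qddot=np.zeros((n, 3)), activations=np.zeros((n, 8)),
        muscle_force=np.zeros((n, 8)), muscle_active=np.zeros((n, 8)),
        muscle_passive=np.zeros((n, 8)), limit_torque=np.zeros((n, 3)),
        seat_force=np.zeros((n, 2)), feet_force=np.zeros((n, 2)),
        feet_moment=np.zeros(n), com=np.zeros((n, 2)),
        com_vel=np.zeros((n, 2)), assist_force=np.zeros((n, 2)),
        zmp_x=np.zeros(n), t_seat_release=None, t_f=0.01,
        model_weight=default_model.weight,
        feet_ref_x=default_model.foot.midpoint_x, n_muscles=8)
    tau = resultant_joint_torques(res, default_model)

    # manual oracle: the holding torque opposes gravity, i.e. minus the
    # summed m g * (horizontal COM offset) moments of the segments above
    # each joint, signed by the joint's positive direction
    segs = default_model.segments
    L = [s.length for s in segs]
    c = [s.com_offset for s in segs]
    g = default_model.gravity
    qi = q[0]
    phi = np.array([qi[0], qi[0] - qi[1], qi[0] - qi[1] + qi[2]])
    ankle = np.asarray(default_model.foot.ankle)
    u = np.stack([np.sin(phi), np.cos(phi)], axis=1)
    knee = ankle + L[0] * u[0]
    hip = knee + L[1] * u[1]
    e = np.stack([np.cos(phi), -np.sin(phi)], axis=1)
    fwd = [getattr(s_, "com_forward", 0.0) for s_ in segs]
    coms = [ankle + c[0] * u[0] + fwd[0] * e[0],
            knee + c[1] * u[1] + fwd[1] * e[1],
            hip + c[2] * u[2] + fwd[2] * e[2]]
    m = [s.mass for s in segs]
    # ankle (dorsiflexion positive): oppose gravity about the ankle
    tau_ankle = -sum(mi * g * (ci[0] - ankle[0]) for mi, ci in zip(m, coms))
    # knee (flexion positive): the chain above rotates opposite to the
    # absolute thigh angle, flipping the sign
    tau_knee = sum(mi * g * (ci[0] - knee[0]) for mi, ci in zip(m[1:], coms[1:]))
    # hip (flexion positive): oppose torso gravity about the hip
    tau_hip = -m[2] * g * (coms[2][0] - hip[0])
    np.testing.assert_allclose(tau[0], [tau_ankle, tau_knee, tau_hip],
                               atol=1e-9)


def test_zero_gravity_static_torques_vanish():
    cfg = ps.default_model_config()
    cfg["gravity"] = 0.0
    model = ps.build_model(cfg)
    tau = ps.inverse_dynamics(model, np.array([0.3, 0.5, -0.2]),
                              np.zeros(3), np.zeros(3))
    np.testing.assert_allclose(tau, 0.0, atol=1e-12)


def test_fd_id_round_trip_on_simulation(default_model, active_rollout):
    """Resultant torques equal muscle + limit-spring + damping contributions."""
    decomp = muscle_torque_contributions(active_rollout, default_model)
    reconstructed = (decomp.per_muscle.sum(axis=0) + decomp.limit_spring
                     + decomp.damping)
    err = np.max(np.abs(decomp.resultant - reconstructed))
    assert err < 1e-3  # N m


def test_contributions_zero_for_unspanned_joints(default_model, active_rollout):
    decomp = muscle_torque_contributions(active_rollout, default_model)
    idx = {n: i for i, n in enumerate(decomp.muscle_names)}
    # VAS spans only the knee; SOL only the ankle
    assert np.all(decomp.per_muscle[idx["VAS"], :, 0] == 0)
    assert np.all(decomp.per_muscle[idx["VAS"], :, 2] == 0)
    assert np.all(decomp.per_muscle[idx["SOL"], :, 1] == 0)
    # HAMS opposes VAS at the knee
    hams_knee = decomp.per_muscle[idx["HAMS"], :, 1]
    vas_knee = decomp.per_muscle[idx["VAS"], :, 1]
    mask = (np.abs(hams_knee) > 1e-6) & (np.abs(vas_knee) > 1e-6)
    assert np.all(np.sign(hams_knee[mask]) == -np.sign(vas_knee[mask]))


def test_contribution_percentages_on_constructed_series(default_model,
                                                        active_rollout):
    decomp = muscle_torque_contributions(active_rollout, default_model)
    pct = contribution_percentages(decomp)
    idx = {n: i for i, n in enumerate(decomp.muscle_names)}
    for (name, joint), value in pct.items():
        j = ("ankle", "knee", "hip").index(joint)
        contr = decomp.per_muscle[idx[name], :, j]
        res = decomp.resultant[:, j]
        expected = 100.0 * contr[np.argmax(np.abs(contr))] \
            / res[np.argmax(np.abs(res))]
        assert value == pytest.approx(expected)


# -- phase segmentation -------------------------------------------------------

def _result_with_hip(times, hip, t_sr):
    from planarsts.simulate import SimulationResult

    n = len(times)
    q = np.zeros((n, 3))
    q[:, 2] = hip
    return SimulationResult(
        times=times, q=q, qdot=np.zeros((n, 3)), qddot=np.zeros((n, 3)),
        activations=np.zeros((n, 8)), muscle_force=np.zeros((n, 8)),
        muscle_active=np.zeros((n, 8)), muscle_passive=np.zeros((n, 8)),
        limit_torque=np.zeros((n, 3)), seat_force=np.zeros((n, 2)),
        feet_force=np.zeros((n, 2)), feet_moment=np.zeros(n),
        com=np.zeros((n, 2)), com_vel=np.zeros((n, 2)),
        assist_force=np.zeros((n, 2)), zmp_x=np.zeros(n),
        t_seat_release=t_sr, t_f=float(times[-1]), n_muscles=8)


def test_segment_phases_known_boundaries():
    t = np.arange(0, 1.0001, 0.001)
    hip = 1.2 - (t - 0.6) ** 2  # peak hip flexion at 0.6 s
    seg = segment_phases(_result_with_hip(t, hip, t_sr=0.4))
    assert seg.t_phase1_end == pytest.approx(0.4)
    assert seg.t_phase2_end == pytest.approx(0.6, abs=1e-3)
    assert seg.t_phase3_end == pytest.approx(1.0)


def test_segment_phases_monotone_decrease_puts_boundary_at_release():
    t = np.arange(0, 1.0001, 0.001)
    hip = 1.5 - t
    seg = segment_phases(_result_with_hip(t, hip, t_sr=0.4))
    assert seg.t_phase2_end == pytest.approx(0.4)


def test_segment_phases_requires_seat_release():
    t = np.arange(0, 1.0001, 0.001)
    with pytest.raises(SegmentationError):
        segment_phases(_result_with_hip(t, np.ones_like(t), t_sr=None))


def test_phases_ordered_on_simulated_transfer(active_rollout):
    seg = segment_phases(active_rollout)
    assert seg.t_phase1_end <= seg.t_phase2_end <= seg.t_phase3_end
    assert seg.t_phase1_end >= active_rollout.times[0]
    assert seg.t_phase3_end == pytest.approx(active_rollout.t_f)


# -- EMG pipeline -------------------------------------------------------------

def test_emg_zero_in_zero_out():
    env = process_emg(np.zeros(4000), fs=2000.0, mvc_peak=0.5)
    np.testing.assert_allclose(env, 0.0, atol=1e-12)


def test_emg_inband_sine_envelope_matches_rectified_mean():
    """A 50 Hz unit sine passes the band; the 3 Hz envelope approaches the
    rectified-sine mean 2/pi."""
    fs = 2000.0
    t = np.arange(0, 4.0, 1 / fs)
    env = process_emg(np.sin(2 * np.pi * 50 * t), fs=fs, mvc_peak=1.0)
    mid = env[int(1.5 * fs):int(2.5 * fs)]
    assert np.mean(mid) == pytest.approx(2 / np.pi, rel=0.05)


def test_emg_below_band_attenuated():
    fs = 2000.0
    t = np.arange(0, 4.0, 1 / fs)
    raw = np.sin(2 * np.pi * 1.0 * t)
    env = process_emg(raw, fs=fs, mvc_peak=1.0)
    assert np.max(env[int(fs):int(3 * fs)]) < 0.1 * (2 / np.pi)


def test_emg_rejects_low_sampling_rate():
    with pytest.raises(ValueError, match="Nyquist"):
        process_emg(np.zeros(100), fs=500.0, mvc_peak=1.0)
    with pytest.raises(ValueError):
        process_emg(np.zeros(100), fs=2000.0, mvc_peak=0.0)


def test_emg_amplitude_linearity():
    rng = np.random.default_rng(4)
    fs = 2000.0
    raw = rng.standard_normal(8000)
    e1 = process_emg(raw, fs, mvc_peak=1.0)
    e3 = process_emg(3.0 * raw, fs, mvc_peak=1.0)
    np.testing.assert_allclose(e3, 3.0 * e1, rtol=1e-8, atol=1e-12)


def test_emg_normalized_by_mvc():
    t, sig, mvc = synthetic_emg(seed=1, fs=2000.0)
    env1 = process_emg(sig[:, 0], 2000.0, mvc_peak=mvc)
    env2 = process_emg(sig[:, 0], 2000.0, mvc_peak=2 * mvc)
    np.testing.assert_allclose(env1, 2 * env2, rtol=1e-10)


# -- event detection ----------------------------------------------------------

def test_constant_angle_has_no_events():
    fs = 200.0
    assert detect_sts_events(np.full(1000, 80.0), fs) == (None, None)


def test_known_onset_detected_within_half_window():
    fs = 200.0
    t, hip = toy_trajectory(onset=1.0, flexion_rate=40.0, fs=fs)
    t_start, t_end = detect_sts_events(hip, fs)
    assert t_start == pytest.approx(1.0, abs=0.05)  # half the 0.1 s window
    assert t_end is not None and t_end > t_start


def test_below_threshold_velocity_no_events():
    fs = 200.0
    t, hip = toy_trajectory(onset=1.0, flexion_rate=15.0, fs=fs)
    # flexion never exceeds 20 deg/s -> no start event
    t_start, _ = detect_sts_events(hip, fs, threshold=20.0)
    assert t_start is None


def test_too_short_series_rejected():
    with pytest.raises(ValueError):
        detect_sts_events(np.zeros(10), fs=200.0)
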