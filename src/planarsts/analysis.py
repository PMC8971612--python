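"""Post-hoc trajectory analysis and experimental signal utilities.

Inverse-dynamics joint torques (muscles excluded, chair/assist supplied as
external forces), per-muscle torque contributions, the three-phase
segmentation of sit-to-stand (trunk flexion to seat-off, seat-off to peak
hip flexion, trunk extension to upright), plus the surface-EMG envelope
pipeline and threshold-based movement event detection used to align
simulated and recorded trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sig

from . import _kernels as K
from .dynamics import pack_model, inverse_dynamics
from .params import JOINTS, PlanarModel
from .simulate import SimulationResult


class SegmentationError(ValueError):
    """Phase segmentation undefined: the model never left the chair."""


@dataclass
class PhaseSegmentation:
    """Boundaries of the three STS phases (seconds).

    Phase 1 ends at seat release, phase 2 at maximal hip flexion, phase 3
    at the end of the movement.
    """

    t_phase1_end: float
    t_phase2_end: float
    t_phase3_end: float

    def validate(self):
        if not (self.t_phase1_end <= self.t_phase2_end <= self.t_phase3_end):
            raise ValueError("phase boundaries out of order")


@dataclass
class TorqueDecomposition:
    """Resultant joint torques and their actuator-wise contributions."""

    times: np.ndarray
    resultant: np.ndarray        # (n, 3) N m
    per_muscle: np.ndarray       # (n_muscles, n, 3)
    limit_spring: np.ndarray     # (n, 3)
    damping: np.ndarray          # (n, 3)
    assist_equivalent: np.ndarray  # (n, 3)
    muscle_names: list


def resultant_joint_torques(result: SimulationResult, model: PlanarModel,
                            packed=None) -> np.ndarray:
    """Inverse dynamics of the recorded kinematics, muscles excluded.

    Seat and assistance forces are applied as external forces; the
    returned generalized-force residual per DOF is what the muscles plus
    passive joint structures must have supplied.
    """
    pm = packed or pack_model(model)
    n = result.n_samples
    tau = np.empty((n, 3))
    for i in range(n):
        tau[i] = inverse_dynamics(model, result.q[i], result.qdot[i],
                                  result.qddot[i],
                                  seat_force=result.seat_force[i],
                                  assist_force=result.assist_force[i],
                                  packed=pm)
    return tau


def muscle_torque_contributions(result: SimulationResult, model: PlanarModel,
                                packed=None) -> TorqueDecomposition:
    """Per-muscle joint torques ``F_tendon x moment arm`` along the motion."""
    pm = packed or pack_model(model)
    n = result.n_samples
    n_mus = model.n_muscles
    per = np.zeros((n_mus, n, 3))
    for mi in range(n_mus):
        for j in range(3):
            c = pm.armc[mi, j]
            if not np.any(c):
                continue
            qj = result.q[:, j]
            arm = c[0] + qj * (c[1] + qj * (c[2] + qj * c[3]))
            per[mi, :, j] = result.muscle_force[:, mi] * arm

    damping = -result.qdot * pm.damping

    assist_eq = np.zeros((n, 3))
    if np.any(result.assist_force):
        for i in range(n):
            assist_eq[i] = K.assist_gen_force(result.q[i], pm.acoef, pm.dphase,
                                              result.assist_force[i, 0],
                                              result.assist_force[i, 1])

    return TorqueDecomposition(
        times=result.times.copy(),
        resultant=resultant_joint_torques(result, model, packed=pm),
        per_muscle=per,
        limit_spring=result.limit_torque.copy(),
        damping=damping,
        assist_equivalent=assist_eq,
        muscle_names=list(model.muscle_names),
    )


def contribution_percentages(decomp: TorqueDecomposition) -> dict:
    """Peak muscle torque as a percentage of the peak resultant per joint."""
    out = {}
    for j, joint in enumerate(JOINTS):
        res = decomp.resultant[:, j]
        peak_res = res[int(np.argmax(np.abs(res)))]
        if peak_res == 0:
            continue
        for mi, name in enumerate(decomp.muscle_names):
            contr = decomp.per_muscle[mi, :, j]
            if not np.any(contr):
                continue
            peak_m = contr[int(np.argmax(np.abs(contr)))]
            out[(name, joint)] = 100.0 * peak_m / peak_res
    return out


def segment_phases(result: SimulationResult) -> PhaseSegmentation:
    """Three-phase segmentation of a successful roll-out.

    Raises :class:`SegmentationError` for failed transfers (no seat
    release).  Peak hip flexion is searched from seat release onward; a
    hip angle that only decreases after release puts the phase-2 boundary
    at the release time itself.
    """
    if result.t_seat_release is None:
        raise SegmentationError("no seat release: sit-to-stand did not occur")
    t_sr = result.t_seat_release
    after = result.times >= t_sr
    hip = result.q[after, 2]
    t_after = result.times[after]
    t_peak = float(t_after[int(np.argmax(hip))])
    seg = PhaseSegmentation(t_phase1_end=float(t_sr), t_phase2_end=t_peak,
                            t_phase3_end=float(result.times[-1]))
    seg.validate()
    return seg


# ---------------------------------------------------------------------------
# Signal utilities
# ---------------------------------------------------------------------------

def process_emg(raw: np.ndarray, fs: float, mvc_peak: float,
                band: tuple = (10.0, 350.0), lowpass: float = 3.0,
                order: int = 4) -> np.ndarray:
    """Surface-EMG linear envelope normalized to a maximum contraction.

    Band-pass (default 10-350 Hz, 4th-order Butterworth), full-wave
    rectify, low-pass (3 Hz) and divide by the MVC peak.  Filtering is
    zero-phase (forward-backward) so envelope timing stays aligned with
    the kinematics.
    """
    raw = np.asarray(raw, dtype=float)
    if fs <= 2.0 * band[1]:
        raise ValueError(
            f"sampling rate {fs} Hz violates Nyquist for the {band[1]} Hz band edge")
    if mvc_peak <= 0:
        raise ValueError("mvc_peak must be > 0")
    sos_bp = sig.butter(order, band, btype="bandpass", fs=fs, output="sos")
    rectified = np.abs(sig.sosfiltfilt(sos_bp, raw))
    sos_lp = sig.butter(order, lowpass, btype="lowpass", fs=fs, output="sos")
    envelope = sig.sosfiltfilt(sos_lp, rectified)
    return envelope / mvc_peak


def detect_sts_events(hip_angle_deg: np.ndarray, fs: float,
                      threshold: float = 20.0, window: float = 0.1):
    """Start/end of a sit-to-stand from the hip angle series (degrees).

    The hip velocity is smoothed with a centred moving average of
    ``window`` seconds; the movement starts when the flexion-direction
    velocity first exceeds ``threshold`` deg/s and ends at the first
    subsequent time the extension-direction velocity falls back below it.
    Returns ``(t_start, t_end)`` with ``None`` for thresholds never
    crossed.
    """
    hip = np.asarray(hip_angle_deg, dtype=float)
    if len(hip) < 3 or len(hip) / fs <= 0.2:
        raise ValueError("series too short for event detection (> 0.2 s needed)")
    t = np.arange(len(hip)) / fs
    vel = np.gradient(hip, t)
    n_win = max(int(round(window * fs)), 1)
    kernel = np.ones(n_win) / n_win
    vel_s = np.convolve(vel, kernel, mode="same")

    above = np.nonzero(vel_s > threshold)[0]
    if len(above) == 0:
        return None, None
    i_start = int(above[0])
    t_start = t[i_start]

    # extension (negative velocity) must first exceed the threshold, then
    # fall back below it
    after = vel_s[i_start:]
    ext = np.nonzero(after < -threshold)[0]
    if len(ext) == 0:
        return t_start, None
    rel = np.nonzero(after[ext[0]:] > -threshold)[0]
    if len(rel) == 0:
        return t_start, None
    return t_start, t[i_start + ext[0] + rel[0]]
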