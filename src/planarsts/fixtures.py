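"""Deterministic, seeded fixture generation.

All test inputs are generated programmatically: model configs across the
20 %-step strength-deficit sweep, band-limited synthetic surface-EMG with
known maximum-contraction peaks, and smooth seated-to-upright reference
joint trajectories for the tracking tools.  The synthetic signals emulate
the *structure* of experimental sit-to-stand recordings (sampled joint
angles, sEMG channels, vertical ground/seat force channels); they carry
none of the physiology of real recordings.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .params import DEG, default_model_config, model_config_with_scale, save_config

FIXTURE_KINDS = ("default_model", "deficit_sweep", "toy_trajectory",
                 "synthetic_emg", "synthetic_reference")

#: The published deficit protocol: strength scaled in steps of 20 %.
DEFICIT_SCALES = (1.0, 0.8, 0.6, 0.4, 0.2)


def deficit_sweep_configs() -> dict:
    """Model configs at strength scales 1.0 ... 0.2 (0-80 % deficit)."""
    return {scale: model_config_with_scale(scale) for scale in DEFICIT_SCALES}


def synthetic_emg(seed: int = 0, fs: float = 1000.0, duration: float = 3.0,
                  n_channels: int = 8, mvc_peak: float = 1.0):
    """Band-limited noise bursts emulating sEMG during one transfer.

    Each channel is white noise band-shaped to 20-250 Hz, amplitude
    modulated by a smooth burst centred mid-trial, scaled so the known
    ``mvc_peak`` is meaningful for normalization.  Returns
    ``(t, signals (n, n_channels), mvc_peak)``.
    """
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    t = np.arange(n) / fs
    out = np.empty((n, n_channels))
    for c in range(n_channels):
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, 1 / fs)
        spec[(f < 20) | (f > 250)] = 0.0
        carrier = np.fft.irfft(spec, n)
        carrier /= max(np.max(np.abs(carrier)), 1e-12)
        centre = duration * (0.35 + 0.3 * rng.random())
        width = 0.25 + 0.15 * rng.random()
        burst = np.exp(-0.5 * ((t - centre) / width) ** 2)
        out[:, c] = 0.6 * mvc_peak * carrier * (0.15 + burst)
    return t, out, mvc_peak


def synthetic_reference(seed: int = 0, duration: float = 1.4, fs: float = 100.0,
                        q_sit_deg=(12.0, 85.0, 85.0), hip_overshoot_deg: float = 12.0):
    """Smooth seated-to-upright joint trajectory for tracking tests.

    A minimum-jerk-like profile takes each joint from the seated angle to
    zero; the hip additionally flexes forward early (trunk lean) so the
    trajectory shows the characteristic hip-flexion peak.  Returns
    ``(times, q (n, 3) radians)``.
    """
    rng = np.random.default_rng(seed)
    n = int(duration * fs) + 1
    t = np.linspace(0.0, duration, n)
    s = t / duration
    blend = 10 * s**3 - 15 * s**4 + 6 * s**5  # minimum-jerk 0 -> 1
    q = np.empty((n, 3))
    for j, q0 in enumerate(q_sit_deg):
        q[:, j] = (1.0 - blend) * q0
    bump = np.sin(np.pi * np.clip(s / 0.55, 0.0, 1.0)) ** 2
    q[:, 2] += hip_overshoot_deg * bump * (1.0 - s)
    q *= DEG
    return t, q


def toy_trajectory(seed: int = 0, fs: float = 200.0, onset: float = 1.0,
                   flexion_rate: float = 40.0):
    """Hip-angle series with known onset/offset for event detection.

    Sitting at 85 deg, trunk flexes at ``flexion_rate`` deg/s from
    ``onset`` for 0.3 s, then extends at 40 deg/s down to the upright
    angle and holds.  Returns ``(t, hip_deg)``.
    """
    t = np.arange(0, 4.0, 1 / fs)
    hip = np.full_like(t, 85.0)
    t1 = onset + 0.3
    flex = (t >= onset) & (t < t1)
    hip[flex] = 85.0 + flexion_rate * (t[flex] - onset)
    peak = 85.0 + flexion_rate * 0.3
    t2 = t1 + (peak - 5.0) / 40.0
    ext = (t >= t1) & (t < t2)
    hip[ext] = peak - 40.0 * (t[ext] - t1)
    hip[t >= t2] = 5.0
    return t, hip


def make_fixture(kind: str, seed: int = 0, out_dir: str | Path = ".") -> list[Path]:
    """Write one fixture family to disk; returns the created paths.

    Identical ``(kind, seed)`` always produce identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    if kind == "default_model":
        p = out_dir / "model_default.yaml"
        save_config(default_model_config(), p)
        paths.append(p)
    elif kind == "deficit_sweep":
        for scale, cfg in deficit_sweep_configs().items():
            p = out_dir / f"model_scale_{int(round(scale * 100)):03d}.yaml"
            save_config(cfg, p)
            paths.append(p)
    elif kind == "toy_trajectory":
        import pandas as pd

        t, hip = toy_trajectory(seed)
        p = out_dir / "toy_hip_angle.csv"
        pd.DataFrame({"time": t, "hip_deg": hip}).to_csv(p, index=False)
        paths.append(p)
    elif kind == "synthetic_emg":
        import pandas as pd

        t, sig, mvc = synthetic_emg(seed)
        p = out_dir / "synthetic_emg.csv"
        df = pd.DataFrame(sig, columns=[f"emg_{c}" for c in range(sig.shape[1])])
        df.insert(0, "time", t)
        df.to_csv(p, index=False)
        paths.append(p)
    elif kind == "synthetic_reference":
        from .io import write_motion

        t, q = synthetic_reference(seed)
        p = out_dir / "synthetic_reference.mot"
        write_motion(p, t, q)
        paths.append(p)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")
    return paths
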