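"""File formats and run bundles.

Time series travel as tidy CSV or as OpenSim-style text Storage files
(.sto/.mot): tab-separated columns with a small header carrying the table
name, ``nRows``/``nColumns`` and an ``endheader`` sentinel, time in the
first column.  Per the .mot convention angles are written in degrees on
disk while the package works in radians in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class StorageParseError(ValueError):
    """Malformed .sto/.mot header, reported with the offending line number."""


def write_storage(path, labels, data, name: str = "planarsts",
                  in_degrees: bool = False) -> None:
    """Write an OpenSim text Storage file (time column first)."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != len(labels):
        raise ValueError(f"data shape {data.shape} does not match {len(labels)} labels")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{name}\n")
        fh.write(f"version=1\n")
        fh.write(f"nRows={data.shape[0]}\n")
        fh.write(f"nColumns={data.shape[1]}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\n")
        fh.write("endheader\n")
        fh.write("\t".join(labels) + "\n")
        for row in data:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_storage(path):
    """Read a text Storage file; returns ``(labels, data, in_degrees)``."""
    path = Path(path)
    labels = None
    meta = {}
    rows = []
    with path.open() as fh:
        lines = fh.readlines()
    i = 0
    for i, line in enumerate(lines):
        s = line.strip()
        if s == "endheader":
            break
        if "=" in s:
            key, _, val = s.partition("=")
            meta[key.strip()] = val.strip()
    else:
        raise StorageParseError(f"{path}: no 'endheader' sentinel found "
                                f"(scanned {len(lines)} lines)")
    body = lines[i + 1:]
    if not body:
        raise StorageParseError(f"{path}: missing column-label line {i + 2}")
    labels = body[0].split()
    for ln, line in enumerate(body[1:], start=i + 3):
        s = line.strip()
        if not s:
            continue
        vals = s.split()
        if len(vals) != len(labels):
            raise StorageParseError(
                f"{path}:{ln}: expected {len(labels)} columns, got {len(vals)}")
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise StorageParseError(f"{path}:{ln}: non-numeric value") from exc
    data = np.asarray(rows, dtype=float)
    if "nRows" in meta and int(meta["nRows"]) != data.shape[0]:
        raise StorageParseError(
            f"{path}: header nRows={meta['nRows']} but {data.shape[0]} data rows")
    if "nColumns" in meta and int(meta["nColumns"]) != len(labels):
        raise StorageParseError(
            f"{path}: header nColumns={meta['nColumns']} but {len(labels)} labels")
    in_degrees = meta.get("inDegrees", "no").lower() in ("yes", "true", "1")
    return labels, data, in_degrees


def write_motion(path, times, q_rad, labels=("ankle", "knee", "hip"),
                 name: str = "coordinates") -> None:
    """Write joint angles as a .mot file (degrees on disk)."""
    data = np.column_stack([times, np.degrees(np.asarray(q_rad, dtype=float))])
    write_storage(path, ["time", *labels], data, name=name, in_degrees=True)


def read_motion(path):
    """Read a .mot/.sto of joint angles; returns ``(times, q_rad, labels)``."""
    labels, data, in_degrees = read_storage(path)
    times = data[:, 0]
    q = data[:, 1:]
    if in_degrees:
        q = np.radians(q)
    return times, q, labels[1:]


def simulation_to_csv(result, path) -> None:
    result.to_frame().to_csv(path, index=False)


def simulation_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"time", "q_ankle", "q_knee", "q_hip"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


@dataclass
class RunBundle:
    """Directory layout of one reproducible run.

    Holds the configuration snapshot, the optimization history, the best
    roll-out series, the cost breakdown log and any analysis outputs so
    every run can be reproduced from its snapshot and seed.
    """

    directory: Path

    def __post_init__(self):
        self.directory = Path(self.directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def path(self, name: str) -> Path:
        return self.directory / name

    def write_config(self, cfg: dict) -> None:
        from .params import save_config

        save_config(cfg, self.path("config.yaml"))

    def write_json(self, name: str, obj: dict) -> None:
        self.path(name).write_text(json.dumps(obj, indent=2, default=_jsonable))

    def write_simulation(self, result, stem: str = "simulation") -> None:
        simulation_to_csv(result, self.path(f"{stem}.csv"))
        self.write_json(f"{stem}.json", result.metadata())
        write_motion(self.path(f"{stem}.mot"), result.times, result.q)

    def write_optimization(self, opt) -> None:
        opt.history_frame().to_csv(self.path("history.csv"), index=False)
        self.write_json("optimization.json", {
            "best_cost": opt.best_cost,
            "restart_log": [list(r) for r in opt.restart_log],
            "best_vector": [float(v) for v in opt.best_vector],
            "best_breakdown": (opt.best_breakdown.as_dict()
                               if opt.best_breakdown else None),
        })


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
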