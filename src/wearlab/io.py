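"""Plain-text file formats: CSV device streams, OpenSim-style .sto series,
JSON events and calibration results."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._quat import check_unit
from .synthetic import ImuSensorStream, ImuTrial

_QUAT = ("qw", "qx", "qy", "qz")
_ACC = ("ax", "ay", "az")
_GYRO = ("gx", "gy", "gz")
_FLOAT_FMT = "%.17g"


def write_imu_table(trial: ImuTrial, path) -> None:
    """CSV with a time column and per-sensor quaternion / acceleration /
    gyro columns (``<sensor>_qw`` etc.)."""
    cols: Dict[str, np.ndarray] = {"time": trial.time}
    for name, s in trial.sensors.items():
        for i, c in enumerate(_QUAT):
            cols[f"{name}_{c}"] = s.quat[:, i]
        for i, c in enumerate(_ACC):
            cols[f"{name}_{c}"] = s.acc[:, i]
        for i, c in enumerate(_GYRO):
            cols[f"{name}_{c}"] = s.gyro[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_imu_table(path) -> ImuTrial:
    """Read a per-sensor IMU CSV back into an :class:`ImuTrial`.

    Quaternions within 1e-3 of unit norm are renormalized, others rejected
    with the offending column named; the time base must be uniform to
    within 1 % jitter.
    """
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError("missing 'time' column")
    t = df["time"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0 or np.any(dt <= 0):
        raise ValueError("time must be strictly increasing")
    if np.ptp(dt) > 0.01 * float(np.median(dt)):
        raise ValueError("non-uniform time base (jitter beyond 1%)")
    rate = 1.0 / float(np.median(dt))

    sensors: Dict[str, ImuSensorStream] = {}
    names = sorted({c.rsplit("_", 1)[0] for c in df.columns if c != "time"})
    for name in names:
        needed = [f"{name}_{c}" for c in _QUAT + _ACC + _GYRO]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        quat = df[[f"{name}_{c}" for c in _QUAT]].to_numpy(dtype=float)
        try:
            quat = check_unit(quat, tol=1e-3, what=f"{name}_q*")
        except ValueError as e:
            raise ValueError(str(e)) from None
        sensors[name] = ImuSensorStream(
            quat=quat,
            acc=df[[f"{name}_{c}" for c in _ACC]].to_numpy(dtype=float),
            gyro=df[[f"{name}_{c}" for c in _GYRO]].to_numpy(dtype=float))
    return ImuTrial(time=t, rate=rate, sensors=sensors,
                    sensor_to_segment={k: k for k in sensors})


def write_sto(names: Sequence[str], data: np.ndarray, time: np.ndarray,
              path, header_name: str = "wearlab") -> None:
    """OpenSim storage format: ``nRows``/``nColumns`` header, ``endheader``,
    tab-delimited body with ``time`` first.

    NaN values are permitted only in CoP-like columns (name contains
    ``_p``) where they mark swing samples, and are written as empty fields;
    NaN anywhere else is rejected.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    time = np.asarray(time, dtype=float)
    if data.shape[0] != len(time):
        raise ValueError("data and time lengths differ")
    if len(names) != data.shape[1]:
        raise ValueError("column-name count does not match data width")
    dt = np.diff(time)
    if len(dt) and np.ptp(dt) > 1e-9 * max(dt[0], 1e-12):
        raise ValueError("time vector must be uniform")
    for j, name in enumerate(names):
        if np.isnan(data[:, j]).any() and "_p" not in name:
            raise ValueError(f"NaN in non-CoP column {name!r}")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{header_name}\nversion=1\n")
        fh.write(f"nRows={data.shape[0]}\nnColumns={data.shape[1] + 1}\n")
        fh.write("inDegrees=no\nendheader\n")
        fh.write("time\t" + "\t".join(names) + "\n")
        for i in range(data.shape[0]):
            row = [_FLOAT_FMT % time[i]]
            for j in range(data.shape[1]):
                v = data[i, j]
                row.append("" if np.isnan(v) else _FLOAT_FMT % v)
            fh.write("\t".join(row) + "\n")


def read_sto(path) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """Read a .sto file -> (column names, data, time)."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    try:
        end = next(i for i, l in enumerate(lines) if l.strip() == "endheader")
    except StopIteration:
        raise ValueError("not a .sto file: no endheader") from None
    cols = lines[end + 1].split("\t")
    if cols[0] != "time":
        raise ValueError("first column must be 'time'")
    body = [l.split("\t") for l in lines[end + 2:] if l]
    arr = np.array([[float(v) if v != "" else np.nan for v in row]
                    for row in body])
    return cols[1:], arr[:, 1:], arr[:, 0]


EXTERNAL_LOADS_COLUMNS = [
    "ground_force_vx", "ground_force_vy", "ground_force_vz",
    "ground_force_px", "ground_force_py", "ground_force_pz",
    "1_ground_force_vx", "1_ground_force_vy", "1_ground_force_vz",
    "1_ground_force_px", "1_ground_force_py", "1_ground_force_pz",
]


def write_external_loads(loads, path) -> None:
    """External loads .sto with the standard ground_force_v/p column dialect
    (unprefixed = right foot, ``1_`` prefixed = left foot)."""
    n = len(loads.time)
    nanp = np.full((n, 3), np.nan)
    cop_r = loads.cop_right if loads.cop_right is not None else nanp
    cop_l = loads.cop_left if loads.cop_left is not None else nanp
    data = np.hstack([loads.right, cop_r, loads.left, cop_l])
    write_sto(EXTERNAL_LOADS_COLUMNS, data, loads.time, path,
              header_name="external_loads")


def write_events_json(events: Mapping[str, np.ndarray], rate: float, path
                      ) -> None:
    """Gait events as JSON with both sample indices and seconds."""
    payload = {
        side: {
            kind: [{"sample": int(i), "time_s": round(float(i) / rate, 9)}
                   for i in np.atleast_1d(arr)]
            for kind, arr in kinds.items()
        }
        for side, kinds in events.items()
    }
    payload["rate_hz"] = rate
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_calibration_json(result, path) -> None:
    from .mtu import MUSCLES
    p = result.params
    payload = {
        "seed": result.seed,
        "initial_objective": result.initial_objective,
        "final_objective": result.final_objective,
        "converged": result.converged,
        "fit_r2": result.fit.r2,
        "rmse_per_kg": result.rmse_per_kg,
        "objective_trace": [float(v) for v in result.objective_trace],
        "muscles": {
            m: {"l_om": float(p.l_om[i]), "l_st": float(p.l_st[i]),
                "strength": float(p.strength[i]),
                "shape_A": float(p.shape_A[i]),
                "f_max": float(p.f_max[i])}
            for i, m in enumerate(MUSCLES)
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
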