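"""Sensor registration, sagittal joint angles, planar ankle inverse
dynamics, cycle normalization and agreement metrics.

The full generalized-coordinate orientation-tracking IK of lab pipelines is
replaced by a direct relative-orientation decomposition: for a sagittal
chain with one sensor per segment the two are equivalent, and the planar
twist about the mediolateral axis is extracted in closed form.  Ankle
torque comes from a planar free-body analysis of the foot.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import stats as _stats
from scipy.spatial.transform import Rotation

from ._quat import (
    GLOBAL_TO_MODEL,
    MODEL_GRAVITY,
    as_rotation,
    cross_z,
    from_rotation,
    twist_about_z,
)
from .kinetics import BodyModel
from .gait_events import GaitPhaseTable
from .preprocess import butterworth_zero_lag
from .synthetic import ImuTrial

log = logging.getLogger(__name__)


@dataclass
class SensorRegistration:
    """Fixed sensor-to-segment rotations estimated from a static pose."""

    rotations: Dict[str, np.ndarray]       # sensor -> scalar-first quaternion
    static_offsets: Dict[str, float]       # assumed static joint angles, rad


@dataclass
class JointAngleSeries:
    """Sagittal knee flexion(+) and ankle dorsiflexion(+) angles, rad."""

    time: np.ndarray
    rate: float
    knee: np.ndarray
    ankle: np.ndarray

    def __post_init__(self):
        for name in ("knee", "ankle"):
            a = getattr(self, name)
            if np.any(np.abs(a) >= np.pi):
                raise ValueError(f"{name} angle out of range (|angle| < pi)")

    @property
    def knee_deg(self) -> np.ndarray:
        return np.degrees(self.knee)

    @property
    def ankle_deg(self) -> np.ndarray:
        return np.degrees(self.ankle)


@dataclass
class TorqueSeries:
    """Ankle dorsi(+)/plantar(-) flexion torque."""

    time: np.ndarray
    rate: float
    torque: np.ndarray          # N m
    body_mass: float
    provenance: str = "ID-IMU"  # ID-reference | ID-IMU | EMG-driven

    @property
    def per_kg(self) -> np.ndarray:
        return self.torque / self.body_mass


@dataclass
class AgreementMetrics:
    r2: Optional[float]
    rmse: float


def _model_frame_rotations(trial: ImuTrial, sensor: str) -> Rotation:
    return GLOBAL_TO_MODEL * as_rotation(trial.sensors[sensor].quat)


def register_sensors_static(static: ImuTrial,
                            default_pose: Optional[Mapping[str, float]] = None,
                            motion_threshold: float = 0.2
                            ) -> SensorRegistration:
    """Estimate fixed sensor-to-segment rotations from a static pose.

    The registration maps each sensor's mean static orientation onto the
    segment's default-pose orientation (neutral upright unless
    ``default_pose`` supplies per-segment sagittal angles, rad).  Trials
    with angular-velocity RMS above ``motion_threshold`` rad/s on any
    sensor are rejected.
    """
    if static.time[-1] - static.time[0] < 2.0:
        raise ValueError("static trial must span at least 2 s")
    pose = dict(default_pose or {})
    rotations: Dict[str, np.ndarray] = {}
    for sensor, stream in static.sensors.items():
        rms = float(np.sqrt(np.mean(stream.gyro**2)))
        if rms > motion_threshold:
            raise ValueError(
                f"static trial rejected: sensor {sensor!r} angular-velocity "
                f"RMS {rms:.3f} rad/s exceeds {motion_threshold} rad/s")
        mean_model = (GLOBAL_TO_MODEL * as_rotation(stream.quat)).mean()
        segment = static.sensor_to_segment.get(sensor, sensor)
        default = Rotation.from_euler("z", pose.get(segment, 0.0))
        rotations[sensor] = from_rotation(mean_model.inv() * default)
    return SensorRegistration(rotations=rotations, static_offsets=dict(pose))


def segment_angles(trial: ImuTrial, reg: SensorRegistration
                   ) -> Dict[str, np.ndarray]:
    """Registered sagittal segment angles (rad) per sensor."""
    out = {}
    for sensor in trial.sensors:
        rot = _model_frame_rotations(trial, sensor) * as_rotation(
            reg.rotations[sensor])
        out[trial.sensor_to_segment.get(sensor, sensor)] = np.unwrap(
            twist_about_z(from_rotation(rot)))
    return out


def joint_angles(trial: ImuTrial, reg: SensorRegistration,
                 foot: str = "foot_impaired") -> JointAngleSeries:
    """Knee and ankle angles from registered segment orientations.

    Knee flexion is the sagittal component of the thigh->shank relative
    rotation, ankle dorsiflexion that of shank->foot; both are zero in the
    registered neutral pose.
    """
    ang = segment_angles(trial, reg)
    for need in ("thigh", "shank", foot):
        if need not in ang:
            raise KeyError(f"missing sensor stream for segment {need!r}")
    knee = ang["thigh"] - ang["shank"]
    ankle = ang[foot] - ang["shank"]
    return JointAngleSeries(time=trial.time, rate=trial.rate,
                            knee=knee, ankle=ankle)


def ankle_inverse_dynamics(foot_pos: np.ndarray, foot_quat: np.ndarray,
                           foot_acc_model: np.ndarray,
                           grf: np.ndarray, cop: np.ndarray,
                           body: BodyModel, rate: float,
                           filter_hz: Optional[float] = 3.0,
                           provenance: str = "ID-IMU") -> TorqueSeries:
    """Planar free-body ankle torque of the impaired foot.

    tau = I_f alpha_f + [r_(com-ankle) x m_f (a_com - g)]_z
        - [(p_cop - p_ankle) x F_grf]_z

    with sagittal z-components; swing samples (NaN CoP or zero force) drop
    the GRF moment.  ``foot_acc_model`` is the true (gravity-removed) foot
    CoM acceleration in the model frame; the angular acceleration is
    obtained by twice-differentiating the sagittal foot angle after
    ``filter_hz`` zero-lag low-pass filtering.
    """
    n = len(foot_pos)
    for name, arr in (("grf", grf), ("cop", cop),
                      ("foot_acc_model", foot_acc_model)):
        if len(arr) != n:
            raise ValueError(f"misaligned series: {name} has {len(arr)} "
                             f"samples, foot kinematics {n}")
    theta = np.unwrap(twist_about_z(foot_quat))
    if filter_hz:
        theta = butterworth_zero_lag(theta, filter_hz, rate, kind="low")
    alpha = np.gradient(np.gradient(theta, edge_order=2), edge_order=2) * rate**2

    rot = as_rotation(foot_quat)
    p_ankle = np.asarray(foot_pos, dtype=float) + rot.apply(body.ankle_offset)
    r_ca = np.asarray(foot_pos, dtype=float) - p_ankle   # CoM relative to ankle
    m_f = body.masses["foot_impaired"]
    tau = (body.foot_inertia_z * alpha
           + cross_z(r_ca, m_f * (np.asarray(foot_acc_model) - MODEL_GRAVITY)))
    r_cop = np.asarray(cop, dtype=float) - p_ankle
    f = np.asarray(grf, dtype=float)
    loaded = ~np.isnan(r_cop[:, 0]) & (np.linalg.norm(f, axis=1) > 0)
    tau = tau - np.where(loaded, cross_z(np.nan_to_num(r_cop), f), 0.0)
    time = np.arange(n) / rate
    return TorqueSeries(time=time, rate=rate, torque=tau,
                        body_mass=body.mass, provenance=provenance)


def normalize_cycles(series: np.ndarray, phases: GaitPhaseTable,
                     n_points: int = 101
                     ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample each IC->IC cycle to ``n_points`` (0-100 % of the cycle).

    Returns (cycles x n_points matrix, mean curve, sd curve).
    """
    bounds = phases.cycle_bounds()
    if not bounds:
        raise ValueError("no complete gait cycles")
    x = np.asarray(series, dtype=float)
    grid = np.linspace(0.0, 1.0, n_points)
    rows = []
    for a, b in bounds:
        src = np.linspace(0.0, 1.0, b - a + 1)
        rows.append(np.interp(grid, src, x[a:b + 1]))
    mat = np.vstack(rows)
    return mat, mat.mean(axis=0), mat.std(axis=0)


def agreement_metrics(reference: np.ndarray, estimate: np.ndarray,
                      mass: Optional[float] = None,
                      r2_variant: str = "pearson") -> AgreementMetrics:
    """Shape (R^2) and amplitude (RMSE) agreement between aligned series.

    R^2 is the squared Pearson correlation by default — a pure shape
    measure, insensitive to offset and gain; ``r2_variant="sse"`` selects
    the 1 - SSE/SST definition instead.  With ``mass`` given, the RMSE is
    additionally divided by it (per-kg torque comparisons).  Zero-variance
    input leaves the Pearson R^2 undefined (None) with a warning.
    """
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape or ref.size < 3:
        raise ValueError("series must share a length of at least 3")
    if not (np.isfinite(ref).all() and np.isfinite(est).all()):
        raise ValueError("series must be finite")
    rmse = float(np.sqrt(np.mean((ref - est) ** 2)))
    if mass:
        rmse /= mass
    if r2_variant == "sse":
        sst = float(np.sum((ref - ref.mean()) ** 2))
        if sst == 0:
            warnings.warn("zero-variance reference: R^2 undefined")
            return AgreementMetrics(r2=None, rmse=rmse)
        return AgreementMetrics(
            r2=1.0 - float(np.sum((ref - est) ** 2)) / sst, rmse=rmse)
    if r2_variant != "pearson":
        raise ValueError("r2_variant must be 'pearson' or 'sse'")
    if np.std(ref) == 0 or np.std(est) == 0:
        warnings.warn("zero-variance input: R^2 undefined")
        return AgreementMetrics(r2=None, rmse=rmse)
    r, _ = _stats.pearsonr(ref, est)
    return AgreementMetrics(r2=float(r**2), rmse=rmse)
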