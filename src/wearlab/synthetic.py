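"""Self-consistent synthetic walking trials.

Every downstream stage of the wearable pipeline (gait-event detection, GRF
estimation, the smooth-transition split, CoP progression, planar inverse
dynamics, EMG envelope extraction) is validated against trials produced
here, where segment kinematics, IMU readings, EMG and the external loads
are all generated from one closed-form description of planar gait and are
therefore mutually consistent by construction.

Model of the gait cycle (impaired-side cycle runs IC -> next IC):

* stance occupies ``duty_factor`` of the cycle, swing the rest; the
  contralateral foot runs the same cycle shifted by half a period, so both
  double-support intervals last ``duty_factor - 0.5`` of the cycle each;
* the foot is exactly flat (origin and orientation frozen) on the foot-flat
  interval ``[rho, duty - rho]`` of the cycle; heel-strike and push-off
  rotations are C4-smooth polynomial steps whose angular-rate peaks sit
  exactly at the prescribed IC and TC instants — these peaks are what the
  IC/TC detector is meant to find;
* small out-of-sagittal "wiggle" angles with a circular (quadrature) phase
  keep the 3D gyro channels busy throughout the motion interval so that the
  foot-flat criterion (simultaneous quiet in all three axes) cannot fire
  mid-swing;
* the pelvis advances at the configured speed with a double-frequency
  vertical bob, which gives the classic double-peaked vertical GRF once
  Newton's summation is applied;
* left/right loads follow an exclusive-support/cosine-ramp sharing rule and
  the CoP rolls heel -> calcaneus CoM -> toe per stance.

Trajectories are C4 piecewise polynomials, so numerical differentiation at
the IMU rate is well behaved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional

import numpy as np
from scipy import signal as _signal

from . import anthropometry as anth
from ._quat import (
    MODEL_GRAVITY,
    MODEL_TO_GLOBAL,
    as_rotation,
    from_rotation,
    quat_about_z,
)

SEGMENTS = ("pelvis", "thigh", "shank", "foot_impaired", "foot_contra")

MUSCLES = (
    "tibialis_anterior",
    "extensor_hallucis_longus",
    "gastrocnemius_medialis",
    "gastrocnemius_lateralis",
    "soleus",
    "peroneus_brevis",
    "peroneus_longus",
)

N_EMG_CHANNELS = 64
NOISY_LABEL = "noisy"


# ---------------------------------------------------------------------------
# smooth building blocks (C4 at interval ends)

def smoothstep(u: np.ndarray) -> np.ndarray:
    """9th-order smoothstep: 0->1 on [0,1] with zero 1st..4th derivatives
    at both ends; clamped outside."""
    u = np.clip(u, 0.0, 1.0)
    return u**5 * (126.0 - 420.0 * u + 540.0 * u**2 - 315.0 * u**3 + 70.0 * u**4)


def bump(u: np.ndarray) -> np.ndarray:
    """Unit-peak bump on [0,1], zero with 4 derivatives at the ends."""
    u = np.clip(u, 0.0, 1.0)
    return (4.0 * u * (1.0 - u)) ** 5


def sine_step(u: np.ndarray) -> np.ndarray:
    """0->1 step whose acceleration is a single sinusoid period (minimal
    high-frequency content; C1 in acceleration at the ends)."""
    u = np.clip(u, 0.0, 1.0)
    return u - np.sin(2 * np.pi * u) / (2 * np.pi)


def lift_bump(u: np.ndarray) -> np.ndarray:
    """Unit-peak C2 bump built from two harmonics only (band-limited)."""
    u = np.clip(u, 0.0, 1.0)
    return ((1.0 - np.cos(2 * np.pi * u)) / 2.0) ** 2


def _vonmises_bump(phase: np.ndarray, centre: float, width: float, amp: float) -> np.ndarray:
    """Smooth periodic activation bump on the 0..1 gait cycle."""
    kappa = 1.0 / max(width, 1e-6) ** 2
    return amp * np.exp(kappa * (np.cos(2 * np.pi * (phase - centre)) - 1.0))


def default_envelope_profiles() -> Dict[str, Callable[[np.ndarray], np.ndarray]]:
    """Gait-phase-locked activation profiles for the seven shank muscles.

    Dorsiflexors fire around heel strike and through swing; the triceps
    surae and peroneals fire through mid/late stance (push-off).  Values
    are in [0, 1] over the 0..100 % cycle.
    """

    def prof(*bumps):
        def f(phase):
            phase = np.asarray(phase, dtype=float) % 1.0
            out = np.zeros_like(phase)
            for c, w, a in bumps:
                out = out + _vonmises_bump(phase, c, w, a)
            return np.clip(out, 0.0, 1.0)
        return f

    return {
        "tibialis_anterior": prof((0.03, 0.22, 0.95), (0.82, 0.30, 0.65)),
        "extensor_hallucis_longus": prof((0.05, 0.25, 0.55), (0.85, 0.30, 0.45)),
        "gastrocnemius_medialis": prof((0.42, 0.28, 1.0)),
        "gastrocnemius_lateralis": prof((0.44, 0.28, 0.85)),
        "soleus": prof((0.45, 0.30, 1.0)),
        "peroneus_brevis": prof((0.40, 0.30, 0.55)),
        "peroneus_longus": prof((0.38, 0.30, 0.60)),
    }


def default_channel_map(n_channels: int = N_EMG_CHANNELS,
                        n_noisy: int = 8) -> List[str]:
    """Assign the 64 grid channels: 8 per muscle plus a noisy set."""
    per = (n_channels - n_noisy) // len(MUSCLES)
    labels: List[str] = []
    for m in MUSCLES:
        labels.extend([m] * per)
    labels.extend([NOISY_LABEL] * (n_channels - len(labels)))
    return labels


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SyntheticConfig:
    """Study conditions of a synthetic walking trial.

    Defaults mirror the recorded protocol: 100 Hz IMUs, 2000 Hz 64-channel
    EMG, at least 10 gait cycles, and the post-stroke cohort's mean height
    (1.775 m) and mass (94.2 kg).  The IMU noise levels are implementation
    defaults chosen for testability (the source recordings do not
    characterize sensor noise).
    """

    cadence: float = 100.0            # steps/min
    walking_speed: float = 1.1        # m/s
    n_cycles: int = 10
    duty_factor: float = 0.6          # stance fraction per foot
    height: float = 1.775             # m
    mass: float = 94.2                # kg
    imu_rate: float = 100.0           # Hz
    emg_rate: float = 2000.0          # Hz
    imu_noise_acc_sd: float = 0.02    # m/s^2
    imu_noise_gyro_sd: float = 0.005  # rad/s
    rng_seed: int = 0
    impaired_side: str = "left"
    #: sensor-mount offsets, segment -> scalar-first quaternion
    mount_offsets: Dict[str, np.ndarray] = field(default_factory=dict)
    envelope_profiles: Dict[str, Callable] = field(
        default_factory=default_envelope_profiles)
    channel_map: List[str] = field(default_factory=default_channel_map)

    # shape parameters of the planar gait construction
    rocker_fraction: float = 0.06     # heel-strike / push-off rotation, cycle
    heelstrike_angle: float = 0.30    # rad, dorsiflexed foot posture at IC
    pushoff_angle: float = 0.45       # rad, plantarflexion at TC
    swing_clearance: float = 0.05     # m, foot lift
    swing_overshoot: float = 0.25     # rad, extra dorsiflexion mid-swing
    pelvis_bob: float = 0.02          # m, vertical CoM excursion amplitude
    wiggle_angle: float = 0.035       # rad, out-of-sagittal foot wiggle
    wiggle_freq: float = 1.5          # Hz

    def __post_init__(self):
        if not (0.5 < self.duty_factor < 0.8):
            raise ValueError("duty_factor must lie in (0.5, 0.8)")
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        if self.walking_speed <= 0:
            raise ValueError("walking_speed must be positive")
        if self.n_cycles < 2:
            raise ValueError("n_cycles must be >= 2")
        if len(self.channel_map) != N_EMG_CHANNELS:
            raise ValueError(
                f"channel_map must cover {N_EMG_CHANNELS} channels, "
                f"got {len(self.channel_map)}")
        allowed = set(MUSCLES) | {NOISY_LABEL}
        bad = [l for l in self.channel_map if l not in allowed]
        if bad:
            raise ValueError(f"unknown channel labels: {sorted(set(bad))}")
        if 2 * self.rocker_fraction >= self.duty_factor - 0.5 + 0.5:
            raise ValueError("rocker_fraction too large for the duty factor")

    @property
    def cycle_time(self) -> float:
        """Stride period, s (a stride is two steps)."""
        return 120.0 / self.cadence

    @property
    def stride_length(self) -> float:
        return self.walking_speed * self.cycle_time

    @property
    def duration(self) -> float:
        return self.n_cycles * self.cycle_time


# ---------------------------------------------------------------------------
# domain containers

@dataclass
class SegmentPose:
    pos: np.ndarray   # (N, 3) m, model frame
    quat: np.ndarray  # (N, 4) scalar-first, model frame


@dataclass
class SegmentPoseSeries:
    time: np.ndarray
    rate: float
    segments: Dict[str, SegmentPose]

    def __post_init__(self):
        dt = np.diff(self.time)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-9 * max(1.0, dt[0])):
            raise ValueError("time must be strictly increasing and uniform")
        for name, seg in self.segments.items():
            norms = np.linalg.norm(seg.quat, axis=-1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise ValueError(f"non-unit quaternion in segment {name!r}")


@dataclass
class ImuSensorStream:
    quat: np.ndarray  # (N, 4) scalar-first, sensor orientation, global z-up frame
    acc: np.ndarray   # (N, 3) m/s^2, sensor-local specific force
    gyro: np.ndarray  # (N, 3) rad/s, sensor-local angular velocity


@dataclass
class ImuTrial:
    time: np.ndarray
    rate: float
    sensors: Dict[str, ImuSensorStream]
    sensor_to_segment: Dict[str, str]


@dataclass
class GroundTruth:
    """Known-answer reference for one synthetic trial."""

    time: np.ndarray
    rate: float
    # event times, s
    ic_impaired: np.ndarray
    tc_impaired: np.ndarray
    ic_contra: np.ndarray
    tc_contra: np.ndarray
    # foot-flat intervals (start, end) in s, per impaired/contra foot
    ff_impaired: np.ndarray
    ff_contra: np.ndarray
    # loads in the model frame
    grf_total: np.ndarray     # (N, 3) N
    grf_impaired: np.ndarray
    grf_contra: np.ndarray
    cop_impaired: np.ndarray  # (N, 3) m, NaN during swing
    cop_contra: np.ndarray
    # kinematics / kinetics
    knee_angle: np.ndarray    # rad, flexion +
    ankle_angle: np.ndarray   # rad, dorsiflexion +
    foot_angle_impaired: np.ndarray
    ankle_torque: np.ndarray  # N m, impaired ankle, plantarflexion -
    activations: np.ndarray   # (N, 7), muscle order = MUSCLES
    duty_factor: float
    cycle_time: float


# ---------------------------------------------------------------------------
# closed-form planar kinematics

def _foot_angle(phase: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Sagittal foot angle over the cycle: dorsiflexed heel contact ->
    flat -> push-off plantarflexion -> swing reposition."""
    d, rho = cfg.duty_factor, cfg.rocker_fraction
    th_hs, th_po = cfg.heelstrike_angle, cfg.pushoff_angle
    p = np.asarray(phase, dtype=float) % 1.0
    theta = np.zeros_like(p)

    # heel rocker, wraps around IC at phase 0: theta_hs -> 0
    m = p >= 1.0 - rho
    theta[m] = th_hs * (1.0 - smoothstep((p[m] - (1.0 - rho)) / (2 * rho)))
    m = p < rho
    theta[m] = th_hs * (1.0 - smoothstep((p[m] + rho) / (2 * rho)))
    # foot flat [rho, d - rho): exactly zero (already)
    # push-off [d - rho, d + rho): 0 -> -theta_po, rate peak at TC
    m = (p >= d - rho) & (p < d + rho)
    theta[m] = -th_po * smoothstep((p[m] - (d - rho)) / (2 * rho))
    # swing reposition [d + rho, 1 - rho): -theta_po -> +theta_hs, with a
    # mid-swing dorsiflexion overshoot (keeps the swing gyro busy)
    m = (p >= d + rho) & (p < 1.0 - rho)
    v = (p[m] - (d + rho)) / (1.0 - d - 2 * rho)
    theta[m] = (-th_po + (th_po + th_hs) * smoothstep(v)
                + cfg.swing_overshoot * bump(v))
    return theta


def _wiggle_window(phase: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """1 during foot motion, exactly 0 on the foot-flat interval.

    The ramps span only half a rocker so the wiggle channels fall quiet
    before foot-flat begins and wake only after it ends (the zero-lag
    detection filter smears edges symmetrically; tighter ramps keep the
    detected foot-flat interval close to the prescribed one).
    """
    d, rho = cfg.duty_factor, cfg.rocker_fraction
    half = 0.5 * rho
    p = np.asarray(phase, dtype=float) % 1.0
    w = np.ones_like(p)
    w[(p >= half) & (p < d - half)] = 0.0
    m = (p >= d - half) & (p < d)
    w[m] = smoothstep((p[m] - (d - half)) / half)
    m = p < half
    w[m] = 1.0 - smoothstep(p[m] / half)
    return w


def _knee_profile(phase: np.ndarray) -> np.ndarray:
    """Two-wave knee flexion profile (rad, flexion positive, >= 0)."""
    p = np.asarray(phase, dtype=float) % 1.0
    return (0.12
            + 0.18 * np.exp(8.0 * (np.cos(2 * np.pi * (p - 0.15)) - 1.0))
            + 0.55 * np.exp(6.0 * (np.cos(2 * np.pi * (p - 0.73)) - 1.0))
            - 0.08 * np.cos(2 * np.pi * (p - 0.45)))


def _thigh_profile(phase: np.ndarray) -> np.ndarray:
    p = np.asarray(phase, dtype=float) % 1.0
    return 0.04 + 0.28 * np.cos(2 * np.pi * p + 0.35)


def _foot_x(phase_global: np.ndarray, cfg: SyntheticConfig,
            offset_cycles: float) -> np.ndarray:
    """Anterior foot-origin position; frozen over stance, smoothstep advance
    of one stride over swing.  ``offset_cycles`` shifts the foot's own cycle
    (0.5 for the contralateral foot)."""
    d = cfg.duty_factor
    pg = np.asarray(phase_global, dtype=float) - offset_cycles
    k = np.floor(pg)
    p = pg - k
    frac = np.where(p < d, 0.0, sine_step((p - d) / (1.0 - d)))
    return (k + offset_cycles + frac) * cfg.stride_length


def _foot_y(phase: np.ndarray, cfg: SyntheticConfig, scale: float) -> np.ndarray:
    d = cfg.duty_factor
    p = np.asarray(phase, dtype=float) % 1.0
    y0 = -min(min(v[1] for v in anth.FOOT_LANDMARKS.values()), 0.0) * scale
    lift = np.where(p < d, 0.0,
                    lift_bump((p - d) / (1.0 - d)) * cfg.swing_clearance)
    return y0 + lift


def generate_segment_kinematics(cfg: SyntheticConfig,
                                rate: Optional[float] = None) -> SegmentPoseSeries:
    """Closed-form planar segment poses for one walking trial.

    Positions and sagittal orientations are C4-smooth and strictly periodic
    cycle to cycle; each foot's pose is frozen on its foot-flat interval.
    """
    rate = float(rate or cfg.imu_rate)
    T = cfg.cycle_time
    n = int(round(cfg.duration * rate))
    t = np.arange(n) / rate
    phase = t / T                      # impaired-foot cycle coordinate
    phase_c = phase - 0.5              # contralateral

    s = cfg.height / anth.GENERIC_HEIGHT_M
    L_th = anth.SEGMENT_LENGTHS["thigh"] * s
    L_sh = anth.SEGMENT_LENGTHS["shank"] * s
    z_imp = -0.10 if cfg.impaired_side == "left" else 0.10
    z_con = -z_imp

    segs: Dict[str, SegmentPose] = {}

    # pelvis: forward progression + double-frequency bob + gentle sway
    x_p = cfg.walking_speed * t + 0.015 * np.sin(4 * np.pi * phase)
    y_p = 0.55 * cfg.height - cfg.pelvis_bob * np.cos(4 * np.pi * phase)
    z_p = 0.015 * np.sin(2 * np.pi * phase)
    th_p = 0.03 * np.sin(2 * np.pi * phase)
    segs["pelvis"] = SegmentPose(np.column_stack([x_p, y_p, z_p]),
                                 quat_about_z(th_p))

    # impaired-side thigh and shank (orientation-consistent open chain)
    th_thigh = _thigh_profile(phase)
    knee = _knee_profile(phase)
    th_shank = th_thigh - knee
    hip = np.column_stack([x_p, y_p, np.full(n, z_imp)])
    hip = hip + as_rotation(quat_about_z(th_p)).apply(
        np.array([0.0, -anth.SEGMENT_LENGTHS["pelvis_to_hip"] * s, 0.0]))
    thigh_com = hip + as_rotation(quat_about_z(th_thigh)).apply(
        np.array([0.0, -0.433 * L_th, 0.0]))
    knee_pt = hip + as_rotation(quat_about_z(th_thigh)).apply(
        np.array([0.0, -L_th, 0.0]))
    shank_com = knee_pt + as_rotation(quat_about_z(th_shank)).apply(
        np.array([0.0, -0.433 * L_sh, 0.0]))
    segs["thigh"] = SegmentPose(thigh_com, quat_about_z(th_thigh))
    segs["shank"] = SegmentPose(shank_com, quat_about_z(th_shank))

    # feet: prescribed flat-interval kinematics + out-of-sagittal wiggle
    for name, ph, off, z_side in (("foot_impaired", phase, 0.0, z_imp),
                                  ("foot_contra", phase_c, 0.5, z_con)):
        x = _foot_x(phase, cfg, off)
        y = _foot_y(ph, cfg, s)
        theta = _foot_angle(ph, cfg)
        w = _wiggle_window(ph, cfg)
        ax = cfg.wiggle_angle * w * np.cos(2 * np.pi * cfg.wiggle_freq * t)
        ay = cfg.wiggle_angle * w * np.sin(2 * np.pi * cfg.wiggle_freq * t)
        rot = (as_rotation(quat_about_z(theta))
               * as_rotation(_quat_about_axis(ax, 0))
               * as_rotation(_quat_about_axis(ay, 1)))
        segs[name] = SegmentPose(np.column_stack([x, y, np.full(n, z_side)]),
                                 from_rotation(rot))

    return SegmentPoseSeries(time=t, rate=rate, segments=segs)


def _quat_about_axis(angle: np.ndarray, axis: int) -> np.ndarray:
    angle = np.asarray(angle, dtype=float)
    half = 0.5 * angle
    q = np.zeros(angle.shape + (4,))
    q[..., 0] = np.cos(half)
    q[..., 1 + axis] = np.sin(half)
    return q


def generate_static_pose(cfg: SyntheticConfig, duration: float = 3.0,
                         rate: Optional[float] = None,
                         joint_angles: Optional[Dict[str, float]] = None
                         ) -> SegmentPoseSeries:
    """A motionless neutral standing pose (used for sensor registration).

    ``joint_angles`` may hold ``knee``/``ankle`` offsets (rad) to emulate a
    participant who cannot stand in the neutral pose; segment orientations
    are then tilted accordingly while staying static.
    """
    rate = float(rate or cfg.imu_rate)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    ja = joint_angles or {}
    th_thigh = 0.0
    th_shank = th_thigh - ja.get("knee", 0.0)
    th_foot = th_shank + ja.get("ankle", 0.0)
    s = cfg.height / anth.GENERIC_HEIGHT_M
    z_imp = -0.10 if cfg.impaired_side == "left" else 0.10

    def const(pos3, theta):
        return SegmentPose(np.tile(np.asarray(pos3, float), (n, 1)),
                           np.tile(quat_about_z(np.asarray(theta)), (n, 1)))

    segs = {
        "pelvis": const([0.0, 0.55 * cfg.height, 0.0], 0.0),
        "thigh": const([0.0, 0.75 * cfg.height, z_imp], th_thigh),
        "shank": const([0.0, 0.35 * cfg.height, z_imp], th_shank),
        "foot_impaired": const([0.05, 0.0107 * s, z_imp], th_foot),
        "foot_contra": const([0.05, 0.0107 * s, -z_imp], 0.0),
    }
    return SegmentPoseSeries(time=t, rate=rate, segments=segs)


# ---------------------------------------------------------------------------
# IMU synthesis

def derive_imu_signals(poses: SegmentPoseSeries, cfg: SyntheticConfig) -> ImuTrial:
    """IMU readings consistent with a pose series.

    Per sensor: orientation = segment orientation composed with its mount
    offset, reported in the z-up global frame; accelerometer = sensor-local
    specific force (second derivative of the segment origin minus gravity,
    rotated into the sensor frame); gyro from quaternion differentiation.
    Gaussian noise with the configured SDs is added to acc and gyro,
    seeded by ``cfg.rng_seed``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    rate = poses.rate
    sensors: Dict[str, ImuSensorStream] = {}
    for name, seg in poses.segments.items():
        mount = cfg.mount_offsets.get(name)
        rot_seg = as_rotation(seg.quat)
        rot_sensor_model = rot_seg * as_rotation(mount) if mount is not None else rot_seg
        rot_sensor_global = MODEL_TO_GLOBAL * rot_sensor_model

        acc_model = np.gradient(np.gradient(seg.pos, axis=0, edge_order=2),
                                axis=0, edge_order=2) * rate**2
        spec_model = acc_model - MODEL_GRAVITY          # specific force, model frame
        acc_local = rot_sensor_model.inv().apply(spec_model)

        from ._quat import angular_velocity_body
        gyro_local = angular_velocity_body(from_rotation(rot_sensor_model), rate)

        acc_local = acc_local + rng.normal(0.0, cfg.imu_noise_acc_sd, acc_local.shape)
        gyro_local = gyro_local + rng.normal(0.0, cfg.imu_noise_gyro_sd, gyro_local.shape)

        sensors[name] = ImuSensorStream(
            quat=from_rotation(rot_sensor_global),
            acc=acc_local, gyro=gyro_local)
    return ImuTrial(time=poses.time, rate=rate, sensors=sensors,
                    sensor_to_segment={k: k for k in sensors})


# ---------------------------------------------------------------------------
# ground-truth loads and torque

def _impaired_share(phase: np.ndarray, duty: float) -> np.ndarray:
    """Load fraction carried by the impaired foot (cosine-ramp double
    support, exclusive single support, zero in swing)."""
    p = np.asarray(phase, dtype=float) % 1.0
    ds = duty - 0.5
    lam = np.zeros_like(p)
    m = p < ds                                   # double support 1, leading
    tau = p[m] / ds
    lam[m] = 1.0 - 0.5 * (1.0 + np.cos(np.pi * tau))
    lam[(p >= ds) & (p < 0.5)] = 1.0             # single stance
    m = (p >= 0.5) & (p < duty)                  # double support 2, trailing
    tau = (p[m] - 0.5) / ds
    lam[m] = 0.5 * (1.0 + np.cos(np.pi * tau))
    return lam


def _landmark_series(seg: SegmentPose, scale: float) -> Dict[str, np.ndarray]:
    rot = as_rotation(seg.quat)
    return {k: seg.pos + rot.apply(np.asarray(v) * scale)
            for k, v in anth.FOOT_LANDMARKS.items()}


def _truth_cop(phase: np.ndarray, duty: float,
               lm: Dict[str, np.ndarray]) -> np.ndarray:
    """Heel -> calcaneus CoM over double support 1, calcaneus -> toe until
    TC; vertical component zero; NaN during swing."""
    p = np.asarray(phase, dtype=float) % 1.0
    ds = duty - 0.5
    cop = np.full(lm["heel"].shape, np.nan)
    m = p < ds
    a = (p[m] / ds)[:, None]
    cop[m] = (1 - a) * lm["heel"][m] + a * lm["calc"][m]
    m = (p >= ds) & (p < duty)
    b = ((p[m] - ds) / (duty - ds))[:, None]
    cop[m] = (1 - b) * lm["calc"][m] + b * lm["toe"][m]
    cop[..., 1] = np.where(np.isnan(cop[..., 0]), np.nan, 0.0)
    return cop


def truth_loads(poses: SegmentPoseSeries, body, cfg: SyntheticConfig) -> GroundTruth:
    """Ground-truth external loads, kinematics and ankle torque.

    The total GRF is the independent Newton summation over the five tracked
    segments, F = sum_i m_i (a_i - g), with accelerations obtained directly
    from the pose series; the left/right split, CoP roll-over and the
    planar ankle free-body torque are evaluated in closed form from the
    prescribed gait phases.  ``body`` is a scaled
    :class:`wearlab.kinetics.BodyModel`.
    """
    t, rate = poses.time, poses.rate
    T, d = cfg.cycle_time, cfg.duty_factor
    phase = t / T
    phase_c = phase - 0.5

    seg_mass = {"pelvis": body.masses["pelvis"],
                "thigh": body.masses["thigh"],
                "shank": body.masses["shank"],
                "foot_impaired": body.masses["foot_impaired"],
                "foot_contra": body.masses["foot_contra"]}
    F_tot = np.zeros((len(t), 3))
    for name, m_i in seg_mass.items():
        acc = np.gradient(np.gradient(poses.segments[name].pos, axis=0,
                                      edge_order=2), axis=0, edge_order=2) * rate**2
        F_tot += m_i * (acc - MODEL_GRAVITY)

    lam = _impaired_share(phase, d)
    # exclusive support: during a foot's swing the other carries everything
    F_imp = lam[:, None] * F_tot
    F_imp[(phase % 1.0) >= d] = 0.0
    F_con = F_tot - F_imp
    # bitwise conservation: re-derive the impaired share from the remainder
    # until fl(F_imp + F_con) == F_tot at every sample
    for _ in range(3):
        bad = (F_imp + F_con) != F_tot
        if not bad.any():
            break
        F_imp = np.where(bad, F_tot - F_con, F_imp)

    scale = body.scale
    lm_imp = _landmark_series(poses.segments["foot_impaired"], scale)
    lm_con = _landmark_series(poses.segments["foot_contra"], scale)
    cop_imp = _truth_cop(phase, d, lm_imp)
    cop_con = _truth_cop(phase_c, d, lm_con)

    # planar ankle free-body torque (impaired side)
    foot = poses.segments["foot_impaired"]
    from ._quat import cross_z, twist_about_z
    theta_f = np.unwrap(twist_about_z(foot.quat))
    alpha = np.gradient(np.gradient(theta_f, edge_order=2), edge_order=2) * rate**2
    acc_com = np.gradient(np.gradient(foot.pos, axis=0, edge_order=2),
                          axis=0, edge_order=2) * rate**2
    p_ankle = foot.pos + as_rotation(foot.quat).apply(
        np.asarray(body.ankle_offset))
    r_ca = foot.pos - p_ankle
    m_f = body.masses["foot_impaired"]
    tau = (body.foot_inertia_z * alpha
           + cross_z(r_ca, m_f * (acc_com - MODEL_GRAVITY)))
    stance = (phase % 1.0) < d
    r_cop = np.where(stance[:, None], cop_imp - p_ankle, 0.0)
    grf_term = cross_z(np.nan_to_num(r_cop), np.where(stance[:, None], F_imp, 0.0))
    tau = tau - grf_term

    th_thigh = _thigh_profile(phase)
    knee = _knee_profile(phase)
    th_shank = th_thigh - knee
    ankle = theta_f - th_shank

    k = np.arange(cfg.n_cycles, dtype=float)
    profiles = [cfg.envelope_profiles[m] for m in MUSCLES]
    act = np.column_stack([pr(phase) for pr in profiles])

    rho = cfg.rocker_fraction
    ff_imp = np.column_stack([(k + rho) * T, (k + d - rho) * T])
    ff_con = np.column_stack([(k + 0.5 + rho) * T, (k + 0.5 + d - rho) * T])
    ff_con = ff_con[ff_con[:, 1] < t[-1] + 1.0 / rate]

    return GroundTruth(
        time=t, rate=rate,
        ic_impaired=k * T,
        tc_impaired=(k + d) * T,
        ic_contra=(k + 0.5) * T,
        tc_contra=(k + d - 0.5) * T,
        ff_impaired=ff_imp, ff_contra=ff_con,
        grf_total=F_tot, grf_impaired=F_imp, grf_contra=F_con,
        cop_impaired=cop_imp, cop_contra=cop_con,
        knee_angle=knee, ankle_angle=ankle,
        foot_angle_impaired=theta_f,
        ankle_torque=tau, activations=act,
        duty_factor=d, cycle_time=T)


# ---------------------------------------------------------------------------
# EMG synthesis

def generate_emg(cfg: SyntheticConfig, truth: GroundTruth):
    """Synthesize the 64-channel grid recording.

    Each clean channel is its muscle's phase-locked envelope amplitude-
    modulating an independent zero-mean 20-450 Hz noise carrier; channels
    labelled noisy additionally carry large sub-3 Hz movement artifacts.
    Returns a :class:`wearlab.preprocess.EmgRecording`.
    """
    from .preprocess import EmgRecording

    rng = np.random.default_rng(cfg.rng_seed + 1)
    rate = cfg.emg_rate
    n = int(round(cfg.duration * rate))
    t = np.arange(n) / rate
    phase = t / cfg.cycle_time

    sos = _signal.butter(4, [20.0, min(450.0, 0.45 * rate)],
                         btype="bandpass", fs=rate, output="sos")
    sos_lf = _signal.butter(2, 3.0, btype="lowpass", fs=rate, output="sos")

    amp = 1.0e-3   # V, scale of a fully active clean channel
    art = 0.1      # V, movement-artifact scale on noisy channels
    data = np.zeros((n, N_EMG_CHANNELS))
    for c, label in enumerate(cfg.channel_map):
        carrier = _signal.sosfilt(sos, rng.standard_normal(n))
        carrier /= max(np.std(carrier), 1e-12)
        if label == NOISY_LABEL:
            drift = _signal.sosfilt(sos_lf, rng.standard_normal(n))
            drift /= max(np.std(drift), 1e-12)
            data[:, c] = art * drift + 0.02 * amp * carrier
        else:
            env = cfg.envelope_profiles[label](phase)
            data[:, c] = amp * env * carrier
    return EmgRecording(data=data, rate=rate, gain=23.0,
                        labels=list(cfg.channel_map))


def simulate_trial(cfg: SyntheticConfig, body=None):
    """Generate a full trial: poses, IMU, EMG and ground truth.

    Returns ``(poses, imu, emg, truth, body)``; ``body`` defaults to the
    scaled model for the configured height and mass.
    """
    from .kinetics import scale_body_model

    if body is None:
        body = scale_body_model(cfg.height, cfg.mass)
    poses = generate_segment_kinematics(cfg)
    imu = derive_imu_signals(poses, cfg)
    truth = truth_loads(poses, body, cfg)
    emg = generate_emg(cfg, truth)
    return poses, imu, emg, truth, body
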