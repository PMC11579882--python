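"""End-to-end pipeline: preprocess -> gait events -> kinetics -> joint
mechanics -> (optional) EMG-driven model, mirroring the wearable-lab
processing order, with a metrics report against the synthetic ground truth
when running in simulation mode."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from . import gait_events as ge
from . import io as wio
from . import joint_mechanics as jm
from . import kinetics as kin
from . import mtu as mtu_mod
from . import preprocess as pre
from . import synthetic as syn
from ._quat import MODEL_GRAVITY
from .config import PipelineConfig

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    body: kin.BodyModel
    phases: ge.GaitPhaseTable
    loads: kin.ExternalLoadSeries
    angles: jm.JointAngleSeries
    torque_id: jm.TorqueSeries
    truth: Optional[syn.GroundTruth] = None
    calibration: Optional[mtu_mod.CalibrationResult] = None
    torque_emg: Optional[jm.TorqueSeries] = None
    report: Dict = field(default_factory=dict)


def _filtered_model_accelerations(imu: syn.ImuTrial, cutoff: float
                                  ) -> Dict[str, np.ndarray]:
    """Sensor-local specific force -> true model-frame acceleration,
    low-pass filtered at the IMU cutoff."""
    out = {}
    for sensor, stream in imu.sensors.items():
        spec = kin.to_model_frame(stream.acc, stream.quat)
        acc = kin.remove_gravity(spec)
        out[imu.sensor_to_segment.get(sensor, sensor)] = \
            pre.butterworth_zero_lag(acc, cutoff, imu.rate, kind="low")
    return out


def detect_events_from_trial(imu: syn.ImuTrial, cfg: PipelineConfig
                             ) -> ge.GaitPhaseTable:
    """Foot-flat / IC / TC / phase segmentation for both feet."""
    impaired, contra = None, None
    for foot, store in (("foot_impaired", "impaired"), ("foot_contra", "contra")):
        gyro = pre.butterworth_zero_lag(imu.sensors[foot].gyro,
                                        cfg.filters.imu_lowpass_hz,
                                        imu.rate, kind="low")
        motion = ge.FootMotionSeries(gyro=gyro, rate=imu.rate)
        ff = ge.detect_foot_flat(motion, k=cfg.events.k,
                                 min_duration_s=cfg.events.min_ff_duration_s,
                                 use=cfg.events.use)
        svm = ge.signal_vector_magnitude(motion)
        ev = ge.detect_ic_tc(svm, ff, imu.rate)
        if store == "impaired":
            impaired = ev
        else:
            contra = ev
    return ge.segment_gait_phases(impaired, contra, imu.rate, len(imu.time))


def process_emg(emg: pre.EmgRecording, cfg: PipelineConfig,
                assignment) -> pre.EnvelopeSet:
    """Raw grid EMG -> normalized muscle-specific envelopes."""
    mask = pre.detect_noisy_channels(emg, mult=cfg.emg.noise_mult)
    reref = pre.rereference(emg, mask)
    env = pre.extract_envelope(reref, highpass_hz=cfg.emg.highpass_hz,
                               median_window_s=cfg.emg.median_window_s)
    env, = pre.normalize_envelopes([env])
    labels = list(assignment)
    for c in np.flatnonzero(mask):
        labels[c] = pre.NOISY_LABEL
    return pre.muscle_envelopes(env, labels)


def _metric_entry(truth_arr, est_arr, mass=None):
    m = jm.agreement_metrics(truth_arr, est_arr, mass=mass)
    return {"r2": m.r2, "rmse": m.rmse}


def run_pipeline(config: PipelineConfig, simulate: bool = True,
                 out_dir: Optional[str] = None,
                 with_emg: bool = True) -> PipelineResult:
    """Execute the full chain and (optionally) write all outputs.

    With ``simulate`` the synthetic generator supplies the raw streams and
    the report scores every stage against the generator's ground truth;
    otherwise ``config.imu_path`` / ``config.emg_path`` are read.  Stages
    fail loudly with the stage name in the exception.
    """
    truth = None
    scfg = None
    if simulate:
        scfg = config.synthetic_config()
        poses, imu, emg, truth, body = syn.simulate_trial(scfg)
        if not with_emg:
            emg = None
        static = syn.derive_imu_signals(
            syn.generate_static_pose(scfg), scfg)
        assignment = scfg.channel_map
    else:
        if not config.imu_path:
            raise ValueError("imu_path required when not simulating")
        imu = wio.read_imu_table(config.imu_path)
        body = kin.scale_body_model(config.participant.height,
                                    config.participant.mass)
        emg = None
        static = None
        poses = None
        assignment = None
        raise NotImplementedError(
            "file-driven runs need externally supplied pose series for the "
            "CoP landmarks; use simulate=True or the stage-level API")

    def stage(name, fn):
        try:
            return fn()
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

    reg = stage("registration",
                lambda: jm.register_sensors_static(static))
    phases = stage("gait_events", lambda: detect_events_from_trial(imu, config))
    if not phases.cycles:
        raise RuntimeError("pipeline stage 'gait_events' found no complete "
                           "gait cycles")

    acc = stage("kinetics.frames", lambda: _filtered_model_accelerations(
        imu, config.filters.imu_lowpass_hz))
    F_tot = stage("kinetics.total_grf", lambda: kin.total_grf(acc, body))
    side = config.participant.impaired_side
    left, right = stage("kinetics.sta",
                        lambda: kin.split_grf_sta(F_tot, phases, side))
    lm_imp = kin.landmark_trajectories(poses.segments["foot_impaired"].pos,
                                       poses.segments["foot_impaired"].quat,
                                       body)
    lm_con = kin.landmark_trajectories(poses.segments["foot_contra"].pos,
                                       poses.segments["foot_contra"].quat,
                                       body)
    cop_imp, cop_con = stage("kinetics.cop",
                             lambda: kin.estimate_cop(phases, lm_imp, lm_con))
    loads = kin.ExternalLoadSeries(
        time=imu.time, total=F_tot, left=left, right=right,
        cop_left=cop_imp if side == "left" else cop_con,
        cop_right=cop_con if side == "left" else cop_imp)

    angles = stage("joint_angles", lambda: jm.joint_angles(imu, reg))
    F_imp = left if side == "left" else right
    torque_id = stage("inverse_dynamics", lambda: jm.ankle_inverse_dynamics(
        poses.segments["foot_impaired"].pos,
        poses.segments["foot_impaired"].quat,
        acc["foot_impaired"], F_imp, cop_imp, body, imu.rate,
        filter_hz=config.filters.imu_lowpass_hz))

    def _per_cycle(ref, est, mass=None):
        rows = []
        for a, b in phases.cycle_bounds():
            m = jm.agreement_metrics(ref[a:b], est[a:b], mass=mass)
            rows.append({"r2": m.r2, "rmse": m.rmse})
        return rows

    # ---- report vs ground truth -------------------------------------------
    report: Dict = {"parameters": json.loads(json.dumps(
        {"filters": vars(config.filters), "emg": vars(config.emg),
         "events": vars(config.events),
         "participant": vars(config.participant)})),
        "n_cycles_detected": phases.n_cycles}
    sl = slice(phases.cycle_bounds()[0][0], phases.cycle_bounds()[-1][1])
    if truth is not None:
        report["vs_truth"] = {
            "knee_angle": _metric_entry(truth.knee_angle[sl], angles.knee[sl]),
            "ankle_angle": _metric_entry(truth.ankle_angle[sl],
                                         angles.ankle[sl]),
            "grf_vertical": _metric_entry(truth.grf_total[sl, 1], F_tot[sl, 1]),
            "grf_anterior": _metric_entry(truth.grf_total[sl, 0], F_tot[sl, 0]),
            "torque_id": _metric_entry(truth.ankle_torque[sl],
                                       torque_id.torque[sl], mass=body.mass),
        }
        report["vs_truth_per_cycle"] = {
            "knee_angle": _per_cycle(truth.knee_angle, angles.knee),
            "ankle_angle": _per_cycle(truth.ankle_angle, angles.ankle),
            "torque_id": _per_cycle(truth.ankle_torque, torque_id.torque,
                                    mass=body.mass),
        }

    calibration = None
    torque_emg = None
    if emg is not None:
        muscle_env = stage("emg", lambda: process_emg(emg, config, assignment))
        geometry = mtu_mod.default_geometry(body.scale)
        init = stage("precalibration", lambda: mtu_mod.precalibrate_lom_lst(
            geometry, body.scale))
        a, b = phases.cycle_bounds()[0]
        cal_angles = jm.JointAngleSeries(time=angles.time[a:b] - angles.time[a],
                                         rate=angles.rate,
                                         knee=angles.knee[a:b],
                                         ankle=angles.ankle[a:b])
        env_idx = (np.arange(a, b) / imu.rate * muscle_env.rate).astype(int)
        env_cal = pre.EnvelopeSet(
            data=muscle_env.data[np.clip(env_idx, 0, len(muscle_env.data) - 1)],
            rate=imu.rate, labels=list(muscle_env.labels))
        ref = jm.TorqueSeries(time=cal_angles.time, rate=imu.rate,
                              torque=torque_id.torque[a:b],
                              body_mass=body.mass, provenance="ID-IMU")
        cc = config.calibration
        calibration = stage("calibration", lambda: mtu_mod.calibrate(
            env_cal, cal_angles, ref, geometry, init, seed=cc.seed,
            lom_lst_frac=cc.lom_lst_frac,
            strength_bounds=(cc.strength_lo, cc.strength_hi),
            shape_bounds=(cc.shape_lo, cc.shape_hi),
            maxiter=cc.maxiter, popsize=cc.popsize))
        env_full_idx = (np.arange(len(imu.time)) / imu.rate
                        * muscle_env.rate).astype(int)
        env_full = pre.EnvelopeSet(
            data=muscle_env.data[np.clip(env_full_idx, 0,
                                         len(muscle_env.data) - 1)],
            rate=imu.rate, labels=list(muscle_env.labels))
        torque_emg = stage("estimation", lambda: mtu_mod.estimate_torque(
            calibration.params, geometry, env_full, angles, body.mass))
        report["calibration"] = {
            "initial_objective": calibration.initial_objective,
            "final_objective": calibration.final_objective,
            "r2": calibration.fit.r2,
            "rmse_per_kg": calibration.rmse_per_kg,
        }
        report["vs_id_torque"] = {
            "emg_driven": _metric_entry(torque_id.torque[sl],
                                        torque_emg.torque[sl],
                                        mass=body.mass)}
    else:
        report["calibration"] = "absent (no EMG input)"

    result = PipelineResult(config=config, body=body, phases=phases,
                            loads=loads, angles=angles, torque_id=torque_id,
                            truth=truth, calibration=calibration,
                            torque_emg=torque_emg, report=report)
    if out_dir:
        write_outputs(result, out_dir)
    return result


def write_outputs(res: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rate = res.angles.rate
    wio.write_events_json(
        {"impaired": {"ic": res.phases.impaired.ic, "tc": res.phases.impaired.tc},
         "contra": {"ic": res.phases.contra.ic, "tc": res.phases.contra.tc}},
        rate, out / "events.json")
    wio.write_external_loads(res.loads, out / "external_loads.sto")
    wio.write_sto(["knee_angle", "ankle_angle"],
                  np.column_stack([res.angles.knee, res.angles.ankle]),
                  res.angles.time, out / "joint_angles.sto")
    wio.write_sto(["ankle_torque_id"], res.torque_id.torque[:, None],
                  res.torque_id.time, out / "ankle_torque_id.sto")
    if res.torque_emg is not None:
        wio.write_sto(["ankle_torque_emg"], res.torque_emg.torque[:, None],
                      res.torque_emg.time, out / "ankle_torque_emg.sto")
    if res.calibration is not None:
        wio.write_calibration_json(res.calibration, out / "calibration.json")
    (out / "report.json").write_text(
        json.dumps(res.report, indent=2, sort_keys=True, allow_nan=True) + "\n")
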