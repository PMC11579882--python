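"""Pipeline configuration: every stage parameter in one serializable tree.

Defaults match the recorded protocol where it prints a value (6 / 3 / 20 Hz
cutoffs, 0.16 s median window, 1.68 m generic height, ±5 % calibration
bounds); the rest are implementation defaults flagged as such in the CLI
help and docs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class ParticipantConfig:
    height: float = 1.775          # m
    mass: float = 94.2             # kg
    impaired_side: str = "left"


@dataclass
class FilterConfig:
    lab_lowpass_hz: float = 6.0    # lab-style kinematic/kinetic streams
    imu_lowpass_hz: float = 3.0    # IMU-derived velocities/accelerations


@dataclass
class EmgConfig:
    highpass_hz: float = 20.0
    median_window_s: float = 0.16
    noise_mult: float = 5.0        # noisy-channel MAD multiplier


@dataclass
class EventConfig:
    k: float = 0.5                 # foot-flat threshold multiplier
    min_ff_duration_s: float = 0.05
    use: str = "angular"           # criterion channels: angular | linear


@dataclass
class CalibrationConfig:
    lom_lst_frac: float = 0.05     # ±5 % of pre-calibrated values
    strength_lo: float = 0.5
    strength_hi: float = 2.0
    shape_lo: float = -3.0
    shape_hi: float = -0.01
    maxiter: int = 60
    popsize: int = 12
    seed: int = 0


@dataclass
class SyntheticSection:
    cadence: float = 100.0
    walking_speed: float = 1.1
    n_cycles: int = 10
    duty_factor: float = 0.6
    imu_rate: float = 100.0
    emg_rate: float = 2000.0
    imu_noise_acc_sd: float = 0.02
    imu_noise_gyro_sd: float = 0.005
    rng_seed: int = 0


@dataclass
class PipelineConfig:
    participant: ParticipantConfig = field(default_factory=ParticipantConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    emg: EmgConfig = field(default_factory=EmgConfig)
    events: EventConfig = field(default_factory=EventConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    synthetic: SyntheticSection = field(default_factory=SyntheticSection)
    imu_path: Optional[str] = None
    emg_path: Optional[str] = None
    out_dir: str = "wearlab_out"

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            raw = yaml.safe_load(Path(source).read_text())
        else:
            raw = yaml.safe_load(source)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
                kwargs[f.name] = f.type(**v)
            elif f.name in ("participant", "filters", "emg", "events",
                            "calibration", "synthetic"):
                sub = {"participant": ParticipantConfig,
                       "filters": FilterConfig, "emg": EmgConfig,
                       "events": EventConfig,
                       "calibration": CalibrationConfig,
                       "synthetic": SyntheticSection}[f.name]
                kwargs[f.name] = sub(**v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    def synthetic_config(self):
        from .synthetic import SyntheticConfig
        s = self.synthetic
        return SyntheticConfig(
            cadence=s.cadence, walking_speed=s.walking_speed,
            n_cycles=s.n_cycles, duty_factor=s.duty_factor,
            height=self.participant.height, mass=self.participant.mass,
            imu_rate=s.imu_rate, emg_rate=s.emg_rate,
            imu_noise_acc_sd=s.imu_noise_acc_sd,
            imu_noise_gyro_sd=s.imu_noise_gyro_sd,
            rng_seed=s.rng_seed,
            impaired_side=self.participant.impaired_side)
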