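"""Gait-event detection from foot-worn IMU signals.

Foot-flat (FF) is the set of samples where all three angular-velocity
components simultaneously stay within k standard deviations of their trial
mean; the initial contact (IC) of a stance is the local maximum of the
angular-velocity signal-vector magnitude (SVM) nearest before the FF run,
terminal contact (TC) the local maximum nearest after it.  The four gait
phases are tiled per impaired-side cycle: double stance 1 (impaired IC ->
contralateral TC), single stance (-> contralateral IC), double stance 2
(-> impaired TC), swing (-> next impaired IC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import signal as _signal

log = logging.getLogger(__name__)


@dataclass
class FootMotionSeries:
    """Filtered 3D foot angular velocity (and optionally linear velocity).

    Channels are anterior-posterior, vertical, mediolateral; inputs are
    expected already low-pass filtered at 3 Hz.
    """

    gyro: np.ndarray                 # (N, 3) rad/s
    rate: float
    linvel: Optional[np.ndarray] = None   # (N, 3) m/s

    def __post_init__(self):
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        if self.gyro.shape[1] != 3:
            raise ValueError("gyro must have 3 channels")


@dataclass
class SideEvents:
    ic: np.ndarray   # sample indices, sorted
    tc: np.ndarray


@dataclass
class GaitPhaseTable:
    """Per-cycle gait phases as half-open sample ranges."""

    rate: float
    n_samples: int
    impaired: SideEvents
    contra: SideEvents
    #: per cycle: dict with keys ds1, single, ds2, swing -> (start, stop)
    cycles: List[Dict[str, Tuple[int, int]]] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def cycle_bounds(self) -> List[Tuple[int, int]]:
        return [(c["ds1"][0], c["swing"][1]) for c in self.cycles]


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) pairs."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    d = np.diff(m.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(len(m))
    return list(zip(starts, stops))


def detect_foot_flat(motion: FootMotionSeries, k: float = 0.5,
                     min_duration_s: float = 0.05,
                     use: str = "angular") -> np.ndarray:
    """Boolean foot-flat mask.

    A sample is FF when, simultaneously in all three directions, the signal
    is within ``k`` standard deviations of its trial mean; runs shorter
    than ``min_duration_s`` are discarded.  ``use`` selects angular
    (default) or linear velocity channels.
    """
    if use == "angular":
        x = motion.gyro
    elif use == "linear":
        if motion.linvel is None:
            raise ValueError("no linear velocity channels available")
        x = motion.linvel
    else:
        raise ValueError("use must be 'angular' or 'linear'")
    if x.shape[0] < motion.rate:
        raise ValueError("series must span at least 1 s")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant input channel (std = 0); cannot apply "
                         "the foot-flat criterion")
    mask = np.all(np.abs(x - mu) <= k * sd, axis=1)
    min_run = int(round(min_duration_s * motion.rate))
    out = np.zeros_like(mask)
    for a, b in _runs(mask):
        if b - a >= min_run:
            out[a:b] = True
    return out


def signal_vector_magnitude(motion: FootMotionSeries) -> np.ndarray:
    """Euclidean norm of the three angular-velocity channels, per sample."""
    return np.linalg.norm(motion.gyro, axis=1)


def detect_ic_tc(svm: np.ndarray, ff: np.ndarray, rate: float,
                 prominence: Optional[float] = None) -> SideEvents:
    """IC/TC events of one foot from its SVM and foot-flat mask.

    For each FF run, IC is the nearest strict local maximum of the SVM
    before the run start (searching no further back than the previous FF
    run) and TC the nearest one after the run end.  FF runs touching the
    series boundary yield no event and are logged.  A small peak-prominence
    floor suppresses numerical ripple left by the zero-lag filtering.
    """
    svm = np.asarray(svm, dtype=float)
    runs = _runs(np.asarray(ff, dtype=bool))
    if not runs:
        raise ValueError("no foot-flat runs: cannot detect events")
    if prominence is None:
        prominence = 0.05 * float(np.ptp(svm))
    peaks, _ = _signal.find_peaks(svm, prominence=prominence)
    ics: List[int] = []
    tcs: List[int] = []
    for i, (a, b) in enumerate(runs):
        lo = runs[i - 1][1] if i > 0 else 0
        hi = runs[i + 1][0] if i + 1 < len(runs) else len(svm)
        before = peaks[(peaks >= lo) & (peaks < a)]
        if len(before):
            ics.append(int(before[-1]))
        elif lo == 0:
            log.warning("foot-flat run near series start (sample %d): "
                        "no IC emitted", a)
        else:
            raise ValueError(f"no local maximum before foot-flat run "
                             f"starting at sample {a}")
        after = peaks[(peaks >= b) & (peaks < hi)]
        if len(after):
            tcs.append(int(after[0]))
        elif hi == len(svm):
            log.warning("foot-flat run near series end (sample %d): "
                        "no TC emitted", b)
        else:
            raise ValueError(f"no local maximum after foot-flat run "
                             f"ending at sample {b}")
    return SideEvents(ic=np.array(sorted(ics), dtype=int),
                      tc=np.array(sorted(tcs), dtype=int))


def _check_alternation(ev: SideEvents, side: str) -> None:
    """Within a side, events must alternate IC, TC, IC, ..."""
    merged = sorted([(i, "ic") for i in ev.ic] + [(i, "tc") for i in ev.tc])
    for (i1, k1), (i2, k2) in zip(merged, merged[1:]):
        if k1 == k2:
            raise ValueError(f"{side} events violate IC/TC alternation at "
                             f"samples {i1}, {i2}")


def segment_gait_phases(impaired: SideEvents, contra: SideEvents,
                        rate: float, n_samples: int) -> GaitPhaseTable:
    """Tile each impaired IC->IC cycle into the four gait phases.

    Cycles whose contralateral events are missing are dropped and logged;
    alternation violations on the impaired (cycle-defining) side abort with
    the offending indices, while contralateral gaps only cost the affected
    cycles.
    """
    _check_alternation(impaired, "impaired")
    try:
        _check_alternation(contra, "contralateral")
    except ValueError as e:
        log.warning("%s; affected cycles will be dropped", e)
    cycles = []
    for ic0, ic1 in zip(impaired.ic, impaired.ic[1:]):
        tc_imp = impaired.tc[(impaired.tc > ic0) & (impaired.tc < ic1)]
        tc_con = contra.tc[(contra.tc > ic0) & (contra.tc < ic1)]
        ic_con = contra.ic[(contra.ic > ic0) & (contra.ic < ic1)]
        if len(tc_imp) != 1 or len(tc_con) < 1 or len(ic_con) < 1:
            log.warning("dropping cycle [%d, %d): missing or ambiguous "
                        "events", ic0, ic1)
            continue
        t_imp = int(tc_imp[0])
        t_con = int(tc_con[0])
        i_con = int(ic_con[0])
        if not ic0 < t_con < i_con < t_imp < ic1:
            log.warning("dropping cycle [%d, %d): events out of order "
                        "(tc_contra=%d, ic_contra=%d, tc_imp=%d)",
                        ic0, ic1, t_con, i_con, t_imp)
            continue
        cycles.append({"ds1": (int(ic0), t_con),
                       "single": (t_con, i_con),
                       "ds2": (i_con, t_imp),
                       "swing": (t_imp, int(ic1))})
    return GaitPhaseTable(rate=rate, n_samples=n_samples,
                          impaired=impaired, contra=contra, cycles=cycles)
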