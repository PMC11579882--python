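"""Zero-lag filtering and the raw-EMG -> normalized envelope chain.

The EMG chain mirrors the recording pipeline of the wearable garment:
noisy-channel zeroing, re-referencing against the clean common average,
20 Hz zero-lag high-pass, full rectification, a 0.16 s moving median
(equivalent in behaviour to a 6 Hz low-pass but robust to residual motion
spikes), task-maximum normalization and averaging into muscle-specific
envelopes.  The grid's channel->muscle assignment is an input; the
automated localization algorithm that produces it on real data is out of
scope here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from scipy import signal as _signal

from .synthetic import MUSCLES, NOISY_LABEL

log = logging.getLogger(__name__)


@dataclass
class EmgRecording:
    """Multi-channel surface EMG, volts, channels in columns."""

    data: np.ndarray          # (N, C)
    rate: float               # Hz (2000 in the recorded protocol)
    gain: float = 23.0        # amplifier gain already applied
    labels: Optional[List[str]] = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate <= 2 * 20.0:
            raise ValueError("sampling rate must exceed twice the 20 Hz "
                             "high-pass corner")

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class EnvelopeSet:
    """Non-negative envelope series per channel (or per muscle)."""

    data: np.ndarray          # (N, C), >= 0
    rate: float
    labels: List[str]
    norms: Optional[np.ndarray] = None   # per-channel normalization constants

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))


#: dual-pass cutoff correction for a 2nd-order Butterworth:
#: (2^(1/2) - 1)^(1/4); the design cutoff is adjusted so the forward-
#: backward cascade has its -3 dB point at the nominal cutoff.
_DUAL_PASS_C = (2.0 ** 0.5 - 1.0) ** 0.25


def butterworth_zero_lag(series: np.ndarray, cutoff: float, rate: float,
                         kind: str = "low", order: int = 2,
                         correct_cutoff: bool = True) -> np.ndarray:
    """Forward-backward 2nd-order Butterworth filter (zero phase shift).

    Reflective edge padding; works column-wise on (N,) or (N, C) input and
    returns the same shape.  With ``correct_cutoff`` (default) the design
    cutoff is adjusted for the double pass so the effective -3 dB frequency
    equals ``cutoff`` (standard dual-pass practice).
    """
    x = np.asarray(series, dtype=float)
    if not 0 < cutoff < rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist="
                         f"{rate / 2:g}) Hz")
    if kind not in ("low", "high"):
        raise ValueError("kind must be 'low' or 'high'")
    fc = cutoff
    if correct_cutoff:
        fc = cutoff / _DUAL_PASS_C if kind == "low" else cutoff * _DUAL_PASS_C
        fc = min(fc, 0.99 * rate / 2)
    sos = _signal.butter(order, fc, btype=kind + "pass", fs=rate,
                         output="sos")
    padlen = 3 * (2 * order + 1)
    if x.shape[0] <= padlen:
        raise ValueError(f"series too short ({x.shape[0]} samples) for "
                         f"edge padding ({padlen})")
    return _signal.sosfiltfilt(sos, x, axis=0, padtype="even")


def detect_noisy_channels(emg: EmgRecording, mult: float = 5.0,
                          percentile: float = 95.0) -> np.ndarray:
    """Flag channels with large voltage fluctuations (movement artifacts).

    A channel is noisy when its robust amplitude — the ``percentile``-th
    percentile of |x - median(x)|, which tracks burst amplitude while
    staying insensitive to isolated spikes — exceeds ``mult`` times the
    across-channel median of that statistic.  Returns a boolean mask.
    """
    if emg.n_channels < 2:
        raise ValueError("need at least 2 channels")
    amp = np.percentile(np.abs(emg.data - np.median(emg.data, axis=0)),
                        percentile, axis=0)
    thr = mult * np.median(amp)
    mask = amp > thr
    if mask.all():
        raise ValueError("all channels flagged as noisy; check the "
                         "recording or the threshold multiplier")
    if mask.any():
        log.info("flagged %d noisy channels: %s", mask.sum(),
                 np.flatnonzero(mask).tolist())
    return mask


def rereference(emg: EmgRecording, mask: np.ndarray) -> EmgRecording:
    """Remove the noisy channels' contribution to the average reference.

    The amplifier records r_i = s_i - mean over all channels of s.  Using
    only clean channels, r_i - mean_clean(r) = s_i - mean_clean(s), i.e.
    the signal referenced against the clean common average.  Noisy channels
    are output as zeros.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (emg.n_channels,):
        raise ValueError("mask shape must match channel count")
    clean = ~mask
    if not clean.any():
        raise ValueError("no clean channels left to re-reference against")
    common = emg.data[:, clean].mean(axis=1, keepdims=True)
    out = emg.data - common
    out[:, mask] = 0.0
    return EmgRecording(data=out, rate=emg.rate, gain=emg.gain,
                        labels=emg.labels)


def median_window_samples(rate: float, window_s: float = 0.16) -> int:
    """Moving-median window: round(window_s * rate) samples, forced odd so
    the window stays centred (0.16 s at 2000 Hz -> 321)."""
    win = int(round(window_s * rate))
    if win % 2 == 0:
        win += 1
    return win


def extract_envelope(emg: EmgRecording, highpass_hz: float = 20.0,
                     median_window_s: float = 0.16) -> EnvelopeSet:
    """Linear envelopes: 20 Hz zero-lag high-pass, full rectification,
    centred moving median.

    The window follows :func:`median_window_samples` (321 samples at
    2000 Hz).
    """
    win = median_window_samples(emg.rate, median_window_s)
    if win > emg.data.shape[0]:
        raise ValueError(f"median window ({win} samples) longer than series "
                         f"({emg.data.shape[0]})")
    hp = butterworth_zero_lag(emg.data, highpass_hz, emg.rate, kind="high")
    rect = np.abs(hp)
    env = ndimage.median_filter(rect, size=(win, 1), mode="reflect")
    labels = emg.labels or [f"ch{i}" for i in range(emg.n_channels)]
    return EnvelopeSet(data=env, rate=emg.rate, labels=list(labels))


def normalize_envelopes(sets: Sequence[EnvelopeSet]) -> List[EnvelopeSet]:
    """Normalize each channel by its maximum across all supplied tasks.

    After normalization the per-channel maximum over the tasks is exactly 1
    (all-zero channels are left at zero and logged).
    """
    if not sets:
        raise ValueError("need at least one task")
    widths = {s.data.shape[1] for s in sets}
    if len(widths) != 1:
        raise ValueError("all tasks must share the same channels")
    peaks = np.max([s.data.max(axis=0) for s in sets], axis=0)
    dead = peaks == 0
    if dead.any():
        log.warning("channels with all-zero envelopes left unnormalized: %s",
                    np.flatnonzero(dead).tolist())
    denom = np.where(dead, 1.0, peaks)
    return [EnvelopeSet(data=s.data / denom, rate=s.rate,
                        labels=list(s.labels), norms=peaks.copy())
            for s in sets]


def muscle_envelopes(env: EnvelopeSet,
                     assignment: Union[Mapping[int, str], Sequence[str]]
                     ) -> EnvelopeSet:
    """Average assigned channels into the seven muscle-specific envelopes.

    ``assignment`` maps channel index -> muscle name (a plain list of
    per-channel labels also works); channels labelled ``"noisy"`` or with
    unknown names are ignored.  Output columns follow
    :data:`wearlab.synthetic.MUSCLES`; values re-clipped to [0, 1].
    """
    if isinstance(assignment, Mapping):
        labels = [assignment.get(i, NOISY_LABEL)
                  for i in range(env.data.shape[1])]
    else:
        labels = list(assignment)
        if len(labels) != env.data.shape[1]:
            raise ValueError("assignment length must match channel count")
    cols = []
    for m in MUSCLES:
        idx = [i for i, l in enumerate(labels) if l == m]
        if not idx:
            raise ValueError(f"muscle {m!r} has no assigned channels")
        cols.append(env.data[:, idx].mean(axis=1))
    data = np.clip(np.column_stack(cols), 0.0, 1.0)
    return EnvelopeSet(data=data, rate=env.rate, labels=list(MUSCLES))
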