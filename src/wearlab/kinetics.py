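"""Body-model scaling, frame transforms, GRF estimation and CoP progression.

The total ground reaction force follows Newton's summation over the five
tracked segments, F = sum_i m_i (a_i - g), with the pelvis segment lumping
the mass of everything except the impaired leg and the contralateral foot.
The left/right split uses the smooth transition assumption (STA): exclusive
support during single stance and a smooth hand-over from the trailing to
the leading foot during double support.  The centre of pressure progresses
linearly from the heel (at IC) to the calcaneus CoM (at the contralateral
TC) and on to the toe (at TC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Optional, Tuple

import numpy as np

from . import anthropometry as anth
from ._quat import GLOBAL_TO_MODEL, MODEL_GRAVITY, as_rotation, check_unit
from .gait_events import GaitPhaseTable

log = logging.getLogger(__name__)


@dataclass
class BodyModel:
    """Scaled planar body model (masses kg, lengths m, model frame)."""

    height: float
    mass: float
    scale: float
    masses: Dict[str, float]
    lengths: Dict[str, float]
    foot_landmarks: Dict[str, np.ndarray]   # heel / calc / toe, scaled
    ankle_offset: np.ndarray                # ankle joint centre, scaled
    foot_inertia_z: float                   # about foot CoM, scaled


@dataclass
class ExternalLoadSeries:
    """Total / left / right GRFs and per-foot CoP, model frame."""

    time: np.ndarray
    total: np.ndarray                 # (N, 3) N
    left: np.ndarray
    right: np.ndarray
    cop_left: Optional[np.ndarray] = None    # (N, 3) m, NaN during swing
    cop_right: Optional[np.ndarray] = None

    def __post_init__(self):
        if not np.allclose(self.left + self.right, self.total, atol=1e-9):
            raise ValueError("left + right GRF must equal total")
        for cop in (self.cop_left, self.cop_right):
            if cop is not None:
                y = cop[..., 1]
                if np.any(y[~np.isnan(y)] != 0.0):
                    raise ValueError("CoP vertical component must be zero")


def scale_body_model(height: float, mass: float,
                     anthropometry: Optional[Mapping] = None) -> BodyModel:
    """Scale the generic 1.68 m model to a participant.

    The scale factor is s = height / 1.68, applied to segment lengths and
    foot landmark offsets; segment masses are generic mass fractions times
    total mass, with the pelvis lump defined as the remainder so the masses
    sum to the total exactly.
    """
    if height <= 0 or mass <= 0:
        raise ValueError("height and mass must be positive")
    a = dict(anthropometry or {})
    fractions = a.get("mass_fractions", anth.MASS_FRACTIONS)
    lengths_g = a.get("segment_lengths", anth.SEGMENT_LENGTHS)
    landmarks_g = a.get("foot_landmarks", anth.FOOT_LANDMARKS)
    ankle_g = a.get("ankle_offset", anth.ANKLE_OFFSET)
    inertia_g = a.get("foot_inertia_z", anth.FOOT_INERTIA_Z)
    generic_h = a.get("generic_height", anth.GENERIC_HEIGHT_M)

    s = height / generic_h
    masses = {
        "thigh": fractions["thigh"] * mass,
        "shank": fractions["shank"] * mass,
        "foot_impaired": fractions["foot"] * mass,
        "foot_contra": fractions["foot"] * mass,
    }
    masses["pelvis"] = mass - sum(masses.values())
    lengths = {k: v * s for k, v in lengths_g.items()}
    landmarks = {k: np.asarray(v, dtype=float) * s
                 for k, v in landmarks_g.items()}
    # inertia scales with mass and the square of the length scale
    inertia = inertia_g * (mass / 75.0) * s**2
    return BodyModel(height=height, mass=mass, scale=s, masses=masses,
                     lengths=lengths, foot_landmarks=landmarks,
                     ankle_offset=np.asarray(ankle_g, dtype=float) * s,
                     foot_inertia_z=inertia)


def to_model_frame(local_acc: np.ndarray, quat: np.ndarray) -> np.ndarray:
    """Rotate sensor-local accelerations into the model frame.

    ``quat`` are unit scalar-first sensor orientations in the z-up global
    frame; the fixed -90 deg rotation about x then maps global (x, y, z)
    to model (x, z, -y).  The output keeps the accelerometer convention
    (specific force: gravity reaction included).
    """
    q = check_unit(quat, tol=1e-3, what="sensor orientation quaternion")
    a_global = as_rotation(q).apply(np.asarray(local_acc, dtype=float))
    return GLOBAL_TO_MODEL.apply(a_global)


def remove_gravity(specific_force_model: np.ndarray) -> np.ndarray:
    """Specific force (accelerometer convention) -> true acceleration."""
    return np.asarray(specific_force_model, dtype=float) + MODEL_GRAVITY


def total_grf(model_acc: Mapping[str, np.ndarray], body: BodyModel) -> np.ndarray:
    """Newton summation F = sum_i m_i (a_i - g) over the five segments.

    ``model_acc`` maps segment name -> true (gravity-removed) acceleration
    in the model frame.
    """
    missing = [k for k in body.masses if k not in model_acc]
    if missing:
        raise KeyError(f"missing segment acceleration streams: {missing}")
    F = None
    for name, m_i in body.masses.items():
        a = np.asarray(model_acc[name], dtype=float)
        term = m_i * (a - MODEL_GRAVITY)
        F = term if F is None else F + term
    return F


def cosine_transition(tau: np.ndarray) -> np.ndarray:
    """Default STA hand-over: trailing-foot share s(tau) = (1+cos(pi tau))/2."""
    return 0.5 * (1.0 + np.cos(np.pi * np.asarray(tau, dtype=float)))


def _impaired_weight(phases: GaitPhaseTable,
                     transition: Callable[[np.ndarray], np.ndarray]
                     ) -> np.ndarray:
    """Impaired-foot load share per sample from the phase table."""
    n = phases.n_samples
    w = np.full(n, np.nan)
    for cyc in phases.cycles:
        a, b = cyc["ds1"]          # impaired leading: ramps 0 -> 1
        tau = np.arange(a, b) - a
        w[a:b] = 1.0 - transition(tau / max(b - a, 1))
        b2, c = cyc["single"]
        w[b2:c] = 1.0
        c2, d = cyc["ds2"]         # impaired trailing: ramps 1 -> 0
        tau = np.arange(c2, d) - c2
        w[c2:d] = transition(tau / max(d - c2, 1))
        d2, e = cyc["swing"]
        w[d2:e] = 0.0
    # clamp uncovered head/tail to the nearest defined state
    idx = np.flatnonzero(~np.isnan(w))
    if len(idx) == 0:
        raise ValueError("phase table covers no samples")
    w[:idx[0]] = w[idx[0]]
    w[idx[-1] + 1:] = w[idx[-1]]
    return w


def split_grf_sta(total: np.ndarray, phases: GaitPhaseTable,
                  impaired_side: str = "left",
                  transition: Optional[Callable] = None
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Split the total GRF into (left, right) via the STA.

    Single stance gives the stance foot 100 %; swing gives 0; during double
    support the trailing foot's share follows the transition function of
    the elapsed double-support fraction (1 at onset, exactly 0 at its TC),
    applied per component; the leading foot takes the exact remainder, so
    left + right = total at every sample.
    """
    total = np.asarray(total, dtype=float)
    if total.shape[0] != phases.n_samples:
        raise ValueError("series length does not match the phase table")
    w = _impaired_weight(phases, transition or cosine_transition)
    imp = w[:, None] * total
    con = total - imp
    # enforce bitwise conservation: re-derive the trailing share from the
    # remainder until fl(imp + con) == total at every sample
    for _ in range(3):
        bad = (imp + con) != total
        if not bad.any():
            break
        imp = np.where(bad, total - con, imp)
    if impaired_side == "left":
        return imp, con
    return con, imp


def landmark_trajectories(foot_pos: np.ndarray, foot_quat: np.ndarray,
                          body: BodyModel) -> Dict[str, np.ndarray]:
    """Global heel / calcaneus-CoM / toe trajectories of one foot:
    p(t) + R(q(t)) applied to the scaled landmark offsets."""
    rot = as_rotation(foot_quat)
    p = np.asarray(foot_pos, dtype=float)
    return {k: p + rot.apply(v) for k, v in body.foot_landmarks.items()}


def estimate_cop(phases: GaitPhaseTable,
                 landmarks_impaired: Mapping[str, np.ndarray],
                 landmarks_contra: Mapping[str, np.ndarray]
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-foot CoP trajectories from the phase table and foot landmarks.

    Within a stance the CoP interpolates heel -> calcaneus CoM over
    [IC, contralateral TC] and calcaneus CoM -> toe over [contralateral TC,
    TC]; the vertical component is set to zero and swing samples are NaN.
    Returns (cop_impaired, cop_contra).
    """
    n = phases.n_samples

    def interp(lm, start, mid, stop):
        out_idx = np.arange(start, stop)
        alpha = np.empty(len(out_idx))
        seg1 = out_idx < mid
        alpha[seg1] = (out_idx[seg1] - start) / max(mid - start, 1)
        alpha[~seg1] = (out_idx[~seg1] - mid) / max(stop - mid, 1)
        a = alpha[:, None]
        p0 = np.where(seg1[:, None], lm["heel"][out_idx], lm["calc"][out_idx])
        p1 = np.where(seg1[:, None], lm["calc"][out_idx], lm["toe"][out_idx])
        return (1 - a) * p0 + a * p1

    cop_imp = np.full((n, 3), np.nan)
    cop_con = np.full((n, 3), np.nan)
    cycles = phases.cycles
    for i, cyc in enumerate(cycles):
        ic = cyc["ds1"][0]
        tc_con = cyc["ds1"][1]
        tc_imp = cyc["ds2"][1]
        if not ic < tc_con < tc_imp:
            raise ValueError("impaired stance lacks an interior "
                             "contralateral TC")
        cop_imp[ic:tc_imp] = interp(landmarks_impaired, ic, tc_con, tc_imp)
        # contralateral stance: its IC is this cycle's single->ds2 boundary,
        # its "contralateral TC" is the impaired TC, and it ends at the
        # next cycle's contralateral TC
        ic_c = cyc["ds2"][0]
        if i + 1 < len(cycles):
            tc_c = cycles[i + 1]["ds1"][1]
            cop_con[ic_c:tc_c] = interp(landmarks_contra, ic_c, tc_imp, tc_c)
    for cop in (cop_imp, cop_con):
        cop[:, 1] = np.where(np.isnan(cop[:, 0]), np.nan, 0.0)
    return cop_imp, cop_con
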