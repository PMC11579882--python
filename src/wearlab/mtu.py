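"""EMG-driven Hill-type muscle-tendon model of the ankle.

Seven muscle-tendon units (MTUs) actuate ankle dorsi-plantar flexion:
tibialis anterior and extensor hallucis longus dorsiflex (positive moment
arms), the two gastrocnemii, soleus and the peroneals plantarflex
(negative moment arms).  Each MTU is a rigid-tendon Hill model:

    F = F_max [a f_l(l~) f_v(v~) + f_p(l~)] cos(phi)

with a Gaussian active force-length curve, a hyperbolic force-velocity
curve anchored at f_v(0) = 1, an exponential passive curve with
f_p(1) = 0, and pennation phi from the constant-muscle-thickness relation.
Excitation u (a normalized EMG envelope) maps to activation through the
nonlinear shaping a = (e^(A u) - 1)/(e^A - 1), A in [-3, 0).

Muscle-tendon length is a per-muscle polynomial in the ankle angle (plus a
linear knee term for the bi-articular gastrocnemii); the moment arm is the
negative analytic derivative with respect to the ankle angle.  Calibration
optimizes, per MTU, the optimal fiber length and tendon slack length
(within ±5 % of their pre-calibrated values), a strength coefficient and
the shape factor, minimizing the mean squared error between the model and
a reference ankle torque normalized by the reference variance over one
calibration gait cycle (seeded bounded global search with local polish).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize as _optimize

from .joint_mechanics import (AgreementMetrics, JointAngleSeries,
                              TorqueSeries, agreement_metrics)
from .preprocess import EnvelopeSet
from .synthetic import MUSCLES

log = logging.getLogger(__name__)

# Hill-curve constants (dimensionless, standard modelling literature values)
FL_WIDTH = 0.45          # Gaussian active force-length width
FV_AF = 0.25             # force-velocity curvature (Hill a/F0)
FV_ECC_GAIN = 0.5        # eccentric force gain above isometric
FV_ECC_CORNER = 0.08
FP_SHAPE = 4.0           # passive exponential shape; f_p(1.5) = 1
VMAX_LOM_PER_S = 10.0    # maximal shortening velocity, optimal lengths/s


@dataclass
class MuscleGeometry:
    """Sagittal MTU path of one muscle.

    ``coeffs`` are polynomial coefficients of L_mt in the ankle angle
    (ascending powers, m vs rad); ``knee_coeff`` adds a linear knee-angle
    term for bi-articular muscles.  Moment arm = -dL_mt/d(theta_ankle).
    """

    coeffs: np.ndarray
    knee_coeff: float
    pennation: float              # at optimal fiber length, rad
    ankle_range: Tuple[float, float] = (-0.9, 0.6)

    def length(self, ankle: np.ndarray, knee: np.ndarray = 0.0) -> np.ndarray:
        th = np.asarray(ankle, dtype=float)
        L = np.polynomial.polynomial.polyval(th, self.coeffs)
        return L + self.knee_coeff * np.asarray(knee, dtype=float)

    def moment_arm(self, ankle: np.ndarray) -> np.ndarray:
        dcoef = np.polynomial.polynomial.polyder(self.coeffs)
        return -np.polynomial.polynomial.polyval(
            np.asarray(ankle, dtype=float), dcoef)


@dataclass
class MtuGeometry:
    muscles: Dict[str, MuscleGeometry]

    def __post_init__(self):
        missing = [m for m in MUSCLES if m not in self.muscles]
        if missing:
            raise ValueError(f"geometry missing muscles: {missing}")


@dataclass
class MtuParams:
    """Per-muscle Hill parameters, muscle order = MUSCLES."""

    l_om: np.ndarray       # optimal fiber length, m
    l_st: np.ndarray       # tendon slack length, m
    strength: np.ndarray   # dimensionless scaling of F_max
    shape_A: np.ndarray    # excitation->activation shape factor, [-3, 0)
    f_max: np.ndarray      # generic maximal isometric force, N

    def __post_init__(self):
        for name in ("l_om", "l_st", "strength", "shape_A", "f_max"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.l_om <= 0) or np.any(self.l_st <= 0):
            raise ValueError("fiber and tendon slack lengths must be positive")
        if np.any(self.shape_A >= 0) or np.any(self.shape_A < -3):
            raise ValueError("shape factor must lie in [-3, 0)")

    def copy(self) -> "MtuParams":
        return MtuParams(self.l_om.copy(), self.l_st.copy(),
                         self.strength.copy(), self.shape_A.copy(),
                         self.f_max.copy())


@dataclass
class CalibrationResult:
    """Outcome of the person-specific calibration."""

    params: MtuParams
    objective_trace: List[float]
    initial_objective: float
    final_objective: float
    fit: AgreementMetrics            # on the calibration cycle
    rmse_per_kg: float
    seed: int
    bounds: np.ndarray
    converged: bool
    message: str = ""


# ---------------------------------------------------------------------------
# default geometry / parameters (plausible sagittal planar asset; the full 3D
# generic-model geometry is deliberately out of scope and users may replace
# every value)

_GENERIC = {
    # name: (l_om, l_st, arm0 at neutral, arm curvature, knee_coeff,
    #        pennation deg, f_max)
    "tibialis_anterior": (0.098, 0.223, +0.040, -0.004, 0.0, 5.0, 905.0),
    "extensor_hallucis_longus": (0.111, 0.305, +0.030, -0.003, 0.0, 6.0, 162.0),
    "gastrocnemius_medialis": (0.060, 0.390, -0.048, +0.005, -0.020, 17.0, 1558.0),
    "gastrocnemius_lateralis": (0.064, 0.385, -0.046, +0.005, -0.018, 8.0, 683.0),
    "soleus": (0.050, 0.250, -0.050, +0.006, 0.0, 25.0, 3549.0),
    "peroneus_brevis": (0.050, 0.161, -0.012, +0.002, 0.0, 5.0, 435.0),
    "peroneus_longus": (0.049, 0.345, -0.014, +0.002, 0.0, 10.0, 943.0),
}


def default_geometry(scale: float = 1.0) -> MtuGeometry:
    """Planar MTU length polynomials scaled from the generic model.

    L_mt(theta) = c0 - arm0 * theta - curv * theta^2 (+ knee term), with c0
    chosen so the fiber sits at optimal length in the neutral pose; all
    length-like coefficients scale linearly with the body scale factor.
    """
    muscles = {}
    for name, (lom, lst, arm0, curv, kc, penn_deg, _) in _GENERIC.items():
        phi = np.radians(penn_deg)
        c0 = lst + lom * np.cos(phi)
        coeffs = np.array([c0, -arm0, -curv]) * scale
        muscles[name] = MuscleGeometry(coeffs=coeffs, knee_coeff=kc * scale,
                                       pennation=phi)
    return MtuGeometry(muscles=muscles)


def generic_params() -> MtuParams:
    g = [_GENERIC[m] for m in MUSCLES]
    return MtuParams(
        l_om=np.array([x[0] for x in g]),
        l_st=np.array([x[1] for x in g]),
        strength=np.ones(len(g)),
        shape_A=np.full(len(g), -1.5),
        f_max=np.array([x[6] for x in g]),
    )


def precalibrate_lom_lst(geometry: MtuGeometry, scale: float,
                         params: Optional[MtuParams] = None,
                         n_grid: int = 25) -> MtuParams:
    """Scale l_om and l_st so the normalized fiber-length curve matches the
    generic model's over a sampled ankle-angle grid (least squares).

    For uniformly scaled geometry the exact solution is l_om' = s l_om,
    l_st' = s l_st; the least-squares formulation also absorbs non-uniform
    geometry edits.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    params = params or generic_params()
    generic_geo = default_geometry(1.0)
    out = params.copy()
    for i, m in enumerate(MUSCLES):
        geo = geometry.muscles[m]
        lo, hi = geo.ankle_range
        grid = np.linspace(lo, hi, n_grid)
        L_scaled = geo.length(grid)
        if np.any(L_scaled <= 0):
            raise ValueError(f"invalid geometry for {m}: non-positive L_mt")
        L_gen = generic_geo.muscles[m].length(grid)
        target = (L_gen - params.l_st[i]) / params.l_om[i]   # ~ l~ cos(phi)
        # L_scaled = l_om' * target + l_st'  (linear least squares)
        A = np.column_stack([target, np.ones_like(target)])
        (lom_new, lst_new), *_ = np.linalg.lstsq(A, L_scaled, rcond=None)
        if lom_new <= 0 or lst_new <= 0:
            raise ValueError(f"pre-calibration produced non-positive lengths "
                             f"for {m}")
        out.l_om[i] = lom_new
        out.l_st[i] = lst_new
    return out


# ---------------------------------------------------------------------------
# Hill-type pipeline

def excitation_to_activation(u: np.ndarray, A: float) -> np.ndarray:
    """Nonlinear excitation-to-activation shaping.

    a = (e^(A u) - 1) / (e^A - 1); monotone with fixed endpoints a(0)=0,
    a(1)=1; tends to the identity as A -> 0-.
    """
    if not -3.0 <= A < 0.0:
        raise ValueError("shape factor A must lie in [-3, 0)")
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    return np.expm1(A * u) / np.expm1(A)


def mtu_length_and_arm(angles: JointAngleSeries, geometry: MtuGeometry
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-muscle MTU length and ankle moment-arm series.

    Ankle angles outside a muscle's validity range are clamped (logged);
    returns (L_mt, arm) arrays of shape (N, n_muscles), muscle order =
    MUSCLES.
    """
    L_cols, r_cols = [], []
    for m in MUSCLES:
        geo = geometry.muscles[m]
        lo, hi = geo.ankle_range
        th = np.asarray(angles.ankle, dtype=float)
        n_clamped = int(np.sum((th < lo) | (th > hi)))
        if n_clamped:
            log.warning("%s: %d ankle samples outside [%g, %g] rad clamped",
                        m, n_clamped, lo, hi)
        th = np.clip(th, lo, hi)
        L_cols.append(geo.length(th, angles.knee))
        r_cols.append(geo.moment_arm(th))
    return np.column_stack(L_cols), np.column_stack(r_cols)


def _force_velocity(v_norm: np.ndarray) -> np.ndarray:
    """Hyperbolic force-velocity curve; v_norm < 0 shortening, f_v(0)=1."""
    v = np.clip(np.asarray(v_norm, dtype=float), -1.0, 1.0)
    con = np.clip((1.0 + v) / (1.0 - v / FV_AF), 0.0, None)
    ecc = 1.0 + FV_ECC_GAIN * v / (v + FV_ECC_CORNER)
    return np.where(v < 0, con, ecc)


def _force_length_active(l_norm: np.ndarray) -> np.ndarray:
    return np.exp(-((np.asarray(l_norm) - 1.0) ** 2) / FL_WIDTH)


def _force_length_passive(l_norm: np.ndarray) -> np.ndarray:
    f = np.expm1(FP_SHAPE * (np.asarray(l_norm) - 1.0)) / np.expm1(FP_SHAPE * 0.5)
    return np.clip(f, 0.0, None)


def hill_mtu_force(a: np.ndarray, L_mt: np.ndarray, dLmt_dt: np.ndarray,
                   l_om: float, l_st: float, f_max: float,
                   pennation: float) -> np.ndarray:
    """Rigid-tendon Hill-type fiber force along the tendon, N.

    Fiber kinematics follow the constant-thickness pennation relation
    (width w = l_om sin(phi0)); MTU segments shorter than the tendon slack
    length produce zero active force (flagged).
    """
    a = np.asarray(a, dtype=float)
    L_mt = np.asarray(L_mt, dtype=float)
    proj = L_mt - l_st                       # fiber length along the tendon
    slack = proj <= 0
    if np.any(slack):
        log.warning("%d samples with L_mt <= tendon slack length; active "
                    "force zeroed", int(slack.sum()))
    w = l_om * np.sin(pennation)
    l_m = np.sqrt(np.clip(proj, 0.0, None) ** 2 + w**2)
    cos_phi = np.where(l_m > 0, np.clip(proj, 0.0, None) / np.where(l_m > 0, l_m, 1.0), 1.0)
    l_norm = l_m / l_om
    v_norm = np.asarray(dLmt_dt, dtype=float) / (VMAX_LOM_PER_S * l_om)
    active = a * _force_length_active(l_norm) * _force_velocity(v_norm)
    active = np.where(slack, 0.0, active)
    force = f_max * (active + _force_length_passive(l_norm)) * cos_phi
    return np.clip(force, 0.0, None)


def ankle_torque_from_mtus(forces: np.ndarray, arms: np.ndarray,
                           time: np.ndarray, rate: float, body_mass: float,
                           provenance: str = "EMG-driven") -> TorqueSeries:
    """Sum per-muscle force x moment-arm contributions into ankle torque.

    Plantar flexors (negative arms) contribute negative torque.
    """
    forces = np.atleast_2d(forces)
    arms = np.atleast_2d(arms)
    if forces.shape != arms.shape:
        raise ValueError("force and moment-arm series have mismatched "
                         "muscle sets")
    tau = np.sum(forces * arms, axis=1)
    return TorqueSeries(time=time, rate=rate, torque=tau,
                        body_mass=body_mass, provenance=provenance)


def _forward_torque(params: MtuParams, geometry: MtuGeometry,
                    envelopes: np.ndarray, angles: JointAngleSeries,
                    activation_lowpass_hz: Optional[float] = None
                    ) -> np.ndarray:
    """Full EMG-driven chain: activation -> MTU kinematics -> Hill force ->
    torque.  ``envelopes`` has one column per muscle (MUSCLES order).

    Envelopes are assumed already low-pass equivalent (the moving-median
    stage); ``activation_lowpass_hz`` optionally applies an extra 2nd-order
    zero-lag smoothing before the nonlinearity.
    """
    if activation_lowpass_hz:
        from .preprocess import butterworth_zero_lag
        envelopes = np.clip(butterworth_zero_lag(
            envelopes, activation_lowpass_hz, angles.rate, kind="low"),
            0.0, 1.0)
    L, arms = mtu_length_and_arm(angles, geometry)
    dL = np.gradient(L, axis=0, edge_order=2) * angles.rate
    tau = np.zeros(L.shape[0])
    for i in range(len(MUSCLES)):
        a = excitation_to_activation(envelopes[:, i], float(params.shape_A[i]))
        f = hill_mtu_force(a, L[:, i], dL[:, i],
                           float(params.l_om[i]), float(params.l_st[i]),
                           float(params.f_max[i] * params.strength[i]),
                           float(geometry.muscles[MUSCLES[i]].pennation))
        tau += f * arms[:, i]
    return tau


def estimate_torque(params: MtuParams, geometry: MtuGeometry,
                    envelopes: EnvelopeSet, angles: JointAngleSeries,
                    body_mass: float,
                    activation_lowpass_hz: Optional[float] = None
                    ) -> TorqueSeries:
    """EMG-driven ankle torque on (possibly unseen) data.

    Consumes normalized muscle-specific envelopes and joint angles only —
    no reference torque.
    """
    env = _aligned_envelopes(envelopes, angles)
    tau = _forward_torque(params, geometry, env, angles,
                          activation_lowpass_hz)
    return TorqueSeries(time=angles.time, rate=angles.rate, torque=tau,
                        body_mass=body_mass, provenance="EMG-driven")


def _aligned_envelopes(envelopes: EnvelopeSet,
                       angles: JointAngleSeries) -> np.ndarray:
    """Resample muscle envelopes onto the joint-angle time base."""
    if list(envelopes.labels) != list(MUSCLES):
        raise ValueError("envelope set must hold the seven muscle-specific "
                         "envelopes (MUSCLES order)")
    n_env = envelopes.data.shape[0]
    if n_env == len(angles.time):
        return envelopes.data
    t_env = np.arange(n_env) / envelopes.rate
    return np.column_stack([
        np.interp(angles.time, t_env, envelopes.data[:, i])
        for i in range(envelopes.data.shape[1])])


def _pack_bounds(init: MtuParams, lom_lst_frac: float,
                 strength_bounds: Tuple[float, float],
                 shape_bounds: Tuple[float, float]) -> np.ndarray:
    rows = []
    for i in range(len(MUSCLES)):
        rows.append((init.l_om[i] * (1 - lom_lst_frac),
                     init.l_om[i] * (1 + lom_lst_frac)))
        rows.append((init.l_st[i] * (1 - lom_lst_frac),
                     init.l_st[i] * (1 + lom_lst_frac)))
        rows.append(strength_bounds)
        rows.append(shape_bounds)
    return np.array(rows)


def _unpack(x: np.ndarray, template: MtuParams) -> MtuParams:
    x = np.asarray(x, dtype=float).reshape(len(MUSCLES), 4)
    p = template.copy()
    p.l_om = x[:, 0].copy()
    p.l_st = x[:, 1].copy()
    p.strength = x[:, 2].copy()
    p.shape_A = x[:, 3].copy()
    return p


def _pack(params: MtuParams) -> np.ndarray:
    return np.column_stack([params.l_om, params.l_st,
                            params.strength, params.shape_A]).ravel()


def calibrate(envelopes: EnvelopeSet, angles: JointAngleSeries,
              ref_torque: TorqueSeries, geometry: MtuGeometry,
              init: MtuParams, seed: int = 0,
              lom_lst_frac: float = 0.05,
              strength_bounds: Tuple[float, float] = (0.5, 2.0),
              shape_bounds: Tuple[float, float] = (-3.0, -0.01),
              maxiter: int = 60, popsize: int = 12,
              polish: bool = True) -> CalibrationResult:
    """Person-specific calibration of the EMG-driven model.

    Minimizes J = MSE(tau_model, tau_ref) / Var(tau_ref) over one
    calibration gait cycle with a seeded bounded differential-evolution
    search over all per-muscle parameters (l_om and l_st within
    ±``lom_lst_frac`` of their pre-calibrated values), followed by a local
    polish.  The returned objective never exceeds the initial one.
    """
    env = _aligned_envelopes(envelopes, angles)
    ref = np.asarray(ref_torque.torque, dtype=float)
    if len(ref) != len(angles.time):
        raise ValueError("reference torque and angles are misaligned")
    var = float(np.var(ref))
    if var == 0:
        raise ValueError("reference torque has zero variance")

    def objective(x: np.ndarray) -> float:
        tau = _forward_torque(_unpack(x, init), geometry, env, angles)
        return float(np.mean((tau - ref) ** 2) / var)

    bounds = _pack_bounds(init, lom_lst_frac, strength_bounds, shape_bounds)
    x0 = np.clip(_pack(init), bounds[:, 0], bounds[:, 1])
    j0 = objective(x0)
    trace: List[float] = [j0]

    result = _optimize.differential_evolution(
        objective, bounds=bounds, x0=x0, seed=seed, maxiter=maxiter,
        popsize=popsize, tol=1e-10, polish=polish, updating="deferred",
        workers=1, init="sobol",
        callback=lambda xk, convergence=0.0: trace.append(objective(xk)))

    best_x, best_j = result.x, float(result.fun)
    if j0 <= best_j:          # never regress below the supplied start
        best_x, best_j = x0, j0
    params = _unpack(best_x, init)
    tau = _forward_torque(params, geometry, env, angles)
    fit = agreement_metrics(ref, tau)
    rmse_kg = float(np.sqrt(np.mean((ref - tau) ** 2)) / ref_torque.body_mass)
    if not result.success:
        log.warning("calibration optimizer did not converge: %s "
                    "(best-so-far returned)", result.message)
    return CalibrationResult(
        params=params, objective_trace=trace, initial_objective=j0,
        final_objective=best_j, fit=fit, rmse_per_kg=rmse_kg, seed=seed,
        bounds=bounds, converged=bool(result.success),
        message=str(result.message))
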