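"""Hill-type MTU model, geometry, pre-calibration and calibration."""

import numpy as np
import pytest

from wearlab import joint_mechanics as jm
from wearlab import mtu
from wearlab import preprocess as pre
from wearlab import synthetic as syn
from wearlab.kinetics import scale_body_model

SCALE = 1.775 / 1.68


@pytest.fixture(scope="module")
def geometry():
    return mtu.default_geometry(SCALE)


@pytest.fixture(scope="module")
def cycle_data():
    """One noise-free gait cycle of truth angles + activations."""
    cfg = syn.SyntheticConfig(n_cycles=3, imu_noise_acc_sd=0.0,
                              imu_noise_gyro_sd=0.0)
    body = scale_body_model(cfg.height, cfg.mass)
    poses = syn.generate_segment_kinematics(cfg)
    truth = syn.truth_loads(poses, body, cfg)
    r = cfg.imu_rate
    a, b = int(cfg.cycle_time * r), int(2 * cfg.cycle_time * r)
    angles = jm.JointAngleSeries(time=truth.time[a:b] - truth.time[a], rate=r,
                                 knee=truth.knee_angle[a:b],
                                 ankle=truth.ankle_angle[a:b])
    env = pre.EnvelopeSet(data=truth.activations[a:b], rate=r,
                          labels=list(syn.MUSCLES))
    return angles, env, body


class TestPrecalibration:
    def test_unit_scale_leaves_parameters_unchanged(self):
        geo = mtu.default_geometry(1.0)
        out = mtu.precalibrate_lom_lst(geo, 1.0)
        gen = mtu.generic_params()
        assert np.allclose(out.l_om, gen.l_om, atol=1e-9)
        assert np.allclose(out.l_st, gen.l_st, atol=1e-9)

    def test_uniform_scaling_preserves_normalized_fiber_length(self, geometry):
        out = mtu.precalibrate_lom_lst(geometry, SCALE)
        gen = mtu.generic_params()
        assert np.allclose(out.l_om, SCALE * gen.l_om, atol=1e-9)
        assert np.allclose(out.l_st, SCALE * gen.l_st, atol=1e-9)

    def test_outputs_always_positive(self, geometry):
        out = mtu.precalibrate_lom_lst(geometry, 0.8)
        assert np.all(out.l_om > 0)
        assert np.all(out.l_st > 0)


class TestActivation:
    def test_endpoints_fixed(self):
        assert mtu.excitation_to_activation(0.0, -2.0) == 0.0
        assert mtu.excitation_to_activation(1.0, -2.0) == pytest.approx(1.0)

    def test_linear_limit_as_shape_vanishes(self):
        u = np.linspace(0, 1, 11)
        a = mtu.excitation_to_activation(u, -1e-6)
        assert np.abs(a - u).max() <= 1e-5

    def test_monotone_increasing(self):
        u = np.linspace(0, 1, 200)
        a = mtu.excitation_to_activation(u, -2.5)
        assert np.all(np.diff(a) > 0)

    def test_shape_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mtu.excitation_to_activation(0.5, 0.5)
        with pytest.raises(ValueError):
            mtu.excitation_to_activation(0.5, -3.5)


class TestGeometryOps:
    def test_constant_length_gives_zero_arm(self):
        geo = mtu.MuscleGeometry(coeffs=np.array([0.3]), knee_coeff=0.0,
                                 pennation=0.1)
        th = np.linspace(-0.5, 0.5, 7)
        assert np.allclose(geo.moment_arm(th), 0.0)

    def test_linear_length_gives_constant_arm(self):
        geo = mtu.MuscleGeometry(coeffs=np.array([0.3, -0.05]), knee_coeff=0.0,
                                 pennation=0.1)
        assert np.allclose(geo.moment_arm(np.linspace(-0.5, 0.5, 7)), 0.05)

    def test_analytic_arm_matches_finite_differences(self, geometry):
        angles = jm.JointAngleSeries(time=np.arange(50) / 100.0, rate=100.0,
                                     knee=np.zeros(50),
                                     ankle=np.linspace(-0.5, 0.4, 50))
        L, arms = mtu.mtu_length_and_arm(angles, geometry)
        h = 1e-6
        for i, m in enumerate(syn.MUSCLES):
            geo = geometry.muscles[m]
            fd = -(geo.length(angles.ankle + h) - geo.length(angles.ankle - h)
                   ) / (2 * h)
            assert np.abs(arms[:, i] - fd).max() <= 1e-6, m

    def test_sign_conventions_over_neutral_range(self, geometry):
        th = np.linspace(-0.3, 0.3, 21)
        for m in ("tibialis_anterior", "extensor_hallucis_longus"):
            assert np.all(geometry.muscles[m].moment_arm(th) > 0), m
        for m in ("gastrocnemius_medialis", "gastrocnemius_lateralis",
                  "soleus", "peroneus_brevis", "peroneus_longus"):
            assert np.all(geometry.muscles[m].moment_arm(th) < 0), m

    def test_missing_muscle_rejected(self):
        with pytest.raises(ValueError):
            mtu.MtuGeometry(muscles={"soleus": mtu.MuscleGeometry(
                coeffs=np.array([0.3]), knee_coeff=0.0, pennation=0.1)})


class TestHillForce:
    L_OM, L_ST, F_MAX, PHI = 0.05, 0.25, 1000.0, np.radians(25.0)

    def _lmt_at_optimal(self):
        return self.L_ST + self.L_OM * np.cos(self.PHI)

    def test_passive_anchor_zero_at_optimal_length(self):
        F = mtu.hill_mtu_force(np.zeros(1), np.full(1, self._lmt_at_optimal()),
                               np.zeros(1), self.L_OM, self.L_ST, self.F_MAX,
                               self.PHI)
        assert F[0] == pytest.approx(0.0, abs=1e-9)

    def test_isometric_anchor_fmax_cos_pennation(self):
        F = mtu.hill_mtu_force(np.ones(1), np.full(1, self._lmt_at_optimal()),
                               np.zeros(1), self.L_OM, self.L_ST, self.F_MAX,
                               self.PHI)
        assert F[0] == pytest.approx(self.F_MAX * np.cos(self.PHI), rel=1e-9)

    def test_force_monotone_in_activation(self):
        a = np.linspace(0, 1, 30)
        L = np.full(30, self._lmt_at_optimal() + 0.003)
        F = mtu.hill_mtu_force(a, L, np.zeros(30), self.L_OM, self.L_ST,
                               self.F_MAX, self.PHI)
        assert np.all(np.diff(F) >= 0)

    def test_slack_mtu_produces_no_active_force(self):
        F = mtu.hill_mtu_force(np.ones(2), np.full(2, self.L_ST - 0.01),
                               np.zeros(2), self.L_OM, self.L_ST, self.F_MAX,
                               self.PHI)
        assert np.all(F >= 0)
        # passive term at near-zero fiber length is clipped to zero too
        assert np.allclose(F, 0.0, atol=1e-9)

    def test_force_never_negative(self):
        rng = np.random.default_rng(3)
        L = self.L_ST + rng.uniform(-0.02, 0.08, 100)
        F = mtu.hill_mtu_force(rng.uniform(0, 1, 100), L,
                               rng.uniform(-0.5, 0.5, 100), self.L_OM,
                               self.L_ST, self.F_MAX, self.PHI)
        assert np.all(F >= 0)


class TestTorqueSum:
    def test_zero_forces_zero_torque(self):
        tq = mtu.ankle_torque_from_mtus(np.zeros((10, 7)), np.ones((10, 7)),
                                        np.arange(10) / 100.0, 100.0, 80.0)
        assert np.all(tq.torque == 0.0)

    def test_single_muscle_arithmetic(self):
        F = np.full((5, 1), 100.0)
        r = np.full((5, 1), -0.05)
        tq = mtu.ankle_torque_from_mtus(F, r, np.arange(5) / 100.0, 100.0, 80.0)
        assert np.allclose(tq.torque, -5.0)

    def test_mismatched_muscle_sets_rejected(self):
        with pytest.raises(ValueError):
            mtu.ankle_torque_from_mtus(np.zeros((5, 7)), np.zeros((5, 6)),
                                       np.arange(5) / 100.0, 100.0, 80.0)

    def test_soleus_bump_gives_plantarflexion_torque(self, geometry,
                                                     cycle_data):
        angles, env, body = cycle_data
        params = mtu.precalibrate_lom_lst(geometry, SCALE)
        data = np.zeros_like(env.data)
        i_sol = list(syn.MUSCLES).index("soleus")
        data[:, i_sol] = env.data[:, i_sol]
        only_sol = pre.EnvelopeSet(data=data, rate=env.rate,
                                   labels=list(env.labels))
        tq = mtu.estimate_torque(params, geometry, only_sol, angles, body.mass)
        passive = mtu.estimate_torque(
            params, geometry,
            pre.EnvelopeSet(data=np.zeros_like(data), rate=env.rate,
                            labels=list(env.labels)),
            angles, body.mass)
        active = tq.torque - passive.torque
        bump = data[:, i_sol] > 0.3
        assert np.all(active[bump] < 0.0)


class TestCalibration:
    def _true_and_ref(self, geometry, cycle_data, seed=7):
        angles, env, body = cycle_data
        rng = np.random.default_rng(seed)
        base = mtu.precalibrate_lom_lst(geometry, SCALE)
        true = base.copy()
        true.l_om = true.l_om * rng.uniform(0.96, 1.04, 7)
        true.l_st = true.l_st * rng.uniform(0.96, 1.04, 7)
        true.strength = rng.uniform(0.7, 1.6, 7)
        true.shape_A = rng.uniform(-2.5, -0.3, 7)
        tau = mtu._forward_torque(true, geometry, env.data, angles)
        ref = jm.TorqueSeries(time=angles.time, rate=angles.rate, torque=tau,
                              body_mass=body.mass, provenance="ID-reference")
        return base, true, ref

    def test_self_consistent_start_has_zero_objective(self, geometry,
                                                      cycle_data):
        angles, env, body = cycle_data
        base, true, ref = self._true_and_ref(geometry, cycle_data)
        res = mtu.calibrate(env, angles, ref, geometry, true, seed=0,
                            maxiter=2, popsize=4, polish=False)
        assert res.initial_objective <= 1e-18
        assert res.final_objective <= res.initial_objective + 1e-18

    def test_parameter_recovery_on_calibration_cycle(self, geometry,
                                                     cycle_data):
        angles, env, body = cycle_data
        base, true, ref = self._true_and_ref(geometry, cycle_data)
        res = mtu.calibrate(env, angles, ref, geometry, base, seed=1,
                            maxiter=45, popsize=10)
        assert res.final_objective <= res.initial_objective
        assert res.fit.r2 >= 0.99
        assert res.rmse_per_kg <= 0.02

    def test_same_seed_gives_identical_result(self, geometry, cycle_data):
        angles, env, body = cycle_data
        base, true, ref = self._true_and_ref(geometry, cycle_data)
        r1 = mtu.calibrate(env, angles, ref, geometry, base, seed=3,
                           maxiter=5, popsize=4, polish=False)
        r2 = mtu.calibrate(env, angles, ref, geometry, base, seed=3,
                           maxiter=5, popsize=4, polish=False)
        assert np.array_equal(r1.params.l_om, r2.params.l_om)
        assert np.array_equal(r1.params.strength, r2.params.strength)
        assert r1.final_objective == r2.final_objective

    def test_zero_variance_reference_rejected(self, geometry, cycle_data):
        angles, env, body = cycle_data
        flat = jm.TorqueSeries(time=angles.time, rate=angles.rate,
                               torque=np.zeros(len(angles.time)),
                               body_mass=body.mass)
        with pytest.raises(ValueError, match="variance"):
            mtu.calibrate(env, angles, flat, geometry,
                          mtu.precalibrate_lom_lst(geometry, SCALE))

    def test_objective_invariant_to_common_torque_rescaling(self, geometry,
                                                            cycle_data):
        angles, env, body = cycle_data
        base, true, ref = self._true_and_ref(geometry, cycle_data)
        res1 = mtu.calibrate(env, angles, ref, geometry, base, seed=0,
                             maxiter=1, popsize=4, polish=False)
        # rescale reference and model torques by the same constant: scale
        # f_max (model output) and the reference by 2
        base2 = base.copy()
        base2.f_max = base2.f_max * 2.0
        ref2 = jm.TorqueSeries(time=ref.time, rate=ref.rate,
                               torque=2.0 * ref.torque,
                               body_mass=body.mass)
        res2 = mtu.calibrate(env, angles, ref2, geometry, base2, seed=0,
                             maxiter=1, popsize=4, polish=False)
        assert res2.initial_objective == pytest.approx(
            res1.initial_objective, rel=1e-12)


class TestEstimation:
    def test_zero_envelopes_give_passive_only_torque(self, geometry,
                                                     cycle_data):
        angles, env, body = cycle_data
        params = mtu.precalibrate_lom_lst(geometry, SCALE)
        zero = pre.EnvelopeSet(data=np.zeros_like(env.data), rate=env.rate,
                               labels=list(env.labels))
        tq = mtu.estimate_torque(params, geometry, zero, angles, body.mass)
        L, arms = mtu.mtu_length_and_arm(angles, geometry)
        passive = np.zeros(len(angles.time))
        for i, m in enumerate(syn.MUSCLES):
            geo = geometry.muscles[m]
            proj = np.clip(L[:, i] - params.l_st[i], 0.0, None)
            w = params.l_om[i] * np.sin(geo.pennation)
            l_m = np.sqrt(proj**2 + w**2)
            fp = np.clip(np.expm1(4.0 * (l_m / params.l_om[i] - 1.0))
                         / np.expm1(2.0), 0.0, None)
            passive += (params.f_max[i] * fp * (proj / l_m)) * arms[:, i]
        assert np.allclose(tq.torque, passive, atol=1e-9)

    def test_halving_envelopes_touches_only_active_component(self, geometry,
                                                             cycle_data):
        angles, env, body = cycle_data
        params = mtu.precalibrate_lom_lst(geometry, SCALE)
        half = pre.EnvelopeSet(data=0.5 * env.data, rate=env.rate,
                               labels=list(env.labels))
        t_full = mtu.estimate_torque(params, geometry, env, angles, body.mass)
        t_half = mtu.estimate_torque(params, geometry, half, angles, body.mass)
        silent = np.all(env.data < 1e-12, axis=1)
        assert silent.sum() == 0 or np.allclose(
            t_full.torque[silent], t_half.torque[silent], atol=1e-12)
        active = env.data.max(axis=1) > 0.3
        assert not np.allclose(t_full.torque[active], t_half.torque[active])

    def test_optional_activation_filter_smooths_torque(self, geometry,
                                                       cycle_data):
        angles, env, body = cycle_data
        params = mtu.precalibrate_lom_lst(geometry, SCALE)
        raw = mtu.estimate_torque(params, geometry, env, angles, body.mass)
        smoothed = mtu.estimate_torque(params, geometry, env, angles,
                                       body.mass, activation_lowpass_hz=4.0)
        assert not np.allclose(raw.torque, smoothed.torque)
        # smoothing reduces high-frequency torque content
        assert np.std(np.diff(smoothed.torque)) <= np.std(np.diff(raw.torque))

    def test_generalizes_to_held_out_cadence(self, geometry, cycle_data):
        """Calibrated on one cycle, the model reproduces the generating
        torque on a cycle at a different cadence (R^2 >= 0.95)."""
        angles, env, body = cycle_data
        rng = np.random.default_rng(7)
        base = mtu.precalibrate_lom_lst(geometry, SCALE)
        true = base.copy()
        true.strength = rng.uniform(0.7, 1.6, 7)
        true.shape_A = rng.uniform(-2.5, -0.3, 7)
        tau = mtu._forward_torque(true, geometry, env.data, angles)
        ref = jm.TorqueSeries(time=angles.time, rate=angles.rate, torque=tau,
                              body_mass=body.mass)
        res = mtu.calibrate(env, angles, ref, geometry, base, seed=2,
                            maxiter=25, popsize=8)
        cfg2 = syn.SyntheticConfig(cadence=85.0, n_cycles=3,
                                   imu_noise_acc_sd=0.0, imu_noise_gyro_sd=0.0)
        body2 = scale_body_model(cfg2.height, cfg2.mass)
        poses2 = syn.generate_segment_kinematics(cfg2)
        truth2 = syn.truth_loads(poses2, body2, cfg2)
        r = cfg2.imu_rate
        a, b = int(cfg2.cycle_time * r), int(2 * cfg2.cycle_time * r)
        angles2 = jm.JointAngleSeries(time=truth2.time[a:b] - truth2.time[a],
                                      rate=r, knee=truth2.knee_angle[a:b],
                                      ankle=truth2.ankle_angle[a:b])
        env2 = pre.EnvelopeSet(data=truth2.activations[a:b], rate=r,
                               labels=list(syn.MUSCLES))
        tau_true = mtu._forward_torque(true, geometry, env2.data, angles2)
        est = mtu.estimate_torque(res.params, geometry, env2, angles2,
                                  body2.mass)
        m = jm.agreement_metrics(tau_true, est.torque)
        assert m.r2 >= 0.95
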