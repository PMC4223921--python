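"""Fourier trajectories, the constraint model, reference extraction,
feed-forward closure and the ZMP feasibility check."""

import dataclasses

import numpy as np
import pytest

from gaitmanifold import BodyParameters, ContactParams, GainSet
from gaitmanifold.params import Schedule, SimConfig
from gaitmanifold.trajectory import (FixtureTemplate, FourierTrajectory,
                                     design_trajectory,
                                     discretize_trajectory, eval_trajectory,
                                     load_fixture, check_zmp,
                                     simulate_constraint_model,
                                     zmp_from_state)
from gaitmanifold.experiments import run_gait


@pytest.fixture(scope="module")
def fixture_traj():
    traj, init, meta = load_fixture()
    return traj, init, meta


class TestFourierTrajectory:
    def test_exact_periodicity(self, fixture_traj):
        traj = fixture_traj[0]
        phases = np.linspace(0, 1, 13, endpoint=False)
        q0, v0, a0 = traj.evaluate(phases)
        q1, v1, a1 = traj.evaluate(phases + 1.0)
        assert np.allclose(q0, q1, atol=1e-12)
        assert np.allclose(v0, v1, atol=1e-10)
        assert np.allclose(a0, a1, atol=1e-8)

    def test_analytic_derivatives_match_finite_differences(self, fixture_traj):
        traj = fixture_traj[0]
        h = 1e-5  # cycle units
        for phi in (0.13, 0.49, 0.77):
            qp, _, _ = traj.evaluate(phi + h)
            qm, _, _ = traj.evaluate(phi - h)
            _, v, a = traj.evaluate(phi)
            v_fd = (qp - qm) / (2 * h * traj.T)
            assert np.abs(v - v_fd).max() < 1e-5 * max(1, np.abs(v).max())
            vp = traj.evaluate(phi + h)[1]
            vm = traj.evaluate(phi - h)[1]
            a_fd = (vp - vm) / (2 * h * traj.T)
            assert np.abs(a - a_fd).max() < 1e-4 * max(1, np.abs(a).max())

    def test_half_period_symmetry(self, fixture_traj):
        traj = fixture_traj[0]
        assert traj.check_symmetry()
        phases = np.linspace(0, 1, 7, endpoint=False)
        qL = traj.evaluate(phases)[0][:, :3]
        qR = traj.evaluate(phases + 0.5)[0][:, 3:]
        assert np.allclose(qL, qR, atol=1e-10)

    def test_csv_round_trip(self, fixture_traj, tmp_path):
        traj = fixture_traj[0]
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = FourierTrajectory.from_csv(path)
        assert back.T == traj.T
        assert np.allclose(back.a, traj.a, atol=0)
        assert np.allclose(back.b, traj.b, atol=0)

    def test_csv_reader_rejects_broken_symmetry(self, fixture_traj, tmp_path):
        traj = fixture_traj[0]
        bad = FourierTrajectory(T=traj.T, a=traj.a.copy(), b=traj.b.copy())
        bad.a[3, 1] += 0.01
        path = tmp_path / "bad.csv"
        bad.to_csv(path)
        with pytest.raises(ValueError):
            FourierTrajectory.from_csv(path)

    def test_functional_wrapper(self, fixture_traj):
        traj = fixture_traj[0]
        q1 = eval_trajectory(traj, 0.2)[0]
        q2 = traj.evaluate(0.2)[0]
        assert np.array_equal(q1, q2)


class TestDiscretization:
    def test_positions_exactly_periodic(self, fixture_traj):
        traj = fixture_traj[0]
        Q, V, A = discretize_trajectory(traj, 1e-4)
        wrap = Q[-1] + 1e-4 * V[-1] - Q[0]
        assert np.abs(wrap).max() < 1e-12

    def test_accelerations_are_forward_differences(self, fixture_traj):
        traj = fixture_traj[0]
        Q, V, A = discretize_trajectory(traj, 1e-4)
        assert np.allclose(V[1:], V[:-1] + 1e-4 * A[:-1], atol=1e-14)

    def test_non_divisible_step_rejected(self, fixture_traj):
        with pytest.raises(ValueError):
            discretize_trajectory(fixture_traj[0], 3e-4)


class TestFixture:
    def test_period_matches_study_value(self, fixture_traj):
        assert fixture_traj[0].T == 1.135

    def test_design_is_deterministic(self, fixture_traj):
        """Re-designing from the committed template reproduces the
        committed coefficients bit for bit."""
        traj, _, meta = fixture_traj
        tpl = FixtureTemplate(**meta["template"])
        redo, init = design_trajectory(tpl)
        assert np.allclose(redo.a, traj.a, atol=1e-12)
        assert np.allclose(redo.b, traj.b, atol=1e-12)
        assert np.all(np.isfinite(init))


class TestConstraintModel:
    def test_steady_state_extraction(self, ref):
        """The packaged fixture walks and converges stroboscopically;
        periodicity holds in every component except the advancing q2."""
        assert ref.strobo_residual < 1e-6
        assert ref.periodicity_residual() < 1e-9
        assert ref.stride > 0.5

    def test_double_support_fraction_physiological(self, ref):
        # one of the two double-support episodes, as a cycle fraction
        assert 0.05 < ref.ds_fraction / 2 < 0.25

    def test_zero_gravity_airborne_is_inertial(self, contact):
        """With gravity off and no contact the total centre of mass
        translates uniformly (limb swing only redistributes momentum)."""
        import oracle
        body = BodyParameters(g=1e-12)
        traj, _, _ = load_fixture()
        init = np.array([0.0, 0.0, 50.0, 0.0, 0.9, 0.1])
        run = simulate_constraint_model(traj, body, contact, init, 2,
                                        dt=1e-5, record=False)
        assert run.fall_cycle is None
        Q, _, _ = discretize_trajectory(traj, 1e-5)
        m = oracle.MASSES

        def com(h):
            st = oracle.body_states(np.concatenate([h[:3], Q[0]]))
            return np.array([sum(m[i] * st[i][0] for i in range(7)),
                             sum(m[i] * st[i][1] for i in range(7))]) / m.sum()

        c = [com(run.strobo[k]) for k in range(3)]
        assert np.allclose(c[1] - c[0], c[2] - c[1], rtol=1e-4, atol=1e-5)

    def test_stiff_tracking_matches_constraint_model(self, ref):
        """Full model with very stiff PD from a perturbed start follows
        the constraint model's HAT motion closely."""
        body, contact = ref.body, ref.contact
        init = ref.init_hat + np.array([1e-3, 0, 0, 0, 0, 0])
        crun = simulate_constraint_model(ref.traj, body, contact, init, 1,
                                         dt=ref.dt, record=True)
        stiff = GainSet(Pa=1e6, Pk=1e6, Ph=1e6, Da=50, Dk=50, Dh=50)
        x0 = ref.X[0].copy()
        x0[:3] = init[:3]
        x0[9:12] = init[3:]
        cfg = SimConfig(dt=ref.dt, n_cycles=1, gains=stiff,
                        schedule=Schedule(mode="off"),
                        perturbation={}, output_stride=100)
        res = run_gait(dataclasses.replace(cfg), ref)
        # compare HAT tilt series (both runs started from the same HAT)
        full = res.states[:, 0]
        red = crun.X[::100, 0]
        x0r = ref.X[0]
        # reconstruct the full-model start: same joints, perturbed HAT
        assert np.abs(full[0] - x0r[0]) < 2e-3
        assert np.abs(full[: len(red)] - (red + (full[0] - red[0]))).max() < 5e-3


class TestFeedForward:
    def test_hat_rows_vanish(self, ref):
        peak = np.abs(ref.Uff[:, 3:]).max()
        assert np.abs(ref.Uff[:, :3]).max() < 1e-3 * peak

    def test_discrete_closure_any_gains(self, ref):
        """Feed-forward playback keeps the model on the reference for a
        full cycle regardless of the PD gains (exact-orbit property)."""
        cases = (
            # open loop: non-normal contact transients amplify rounding,
            # so the envelope is wider while still tiny on state scale
            (GainSet(Pa=0, Pk=0, Ph=0, Da=0, Dk=0, Dh=0), 1e-3),
            (GainSet(Pa=500, Pk=500, Ph=500, Da=30, Dk=30, Dh=30), 1e-9),
            (GainSet(), 1e-9),
        )
        for gains, envelope in cases:
            cfg = SimConfig(dt=ref.dt, n_cycles=1, gains=gains,
                            schedule=Schedule(mode="off"), perturbation={},
                            output_stride=ref.N)
            res = run_gait(cfg, ref)
            assert not res.fell
            err = res.strobo[1] - ref.X[0]
            err[1] -= ref.stride
            assert np.abs(err).max() < envelope


class TestZmp:
    def test_static_posture_zmp_is_com(self, body, contact):
        q = np.zeros(9)
        q[1] = 3.7
        q[2] = body.l0 + body.L3 + body.L2 + contact.sole_drop - 0.005
        zmp = zmp_from_state(q, np.zeros(9), np.zeros(9), body, contact)
        # CoM x of the straight posture: all segment CoMs at q[1] except
        # the feet, whose CoM sits l1 ahead of the ankle
        com_x = (body.m0 + 2 * (body.m3 + body.m2)) * q[1] \
            + 2 * body.m1 * (q[1] + body.l1)
        com_x /= body.total_mass
        assert zmp == pytest.approx(com_x, abs=1e-12)

    def test_fixture_reference_feasible(self, ref):
        trace = check_zmp(ref, ref.body, ref.contact)
        assert trace.all_feasible

    def test_shifted_reference_infeasible(self, ref):
        import copy
        doctored = copy.copy(ref)
        doctored.Qdd = ref.Qdd.copy()
        X = ref.X.copy()
        X[:, 1] += 1.0  # CoM one metre ahead of the feet
        doctored.X = X
        trace = check_zmp(doctored, ref.body, ref.contact)
        assert not trace.all_feasible
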