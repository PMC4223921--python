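"""Rigid-body terms and contact law against an independent oracle."""

import numpy as np
import pytest

import oracle
from gaitmanifold import BodyParameters, ContactParams
from gaitmanifold.dynamics import (bias_and_gravity, forward_dynamics,
                                   ground_reaction, mass_matrix,
                                   total_energy)

TOTAL_MASS = 62.0
WEIGHT = 607.6


def random_states(rng, n, scale=0.5):
    q = rng.normal(0.0, scale, (n, 9))
    q[:, 2] += 1.1
    qd = rng.normal(0.0, 1.0, (n, 9))
    return q, qd


class TestMassMatrix:
    def test_symmetric_positive_definite(self, rng):
        q, _ = random_states(rng, 50)
        for qi in q:
            J = mass_matrix(qi)
            assert np.allclose(J, J.T, atol=1e-12)
            assert np.linalg.eigvalsh(J).min() > 0.0

    def test_translation_rows_carry_total_mass(self, rng, body):
        q, _ = random_states(rng, 10)
        for qi in q:
            J = mass_matrix(qi)
            assert J[1, 1] == pytest.approx(TOTAL_MASS, abs=1e-12)
            assert J[2, 2] == pytest.approx(TOTAL_MASS, abs=1e-12)
        assert body.total_mass == pytest.approx(TOTAL_MASS)

    def test_matches_kinetic_energy_hessian(self, rng):
        q, qd = random_states(rng, 5)
        for qi, qdi in zip(q, qd):
            J = mass_matrix(qi)
            assert np.abs(J - oracle.mass_matrix(qi)).max() < 1e-10
            ke2 = qdi @ J @ qdi
            assert ke2 == pytest.approx(2.0 * oracle.kinetic(qi, qdi),
                                        rel=1e-12)

    def test_invalid_posture_rejected(self):
        with pytest.raises(ValueError):
            mass_matrix(np.full(9, np.nan))


class TestBiasGravity:
    def test_bias_vanishes_at_rest(self, rng):
        q, _ = random_states(rng, 5)
        for qi in q:
            B, _ = bias_and_gravity(qi, np.zeros(9))
            assert np.abs(B).max() == 0.0

    def test_gravity_vertical_only_through_translation(self, rng):
        q, _ = random_states(rng, 5)
        for qi in q:
            _, K = bias_and_gravity(qi, np.zeros(9))
            assert K[1] == 0.0
            assert K[2] == pytest.approx(WEIGHT, rel=1e-12)

    def test_euler_lagrange_oracle(self, rng):
        """J qdd + B + K reproduces an independently derived Lagrangian
        acceleration to <= 1e-8 relative error (contact-free)."""
        q, qd = random_states(rng, 4)
        for qi, qdi in zip(q, qd):
            B, K = bias_and_gravity(qi, qdi)
            assert np.abs(K - oracle.gravity(qi)).max() < 1e-10
            Bo = oracle.bias(qi, qdi)
            assert np.abs(B - Bo).max() < 1e-8 * max(np.abs(Bo).max(), 1.0)
            U = rng.normal(0.0, 50.0, 9)
            qdd = np.linalg.solve(mass_matrix(qi), U - B - K)
            qdd_o = oracle.lagrangian_accel(qi, qdi, U)
            rel = np.abs(qdd - qdd_o).max() / max(np.abs(qdd_o).max(), 1.0)
            assert rel < 1e-8


class TestGroundReaction:
    def test_airborne_zero(self):
        q = np.zeros(9)
        q[2] = 5.0
        r = ground_reaction(q, np.zeros(9))
        assert np.abs(r.G).max() == 0.0
        assert not r.flags.any()

    def test_static_double_support_carries_weight(self, body, contact):
        """Standing straight with both soles at the static penetration
        depth: total vertical force balances total weight."""
        delta = np.sqrt(WEIGHT / (4.0 * contact.vertical_stiffness))
        q = np.zeros(9)
        # sole level = y - l0 - L3 - L2 - sole_drop; place it at -delta
        q[2] = body.l0 + body.L3 + body.L2 + contact.sole_drop - delta
        r = ground_reaction(q, np.zeros(9), contact, body)
        assert r.flags.all()
        assert r.total_vertical == pytest.approx(WEIGHT, rel=1e-9)
        # generalized force equals Jacobian-transpose image: vertical
        # translation row carries the whole load
        assert r.G[2] == pytest.approx(WEIGHT, rel=1e-9)

    def test_damping_adds_to_loading(self, body, contact):
        q = np.zeros(9)
        q[2] = body.l0 + body.L3 + body.L2 + contact.sole_drop - 0.01
        qd = np.zeros(9)
        still = ground_reaction(q, qd, contact, body).total_vertical
        qd[2] = -0.2  # moving down
        loaded = ground_reaction(q, qd, contact, body).total_vertical
        assert loaded > still

    def test_unilateral(self, rng, body, contact):
        q, qd = random_states(rng, 200, scale=0.7)
        for qi, qdi in zip(q, qd):
            r = ground_reaction(qi, qdi, contact, body)
            assert (r.forces[:, 1] >= 0.0).all()

    def test_jacobian_transpose_consistency(self, rng, body, contact):
        """G equals the finite-difference contact-point Jacobian transpose
        applied to the point forces."""
        q, qd = random_states(rng, 20, scale=0.6)
        h = 1e-7
        for qi, qdi in zip(q, qd):
            r = ground_reaction(qi, qdi, contact, body)
            if not r.flags.any():
                continue
            G_fd = np.zeros(9)
            for j in range(9):
                qp = qi.copy(); qp[j] += h
                qm = qi.copy(); qm[j] -= h
                pp = ground_reaction(qp, qdi, contact, body).positions
                pm = ground_reaction(qm, qdi, contact, body).positions
                Jcol = (pp - pm) / (2 * h)      # (4, 2)
                G_fd[j] = np.sum(Jcol * r.forces)
            scale = max(np.abs(r.G).max(), 1.0)
            assert np.abs(G_fd - r.G).max() < 2e-4 * scale


class TestForwardDynamics:
    def test_state_space_structure(self, rng):
        q, qd = random_states(rng, 5)
        for qi, qdi in zip(q, qd):
            x = np.concatenate([qi, qdi])
            xdot = forward_dynamics(x, np.zeros(9))
            assert np.array_equal(xdot[:9], qdi)

    def test_static_torque_cancels(self, body, contact):
        """With qd = 0 and U chosen as K - G the acceleration vanishes."""
        q = np.zeros(9)
        q[2] = 2.0  # airborne
        _, K = bias_and_gravity(q, np.zeros(9), body)
        x = np.concatenate([q, np.zeros(9)])
        xdot = forward_dynamics(x, K, body=body, contact=contact)
        assert np.abs(xdot[9:]).max() < 1e-10

    def test_ballistic_energy_drift_first_order(self, body, contact):
        """Airborne passive flight conserves energy up to O(dt) Euler
        error; halving dt roughly halves the drift."""
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 0.3, 9), rng.normal(0, 0.5, 9)])
        x[2] = 5.0

        def drift(dt, steps):
            xi = x.copy()
            e0 = total_energy(xi, body)
            for _ in range(steps):
                xi = xi + dt * forward_dynamics(xi, np.zeros(9), body=body,
                                                contact=contact)
            return abs(total_energy(xi, body) - e0)

        d1 = drift(1e-4, 500)
        d2 = drift(5e-5, 1000)
        assert d1 < 5e-2                      # J over 0.05 s
        assert d2 < 0.6 * d1                  # first-order convergence


class TestTotalEnergy:
    def test_rest_energy_is_potential(self, rng):
        q, _ = random_states(rng, 5)
        for qi in q:
            x = np.concatenate([qi, np.zeros(9)])
            assert total_energy(x) == pytest.approx(oracle.potential(qi),
                                                    rel=1e-12)

    def test_kinetic_part_quadratic(self, rng):
        q, qd = random_states(rng, 5)
        for qi, qdi in zip(q, qd):
            x1 = np.concatenate([qi, qdi])
            x2 = np.concatenate([qi, 2.0 * qdi])
            pe = total_energy(np.concatenate([qi, np.zeros(9)]))
            k1 = total_energy(x1) - pe
            k2 = total_energy(x2) - pe
            assert k2 == pytest.approx(4.0 * k1, rel=1e-10)
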