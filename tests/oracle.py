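"""Independent mechanics oracle used by the dynamics tests.

Segment kinematics are written as explicit trigonometric expressions --
a formulation independent of the package's rotated-vector chain with
assembled point Jacobians -- and derivatives are taken either by exact
polarization of the kinetic-energy quadratic form or by complex-step
differentiation (machine precision), with 4th-order central differences
only where two derivative channels would collide.
"""

import numpy as np

from gaitmanifold import BodyParameters

_BODY = BodyParameters()

MASSES = np.array([_BODY.m0, _BODY.m3, _BODY.m2, _BODY.m1,
                   _BODY.m3, _BODY.m2, _BODY.m1])
INERTIAS = np.array([_BODY.I0, _BODY.I3, _BODY.I2, _BODY.I1,
                     _BODY.I3, _BODY.I2, _BODY.I1])


def body_states(q):
    """Per-segment (x, y, absolute angle) tuples; holomorphic in q so
    complex-step differentiation is exact."""
    sin, cos = np.sin, np.cos
    th, x, y = q[0], q[1], q[2]
    out = [(x, y, th)]
    for b in (3, 6):
        qa, qk, qh = q[b], q[b + 1], q[b + 2]
        hx = x + _BODY.l0 * sin(th)
        hy = y - _BODY.l0 * cos(th)
        pt = th + qh
        ps = pt + qk
        pf = ps + qa
        tx = hx + _BODY.l3 * sin(pt)
        ty = hy - _BODY.l3 * cos(pt)
        kx = hx + _BODY.L3 * sin(pt)
        ky = hy - _BODY.L3 * cos(pt)
        sx = kx + _BODY.l2 * sin(ps)
        sy = ky - _BODY.l2 * cos(ps)
        ax = kx + _BODY.L2 * sin(ps)
        ay = ky - _BODY.L2 * cos(ps)
        fx = ax + _BODY.l1 * cos(pf)
        fy = ay + _BODY.l1 * sin(pf)
        out += [(tx, ty, pt), (sx, sy, ps), (fx, fy, pf)]
    return out


def kinetic(q, qd):
    """Kinetic energy via complex-step velocities along the path q + t qd."""
    h = 1e-200
    qc = np.asarray(q, dtype=complex) + 1j * h * np.asarray(qd, dtype=float)
    ke = 0.0
    for i, (px, py, a) in enumerate(body_states(qc)):
        vx = px.imag / h
        vy = py.imag / h
        w = a.imag / h
        ke += 0.5 * MASSES[i] * (vx * vx + vy * vy) + 0.5 * INERTIAS[i] * w * w
    return ke


def potential(q):
    st = body_states(np.asarray(q, dtype=float))
    return float(sum(MASSES[i] * _BODY.g * st[i][1] for i in range(7)))


def mass_matrix(q):
    """J(q) by exact polarization of the kinetic-energy quadratic form."""
    e = np.eye(9)
    T_i = [kinetic(q, e[i]) for i in range(9)]
    J = np.empty((9, 9))
    for i in range(9):
        for j in range(i, 9):
            T_ij = kinetic(q, e[i] + e[j])
            J[i, j] = J[j, i] = T_ij - T_i[i] - T_i[j]
    return J


def gravity(q):
    """K = dV/dq via complex step on the potential."""
    h = 1e-200
    out = np.empty(9)
    for i in range(9):
        qc = np.asarray(q, dtype=complex).copy()
        qc[i] += 1j * h
        V = sum(MASSES[k] * _BODY.g * body_states(qc)[k][1] for k in range(7))
        out[i] = V.imag / h
    return out


def bias(q, qd):
    """Centrifugal/Coriolis vector B = Jdot qd - (1/2) d(qd^T J qd)/dq.

    The q-derivatives use 4th-order central differences on machine-exact
    values (the complex channel is already used for velocities), giving
    ~1e-10 accuracy.
    """
    q = np.asarray(q, dtype=float)
    qd = np.asarray(qd, dtype=float)
    e = np.eye(9)
    hh = 1e-3
    Jdot = np.zeros((9, 9))
    for k in range(9):
        if qd[k] == 0.0:
            continue
        Jp = mass_matrix(q + hh * e[k])
        Jm = mass_matrix(q - hh * e[k])
        Jp2 = mass_matrix(q + 2 * hh * e[k])
        Jm2 = mass_matrix(q - 2 * hh * e[k])
        Jdot += qd[k] * (8 * (Jp - Jm) - (Jp2 - Jm2)) / (12 * hh)
    gradT = np.zeros(9)
    for i in range(9):
        fp = kinetic(q + hh * e[i], qd)
        fm = kinetic(q - hh * e[i], qd)
        fp2 = kinetic(q + 2 * hh * e[i], qd)
        fm2 = kinetic(q - 2 * hh * e[i], qd)
        gradT[i] = (8 * (fp - fm) - (fp2 - fm2)) / (12 * hh)
    return Jdot @ qd - gradT


def lagrangian_accel(q, qd, U9):
    """Accelerations from the Euler-Lagrange equations (no contact)."""
    J = mass_matrix(q)
    return np.linalg.solve(J, np.asarray(U9, float) - bias(q, qd) - gravity(q))
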