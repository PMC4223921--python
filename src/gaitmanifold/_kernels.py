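"""Compiled numerical core: rigid-body terms, contact forces and integrators.

Coordinate layout (generalized coordinates ``q``):
``q[0]`` HAT tilt ``theta`` (rad, CCW positive), ``q[1]``/``q[2]`` HAT-CoM
``x``/``y`` (m), ``q[3..5]`` left ankle/knee/hip angles, ``q[6..8]`` right
ankle/knee/hip angles.  State ``x = (q, qd)`` is 18-dimensional.

Segment angles accumulate additively along each chain: thigh absolute angle
``theta + q_hip``, shank ``+ q_knee``, foot ``+ q_ankle``; the foot frame is
flat on the ground at absolute angle zero (toe at ``(L1, -sole_drop)`` from
the ankle, heel at ``(-heel_offset, -sole_drop)``).

Every kinematic quantity is expressed as a sum of rotated constant vectors
``R(psi) u`` with ``psi`` a 0/1-weighted sum of angle coordinates; point
Jacobian columns are then the perpendiculars of partial sums and the
qdd-free acceleration is ``-sum psi_dot^2 R(psi) u``.

Parameter array layouts (see :mod:`gaitmanifold.params`):

``bp``: g, m0, m1, m2, m3, L1, L2, L3, l0, l1, l2, l3, I0, I1, I2, I3
``cp``: k_v, exponent, c_v, c_h, ramp_depth, heel_offset, sole_drop,
        k_h (anchor stiffness), slip_force
"""

import numpy as np
from numba import njit

__all__ = [
    "dyn_terms", "accel9", "total_energy_k", "com_kin",
    "run_constraint", "inverse_dyn", "run_full",
    "variational_precompute", "monodromy_propagate",
]


@njit(cache=True)
def _acc_body(J, B, K, m, g, Jp, ax, ay):
    """Accumulate one point mass: J += m Jp^T Jp, B += m Jp^T a_bias,
    K += m g * (d y / d q)."""
    for i in range(9):
        j0 = Jp[0, i]
        j1 = Jp[1, i]
        if j0 == 0.0 and j1 == 0.0:
            continue
        for k in range(9):
            J[i, k] += m * (j0 * Jp[0, k] + j1 * Jp[1, k])
        B[i] += m * (j0 * ax + j1 * ay)
        K[i] += m * g * j1


@njit(cache=True)
def _leg(q, qd, b, bp, cp, anc, aflag, J, B, K, Gv, pts, ip0, Jp):
    """Accumulate thigh, shank, foot and the two contact points of one leg.

    ``b`` is the ankle coordinate index (3 left, 6 right); ``ip0`` the row
    offset into ``pts`` / ``anc`` (0 left, 2 right).
    """
    g = bp[0]
    mf = bp[2]; ms = bp[3]; mt = bp[4]
    Lf = bp[5]; Ls = bp[6]; Lt = bp[7]
    l0 = bp[8]; l1 = bp[9]; l2 = bp[10]; l3 = bp[11]
    If = bp[13]; Is = bp[14]; It = bp[15]
    ah = cp[5]; hf = cp[6]

    th = q[0]
    qa = q[b]; qk = q[b + 1]; qh = q[b + 2]
    pt = th + qh
    ps = pt + qk
    pf = ps + qa
    dth = qd[0]
    dpt = dth + qd[b + 2]
    dps = dpt + qd[b + 1]
    dpf = dps + qd[b]

    c = np.cos(th); s = np.sin(th)
    w0x = l0 * s; w0y = -l0 * c                       # hip joint offset
    c = np.cos(pt); s = np.sin(pt)
    w1tx = l3 * s; w1ty = -l3 * c                     # thigh CoM
    w1Tx = Lt * s; w1Ty = -Lt * c                     # knee joint
    c = np.cos(ps); s = np.sin(ps)
    w2sx = l2 * s; w2sy = -l2 * c                     # shank CoM
    w2Sx = Ls * s; w2Sy = -Ls * c                     # ankle joint
    c = np.cos(pf); s = np.sin(pf)
    w3cx = l1 * c; w3cy = l1 * s                      # foot CoM
    w3hx = -ah * c + hf * s; w3hy = -ah * s - hf * c  # heel point
    w3tx = Lf * c + hf * s;  w3ty = Lf * s - hf * c   # toe point

    # --- thigh ---------------------------------------------------------
    for _z in range(9):
        Jp[0, _z] = 0.0
        Jp[1, _z] = 0.0
    Jp[0, 1] = 1.0; Jp[1, 2] = 1.0
    sx = w0x + w1tx; sy = w0y + w1ty
    Jp[0, 0] = -sy; Jp[1, 0] = sx
    Jp[0, b + 2] = -w1ty; Jp[1, b + 2] = w1tx
    ax = -dth * dth * w0x - dpt * dpt * w1tx
    ay = -dth * dth * w0y - dpt * dpt * w1ty
    _acc_body(J, B, K, mt, g, Jp, ax, ay)
    J[0, 0] += It
    J[0, b + 2] += It; J[b + 2, 0] += It; J[b + 2, b + 2] += It

    # --- shank ---------------------------------------------------------
    for _z in range(9):
        Jp[0, _z] = 0.0
        Jp[1, _z] = 0.0
    Jp[0, 1] = 1.0; Jp[1, 2] = 1.0
    sx = w0x + w1Tx + w2sx; sy = w0y + w1Ty + w2sy
    Jp[0, 0] = -sy; Jp[1, 0] = sx
    tx = w1Tx + w2sx; ty = w1Ty + w2sy
    Jp[0, b + 2] = -ty; Jp[1, b + 2] = tx
    Jp[0, b + 1] = -w2sy; Jp[1, b + 1] = w2sx
    ax = -dth * dth * w0x - dpt * dpt * w1Tx - dps * dps * w2sx
    ay = -dth * dth * w0y - dpt * dpt * w1Ty - dps * dps * w2sy
    _acc_body(J, B, K, ms, g, Jp, ax, ay)
    for i in range(3):
        ii = 0 if i == 0 else b + i
        for k in range(3):
            kk = 0 if k == 0 else b + k
            J[ii, kk] += Is

    # --- foot ----------------------------------------------------------
    for _z in range(9):
        Jp[0, _z] = 0.0
        Jp[1, _z] = 0.0
    Jp[0, 1] = 1.0; Jp[1, 2] = 1.0
    sx = w0x + w1Tx + w2Sx + w3cx; sy = w0y + w1Ty + w2Sy + w3cy
    Jp[0, 0] = -sy; Jp[1, 0] = sx
    tx = w1Tx + w2Sx + w3cx; ty = w1Ty + w2Sy + w3cy
    Jp[0, b + 2] = -ty; Jp[1, b + 2] = tx
    ux = w2Sx + w3cx; uy = w2Sy + w3cy
    Jp[0, b + 1] = -uy; Jp[1, b + 1] = ux
    Jp[0, b] = -w3cy; Jp[1, b] = w3cx
    ax = -dth * dth * w0x - dpt * dpt * w1Tx - dps * dps * w2Sx - dpf * dpf * w3cx
    ay = -dth * dth * w0y - dpt * dpt * w1Ty - dps * dps * w2Sy - dpf * dpf * w3cy
    _acc_body(J, B, K, mf, g, Jp, ax, ay)
    for i in range(4):
        ii = 0 if i == 0 else b + i - 1
        for k in range(4):
            kk = 0 if k == 0 else b + k - 1
            J[ii, kk] += If

    # --- contact points ------------------------------------------------
    basex = q[1] + w0x + w1Tx + w2Sx
    basey = q[2] + w0y + w1Ty + w2Sy
    for ipt in range(2):
        if ipt == 0:
            wx = w3hx; wy = w3hy
        else:
            wx = w3tx; wy = w3ty
        px = basex + wx
        py = basey + wy
        for _z in range(9):
            Jp[0, _z] = 0.0
            Jp[1, _z] = 0.0
        Jp[0, 1] = 1.0; Jp[1, 2] = 1.0
        sx = w0x + w1Tx + w2Sx + wx; sy = w0y + w1Ty + w2Sy + wy
        Jp[0, 0] = -sy; Jp[1, 0] = sx
        tx = w1Tx + w2Sx + wx; ty = w1Ty + w2Sy + wy
        Jp[0, b + 2] = -ty; Jp[1, b + 2] = tx
        ux = w2Sx + wx; uy = w2Sy + wy
        Jp[0, b + 1] = -uy; Jp[1, b + 1] = ux
        Jp[0, b] = -wy; Jp[1, b] = wx
        vx = 0.0; vy = 0.0
        for k in range(9):
            vx += Jp[0, k] * qd[k]
            vy += Jp[1, k] * qd[k]
        fh = 0.0; fv = 0.0
        ip = ip0 + ipt
        d = -py
        if d > 0.0:
            fv = cp[0] * d ** cp[1] * (1.0 - cp[2] * vy)
            if fv < 0.0:
                fv = 0.0
            t = d / cp[4]
            if t >= 1.0:
                ramp = 1.0
            else:
                ramp = t * t * (3.0 - 2.0 * t)   # C1 smoothstep engagement
            fh = -cp[3] * ramp * vx
            if cp[7] > 0.0 and aflag[ip] != 0:
                fh += -cp[7] * ramp * (px - anc[ip])
            if cp[8] > 0.0:
                if fh > cp[8]:
                    fh = cp[8]
                elif fh < -cp[8]:
                    fh = -cp[8]
            for k in range(9):
                Gv[k] += Jp[0, k] * fh + Jp[1, k] * fv
        pts[ip, 0] = px; pts[ip, 1] = py
        pts[ip, 2] = vx; pts[ip, 3] = vy
        pts[ip, 4] = fh; pts[ip, 5] = fv


@njit(cache=True)
def _dyn_terms_s(q, qd, bp, cp, anc, aflag, J, B, K, Gv, pts, Jp):
    J[:, :] = 0.0
    B[:] = 0.0
    K[:] = 0.0
    Gv[:] = 0.0
    # HAT: translates with (q1, q2), spins about its own CoM
    J[0, 0] += bp[12]
    J[1, 1] += bp[1]
    J[2, 2] += bp[1]
    K[2] += bp[1] * bp[0]
    _leg(q, qd, 3, bp, cp, anc, aflag, J, B, K, Gv, pts, 0, Jp)
    _leg(q, qd, 6, bp, cp, anc, aflag, J, B, K, Gv, pts, 2, Jp)


@njit(cache=True)
def dyn_terms(q, qd, bp, cp, anc, aflag, J, B, K, Gv, pts):
    """Fill J(9,9), B(9), K(9), contact generalized force Gv(9) and the
    per-contact-point table pts(4,6): x, y, vx, vy, Fh, Fv."""
    Jp = np.empty((2, 9))
    _dyn_terms_s(q, qd, bp, cp, anc, aflag, J, B, K, Gv, pts, Jp)


@njit(cache=True)
def _solve9(A, rhs, out, L):
    """Solve the SPD 9x9 system A x = rhs by Cholesky (A untouched)."""
    for i in range(9):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                L[i, j] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    for i in range(9):
        s = rhs[i]
        for k in range(i):
            s -= L[i, k] * out[k]
        out[i] = s / L[i, i]
    for i in range(8, -1, -1):
        s = out[i]
        for k in range(i + 1, 9):
            s -= L[k, i] * out[k]
        out[i] = s / L[i, i]


@njit(cache=True)
def _solve3(A, r, out):
    d = (A[0, 0] * (A[1, 1] * A[2, 2] - A[1, 2] * A[2, 1])
         - A[0, 1] * (A[1, 0] * A[2, 2] - A[1, 2] * A[2, 0])
         + A[0, 2] * (A[1, 0] * A[2, 1] - A[1, 1] * A[2, 0]))
    out[0] = (r[0] * (A[1, 1] * A[2, 2] - A[1, 2] * A[2, 1])
              - A[0, 1] * (r[1] * A[2, 2] - A[1, 2] * r[2])
              + A[0, 2] * (r[1] * A[2, 1] - A[1, 1] * r[2])) / d
    out[1] = (A[0, 0] * (r[1] * A[2, 2] - A[1, 2] * r[2])
              - r[0] * (A[1, 0] * A[2, 2] - A[1, 2] * A[2, 0])
              + A[0, 2] * (A[1, 0] * r[2] - r[1] * A[2, 0])) / d
    out[2] = (A[0, 0] * (A[1, 1] * r[2] - r[1] * A[2, 1])
              - A[0, 1] * (A[1, 0] * r[2] - r[1] * A[2, 0])
              + r[0] * (A[1, 0] * A[2, 1] - A[1, 1] * A[2, 0])) / d


@njit(cache=True)
def _accel_into(q, qd, U, bp, cp, anc, aflag, J, B, K, Gv, pts, Jp,
                rhs, L, qdd):
    _dyn_terms_s(q, qd, bp, cp, anc, aflag, J, B, K, Gv, pts, Jp)
    for i in range(9):
        rhs[i] = Gv[i] + U[i] - B[i] - K[i]
    _solve9(J, rhs, qdd, L)


@njit(cache=True)
def accel9(q, qd, U, bp, cp, anc, aflag):
    """Generalized accelerations solving J qdd = Gv + U - B - K."""
    J = np.zeros((9, 9))
    B = np.zeros(9)
    K = np.zeros(9)
    Gv = np.zeros(9)
    pts = np.zeros((4, 6))
    dyn_terms(q, qd, bp, cp, anc, aflag, J, B, K, Gv, pts)
    rhs = np.empty(9)
    for i in range(9):
        rhs[i] = Gv[i] + U[i] - B[i] - K[i]
    return np.linalg.solve(J, rhs), pts


@njit(cache=True)
def _leg_energy(q, qd, b, bp):
    mf = bp[2]; ms = bp[3]; mt = bp[4]
    Lf = bp[5]; Ls = bp[6]; Lt = bp[7]
    l0 = bp[8]; l1 = bp[9]; l2 = bp[10]; l3 = bp[11]
    If = bp[13]; Is = bp[14]; It = bp[15]
    th = q[0]
    pt = th + q[b + 2]
    ps = pt + q[b + 1]
    pf = ps + q[b]
    dth = qd[0]
    dpt = dth + qd[b + 2]
    dps = dpt + qd[b + 1]
    dpf = dps + qd[b]

    w0x = l0 * np.sin(th); w0y = -l0 * np.cos(th)
    w1tx = l3 * np.sin(pt); w1ty = -l3 * np.cos(pt)
    w1Tx = Lt * np.sin(pt); w1Ty = -Lt * np.cos(pt)
    w2sx = l2 * np.sin(ps); w2sy = -l2 * np.cos(ps)
    w2Sx = Ls * np.sin(ps); w2Sy = -Ls * np.cos(ps)
    w3cx = l1 * np.cos(pf); w3cy = l1 * np.sin(pf)

    ke = 0.0
    pe = 0.0
    # thigh
    vx = qd[1] + dth * (-w0y) + dpt * (-w1ty)
    vy = qd[2] + dth * w0x + dpt * w1tx
    ke += 0.5 * mt * (vx * vx + vy * vy) + 0.5 * It * dpt * dpt
    pe += mt * bp[0] * (q[2] + w0y + w1ty)
    # shank
    vx = qd[1] + dth * (-w0y) + dpt * (-w1Ty) + dps * (-w2sy)
    vy = qd[2] + dth * w0x + dpt * w1Tx + dps * w2sx
    ke += 0.5 * ms * (vx * vx + vy * vy) + 0.5 * Is * dps * dps
    pe += ms * bp[0] * (q[2] + w0y + w1Ty + w2sy)
    # foot
    vx = qd[1] + dth * (-w0y) + dpt * (-w1Ty) + dps * (-w2Sy) + dpf * (-w3cy)
    vy = qd[2] + dth * w0x + dpt * w1Tx + dps * w2Sx + dpf * w3cx
    ke += 0.5 * mf * (vx * vx + vy * vy) + 0.5 * If * dpf * dpf
    pe += mf * bp[0] * (q[2] + w0y + w1Ty + w2Sy + w3cy)
    return ke, pe


@njit(cache=True)
def total_energy_k(x, bp):
    """Kinetic + gravitational potential energy (datum y = 0)."""
    q = x[:9]
    qd = x[9:]
    ke = 0.5 * bp[1] * (qd[1] * qd[1] + qd[2] * qd[2]) + 0.5 * bp[12] * qd[0] * qd[0]
    pe = bp[1] * bp[0] * q[2]
    kl, pl = _leg_energy(q, qd, 3, bp)
    kr, pr = _leg_energy(q, qd, 6, bp)
    return ke + kl + kr, pe + pl + pr


@njit(cache=True)
def com_kin(q, qd, qdd, bp, cp):
    """Per-segment CoM positions/accelerations, angular accelerations and
    contact-point world positions; inputs to the zero-moment-point balance.

    Returns P(7,2), A(7,2), omdd(7), cpts(4,2); body order: HAT, left
    thigh/shank/foot, right thigh/shank/foot.
    """
    P = np.zeros((7, 2))
    A = np.zeros((7, 2))
    omdd = np.zeros(7)
    cpts = np.zeros((4, 2))
    P[0, 0] = q[1]; P[0, 1] = q[2]
    A[0, 0] = qdd[1]; A[0, 1] = qdd[2]
    omdd[0] = qdd[0]
    Lf = bp[5]; Ls = bp[6]; Lt = bp[7]
    l0 = bp[8]; l1 = bp[9]; l2 = bp[10]; l3 = bp[11]
    ah = cp[5]; hf = cp[6]
    for leg in range(2):
        b = 3 + 3 * leg
        ib = 1 + 3 * leg
        th = q[0]
        pt = th + q[b + 2]
        ps = pt + q[b + 1]
        pf = ps + q[b]
        dth = qd[0]
        dpt = dth + qd[b + 2]
        dps = dpt + qd[b + 1]
        dpf = dps + qd[b]
        ath = qdd[0]
        apt = ath + qdd[b + 2]
        aps = apt + qdd[b + 1]
        apf = aps + qdd[b]
        w0x = l0 * np.sin(th); w0y = -l0 * np.cos(th)
        w1tx = l3 * np.sin(pt); w1ty = -l3 * np.cos(pt)
        w1Tx = Lt * np.sin(pt); w1Ty = -Lt * np.cos(pt)
        w2sx = l2 * np.sin(ps); w2sy = -l2 * np.cos(ps)
        w2Sx = Ls * np.sin(ps); w2Sy = -Ls * np.cos(ps)
        c = np.cos(pf); s = np.sin(pf)
        w3cx = l1 * c; w3cy = l1 * s
        w3hx = -ah * c + hf * s; w3hy = -ah * s - hf * c
        w3tx = Lf * c + hf * s;  w3ty = Lf * s - hf * c
        # d2/dt2 of a rotated term w(psi): psidd*perp(w) - psid^2*w
        # thigh CoM
        P[ib, 0] = q[1] + w0x + w1tx
        P[ib, 1] = q[2] + w0y + w1ty
        A[ib, 0] = qdd[1] + ath * (-w0y) - dth * dth * w0x + apt * (-w1ty) - dpt * dpt * w1tx
        A[ib, 1] = qdd[2] + ath * w0x - dth * dth * w0y + apt * w1tx - dpt * dpt * w1ty
        omdd[ib] = apt
        # shank CoM
        P[ib + 1, 0] = q[1] + w0x + w1Tx + w2sx
        P[ib + 1, 1] = q[2] + w0y + w1Ty + w2sy
        A[ib + 1, 0] = (qdd[1] + ath * (-w0y) - dth * dth * w0x
                        + apt * (-w1Ty) - dpt * dpt * w1Tx
                        + aps * (-w2sy) - dps * dps * w2sx)
        A[ib + 1, 1] = (qdd[2] + ath * w0x - dth * dth * w0y
                        + apt * w1Tx - dpt * dpt * w1Ty
                        + aps * w2sx - dps * dps * w2sy)
        omdd[ib + 1] = aps
        # foot CoM
        P[ib + 2, 0] = q[1] + w0x + w1Tx + w2Sx + w3cx
        P[ib + 2, 1] = q[2] + w0y + w1Ty + w2Sy + w3cy
        A[ib + 2, 0] = (qdd[1] + ath * (-w0y) - dth * dth * w0x
                        + apt * (-w1Ty) - dpt * dpt * w1Tx
                        + aps * (-w2Sy) - dps * dps * w2Sx
                        + apf * (-w3cy) - dpf * dpf * w3cx)
        A[ib + 2, 1] = (qdd[2] + ath * w0x - dth * dth * w0y
                        + apt * w1Tx - dpt * dpt * w1Ty
                        + aps * w2Sx - dps * dps * w2Sy
                        + apf * w3cx - dpf * dpf * w3cy)
        omdd[ib + 2] = apf
        cpts[2 * leg, 0] = q[1] + w0x + w1Tx + w2Sx + w3hx
        cpts[2 * leg, 1] = q[2] + w0y + w1Ty + w2Sy + w3hy
        cpts[2 * leg + 1, 0] = q[1] + w0x + w1Tx + w2Sx + w3tx
        cpts[2 * leg + 1, 1] = q[2] + w0y + w1Ty + w2Sy + w3ty
    return P, A, omdd, cpts


@njit(cache=True)
def run_constraint(h0, ncyc, N, dt, bp, cp, Qj, Vj, Aj, fall_ylow,
                   outX, outQdd, outPts, record):
    """Forward-Euler integration of the joint-constrained (3-DOF) model.

    ``h0`` = (theta, x, y, theta_dot, x_dot, y_dot).  Joint angles follow
    the discretized trajectory tables Qj/Vj/Aj of one period (N rows).
    Records the final cycle into outX/outQdd/outPts when ``record``.
    Returns (strobo states (ncyc+1, 6), fall_cycle or -1).
    """
    h = h0.copy()
    strobo = np.zeros((ncyc + 1, 6))
    strobo[0] = h
    q = np.zeros(9)
    qd = np.zeros(9)
    J = np.zeros((9, 9)); B = np.zeros(9); K = np.zeros(9); Gv = np.zeros(9)
    pts = np.zeros((4, 6))
    anc = np.zeros(4)
    aflag = np.zeros(4, dtype=np.int8)
    A3 = np.zeros((3, 3)); r3 = np.zeros(3)
    hdd = np.zeros(3)
    Jp = np.empty((2, 9))
    fall = -1
    for cidx in range(ncyc):
        rec = record and (cidx == ncyc - 1)
        for k in range(N):
            q[0] = h[0]; q[1] = h[1]; q[2] = h[2]
            qd[0] = h[3]; qd[1] = h[4]; qd[2] = h[5]
            for j in range(6):
                q[3 + j] = Qj[k, j]
                qd[3 + j] = Vj[k, j]
            _dyn_terms_s(q, qd, bp, cp, anc, aflag, J, B, K, Gv, pts, Jp)
            for i in range(3):
                acc = Gv[i] - B[i] - K[i]
                for j in range(6):
                    acc -= J[i, 3 + j] * Aj[k, j]
                r3[i] = acc
                for j in range(3):
                    A3[i, j] = J[i, j]
            _solve3(A3, r3, hdd)
            if rec:
                for i in range(9):
                    outX[k, i] = q[i]
                    outX[k, 9 + i] = qd[i]
                outQdd[k, 0] = hdd[0]; outQdd[k, 1] = hdd[1]; outQdd[k, 2] = hdd[2]
                for j in range(6):
                    outQdd[k, 3 + j] = Aj[k, j]
                for ip in range(4):
                    for jj in range(6):
                        outPts[k, ip, jj] = pts[ip, jj]
            for ip in range(4):
                if pts[ip, 1] < 0.0:
                    if aflag[ip] == 0:
                        aflag[ip] = 1
                        anc[ip] = pts[ip, 0]
                else:
                    aflag[ip] = 0
            h[0] += dt * h[3]; h[1] += dt * h[4]; h[2] += dt * h[5]
            h[3] += dt * hdd[0]; h[4] += dt * hdd[1]; h[5] += dt * hdd[2]
            if h[2] <= fall_ylow or abs(h[0]) >= 1.0:
                fall = cidx + 1
                break
        strobo[cidx + 1] = h
        if fall >= 0:
            break
    return strobo, fall


@njit(cache=True)
def inverse_dyn(X, Qdd, bp, cp, Uff):
    """Joint torques J qdd + B + K - Gv along a recorded trajectory."""
    n = X.shape[0]
    J = np.zeros((9, 9)); B = np.zeros(9); K = np.zeros(9); Gv = np.zeros(9)
    pts = np.zeros((4, 6))
    anc = np.zeros(4)
    aflag = np.zeros(4, dtype=np.int8)
    Jp = np.empty((2, 9))
    for k in range(n):
        q = X[k, :9]
        qd = X[k, 9:]
        _dyn_terms_s(q, qd, bp, cp, anc, aflag, J, B, K, Gv, pts, Jp)
        for i in range(9):
            acc = B[i] + K[i] - Gv[i]
            for j in range(9):
                acc += J[i, j] * Qdd[k, j]
            Uff[k, i] = acc


@njit(cache=True)
def run_full(x0, nsteps, k0, N, dt, bp, cp, refX, refUff, stride_len,
             Pd, Dd, sched, PiA, PiB, Pint, Dint, use_int,
             fall_ylow, rec_stride, out_rec, out_strobo):
    """Forward-Euler integration of the full 18-state controlled model.

    Torques: feed-forward table + continuous PD towards the reference
    (+ the intermittent torque where ``sched`` marks an on-period; target
    point ``x_s = x_r + Pi (x - x_r)`` with the window's projection Pi).
    Returns (final state, fall cycle or -1, #records, #strobo).
    """
    x = x0.copy()
    q = x[:9]
    qd = x[9:]
    anc = np.zeros(4)
    aflag = np.zeros(4, dtype=np.int8)
    U = np.zeros(9)
    xt = np.zeros(18)
    Jm = np.zeros((9, 9)); Bv = np.zeros(9); Kv = np.zeros(9); Gv = np.zeros(9)
    pts = np.zeros((4, 6)); Jp = np.empty((2, 9))
    rhs = np.empty(9); L = np.zeros((9, 9)); qdd = np.empty(9)
    fall = -1
    nrec = 0
    nstr = 0
    for k in range(nsteps):
        kidx = k0 + k
        kr = kidx % N
        wraps = kidx // N
        if k % N == 0 and nstr < out_strobo.shape[0]:
            for j in range(18):
                out_strobo[nstr, j] = x[j]
            nstr += 1
        if rec_stride > 0 and k % rec_stride == 0 and nrec < out_rec.shape[0]:
            for j in range(18):
                out_rec[nrec, j] = x[j]
            nrec += 1
        for j in range(9):
            U[j] = refUff[kr, j]
        for j in range(3, 9):
            U[j] += (-Pd[j] * (q[j] - refX[kr, j])
                     - Dd[j] * (qd[j] - refX[kr, 9 + j]))
        if use_int != 0 and sched[kr] != 0:
            for j in range(18):
                xt[j] = x[j] - refX[kr, j]
            xt[1] -= stride_len * wraps
            if sched[kr] == 1:
                Pi = PiA
            else:
                Pi = PiB
            for j in range(3, 9):
                sq = 0.0
                sd = 0.0
                for m in range(18):
                    sq += Pi[j, m] * xt[m]
                    sd += Pi[9 + j, m] * xt[m]
                U[j] += -Pint[j] * (xt[j] - sq) - Dint[j] * (xt[9 + j] - sd)
        _accel_into(q, qd, U, bp, cp, anc, aflag, Jm, Bv, Kv, Gv, pts, Jp,
                    rhs, L, qdd)
        for ip in range(4):
            if pts[ip, 1] < 0.0:
                if aflag[ip] == 0:
                    aflag[ip] = 1
                    anc[ip] = pts[ip, 0]
            else:
                aflag[ip] = 0
        for j in range(9):
            x[j] += dt * x[9 + j]
        for j in range(9):
            x[9 + j] += dt * qdd[j]
        if x[2] <= fall_ylow or abs(x[0]) >= 1.0:
            fall = k // N + 1
            break
    if fall < 0 and nsteps % N == 0 and nstr < out_strobo.shape[0]:
        for j in range(18):
            out_strobo[nstr, j] = x[j]
        nstr += 1
    return x, fall, nrec, nstr


@njit(cache=True)
def variational_precompute(refX, refUff, bp, cp, fd_eps=1e-7):
    """Open-loop (zero-gain) Jacobian blocks of the vector field along the
    reference: A21 = d(qdd)/dq, A22 = d(qdd)/dqd by central differences,
    plus the inverse mass matrix, per reference sample."""
    N = refX.shape[0]
    A21 = np.zeros((N, 9, 9))
    A22 = np.zeros((N, 9, 9))
    Jinv = np.zeros((N, 9, 9))
    anc = np.zeros(4)
    aflag = np.zeros(4, dtype=np.int8)
    J = np.zeros((9, 9)); B = np.zeros(9); K = np.zeros(9); Gv = np.zeros(9)
    pts = np.zeros((4, 6)); Jp = np.empty((2, 9))
    rhs = np.empty(9); L = np.zeros((9, 9))
    ap = np.empty(9); am = np.empty(9)
    xb = np.empty(18)
    for k in range(N):
        xk = refX[k]
        U = refUff[k]
        _dyn_terms_s(xk[:9], xk[9:], bp, cp, anc, aflag, J, B, K, Gv, pts, Jp)
        Jinv[k] = np.linalg.inv(J)
        for j in range(18):
            h = fd_eps * max(1.0, abs(xk[j]))
            for i in range(18):
                xb[i] = xk[i]
            xb[j] = xk[j] + h
            _accel_into(xb[:9], xb[9:], U, bp, cp, anc, aflag, J, B, K, Gv,
                        pts, Jp, rhs, L, ap)
            xb[j] = xk[j] - h
            _accel_into(xb[:9], xb[9:], U, bp, cp, anc, aflag, J, B, K, Gv,
                        pts, Jp, rhs, L, am)
            inv2h = 0.5 / h
            if j < 9:
                for i in range(9):
                    A21[k, i, j] = (ap[i] - am[i]) * inv2h
            else:
                for i in range(9):
                    A22[k, i, j - 9] = (ap[i] - am[i]) * inv2h
    return A21, A22, Jinv


@njit(cache=True)
def monodromy_propagate(A21o, A22o, Jinv, Pd, Dd, k0, dt):
    """One-period product of per-step flow Jacobians I + dt*DF(t_k).

    DF's lower blocks are the open-loop blocks minus J^-1 P / J^-1 D
    (diagonal gain matrices); upper blocks are structural (0 | I).
    """
    N = A21o.shape[0]
    Zt = np.zeros((9, 18))
    Zb = np.zeros((9, 18))
    for i in range(9):
        Zt[i, i] = 1.0
        Zb[i, 9 + i] = 1.0
    A21 = np.zeros((9, 9))
    A22 = np.zeros((9, 9))
    for k in range(N):
        kr = (k0 + k) % N
        for i in range(9):
            for j in range(9):
                A21[i, j] = A21o[kr, i, j] - Jinv[kr, i, j] * Pd[j]
                A22[i, j] = A22o[kr, i, j] - Jinv[kr, i, j] * Dd[j]
        Ztn = Zt + dt * Zb
        Zbn = Zb + dt * (A21 @ Zt + A22 @ Zb)
        Zt = Ztn
        Zb = Zbn
    M = np.empty((18, 18))
    M[:9] = Zt
    M[9:] = Zb
    return M


@njit(cache=True)
def switched_monodromy_propagate(A21o, A22o, Jinv, Pd, Dd, TA, TB,
                                 sched, k0, dt):
    """Monodromy of the intermittently controlled (switched) linear system.

    ``TA``/``TB`` are the 9x18 on-period feedback terms of the two windows
    (P+/D+ gains composed with the window's error-target map); ``sched``
    holds the window id per reference step (0 off, 1, 2).
    """
    N = A21o.shape[0]
    Zt = np.zeros((9, 18))
    Zb = np.zeros((9, 18))
    for i in range(9):
        Zt[i, i] = 1.0
        Zb[i, 9 + i] = 1.0
    low = np.zeros((9, 18))
    for k in range(N):
        kr = (k0 + k) % N
        for i in range(9):
            for j in range(9):
                low[i, j] = A21o[kr, i, j] - Jinv[kr, i, j] * Pd[j]
                low[i, 9 + j] = A22o[kr, i, j] - Jinv[kr, i, j] * Dd[j]
        s = sched[kr]
        if s != 0:
            T = TA if s == 1 else TB
            JT = Jinv[kr] @ T
            for i in range(9):
                for j in range(18):
                    low[i, j] -= JT[i, j]
        Ztn = Zt + dt * Zb
        Zbn = Zb + dt * (low[:, :9] @ Zt + low[:, 9:] @ Zb)
        Zt = Ztn
        Zb = Zbn
    M = np.empty((18, 18))
    M[:9] = Zt
    M[9:] = Zb
    return M
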