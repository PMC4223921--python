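"""Desired-trajectory machinery and the reference limit cycle.

A desired gait is a 6-joint periodic trajectory (truncated Fourier series,
period ``T``) tracked by the walker.  The *constraint model* prescribes all
six joint angles kinematically, leaving only the three HAT coordinates
dynamic; its steady-state solution, found by stroboscopic convergence, is
the reference limit cycle ``x_r(t)`` of the torque-driven model, and the
inverse-dynamics torque along it is the feed-forward control ``U_ff(t)``.

The reference is stored at every forward-Euler step of one period, with
joint positions discretely integrated from the analytic Fourier
velocities.  This makes ``x_r`` an exact orbit of the discrete dynamics:
simulating the full model from ``x_r(0)`` with ``U_ff`` reproduces the
reference to rounding error regardless of the feedback gains.

The packaged fixture trajectory is synthesized here as well: a task-space
gait design (constant-speed hip, heel-strike/flat/toe-pivot/swing ankle
path, physiological foot-pitch profile) converted to joint angles by
two-link inverse kinematics and projected on 8 Fourier harmonics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels as _k
from .params import BodyParameters, ContactParams

__all__ = [
    "FourierTrajectory",
    "ReferenceGait",
    "ConstraintRun",
    "ZmpTrace",
    "FixtureTemplate",
    "CalibrationResult",
    "eval_trajectory",
    "discretize_trajectory",
    "simulate_constraint_model",
    "find_steady_state",
    "build_reference",
    "inverse_dynamics_Uff",
    "check_zmp",
    "design_trajectory",
    "calibrate_fixture",
    "load_fixture",
    "fixture_reference",
]

JOINT_NAMES = ("ankle_l", "knee_l", "hip_l", "ankle_r", "knee_r", "hip_r")
N_HARMONICS = 8


# --------------------------------------------------------------------------
# Fourier trajectory
# --------------------------------------------------------------------------

@dataclass
class FourierTrajectory:
    """Per-joint truncated Fourier series q_hat(t) with period ``T``.

    ``a`` holds the cosine coefficients (column 0 is the constant term),
    ``b`` the sine coefficients of harmonics 1..8; row order follows
    ``JOINT_NAMES`` (left ankle/knee/hip, then right).  Phase origin is
    left heel-contact; the right-limb series must equal the left-limb
    series advanced by half a period.
    """

    T: float
    a: np.ndarray  # (6, 9)
    b: np.ndarray  # (6, 9); column 0 unused (zero)

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != (6, 9) or self.b.shape != (6, 9):
            raise ValueError("coefficient arrays must have shape (6, 9)")
        if self.T <= 0:
            raise ValueError("period must be positive")

    @classmethod
    def from_left(cls, T: float, a_left: np.ndarray, b_left: np.ndarray
                  ) -> "FourierTrajectory":
        """Build the 6-joint set from left-limb series; the right limb is
        the left advanced by T/2 (harmonic n picks up a factor (-1)^n)."""
        a = np.zeros((6, 9))
        b = np.zeros((6, 9))
        a[:3] = a_left
        b[:3] = b_left
        parity = np.array([(-1.0) ** n for n in range(9)])
        a[3:] = a_left * parity
        b[3:] = b_left * parity
        return cls(T=T, a=a, b=b)

    def check_symmetry(self, tol: float = 1e-9) -> bool:
        parity = np.array([(-1.0) ** n for n in range(9)])
        return (np.abs(self.a[3:] - self.a[:3] * parity).max() < tol
                and np.abs(self.b[3:] - self.b[:3] * parity).max() < tol)

    def __call__(self, phase):
        return self.evaluate(phase)

    def evaluate(self, phase):
        """Angles, velocities and accelerations at ``phase`` (cycle units).

        ``phase`` may be scalar or an array; velocities/accelerations are
        the analytic term-wise derivatives with respect to time.
        """
        phase = np.atleast_1d(np.asarray(phase, dtype=float))
        n = np.arange(9)
        ang = 2.0 * np.pi * np.outer(phase, n)       # (m, 9)
        c = np.cos(ang)
        s = np.sin(ang)
        w = 2.0 * np.pi * n / self.T                 # d/dt of harmonic n
        q = c @ self.a.T + s @ self.b.T              # (m, 6)
        qd = (-s * w) @ self.a.T + (c * w) @ self.b.T
        qdd = (-c * w ** 2) @ self.a.T + (-s * w ** 2) @ self.b.T
        if q.shape[0] == 1:
            return q[0], qd[0], qdd[0]
        return q, qd, qdd

    # -- CSV round trip ----------------------------------------------------

    def to_csv(self, path):
        cols = (["joint"] + [f"a{i}" for i in range(9)]
                + [f"b{i}" for i in range(1, 9)])
        rows = []
        for j, name in enumerate(JOINT_NAMES):
            rows.append([name] + list(self.a[j]) + list(self.b[j, 1:]))
        df = pd.DataFrame(rows, columns=cols)
        with open(path, "w") as fh:
            fh.write(f"# gaitmanifold Fourier trajectory, T={self.T!r}\n")
            df.to_csv(fh, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, check_symmetry: bool = True) -> "FourierTrajectory":
        with open(path) as fh:
            header = fh.readline()
            if "T=" not in header:
                raise ValueError("missing period header line '# ..., T=<s>'")
            T = float(header.split("T=")[1].strip())
            df = pd.read_csv(fh)
        df = df.set_index("joint").loc[list(JOINT_NAMES)]
        a = df[[f"a{i}" for i in range(9)]].to_numpy()
        b = np.zeros((6, 9))
        b[:, 1:] = df[[f"b{i}" for i in range(1, 9)]].to_numpy()
        traj = cls(T=T, a=a, b=b)
        if check_symmetry and not traj.check_symmetry(tol=1e-8):
            raise ValueError("right-limb series is not the left advanced by T/2")
        return traj


def eval_trajectory(traj: FourierTrajectory, phase):
    """Functional wrapper over :meth:`FourierTrajectory.evaluate`."""
    return traj.evaluate(phase)


def discretize_trajectory(traj: FourierTrajectory, dt: float):
    """Euler-consistent joint tables over one period.

    Velocities ``V`` are analytic samples; positions ``Q`` are the forward
    Euler integral of ``V`` (exactly periodic for a trigonometric
    polynomial on a uniform grid); accelerations ``A`` are the forward
    differences of ``V``.  A reference built on these tables is an exact
    orbit of the discrete dynamics.
    """
    steps = traj.T / dt
    N = int(round(steps))
    if abs(steps - N) > 1e-9 * N:
        raise ValueError("period must be an integer multiple of dt")
    phases = np.arange(N) / N
    q0, V, _ = traj.evaluate(phases)
    Q = np.empty_like(V)
    Q[0] = q0[0]
    np.cumsum(V[:-1] * dt, axis=0, out=Q[1:])
    Q[1:] += q0[0]
    A = (np.roll(V, -1, axis=0) - V) / dt
    return Q, V, A


# --------------------------------------------------------------------------
# Constraint model and reference extraction
# --------------------------------------------------------------------------

#: stroboscopic components compared for convergence (q2 = x excluded)
_STROBO_COMPONENTS = np.array([0, 2, 3, 4, 5])


@dataclass
class ConstraintRun:
    """Output of a constraint-model (3-DOF) simulation."""

    strobo: np.ndarray          # (n_cycles+1, 6) HAT states at cycle starts
    fall_cycle: int | None
    X: np.ndarray | None        # last-cycle full state samples (N, 18)
    Qdd: np.ndarray | None      # last-cycle accelerations (N, 9)
    pts: np.ndarray | None      # last-cycle contact table (N, 4, 6)
    traj: FourierTrajectory = None
    body: BodyParameters = None
    contact: ContactParams = None
    dt: float = 0.0

    @property
    def n_cycles(self) -> int:
        return self.strobo.shape[0] - 1

    def strobo_residuals(self) -> np.ndarray:
        d = np.diff(self.strobo, axis=0)[:, _STROBO_COMPONENTS[_STROBO_COMPONENTS < 6]]
        return np.linalg.norm(d, axis=1)


def simulate_constraint_model(traj: FourierTrajectory,
                              body: BodyParameters,
                              contact: ContactParams,
                              init,
                              n_cycles: int,
                              dt: float = 1e-5,
                              record: bool = True) -> ConstraintRun:
    """Integrate the reduced 3-DOF dynamics with joints prescribed.

    ``init`` = (theta, x, y, theta_dot, x_dot, y_dot) of the HAT.  A fall
    (HAT-CoM below 60% of its initial height, or |tilt| > 1 rad) is
    reported through ``fall_cycle``, not an exception.
    """
    init = np.asarray(init, dtype=float)
    if init.shape != (6,) or not np.all(np.isfinite(init)):
        raise ValueError("init must be a finite 6-vector")
    Q, V, A = discretize_trajectory(traj, dt)
    N = Q.shape[0]
    outX = np.zeros((N, 18)) if record else np.zeros((1, 18))
    outQdd = np.zeros((N, 9)) if record else np.zeros((1, 9))
    outPts = np.zeros((N, 4, 6)) if record else np.zeros((1, 4, 6))
    strobo, fall = _k.run_constraint(
        init, n_cycles, N, dt, body.to_array(), contact.to_array(),
        Q, V, A, 0.6 * init[2], outX, outQdd, outPts, record)
    fall_cycle = None if fall < 0 else int(fall)
    if fall_cycle is not None:
        strobo = strobo[:fall_cycle + 1]
    return ConstraintRun(strobo=strobo, fall_cycle=fall_cycle,
                         X=outX if record and fall_cycle is None else None,
                         Qdd=outQdd if record and fall_cycle is None else None,
                         pts=outPts if record and fall_cycle is None else None,
                         traj=traj, body=body, contact=contact, dt=dt)


@dataclass
class ReferenceGait:
    """One period of the steady-state reference gait, sampled per step.

    ``X[k]`` is the 18-state at step k, ``Qdd[k]`` the accelerations,
    ``Uff[k]`` the feed-forward torque (rows 0..2 vanish), ``pts[k]`` the
    contact table.  ``stride`` is the forward advance of q2 per cycle.
    """

    T: float
    dt: float
    X: np.ndarray
    Qdd: np.ndarray
    pts: np.ndarray
    stride: float
    traj: FourierTrajectory
    body: BodyParameters
    contact: ContactParams
    Uff: np.ndarray = None
    strobo_residual: float = np.nan
    events: dict = field(default_factory=dict)
    ds_fraction: float = np.nan
    init_hat: np.ndarray = None
    _var_cache: dict = field(default_factory=dict, repr=False)

    @property
    def N(self) -> int:
        return self.X.shape[0]

    def index_of_phase(self, phi0: float) -> int:
        return int(round((phi0 % 1.0) * self.N)) % self.N

    def state_at_phase(self, phi0: float) -> np.ndarray:
        return self.X[self.index_of_phase(phi0)].copy()

    def mean_height(self) -> float:
        return float(self.X[:, 2].mean())

    def fall_threshold(self) -> float:
        return 0.6 * self.mean_height()

    def periodicity_residual(self) -> float:
        """Wrap defect of the stored cycle (q2 advance removed)."""
        d = self.X[-1] + self.dt * np.concatenate(
            [self.X[-1, 9:], self.Qdd[-1]]) - self.X[0]
        d[1] -= self.stride
        return float(np.linalg.norm(np.delete(d, 1)))

    def save(self, path):
        path = Path(path)
        np.savez_compressed(
            path, X=self.X, Qdd=self.Qdd, pts=self.pts, Uff=self.Uff,
            meta=json.dumps({
                "T": self.T, "dt": self.dt, "stride": self.stride,
                "strobo_residual": self.strobo_residual,
                "ds_fraction": self.ds_fraction,
                "events": self.events,
                "init_hat": list(self.init_hat) if self.init_hat is not None else None,
                "body": self.body.to_dict(), "contact": self.contact.to_dict(),
                "traj": {"T": self.traj.T, "a": self.traj.a.tolist(),
                         "b": self.traj.b.tolist()},
            }))

    @classmethod
    def load(cls, path) -> "ReferenceGait":
        z = np.load(path, allow_pickle=False)
        meta = json.loads(str(z["meta"]))
        traj = FourierTrajectory(T=meta["traj"]["T"],
                                 a=np.array(meta["traj"]["a"]),
                                 b=np.array(meta["traj"]["b"]))
        return cls(T=meta["T"], dt=meta["dt"], X=z["X"], Qdd=z["Qdd"],
                   pts=z["pts"], Uff=z["Uff"], stride=meta["stride"],
                   traj=traj, body=BodyParameters(**meta["body"]),
                   contact=ContactParams(**meta["contact"]),
                   strobo_residual=meta["strobo_residual"],
                   events=meta["events"], ds_fraction=meta["ds_fraction"],
                   init_hat=None if meta["init_hat"] is None
                   else np.array(meta["init_hat"]))


class SteadyStateError(RuntimeError):
    """No stroboscopic convergence within the supplied run."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


def _contact_summary(pts: np.ndarray):
    """Loaded-foot flags, double-support fraction and contact-event phases."""
    N = pts.shape[0]
    left = (pts[:, 0, 5] + pts[:, 1, 5]) > 0.0
    right = (pts[:, 2, 5] + pts[:, 3, 5]) > 0.0
    ds = float(np.mean(left & right))
    events = {}
    for name, flags in (("left", left), ("right", right)):
        rising = np.nonzero(flags & ~np.roll(flags, 1))[0]
        falling = np.nonzero(~flags & np.roll(flags, 1))[0]
        events[f"heel_contact_{name}"] = sorted(float(k) / N for k in rising)
        events[f"toe_off_{name}"] = sorted(float(k) / N for k in falling)
    return left, right, ds, events


def find_steady_state(run: ConstraintRun, tol: float = 1e-6,
                      consecutive: int = 5) -> ReferenceGait:
    """Extract one steady-state cycle from a converged constraint run.

    Requires the stroboscopic HAT-state residual (q2 excluded) to stay
    below ``tol`` for ``consecutive`` cycles; the recorded final cycle of a
    re-run from the most converged state becomes the reference.
    """
    if run.fall_cycle is not None:
        raise SteadyStateError(
            f"constraint model fell at cycle {run.fall_cycle}")
    res = run.strobo_residuals()
    ok = res < tol
    converged = any(ok[i:i + consecutive].all()
                    for i in range(len(ok) - consecutive + 1))
    if not converged:
        raise SteadyStateError(
            f"no stroboscopic convergence below {tol} over "
            f"{consecutive} consecutive cycles (last residuals "
            f"{res[-consecutive:] if len(res) >= consecutive else res})",
            residuals=res)
    rerun = simulate_constraint_model(run.traj, run.body, run.contact,
                                      run.strobo[-1], 1, run.dt, record=True)
    if rerun.fall_cycle is not None:
        raise SteadyStateError("re-run from converged state fell")
    X, Qdd, pts = rerun.X, rerun.Qdd, rerun.pts
    stride = float(rerun.strobo[-1][1] - rerun.strobo[0][1])
    _, _, ds, events = _contact_summary(pts)
    ref = ReferenceGait(T=run.traj.T, dt=run.dt, X=X, Qdd=Qdd, pts=pts,
                        stride=stride, traj=run.traj, body=run.body,
                        contact=run.contact,
                        strobo_residual=float(res[-1]),
                        events=events, ds_fraction=ds,
                        init_hat=run.strobo[-1].copy())
    inverse_dynamics_Uff(ref, run.body, run.contact)
    return ref


def build_reference(traj: FourierTrajectory, body: BodyParameters,
                    contact: ContactParams, init, dt: float = 1e-5,
                    n_cycles: int = 120, tol: float = 1e-6) -> ReferenceGait:
    """Convenience: run the constraint model and extract the reference."""
    run = simulate_constraint_model(traj, body, contact, init, n_cycles, dt,
                                    record=False)
    return find_steady_state(run, tol=tol)


def inverse_dynamics_Uff(ref: ReferenceGait, body: BodyParameters,
                         contact: ContactParams,
                         hat_tol: float = 1e-3) -> np.ndarray:
    """Feed-forward torque U_ff = J qdd + B + K - G along the reference.

    The three HAT rows are unactuated; a residual there above ``hat_tol``
    times the peak joint torque marks an inconsistent reference.
    """
    if contact.horizontal_stiffness > 0:
        raise ValueError("inverse dynamics requires the anchor-free contact law")
    Uff = np.zeros((ref.N, 9))
    _k.inverse_dyn(ref.X, ref.Qdd, body.to_array(), contact.to_array(), Uff)
    peak = np.abs(Uff[:, 3:]).max()
    hat_res = np.abs(Uff[:, :3]).max()
    if hat_res > hat_tol * max(peak, 1.0):
        raise ValueError(
            f"reference inconsistent: HAT torque residual {hat_res:.3e} "
            f"exceeds {hat_tol} x peak joint torque {peak:.3e}")
    ref.Uff = Uff
    return Uff


# --------------------------------------------------------------------------
# Zero-moment-point feasibility
# --------------------------------------------------------------------------

@dataclass
class ZmpTrace:
    """ZMP x-position versus phase with the instantaneous support bounds."""

    phases: np.ndarray
    zmp: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    feasible: np.ndarray
    margin: float

    @property
    def all_feasible(self) -> bool:
        return bool(self.feasible.all())


def zmp_from_state(q, qd, qdd, body: BodyParameters,
                   contact: ContactParams) -> float:
    """Acting point of the net ground reaction from the moment balance."""
    bp = body.to_array()
    P, A, omdd, _ = _k.com_kin(np.asarray(q, float), np.asarray(qd, float),
                               np.asarray(qdd, float), bp,
                               contact.to_array())
    m = np.array([body.m0, body.m3, body.m2, body.m1,
                  body.m3, body.m2, body.m1])
    inert = np.array([body.I0, body.I3, body.I2, body.I1,
                      body.I3, body.I2, body.I1])
    fy = float(np.sum(m * (A[:, 1] + body.g)))
    mom = float(np.sum(m * (P[:, 0] * (A[:, 1] + body.g) - P[:, 1] * A[:, 0]))
                + np.sum(inert * omdd))
    return mom / fy


def check_zmp(ref: ReferenceGait, body: BodyParameters,
              contact: ContactParams, stride: int = 10,
              margin: float = 0.02) -> ZmpTrace:
    """ZMP per phase against the span of the loaded contact points.

    ``margin`` (m) widens the support interval to absorb the point-contact
    idealization of the foot.
    """
    ks = np.arange(0, ref.N, stride)
    zmp = np.array([zmp_from_state(ref.X[k, :9], ref.X[k, 9:], ref.Qdd[k],
                                   body, contact) for k in ks])
    lo = np.empty(len(ks))
    hi = np.empty(len(ks))
    for i, k in enumerate(ks):
        loaded = ref.pts[k, :, 5] > 0.0
        if loaded.any():
            xs = ref.pts[k, loaded, 0]
            lo[i], hi[i] = xs.min(), xs.max()
        else:
            lo[i], hi[i] = np.nan, np.nan
    feas = (zmp >= lo - margin) & (zmp <= hi + margin)
    feas[np.isnan(lo)] = False
    return ZmpTrace(phases=ks / ref.N, zmp=zmp, lo=lo, hi=hi,
                    feasible=feas, margin=margin)


# --------------------------------------------------------------------------
# Synthetic fixture trajectory: task-space design + inverse kinematics
# --------------------------------------------------------------------------

@dataclass
class FixtureTemplate(object):
    """Parametric task-space gait design behind the packaged fixture.

    The hip joint translates at constant speed with a double bob; the
    ankle follows heel-strike / flat-foot / toe-pivot / swing segments;
    the foot pitch interpolates heel-strike toe-up, flat stance and
    push-off plantarflexion.  All quantities in SI units and cycle phase.
    """

    T: float = 1.135          # gait period, s
    speed: float = 0.90       # forward speed, m/s
    hip_height: float = 0.80  # mean hip-joint height, m
    bob: float = 0.012        # hip vertical oscillation amplitude, m
    phi_ff: float = 0.08      # foot-flat phase after heel strike
    phi_ho: float = 0.40      # heel-off phase
    phi_to: float = 0.60      # toe-off phase
    pitch_hs: float = 0.15    # toe-up pitch at heel strike, rad
    pitch_po: float = 0.32    # plantarflexion magnitude at toe-off, rad
    clearance: float = 0.135  # peak swing ankle height, m
    phi_peak: float = 0.78    # phase of peak swing height
    heel_slope: float = -0.12 # ankle-height slope into heel strike, m/cycle
    anchor_frac: float = 0.30 # stance-anchor phase (foot under hip)
    foot_lead: float = 0.0    # fore-aft shift of the footfalls, m
    settle: float = 0.012     # initial-height allowance for penetration, m
    trunk_lean: float = 0.0   # design HAT tilt, rad


def _hermite(knots, phi):
    """Piecewise-cubic Hermite through (phi_i, value_i, slope_i) knots."""
    phis = np.array([k[0] for k in knots])
    vals = np.array([k[1] for k in knots])
    slps = np.array([k[2] for k in knots])
    out = np.empty_like(phi)
    idx = np.clip(np.searchsorted(phis, phi, side="right") - 1, 0, len(knots) - 2)
    h = phis[idx + 1] - phis[idx]
    t = (phi - phis[idx]) / h
    h00 = (1 + 2 * t) * (1 - t) ** 2
    h10 = t * (1 - t) ** 2
    h01 = t ** 2 * (3 - 2 * t)
    h11 = t ** 2 * (t - 1)
    out = (h00 * vals[idx] + h10 * h * slps[idx]
           + h01 * vals[idx + 1] + h11 * h * slps[idx + 1])
    return out


def _design_task_space(tpl: FixtureTemplate, contact: ContactParams, npts: int):
    """World-frame ankle path, foot pitch and hip path over one cycle."""
    ah, hf = contact.heel_offset, contact.sole_drop
    L1 = BodyParameters().L1
    phi = np.arange(npts) / npts
    vT = tpl.speed * tpl.T
    x_a = tpl.anchor_frac * vT + tpl.foot_lead

    pitch = np.empty(npts)
    ax = np.empty(npts)
    ay = np.empty(npts)

    m_hp = phi < tpl.phi_ff
    m_fl = (phi >= tpl.phi_ff) & (phi < tpl.phi_ho)
    m_tp = (phi >= tpl.phi_ho) & (phi < tpl.phi_to)
    m_sw = phi >= tpl.phi_to

    # heel pivot: rotate about the heel point until foot flat
    p = _hermite([(0.0, tpl.pitch_hs, 0.0), (tpl.phi_ff, 0.0, 0.0)],
                 phi[m_hp])
    pitch[m_hp] = p
    ax[m_hp] = x_a - ah + ah * np.cos(p) - hf * np.sin(p)
    ay[m_hp] = ah * np.sin(p) + hf * np.cos(p)

    pitch[m_fl] = 0.0
    ax[m_fl] = x_a
    ay[m_fl] = hf

    # toe pivot: rotate about the toe point into push-off
    p = _hermite([(tpl.phi_ho, 0.0, 0.0), (tpl.phi_to, -tpl.pitch_po, 0.0)],
                 phi[m_tp])
    pitch[m_tp] = p
    ax[m_tp] = x_a + L1 - L1 * np.cos(p) - hf * np.sin(p)
    ay[m_tp] = -L1 * np.sin(p) + hf * np.cos(p)

    # swing: Hermite from the toe-off pose to the next heel strike
    p_to = -tpl.pitch_po
    x_to = x_a + L1 - L1 * np.cos(p_to) - hf * np.sin(p_to)
    y_to = -L1 * np.sin(p_to) + hf * np.cos(p_to)
    x_hs = (x_a + vT) - ah + ah * np.cos(tpl.pitch_hs) - hf * np.sin(tpl.pitch_hs)
    y_hs = ah * np.sin(tpl.pitch_hs) + hf * np.cos(tpl.pitch_hs)
    span = 1.0 - tpl.phi_to
    x_mid = x_to + 0.55 * (x_hs - x_to)
    pitch[m_sw] = _hermite([(tpl.phi_to, p_to, 0.0),
                            (0.90, tpl.pitch_hs, 0.0),
                            (1.0, tpl.pitch_hs, 0.0)], phi[m_sw])
    ax[m_sw] = _hermite([(tpl.phi_to, x_to, 0.0),
                         (0.80, x_mid, 2.0 * (x_hs - x_to) / span),
                         (1.0, x_hs, 0.0)], phi[m_sw])
    ay[m_sw] = _hermite([(tpl.phi_to, y_to, 0.0),
                         (tpl.phi_peak, tpl.clearance, 0.0),
                         (1.0, y_hs, tpl.heel_slope)], phi[m_sw])

    hip_x = vT * phi
    hip_y = tpl.hip_height - tpl.bob * np.cos(4 * np.pi * phi)
    return phi, ax, ay, pitch, hip_x, hip_y


def _ik_leg(dx, dy, pitch, body: BodyParameters, trunk: float,
            margin: float = 0.002):
    """Two-link inverse kinematics of hip/knee plus pitch-matching ankle.

    ``dx``/``dy``: ankle position relative to the hip joint.  The knee
    bends backward (negative knee angle in the additive convention).
    """
    L2, L3 = body.L2, body.L3
    r = np.hypot(dx, dy)
    rmax = (L2 + L3) * (1.0 - margin)
    scale = np.minimum(1.0, rmax / r)
    dx = dx * scale
    dy = dy * scale
    r = np.minimum(r, rmax)
    cqk = np.clip((r ** 2 - L2 ** 2 - L3 ** 2) / (2.0 * L2 * L3), -1.0, 1.0)
    qk = -np.arccos(cqk)
    gamma = np.arctan2(dx, -dy)
    psi_t = gamma - np.arctan2(L2 * np.sin(qk), L3 + L2 * np.cos(qk))
    qh = psi_t - trunk
    qa = pitch - trunk - qh - qk
    return qh, qk, qa


def _fourier_fit(y: np.ndarray, n_harm: int = N_HARMONICS):
    """Projection of periodic samples on harmonics 0..n_harm."""
    n = y.shape[0]
    F = np.fft.rfft(y) / n
    a = np.zeros(9)
    b = np.zeros(9)
    a[0] = F[0].real
    a[1:n_harm + 1] = 2.0 * F[1:n_harm + 1].real
    b[1:n_harm + 1] = -2.0 * F[1:n_harm + 1].imag
    return a, b


def design_trajectory(tpl: FixtureTemplate,
                      body: BodyParameters | None = None,
                      contact: ContactParams | None = None,
                      npts: int = 2048):
    """Synthesize the fixture trajectory and an initial HAT state guess."""
    body = body or BodyParameters()
    contact = contact or ContactParams()
    phi, ax, ay, pitch, hip_x, hip_y = _design_task_space(tpl, contact, npts)
    qh, qk, qa = _ik_leg(ax - hip_x, ay - hip_y, pitch, body, tpl.trunk_lean)
    a_left = np.zeros((3, 9))
    b_left = np.zeros((3, 9))
    for row, series in enumerate((qa, qk, qh)):
        a_left[row], b_left[row] = _fourier_fit(series)
    traj = FourierTrajectory.from_left(tpl.T, a_left, b_left)
    th0 = tpl.trunk_lean
    y0 = hip_y[0] + body.l0 * np.cos(th0) - tpl.settle
    x0 = -body.l0 * np.sin(th0)
    init = np.array([th0, x0, y0, 0.0, tpl.speed, 0.0])
    return traj, init


# --------------------------------------------------------------------------
# Fixture calibration and packaged data
# --------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    traj: FourierTrajectory
    init: np.ndarray
    template: FixtureTemplate
    residual: float
    ds_fraction: float
    stride: float
    cycles_walked: int


class CalibrationError(RuntimeError):
    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


def _try_template(tpl, body, contact, dt, n_cycles, tol):
    traj, init = design_trajectory(tpl, body, contact)
    run = simulate_constraint_model(traj, body, contact, init, n_cycles, dt,
                                    record=False)
    if run.fall_cycle is not None:
        return None, (tpl, run.fall_cycle, np.inf)
    res = run.strobo_residuals()
    if not (res[-3:] < tol).all():
        return None, (tpl, run.n_cycles, float(res[-1]))
    ref = find_steady_state(run, tol=tol)
    return (traj, run.strobo[-1], ref), None


def calibrate_fixture(template: FixtureTemplate | None = None,
                      body: BodyParameters | None = None,
                      contact: ContactParams | None = None,
                      seed: int = 0,
                      dt: float = 1e-5,
                      n_cycles: int = 120,
                      tol: float = 1e-6) -> CalibrationResult:
    """Deterministic search for a walking fixture trajectory.

    Candidate templates are tried in a fixed order starting from the
    supplied (or default) template, perturbing the fore-aft foot placement
    and speed until the constraint model walks ``n_cycles`` cycles with
    stroboscopic convergence.  ``seed`` is accepted for interface
    uniformity; the procedure involves no randomness.
    """
    del seed
    body = body or BodyParameters()
    contact = contact or ContactParams()
    base = template or FixtureTemplate()
    attempts = []
    candidates = [base]
    for lead in (-0.01, 0.01, -0.02, 0.02, -0.03, 0.03):
        d = asdict(base)
        d["foot_lead"] = base.foot_lead + lead
        candidates.append(FixtureTemplate(**d))
    for dv in (-0.05, 0.05, -0.1):
        d = asdict(base)
        d["speed"] = base.speed + dv
        candidates.append(FixtureTemplate(**d))
    for tpl in candidates:
        got, diag = _try_template(tpl, body, contact, dt, n_cycles, tol)
        if got is not None:
            traj, init, ref = got
            return CalibrationResult(
                traj=traj, init=init, template=tpl,
                residual=ref.strobo_residual, ds_fraction=ref.ds_fraction,
                stride=ref.stride, cycles_walked=n_cycles)
        attempts.append(diag)
    best = max(attempts, key=lambda t: (t[1], -t[2]))
    raise CalibrationError(
        f"no candidate template walked {n_cycles} cycles with residual "
        f"< {tol}; best candidate walked {best[1]} cycles "
        f"(final residual {best[2]:.3e})", best=best)


def _data_path(name: str):
    return resources.files("gaitmanifold").joinpath("data", name)


def load_fixture():
    """The packaged fixture trajectory, initial HAT state and metadata."""
    traj = FourierTrajectory.from_csv(_data_path("fixture_trajectory.csv"))
    meta = json.loads(_data_path("fixture_init.json").read_text())
    return traj, np.array(meta["hat_state"]), meta


_REF_CACHE: dict = {}


def fixture_reference(body: BodyParameters | None = None,
                      contact: ContactParams | None = None,
                      dt: float = 1e-5,
                      n_cycles: int = 120,
                      tol: float = 1e-6) -> ReferenceGait:
    """Reference limit cycle of the packaged fixture (memoized per dt)."""
    if body is None and contact is None and dt in _REF_CACHE:
        return _REF_CACHE[dt]
    traj, init, _ = load_fixture()
    ref = build_reference(traj, body or BodyParameters(),
                          contact or ContactParams(), init, dt=dt,
                          n_cycles=n_cycles, tol=tol)
    if body is None and contact is None:
        _REF_CACHE[dt] = ref
    return ref
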