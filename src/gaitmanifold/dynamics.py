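"""Rigid-body mechanics of the planar 7-link walker and its ground contact.

The walker has nine degrees of freedom: HAT tilt, HAT-CoM position (x, y)
and the ankle/knee/hip angles of both legs.  The equation of motion is

    J(q) qdd + B(q, qd) + K(q) = G(q, qd) + U

with inertia matrix J, centrifugal/Coriolis vector B, gravity vector K,
generalized ground-reaction force G and applied torque U (zero on the
three unactuated HAT coordinates).  Functions here are thin validated
wrappers over the compiled kernels in :mod:`gaitmanifold._kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .params import BodyParameters, ContactParams

__all__ = [
    "GrfResult",
    "mass_matrix",
    "bias_and_gravity",
    "ground_reaction",
    "forward_dynamics",
    "total_energy",
    "CONTACT_POINT_NAMES",
]

CONTACT_POINT_NAMES = ("heel_left", "toe_left", "heel_right", "toe_right")

_NO_ANCHOR = np.zeros(4)
_NO_AFLAG = np.zeros(4, dtype=np.int8)


def _check_q(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (9,):
        raise ValueError("posture must be a 9-vector")
    if not np.all(np.isfinite(q)):
        raise ValueError("posture contains non-finite entries")
    return q


def _check_state(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (18,):
        raise ValueError("state must be an 18-vector (q, qd)")
    if not np.all(np.isfinite(x)):
        raise ValueError("state contains non-finite entries")
    return x


@dataclass
class GrfResult:
    """Ground reaction at the four contact points (heel/toe, left/right).

    ``G`` is the generalized force (Jacobian-transpose image of the point
    forces); ``forces`` the per-point (Fh, Fv) pairs in N, ``positions`` /
    ``velocities`` the world-frame contact-point kinematics, ``flags``
    whether each point penetrates the ground.
    """

    G: np.ndarray
    forces: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    flags: np.ndarray

    @property
    def total_vertical(self) -> float:
        return float(self.forces[:, 1].sum())


def _terms(q, qd, body: BodyParameters, contact: ContactParams,
           anchors=None, active=None):
    J = np.zeros((9, 9))
    B = np.zeros(9)
    K = np.zeros(9)
    Gv = np.zeros(9)
    pts = np.zeros((4, 6))
    anc = _NO_ANCHOR if anchors is None else np.asarray(anchors, dtype=float)
    afl = _NO_AFLAG if active is None else np.asarray(active, dtype=np.int8)
    _k.dyn_terms(q, qd, body.to_array(), contact.to_array(), anc, afl,
                 J, B, K, Gv, pts)
    return J, B, K, Gv, pts


def mass_matrix(q, body: BodyParameters | None = None) -> np.ndarray:
    """Configuration-dependent inertia matrix J(q): symmetric positive
    definite; rows/columns 1 and 2 carry the total mass on the diagonal."""
    q = _check_q(q)
    body = body or BodyParameters()
    J, *_ = _terms(q, np.zeros(9), body, ContactParams())
    return J


def bias_and_gravity(q, qd, body: BodyParameters | None = None):
    """Centrifugal/Coriolis vector B (quadratic in qd, zero at rest) and
    gravity vector K = d(potential)/dq (positive y is up)."""
    q = _check_q(q)
    qd = _check_q(qd)
    body = body or BodyParameters()
    _, B, K, *_ = _terms(q, qd, body, ContactParams())
    return B, K


def ground_reaction(q, qd, contact: ContactParams | None = None,
                    body: BodyParameters | None = None,
                    anchors=None, active=None) -> GrfResult:
    """Unilateral spring-damper ground reaction; zero for separated points.

    ``anchors``/``active`` carry per-point anchor state for the optional
    anchored horizontal spring (``contact.horizontal_stiffness > 0``).
    """
    q = _check_q(q)
    qd = _check_q(qd)
    body = body or BodyParameters()
    contact = contact or ContactParams()
    *_, Gv, pts = _terms(q, qd, body, contact, anchors, active)
    return GrfResult(
        G=Gv,
        forces=pts[:, 4:6].copy(),
        positions=pts[:, 0:2].copy(),
        velocities=pts[:, 2:4].copy(),
        flags=pts[:, 1] < 0.0,
    )


def forward_dynamics(x, U, t: float = 0.0,
                     body: BodyParameters | None = None,
                     contact: ContactParams | None = None,
                     anchors=None, active=None) -> np.ndarray:
    """State derivative f(x, t) = (qd, J^-1 (G + U - B - K)).

    ``t`` is accepted for signature compatibility; the vector field itself
    is autonomous apart from the torque ``U`` supplied by the caller.
    """
    x = _check_state(x)
    U = np.asarray(U, dtype=float)
    if U.shape != (9,):
        raise ValueError("torque must be a 9-vector")
    if not np.all(np.isfinite(U)):
        raise ValueError("torque contains non-finite entries")
    body = body or BodyParameters()
    contact = contact or ContactParams()
    anc = _NO_ANCHOR if anchors is None else np.asarray(anchors, dtype=float)
    afl = _NO_AFLAG if active is None else np.asarray(active, dtype=np.int8)
    try:
        qdd, _ = _k.accel9(x[:9].copy(), x[9:].copy(), U,
                           body.to_array(), contact.to_array(), anc, afl)
    except Exception as exc:  # pragma: no cover - singular mass matrix
        raise ValueError("mass-matrix solve failed") from exc
    return np.concatenate([x[9:], qdd])


def total_energy(x, body: BodyParameters | None = None) -> float:
    """Total mechanical energy (kinetic + gravitational, datum y = 0)."""
    x = _check_state(x)
    body = body or BodyParameters()
    ke, pe = _k.total_energy_k(x, body.to_array())
    return float(ke + pe)
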