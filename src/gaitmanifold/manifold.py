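"""Stable/unstable subspace decomposition of the gait error state.

Near the limit cycle the stable and unstable manifolds are tangent to the
subspaces spanned by the monodromy eigenvectors of stable and unstable
Floquet multipliers at the chosen phase.  Expressed in the real Jordan
basis ``V(phi0)``, an error state ``x~ = x - x_r`` has coefficients
``c = V^-1 x~``; zeroing the unstable coefficients and reconstructing
projects the state onto the local stable manifold -- the nominal target
of the stable-manifold intermittent controller.  The neutral translation
mode (unity multiplier, horizontal HAT-CoM position) is kept by the
projection: distance travelled is not an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .floquet import FloquetError, MonodromyResult
from .params import GainSet
from .trajectory import ReferenceGait

__all__ = [
    "PhaseBasis",
    "phase_basis",
    "decompose_error",
    "reference_error",
    "project_to_stable",
    "projection_matrix",
    "stroboscopic_coefficients",
    "poincare_map",
]

#: classification margin around unit modulus
MOD_TOL = 1e-3


@dataclass
class PhaseBasis:
    """Real monodromy basis at one phase with its mode classification.

    Columns of ``V`` are unit-norm; ``unstable``/``stable`` index the
    columns spanning the locally unstable/stable subspaces and ``neutral``
    the translation mode.  ``moduli`` carries the multiplier modulus of
    each column; ``cond`` the condition number of ``V``.
    """

    phi0: float
    V: np.ndarray
    Vinv: np.ndarray
    unstable: tuple
    stable: tuple
    neutral: int
    moduli: np.ndarray
    cond: float
    gains: GainSet = None

    @property
    def n_unstable(self) -> int:
        return len(self.unstable)


#: multipliers below this modulus are numerically indistinguishable from
#: zero (strong contact/viscous damping underflows e^{-lambda T}); their
#: individual eigendirections carry no information
MOD_FLOOR = 1e-6


def _real_columns(w, V, idx):
    """Real column set for the eigenpairs in ``idx`` (conjugates paired as
    Re/Im with a common unit-complex-vector scale)."""
    cols = []
    mods = []
    used = set()
    for i in idx:
        if i in used:
            continue
        lam = w[i]
        if abs(lam.imag) <= 1e-10 * max(abs(lam), 1.0):
            used.add(i)
            v = V[:, i].real / np.linalg.norm(V[:, i].real)
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            cols.append(v)
            mods.append(abs(lam))
        else:
            js = [j for j in idx if j not in used and j != i
                  and abs(w[j] - lam.conjugate()) < 1e-6 * max(abs(lam), 1.0)]
            if not js:
                raise FloquetError(f"unpaired complex multiplier {lam}")
            j = min(js, key=lambda j: abs(w[j] - lam.conjugate()))
            used.update((i, j))
            v = V[:, i] if lam.imag > 0 else V[:, j]
            v = v / np.linalg.norm(v)
            vR, vI = v.real.copy(), v.imag.copy()
            if vR[np.argmax(np.abs(vR))] < 0:
                vR, vI = -vR, -vI
            cols.extend((vR, vI))
            mods.extend((abs(lam), abs(lam)))
    return cols, mods


def phase_basis(result: MonodromyResult, tol: float = MOD_TOL,
                mod_floor: float = MOD_FLOOR) -> PhaseBasis:
    """Build the phase basis from a monodromy result and classify modes.

    Columns for multipliers with modulus above ``mod_floor`` are real
    Jordan eigendirections; the remaining directions (multipliers that
    have contracted below numerical resolution within one period) are
    represented by an orthonormal basis of the complementary invariant
    subspace, computed from the left eigenvectors of the resolved modes.
    With this construction the dual rows of ``V^-1`` for the resolved
    modes are their exact left eigenvectors, so zeroing unstable
    coefficients performs the exact spectral projection.

    Moduli above ``1 + tol`` are unstable, below ``1 - tol`` stable; the
    translation mode is neutral.  A non-translation modulus inside the
    margin makes the split ambiguous and raises.
    """
    w = result.eigvals
    dom = [i for i in range(18) if abs(w[i]) > mod_floor]
    cols, mods_dom = _real_columns(w, result.eigvecs, dom)
    k = len(cols)
    if k < 18:
        # left eigenvectors of the resolved modes span the annihilator of
        # the unresolved invariant subspace
        wl, Vl = np.linalg.eig(result.M.T)
        lidx = []
        for i in dom:
            j = int(np.argmin(np.abs(wl - w[i])))
            if abs(wl[j] - w[i]) > 1e-6 * max(abs(w[i]), 1.0):
                raise FloquetError("left/right spectra do not match")
            lidx.append(j)
        lcols, _ = _real_columns(wl, Vl, lidx)
        W = np.array(lcols)
        _, _, vt = np.linalg.svd(W)
        comp = vt[W.shape[0]:].T
        V = np.column_stack(cols + [comp[:, j] for j in range(18 - k)])
        rest = sorted((abs(w[i]) for i in range(18) if i not in dom),
                      reverse=True)
        mods = np.array(mods_dom + rest)
    else:
        V = np.column_stack(cols)
        mods = np.array(mods_dom)
    cond = float(np.linalg.cond(V))
    if cond > 1e10:
        raise FloquetError(f"basis is numerically singular (cond {cond:.2e})")
    Vinv = np.linalg.inv(V)
    # translation column: modulus ~1 with a dominant q2 component
    cands = [j for j in range(18) if abs(mods[j] - 1.0) < tol]
    scores = {j: abs(V[1, j]) for j in cands}
    neutral = max(cands, key=scores.get, default=None)
    if neutral is None or scores[neutral] <= 0.5:
        raise FloquetError("translation mode not found in the basis")
    unstable = []
    stable = []
    for j in range(18):
        if j == neutral:
            continue
        if mods[j] > 1.0 + tol:
            unstable.append(j)
        elif mods[j] < 1.0 - tol:
            stable.append(j)
        else:
            raise FloquetError(
                f"ambiguous split: column {j} has modulus {mods[j]:.6f} "
                f"within {tol} of 1 but is not the translation mode")
    return PhaseBasis(phi0=result.phi0, V=V, Vinv=Vinv,
                      unstable=tuple(unstable), stable=tuple(stable),
                      neutral=neutral, moduli=mods, cond=cond,
                      gains=result.gains)


def reference_error(x, ref: ReferenceGait, phase: float,
                    cycles: int = 0) -> np.ndarray:
    """Error state ``x - x_r`` at a phase, removing ``cycles`` stride
    advances from the horizontal position."""
    xt = np.asarray(x, dtype=float) - ref.state_at_phase(phase)
    xt[1] -= cycles * ref.stride
    return xt


def decompose_error(x, ref: ReferenceGait, basis: PhaseBasis,
                    phase: float | None = None, cycles: int = 0,
                    rtol: float = 1e-10) -> np.ndarray:
    """Coefficients ``c = V^-1 (x - x_r)`` of the error state in the basis.

    The reconstruction ``V c`` must agree with the error state to
    ``rtol`` (relative); a failure indicates an ill-conditioned basis.
    """
    phase = basis.phi0 if phase is None else phase
    xt = reference_error(x, ref, phase, cycles)
    c = basis.Vinv @ xt
    res = np.linalg.norm(basis.V @ c - xt)
    if res > rtol * max(np.linalg.norm(xt), 1e-300):
        raise FloquetError(
            f"decomposition residual {res:.2e} exceeds tolerance")
    return c


def projection_matrix(basis: PhaseBasis) -> np.ndarray:
    """Oblique projection onto the stable (+ neutral) subspace along the
    unstable one: ``Pi = V diag(keep) V^-1`` with unstable columns zeroed."""
    keep = np.ones(18)
    keep[list(basis.unstable)] = 0.0
    return (basis.V * keep) @ basis.Vinv


def project_to_stable(coeffs, basis: PhaseBasis, ref: ReferenceGait,
                      phase: float | None = None, cycles: int = 0):
    """Nominal state on the local stable manifold: zero the unstable
    coefficients and rebuild.  Returns ``(x_s, q_s, qd_s)``."""
    phase = basis.phi0 if phase is None else phase
    c = np.asarray(coeffs, dtype=float).copy()
    c[list(basis.unstable)] = 0.0
    x_s = ref.state_at_phase(phase) + basis.V @ c
    x_s[1] += cycles * ref.stride
    return x_s, x_s[:9], x_s[9:]


def stroboscopic_coefficients(strobo_states, basis: PhaseBasis,
                              ref: ReferenceGait) -> np.ndarray:
    """Per-cycle basis coefficients of stroboscopic error observations.

    ``strobo_states`` holds the state once per cycle at the basis phase
    (cycle index k along rows); the k-th row of the result is
    ``V^-1 (x(kT) - x_r)`` with the accumulated stride advance removed.
    """
    S = np.atleast_2d(np.asarray(strobo_states, dtype=float))
    out = np.empty((S.shape[0], 18))
    xr = ref.state_at_phase(basis.phi0)
    for k in range(S.shape[0]):
        xt = S[k] - xr
        xt[1] -= k * ref.stride
        out[k] = basis.Vinv @ xt
    return out


def poincare_map(x, ref: ReferenceGait, gains: GainSet,
                 phi0: float = 0.0) -> np.ndarray:
    """Image of a state on the section at ``phi0`` after one period of the
    controlled nonlinear flow, with the stride advance subtracted so that
    ``x_r(phi0)`` is a fixed point.  Raises if the walker falls."""
    bp = ref.body.to_array()
    cp = ref.contact.to_array()
    k0 = ref.index_of_phase(phi0)
    sched = np.zeros(ref.N, np.int8)
    Pi = np.zeros((18, 18))
    rec = np.zeros((1, 18))
    strobo = np.zeros((3, 18))
    xf, fall, _, _ = _k.run_full(
        np.asarray(x, dtype=float).copy(), ref.N, k0, ref.N, ref.dt, bp, cp,
        ref.X, ref.Uff, ref.stride, gains.p_diag(), gains.d_diag(),
        sched, Pi, Pi, gains.p_diag(), gains.d_diag(), 0,
        ref.fall_threshold(), 0, rec, strobo)
    if fall >= 0:
        raise FloquetError("fall during the Poincare return")
    out = xf.copy()
    out[1] -= ref.stride
    return out
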