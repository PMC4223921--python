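"""Floquet analysis of the reference limit cycle.

The gait dynamics form a T-periodically forced system; perturbations
``x~ = x - x_r(t)`` evolve by the variational equation ``x~' = DF(t) x~``
with the 18x18 Jacobian of the vector field along the cycle.  Integrating
the variational equation over one period from the identity yields the
monodromy matrix; its eigenvalues are the Floquet multipliers (FMs).  One
multiplier is exactly unity: the model is invariant under translation of
the horizontal HAT-CoM position (q2), so the q2 direction is neutrally
stable and is excluded from stability verdicts.

Because the reference is stored per Euler step and both the nonlinear and
the variational integration use the same forward-Euler rule, the monodromy
computed here is the exact derivative of the discrete period map, which a
brute-force finite-difference of the nonlinear flow must reproduce.

The Jacobian splits into an open-loop part (sampled once per reference,
cached) plus the feedback part ``-J(q_r)^-1 P~`` / ``-J(q_r)^-1 D~``,
making gain scans cheap; the total joint impedance along the cycle is
recovered from the same blocks as ``K_total = -J A21``, ``B_total = -J A22``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as _k
from .params import BodyParameters, ContactParams, GainSet
from .trajectory import ReferenceGait

__all__ = [
    "MonodromyResult",
    "TotalImpedance",
    "variational_blocks",
    "jacobian_at",
    "monodromy",
    "brute_force_monodromy",
    "real_jordan_basis",
    "classify_stability",
    "total_impedance",
    "scan_gains",
    "root_loci",
]

#: FD step scale for the open-loop Jacobian blocks.  Chosen small because
#: the quadratic contact law leaves little truncation bias while the
#: difference itself stays well above rounding noise.
FD_EPS = 3e-8

#: moduli within this distance of 1 are unity-mode candidates
UNITY_TOL = 1e-3


class FloquetError(RuntimeError):
    pass


def variational_blocks(ref: ReferenceGait, fd_eps: float = FD_EPS):
    """Open-loop Jacobian blocks (A21, A22) and inverse mass matrices along
    the reference, cached on the reference object."""
    key = ("blocks", fd_eps)
    if key not in ref._var_cache:
        if ref.Uff is None:
            raise FloquetError("reference carries no feed-forward torque")
        if ref.contact.horizontal_stiffness > 0:
            raise FloquetError(
                "Floquet analysis requires the anchor-free contact law "
                "(horizontal_stiffness = 0)")
        ref._var_cache[key] = _k.variational_precompute(
            ref.X, ref.Uff, ref.body.to_array(), ref.contact.to_array(),
            fd_eps)
    return ref._var_cache[key]


def jacobian_at(ref: ReferenceGait, gains: GainSet, phase: float,
                fd_eps: float = FD_EPS) -> np.ndarray:
    """18x18 Jacobian DF of the vector field at ``x_r(phase)``.

    The structural blocks (top-left zero, top-right identity) are exact;
    the lower blocks combine the cached open-loop finite differences with
    the analytic feedback contribution.
    """
    A21o, A22o, Jinv = variational_blocks(ref, fd_eps)
    k = ref.index_of_phase(phase)
    DF = np.zeros((18, 18))
    DF[:9, 9:] = np.eye(9)
    DF[9:, :9] = A21o[k] - Jinv[k] * gains.p_diag()
    DF[9:, 9:] = A22o[k] - Jinv[k] * gains.d_diag()
    return DF


def _eig_order(w: np.ndarray) -> list:
    """Descending modulus; ties by descending real part, then the member
    with nonnegative imaginary part first."""
    return sorted(range(len(w)),
                  key=lambda i: (-abs(w[i]), -w[i].real, w[i].imag < 0))


def real_jordan_basis(M: np.ndarray, tol: float = 1e-8):
    """Real basis V and block-diagonal Lam with M V = V Lam.

    Real eigenvalues give scalar diagonal entries; conjugate pairs give
    2x2 blocks [[a, b], [-b, a]] on the (Re v, Im v) column pair.  Column
    pairs keep a common scale (unit complex eigenvector) so the block form
    is exact; the sign is fixed by the largest-magnitude entry of Re v.
    Raises on defective matrices.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    w, V = np.linalg.eig(M)
    order = _eig_order(w)
    scale = max(np.abs(w).max(), 1.0)
    Vr = np.zeros((n, n))
    Lam = np.zeros((n, n))
    pairs = []
    used = np.zeros(n, dtype=bool)
    col = 0
    for i in order:
        if used[i]:
            continue
        lam = w[i]
        if abs(lam.imag) <= 1e-12 * scale:
            used[i] = True
            v = V[:, i].real.copy()
            v /= np.linalg.norm(v)
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            Vr[:, col] = v
            Lam[col, col] = lam.real
            pairs.append((col, i, None))
            col += 1
        else:
            # find the unused conjugate partner
            cands = [j for j in range(n)
                     if not used[j] and j != i
                     and abs(w[j] - lam.conjugate()) <= 1e-8 * scale]
            if not cands:
                raise FloquetError(
                    f"no conjugate partner for eigenvalue {lam}")
            j = min(cands, key=lambda j: abs(w[j] - lam.conjugate()))
            used[i] = True
            used[j] = True
            lam_pos = lam if lam.imag > 0 else w[j]
            v = V[:, i] if lam.imag > 0 else V[:, j]
            v = v / np.linalg.norm(v)
            vR = v.real.copy()
            vI = v.imag.copy()
            if vR[np.argmax(np.abs(vR))] < 0:
                vR, vI = -vR, -vI
            Vr[:, col] = vR
            Vr[:, col + 1] = vI
            a, b = lam_pos.real, lam_pos.imag
            Lam[col, col] = a
            Lam[col, col + 1] = b
            Lam[col + 1, col] = -b
            Lam[col + 1, col + 1] = a
            pairs.append((col, i, j))
            col += 2
    res = np.linalg.norm(M @ Vr - Vr @ Lam) / max(np.linalg.norm(M), 1.0)
    if res > tol:
        raise FloquetError(
            f"defective matrix: real-Jordan reconstruction residual {res:.2e}")
    return Vr, Lam


@dataclass
class MonodromyResult:
    """Monodromy matrix at a given initial phase with its eigenstructure.

    ``eigvals`` are sorted by descending modulus; ``V``/``Lam`` form the
    real Jordan factorization M V = V Lam whose column order matches
    ``eigvals`` (a conjugate pair occupies two adjacent columns).
    ``unity_index`` marks the translation (q2) mode.
    """

    phi0: float
    M: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    V: np.ndarray
    Lam: np.ndarray
    unity_index: int
    gains: GainSet
    dt: float

    @property
    def moduli(self) -> np.ndarray:
        return np.abs(self.eigvals)

    @property
    def max_nonunity_modulus(self) -> float:
        m = self.moduli.copy()
        m[self.unity_index] = -np.inf
        return float(m.max())

    @property
    def unity_modulus(self) -> float:
        return float(self.moduli[self.unity_index])


def _find_unity_mode(w, V, tol=UNITY_TOL):
    """Translation mode: eigenvalue near 1 whose eigenvector is dominated
    by the horizontal HAT-CoM position component (q2)."""
    cands = [i for i in range(len(w)) if abs(w[i] - 1.0) < tol]
    if not cands:
        raise FloquetError("no Floquet multiplier within tolerance of 1")
    scores = {i: abs(V[1, i]) / np.linalg.norm(V[:, i]) for i in cands}
    best = max(cands, key=scores.get)
    dominant = [i for i in cands if scores[i] > 0.5]
    if len(dominant) > 1:
        raise FloquetError(
            f"ambiguous unity mode: candidates {dominant} all have a "
            f"dominant q2 component")
    if scores[best] <= 0.5:
        raise FloquetError(
            f"unity-mode candidate {best} lacks a dominant q2 component "
            f"(score {scores[best]:.3f})")
    return best


def monodromy(ref: ReferenceGait, gains: GainSet, phi0: float = 0.0,
              fd_eps: float = FD_EPS) -> MonodromyResult:
    """Integrate the variational equation over one period from identity.

    The per-step flow Jacobians ``I + dt DF(t_k)`` are multiplied along
    the cycle starting at ``phi0``; the result is eigen-decomposed, the
    unity (translation) mode identified, and a real Jordan basis built.
    """
    A21o, A22o, Jinv = variational_blocks(ref, fd_eps)
    k0 = ref.index_of_phase(phi0)
    M = _k.monodromy_propagate(A21o, A22o, Jinv, gains.p_diag(),
                               gains.d_diag(), k0, ref.dt)
    if not np.all(np.isfinite(M)):
        raise FloquetError("variational integration blew up")
    w, Vc = np.linalg.eig(M)
    order = _eig_order(w)
    w = w[order]
    Vc = Vc[:, order]
    Vr, Lam = real_jordan_basis(M)
    unity = _find_unity_mode(w, Vc)
    return MonodromyResult(phi0=phi0, M=M, eigvals=w, eigvecs=Vc, V=Vr,
                           Lam=Lam, unity_index=unity, gains=gains,
                           dt=ref.dt)


def brute_force_monodromy(ref: ReferenceGait, gains: GainSet,
                          phi0: float = 0.0, eps: float = 1e-6) -> np.ndarray:
    """Independent oracle: column-wise central differences of the nonlinear
    period map around ``x_r(phi0)``."""
    bp = ref.body.to_array()
    cp = ref.contact.to_array()
    k0 = ref.index_of_phase(phi0)
    N = ref.N
    Pd, Dd = gains.p_diag(), gains.d_diag()
    sched = np.zeros(N, np.int8)
    Pi = np.zeros((18, 18))
    rec = np.zeros((1, 18))
    strobo = np.zeros((3, 18))
    M = np.zeros((18, 18))
    for j in range(18):
        shots = []
        h = eps * max(1.0, abs(ref.X[k0, j]))
        for sgn in (1.0, -1.0):
            x0 = ref.X[k0].copy()
            x0[j] += sgn * h
            xf, fall, _, _ = _k.run_full(
                x0, N, k0, N, ref.dt, bp, cp, ref.X, ref.Uff, ref.stride,
                Pd, Dd, sched, Pi, Pi, Pd, Dd, 0,
                ref.fall_threshold(), 0, rec, strobo)
            if fall >= 0:
                raise FloquetError(f"fall during perturbed column {j}")
            shots.append(xf)
        M[:, j] = (shots[0] - shots[1]) / (2.0 * h)
    return M


def classify_stability(result: MonodromyResult,
                       tol_margin: float = 1e-3):
    """Verdict on the limit cycle ignoring the unity translation mode.

    Returns ``(verdict, max_nonunity_modulus)`` with verdict ``"stable"``
    iff every non-unity modulus is below ``1 - tol_margin``; moduli inside
    the margin (other than the identified unity mode) are ambiguous.
    """
    m = result.moduli.copy()
    m[result.unity_index] = -np.inf
    mx = float(m.max())
    if mx >= 1.0 - tol_margin and mx <= 1.0 + tol_margin:
        raise FloquetError(
            f"ambiguous verdict: non-unity modulus {mx:.6f} within "
            f"{tol_margin} of 1")
    return ("stable" if mx < 1.0 else "unstable"), mx


@dataclass
class TotalImpedance:
    """Effective joint stiffness/viscosity along the cycle.

    ``K_total[k] = -J(q_r) A21(t_k)``, ``B_total[k] = -J(q_r) A22(t_k)``
    with the Jacobian blocks of the closed-loop vector field, so the PD
    feedback enters exactly as its gain matrices while the inertial,
    gravitational and contact terms contribute the configuration-dependent
    remainder.
    """

    phases: np.ndarray
    K_total: np.ndarray  # (m, 9, 9)
    B_total: np.ndarray  # (m, 9, 9)
    gains: GainSet


def total_impedance(ref: ReferenceGait, gains: GainSet,
                    stride: int = 100) -> TotalImpedance:
    A21o, A22o, Jinv = variational_blocks(ref)
    ks = np.arange(0, ref.N, stride)
    Kt = np.empty((len(ks), 9, 9))
    Bt = np.empty((len(ks), 9, 9))
    Pd, Dd = gains.p_diag(), gains.d_diag()
    for m, k in enumerate(ks):
        J = np.linalg.inv(Jinv[k])
        Kt[m] = -J @ A21o[k] + np.diag(Pd)
        Bt[m] = -J @ A22o[k] + np.diag(Dd)
    return TotalImpedance(phases=ks / ref.N, K_total=Kt, B_total=Bt,
                          gains=gains)


def scan_gains(ref: ReferenceGait, Pa_values, Pk_values, Ph_values,
               base: GainSet | None = None, phi0: float = 0.0) -> pd.DataFrame:
    """Max non-unity Floquet modulus over a (Pa, Pk, Ph) grid, D fixed.

    Failures at individual grid points are recorded in the ``error``
    column and the scan continues.
    """
    base = base or GainSet()
    rows = []
    for Pa in Pa_values:
        for Pk in Pk_values:
            for Ph in Ph_values:
                g = base.replace(Pa=float(Pa), Pk=float(Pk), Ph=float(Ph))
                row = {"Pa": Pa, "Pk": Pk, "Ph": Ph,
                       "max_fm": np.nan, "stable": False,
                       "n_unstable": -1, "error": ""}
                try:
                    res = monodromy(ref, g, phi0)
                    verdict, mx = classify_stability(res)
                    row["max_fm"] = mx
                    row["stable"] = verdict == "stable"
                    m = res.moduli.copy()
                    m[res.unity_index] = 0.0
                    row["n_unstable"] = int((m > 1.0).sum())
                except FloquetError as exc:
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RootLoci:
    """Floquet-multiplier loci along a path through gain space."""

    p_values: np.ndarray
    loci: np.ndarray        # (n_p, 18) complex, matched across steps
    unity_locus: np.ndarray  # (n_p,) complex
    gains: list = field(default_factory=list)
    pairing_breaks: list = field(default_factory=list)


def intermittent_monodromy(ref: ReferenceGait, gains: GainSet,
                           igains, schedule) -> np.ndarray:
    """Monodromy of the intermittently controlled (switched) linear
    system: the one-period Jacobian product including the on-period
    feedback towards the SMC or LCC target.

    Predicts the local stability of the gait under the intermittent
    controller without nonlinear simulation; eigenvalues of the result
    below unit modulus (except the translation mode) mean the windows
    stabilize the cycle.
    """
    from .control import schedule_array
    from .manifold import phase_basis, projection_matrix

    A21o, A22o, Jinv = variational_blocks(ref)
    Pp9 = igains.p_diag()
    Dp9 = igains.d_diag()
    eye = np.eye(18)
    if schedule.mode == "smc":
        GA = eye - projection_matrix(phase_basis(
            monodromy(ref, gains, schedule.phi_on)))
        GB = eye - projection_matrix(phase_basis(
            monodromy(ref, gains, (schedule.phi_on + 0.5) % 1.0)))
    elif schedule.mode == "lcc":
        GA = GB = eye
    else:
        raise ValueError("schedule.mode must be 'smc' or 'lcc'")
    TA = (Pp9[:, None] * GA[:9, :]) + (Dp9[:, None] * GA[9:, :])
    TB = (Pp9[:, None] * GB[:9, :]) + (Dp9[:, None] * GB[9:, :])
    sarr = schedule_array(schedule, ref.N, ref.T)
    return _k.switched_monodromy_propagate(
        A21o, A22o, Jinv, gains.p_diag(), gains.d_diag(), TA, TB, sarr,
        ref.index_of_phase(schedule.phi_on), ref.dt)


def root_loci(ref: ReferenceGait, p_values,
              base=(2400.0, 2400.0, 2400.0),
              direction=(1.0, 1.0, 1.0),
              gains_base: GainSet | None = None,
              phi0: float = 0.0) -> RootLoci:
    """Track the FMs while the P-gains decrease along
    ``(Pa, Pk, Ph) = base - p * direction``.

    Consecutive spectra are matched by greedy nearest-neighbour pairing in
    the complex plane (most-unstable first); ambiguous collisions are
    recorded and the pairing restarts there.  The unity mode is tracked
    separately.
    """
    gains_base = gains_base or GainSet()
    p_values = np.asarray(p_values, dtype=float)
    loci = np.zeros((len(p_values), 18), dtype=complex)
    unity = np.zeros(len(p_values), dtype=complex)
    breaks = []
    gains_list = []
    prev = None
    for m, p in enumerate(p_values):
        Pa, Pk, Ph = (base[0] - p * direction[0],
                      base[1] - p * direction[1],
                      base[2] - p * direction[2])
        g = gains_base.replace(Pa=max(Pa, 0.0), Pk=max(Pk, 0.0),
                               Ph=max(Ph, 0.0))
        gains_list.append(g)
        res = monodromy(ref, g, phi0)
        w = res.eigvals
        unity[m] = w[res.unity_index]
        if prev is None:
            loci[m] = w
        else:
            cur = list(range(18))
            matched = np.zeros(18, dtype=complex)
            ok = True
            for slot in np.argsort(-np.abs(prev)):
                j = min(cur, key=lambda j: abs(w[j] - prev[slot]))
                if abs(w[j] - prev[slot]) > 0.5 * (1.0 + abs(prev[slot])):
                    ok = False
                matched[slot] = w[j]
                cur.remove(j)
            if not ok:
                breaks.append(m)
                loci[m] = w
            else:
                loci[m] = matched
        prev = loci[m]
    return RootLoci(p_values=p_values, loci=loci, unity_locus=unity,
                    gains=gains_list, pairing_breaks=breaks)
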